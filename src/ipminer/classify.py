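"""Random-forest base predictors and the logistic-regression stacked ensemble.

Three level-0 random forests are trained on three feature spaces of the same
labeled pairs: the raw 599-dim k-mer composition ("raw", the RPISeq-RF
predictor), the autoencoder features before fine-tuning ("sda", SDA-RF) and
after fine-tuning ("sda_ft", SDA-FT-RF).  A level-1 logistic regression
combines their predicted probabilities:

    P(y=1 | p) = 1 / (1 + exp(-(w . p + bias)))

The level-1 model is fitted Wolpert-style on out-of-fold level-0
predictions from an internal stratified K-fold, after which the base
forests are refit on all training data.  With equal weights and zero bias
the combiner reduces to probability averaging.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .features import N_PROTEIN_FEATURES, N_PAIR_FEATURES, build_raw_pair_matrix
from .sda import (
    StackedDenoisingAutoencoder,
    extract_pair_features,
    fine_tune,
    load_sda,
    save_sda,
)

__all__ = [
    "FEATURE_SPACES",
    "train_base",
    "combine",
    "fit_stack",
    "IPMinerClassifier",
    "train_ipminer",
    "predict_pairs",
    "save_model",
    "load_model",
]

FEATURE_SPACES = ("raw", "sda", "sda_ft")

SEP_ARCHITECTURE = (256, 128, 64)
CON_ARCHITECTURE = (256, 128, 128)


def _check_two_classes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int).ravel()
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be 0 or 1")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes")
    return y


def train_base(
    features: np.ndarray, labels: np.ndarray, n_trees: int = 100,
    seed: int | None = None,
) -> RandomForestClassifier:
    """Fit one level-0 random forest; probability = tree-vote fraction."""
    y = _check_two_classes(labels)
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(np.asarray(features, dtype=float), y)
    return forest


def combine(w: np.ndarray, bias: float, p: np.ndarray) -> np.ndarray:
    """Level-1 logistic combiner: sigmoid(w . p + bias).

    ``p`` is one 3-vector of base probabilities or an (n, 3) matrix.
    """
    p = np.asarray(p, dtype=float)
    z = p @ np.asarray(w, dtype=float) + bias
    return 1.0 / (1.0 + np.exp(-z))


def fit_stack(level0_probs: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Maximum-likelihood logistic regression on level-0 probabilities.

    Returns the weight vector (one entry per base classifier) and intercept.
    """
    y = _check_two_classes(labels)
    # unpenalized maximum-likelihood fit
    lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
    lr.fit(np.asarray(level0_probs, dtype=float), y)
    return lr.coef_.ravel().copy(), float(lr.intercept_[0])


class IPMinerClassifier(BaseEstimator, ClassifierMixin):
    """End-to-end interaction-pattern classifier for RNA-protein pairs.

    Input samples are raw 599-dim pair vectors (protein conjoint-triad 343
    columns, then RNA 4-mer 256 columns).  ``fit`` runs the full pipeline:

    1. greedy layer-wise pretraining of the autoencoder sub-network(s),
    2. supervised fine-tuning through a merged sigmoid head,
    3. construction of the raw / SDA / SDA-FT feature sets,
    4. three random-forest base classifiers,
    5. a logistic-regression stacking layer fitted on out-of-fold base
       predictions (internal stratified K-fold), then base refits on all data.

    Parameters
    ----------
    mode : {"sep", "con"}, default "sep"
        "sep" trains two separate sub-networks (protein 343 -> 256-128-64,
        RNA 256 -> 256-128-64) whose top layers are concatenated; "con"
        routes the concatenated 599-dim input through a single 256-128-128
        stack.  "sep" is the default as it keeps protein and RNA neurons
        from mixing before the top layer.
    architecture : sequence of int or None
        Overrides the mode's hidden sizes.
    noise_prob : float, default 0.5
        Masking-noise probability during pretraining.
    pretrain_epochs, finetune_epochs, batch_size : int, default 100
    pretrain_lr, finetune_lr, momentum : float
        Adam rate for pretraining; SGD rate and momentum for fine-tuning.
    n_trees : int, default 100
        Trees per base forest.
    stack_folds : int, default 5
        Internal folds for leakage-safe level-1 training.
    random_state : int or None
        Single seed from which all component seeds are derived.
    """

    def __init__(
        self,
        mode: str = "sep",
        architecture=None,
        noise_prob: float = 0.5,
        pretrain_epochs: int = 100,
        finetune_epochs: int = 100,
        batch_size: int = 100,
        pretrain_lr: float = 1e-3,
        finetune_lr: float = 0.01,
        momentum: float = 0.9,
        n_trees: int = 100,
        stack_folds: int = 5,
        random_state: int | None = None,
    ):
        self.mode = mode
        self.architecture = architecture
        self.noise_prob = noise_prob
        self.pretrain_epochs = pretrain_epochs
        self.finetune_epochs = finetune_epochs
        self.batch_size = batch_size
        self.pretrain_lr = pretrain_lr
        self.finetune_lr = finetune_lr
        self.momentum = momentum
        self.n_trees = n_trees
        self.stack_folds = stack_folds
        self.random_state = random_state

    # -- internal helpers -------------------------------------------------
    def _split(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return X[:, :N_PROTEIN_FEATURES], X[:, N_PROTEIN_FEATURES:]

    def _seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.random_state)
        children = ss.spawn(6)
        names = ["sda_p", "sda_r", "finetune", "rf", "stack_cv", "spare"]
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, children)
        }

    def _make_sda(self, arch, seed) -> StackedDenoisingAutoencoder:
        return StackedDenoisingAutoencoder(
            architecture=arch,
            noise_prob=self.noise_prob,
            epochs=self.pretrain_epochs,
            batch_size=self.batch_size,
            learning_rate=self.pretrain_lr,
            random_state=seed,
        )

    def _feature_sets(self, X: np.ndarray) -> dict[str, np.ndarray]:
        if self.mode == "sep":
            Xp, Xr = self._split(X)
            return {
                "raw": X,
                "sda": extract_pair_features(self.protein_sda_, self.rna_sda_, Xp, Xr),
                "sda_ft": extract_pair_features(
                    self.protein_sda_ft_, self.rna_sda_ft_, Xp, Xr
                ),
            }
        return {
            "raw": X,
            "sda": self.sda_.transform(X),
            "sda_ft": self.sda_ft_.transform(X),
        }

    # -- sklearn API ------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "IPMinerClassifier":
        X = np.asarray(X, dtype=float)
        y = _check_two_classes(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must be row-aligned")
        if self.mode not in ("sep", "con"):
            raise ValueError(f"unknown mode {self.mode!r}")
        seeds = self._seeds()

        if self.mode == "sep":
            arch = tuple(self.architecture) if self.architecture else SEP_ARCHITECTURE
            Xp, Xr = self._split(X)
            self.protein_sda_ = self._make_sda(arch, seeds["sda_p"]).fit(Xp)
            self.rna_sda_ = self._make_sda(arch, seeds["sda_r"]).fit(Xr)
            self.protein_sda_ft_, self.rna_sda_ft_, self.head_ = fine_tune(
                self.protein_sda_, self.rna_sda_, Xp, Xr, y,
                epochs=self.finetune_epochs, batch_size=self.batch_size,
                learning_rate=self.finetune_lr, momentum=self.momentum,
                seed=seeds["finetune"],
            )
        else:
            arch = tuple(self.architecture) if self.architecture else CON_ARCHITECTURE
            self.sda_ = self._make_sda(arch, seeds["sda_p"]).fit(X)
            self.sda_ft_, self.head_ = _fine_tune_single(
                self.sda_, X, y,
                epochs=self.finetune_epochs, batch_size=self.batch_size,
                learning_rate=self.finetune_lr, momentum=self.momentum,
                seed=seeds["finetune"],
            )

        feats = self._feature_sets(X)

        # leakage-safe level-0 predictions: each sample is scored by forests
        # that never saw it
        skf = StratifiedKFold(
            n_splits=self.stack_folds, shuffle=True, random_state=seeds["stack_cv"]
        )
        n = X.shape[0]
        oof = np.zeros((n, len(FEATURE_SPACES)))
        fold_ids = np.full(n, -1, dtype=int)
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            fold_ids[te] = fold
            for j, space in enumerate(FEATURE_SPACES):
                forest = train_base(
                    feats[space][tr], y[tr], n_trees=self.n_trees,
                    seed=seeds["rf"] + fold,
                )
                oof[te, j] = forest.predict_proba(feats[space][te])[:, 1]
        self.oof_probs_ = oof
        self.oof_fold_ids_ = fold_ids

        self.stack_w_, self.stack_bias_ = fit_stack(oof, y)

        # refit bases on all training data for deployment
        self.base_classifiers_ = {
            space: train_base(feats[space], y, n_trees=self.n_trees, seed=seeds["rf"])
            for space in FEATURE_SPACES
        }
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def base_probabilities(self, X: np.ndarray) -> np.ndarray:
        """Level-0 probabilities, columns ordered raw / sda / sda_ft."""
        check_is_fitted(self, "base_classifiers_")
        X = np.asarray(X, dtype=float)
        feats = self._feature_sets(X)
        cols = [
            self.base_classifiers_[s].predict_proba(feats[s])[:, 1]
            for s in FEATURE_SPACES
        ]
        return np.column_stack(cols) if X.shape[0] else np.zeros((0, 3))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p1 = combine(self.stack_w_, self.stack_bias_, self.base_probabilities(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        # ties at exactly 0.5 are called positive
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _fine_tune_single(
    model: StackedDenoisingAutoencoder,
    X: np.ndarray,
    y: np.ndarray,
    **kwargs,
):
    """Fine-tune one stack ("con" mode) by pairing it with a width-0 partner."""
    pm, _, head = fine_tune(
        model, _ZeroWidthSDA(), X, np.zeros((X.shape[0], 0)), y, **kwargs
    )
    return pm, head


class _ZeroWidthSDA(StackedDenoisingAutoencoder):
    """Degenerate partner sub-network contributing no features."""

    def __init__(self):
        super().__init__(architecture=())
        self.layers_ = []
        self.n_features_in_ = 0

    @property
    def output_dim_(self) -> int:
        return 0

    def transform(self, X):
        return np.zeros((np.asarray(X).shape[0], 0))


def train_ipminer(pairs, protein_seqs, rna_seqs, config=None) -> IPMinerClassifier:
    """Train the full pipeline from (protein_id, rna_id, label) pairs.

    ``config`` maps IPMinerClassifier parameter names to values.
    """
    X = build_raw_pair_matrix(pairs, protein_seqs, rna_seqs)
    y = np.array([p[2] for p in pairs], dtype=int)
    model = IPMinerClassifier(**(config or {}))
    return model.fit(X, y)


def predict_pairs(
    model: IPMinerClassifier, pairs, protein_seqs, rna_seqs
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and binary calls for pairs, in input order."""
    if len(pairs) == 0:
        return np.zeros(0), np.zeros(0, dtype=int)
    X = build_raw_pair_matrix(pairs, protein_seqs, rna_seqs)
    probs = model.predict_proba(X)[:, 1]
    return probs, (probs >= 0.5).astype(int)


# -- model directory serialization ----------------------------------------

MODEL_SCHEMA_VERSION = 1


def save_model(model: IPMinerClassifier, directory: str | Path) -> None:
    """Write a fitted model to a versioned directory (json + npz + joblib)."""
    check_is_fitted(model, "base_classifiers_")
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in model.get_params().items()},
        "stack_w": [float(x) for x in model.stack_w_],
        "stack_bias": model.stack_bias_,
        "mode": model.mode,
        "n_features_in": int(model.n_features_in_),
    }
    (d / "model.json").write_text(json.dumps(meta, indent=2))
    if model.mode == "sep":
        save_sda(model.protein_sda_, d / "sda_protein.npz")
        save_sda(model.rna_sda_, d / "sda_rna.npz")
        save_sda(model.protein_sda_ft_, d / "sda_protein_ft.npz", head=model.head_)
        save_sda(model.rna_sda_ft_, d / "sda_rna_ft.npz")
    else:
        save_sda(model.sda_, d / "sda_con.npz")
        save_sda(model.sda_ft_, d / "sda_con_ft.npz", head=model.head_)
    for space, forest in model.base_classifiers_.items():
        joblib.dump(forest, d / f"forest_{space}.joblib")


def load_model(directory: str | Path) -> IPMinerClassifier:
    d = Path(directory)
    meta = json.loads((d / "model.json").read_text())
    if meta["schema_version"] != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema {meta['schema_version']}")
    params = dict(meta["params"])
    if params.get("architecture") is not None:
        params["architecture"] = tuple(params["architecture"])
    model = IPMinerClassifier(**params)
    if meta["mode"] == "sep":
        model.protein_sda_, _ = load_sda(d / "sda_protein.npz")
        model.rna_sda_, _ = load_sda(d / "sda_rna.npz")
        model.protein_sda_ft_, model.head_ = load_sda(d / "sda_protein_ft.npz")
        model.rna_sda_ft_, _ = load_sda(d / "sda_rna_ft.npz")
    else:
        model.sda_, _ = load_sda(d / "sda_con.npz")
        model.sda_ft_, model.head_ = load_sda(d / "sda_con_ft.npz")
    model.stack_w_ = np.asarray(meta["stack_w"], dtype=float)
    model.stack_bias_ = float(meta["stack_bias"])
    model.base_classifiers_ = {
        space: joblib.load(d / f"forest_{space}.joblib") for space in FEATURE_SPACES
    }
    model.classes_ = np.array([0, 1])
    model.n_features_in_ = meta["n_features_in"]
    return model
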