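"""Composition features for protein and RNA sequences.

Proteins are encoded as conjoint-triad frequencies: the 20 standard amino
acids are collapsed into 7 groups (by dipole moment and side-chain volume)
and every overlapping 3-mer over the reduced alphabet is counted, giving a
7**3 = 343-dimensional vector.  RNA sequences are encoded as overlapping
4-mer frequencies over A/C/G/U, giving 4**4 = 256 dimensions.  Both vectors
are normalized by the number of valid windows, so each is a probability
vector over windowed composition whenever at least one valid window exists.

A raw pair representation is the 343 + 256 = 599-dimensional concatenation
of the two.
"""

from __future__ import annotations

import warnings
from itertools import product
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "AMINO_ACID_GROUPS",
    "SENTINEL",
    "N_PROTEIN_FEATURES",
    "N_RNA_FEATURES",
    "N_PAIR_FEATURES",
    "reduce_protein_sequence",
    "protein_conjoint_triad",
    "rna_kmer_frequency",
    "protein_feature_names",
    "rna_feature_names",
    "build_raw_pair_matrix",
    "ConjointTriadEncoder",
    "RNAKmerEncoder",
]

#: 7-group reduced amino-acid alphabet: (Ala,Gly,Val) (Ile,Leu,Phe,Pro)
#: (Tyr,Met,Thr,Ser) (His,Asn,Gln,Trp) (Arg,Lys) (Asp,Glu) (Cys).
AMINO_ACID_GROUPS: Mapping[str, int] = {
    "A": 1, "G": 1, "V": 1,
    "I": 2, "L": 2, "F": 2, "P": 2,
    "Y": 3, "M": 3, "T": 3, "S": 3,
    "H": 4, "N": 4, "Q": 4, "W": 4,
    "R": 5, "K": 5,
    "D": 6, "E": 6,
    "C": 7,
}

#: Placeholder for non-standard residues/nucleotides; windows containing it
#: are excluded from counting rather than raising.
SENTINEL = "?"

N_GROUPS = 7
N_PROTEIN_FEATURES = N_GROUPS ** 3          # 343
RNA_ALPHABET = "ACGU"                        # index order A<C<G<U
N_RNA_FEATURES = len(RNA_ALPHABET) ** 4      # 256
N_PAIR_FEATURES = N_PROTEIN_FEATURES + N_RNA_FEATURES  # 599


def reduce_protein_sequence(seq: str) -> str:
    """Map an amino-acid sequence onto the 7-letter reduced alphabet.

    Standard residues become their group digit "1".."7"; anything else
    (X, B, Z, U, O, ``*`` ...) becomes the sentinel ``?``.

    Raises
    ------
    ValueError
        If ``seq`` is empty.
    """
    if not seq:
        raise ValueError("empty sequence")
    return "".join(
        str(AMINO_ACID_GROUPS.get(ch, SENTINEL)) for ch in seq.upper()
    )


def _count_windows(digits: Sequence[int | None], k: int, base: int) -> np.ndarray:
    """Count overlapping k-mers of base-`base` digits; None marks invalid."""
    counts = np.zeros(base ** k, dtype=float)
    n_valid = 0
    for i in range(len(digits) - k + 1):
        window = digits[i : i + k]
        if any(d is None for d in window):
            continue
        idx = 0
        for d in window:
            idx = idx * base + d  # type: ignore[operator]
        counts[idx] += 1.0
        n_valid += 1
    if n_valid > 0:
        counts /= n_valid
    return counts


def protein_conjoint_triad(seq: str) -> np.ndarray:
    """Conjoint-triad frequency vector (length 343) of a protein sequence.

    The flat index of triad (g1, g2, g3), groups in 1..7, is
    ``(g1-1)*49 + (g2-1)*7 + (g3-1)``.  Windows containing a non-standard
    residue are skipped; the remaining counts are divided by the number of
    valid windows.  If no window is valid, an all-zero vector is returned
    with a warning.
    """
    reduced = reduce_protein_sequence(seq)
    if len(reduced) < 3:
        raise ValueError("sequence too short for 3-mer")
    digits = [None if ch == SENTINEL else int(ch) - 1 for ch in reduced]
    vec = _count_windows(digits, 3, N_GROUPS)
    if vec.sum() == 0.0:
        warnings.warn("no valid 3-mer windows; returning all-zero vector")
    return vec


def rna_kmer_frequency(seq: str, k: int = 4) -> np.ndarray:
    """Overlapping k-mer frequency vector of an RNA sequence (default 4-mers).

    T is treated as U.  The flat index of a k-mer is its base-4 expansion
    with A=0, C=1, G=2, U=3 (so "AAAA" is 0 and "UUUU" is 255).  Windows
    containing any other letter (e.g. N) are skipped.
    """
    if len(seq) < k:
        raise ValueError(f"sequence too short for {k}-mer")
    lookup = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
    digits = [lookup.get(ch) for ch in seq.upper()]
    vec = _count_windows(digits, k, 4)
    if vec.sum() == 0.0:
        warnings.warn(f"no valid {k}-mer windows; returning all-zero vector")
    return vec


def protein_feature_names() -> list[str]:
    """Column names '111'..'777' in flat-index order."""
    return ["".join(str(g) for g in t) for t in product(range(1, 8), repeat=3)]


def rna_feature_names(k: int = 4) -> list[str]:
    """Column names 'AAAA'..'UUUU' in flat-index order."""
    return ["".join(t) for t in product(RNA_ALPHABET, repeat=k)]


class ConjointTriadEncoder(BaseEstimator, TransformerMixin):
    """Transformer: list of protein sequences -> (n, 343) conjoint-triad matrix.

    Stateless; ``fit`` only validates input.
    """

    def fit(self, X: Sequence[str], y=None) -> "ConjointTriadEncoder":
        self.n_features_out_ = N_PROTEIN_FEATURES
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        if len(X) == 0:
            return np.zeros((0, N_PROTEIN_FEATURES))
        return np.vstack([protein_conjoint_triad(s) for s in X])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(protein_feature_names(), dtype=object)


class RNAKmerEncoder(BaseEstimator, TransformerMixin):
    """Transformer: list of RNA sequences -> (n, 4**k) k-mer frequency matrix."""

    def __init__(self, k: int = 4):
        self.k = k

    def fit(self, X: Sequence[str], y=None) -> "RNAKmerEncoder":
        self.n_features_out_ = 4 ** self.k
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        if len(X) == 0:
            return np.zeros((0, 4 ** self.k))
        return np.vstack([rna_kmer_frequency(s, self.k) for s in X])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(rna_feature_names(self.k), dtype=object)


def build_raw_pair_matrix(
    pairs: Sequence[tuple],
    protein_seqs: Mapping[str, str],
    rna_seqs: Mapping[str, str],
) -> np.ndarray:
    """Raw 599-dim feature matrix for (protein_id, rna_id[, label]) pairs.

    Row i is the concatenation of the protein conjoint-triad vector and the
    RNA 4-mer vector of pair i; row order follows the input order.

    Raises
    ------
    KeyError
        Naming the offending id when a pair references an unknown sequence.
    """
    rows = []
    prot_cache: dict[str, np.ndarray] = {}
    rna_cache: dict[str, np.ndarray] = {}
    for pair in pairs:
        pid, rid = pair[0], pair[1]
        if pid not in protein_seqs:
            raise KeyError(f"unknown protein id: {pid!r}")
        if rid not in rna_seqs:
            raise KeyError(f"unknown RNA id: {rid!r}")
        if pid not in prot_cache:
            prot_cache[pid] = protein_conjoint_triad(protein_seqs[pid])
        if rid not in rna_cache:
            rna_cache[rid] = rna_kmer_frequency(rna_seqs[rid])
        rows.append(np.concatenate([prot_cache[pid], rna_cache[rid]]))
    if not rows:
        return np.zeros((0, N_PAIR_FEATURES))
    return np.vstack(rows)
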