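"""Labeled pair construction from macromolecular structures.

A protein chain and an RNA chain in the same complex are labeled
*interactive* when their least atom distance — the minimum Euclidean
distance over all protein-atom x RNA-atom pairs — is strictly below a
cutoff (default 5 angstrom); otherwise *non-interactive*.  Sequences are
taken from the SEQRES records (the full deposited chain sequence), never
from the subset of residues that happen to have coordinates, because the
downstream predictor is sequence-based.

Negative pairs for training sets are generated by uniform random pairing
of proteins with RNAs, excluding known positives.

Redundancy reduction by sequence identity is out of scope; callers may pass
an externally produced keep-list of chain ids to ``filter_pairs``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "ChainRecord",
    "LabeledPair",
    "parse_structure",
    "least_atom_distance",
    "label_pairs",
    "generate_negatives",
    "filter_pairs",
    "build_dataset",
]

RNA_RESIDUES = {"A", "C", "G", "U", "I"}
AA3 = {k.upper() for k in protein_letters_3to1}
RNA_1TO1 = {"A": "A", "C": "C", "G": "G", "U": "U", "I": "G", "T": "U", "N": "N"}


@dataclass
class ChainRecord:
    """One chain of a complex: identity, kind, full sequence, coordinates.

    ``atoms`` holds the coordinates actually present in the structure and
    may cover only a subset of ``sequence`` (unresolved residues have no
    atoms).
    """

    complex_id: str
    chain_id: str
    molecule_kind: str  # "protein" | "rna"
    sequence: str       # full SEQRES-derived sequence
    atoms: np.ndarray   # (n_atoms, 3) in angstrom

    @property
    def full_id(self) -> str:
        return f"{self.complex_id}_{self.chain_id}"


@dataclass(frozen=True)
class LabeledPair:
    protein_id: str
    rna_id: str
    label: int
    min_distance: float


def _chain_kind(resnames: list[str]) -> str | None:
    """Type a chain by its residue vocabulary; None for hybrid/unknown."""
    names = {r.strip().upper() for r in resnames}
    if names and names <= RNA_RESIDUES:
        return "rna"
    if names and names <= AA3:
        return "protein"
    # tolerate a few modified residues as long as one vocabulary dominates
    n_rna = sum(1 for r in resnames if r.strip().upper() in RNA_RESIDUES)
    n_prot = sum(1 for r in resnames if r.strip().upper() in AA3)
    if n_rna >= 0.8 * len(resnames) and n_rna > n_prot:
        return "rna"
    if n_prot >= 0.8 * len(resnames) and n_prot > n_rna:
        return "protein"
    return None


def _seqres_sequences(path: Path) -> dict[str, str]:
    """Chain id -> full sequence from SEQRES records (empty if absent)."""
    seqs: dict[str, str] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with open(path) as fh:
            for rec in SeqIO.parse(fh, "pdb-seqres"):
                chain = rec.annotations.get("chain", rec.id.split(":")[-1])
                seqs[chain] = str(rec.seq).upper()
    return seqs


def parse_structure(
    path: str | Path, include_hetatm: bool = False
) -> list[ChainRecord]:
    """Parse a PDB file into typed chain records.

    Only the first model is used.  HETATM records are excluded from the
    coordinate sets by default.  Chains whose residue vocabulary is neither
    protein nor RNA are skipped with a warning.
    """
    path = Path(path)
    complex_id = path.stem
    seqres = _seqres_sequences(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = next(parser.get_structure(complex_id, str(path)).get_models())
    records = []
    for chain in model:
        resnames = []
        coords = []
        for residue in chain:
            hetflag = residue.id[0]
            if hetflag != " " and not include_hetatm:
                continue
            if hetflag == "W":  # waters never count
                continue
            resnames.append(residue.resname)
            for atom in residue:
                coords.append(atom.coord)
        if not resnames:
            continue
        kind = _chain_kind(resnames)
        if kind is None:
            logger.warning(
                "skipping chain %s:%s with mixed/unknown residue vocabulary",
                complex_id, chain.id,
            )
            continue
        sequence = seqres.get(chain.id, "")
        if not sequence:
            # fall back to the coordinate-derived sequence
            if kind == "protein":
                sequence = "".join(
                    protein_letters_3to1.get(r.strip().upper().capitalize(),
                                             protein_letters_3to1.get(r.strip().upper(), "X"))
                    for r in resnames
                )
            else:
                sequence = "".join(RNA_1TO1.get(r.strip().upper(), "N") for r in resnames)
        records.append(
            ChainRecord(
                complex_id=complex_id,
                chain_id=chain.id,
                molecule_kind=kind,
                sequence=sequence,
                atoms=np.asarray(coords, dtype=float).reshape(-1, 3),
            )
        )
    return records


def least_atom_distance(a: ChainRecord, b: ChainRecord) -> float:
    """Minimum Euclidean distance over all atom pairs of two chains."""
    if a.atoms.shape[0] == 0 or b.atoms.shape[0] == 0:
        raise ValueError("no coordinates")
    return float(cdist(a.atoms, b.atoms).min())


def label_pairs(chains: list[ChainRecord], cutoff: float = 5.0) -> list[LabeledPair]:
    """Label every protein x RNA chain pair within each complex.

    Interactive means least atom distance strictly less than ``cutoff``;
    a pair at exactly the cutoff is non-interactive.
    """
    by_complex: dict[str, list[ChainRecord]] = {}
    for c in chains:
        by_complex.setdefault(c.complex_id, []).append(c)
    out = []
    for members in by_complex.values():
        proteins = [c for c in members if c.molecule_kind == "protein"]
        rnas = [c for c in members if c.molecule_kind == "rna"]
        for p in proteins:
            for r in rnas:
                d = least_atom_distance(p, r)
                out.append(
                    LabeledPair(
                        protein_id=p.full_id, rna_id=r.full_id,
                        label=int(d < cutoff), min_distance=d,
                    )
                )
    return out


def generate_negatives(
    positives, protein_ids, rna_ids, n: int | None = None,
    seed: int | None = None,
) -> list[tuple[str, str, int]]:
    """Random non-positive pairs: uniform without replacement.

    ``n`` defaults to the number of positives (balanced dataset).  Raises
    when the complement of the positive set is too small.
    """
    positive_set = {(p[0], p[1]) for p in positives}
    if n is None:
        n = len(positives)
    protein_ids = sorted(set(protein_ids))
    rna_ids = sorted(set(rna_ids))
    candidates = [
        (p, r) for p in protein_ids for r in rna_ids if (p, r) not in positive_set
    ]
    if len(candidates) < n:
        raise ValueError(
            f"not enough negative candidates: need {n}, have {len(candidates)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n, replace=False)
    return [(candidates[i][0], candidates[i][1], 0) for i in sorted(chosen)]


def filter_pairs(pairs, keep_ids) -> list:
    """Keep only pairs whose protein and RNA ids are in an external keep-list."""
    keep = set(keep_ids)
    return [p for p in pairs if p[0] in keep and p[1] in keep]


def build_dataset(
    structure_paths, cutoff: float = 5.0, neg_seed: int | None = None,
    keep_ids=None,
) -> tuple[list[tuple[str, str, int]], dict[str, str], dict[str, str]]:
    """Structures -> (labeled pairs, protein sequences, RNA sequences).

    Structure-derived non-interactive pairs keep their label 0; additional
    negatives by random pairing are appended only if the structural
    negatives do not already balance the positives.
    """
    chains: list[ChainRecord] = []
    for path in structure_paths:
        chains.extend(parse_structure(path))
    labeled = label_pairs(chains, cutoff=cutoff)
    prot_seqs = {c.full_id: c.sequence for c in chains if c.molecule_kind == "protein"}
    rna_seqs = {c.full_id: c.sequence for c in chains if c.molecule_kind == "rna"}
    pairs = [(lp.protein_id, lp.rna_id, lp.label) for lp in labeled]
    if keep_ids is not None:
        pairs = filter_pairs(pairs, keep_ids)
    n_pos = sum(1 for p in pairs if p[2] == 1)
    n_neg = sum(1 for p in pairs if p[2] == 0)
    if n_neg < n_pos:
        positives = [p for p in pairs if p[2] == 1]
        extra = generate_negatives(
            [(p[0], p[1]) for p in pairs],  # exclude every observed pair
            prot_seqs, rna_seqs, n=n_pos - n_neg, seed=neg_seed,
        )
        pairs.extend(extra)
    return pairs, prot_seqs, rna_seqs
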