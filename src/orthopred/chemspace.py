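"""ECFP_4 fingerprints and nearest-neighbour chemical-space analysis.

Fingerprints are 2048-bit binary Morgan fingerprints of radius 2 (the
ECFP_4 equivalent).  Similarity is the Tanimoto coefficient on bit sets,
and a compound's nearest-neighbour (NN) similarity to a reference set is
its maximum Tc over that set — the quantity used to ask whether
orthologue actives occupy chemical space the human actives do not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)

DEFAULT_WIDTH = 2048
DEFAULT_RADIUS = 2

_generators: dict[tuple[int, int], object] = {}


def _generator(radius: int, width: int):
    key = (radius, width)
    if key not in _generators:
        _generators[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=width
        )
    return _generators[key]


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-width binary substructure fingerprint."""

    bits: np.ndarray
    compound_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))

    @property
    def width(self) -> int:
        return self.bits.shape[0]

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def fingerprint(
    smiles: str,
    compound_id: str = "",
    radius: int = DEFAULT_RADIUS,
    width: int = DEFAULT_WIDTH,
) -> Fingerprint:
    """Hash a molecule's circular substructures into a binary fingerprint.

    Deterministic, and independent of the input atom ordering because
    hashing happens on the molecular graph.

    Raises
    ------
    ValueError
        If the SMILES does not parse.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    bv = _generator(radius, width).GetFingerprint(mol)
    bits = np.zeros(width, dtype=bool)
    bits[list(bv.GetOnBits())] = True
    return Fingerprint(bits=bits, compound_id=compound_id)


def fingerprint_many(
    smiles_ids, radius: int = DEFAULT_RADIUS, width: int = DEFAULT_WIDTH
) -> list[Fingerprint]:
    """Fingerprint an iterable of (smiles, compound_id) pairs."""
    return [fingerprint(s, i, radius, width) for s, i in smiles_ids]


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b| of two equal-width fingerprints.

    Two all-zero fingerprints are identical objects, so their similarity
    is defined as 1 (with a warning — this cannot arise for the carbon-
    containing chemistry that survives curation).
    """
    if a.width != b.width:
        raise ValueError(f"fingerprint width mismatch: {a.width} vs {b.width}")
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        logger.warning("tanimoto of two empty fingerprints; defined as 1.0")
        return 1.0
    return int(np.logical_and(a.bits, b.bits).sum()) / union


def _stack(fps: list[Fingerprint]) -> np.ndarray:
    widths = {fp.width for fp in fps}
    if len(widths) > 1:
        raise ValueError(f"mixed fingerprint widths: {sorted(widths)}")
    return np.stack([fp.bits for fp in fps])


def bulk_tanimoto(queries: list[Fingerprint], references: list[Fingerprint]) -> np.ndarray:
    """Pairwise Tc matrix (|queries| × |references|) via popcount algebra."""
    q = _stack(queries).astype(np.int32)
    r = _stack(references).astype(np.int32)
    if q.shape[1] != r.shape[1]:
        raise ValueError("fingerprint width mismatch between sets")
    inter = q @ r.T
    union = q.sum(axis=1)[:, None] + r.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore"):
        tc = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return tc


@dataclass
class NNSummary:
    """Per-compound nearest-neighbour similarities with group summaries."""

    per_compound: pd.DataFrame  # compound_id, group, nn_tc

    def __post_init__(self):
        vals = self.per_compound["nn_tc"].to_numpy(dtype=float)
        if len(vals) and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("nearest-neighbour similarities outside [0, 1]")

    @property
    def values(self) -> np.ndarray:
        return self.per_compound["nn_tc"].to_numpy(dtype=float)

    def fraction_below(self, cutoff: float) -> float:
        """Fraction of compounds whose NN similarity is below ``cutoff``."""
        if len(self.per_compound) == 0:
            return float("nan")
        return float((self.values < cutoff).mean())

    def group_summary(self, quantiles=(0.25, 0.5, 0.75)) -> pd.DataFrame:
        """Median and quantiles of NN similarity per group label."""
        rows = []
        for grp, sub in self.per_compound.groupby("group", sort=True, dropna=False):
            v = sub["nn_tc"].to_numpy(dtype=float)
            row = {"group": grp, "n": len(v), "median": float(np.median(v))}
            for q in quantiles:
                row[f"q{int(round(q * 100)):02d}"] = float(np.quantile(v, q))
            rows.append(row)
        return pd.DataFrame(rows)


def nn_to_reference(
    query_fps: list[Fingerprint],
    reference_fps: list[Fingerprint],
    query_groups=None,
) -> NNSummary:
    """Maximum Tc of each query compound to a reference set.

    Self-pairs (shared ``compound_id``) are excluded so a compound in
    both sets is compared only with the *other* members.
    """
    if not query_fps:
        raise ValueError("empty query set")
    if not reference_fps:
        raise ValueError("empty reference set")
    tc = bulk_tanimoto(query_fps, reference_fps)
    ref_ids = [fp.compound_id for fp in reference_fps]
    for qi, q in enumerate(query_fps):
        for ri, rid in enumerate(ref_ids):
            if q.compound_id and q.compound_id == rid:
                tc[qi, ri] = -np.inf
    nn = tc.max(axis=1)
    if np.isneginf(nn).any():
        raise ValueError("some query has no non-self reference compound")
    groups = list(query_groups) if query_groups is not None else [""] * len(query_fps)
    return NNSummary(pd.DataFrame({
        "compound_id": [fp.compound_id for fp in query_fps],
        "group": groups,
        "nn_tc": nn,
    }))


def intra_group_nn(group_fps: list[Fingerprint], group_label: str = "") -> NNSummary:
    """Leave-one-out nearest-neighbour similarity within one group.

    Raises for singleton groups, where the quantity is undefined.
    """
    if len(group_fps) < 2:
        raise ValueError("intra-group NN undefined for groups of size < 2")
    tc = bulk_tanimoto(group_fps, group_fps)
    np.fill_diagonal(tc, -np.inf)
    nn = tc.max(axis=1)
    return NNSummary(pd.DataFrame({
        "compound_id": [fp.compound_id for fp in group_fps],
        "group": group_label,
        "nn_tc": nn,
    }))


def save_fingerprints(fps: list[Fingerprint], matrix_path, ids_path) -> None:
    """Cache fingerprints as an .npy bit matrix plus an id sidecar."""
    np.save(matrix_path, _stack(fps))
    with open(ids_path, "w") as fh:
        for fp in fps:
            fh.write(fp.compound_id + "\n")


def load_fingerprints(matrix_path, ids_path) -> list[Fingerprint]:
    mat = np.load(matrix_path)
    with open(ids_path) as fh:
        ids = [line.rstrip("\n") for line in fh]
    if len(ids) != mat.shape[0]:
        raise ValueError("id sidecar length does not match matrix rows")
    return [Fingerprint(bits=row, compound_id=i) for row, i in zip(mat, ids)]
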