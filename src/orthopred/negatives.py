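"""Putative-inactive sampling by sphere exclusion.

Target models need roughly two orders of magnitude more inactives than
actives (1:100 by default), but measured inactives are scarce for most
targets.  Candidates are drawn from a background pool under sphere
exclusion: any pool compound whose nearest-neighbour Tanimoto similarity
to the actives reaches the exclusion radius (default 0.424, the 95%
NN-similarity radius reported for ChEMBL actives) is ineligible, and the
required number is then drawn uniformly at random from the eligible
remainder with a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from orthopred.chemspace import Fingerprint, bulk_tanimoto, fingerprint
from orthopred.orthomap import TrainingSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplingConfig:
    """Sphere-exclusion sampling parameters.

    ratio : inactives per active (default 100, i.e. 1:100).
    exclusion_tc : Tanimoto radius; pool compounds with NN similarity to
        the actives >= this value are excluded.
    seed : RNG seed; a fixed seed makes the sample deterministic.
    enforce_intra_diversity : reserved flag; no mutual-dissimilarity
        constraint is applied among the sampled inactives.
    """

    ratio: int = 100
    exclusion_tc: float = 0.424
    seed: int = 0
    max_pool_passes: int = 1
    enforce_intra_diversity: bool = False

    def __post_init__(self):
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if not 0.0 < self.exclusion_tc <= 1.0:
            raise ValueError("exclusion_tc must be in (0, 1]")


def eligible_pool(
    active_fps: list[Fingerprint],
    pool_fps: list[Fingerprint],
    exclusion_tc: float,
) -> np.ndarray:
    """Boolean mask of pool members outside every active's exclusion sphere."""
    if not active_fps:
        raise ValueError("empty active set: no exclusion spheres definable")
    if not pool_fps:
        return np.zeros(0, dtype=bool)
    nn = bulk_tanimoto(pool_fps, active_fps).max(axis=1)
    return nn < exclusion_tc


def sphere_exclusion_sample(
    active_fps: list[Fingerprint],
    pool_fps: list[Fingerprint],
    config: SamplingConfig,
    n_measured_inactives: int = 0,
) -> list[str]:
    """Sample putative-inactive compound ids from a background pool.

    The sample size is ``min(ratio·|actives| − n_measured_inactives,
    |eligible pool|)``; selection is a seeded uniform shuffle of the
    eligible pool, so the result is deterministic given the seed and
    input order.

    Returns the sampled compound ids (possibly empty, with a warning,
    when the pool is empty or fully excluded).
    """
    if not active_fps:
        raise ValueError("empty active set: no exclusion spheres definable")
    if not pool_fps:
        logger.warning("empty candidate pool; returning empty sample")
        return []
    needed = max(config.ratio * len(active_fps) - n_measured_inactives, 0)
    mask = eligible_pool(active_fps, pool_fps, config.exclusion_tc)
    eligible_ids = [fp.compound_id for fp, ok in zip(pool_fps, mask) if ok]
    if not eligible_ids:
        logger.warning("no pool compound outside the exclusion spheres")
        return []
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(eligible_ids))
    n_take = min(needed, len(eligible_ids))
    return [eligible_ids[i] for i in order[:n_take]]


def fill_inactives(
    training_set: TrainingSet,
    pool: pd.DataFrame,
    config: SamplingConfig,
    fp_cache: dict[str, Fingerprint] | None = None,
) -> tuple[TrainingSet, int]:
    """Top a training set up to the configured inactive:active ratio.

    Measured inactives are used first; the shortfall is filled by
    sphere-exclusion sampling from ``pool`` (columns compound_id,
    smiles), tagging sampled rows with provenance ``sampled``.  Pool
    compounds already present in the set are never candidates.

    Returns the augmented set and the number of compounds sampled.
    """
    fp_cache = fp_cache if fp_cache is not None else {}

    def fp_of(smiles: str, cid: str) -> Fingerprint:
        if smiles not in fp_cache:
            fp_cache[smiles] = fingerprint(smiles, cid)
        base = fp_cache[smiles]
        return Fingerprint(bits=base.bits, compound_id=cid)

    n_measured = len(training_set.inactives)
    needed = config.ratio * training_set.n_actives - n_measured
    if needed <= 0:
        return training_set, 0

    known = set(training_set.actives["smiles"]) | set(training_set.inactives["smiles"])
    candidates = pool[~pool["smiles"].isin(known)].drop_duplicates(subset="smiles")
    active_fps = [
        fp_of(s, c) for s, c in
        zip(training_set.actives["smiles"], training_set.actives["compound_id"])
    ]
    pool_fps = [
        fp_of(s, c) for s, c in zip(candidates["smiles"], candidates["compound_id"])
    ]
    sampled_ids = sphere_exclusion_sample(
        active_fps, pool_fps, config, n_measured_inactives=n_measured
    )
    picked = candidates[candidates["compound_id"].isin(set(sampled_ids))]
    addition = pd.DataFrame({
        "compound_id": picked["compound_id"].values,
        "smiles": picked["smiles"].values,
        "provenance": "sampled",
    })
    out = TrainingSet(
        training_set.target_accession,
        training_set.actives.copy(),
        pd.concat([training_set.inactives, addition], ignore_index=True),
    )
    return out, len(sampled_ids)
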