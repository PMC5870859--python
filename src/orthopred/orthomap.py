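"""Orthologue-to-human bioactivity mapping and its audit reports.

Actives measured at orthologous (non-human) targets are re-assigned to
the mapped human accession through homology groups, duplicate structures
removed (the human copy wins).  The audits quantify how defensible that
transfer is:

* conflict analysis — how often the identical standardized structure is
  active at one species' target but annotated inactive at its homology
  partner;
* concordance analysis — how well paired human/orthologue pChEMBL values
  agree (squared Pearson correlation, median absolute discordance,
  fraction active in both species);
* protein-change binning — whether the amino-acid difference ratio of a
  homology pair predicts the affinity disagreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HOMOLOGENE_COLUMNS = ["group_id", "taxon_id", "accession", "gene_symbol", "prot_change"]


@dataclass(frozen=True)
class OrthologueMapping:
    """One human ↔ orthologue accession pair within a homology group."""

    group_id: str
    human_accession: str
    orthologue_accession: str
    orthologue_species: str
    prot_change: float | None = None

    def __post_init__(self):
        if self.human_accession == self.orthologue_accession:
            raise ValueError("human and orthologue accessions must differ")
        if self.prot_change is not None and not 0.0 <= self.prot_change <= 1.0:
            raise ValueError(f"prot_change {self.prot_change} outside [0, 1]")


@dataclass
class TrainingSet:
    """Per-target actives and inactives with provenance tags.

    ``actives`` and ``inactives`` are DataFrames with columns
    (compound_id, smiles, provenance).  Active provenance is ``human``
    or ``orthologue:<species>``; inactive provenance is ``measured`` or
    ``sampled``.  No structure appears twice within the actives and no
    structure is both active and inactive.
    """

    target_accession: str
    actives: pd.DataFrame = field(default_factory=lambda: _empty_members())
    inactives: pd.DataFrame = field(default_factory=lambda: _empty_members())

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.actives["smiles"].duplicated().any():
            raise ValueError(f"{self.target_accession}: duplicate smiles in actives")
        overlap = set(self.actives["smiles"]) & set(self.inactives["smiles"])
        if overlap:
            raise ValueError(
                f"{self.target_accession}: {len(overlap)} smiles both active and inactive"
            )

    @property
    def n_actives(self) -> int:
        return len(self.actives)

    @property
    def n_orthologue_actives(self) -> int:
        return int(self.actives["provenance"].str.startswith("orthologue").sum())


def _empty_members() -> pd.DataFrame:
    return pd.DataFrame(columns=["compound_id", "smiles", "provenance"])


def read_homologene(path) -> list[OrthologueMapping]:
    """Read a HomoloGene-style TSV into human↔orthologue mapping pairs.

    Within each group the human rows (taxon_id 9606) pair with every
    non-human row; ``prot_change`` is taken from the orthologue row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"group_id": str, "taxon_id": str,
                                            "accession": str})
    mappings = []
    for gid, grp in df.groupby("group_id", sort=True):
        humans = grp[grp["taxon_id"] == "9606"]
        others = grp[grp["taxon_id"] != "9606"]
        for _, h in humans.iterrows():
            for _, o in others.iterrows():
                pc = o.get("prot_change")
                mappings.append(OrthologueMapping(
                    group_id=str(gid),
                    human_accession=h["accession"],
                    orthologue_accession=o["accession"],
                    orthologue_species=str(o.get("gene_symbol", o["taxon_id"])),
                    prot_change=None if pd.isna(pc) else float(pc),
                ))
    return mappings


def mappings_frame(mappings) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_id": m.group_id,
                "human_accession": m.human_accession,
                "orthologue_accession": m.orthologue_accession,
                "orthologue_species": m.orthologue_species,
                "prot_change": m.prot_change,
            }
            for m in mappings
        ]
    )


def training_sets_from_records(records: pd.DataFrame) -> dict[str, TrainingSet]:
    """Group curated records into per-target training sets.

    Active rows become actives with provenance ``human`` or
    ``orthologue:<species>``; inactive rows become measured inactives.
    """
    sets: dict[str, TrainingSet] = {}
    for acc, grp in records.groupby("target_accession", sort=True):
        act = grp[grp["label"] == "active"]
        inact = grp[grp["label"] == "inactive"]
        actives = pd.DataFrame({
            "compound_id": act["compound_id"].values,
            "smiles": act["smiles"].values,
            "provenance": [
                "human" if sp == "human" else f"orthologue:{sp}"
                for sp in act["species"]
            ],
        }).drop_duplicates(subset="smiles", keep="first")
        inactives = pd.DataFrame({
            "compound_id": inact["compound_id"].values,
            "smiles": inact["smiles"].values,
            "provenance": "measured",
        }).drop_duplicates(subset="smiles", keep="first")
        inactives = inactives[~inactives["smiles"].isin(set(actives["smiles"]))]
        sets[acc] = TrainingSet(acc, actives.reset_index(drop=True),
                                inactives.reset_index(drop=True))
    return sets


def merge_orthologue_actives(
    human_sets: dict[str, TrainingSet],
    orthologue_records: pd.DataFrame,
    mappings,
) -> tuple[dict[str, TrainingSet], pd.DataFrame]:
    """Re-assign orthologue actives to their mapped human targets.

    Duplicate structures keep the human-provenance copy; orthologue
    records whose accession is absent from the mappings are skipped and
    logged.  Returns the merged sets and a per-target merge log with
    counts of orthologue compounds added, duplicates dropped and
    orphans skipped.
    """
    by_ortho: dict[str, list] = {}
    for m in mappings:
        by_ortho.setdefault(m.orthologue_accession, []).append(m)

    merged = {
        acc: TrainingSet(acc, ts.actives.copy(), ts.inactives.copy())
        for acc, ts in human_sets.items()
    }
    log_rows: dict[str, dict] = {}

    if len(orthologue_records) == 0 or "label" not in orthologue_records.columns:
        act = pd.DataFrame(columns=["compound_id", "smiles", "target_accession",
                                    "species", "label"])
    else:
        act = orthologue_records[orthologue_records["label"] == "active"]
    for _, row in act.iterrows():
        maps = by_ortho.get(row["target_accession"])
        if not maps:
            log_rows.setdefault("__orphans__", {"added": 0, "duplicates": 0,
                                                "orphans": 0})["orphans"] += 1
            continue
        for m in maps:
            human_acc = m.human_accession
            entry = log_rows.setdefault(
                human_acc, {"added": 0, "duplicates": 0, "orphans": 0})
            ts = merged.setdefault(human_acc, TrainingSet(human_acc))
            if row["smiles"] in set(ts.actives["smiles"]):
                entry["duplicates"] += 1
                continue
            addition = pd.DataFrame({
                "compound_id": [row["compound_id"]],
                "smiles": [row["smiles"]],
                "provenance": [f"orthologue:{row['species']}"],
            })
            ts.actives = pd.concat([ts.actives, addition], ignore_index=True)
            # an orthologue active overrides a measured inactive duplicate
            ts.inactives = ts.inactives[ts.inactives["smiles"] != row["smiles"]]
            entry["added"] += 1

    for ts in merged.values():
        ts.validate()
    orphans = log_rows.pop("__orphans__", {"orphans": 0})["orphans"]
    if orphans:
        logger.warning("merge: %d orthologue actives had no mapping and were skipped", orphans)
    log = pd.DataFrame(
        [{"target_accession": k, **v} for k, v in sorted(log_rows.items())]
    )
    if log.empty:
        log = pd.DataFrame(columns=["target_accession", "added", "duplicates", "orphans"])
    log.attrs["n_orphans"] = orphans
    return merged, log


def apply_min_actives(
    sets: dict[str, TrainingSet],
    min_actives: int = 10,
    sets_before: dict[str, TrainingSet] | None = None,
) -> tuple[dict[str, TrainingSet], list[str]]:
    """Drop targets with fewer than ``min_actives`` actives.

    Also reports the targets that pass the threshold only thanks to
    orthologue additions — the models that would not exist at all from
    human data alone.
    """
    retained = {acc: ts for acc, ts in sets.items() if ts.n_actives >= min_actives}
    newly_enabled = []
    for acc, ts in retained.items():
        n_human = ts.n_actives - ts.n_orthologue_actives
        if sets_before is not None and acc in sets_before:
            n_human = sets_before[acc].n_actives
        if n_human < min_actives and ts.n_orthologue_actives > 0:
            newly_enabled.append(acc)
    return retained, sorted(newly_enabled)


def coverage_summary(
    sets_before: dict[str, TrainingSet],
    sets_after: dict[str, TrainingSet],
    target_classes: dict[str, str],
) -> pd.DataFrame:
    """Per-class model counts before/after orthologue inclusion.

    Unknown class labels are bucketed as ``other``.  The returned frame
    carries ``n_before``, ``n_after`` and ``pct_change`` per class and
    the overall share of models that received orthologue compounds in
    ``.attrs['share_with_orthologues']`` (percent).
    """
    def classes_of(sets):
        return pd.Series(
            {acc: target_classes.get(acc, "other") for acc in sets}, dtype=object
        )

    before = classes_of(sets_before).value_counts()
    after = classes_of(sets_after).value_counts()
    all_classes = sorted(set(before.index) | set(after.index))
    rows = []
    for cls in all_classes:
        nb = int(before.get(cls, 0))
        na = int(after.get(cls, 0))
        pct = float("nan") if nb == 0 else 100.0 * (na - nb) / nb
        rows.append({"target_class": cls, "n_before": nb, "n_after": na,
                     "pct_change": pct})
    out = pd.DataFrame(rows)
    n_with = sum(1 for ts in sets_after.values() if ts.n_orthologue_actives > 0)
    out.attrs["share_with_orthologues"] = (
        100.0 * n_with / len(sets_after) if sets_after else float("nan")
    )
    return out


@dataclass
class ConflictReport:
    """Counts of mapped bioactivities that conflict across a homology pair.

    ``per_mapping`` has one row per human↔orthologue pair with the
    number of compounds mapped through it and how many of those carry a
    conflicting (opposite-label) annotation at the partner target.
    """

    per_mapping: pd.DataFrame
    n_mapped: int
    n_conflicting: int
    n_pairs: int
    n_pairs_conflict_free: int
    direction: str = ""

    def __post_init__(self):
        if not 0 <= self.n_conflicting <= max(self.n_mapped, 0):
            raise ValueError("conflict count outside [0, n_mapped]")

    @property
    def conflict_pct(self) -> float:
        """Percentage of mapped bioactivities with conflicting annotation."""
        if self.n_mapped == 0:
            return 0.0
        return 100.0 * self.n_conflicting / self.n_mapped

    @property
    def compatibility_pct(self) -> float:
        """100 · (1 − conflicting/mapped): how often annotations agree."""
        return 100.0 - self.conflict_pct

    @property
    def pair_conflict_free_pct(self) -> float:
        """Percentage of homology pairs with no conflicting compound."""
        if self.n_pairs == 0:
            return 100.0
        return 100.0 * self.n_pairs_conflict_free / self.n_pairs

    @classmethod
    def from_counts(cls, n_mapped: int, n_conflicting: int,
                    n_pairs: int = 0, n_pairs_conflict_free: int = 0,
                    direction: str = "") -> "ConflictReport":
        """Summarize externally tabulated counts (no per-mapping detail)."""
        return cls(pd.DataFrame(columns=["human_accession", "orthologue_accession",
                                         "n_mapped", "n_conflicting"]),
                   n_mapped, n_conflicting, n_pairs, n_pairs_conflict_free, direction)

    def to_frame(self) -> pd.DataFrame:
        return self.per_mapping.copy()


def conflict_analysis(
    active_records: pd.DataFrame,
    inactive_records: pd.DataFrame,
    mappings,
    direction: str = "ortho-active-vs-human-inactive",
) -> ConflictReport:
    """Count cross-species active/inactive conflicts on identical structures.

    For each homology mapping, every active measured at the source
    accession is "mapped"; it conflicts when the identical standardized
    SMILES is annotated inactive at the partner accession.  Totals are
    mapping-level: a compound reached through several mappings counts
    once per mapping.

    ``direction`` selects which side holds the actives:
    ``ortho-active-vs-human-inactive`` maps orthologue actives onto
    human inactives; ``ortho-inactive-vs-human-active`` the reverse.
    """
    if direction not in ("ortho-active-vs-human-inactive",
                         "ortho-inactive-vs-human-active"):
        raise ValueError(f"unknown direction {direction!r}")

    act_by_target: dict[str, set] = {
        acc: set(grp["smiles"])
        for acc, grp in active_records.groupby("target_accession")
    }
    inact_by_target: dict[str, set] = {
        acc: set(grp["smiles"])
        for acc, grp in inactive_records.groupby("target_accession")
    }

    rows = []
    for m in mappings:
        if direction == "ortho-active-vs-human-inactive":
            src, partner = m.orthologue_accession, m.human_accession
        else:
            src, partner = m.human_accession, m.orthologue_accession
        mapped = act_by_target.get(src, set())
        conflicting = mapped & inact_by_target.get(partner, set())
        rows.append({
            "group_id": m.group_id,
            "human_accession": m.human_accession,
            "orthologue_accession": m.orthologue_accession,
            "n_mapped": len(mapped),
            "n_conflicting": len(conflicting),
        })
    per_mapping = pd.DataFrame(
        rows, columns=["group_id", "human_accession", "orthologue_accession",
                       "n_mapped", "n_conflicting"])
    per_mapping = per_mapping.sort_values(
        ["n_conflicting", "n_mapped"], ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    considered = per_mapping[per_mapping["n_mapped"] > 0]
    return ConflictReport(
        per_mapping=per_mapping,
        n_mapped=int(per_mapping["n_mapped"].sum()),
        n_conflicting=int(per_mapping["n_conflicting"].sum()),
        n_pairs=int(len(considered)),
        n_pairs_conflict_free=int((considered["n_conflicting"] == 0).sum()),
        direction=direction,
    )


@dataclass
class ConcordanceReport:
    """Agreement statistics for compounds measured in both species.

    ``r_squared`` is the squared Pearson correlation of paired pChEMBL
    values; discordance is |human − orthologue| on the pChEMBL scale.
    Per-group statistics (grouped by standard_units / standard_type /
    assay_type) are NaN for groups with fewer than 3 pairs.
    """

    pairs: pd.DataFrame
    per_group: pd.DataFrame
    r_squared: float
    median_abs_discordance: float
    frac_both_active: float
    activity_cutoff: float
    n_pairs: int

    @staticmethod
    def both_active_fraction(n_both_active: int, n_pairs: int) -> float:
        """Fraction of paired measurements active in both species."""
        if n_pairs <= 0:
            raise ValueError("n_pairs must be positive")
        return n_both_active / n_pairs


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def concordance_analysis(
    paired: pd.DataFrame, activity_cutoff: float = 5.0
) -> ConcordanceReport:
    """Compare paired human/orthologue pChEMBL measurements.

    ``paired`` needs columns ``human_pchembl`` and ``ortho_pchembl``
    plus the grouping fields ``standard_units``, ``standard_type`` and
    ``assay_type``.
    """
    required = {"human_pchembl", "ortho_pchembl"}
    if not required <= set(paired.columns):
        raise ValueError(f"paired table needs columns {sorted(required)}")
    h = paired["human_pchembl"].to_numpy(dtype=float)
    o = paired["ortho_pchembl"].to_numpy(dtype=float)
    disc = np.abs(h - o)
    both = (h >= activity_cutoff) & (o >= activity_cutoff)

    group_cols = [c for c in ("standard_units", "standard_type", "assay_type")
                  if c in paired.columns]
    rows = []
    if group_cols:
        for key, grp in paired.groupby(group_cols, sort=True, dropna=False):
            key = key if isinstance(key, tuple) else (key,)
            gh = grp["human_pchembl"].to_numpy(dtype=float)
            go = grp["ortho_pchembl"].to_numpy(dtype=float)
            rows.append({
                **dict(zip(group_cols, key)),
                "n_pairs": len(grp),
                "r_squared": _r_squared(gh, go),
                "median_abs_discordance": float(np.median(np.abs(gh - go)))
                if len(grp) else float("nan"),
            })
    per_group = pd.DataFrame(rows, columns=group_cols + ["n_pairs", "r_squared",
                                                         "median_abs_discordance"])
    return ConcordanceReport(
        pairs=paired.copy(),
        per_group=per_group,
        r_squared=_r_squared(h, o),
        median_abs_discordance=float(np.median(disc)) if len(disc) else float("nan"),
        frac_both_active=float(both.mean()) if len(both) else float("nan"),
        activity_cutoff=activity_cutoff,
        n_pairs=len(paired),
    )


def prot_change_binning(
    paired: pd.DataFrame,
    mappings,
    bin_width: float = 0.1,
) -> tuple[pd.DataFrame, float, int]:
    """Bin affinity discordance by the amino-acid difference ratio.

    Each pair is looked up in the mappings on
    (human_accession, orthologue_accession) to fetch ``prot_change``;
    pairs without one are excluded and counted.  Bins are
    [0, w), [w, 2w), …

    Returns (per-bin frame with median |ΔpChEMBL| and counts,
    trend R² between prot_change and |ΔpChEMBL|, n_excluded).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pc_lookup = {
        (m.human_accession, m.orthologue_accession): m.prot_change for m in mappings
    }
    keys = list(zip(paired["human_accession"], paired["orthologue_accession"]))
    pc = np.array([pc_lookup.get(k) for k in keys], dtype=object)
    have = np.array([v is not None and not pd.isna(v) for v in pc])
    n_excluded = int((~have).sum())

    pcv = pc[have].astype(float)
    disc = np.abs(
        paired["human_pchembl"].to_numpy(dtype=float)[have]
        - paired["ortho_pchembl"].to_numpy(dtype=float)[have]
    )
    bin_idx = np.floor(pcv / bin_width).astype(int)
    rows = []
    for b in sorted(set(bin_idx)):
        sel = bin_idx == b
        rows.append({
            "bin_lo": b * bin_width,
            "bin_hi": (b + 1) * bin_width,
            "n_pairs": int(sel.sum()),
            "median_abs_discordance": float(np.median(disc[sel])),
        })
    bins = pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "n_pairs",
                                       "median_abs_discordance"])
    trend_r2 = _r_squared(pcv, disc)
    if np.isnan(trend_r2) and len(pcv) >= 3 and np.std(disc) == 0:
        trend_r2 = 0.0  # constant discordance: no trend by definition
    return bins, trend_r2, n_excluded
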