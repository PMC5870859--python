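"""End-to-end orchestration: curation → orthologue merge → negative
sampling → audits → paired before/after benchmarking.

The pipeline is deterministic under a fixed seed; every stage logs its
in/out counts and the artifact writers use stable column orders.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from orthopred import chemspace, curation, evaluation, modeling, negatives, orthomap

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths plus stage configurations for one pipeline run."""

    chembl_path: str = ""
    pubchem_path: str = ""
    homologene_path: str = ""
    pool_path: str = ""
    outdir: str = "orthopred-run"
    seed: int = 0
    curation: curation.CurationConfig = field(default_factory=curation.CurationConfig)
    sampling: negatives.SamplingConfig = field(default_factory=negatives.SamplingConfig)
    metrics: evaluation.MetricConfig = field(default_factory=evaluation.MetricConfig)

    _SCALARS = ("chembl_path", "pubchem_path", "homologene_path", "pool_path",
                "outdir", "seed")

    def to_file(self, path) -> None:
        """Write a plain ``key = value`` config file (lossless round-trip)."""
        lines = []
        for k in self._SCALARS:
            lines.append(f"{k} = {getattr(self, k)}")
        for section, cfg in (("curation", self.curation),
                             ("sampling", self.sampling),
                             ("metrics", self.metrics)):
            for k, v in asdict(cfg).items():
                if k == "forbidden_z_ranges":
                    v = ";".join(f"{lo}-{'' if hi is None else hi}" for lo, hi in v)
                lines.append(f"{section}.{k} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kv = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            k, v = (part.strip() for part in line.split("=", 1))
            kv[k] = v
        cfg = cls()
        for k in cls._SCALARS:
            if k in kv:
                setattr(cfg, k, int(kv[k]) if k == "seed" else kv[k])
        cfg.curation = _config_from_kv(curation.CurationConfig, kv, "curation")
        cfg.sampling = _config_from_kv(negatives.SamplingConfig, kv, "sampling")
        cfg.metrics = _config_from_kv(evaluation.MetricConfig, kv, "metrics")
        return cfg


def _config_from_kv(cls, kv, section):
    import dataclasses

    kwargs = {}
    for f in dataclasses.fields(cls):
        key = f"{section}.{f.name}"
        if key not in kv:
            continue
        raw = kv[key]
        if f.name == "forbidden_z_ranges":
            ranges = []
            for part in raw.split(";"):
                lo, hi = part.split("-")
                ranges.append((int(lo), None if hi == "" else int(hi)))
            kwargs[f.name] = tuple(ranges)
        elif f.type in ("bool", bool):
            kwargs[f.name] = raw.lower() in ("1", "true", "yes", "on")
        elif f.type in ("int", int):
            kwargs[f.name] = int(raw)
        else:
            kwargs[f.name] = float(raw)
    return cls(**kwargs)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class BuildResult:
    """Artifacts of the curation/merge/audit stages."""

    curated: pd.DataFrame
    mappings: list
    sets_human: dict
    sets_merged: dict
    sets_retained: dict
    newly_enabled: list
    conflicts_fwd: orthomap.ConflictReport
    conflicts_rev: orthomap.ConflictReport
    concordance: orthomap.ConcordanceReport | None
    merge_log: pd.DataFrame
    counts: dict


def run_build(config: RunConfig, tables: dict | None = None) -> BuildResult:
    """Run curation, orthologue merge and the audit reports.

    ``tables`` may supply in-memory DataFrames (keys chembl, pubchem,
    homologene and optionally paired) instead of the configured paths.
    """
    try:
        if tables is None:
            tables = {
                "chembl": curation.read_bioactivity_table(config.chembl_path),
                "pubchem": curation.read_bioactivity_table(config.pubchem_path),
            }
            tables["homologene_mappings"] = orthomap.read_homologene(
                config.homologene_path)
        if "homologene_mappings" in tables:
            mappings = tables["homologene_mappings"]
        else:
            mappings = _mappings_from_frame(tables["homologene"])
    except Exception as exc:
        raise StageError(f"input stage failed: {exc}") from exc

    counts = {}
    try:
        chembl_ok, chembl_rej = curation.curate_structures(tables["chembl"],
                                                           config.curation)
        pubchem_ok, pubchem_rej = curation.curate_structures(tables["pubchem"],
                                                             config.curation)
        counts["chembl_in"] = len(tables["chembl"])
        counts["chembl_structure_ok"] = len(chembl_ok)
        counts["pubchem_in"] = len(tables["pubchem"])
        counts["pubchem_structure_ok"] = len(pubchem_ok)
    except Exception as exc:
        raise StageError(f"structure curation failed: {exc}") from exc

    try:
        actives, act_rej = curation.select_actives(chembl_ok, config.curation)
        inactives = pubchem_ok.copy()
        inactives["label"] = "inactive"
        merged_table, n_samepair = curation.resolve_conflicting_labels(
            actives, inactives)
        counts["actives"] = len(actives)
        counts["inactives"] = int((merged_table["label"] == "inactive").sum())
        counts["same_target_conflicts_resolved"] = n_samepair
    except Exception as exc:
        raise StageError(f"activity curation failed: {exc}") from exc

    try:
        human = merged_table[merged_table["species"] == "human"]
        ortho = merged_table[(merged_table["species"] != "human")
                             & (merged_table["label"] == "active")]
        sets_human = orthomap.training_sets_from_records(human)
        sets_merged, merge_log = orthomap.merge_orthologue_actives(
            sets_human, ortho, mappings)
        retained_before, _ = orthomap.apply_min_actives(
            sets_human, config.curation.min_actives)
        sets_retained, newly_enabled = orthomap.apply_min_actives(
            sets_merged, config.curation.min_actives, sets_before=sets_human)
        counts["targets_human_only"] = len(retained_before)
        counts["targets_after_merge"] = len(sets_retained)
        counts["newly_enabled"] = len(newly_enabled)
    except Exception as exc:
        raise StageError(f"orthologue merge failed: {exc}") from exc

    try:
        act_tbl = merged_table[merged_table["label"] == "active"]
        inact_tbl = merged_table[merged_table["label"] == "inactive"]
        conflicts_fwd = orthomap.conflict_analysis(
            act_tbl[act_tbl["species"] != "human"], inact_tbl, mappings,
            direction="ortho-active-vs-human-inactive")
        conflicts_rev = orthomap.conflict_analysis(
            act_tbl[act_tbl["species"] == "human"], inact_tbl, mappings,
            direction="ortho-inactive-vs-human-active")
        concordance = None
        if "paired" in tables and len(tables["paired"]):
            concordance = orthomap.concordance_analysis(tables["paired"])
    except Exception as exc:
        raise StageError(f"audit stage failed: {exc}") from exc

    logger.info("build counts: %s", counts)
    return BuildResult(
        curated=merged_table, mappings=mappings, sets_human=sets_human,
        sets_merged=sets_merged, sets_retained=sets_retained,
        newly_enabled=newly_enabled, conflicts_fwd=conflicts_fwd,
        conflicts_rev=conflicts_rev, concordance=concordance,
        merge_log=merge_log, counts=counts,
    )


def _mappings_from_frame(df: pd.DataFrame) -> list:
    import tempfile, os

    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        df.to_csv(fh, sep="\t", index=False)
        path = fh.name
    try:
        return orthomap.read_homologene(path)
    finally:
        os.unlink(path)


def _with_dates(training_set, curated: pd.DataFrame) -> pd.DataFrame:
    """Attach dates to a training set's members.

    Actives and measured inactives inherit their record dates; sampled
    putative inactives have none, so they inherit evenly spaced dates
    across the observed date range by insertion order, keeping the
    chronological folds defined for every row.
    """
    date_of = dict(zip(zip(curated["smiles"], curated["target_accession"]),
                       pd.to_datetime(curated["record_date"], errors="coerce")))
    rows = []
    for frame, y in ((training_set.actives, 1), (training_set.inactives, 0)):
        for _, r in frame.iterrows():
            d = date_of.get((r["smiles"], training_set.target_accession), pd.NaT)
            rows.append({"smiles": r["smiles"], "compound_id": r["compound_id"],
                         "y": y, "date": d, "provenance": r["provenance"]})
    df = pd.DataFrame(rows)
    known = df["date"].dropna()
    if len(known) and df["date"].isna().any():
        lo, hi = known.min(), known.max()
        nan_idx = df.index[df["date"].isna()]
        fills = pd.to_datetime(np.linspace(lo.value, hi.value, len(nan_idx)))
        df.loc[nan_idx, "date"] = fills
    return df


def cross_validate_target(
    members: pd.DataFrame,
    hyperparams: modeling.HyperParams,
    metric_config: evaluation.MetricConfig,
    seed: int,
    fp_cache: dict | None = None,
) -> dict[str, float] | None:
    """Time-series CV of one target; metrics pooled over all test folds.

    ``members`` needs columns smiles, y, date.  Folds whose training
    block lacks one of the classes are skipped with a log message;
    returns None when no fold is usable.
    """
    fp_cache = fp_cache if fp_cache is not None else {}

    def bits(s):
        if s not in fp_cache:
            fp_cache[s] = chemspace.fingerprint(s)
        return fp_cache[s].bits

    X = np.stack([bits(s) for s in members["smiles"]])
    y = members["y"].to_numpy(dtype=int)
    folds = evaluation.time_series_folds(members["date"], metric_config.n_splits)
    pooled_p, pooled_y = [], []
    for k, (tr, te) in enumerate(folds):
        if len(np.unique(y[tr])) < 2:
            logger.info("fold %d skipped: single-class training block", k)
            continue
        model = modeling.train_matrix(X[tr], y[tr], hyperparams, seed=seed)
        pooled_p.append(model.predict(X[te]))
        pooled_y.append(y[te])
    if not pooled_p:
        return None
    p = np.concatenate(pooled_p)
    yy = np.concatenate(pooled_y)
    if yy.sum() == 0:
        return None
    return evaluation.fold_metrics(p, yy, metric_config)


def run_benchmark(
    config: RunConfig,
    build: BuildResult,
    pool: pd.DataFrame,
    grid: list[modeling.HyperParams] | None = None,
) -> dict[str, evaluation.BenchmarkReport]:
    """Paired before/after-orthologue time-series CV over the grid.

    Both arms use the same fold rule, seeds and sphere-exclusion
    configuration; the "before" arm is the human-only training sets, the
    "after" arm the orthologue-merged sets.  Targets must meet the
    minimum-actives threshold in both arms to be paired.

    Returns one :class:`~orthopred.evaluation.BenchmarkReport` per
    hyper-parameter label.
    """
    grid = grid or modeling.default_grid()
    fp_cache: dict = {}
    min_act = config.curation.min_actives
    targets = sorted(
        acc for acc, ts in build.sets_retained.items()
        if acc in build.sets_human
        and build.sets_human[acc].n_actives >= min_act
    )
    if not targets:
        raise StageError("benchmark stage failed: no target meets the "
                         "minimum-actives threshold in both arms")

    arm_members: dict[str, dict[str, pd.DataFrame]] = {"before": {}, "after": {}}
    for acc in targets:
        for arm, sets in (("before", build.sets_human),
                          ("after", build.sets_retained)):
            filled, n_sampled = negatives.fill_inactives(
                sets[acc], pool, config.sampling, fp_cache=fp_cache)
            logger.info("%s/%s: %d sampled inactives", arm, acc, n_sampled)
            arm_members[arm][acc] = _with_dates(filled, build.curated)

    reports = {}
    for hp in grid:
        per_arm = {}
        for arm in ("before", "after"):
            rows = []
            for acc in targets:
                m = cross_validate_target(arm_members[arm][acc], hp,
                                          config.metrics, config.seed, fp_cache)
                if m is not None:
                    rows.append({"target": acc, **m})
            per_arm[arm] = pd.DataFrame(rows)
        common = sorted(set(per_arm["before"]["target"])
                        & set(per_arm["after"]["target"]))
        before = per_arm["before"][per_arm["before"]["target"].isin(common)]
        after = per_arm["after"][per_arm["after"]["target"].isin(common)]
        reports[hp.label] = evaluation.benchmark(before, after)
    return reports


def external_validate(
    models: dict[str, modeling.CalibratedModel],
    external: pd.DataFrame,
    metric_config: evaluation.MetricConfig | None = None,
) -> pd.DataFrame:
    """Score labelled external bioactivities against fitted models.

    ``external`` needs columns target_accession, smiles and label
    (active/inactive); metrics are computed per target over the rows
    whose target has a model.
    """
    metric_config = metric_config or evaluation.MetricConfig()
    fp_cache: dict = {}
    rows = []
    for acc, grp in external.groupby("target_accession", sort=True):
        if acc not in models:
            continue
        fps = []
        for s in grp["smiles"]:
            if s not in fp_cache:
                fp_cache[s] = chemspace.fingerprint(s)
            fps.append(fp_cache[s])
        p = models[acc].predict(fps)
        y = (grp["label"] == "active").to_numpy(dtype=int)
        if y.sum() == 0 or y.sum() == len(y):
            logger.info("external set for %s is single-class; skipped", acc)
            continue
        rows.append({"target": acc, "n": len(y),
                     **evaluation.fold_metrics(p, y, metric_config)})
    return pd.DataFrame(rows)


def write_build_artifacts(build: BuildResult, outdir) -> None:
    """Write curated table, audit reports and a manifest under outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    curation.write_bioactivity_table(build.curated, outdir / "curated.tsv")
    build.conflicts_fwd.per_mapping.to_csv(outdir / "conflicts_fwd.tsv",
                                           sep="\t", index=False)
    build.conflicts_rev.per_mapping.to_csv(outdir / "conflicts_rev.tsv",
                                           sep="\t", index=False)
    build.merge_log.to_csv(outdir / "merge_log.tsv", sep="\t", index=False)
    manifest = {
        "counts": build.counts,
        "newly_enabled": build.newly_enabled,
        "conflicts_forward": {
            "n_mapped": build.conflicts_fwd.n_mapped,
            "n_conflicting": build.conflicts_fwd.n_conflicting,
            "compatibility_pct": build.conflicts_fwd.compatibility_pct,
            "pair_conflict_free_pct": build.conflicts_fwd.pair_conflict_free_pct,
        },
        "conflicts_reverse": {
            "n_mapped": build.conflicts_rev.n_mapped,
            "n_conflicting": build.conflicts_rev.n_conflicting,
            "compatibility_pct": build.conflicts_rev.compatibility_pct,
        },
    }
    if build.concordance is not None:
        manifest["concordance"] = {
            "r_squared": build.concordance.r_squared,
            "median_abs_discordance": build.concordance.median_abs_discordance,
            "frac_both_active": build.concordance.frac_both_active,
            "n_pairs": build.concordance.n_pairs,
        }
        build.concordance.per_group.to_csv(outdir / "concordance_groups.tsv",
                                           sep="\t", index=False)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
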