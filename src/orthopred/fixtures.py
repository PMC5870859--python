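"""Synthetic ChEMBL/PubChem/HomoloGene-style inputs.

The generator emulates the shapes of the three real inputs so the whole
pipeline is testable without downloads: a drug-like SMILES library built
from scaffold clusters (so intra-cluster similarity exceeds
inter-cluster similarity), a ChEMBL-like table of human and orthologue
actives, a PubChem-like inactive table with a controllable planted
conflict rate, a HomoloGene-like orthologue group table, and paired
human/orthologue affinity measurements with controllable concordance
noise.  Every planted quantity is returned in a ledger so tests can
compare pipeline output against generator truth.

Affinities are generated directly on the pChEMBL scale.  The defaults
emulate the concordance regime reported for real cross-species pairs:
human affinities N(6.8, 0.7) with orthologue noise sd 0.75, giving a
planted median |ΔpChEMBL| near 0.51, a paired R² near 0.46 and a
both-active fraction near 0.96 at the pChEMBL 5 cutoff.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from orthopred.curation import standardize_structure

logger = logging.getLogger(__name__)

# drug-like cores; each cluster of the library shares one scaffold
SCAFFOLDS = (
    "c1ccc2ccccc2c1",           # naphthalene
    "c1ccncc1",                 # pyridine
    "c1ccc(cc1)C(=O)N",         # benzamide
    "c1ccc(cc1)S(=O)(=O)N",     # benzenesulfonamide
    "C1CCNCC1",                 # piperidine
    "c1ccc2ncccc2c1",           # quinoline
    "c1ccc(cc1)Oc1ccccc1",      # diphenyl ether
    "c1ccc(cc1)c1ccccc1",       # biphenyl
    "c1ccsc1",                  # thiophene
    "C1COCCN1",                 # morpholine
    "c1ccc(cc1)CN",             # benzylamine
    "c1ccc(cc1)N1CCNCC1",       # phenylpiperazine
    "c1ccc(cc1)NC(=O)C",        # acetanilide
)
LINKERS = ("C", "CC", "CCC", "CCO", "CC(=O)N", "CCN", "COC", "CC(C)", "CS", "CCCO")
TERMINALS = ("C", "CC", "CCO", "C(=O)OC", "C#N", "Cl", "F", "CC(C)C",
             "c1ccccc1", "C(F)(F)F", "OC", "N")

SPECIES_TAXA = {"rat": "10116", "mouse": "10090", "bovine": "9913"}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study conditions.

    conflict_rate is the probability that an orthologue active is also
    planted as a human inactive (default 0.011, the regime observed for
    real orthologue bioactivities); concordance_sd is the pChEMBL noise
    between paired human and orthologue measurements.  The orthologue
    species mix defaults to the rat-dominated distribution seen in real
    orthologue bioactivity data.
    """

    n_targets: int = 10
    n_human_actives: int = 30
    n_ortho_actives: int = 15
    ortho_species_mix: tuple = (("rat", 0.67), ("mouse", 0.25), ("bovine", 0.08))
    conflict_rate: float = 0.011
    concordance_sd: float = 0.75
    pool_size: int = 1200
    date_span: tuple = ("2001-01-01", "2015-12-31")
    seed: int = 0
    n_measured_inactives: int = 40
    paired_per_target: int = 20
    human_pchembl_mean: float = 6.8
    human_pchembl_sd: float = 0.7

    def __post_init__(self):
        if not 0.0 <= self.conflict_rate <= 1.0:
            raise ValueError("conflict_rate must be in [0, 1]")
        if self.pool_size < 10:
            raise ValueError("pool_size must be >= 10")
        if abs(sum(w for _, w in self.ortho_species_mix) - 1.0) > 1e-9:
            raise ValueError("ortho_species_mix weights must sum to 1")


_library_cache: dict[tuple, pd.DataFrame] = {}


def generate_library(spec: FixtureSpec) -> pd.DataFrame:
    """Build a clustered drug-like SMILES library.

    Compounds are scaffold + linker + terminal combinations,
    standardized and deduplicated; the cluster label is the scaffold
    index, so compounds within a cluster share a core and are more
    similar to each other than to other clusters.  Deterministic given
    the seed.

    Returns a frame with columns (compound_id, smiles, cluster).
    """
    key = (spec.pool_size, spec.seed)
    if key in _library_cache:
        return _library_cache[key].copy()
    combos = [
        (ci, s + l + t)
        for ci, s in enumerate(SCAFFOLDS)
        for l in LINKERS
        for t in TERMINALS
    ]
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(combos))
    rows, seen = [], set()
    for idx in order:
        if len(rows) >= spec.pool_size:
            break
        cluster, raw = combos[idx]
        std, reason = standardize_structure(raw)
        if std is None or std in seen:  # pragma: no cover - bank is curated
            continue
        seen.add(std)
        rows.append({"compound_id": f"CPD{len(rows):06d}", "smiles": std,
                     "cluster": cluster})
    if len(rows) < spec.pool_size:
        logger.warning("library exhausted at %d compounds (requested %d)",
                       len(rows), spec.pool_size)
    lib = pd.DataFrame(rows)
    _library_cache[key] = lib
    return lib.copy()


def _truncated_normal(rng, mean, sd, lower, size):
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = out < lower
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, lower, None)


def _dates(rng, span, size):
    lo, hi = (pd.Timestamp(d) for d in span)
    days = rng.integers(0, (hi - lo).days + 1, size=size)
    return [(lo + pd.Timedelta(int(d), "D")).strftime("%Y-%m-%d") for d in days]


def _activity_rows(rng, spec, lib_rows, target, species, source, label, dates=None,
                   pchembl=None):
    n = len(lib_rows)
    if pchembl is None and label == "active":
        pchembl = _truncated_normal(rng, spec.human_pchembl_mean,
                                    spec.human_pchembl_sd, 5.0, n)
    rows = []
    for k, (_, cpd) in enumerate(lib_rows.iterrows()):
        pc = None if pchembl is None else float(pchembl[k])
        value_nm = None if pc is None else 10.0 ** (9.0 - pc)
        rows.append({
            "compound_id": cpd["compound_id"],
            "smiles": cpd["smiles"],
            "target_accession": target,
            "species": species,
            "pchembl": pc,
            "standard_type": "IC50" if rng.random() < 0.5 else "Ki",
            "standard_units": "nM",
            "standard_value": value_nm,
            "assay_type": "binding" if rng.random() < 0.7 else "functional",
            "confidence": int(rng.integers(6, 10)),
            "activity_comment": None,
            "label": label,
            "record_date": dates[k] if dates is not None else None,
            "source": source,
        })
    return rows


def generate_bioactivity_tables(spec: FixtureSpec) -> dict:
    """Generate the three input tables plus paired measurements.

    Per target t the human accession holds actives from one scaffold
    cluster and the orthologue accession actives from a *different*
    cluster (so orthologue chemistry genuinely extends the modelled
    space).  A ``conflict_rate`` fraction of orthologue actives is also
    planted as human inactives in the PubChem-like table.  Paired
    human/orthologue measurements share a compound, the orthologue value
    being the human value plus N(0, concordance_sd).

    Returns a dict with keys ``library``, ``chembl``, ``pubchem``,
    ``homologene``, ``paired`` and a ``ledger`` of every planted count.
    """
    rng = np.random.default_rng(spec.seed)
    lib = generate_library(spec)
    clusters = sorted(lib["cluster"].unique())
    n_cl = len(clusters)
    species_names = [s for s, _ in spec.ortho_species_mix]
    species_w = np.array([w for _, w in spec.ortho_species_mix])

    chembl_rows: list[dict] = []
    pubchem_rows: list[dict] = []
    homologene_rows: list[dict] = []
    paired_rows: list[dict] = []
    ledger: dict = {
        "targets": {}, "n_conflicts_planted": 0, "n_ortho_actives": 0,
        "n_human_actives": 0, "n_paired": 0,
        "human_cluster": {}, "ortho_cluster": {},
    }

    for t in range(spec.n_targets):
        human_acc = f"P{10000 + t}"
        ortho_acc = f"Q{20000 + t}"
        group = f"G{t:04d}"
        species = species_names[rng.choice(len(species_names), p=species_w)]
        prot_change = float(np.round(rng.uniform(0.0, 0.45), 3))
        h_cl = clusters[(2 * t) % n_cl]
        o_cl = clusters[(2 * t + 1) % n_cl]
        ledger["human_cluster"][human_acc] = int(h_cl)
        ledger["ortho_cluster"][human_acc] = int(o_cl)

        homologene_rows.append({"group_id": group, "taxon_id": "9606",
                                "accession": human_acc, "gene_symbol": "human",
                                "prot_change": 0.0})
        homologene_rows.append({"group_id": group,
                                "taxon_id": SPECIES_TAXA.get(species, "0"),
                                "accession": ortho_acc, "gene_symbol": species,
                                "prot_change": prot_change})

        h_pool = lib[lib["cluster"] == h_cl]
        o_pool = lib[lib["cluster"] == o_cl]
        h_pick = h_pool.iloc[rng.choice(len(h_pool), size=min(spec.n_human_actives,
                                                              len(h_pool)),
                                        replace=False)]
        o_idx = rng.choice(len(o_pool),
                           size=min(spec.n_ortho_actives + spec.paired_per_target,
                                    len(o_pool)),
                           replace=False)
        o_pick = o_pool.iloc[o_idx[: spec.n_ortho_actives]]
        p_pick = o_pool.iloc[o_idx[spec.n_ortho_actives:
                                   spec.n_ortho_actives + spec.paired_per_target]]

        chembl_rows += _activity_rows(
            rng, spec, h_pick, human_acc, "human", "chembl-like", "active",
            dates=_dates(rng, spec.date_span, len(h_pick)))
        chembl_rows += _activity_rows(
            rng, spec, o_pick, ortho_acc, species, "chembl-like", "active",
            dates=_dates(rng, spec.date_span, len(o_pick)))
        ledger["n_human_actives"] += len(h_pick)
        ledger["n_ortho_actives"] += len(o_pick)

        # paired measurements: same compound measured at both partners
        v_h = rng.normal(spec.human_pchembl_mean, spec.human_pchembl_sd,
                         size=len(p_pick))
        v_o = v_h + rng.normal(0.0, spec.concordance_sd, size=len(p_pick))
        su = np.where(rng.random(len(p_pick)) < 0.8, "nM", "uM")
        st = np.where(rng.random(len(p_pick)) < 0.5, "IC50", "Ki")
        at = np.where(rng.random(len(p_pick)) < 0.7, "binding", "functional")
        for k, (_, cpd) in enumerate(p_pick.iterrows()):
            paired_rows.append({
                "compound_id": cpd["compound_id"], "smiles": cpd["smiles"],
                "human_accession": human_acc, "orthologue_accession": ortho_acc,
                "orthologue_species": species,
                "human_pchembl": float(v_h[k]), "ortho_pchembl": float(v_o[k]),
                "standard_units": su[k], "standard_type": st[k],
                "assay_type": at[k],
            })
        ledger["n_paired"] += len(p_pick)

        # planted conflicts: orthologue active also inactive at the human partner
        conflict_mask = rng.random(len(o_pick)) < spec.conflict_rate
        conflicted = o_pick[conflict_mask]
        pubchem_rows += _activity_rows(
            rng, spec, conflicted, human_acc, "human", "pubchem-like", "inactive",
            dates=_dates(rng, spec.date_span, len(conflicted)))
        ledger["n_conflicts_planted"] += int(conflict_mask.sum())

        # background measured inactives from unrelated clusters
        bg = lib[~lib["cluster"].isin([h_cl, o_cl])]
        bg_pick = bg.iloc[rng.choice(len(bg), size=min(spec.n_measured_inactives,
                                                       len(bg)), replace=False)]
        pubchem_rows += _activity_rows(
            rng, spec, bg_pick, human_acc, "human", "pubchem-like", "inactive",
            dates=_dates(rng, spec.date_span, len(bg_pick)))

        ledger["targets"][human_acc] = {
            "orthologue_accession": ortho_acc, "species": species,
            "n_human_actives": len(h_pick), "n_ortho_actives": len(o_pick),
            "n_conflicts": int(conflict_mask.sum()),
        }

    def _table(rows):
        df = pd.DataFrame(rows)
        if len(df):
            for col in ("pchembl", "standard_value"):
                df[col] = pd.to_numeric(df[col])
            df["activity_comment"] = df["activity_comment"].astype("string")
        return df

    return {
        "library": lib,
        "chembl": _table(chembl_rows),
        "pubchem": _table(pubchem_rows),
        "homologene": pd.DataFrame(homologene_rows),
        "paired": pd.DataFrame(paired_rows),
        "ledger": ledger,
    }


def write_fixture_tables(tables: dict, outdir) -> dict:
    """Write the generated tables as TSVs; returns the path map."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("chembl", "pubchem", "homologene", "paired"):
        p = outdir / f"{name}.tsv"
        tables[name].to_csv(p, sep="\t", index=False)
        paths[name] = str(p)
    lib_path = outdir / "library.smi"
    with open(lib_path, "w") as fh:
        for _, row in tables["library"].iterrows():
            fh.write(f"{row['smiles']}\t{row['compound_id']}\n")
    paths["library"] = str(lib_path)
    return paths
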