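# orthopred

Orthologue-aware ligand-based target prediction.

Target-prediction models infer the protein targets of a compound from
the similarity of its structure to known ligands, one classifier per
protein. Most pipelines train only on human bioactivities and discard
the measurements made at *orthologues* — the closest relatives of a
human gene in rat, mouse, bovine and other species — even though
orthologues share function and often share ligands. `orthopred`
implements the full workflow for exploiting that data, and the audits
that tell you whether doing so is defensible for your targets:

1. **Curation** — ChEMBL-style actives (pChEMBL = −log₁₀ molar
   Ki/Kd/IC50/EC50 ≥ 5, i.e. ≤ 10 µM, in binding/functional assays with
   confidence score > 5, or comment-declared actives) and PubChem-style
   inactives; structure standardization (largest fragment, neutralize,
   canonical tautomer) and drug-likeness filters (carbon required,
   100–1000 Da, no atoms with Z in 21–32, 36–52 or ≥ 54).
2. **Orthologue merge** — HomoloGene-style groups re-assign orthologue
   actives to the mapped human accession, duplicates removed with the
   human copy winning; targets need ≥ 10 actives to be modelled, and
   targets that reach the threshold only through orthologues are
   flagged as newly enabled.
3. **Audits** — cross-species conflict counting (identical standardized
   SMILES active at one partner, inactive at the other), pChEMBL
   concordance (paired R², median |ΔpChEMBL|, fraction active in both
   species), protein-change binning, and ECFP\_4 nearest-neighbour
   chemical-space analysis.
4. **Negatives** — putative inactives sampled from a background pool by
   sphere exclusion: nothing within Tanimoto 0.424 of any active, up to
   a 1:100 active:inactive ratio.
5. **Models** — per-target random forest (5/50/500 trees), Bernoulli
   naive Bayes (α = 1.0/0.1) and linear SVM (C = 1e−2/1/1e2)
   classifiers on 2048-bit ECFP\_4 fingerprints, class-balanced and
   Platt-calibrated (two-fold sigmoid) so outputs are probabilities.
6. **Evaluation** — five-fold time-series cross-validation (every test
   compound strictly newer than its training set), scored with
   precision/recall/F1 at p > 0.5, PR-AUC and BEDROC (α = 20), paired
   before/after orthologue inclusion; plus an external-validation
   harness for any labelled bioactivity table.

A synthetic-fixture generator emulates all three input shapes
(clustered drug-like SMILES library, bioactivity tables, homology
groups) with controllable conflict rate and concordance noise, so
everything is testable without downloads.

## Worked example

Generate a six-target synthetic study with a planted 5% conflict rate,
then run the audits:

```sh
orthopred make-fixtures --outdir fx --n-targets 6 --pool-size 600 \
    --conflict-rate 0.05 --seed 7
orthopred audit --config run.cfg --paired fx/paired.tsv
```

(where `run.cfg` points at the generated tables; see
`pipeline.RunConfig.to_file`). This prints:

```
forward conflicts: 6 of 90 mapped (93.33% compatible; 50.0% of pairs conflict-free)
reverse conflicts: 0 of 180 mapped (100.00% compatible)
concordance: R²=0.475, median |Δ|=0.51, both-active 95%
```

Reading: of the 90 orthologue actives mapped onto human targets, 6
(≈ the planted 5%) are annotated inactive at the human partner, so the
annotations are 93.3% compatible; no human active conflicts with an
orthologue inactive; and the paired human/orthologue affinities agree
with a squared Pearson correlation of 0.475, a median disagreement of
0.51 pChEMBL units, with 95% of compounds active (pChEMBL ≥ 5) in both
species. The same objects are available as a library:

```python
from orthopred import fixtures, pipeline

tables = fixtures.generate_bioactivity_tables(fixtures.FixtureSpec(seed=7))
build = pipeline.run_build(pipeline.RunConfig(seed=7), tables=tables)
print(build.conflicts_fwd.compatibility_pct)
```

`orthopred build`, `train`, `cv`, `sample-negatives`,
`external-validate` and `benchmark` chain the remaining stages; every
command is deterministic under a fixed seed.

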