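# Methods

## Curation model

A bioactivity record is a compound–target measurement with species,
affinity and assay metadata. Affinities are handled on the pChEMBL
scale (−log₁₀ molar; 5 ⇔ 10 µM). Only nM/µM/mM/M/pM units are
converted; anything else (percent effects, mg/kg doses) is rejected
with the unit named rather than guessed. A record counts as *active*
when it comes from a binding or functional assay with target-assignment
confidence strictly greater than 5 and either pChEMBL ≥ 5 or an
activity comment declaring it active; percentage activation/inhibition
records therefore carry a label but no affinity. Duplicate measurements
of one structure at one target and species collapse to the earliest
record date, so the chronological cross-validation sees each structure
once, at first appearance.

Structures are standardized with RDKit: largest fragment, charge
neutralization where valence allows, explicit-hydrogen removal and a
canonical tautomer. The canonical-tautomer step is RDKit's enumerator;
string-level agreement with other vendors' standardizers is not
promised — idempotence and invariant preservation are, and both are
tested. Drug-likeness filtering requires carbon, molecular weight in
[100, 1000] Da and no atom with atomic number in 21–32, 36–52 or ≥ 54.
The last interval is deliberately open at 54 so that iodine (Z = 53)
passes, consistent with drug-like halogen chemistry; the intervals are
configuration, not constants.

When the same (structure, target) pair is active in the curated-source
table and inactive in the screening-source table, the active annotation
wins, on the grounds that curated affinity measurements are more
trustworthy than high-throughput inactive flags; the number of such
resolutions is reported.

## Orthologue merge and audits

Homology groups pair each human accession with its orthologues and
carry the repository's protein-change ratio (fraction of differing
amino acids). Orthologue actives are re-assigned to the mapped human
accession; duplicate SMILES keep the human-provenance copy, and an
orthologue active overrides a measured inactive of the same structure
at the human target. Targets need ≥ 10 actives (configurable) to be
modelled; targets that pass only because of orthologue additions are
reported as newly enabled.

Conflict identity is exact standardized-SMILES equality — no similarity
fuzz — which makes the audit deterministic and mirrors the
duplicate-removal convention of the merge. Counts are mapping-level: a
compound reached through several homology mappings counts once per
mapping. The report carries, per mapping and in total, the number
mapped and conflicting, the compatibility percentage
100·(1 − conflicting/mapped) and the fraction of mappings with no
conflict at all; both directions (orthologue-active vs human-inactive
and the reverse) are computed.

Concordance uses squared Pearson correlation of paired human and
orthologue pChEMBL values — matching the linear-regression framing of
the analysis — grouped by standard units, standard type and assay
type; groups with fewer than three pairs report NaN, never zero.
Discordance is |ΔpChEMBL|, summarized by its median, and the
both-active fraction uses the pChEMBL 5 cutoff. Protein-change binning
assigns pairs to [0, w), [w, 2w), … bins (default width 0.1) and
reports per-bin median discordance plus the trend R² between the
protein-change ratio and discordance; a constant-discordance input is
defined to have trend R² = 0.

## Chemical space

Fingerprints are 2048-bit binary Morgan fingerprints of radius 2
(ECFP\_4 equivalent). Folding collisions are accepted as inherent;
determinism, not collision-freedom, is the tested contract. The
Tanimoto coefficient of two all-zero fingerprints is defined as 1
(identical objects) with a logged warning — the case cannot arise for
curated, carbon-containing chemistry. Nearest-neighbour similarity is
the maximum Tc to a reference set, excluding self-pairs by compound id;
intra-group similarity is the leave-one-out maximum and is undefined
(an error) for singletons.

## Negative sampling

Putative inactives are drawn from a background pool under sphere
exclusion: any pool compound whose nearest-neighbour Tc to the actives
reaches the exclusion radius is ineligible, and the shortfall below
ratio·|actives| − |measured inactives| is drawn by a seeded uniform
shuffle of the eligible remainder. The default radius 0.424 is the
reported 95% nearest-neighbour similarity radius of curated actives,
and the default ratio is 1:100; both are configuration. No mutual
dissimilarity among the sampled inactives is enforced (the upstream
protocol leaves this ambiguous); a flag reserves the option. A post-hoc
brute-force check that no sampled compound violates the radius runs in
the test suite.

## Models and calibration

Per-target classifiers are scikit-learn estimators with the benchmark
grid: random forests of 5/50/500 trees (√n\_features per split,
unlimited depth, balanced class weights), Bernoulli naive Bayes with
α ∈ {1.0, 0.1}, and linear SVMs with C ∈ {1e−2, 1, 1e2}. Class
imbalance is additionally countered with balanced sample weights at
fit time. Calibration is two-fold Platt scaling: the training data are
split into two stratified halves (stratified is a choice, documented
here, since only the fold count is prescribed), a classifier is fitted
on one half and a sigmoid on its held-out scores, both ways, and the
two calibrated probabilities averaged. With this ensemble the averaged
output is not formally guaranteed to preserve the raw-score ranking of
a single classifier; a single-calibrator mode (`ensemble=False`) is
provided where rank preservation is exact, and the standalone Platt
fit is sigmoid-monotone by construction. The standalone
`fit_platt` maximizes the Bernoulli likelihood with Platt's smoothed
targets t₊ = (N₊+1)/(N₊+2), t₋ = 1/(N₋+2) by Nelder–Mead on a stable
log-sum-exp objective; it is cross-checked in the tests against both a
brute-force grid search of the negative log-likelihood and
scikit-learn's sigmoid calibration. Seeds are explicit everywhere; no
global RNG state is touched.

## Evaluation

Chronological folds follow the expanding-window convention: records
sorted by date (missing dates last, stable), test blocks of size
⌊n/(n\_splits+1)⌋ ending at the newest record, each fold training on
everything strictly older; the oldest block is never tested. Inactives
that lack dates (sampled putatives) inherit evenly spaced dates across
the observed range by insertion order, so folds remain defined; this
is a convention, documented here, not data.

Precision is reported as undefined (NaN), never zero, when no compound
is called positive. PR-AUC is interpolation-free step summation
(average precision) with tied scores grouped. BEDROC implements the
Truchon–Bayly formula

    RIE    = Σᵢ exp(−α·rᵢ/N) / [ (n/N)·(1−e^{−α}) / (e^{α/N}−1) ]
    BEDROC = RIE · Ra·sinh(α/2) / (cosh(α/2) − cosh(α/2 − α·Ra))
             + 1 / (1 − e^{α(1−Ra)})

with α = 20 by default, ties broken by stable input order with a
logged warning, and the all-active degenerate case defined as 1. Per
target, predictions are pooled across all test folds before metrics
are computed ("across all folds per target"); aggregates across
targets are median and interquartile range, since a bare "±" is
ambiguous. The paired benchmark requires identical target lists in
both arms and reports per-target F1 deltas and the share of targets
with stable-or-improved F1. Whether the sphere-exclusion sample should
be redrawn per fold is left off by default (one global sample), since
per-fold resampling would change the inactive sets between arms.

## Synthetic fixtures: what they emulate and what they do not

The library is a combinatorial scaffold × linker × terminal enumeration
over 13 drug-like cores, standardized and deduplicated; the cluster
label is the scaffold, so intra-cluster similarity exceeds
inter-cluster similarity on average. Each synthetic target draws its
human actives from one cluster and its orthologue actives from a
different cluster, so orthologue chemistry genuinely extends the
modelled space; background inactives come from the remaining clusters.
Planted conditions: conflict rate 0.011 (each orthologue active is
independently duplicated as a human inactive with that probability —
the regime observed in real cross-species audits), paired affinities
human ~ N(6.8, 0.7) with orthologue noise N(0, 0.75), chosen once so
the planted population values sit at the observed cross-species regime
(median |ΔpChEMBL| ≈ 0.51, paired R² ≈ 0.47, both-active ≈ 96% at
cutoff 5), and dates uniform over 2001–2015.

What passing tests on these fixtures show: the pipeline's bookkeeping,
determinism and statistical summarizers recover planted truth within
sampling tolerance. What they do not show: real-data behaviour. The
library spans a far narrower chemical space than a bioactivity
database, there is no structure–activity noise, no assay
heterogeneity, and the planted actives/inactives are cleanly separable
in fingerprint space — which is why synthetic cross-validation F1 and
BEDROC values saturate near 1.0 and should not be read as performance
estimates for real targets.

## Problem sizes and numerical choices

The acceptance script runs the audit-scale study at 6 targets × (40
human + 60 orthologue) actives with 45 affinity pairs per target from
a 1400-compound library (6 targets keeps the human and orthologue
cluster sets disjoint), and the benchmark-scale study at 6 targets ×
(30 + 15) actives with a 1:20 sampling ratio over the full
eight-setting grid — sizes chosen so a complete run takes a few
minutes on one CPU while leaving the planted statistics resolvable.
Unit conversion round-trips to 1e−9 relative tolerance; Pearson R² is
NaN for fewer than three pairs or zero variance; Nelder–Mead tolerances
for the Platt fit are 1e−9 (parameters) and 1e−12 (objective).

## Known limitations

* Orthologue transfer is all-or-nothing per mapping; no weighting by
  protein-change ratio or species is applied (the audits exist to
  inform that decision, not to make it).
* Non-molar affinity units are rejected rather than converted.
* The tautomer canonicalizer differs from commercial standardizers at
  the string level for some inputs.
* Pathway/disease coverage joins, sequence alignment and structural
  superposition analyses are out of scope.
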