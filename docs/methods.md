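# Methods

## Median-effect dose-response model

Single-agent response is modelled by the mass-action median-effect equation
`fa/fu = (D/Dm)^m`, with `fa` the fraction affected (1 − control-normalized
viability), `fu = 1 − fa`, `Dm` the median-effect dose (µM; reported as the
IC50) and `m` the sigmoidicity. Replicate luminescence is averaged at the
raw level before normalization; viability above 1 (apparent stimulation) is
clipped to 1 and counted. The linearization `log(fa/fu) = m log D − m log Dm`
is fitted by unweighted OLS.

Numerical choices:

* `fa` is clipped to `[1e-4, 1 − 1e-4]` before the log-odds transform;
  points landing on the clip boundary carry no effect information and are
  excluded.
* The regression is restricted to doses with `fa ≥ 0.1`. Under
  multiplicative (CV-type) assay noise the standard deviation of
  `log(fa/fu)` scales as `ε/fa`, so doses with near-zero true effect turn
  pure noise into extreme leverage points that can destroy the slope; doses
  near complete kill remain precise (the error of `log fu` is the relative
  luminescence error) and are kept. When fewer than 3 doses pass the floor,
  the unclipped points nearest `fa = 0.5` are added deterministically, so
  steep curves on sparse 1:3 ladders stay fittable and noiseless data is
  still reproduced to machine precision.
* The 4PL fit (`scipy.optimize.curve_fit`, bounded) is a diagnostic only;
  with bottom 0 / top 1 the 4PL and median-effect curves coincide, and the
  two IC50 estimates agree within 10% on clean data.

## Combination index

The two-term ("mutually exclusive") Chou–Talalay index is used:
`CI = d1/Dx1(fa) + d2/Dx2(fa)`, with `Dx_i(fa) = Dm_i (fa/fu)^{1/m_i}` and
`fa` the *measured* effect of the dose pair (non-constant-ratio design:
drug 1 serial dilution × fixed partner doses). The variant without the
cross term is the field standard reported by common synergy software.
Interaction calls use an additive band of `[0.9, 1.1]` (configurable); the
lowest-CI search is restricted to cells with `fa ≥ 0.2` by default because
low-effect CI estimates are noise-dominated, and the unrestricted minimum
is reported alongside.

Known limitation: the lowest CI is an extreme-value statistic over ~48
noisy cells and is therefore biased low on truly additive surfaces (mean
≈ 0.86 at 5% luminescence CV on the default grid). Planted synergy is
called reliably; a truly additive model may still dip under the band in a
sizeable fraction of replicates. The per-model summary table therefore also
carries the near-unbiased unrestricted minimum, and the noiseless oracle
(below) pins CI = 1 exactly. "Viability decrease" for fixed-dose
combinations is reported both as percentage points of control-normalized
viability and as a relative decrease.

## Limiting-dilution (single-hit) model

Wells are positive when at least one active cell was seeded:
`P(negative | dose d) = exp(−f d)`, giving a binomial likelihood with
`p(d) = 1 − exp(−f d)`. The MLE of `log f` — equivalent to a binomial GLM
with complementary log-log link and offset `log d` — is found by bounded
1-D optimisation polished by a root-find on the analytic score (machine
precision; the single-dose case reproduces the closed form
`−ln(1−p̂)/d` exactly). 95% intervals come from the profile likelihood on
`log f` (likelihood drop `χ²₀.₉₅,₁/2`), with a Wald fallback. Boundary data
(all wells negative, or saturated) yield flagged one-sided bounds rather
than pseudo-counts. Group comparisons use the likelihood-ratio test of a
common frequency versus group-specific frequencies (1 df); pairwise tables
are unadjusted with an optional Bonferroni column. No overdispersion or
multi-hit extension is fitted. (Assay protocols sometimes quote a sphere
threshold of "150 nm"; at the count level this is irrelevant, but it is
almost certainly a µm-scale typo in such protocols.)

Measured operating characteristics at the study ladder (1–500 cells/well,
12 wells/dose): profile-CI coverage 0.948 at a true frequency of 1/87
(1000 replicates); median relative bias of `1/f` below 5% for true
frequencies between 1/41 and 1/1348.

## Enrichment machinery

* **Ranking**: per-gene Spearman ρ between expression and a per-sample
  phenotype (continuous IC50 by default), mid-rank ties, zero-variance
  genes flagged at ρ = 0, descending order with gene-id tie stability.
* **Preranked GSEA**: weighted KS running sum (hit increment
  `|score|^w / Σ|score|^w`, miss decrement `1/(n−K)`, `w = 1` default);
  ES is the signed extreme (positive branch wins exact ties); the running
  sum returns to 0 at the list end by construction. Significance by
  gene-label permutation (default 10,000, seeded); NES is sign-stratified
  (ES divided by the mean permuted ES of the same sign); BH FDR across
  sets. Set-size filter 5–500.
* **ssGSEA**: per sample, the cumulative difference between the in-set
  ECDF weighted by `rank^α` (α = 0.25) and the uniform out-of-set ECDF,
  walking the genes in descending expression order. Purely rank-based, so
  invariant to monotone within-sample transforms. Optional min-max
  normalization over the whole matrix is off by default.
* **Overrepresentation**: one-sided Fisher exact (hypergeometric tail) per
  term with BH FDR; fold enrichment `(k/n)/(K/N)`; only terms with fold
  enrichment > 1 are reported. The background is the set of all tested
  genes.
* **Heatmap ordering**: rows z-scored; complete-linkage Euclidean
  clustering of rows and columns; flat labels at a requested cut.
  Cluster recovery of planted sample groups requires the informative score
  rows (e.g. the most variable pathways, mirroring a top-pathways
  selection); clustering over many null pathways dilutes the signal.

## Per-gene ANCOVA biomarker gate

For each gene, `ci ~ tpm + subtype + ic50` by least squares; the expression
term's partial F (full-vs-reduced RSS, 1 and n−4 df) is computed through
the equivalent partial-correlation identity after residualizing on the
reduced design — identical to the explicit RSS decomposition to 1e-10.
Expression enters on the natural TPM scale by default (log2(TPM+1)
optional, recorded in output metadata); subtype is a single binary
indicator (mesenchymal vs not), dropped with a flag if only one level is
present. Selection: F p ≤ 0.1 and raw Spearman ρ(tpm, ci) ≤ −0.2 (synergy
list) or ≥ +0.2 (additive list); lists are disjoint by construction; no
multiplicity correction at this step (FDR applies at the ORA stage). A
partial Spearman ρ (rank-residualized on the covariates) is emitted as an
extra column. Null genes pass the gate at the nominal 10% rate.

## Synthetic-data generators

All generators are bit-reproducible given `(seed, config)`.

* **Viability panel** (default): 14 models with `Dm1` log-spaced 0.5–5 µM,
  the five most resistant labelled mesenchymal-like; slopes `m` cycle over
  1.1–2.0; partner `Dm2` 8–15 µM. Synergy is a potency shift: drug 2
  multiplies drug 1's effective dose by `1 + α·d2/(d2 + Dm2)`, and the
  combination effect is the exact Loewe-additive response to the boosted
  dose. With `α = 0` the surface satisfies Loewe additivity exactly —
  the oracle input for the CI machinery. `α` rises linearly (0 → 2.5) with
  log-resistance, reproducing a negative IC50–CI association across the
  panel (measured mean Pearson r ≈ −0.75 at 5% noise). Noise is
  multiplicative lognormal on luminescence (CV 5% default) with 3
  replicates per condition — a typical 384-well screening layout; plate
  or edge effects are not simulated.
* **Limiting dilution**: independent Bernoulli wells with
  `p = 1 − exp(−f d)` on the 1–500 cells/well ladder, 12 wells/dose
  default.
* **Expression cohorts**: log-normal TPM baseline (mean log2 ≈ 3, SD 1.5;
  per-sample noise 0.5 log2 units), 2000 genes default. Two planted
  50-gene programs with 1.0 log2-unit effect size: a "translation" program
  elevated in drug-sensitive samples (clinical mode: the 4 sensitive of
  20; PDX mode: proportional to −log IC50) and a "synergy" program
  negatively coupled to the combination index. Because sensitivity and
  synergy are coupled by design, the two programs are collinear with
  respect to either phenotype — both always outrank the 20 random decoy
  sets, and single-signal recovery tests plant one program at a time.
  No attempt is made to simulate realistic transcriptome covariance
  beyond the planted blocks, so passing recovery tests demonstrates
  correctness of the chain, not performance on correlated real data.

## Pipeline and formats

Long-format plate CSV (`model_id, agent, dose_uM, luminescence, replicate`,
optional `dose2_uM` for combination wells; dose-0 rows are vehicle
controls); wide 384-well grids enter via a well→metadata layout map. Doses
are µM everywhere; readers take only explicitly unit-tagged columns. Well
counts as CSV, expression/phenotypes as TSV, gene sets as GMT, run manifest
as JSON. Output tables are TSV with fixed column order, 10 significant
digits and a leading comment carrying the manifest hash; the hash covers
parameters and input content (not paths), so reruns with identical inputs
and seed are byte-identical. Config validation runs before any compute.

## Problem sizes in tests

The test suite uses the study-scale defaults throughout (14 models, 48-cell
grids, 12 wells/dose, 2000-gene cohorts), with replicate counts per check
chosen for stable Monte-Carlo estimates: 100 seeds for interaction-call and
sign-recovery rates, 1000 profile-CI coverage replicates (4000 for the
rarest limiting-dilution frequency, whose discrete estimate needs more
draws near the bias bound), 200 seeds for GSEA null calibration and 500 for
the ANCOVA gate rate.
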