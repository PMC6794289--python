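# Methods

## The decay model and what sequencing observes

Each gene `g` has a baseline abundance `a_g > 0` (arbitrary molecule
units) and a decay rate `λ_g ≥ 0` per hour. Post-mortem, with no new
transcription, abundance follows a pure exponential `a_g e^{-λ_g t}`.
Sequencing at a fixed depth `L` observes only composition: the expected
count of gene `g` at PMI `t` is `μ_g = L · p_g(t)` with

    p_g(t) = a_g e^{-λ_g t} / Σ_h a_h e^{-λ_h t}.

Two consequences shape everything downstream. First, a uniform rate shift
cancels exactly (only rate *differences* are observable), so "preserved"
and "degraded" are intrinsically relative labels. Second, when a large
abundance mass decays, every other gene's relative abundance genuinely
rises — such calls are true discoveries on the relative scale, not
artifacts.

Replicate noise is negative-binomial via an explicit gamma–Poisson
mixture: counts have mean `μ` and variance `μ + φ μ²` with `φ = BCV²`.
`BCV = 0.1` is the conventional level for genetically identical model
organisms and `0.4` for human data; the simulator defaults to 0.1.
`BCV = 0` takes an exact Poisson branch rather than a degenerate NB.

Decay classes default to 10% stable (λ ∈ [0, 0.002]/h), 80% background
(λ ∈ [0.02, 0.06]/h) and 10% fast (λ ∈ [0.1, 0.3]/h). No study reports
per-gene post-mortem rate magnitudes, so these were fixed once to
reproduce the qualitative behaviour of the system — few calls within the
first hour, non-empty preserved and degraded sets by 24 h — and are fully
configurable. Baseline abundances are log-normal (log-SD 1.0). The default
sequencing depth is 10⁶ reads/sample, a desk-scale stand-in for the ~40 M
reads of a production run; all rate/power statements in the tests are made
at this depth.

The qPCR simulator writes `Ct = c₀ − log₂(a_g e^{-λ_g t}) + N(0, σ)` with
amplification efficiency fixed at 2 and `σ = 0.25` cycles by default — a
transcript halving per hour gains exactly one cycle per hour. Homolog maps
assign each source gene 0 targets (11% by default, matching typical
mouse→human dropout), 2–3 targets (multi-mapped), or exactly 1.

## Dispersion estimation

BCV is estimated by maximising the Cox–Reid adjusted profile likelihood
(APL): at each candidate `φ`, group means are profiled out by Fisher
scoring on `log p` with `log L_s` offsets, and half the log observed
information of the mean parameters is subtracted. The adjustment matters:
the plain profile MLE at n = 4 replicates is biased low by roughly the
fraction of degrees of freedom the means consume, which alone would exceed
a ±10% recovery band. The common estimate maximises the mean APL over all
genes (bounded scalar optimisation on log φ in [10⁻⁶, 5]).

Tagwise (per-gene) estimates use weighted-likelihood empirical Bayes: gene
`g` maximises `APL_g(φ) + (prior_df / residual_df) · mean_APL(φ)` on a
φ-grid that always contains 0 and the common estimate, so `prior_df → ∞`
recovers the common value exactly and `prior_df = 0` the per-gene MLE.
The default `prior_df = 10` matches common practice. Singleton groups
carry no replicate information and are dropped from estimation.

## Testing and classification

Each non-zero PMI is contrasted against the 0 h group by a likelihood-
ratio test at fixed (tagwise) dispersion: the full model fits one relative
abundance per group, the null one shared value, and `2(ℓ_full − ℓ_null)`
is referred to χ²₁. p-values are BH-adjusted within each contrast (one
family per timepoint, matching per-timepoint reporting), and genes are
classified preserved (q ≤ 0.05, logFC > 0), degraded (q ≤ 0.05,
logFC < 0) or not-DE. The boundary is inclusive (q = 0.05 counts).
logFC is `log₂` of the pseudocounted (0.5 CPM) group-mean CPM ratio; the
pseudocount avoids infinities for empty groups but biases |logFC| toward 0
at low abundance — power statements in the tests therefore pin exact
fold-change bands on well-expressed genes only. p-values are clipped into
(0, 1]; a numerically negative LR statistic is truncated at 0.

Expression filtering (CPM ≥ 1 in ≥ 4 samples) is applied once across all
samples of an experiment before any testing; a flag switches to
within-timepoint counting since the original rule's scope is ambiguous.

**Validated behaviour.** With the true or common dispersion the LRT is
well calibrated at this design (null tail inflation ≤ 4% at p < 0.005
over 10 × 5,000-gene null simulations; KS-uniform at the 95% level).
Plugging in *tagwise* estimates is mildly anticonservative under an LRT:
genes whose replicate variance sampled low receive both a small φ̂ and a
small p (measured FDP 0.068 vs 0.045 at nominal 0.05 in the benchmark
below). This selection feedback is precisely what quasi-likelihood F-tests
absorb in production DE tools; it is the main caveat of the LRT design
choice and is documented rather than hidden. The FDR benchmark pairs the
test with the common estimator, which is also the analysis matched to the
generator (one shared BCV for all genes).

**FDR benchmark design.** 20 replicate simulations, 5,000 genes, 4 vs 4
replicates at 24 h, 10% of genes decaying 4-fold. The decayed genes'
baseline abundances are scaled ×0.1 so they carry ≈1% of library mass:
with a full 10% mass share, every null gene's relative abundance would
genuinely rise by ~0.11 log₂ — a *true* compositional signal that would be
miscounted as false discovery under class-label truth. Keeping the decayed
mass small isolates what the benchmark is meant to measure (error-rate
calibration of test + BH) from the compositional relabelling effect, which
is validated separately: with 10% non-decaying genes against a decaying
background, their expected proportions strictly increase in `t` and ≥ 90%
of them are called preserved at 24 h at sequencing scale.

## Marker selection

Candidates must hold per-timepoint BCV < 0.075 (unshrunk per-gene MLE
within each replicate group) at 0/3/6/12/24 h. For each candidate, the
mean log₂(CPM + 0.5) per timepoint is standardised across timepoints
(sample SD, n−1; constant timelines map to all-zero Z), and Z is regressed
on hours by OLS. "Visually consistent slope" is operationalised as
R² ≥ 0.8 — a reproducible surrogate for the by-eye screen, exposed in
config. The selection takes the 9 largest positive and 9 most negative
slopes among eligible genes, breaking slope ties by lexicographic gene ID
so the result is order-independent. Note that with one shared BCV in the
simulator, the per-timepoint filter passes genes whose *realised*
replicate variance sampled low; real data additionally have gene-level
variance heterogeneity that the generator does not emulate.

## PMI estimation

Raw Ct values are normalised within each animal by subtracting the
animal's mean Ct across the panel (ΔCt), removing per-animal template
amount without a housekeeping gene; normalisation is idempotent-guarded
(a second call errors) and per-animal shift-invariant. Every 3-gene
combination of the panel is fitted by OLS, `PMI ~ 1 + ΔCt₁ + ΔCt₂ + ΔCt₃`,
and screened on the overall F-test p-value. The filter direction is a
flag: the default keeps p ≤ threshold; the opposite (≥) reading is
available because the originating protocol's wording is ambiguous.
Singular designs (e.g. noise-free panels, where all ΔCt columns are
proportional to `t`) are skipped with a logged count, not an error. The
final estimate is the unweighted mean of retained models' predictions
(median available, off by default), unclipped — negative hours are
reported as-is. Evaluation is leave-one-animal-out; because normalisation
is within-animal, training and test animals share no fitted scaling and
leakage is structurally impossible.

On the synthetic 18-gene panel (9 slow decayers λ ∈ [0, 0.02], 9 fast
λ ∈ [0.1, 0.25]/h, 0.25-cycle noise, PMIs 0/6/12/18/24 h × 4 animals) the
LOAO MAE is ~0.3–0.5 h, comfortably inside the 2 h acceptance band.

## Homolog overlap

Gene sets are mapped to a shared namespace before any set operation:
unmapped sources are dropped and multi-mapped sources keep the target with
the lowest numeric ID suffix (deterministic and order-independent).
Overlap tables satisfy the exact identities `overlap + exclusive_a = |A|`
(and likewise for B). The cross-comparison ratio divides total
between-tissue (intra-species) overlap by total between-species
(intra-tissue) overlap; the strata are passed explicitly because multiple
readings exist, and the default pipeline computes species overlap at the
0–6 h and 0–24 h contrasts.

## Pipeline, determinism, numerics

One master seed drives everything: per-stage seeds derive from a
`SeedSequence`, every table begins with `#seed` and `#config_hash` comment
lines, and identical configs yield byte-identical reports. Unknown config
keys are rejected. Numerical guards: per-gene mean fits floor proportions
at 10⁻¹², dispersion optimisation is bounded in [10⁻⁶, 5], Fisher-scoring
steps are clamped at ±5 on the log scale, and BH is delegated to
statsmodels with the exhaustive step-up definition kept as a test oracle.

Default problem sizes (15,000 genes × 36 + 16 samples for the pipeline;
10,000 × 4 for dispersion recovery; 20 × 5,000 × 8 for the FDR benchmark;
2,000 genes for null calibration) were chosen as desk-scale versions of
the full study that keep a complete run to about a minute on one CPU.

## Known limitations

- The generator has no gene-level BCV heterogeneity, no cell-type
  mixtures, no rRNA/RIN dynamics, and no batch structure; passing tests
  show the machinery is correct under the stated model, not that real
  retina/RPE data meet its assumptions.
- The LRT with tagwise plug-in dispersions is mildly anticonservative
  (see above); for dispersion-heterogeneous real data a quasi-likelihood
  F-test is the stronger choice and is out of scope here.
- The Ct model assumes perfect amplification efficiency (2.0) and Gaussian
  cycle noise; efficiency correction and reference-gene schemes are not
  modelled.
- PMI estimates extrapolate linearly outside the training PMI range and
  are deliberately not clipped.
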