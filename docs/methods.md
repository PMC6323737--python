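# Methods

## Background and model

A developmental program such as flower formation can be described as a
dynamical system that passes through three regimes: a stable
before-transition state, a critical transition state just before a
bifurcation, and a stable after-transition state. Close to the
bifurcation, generic early-warning behaviour appears in a restricted
group of genes — the dynamic network biomarker (DNB) module: the
deviations of its members inflate sharply, the members become strongly
mutually correlated, and their correlation with the rest of the
transcriptome weakens, while no comparable change happens among
non-member genes.

For a candidate module *d* evaluated in one case–control window, the
three signatures are summarized by the composite index

```
CI = (SD_d · PCC_d) / PCC_o
```

where `SD_d` is the mean standard deviation of the member genes across
the window's case samples, `PCC_d` is the mean Pearson correlation over
all member pairs, and `PCC_o` the mean correlation between members and
all non-members. Scanning CI over a sequence of windows and taking the
peak locates the tipping point; the peak window's best-scoring module is
the DNB gene set.

Among the DNB genes a directed regulatory network is then inferred in
the NARROMI style: mutual information (MI) between gene pairs screens
out weakly dependent regulator candidates (noise reduction), a
recursive-optimization (RO) regression prunes redundant and indirect
regulators per target (redundancy reduction), and the two strengths are
merged per edge as

```
β = sign(β_RO) · (ω·|β_RO| + (1−ω)·β_MI)
```

## Pipeline conventions

**Windows.** A time course with T time points is split into T−1
case–control windows: window *k* uses time point *k* as the reference
(control) state and time point *k*+1 as the tested (case) state. A
14-point series therefore yields 13 windows, a 15-point series 14.

**Standardization.** Case values are standardized gene-wise by the
control mean and control SD (n−1 denominator), so deviations are
expressed relative to the reference state and comparable across windows.
Because the control SD is estimated from very few replicates (2 degrees
of freedom at triplicate designs), the per-gene control variance is
moderated toward the cross-gene median variance with `shrink_df = 3`
prior degrees of freedom (the same logic as limma's variance
moderation). Without it, division by an accidentally tiny control SD
turns ordinary background genes into spurious high-deviation clusters —
on planted-transition simulations with 3 replicates this single artifact
dominated the CI curve. The moderation vanishes as replication grows and
is exactly the identity for a single-gene dataset. Genes constant in the
control samples fall back to an `ε_sd = 1e−8` floor.

**Correlations.** PCC_d and PCC_o average *absolute* correlations: the
DNB conditions concern correlation strength, and signed averaging can
cancel opposing pairs. PCC_o is floored at `ε_pcc = 1e−6` in the CI
quotient so a perfectly isolated module keeps a finite score.

**Candidate modules.** Average-linkage hierarchical clustering on the
distance 1 − |PCC|, tree cut at `cut_height`; all clusters with at least
`min_size` (default 5) genes are scored. The default cut height is 0.35.
This was calibrated on the synthetic generator's ground truth: with 6–12
samples per window the null distribution of a sample correlation is wide
(SD ≈ 0.3–0.45), so at a cut of 0.5 a background gene whose chance
correlation to the module's latent factor exceeds ~0.5 is absorbed into
the module — about 50–100 false members per 470 background genes at the
default simulation scale. A cut of 0.35 keeps the planted module intact
while absorbing few background genes. Both parameters are exposed;
larger sample counts tolerate larger cuts.

**Neighbor pooling.** With triplicate time points, correlation matrices
estimated from 3 case samples are too noisy to cluster. Samples from
other time points within `neighbor_interval` of the case time can be
pooled into the case side. Pooling feeds only the correlation statistics
(clustering, PCC_d, PCC_o); SD_d is always computed on the window's own
case samples. The reason is asymmetry of the two estimators: per-gene SD
is estimable from 3 samples and is the quantity that must stay local to
the window, whereas correlations need the extra samples and keep most of
their structure under pooling (the high-variance transition samples
dominate the pooled correlation). Pooling the SD as well leaks the
transition signal into neighbouring windows — their neighbor pool
contains the active time point — and halves window-recovery rates in
simulation. The per-window case-sample count (n) is written to
`ci_curve.tsv`.

**Tie-breaking.** Wherever an argmax is taken the earliest window wins,
and within a window the lexicographically smallest module; detection is
therefore fully deterministic given inputs and parameters.

**Bootstrap.** The observed module's CI is compared with `n_boot`
(default 1000) uniformly drawn gene sets of the same size in the same
window; p = (1 + #{CI_rand ≥ CI_obs}) / (1 + n_boot), so p ∈ (0, 1].

## Network inference

**MI estimator.** Plug-in MI (nats) on equal-frequency bins
(`bins = ⌈√n⌉` by default), computed rank-wise so the null distribution
of MI between independent genes depends only on (n, bins). The default
screening threshold is the 95th percentile of a 200-permutation null;
with equal-frequency labels one simulated null serves all pairs.

**RO regression.** The steady-state linearization of a kinetic
transcription model makes each target a linear combination of its
candidate regulators. The fit minimizes the sum of absolute residuals
plus λ·Σ|β| (λ = 0.01), solved as a linear program (HiGHS dual simplex,
deterministic). The regulator of smallest |β| is then removed and the LP
re-solved for as long as the residual stays within a factor
(1 + δ_fit), δ_fit = 0.05, of the full-model fit — leaving a minimal
direct-regulator set with zeros for eliminated regulators. This
implements the described recursive redundancy reduction without claiming
bit-compatibility with any particular historical implementation.

**Combination.** β_MI is min–max scaled to [0, 1] across all screened
pairs so the MI and regression terms are commensurable; ω defaults to
0.5; sign(0) = 0, so an RO-eliminated regulator carries no combined
strength. Edges with |β| below `beta_threshold` (default 0.05) are
dropped. A pair supported in both directions is reported as two edges.

**Sample size.** Three case replicates cannot support inference; the
pipeline pools case samples of the tipping window ± 1 window by default
(`pool_windows`), logged in the manifest.

## Synthetic data

`simulate_transition` plants the three DNB signatures at exactly one
window of a replicated Gaussian time course: at the case time point of
the tipping window each of the m module genes becomes
`g·σ·(√ρ·z + √(1−ρ)·e_i)` with a latent factor z shared within a
replicate, so the expected per-gene SD is g·σ, the within-module
correlation ρ, and the module/background correlation 0. Defaults —
500 genes, 30-gene module, 10 time points × 6 replicates, g = 5,
ρ = 0.9, σ = 1 — are the conditions used throughout the recovery
benchmarks; the two flowering study layouts (14 × 3 and 15 × 3) are
exercised with the transition planted at windows 11 and 8 respectively.
Everything else (background genes, module genes away from the tipping
window) is stationary independent noise.

What the generator deliberately does not emulate: mechanistic
bifurcation dynamics, autocorrelation along the time axis, heavy-tailed
or platform-specific noise, probe-level artifacts, or a transition that
persists after its window. Passing the recovery tests therefore shows
the statistics and the search behave correctly under the model's own
assumptions, not that real microarray data meet those assumptions.
Gaussian noise is used throughout because the objects under test are
SD/PCC statistics, not distributional robustness.

`simulate_grn` draws a sparse signed coefficient matrix (no self-loops,
spectral radius rescaled to 0.8 so a stable steady state exists) and
samples i.i.d. steady states `x = (I−B)^{-1}·ε`. Note the inference
benchmark scores directed recovery, and a linear steady-state ensemble
is nearly symmetric in each linked pair, which bounds attainable AUROC
below 1 even for a perfect dependence detector.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the recovery benchmark at
50 seeds (500 × 60 matrices), the null uniformity check at 100 seeds,
bootstrap calibration at 200 null repetitions (100-gene datasets,
n_boot = 200) plus one planted run at n_boot = 1000, and the network
benchmark at 30 seeds (10 genes, 200 samples). These sizes were chosen
so each property is measured with usable statistical resolution while
the whole suite completes in a few minutes on one core.

## Known limitations

- The clustering cut and minimum module size interact with sample count;
  the shipped defaults are tuned for 6–12 samples per window.
- CI values are comparable across windows of one dataset but not across
  datasets (they scale with the deviation units).
- The GEO flowering datasets (GSE64581, GSE21396) are not bundled and
  are not downloaded; the corresponding end-to-end checks run on
  synthetic data with the same designs. Reproducing the published curves
  additionally depends on preprocessing and threshold choices that are
  not fully specified anywhere.
- MI screening with equal-frequency binning needs n ≥ ~12 before the
  null quantile separates from the signal; below that, use an absolute
  threshold or pool more windows.
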