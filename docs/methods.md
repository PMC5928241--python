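# Methods

This note records the statistical model, the simulation design, the
numerical choices, and the limitations of `hzemeth`.

## The per-CpG mixed model

For one exposure series, the methylation proportion of probe *j* in sample
*i* is modeled as

    beta_ij = b0 + b1 * dose_i + b2 * time_i + row_i + u_chip(i) + e_ij,
    u ~ N(0, sigma_u^2),  e ~ N(0, sigma_e^2)

with dose (Gy) and time after exposure (days) as numeric covariates, chip
row as a categorical fixed effect, and a random intercept per array chip.
For the time ("drift") scan the roles of dose and time swap. Modeling dose
and time numerically follows from treating methylation change as a linear
function of exposure; the alternative (categorical time) was considered
and rejected because the drift analysis estimates a *rate* per day.

The fit is restricted maximum likelihood, profiled over the variance ratio
lambda = sigma_u^2 / sigma_e^2. Because the grouping structure is shared
by all probes with the same missingness pattern, Z Z' is eigendecomposed
once per pattern; each candidate lambda then costs a single weighted
least-squares solve in the rotated basis, and a bounded scalar
minimization over log(lambda) in [-12, 10] (xatol 1e-6) finds the REML
optimum, with lambda = 0 always evaluated as a candidate and estimates
below 1e-10 snapped to the boundary. This is what makes a 10,000-probe
scan run in seconds where a generic mixed-model fitter would take an hour;
the generic fitter (statsmodels MixedLM) is retained in the test suite as
an independent oracle and agrees with this implementation to ~1e-4 on
slopes and variance components.

Inference is a Wald t-test on the target coefficient with n − p residual
degrees of freedom, so that constraining sigma_u^2 = 0 reproduces the OLS
t-test *exactly* (verified to 1e-6 relative). With 4 chips of 12 samples
and dose randomized across chips, the dose contrast is essentially
within-chip and the n − p reference is accurate; simulated 95% CI coverage
is 0.94–0.95 and the null p < 0.001 tail rate sits inside its binomial
interval at 10,000 probes. Constant responses and singular designs are
flagged and return missing statistics; probes with fewer than 80% of
samples present after listwise deletion are skipped with a flag.

Multiplicity: Holm step-down (family-wise control; "nominal" tier at
corrected p < 0.05) and Benjamini–Hochberg q-values; a raw p < 0.001
defines the "moderate" tier. Both adjustments are closed-form and tested
for exact agreement with brute-force oracles and statsmodels.

## Preprocessing

The chain is fixed: joint quantile normalization of the stacked (M, U)
vector per sample onto the mean order-statistic reference (ties get the
reference interpolated at their average rank), beta = M/(M+U) with no
stabilizing offset, detection masking at p > 0.001, probe filtering at
>10% missing (strict), then sample filtering (call rate < 95%, mean signal
< 2,000 AU, or < 50% of the experiment-median sample intensity; any rule
suffices). Call rate and the intensity rules are evaluated on the *raw*
(pre-normalization) intensities and pre-masking detection table, and the
QC report records that basis. Quantile normalization is a fixed point on
already-normalized data, so re-running the chain on clean output is a
no-op; when probes have been removed, renormalization can shift surviving
values slightly (different ranks are deleted in different samples) —
membership decisions, however, are stable.

One consequence worth knowing: quantile normalization attenuates planted
dose effects in proportion to how much of the array is dose-responsive
(it forces all samples to share one signal distribution). At the ~2%
planted fraction used throughout, the attenuation is ≈5% of the slope; at
10% it becomes visible (~15%) and power calculations should account for it.

## The synthetic experiment

The generator emulates one exposure series of the design it models:
doses {0, 0.1, 0.3, 1} Gy × times {2, 20, 40, 56} days × 3 replicates
(48 samples), samples shuffled onto chips of 12 (6 rows × 2 columns).
Time points span the ~8-week continuous-culture window, with day 2 the
acute (48 h) collection.

The synthetic chromosome is a run of 20-kb units, each carrying a
CGI-promoter gene: island [5.0, 6.0) kb, TSS at 5.5 kb inside the island,
TES at 15 kb, 2-kb shores, gene body from the 3′ shore edge to the TES.
Odd units are mirrored on the minus strand so both orientations of the
shore and gene-body logic are exercised. Chromatin-state segments tile
each unit and align with the layout — promoter states over islands,
enhancer states over shores, transcription states over gene bodies,
polycomb/heterochromatin elsewhere — so CGI context, chromatin context and
baseline methylation are coupled the way they are on a real array:
island probes draw their baseline mostly from the unmethylated mixture
mode, gene-body and intergenic probes from the methylated mode, shores are
mixed. The marginal baseline distribution is the familiar bimodal shape
(Beta mixture, modes at 0.10 and 0.85, concentration 20).

Planted effects:

- **Dose**: `n_dose_probes` sites gain `dose_effect` (default 0.05) β per
  Gy. The effect profile couples selection and direction to context:
  `fe_like` plants hypermethylation at low-baseline sites with a 3×
  preference for open chromatin; `si_like` plants mixed directions at
  intermediate-baseline sites; `x_like` plants hypomethylation at
  high-baseline sites.
- **Drift**: `n_drift_probes` sites change by `drift_rate` (default
  0.001) β per day with a per-probe fixed random sign — site-consistent
  within a series, direction-free across series. The 0.001/day default is
  the "1 in 1,000 molecules per day" reading of the reported culture-drift
  rate; the parameter is exposed because the rate is also quotable as
  0.001%/day (100× smaller).
- A `n_both_probes` class carries both effects (default 0).

Chip intercepts (sd 0.01), row effects (sd 0.005) and residual noise
(sd 0.02) are drawn per probe; the latent proportion is clamped to
[0.001, 0.999] (keeps M and U positive), and M is Binomial(total, β) at
total 10,000 AU — or exactly β·total when residual noise is disabled, so
noise-free identities hold bit-exactly. Detection p-values exceed 0.001
with probability `detection_fail_rate` (default 0.002).

The clamp truncates the noise distribution for baselines within ~2 sd of
the boundary, which raises the 0-dose mean and shaves a few thousandths
off recovered slopes at the very lowest baselines. This is a faithful
consequence of proportions living in [0, 1], not a bug; it is why
recovered mean slopes read ≈0.047 for a planted 0.05 under the fe-like
(low-baseline) profile.

### Tumor/normal matrices

`generate_tumor_normal` produces paired samples: a per-probe baseline, a
per-patient random effect (sd `patient_sd`, default 0.10) shared by the
tumor and normal of each pair at every probe, iid noise, and a shift of
±`delta` (sign per probe, shared across patients) at the signature probes
in tumors only. Signature baselines are drawn with headroom so the shift
never saturates.

The patient effect is essential, not cosmetic. Inter-individual
methylation variation dominates tumor/normal differences at most CpGs on
real arrays; it is what makes *random* probe subsets cluster samples by
patient (balanced 2×2 tables, chi-square p ≈ 1) instead of by tissue, even
though a random subset of a 20,000-probe pool contains ~4% signature
probes. Without it, the tissue shift carried by those few overlapping
probes out-competes iid noise and every random subset separates tumor from
normal — the Monte-Carlo test would have no power to distinguish the
signature from noise draws. With it, the planted 800-probe signature
(tissue signal 800·0.3 = 240 in Manhattan distance, versus ~90 of patient
noise) separates tissues cleanly while random draws do not.

### What the generator does not emulate

Type I/II probe chemistry, color-channel dye bias, bisulfite conversion
efficiency, genomic repeats, copy-number artifacts in tumors, and
correlated (regional) methylation between neighboring CpGs. Passing tests
therefore demonstrate the statistical machinery — calibration, power,
exactness of annotation and resampling logic — under an idealized array,
not robustness to platform artifacts that dedicated normalization methods
(BMIQ/SWAN, not used here by design) exist to fix.

## Annotation conventions

Intervals are 0-based half-open (BED); probe manifests are 1-based and
converted internally. Category precedence is Island > Shore > GeneBody >
Other, all measured from the probe's *nearest* island (ties to the
smaller island start): shores are 2 kb from the island edge; 5′/3′ is
resolved by the strand of the gene whose TSS is nearest the island (ties
to the smaller gene id; islands with no TSS within 10 kb default to
genomic orientation); the gene body runs from the 3′ shore edge to that
gene's TES. The island-scaled coordinate maps the island interior to
[0, 1] and flanks (default ±2.5 kb — deliberately distinct from the 2-kb
shore used for categories) to bp offsets. Chromatin lookups go through a
merge table pooling the two strong-enhancer states, the two weak-enhancer
states, and the three transcription states ("Transcribed Regions").

Compartment enrichment uses the sample odds ratio (a·d)/(b·c) with a
two-sided Fisher's exact p and a Woolf (log-OR normal) 95% CI, adding 0.5
to all cells only when one is zero — chosen over the conditional-MLE OR
for reproducibility without iteration; the exact p is unaffected. Tag
densities count reads by any-overlap (≥1 bp) in 20-bp bins and are scaled
to reads per million mapped.

## Monte-Carlo signature test

Observed and null statistics are the Pearson chi-square p (1 df, no
continuity correction by default — exposed as an option) of the 2×2
cluster × tissue table after a complete-linkage, Manhattan-distance, k=2
cut. Resamples draw |signature| probes uniformly without replacement from
the detection-filtered pool (probes with detection p ≤ 0.05 in *every*
sample), independently across the M draws.

The reported mc_p is the add-one estimator (1 + #{null ≤ observed})/(M+1):
never zero, conservative when the discrete chi-square p produces ties
between the observed and null draws. Because ties are common under the
null (patient-driven clusters give balanced tables with p = 1), the
conservative estimator is *valid but not uniform*; the `ties="random"`
option breaks each tie with a fair coin (lexicographic comparison with iid
uniform jitter), which is exactly uniform on {1/(M+1), …, 1} under
exchangeability and is what the calibration tests exercise. For a
well-separated signature the two coincide.

## Problem sizes and determinism

Every generator derives its streams from `(seed, stage-id)` with numpy's
seed-sequence spawning: identical config and seed give byte-identical
TSV/JSON outputs, and distinct stages never share a stream. The test
suite and the acceptance script run at the scale the package targets for
interactive work — 10,000-probe scans, 100-family error-rate studies,
50-seed resampling power studies with M = 1,000 — chosen to put Monte
Carlo error well below every asserted margin while keeping a full run in
the minutes range on one CPU.

## Known limitations

- Wald t inference with n − p df is slightly anticonservative for
  between-chip contrasts when chips are few; a Satterthwaite or
  Kenward-Roger correction is the standard remedy and is not implemented.
- The quantile-normalization attenuation described above biases recovered
  slopes low when a large fraction of the array carries true effects.
- `run_ewas` fits probes sequentially; at 450K scale a real run takes
  ~10 minutes. Chunked parallelism would be the first optimization.
- The Fisher CI is the Woolf approximation; for very sparse tables the
  interval is approximate even though the p-value is exact.
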