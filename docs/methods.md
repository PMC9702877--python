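# Methods

This note documents the models behind `fragkin`: what each component
assumes, the parameters that matter, how the synthetic defaults were
chosen and calibrated, the numerical choices, and what the generators
do and do not emulate.

## Fragment-length populations

A fragment population is a finite mixture over integer lengths
(1 bp resolution) of five component families reflecting the chromatin
states of circulating DNA:

| family | distribution | default location | default scale | meaning |
|---|---|---|---|---|
| `monoN` | discretized Laplace | 167 bp | 8 bp | chromatosome-protected fragments |
| `diN` | discretized Laplace | 330–365 bp | 20 bp | dinucleosomes |
| `triN` | discretized Laplace | 560 bp | 25 bp | trinucleosomes |
| `subnuc` | exponential baseline × sawtooth | support 41–166 bp | τ = 45 bp | nicked mononucleosomes |
| `hmw` | log-normal | median 7.2–12 kb | σ = 0.6 (log) | HMW chromatin fibers |

Laplace peaks were chosen over Gaussians because observed 1 bp size
profiles are cusped at the mode; the sharp mode also makes modal-length
estimates stable at moderate sampling depth. The sub-nucleosomal ladder
multiplies a baseline rising toward the mononucleosome mode by a
sawtooth of period 10 bp (configurable), the signature of periodic
nuclease access on the nucleosome surface; its phase puts subpeaks at
…147, 157 bp. The log-normal HMW component with median 12 kb and
σ = 0.6 spans roughly 2–40 kb, matching genomic HMW chromatin from
cell lysate; the NET-supernatant variant uses a 7.2 kb median so the
mean is near 8.6 kb.

Sampling inverts the exact per-component CDF, so draws are
bit-reproducible given (spec, seed) and empirical frequencies converge
to the mixture weights.

Four named defaults define the study conditions: `healthy_population`
(mono-dominated: weights 0.68/0.22/0.05 mono/di/tri, faint ladder and
HMW tail), `late_degradation_population` (ladder weight 0.40, amplitude
3 — the state after prolonged serum incubation), `net_supernatant_population`
(mono/di/tri ≈ 65/22/9% of the sub-kilobase fragments, di-N at 365 bp,
plus a 14% HMW count weight so HMW carries ~85% of the mass), and
`ghmw_population` (94% HMW count weight).

## Degradation cascade

DNA mass (ng/mL) moves through four compartments, HMW → tri-N → di-N →
mono-N, each degrading at first order; a conversion fraction `f_i` of
degraded mass enters the next shorter class, the rest is lost, and
degraded mononucleosomal DNA is lost entirely. The 5-state linear
system (including the lost pool) is integrated with a matrix
exponential, so mass is conserved to numerical precision (tested at
1e-9 relative) and the remaining total is non-increasing for any
non-negative rates. Incubation conditions scale all rates by one
multiplier: EDTA plasma ≈ 0.008 (near-complete nuclease inhibition),
serum 1, NE/MPO-supplemented sera > 1.

The mass/count duality matters: qPCR measures mass, whereas a
sequencing profile counts one read pair per fragment. Compartment
masses are converted to fragment-count weights by dividing by the
component mean lengths, so the same simulation yields a consistent
concentration time course (mass) and evolving size profile (counts).
Within the mono compartment, the sub-nucleosomal share of counts
interpolates linearly from its initial value to 0.35 as cumulative
mass loss proceeds, so the nicked-fragment ladder emerges during
degradation.

No published rate constants exist for this process, so the serum
defaults were calibrated once against the reported endpoints of
NET degradation in serum — 28/48/71% total-mass loss at
10 min/30 min/24 h and endpoint count fractions mono ≈ 0.80 /
di ≈ 0.15 among the 20–1000 bp fragments — giving

```
k_hmw = 0.0738 /min   f_hmw = 0.369
k_tri = 0.00155 /min  f_tri = 0.7625
k_di  = 0.00147 /min  f_di  = 0.7726
k_mono = 0.00029 /min
```

(the six targets are met essentially exactly; the fit residual is
~1e-20). The HMW phase dominates early loss — its half-life is
~9 min — while the mono-N half-life of ~40 h produces the slow late
phase and the mononucleosomal accumulation. A second default
(`default_ghmw_kinetics`) reuses these base rates with per-condition
multipliers fitted to the 2 h/8 h endpoint concentrations of the
enzyme-supplementation experiment (serum 2.09, +NE 15.1, +MPO 18.6,
+NE+MPO 25.2, EDTA plasma 0.0078). A single multiplier per condition
cannot match both the 2 h and 8 h endpoints of the strongly
enzyme-accelerated conditions (the observed two-phase decline is
steeper than the cascade's), so those fits are approximate; analyses
of that experiment therefore operate on the printed concentration
table directly (`pipeline.PRINTED_GHMW_TABLE`).

## Fragmentomics estimators

*Insert-size extraction* takes the positive-TLEN mate of each pair
(counting each pair once), drops supplementary/secondary, duplicate,
unmapped and MapQ < 20 records, restricts to the half-open (0, 1000] bp
window, and optionally to a chromosome set — `{"chrY"}` reproduces the
sex-mismatch design in which male (NET-derived) DNA is tracked inside
female fluid. TSV input deduplicates identical (chrom, start, length)
triples when coordinates are present, mirroring coordinate-based
duplicate marking.

*Peak detection* smooths the frequency profile with a centered moving
average (default 3 bp, preserving 10 bp subpeaks while suppressing
single-bin shot noise) and keeps local maxima whose prominence exceeds
a fraction (default 10%) of the smoothed maximum. The global mode is
reported first; ties break toward the smaller length. The faint tri-N
mode requires lowering the prominence threshold (e.g. 0.5–1%).

*Periodicity estimation* works on the 41–166 bp window. The profile
rises steeply toward the 167 bp mode there, and a linear detrend leaves
enough curvature to dominate the autocorrelation (favoring the smallest
lag); the estimator therefore subtracts a centered moving-average
baseline (width 11 bp = 2·min-lag + 1) and autocorrelates the residual
over integer lags 5–15 bp. Significance is a permutation test: the
winning autocorrelation must exceed the 95th percentile of the maxima
from 1000 seeded shuffles of the residual, otherwise "none detected" is
returned rather than a number. A smooth (e.g. strictly monotone)
profile short-circuits to "none detected" via a residual-energy guard.

*Nucleosomal fractions* use inclusive default bins mono 20–259,
di 260–459 (the reported di-N peak interval), tri 460–700 (above the
560 bp tri-N mode), long 701–1000, within the overall 20–1000 bp
window; all boundaries are overridable. Fractions plus residual sum to
one and are invariant to normalization state.

*CE summaries* integrate (size, signal) traces trapezoidally; the long
fraction is the share of total area in a range (default 1–10 kb) and
the mean size is signal-weighted within that range, reported as absent
when the range holds no signal.

## qPCR model

The amplifiability of an A bp amplicon against a fragment population is
locus-centric: a fragment of length L covering a random genomic
position is sampled with length-biased weight L and retains an intact
amplicon with probability max(0, (L−A+1)/L), giving
`Σ w_i max(0, L_i − A + 1) / Σ w_i L_i` — equal to 1 at A = 1,
non-increasing in A, zero once every fragment is shorter than the
amplicon. The closed form is validated in tests against a Monte-Carlo
oracle that concatenates the fragment multiset and drops amplicon start
positions uniformly. The forward simulator multiplies total
concentration by this fraction, maps it through the extraction geometry
(default 0.5 mL fluid → 80 µL eluate, 5 µL per reaction) and the
standard curve, and adds homoscedastic Gaussian Cq noise (default SD
0.15 cycles, typical replicate scatter); an amplicon with zero
amplifiable template yields a NaN "not detected" sentinel, which
quantification maps to concentration 0. Replicate Cq values aggregate
by mean after removing values more than 1 cycle from the replicate
median. The mitochondrial short amplicon length is not fixed by the
assay table and defaults to 67 bp, mirroring the nuclear short design.
Concentrations are reported per mL of source fluid; copy numbers follow
from a configurable genome mass constant (3.3 pg/haploid genome).

## Kinetics estimators

Rates are concentration differences over shared time grids — the
subtraction scheme requires both courses to sample the interval
endpoints exactly, and no interpolation is performed, to avoid
inventing data between sampling times. Negative rates (treated
degrading slower than control) are flagged with a warning, never
clipped. Fold-decreases carry a reporting rule mirroring mixed
publication style: raw value, one decimal below 7.5, nearest integer
above. Decay fits run nonlinear least squares on log-concentration;
the biexponential orders its phases k_fast > k_slow and flags fits
with no more points than parameters as underdetermined. The recovery
experiment in the test suite uses a sampling grid with early dense
points (2–30 min) so both phases are identifiable; at 5% multiplicative
noise and 50 replicates the per-parameter median error is well under
10%.

## NET production and cohorts

Supernatant marker kinetics share one saturating latent release curve
(τ = 90 min, normalized at the 5 h endpoint) with multiplicative
log-normal noise (default CV 3%); endpoint fold-changes over control
are 35/12/5/5 for cf-nDNA/cf-mtDNA/NE/MPO under PMA and 7/4/5/5 under
LPS, with a 1.3-fold control drift. Mitochondrial DNA rises less than
nuclear, so the MNR declines monotonically under stimulation. The
shared latent makes pairwise marker correlations ≈ 1 across a series.

Cohorts use a Gaussian copula: markers are jointly normal on the log
scale with the group's correlation matrix (validated symmetric, unit
diagonal, PSD), then exponentiated to log-normal margins. Default
groups mirror the clinical arm — HI (n = 114, medians cirDNA 5.76 /
NE 12.88 / MPO 11.91 ng/mL, no cirDNA–enzyme correlation), COVID-19
(n = 28, medians 116/45.3/90.85, r = 0.6), SLE (n = 10, r = 0.85/0.84
with NE/MPO), mCRC (n = 10, r = 0.55); dispersions are 0.25–0.5 log
units. With these dispersions the raw-scale Pearson correlation of the
log-normal margins sits within ~0.01 of the log-scale target, so
either scale recovers the specified association at large n.

Group comparisons use the two-sided Mann–Whitney test: exact null for
min(n) ≤ 20 without ties, otherwise a tie-corrected normal
approximation whose continuity correction takes the form
max(0, |U − μ| − ½) — identical samples then give p = 1 exactly. The
implementation is verified against brute-force enumeration of all rank
assignments for group sizes up to 8. Medians carry distribution-free
95% CIs from binomial order statistics. Raw p-values are reported (no
multiple-testing correction by default, matching common practice in
this literature; Benjamini–Hochberg is available on request).
Correlation matrices are Pearson with pairwise-complete observations,
optionally on the log scale; the handling is declared in the result
metadata.

## Pipeline and determinism

Six scenarios orchestrate the generators and estimators end to end
(gHMW degradation, NET production, NET degradation, NE/MPO enzyme
supplementation, a two-group mouse fragmentome comparison, and the
clinical cohort). Every stochastic step derives from one mandatory
seed; outputs are CSV/JSON with fixed float formatting and sorted keys,
so re-running a scenario with the same config and seed produces
byte-identical files. A provenance sidecar records package version,
config hash and seed. Default problem sizes (50,000–100,000 fragments
per profile, 200,000 for endpoint fraction estimates) keep component
proportion errors below ~0.3 percentage points while scenarios complete
in seconds.

## What the generators do and do not emulate

The generators reproduce the statistical structure the analyses
consume: nucleosomal mixture shapes, first-order condition-dependent
decay, qPCR observables derived from fragment lengths, co-released NET
markers, and inter-marker cohort correlations. They do not emulate read
sequences, base qualities, reference-genome coordinates (positions are
synthetic), GC or library-preparation biases, CE electrophoretic
artifacts, or biphasic nuclease kinetics beyond the linear cascade.
Passing tests therefore demonstrate the correctness of the estimators
on data with known ground truth — not the biological fidelity of any
particular rate constant, which real sequencing data would be needed
to establish.

## Known limitations

- The degradation cascade is linear and memoryless; saturation or
  substrate-dependent nuclease kinetics are out of scope.
- A single per-condition rate multiplier cannot reproduce strongly
  biphasic enzyme-supplemented declines at both sampled endpoints.
- The periodicity estimator reports one dominant spacing in 5–15 bp;
  it does not decompose superimposed periodicities.
- The amplifiability model ignores primer-site placement within the
  amplicon and PCR inhibition; Cq values are taken as given.
- Serum-vs-plasma rate ratios that depend on unpublished intermediate
  concentrations are computable only when those time courses are
  supplied as input.
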