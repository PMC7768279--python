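# Methods

This note documents the models and procedures `prescout` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish.

## 1. Coverage model and peak calling

Coverage lives in fixed-width bins (default 50 bp). The caller is a
deliberately simple stand-in for broad-peak callers used on
histone-modification ChIP-seq, not a port of any of them:

- **Expected count per bin**: the matched input track supplies
  λ = depth-scale × max(input bin value, 1 kb window mean, genome-wide
  mean). The max acts as a local-bias floor: a bin is only called enriched
  if it beats the most pessimistic of the three background estimates.
- **Significance**: upper-tail Poisson p = P(X ≥ k; λ) per bin,
  Benjamini–Hochberg across *all* genome bins (a single genome-wide FDR,
  not per-chromosome). Core bins satisfy q ≤ 0.01; with broad calling,
  cores extend through contiguous bins with q ≤ broad cutoff (default also
  0.01). Each emitted peak carries −log10 of its best q-value.
- **RPKM**: value = count / (bin kb × million fragments). Raw counts are
  used for inference; RPKM exists for track export and display.

Defaults (`PeakCallConfig`): q cutoff 0.01, broad cutoff 0.01, fragment
extension 200 bp, minimum differential length 150 bp, LLR10 cutoff 3.0.

### Differential classification

Counts are depth-scaled to the smaller library. Per bin,

LLR10 = log10[ Pois(k₁; k₁⁺) Pois(k₂; k₂⁺) / (Pois(k₁; m) Pois(k₂; m)) ],
m = (k₁+k₂)/2, with a pseudocount floor of 1 on every rate (the log-Gamma
terms cancel in the ratio), signed by k₁ − k₂. Contiguous same-sign runs
with |LLR10| ≥ 3 and length ≥ 150 bp become condition-enriched regions.

The **common** class is defined against a shared input: bins called as
peaks versus the input in *both* conditions, minus any base already claimed
by an enriched class. The published description of this step does not pass
an input track through the differential interface, so `classify_differential`
takes an optional `control=`; without one, a flat pseudo-control at the
pooled genome-wide mean stands in. The LLR10 cutoff (3.0) and the exact
delimitation of common regions are stand-in choices exposed in config — the
original study states only the 150 bp minimum length.

## 2. Reproducibility (IDR)

Replicate peak scores are paired by greedy maximum-overlap matching (each
peak used at most once, ties to the leftmost pair). Scores should be
continuous; the pipeline rescores peaks with log10 fold enrichment over the
depth-scaled input mean before matching, because q-value scores saturate
and tie on strong peaks.

The model is the standard two-component Gaussian copula mixture:
irreproducible pairs are standard bivariate normal with ρ = 0;
reproducible pairs are N((μ, μ), σ², ρ) with mixing proportion π. EM starts
from the conventional values (μ = 2.6, σ = 1.3, ρ = 0.8, π = 0.7), which we
treat as starting values, not fixed settings (the semantics of the
reference R package).

**Pseudo-values.** Ranks u = (rank − 0.5)/n are mapped through the inverse
of the *mixture-implied* marginal CDF G(z) = πΦ((z−μ)/σ) + (1−π)Φ(z),
refreshed from the current parameters between EM passes (grid inversion,
4000 points). A plain rank-normal transform was tried first and rejected:
it forces the transformed marginal to be exactly standard normal, which
makes the two components unidentifiable — on simulated data with π = 0.7
the EM collapsed to π ≈ 0.98. With the semiparametric refresh the same
simulation recovers π to 0.698 and ρ to 0.814 (truth 0.7 / 0.8).

**Convergence.** The inner EM (fixed pseudo-data) has a monotone
log-likelihood and stops on relative change < 1e-6. The outer alternation
drifts very slowly (≈1e-4 relative per pass on 2000 pairs) and may hit the
pass limit first; the result is then flagged `converged=False` with the
best parameters — the standard behaviour for this estimator family.

**Outputs.** local idr = posterior probability of the irreproducible
component; global IDR = running mean of local idr over pairs sorted
ascending (the expected irreproducible rate among all pairs at least as
reproducible). Thresholding (`idr_threshold`) is provided but optional: the
high-confidence sets come from replicate intersection, with IDR used as a
replicate-quality diagnostic, mirroring the published workflow.

**Desk-scale caveat.** In the demo pipeline only ~60 peak pairs exist and
*all* of them are genuinely reproducible (the simulation plants no
irreproducible peaks), so the mixture is weakly identified there and the
fitted π is not meaningful; the parameter-recovery guarantee applies to the
module's own simulation (2000 pairs from the assumed model).

## 3. High-confidence sets and candidate integration

Within each replicate's class, peaks separated by ≤ 500 bp are merged
(inclusive gap: 500 exactly still merges); the high-confidence set of a
class is then the base-level intersection across replicates. The order —
merge first, intersect second — is fixed and tested (merging can create
intersection that plain intersection misses). Merging is applied uniformly
to every set entering HC construction; the alternative (merging only the
differential sets) is noted as ambiguous in the source description.
Cross-class overlaps that merging re-creates are trimmed afterwards, with
enriched classes taking priority over common.

Candidates are HC condition-1-enriched peaks annotated with per-evidence
boolean overlap flags (≥1 bp, half-open semantics: touching does not
overlap), a TF union/intersection summary, and a nearest gene by TSS
distance (no distance cap — informational only; enrichment statistics use
the regulatory-domain rule instead). Ranking is lexicographic descending on
(TF intersection, TF hit count, conservation, accessibility hit count, peak
score), ties broken by coordinate — a deterministic stand-in for the
study's manual screening of loci.

## 4. Motif and region–gene enrichment

Motif scanning covers both strands; `N` in a sequence never matches. PWM
mode scores log-odds against a uniform background (probabilities floored at
1e-4) and calls a hit at ≥ `match_threshold` × the maximum achievable score
(default 0.8). Fold enrichment is exactly (% targets hit)/(% background
hit); the p-value is the upper-tail binomial at the background hit rate,
with the rate floored at 0.5/n_background when background hits are zero
(fold then reported as infinite). This binomial null is a documented
simplification of motif-tool nulls; the fold formula is the published one.

Region–gene association uses the basal+extension rule: basal domain
5 kb upstream / 1 kb downstream of the TSS (strand-aware), extended on each
side to the nearest neighbouring basal-domain boundary, at most 1 Mb from
the TSS, never cutting into the gene's own basal domain, clipped to the
chromosome. Extensions from adjacent genes may overlap, so inter-gene
regions typically associate with both flanking genes. Curated-domain
exceptions of the original web tool are not implemented.

Term enrichment per term: binomial over regions (success probability =
fraction of the genome covered by the term genes' domain union) and
hypergeometric over genes; fold = observed/expected region hits;
significant iff both BH FDRs < 0.05 and fold > 2. The gene-level
hypergeometric has little power when most genes are hit — tests use designs
with ≥100 genes.

Genomic-context annotation classifies the peak *midpoint* with precedence
promoter-TSS (−1 kb…+100 bp of TSS) > 5′UTR > exon > intron > TTS
(−100 bp…+1 kb of the gene end) > intergenic. 5′UTR calls require explicit
UTR spans on the gene model; without exon structure a gene contributes only
its promoter window.

## 5. Electrophysiology

Protocols: firing, 800 ms steps, 25–500 pA; subthreshold, −50…+20 pA in
10 pA steps for RMP/input resistance. Sampling ≥ 10 kHz enforced (the
synthetic protocol uses 50 kHz so that sub-millisecond half-widths are
resolvable).

- **RMP**: mean over the 50 ms pre-stimulus baseline of the 0 pA sweep.
- **Input resistance**: OLS slope of steady-state deflection (last 100 ms
  of the step, minus baseline) against current, spike-free sweeps only,
  ≥ 3 required; mV/nA = MΩ.
- **Spike detection**: peak above 0 mV preceded by an upward crossing of
  −20 mV with dV/dt ≥ 10 mV/ms; minimum inter-peak interval 1 ms.
- **Firing**: counts over the step window; frequency = count/0.8 s (mean
  rate — "maximum firing frequency" is the max across sweeps of this mean
  rate, not an instantaneous rate; the alternative reading is noted).
  Rheobase = smallest current with ≥ 1 spike.
- **Single-AP features**: first AP of the sweep 50 pA above rheobase
  (nearest larger sweep if absent). Derivatives come straight from a
  Savitzky–Golay local polynomial fit (0.5 ms window; cubic for dV/dt,
  order 5 for the third derivative) — cascading finite differences on a
  noisy trace drowns the third derivative in noise. Threshold = voltage at
  the third-derivative maximum within the 2 ms before the peak; because the
  smoothed-derivative argmax sits systematically ~half a window early, the
  voltage is read as the median of the raw trace over the 0.1 ms after that
  index (validated on template cells: max error < 0.7 mV at 0.3 mV noise).
  Amplitude = raw peak − threshold; half-width between linearly
  interpolated crossings of threshold + amplitude/2; fAHP = threshold −
  trough between the peak and the next spike onset, capped at 10 ms.
  Clipped traces (flat-topped peaks) are rejected.
- **SFA** = last ISI / first ISI, needs ≥ 3 spikes; measured on the
  maximal-firing sweep.
- **Classification**: FS iff ≥ 3 of {half-width < 0.5 ms, max rate
  > 50 Hz, fAHP > 15 mV, SFA < 2} (strict inequalities). If SFA is
  undefined (too few spikes), the cell must meet all three remaining
  criteria — a documented convention, not inferred from any source.

## 6. Synthetic data — the stated world

Every generator is a pure function of (spec, seed).

**Coverage** (`SimulationDesign` defaults): 2 Mb toy genome (2 × 1 Mb
chromosomes), 50 bp bins, Poisson fragment starts at 2/bin laid down as
200 bp spans (≈8× base coverage), replicate depth factors 1.0/0.85, and 80
planted regions — 20 condition-1-specific, 20 condition-2-specific, 40
shared — of 1.5–3 kb at 8–12× multiplicative enrichment, ≥5 kb apart.
Region sizes reflect that active-mark histone domains are kilobase-scale
(unlike point-source TF peaks); folds and counts follow the stated design.
Not emulated: fragment-length variability, GC bias, mappability structure,
chromosome-scale genomes. A green recovery test therefore establishes
correctness of the inference given the Poisson model, not robustness to
real-data artifacts.

**Ephys cells** are template-rendered, not conductance models: subthreshold
sweeps follow the RC step response V = RMP + I·R·(1 − e^(−t/τ)); spiking
sweeps ride a fast depolarized plateau clamped above the programmed fAHP
trough; each spike is piecewise linear (1.5 ms ramp to threshold, linear
rise, linear fall to threshold − fAHP, 2 ms exponential recovery) with
rise/fall durations chosen so the half-width at half amplitude equals the
programmed value exactly. Spike counts follow a deterministic f–I rule
(count = round(gain × (I − rheobase) × 0.8), ≥ 1 at rheobase) with
geometric ISIs whose last/first ratio equals the programmed SFA. FS presets
(n=100 bank): threshold ≈ −42 mV, amplitude ≈ 80 mV, half-width
0.30 ± 0.04 ms, fAHP ≈ 20 mV, gain 0.3 Hz/pA, SFA 1.1–1.6; RS presets:
half-width 0.8 ± 0.1 ms, fAHP ≈ 8 mV, gain 0.08 Hz/pA, SFA 2.8–4.0; white
noise 0.3 mV throughout. Every analysis feature has an exactly programmed
target; a conductance-based generator is an extension point.

**qPCR** tables are built so the noise-free ΔΔCt log2 ratio equals the
stated truth exactly (non-CIN sample constructed at ΔΔCt = 0, CIN at
−truth), with optional Gaussian Ct noise.

**Evidence tracks** for the end-to-end demo cover a random subset of the
planted condition-1 regions (TF sites at rate 0.6 each, conservation 0.7,
accessibility 0.5/0.3) plus 50 random decoys each.

## 7. Statistics

Fisher's exact test enumerates the hypergeometric support and sums point
probabilities ≤ that of the observed table, with a relative tolerance of
1e-7 on the comparison to absorb float ties — this convention reproduces
the published p = 0.0414 on the FS/RS contingency. Zero-variance t inputs
return a flagged degenerate result rather than ±∞ (except the one-sample
case exactly at the null mean, which is t = 0, p = 1; a paired test on
identical vectors is flagged). Tukey HSD uses the studentized-range
distribution with the Tukey–Kramer standard error (exact at equal n). BH is
the literal step-up. scipy supplies distribution functions only; scipy's
and statsmodels' own test implementations appear in the test suite as
independent cross-checks.

## 8. Known limitations

- The peak caller and differential classifier are desk-scale stand-ins;
  they are not expected to reproduce any genome-wide peak counts from real
  data, which require the original sequencing reads.
- The IDR fit assumes exactly two components and a Gaussian copula;
  score ties (e.g. saturated q-values) degrade the rank transform.
- Motif enrichment uses a per-sequence binomial null, not a
  matched-background resampling null.
- The GREAT implementation covers only the default basal+extension rule.
- Ephys feature tolerances are validated against template waveforms with
  0.3 mV noise; heavily distorted or clipped recordings are rejected, not
  repaired.
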