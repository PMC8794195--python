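# Methods

This note records the models, conventions and numerical choices behind
`censuswalk`, in the order the pipeline uses them.

## The dimension estimator and its variance

The estimator embeds a uniformly sampled waveform {xᵢ, yᵢ} in the unit
square.  As printed in the source algorithm the abscissa transform divides by
the span without subtracting the minimum; we therefore require the abscissa
to start at 0 (the default is the sample index 0..N−1), which makes the
transform identical to full min-max normalisation.  The estimate is

    D_s = 1 + (ln L − ln 2)/ln(2N′),   N′ = N − 1,

with L the embedded polyline length.  The variance formula's typography
admits two groupings of the N′ factors, but both reduce algebraically to

    var(D_s) = Σᵢ(Δyᵢ − Δȳ)² / (L·ln(2N′))²,

where Δyᵢ is the length of embedded segment i (the distance between
consecutive embedded points, not the raw ordinate difference).  This reading
was validated against two independent anchors before freezing: a single
10⁴-point white-noise trace yields s(D_s) ≈ 7.6·10⁻⁴, and a 100-trace
white-noise ensemble at N = 1329 yields D̄_s ≈ 1.598 with total spread
≈ 0.009–0.011 — both matching the published reference values for those
exact configurations.

Degenerate input: a flat waveform cannot be embedded (y_max = y_min).
`sevcik_dimension` returns the topological dimension D_s = 1 with zero
variance and a warning rather than failing, since a constant line is
legitimately one-dimensional.

D_s is location- and scale-free by construction (the embedding removes both),
which is the self-affinity property the tests check; it underestimates the
limiting dimension at any finite N, which is why every comparison in the
pipeline is made at matched N against freshly calibrated standards, never
against the textbook limits 2 and 1.5.

## Calibration ensembles

`calibrate(kind, n, m, seed)` draws M traces (white: i.i.d. N(0,1) via
Box–Muller; brownian: the cumulative sum of such deviates starting at 0) and
reports the ensemble mean D̄_s, the between-trace variance (denominator
M − 1), the mean within-trace variance, and their sum (the "total" variance).
The total-variance additivity is exact by construction.  Defaults are M = 100
at the analysed series length, matching the study design.  The published
"±" values are ambiguous between s(D̄_s) and s(D_s) readings, so the
ensemble object exposes all three variance components and the per-trace
dimensions; comparisons use the total variance.

Band membership ("does this series look white/Brownian at this length?") is
defined as D̄_s ± 3·√(var_total).

## The Vysochanskij–Petunin comparison

For unimodal X with finite variance, P(|X − μ| ≥ λσ) ≤ 4/(9λ²) when
λ > √(8/3).  The decision rule is derived solely from the theorem and its
one-tailed inversion — the intermediate printed form of the bound in the
source derivation is typographically garbled and is not used.  Conventions:

- one-tailed by default (the use case is directional: "is this dimension
  *below* the white standard?"), critical λ = √(2/(9α)) = √(40/9) at
  α = 0.05; a flag switches to the two-tailed √(4/(9α)) = √(80/9);
- at or below the threshold √(8/3) the result is reported as the interval
  1/6 ≤ P ≤ 1, never as a point p-value, and is never significant;
- the test is conservative for any actual distribution (for Gaussian data
  the same α needs only λ ≈ 1.65), property-checked by simulation.

## Cleaning rules

Two recording pathologies are repaired, and only these:

1. **Year-rollover spikes.**  A count above the bed capacity is physically
   impossible; on a suspect day it is replaced by the arithmetic mean of the
   flanking days.  Suspect days come from the date index (January 1), from an
   explicit list, or from an automatic scan for impossible values — the scan
   is a superset of the date rule and is what the pipeline uses on dateless
   CSVs, justified because the impossibility criterion itself is value-based.
   Two consecutive spike days are refused (the flank is itself corrupt) — an
   explicit error rather than a silent cascade.
2. **Gaps.**  A maximal run of missing days is bridged with a constant daily
   change (y_after − y_before)/gap_len, applied cumulatively, so the last
   bridged day lands exactly on the after-flank (for a 9-day gap the
   flank-to-flank jump is divided by 9).  Bridged values are kept as reals —
   rounding would break the telescoping identity between a series and its
   accumulated differences.

Cleaning is idempotent, touches only flagged days, and emits a JSON log
(day, column, rule, old, new).  Note that a spike repair estimates the lost
true value; the reconstructed walk built from repaired flows can therefore
carry a small step offset relative to the census, and on occasional
realizations this is enough to push the census-vs-walk comparison out of the
corollary regime — visible in the simulator, and an honest property of the
flank-average rule rather than a defect.

## Difference and walk conventions

- One-day differences use Δy₀ = 0, so the difference series has the length of
  its parent.
- DDiAd is admissions − discharges: only this sign makes the accumulated walk
  rise with admission surpluses and reproduce the census.  (The source
  prose is contradictory on the sign; this is the reading under which the
  reconstruction identity holds.)
- The walk starts at 0 and does not accumulate element 0 of its input; with
  that convention cumulating DDiAd plus the day-0 census equals the census
  exactly on artifact-free data.

## The hospital simulator

A minimal conserved-refill model: each day a Poisson(μ_dis) number of
patients is discharged (capped at the current census) and each discharged bed
schedules exactly one replacement admission after a random lag; admissions
that would exceed capacity are deferred a day.  The in-transit pool is
initialised at its stationary Poisson size (with memoryless residual lags in
the geometric family) so the census starts in equilibrium at the target.

Defaults are the study scale: 192 beds, 1329 days, target census 150.
μ_dis = 3/day corresponds to ~150 occupied beds with a ~50-day mean stay, the
regime of a long-stay hospital.  The lag is geometric with a 60-day mean:
in this model the lag pool is the *only* source of low-frequency census
variance, and a mean lag of weeks-to-months is what produces census
meandering at the observed amplitude (a slow referral pipeline).  With that
choice the census lands in the Brownian calibration band and the
admissions−discharges difference in the white band in ~19 of 20 runs, and
the full qualitative significance pattern (census ≍ reconstructed walk,
daily variation ≍ white, census ≠ white) holds in ≥ 18 of 20 seeded runs.

What the generator does **not** emulate: demand-side variance (a real
hospital's low-frequency census movement also reflects referral-pressure
changes, so a real system reaches the same meandering with shorter lags),
over-dispersed and weekday-patterned flows, per-patient lengths of stay, and
multi-unit structure.  Passing tests on simulated panels therefore
demonstrate that the analysis chain detects the lag mechanism when it is the
generating mechanism — not that every real census is lag-generated.

Lag families: geometric (mean θ, support 0,1,2,…), fixed, and integer-uniform
on 0..k.  Lag 0 reproduces the degenerate limit (constant census, DDiAd ≡ 0),
and Var(DDiAd) shrinks monotonically as the lag parameter shrinks.

Artifact injection: counts > 900 placed on the first two January-1-equivalent
days (offsets 245 and 610 for a May-1 start; admissions first, discharges
second), and an NaN gap in the census.  Both mirror the pathologies the
cleaning stage exists for.

Randomness: one master integer seed per call; numpy's seeded PCG64 generator
(counter-stable; the original MT19937 is not required — any seeded generator
meeting the calibration targets is acceptable).  Ensembles spawn per-trace
seeds from the master via `SeedSequence`; the pipeline spawns per-component
child seeds the same way.  Identical seeds reproduce outputs byte-for-byte,
including serialized CSVs and JSON reports.

## Nonparametric battery

- **Runs test**: ties at the median are discarded; the exact combinatorial
  run-count distribution is used for ≤ 40 usable points (combinatorics are
  cheap there and the approximation is weakest), a continuity-corrected
  normal approximation beyond.  Both P(R ≤ obs) (the walk/trend-sensitive
  tail) and a two-sided p are reported, since the source's tail convention
  is self-contradictory.
- **Hodges–Lehmann**: median of all Walsh averages; CI endpoints are the
  k-th extreme Walsh averages with k from the exact signed-rank null
  distribution (n ≤ 50, by convolution) or its normal approximation.
- **Theil regression**: slope and its rank-based CI via
  `scipy.stats.theilslopes` (joint-median intercept, i.e. median(y − βx));
  intercept CI from the signed-rank interval of the residuals; tie-corrected
  Spearman ρ with its large-sample p.
- **Jarque–Bera**: implemented directly from population-moment skewness and
  kurtosis (JB = n/6·(S² + (K−3)²/4), χ²₂ reference) and cross-checked
  against scipy; Shapiro–Wilk and robustified variants are deliberately out
  of scope (use an established implementation when needed).
- **Smirnov**: delegated to `scipy.stats.ks_2samp` (asymptotic two-sided p).
- No multiple-testing correction is applied across units or matrix cells;
  the comparison matrix is reported raw, as in the study design.

## Spectral classification

ψ_f = a_f² + b_f² from the FFT of the mean-removed series (without mean
removal the DC term dominates), windowed (Hann by default; Hamming
selectable — the source names both) and zero-padded to the next power of
two.  The zero-frequency term is excluded.  Slope fits use the Theil
estimator on log₁₀ψ vs log₁₀f and exclude the top decade of frequencies,
which discrete sampling contaminates with rapid oscillations.

`classify_series` combines two votes — spectral slope (> −0.5 white,
< −1.2 Brownian) and dimension-band membership at matched length — and
returns `indeterminate` on disagreement.  A dominant-peak screen catches
periodic signals first: a peak 100× the median ψ that also towers 50× over
the median of its ±3..10-bin ring, and does not sit in the first five bins
(a red spectrum's maximum always does; the ring median is used because
individual periodogram ordinates scatter exponentially).  The slope cuts
sit at the midpoints between the theoretical 0 and −2 with a guard band;
on 2048-point standards the classifier is ≥ 90% correct per type with the
remainder indeterminate rather than wrong.

## Pipeline sizes and determinism

The full run on a 1329-day panel (two M = 100 calibrations, six dimension
estimates, 28 pairwise comparisons, runs/occupancy/Smirnov summaries, two
spectral classifications) takes well under a second on one CPU; the test
suite's Monte Carlo checks use 20–500 replicates per property, sizes chosen
so each statistical assertion has comfortable margin at its stated band.
Reports serialize to sorted-key JSON and re-running the same configuration
byte-reproduces them.

## Known limitations

- The V-P bound is a bound, not a p-value; borderline verdicts ("undecided
  significance") are inherent to the method.
- The exact runs distribution assumes exchangeability under the null; heavy
  median-tie discarding (integer data on a narrow range) reduces power.
- The simulator's bed-capacity clipping makes high-occupancy realizations
  pin at the cap, which whitens the census and colours the flow differences;
  at the default parameters this affects a minority of seeds but is visible
  in ensemble tests.
- Workbook ingestion expects one sheet with one header row and
  column-letter addressing; multi-sheet monthly exports must be concatenated
  first.
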