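# censuswalk

Random-walk and fractal-dimension analysis of hospital bed-occupancy time
series.

## The problem

A hospital's daily in-patient census (InP) often meanders between full and
half-empty in what looks like seasonality, demand cycles, or administrative
failure.  `censuswalk` implements an analysis chain for a sharper diagnosis:
the census can be a **Brownian random walk** (Rw) generated by a single hidden
factor — discharges are refilled by admissions only after a random lag — in
which case the apparent trends and cycles are statistical artifacts, and the
lever for improving efficiency is shrinking the daily admissions−discharges
mismatch, not chasing seasonal demand.

The package is aimed at health-services researchers and biostatisticians with
daily admission (Adm), discharge (Dis) and census (InP) counts, and at anyone
needing its general-purpose pieces: a waveform fractal-dimension estimator
with finite-length calibration, a distribution-free two-mean test, and a
nonparametric trend/dependence toolbox.

## The method

**Fractal dimension (Sevcik's estimator).**  A uniformly sampled waveform of
N points is embedded in the unit square (x* = x/(x_max − x_min),
y* = (y − y_min)/(y_max − y_min)); with L the embedded polyline length and
N′ = N − 1,

    D_s = 1 + (ln L − ln 2) / ln(2N′),
    var(D_s) = Σᵢ(Δyᵢ − Δȳ)² / (L · ln(2N′))²,

where Δyᵢ are the embedded segment lengths.  D_s → D_h (the
Hausdorff–Besicovitch dimension) only as N′ → ∞: white noise has D_h = 2 and
a Brownian walk D_h = 1.5, but at N = 1329 they measure ≈ 1.598 and ≈ 1.289.
Comparisons are therefore made only against Monte Carlo **calibration
ensembles** of M standard-noise traces at the *same* N, summarised by the
ensemble mean D̄_s and a total variance (between-trace + mean within-trace).

**Distribution-free significance (Vysochanskij–Petunin).**  The distribution
of D_s is unknown, so differences are tested with the V-P inequality for
unimodal laws: P(|X − μ| ≥ λσ) ≤ 4/(9λ²) for λ > √(8/3).  With
λ = |ΔD̄_s|/√(var_t,1 + var_t,2), the one-tailed rule declares significance at
α = 0.05 when λ ≥ √(40/9) ≈ 2.108 (two-tailed: √(80/9) ≈ 2.981).  Below
√(8/3) ≈ 1.633 only the bound 1/6 ≤ P ≤ 1 exists and the difference is never
declared significant.

**Random-walk reconstruction.**  From the daily difference
DDiAd_t = Adm_t − Dis_t the walk Ξ is rebuilt by accumulation (Ξ₀ = 0,
Ξᵢ = Ξᵢ₋₁ + DDiAdᵢ).  The headline check: if D_s(Ξ) and D_s(InP) are
statistically indistinguishable, the census meandering is fully explained by
the admission/discharge lag.

**Supporting battery.**  Runs-about-the-median (exact combinatorial tail for
≤ 40 usable points), Hodges–Lehmann median with rank-based CI, Theil
regression with tie-corrected Spearman ρ, Jarque–Bera Gaussianity check,
two-sample Smirnov test, and windowed spectral densities ψ_f = a_f² + b_f²
whose log-log Theil slope separates white (flat) from Brownian (1/f²) noise.

**Synthetic data.**  `simulate_hospital` runs a conserved-refill census model
(Poisson discharges; each discharged bed schedules one admission after a
random lag) with optional injected recording artifacts — impossible New-Year
spikes and a 9-day gap — so the cleaning rules (flank-average repair, linear
gap bridge) are exercisable end to end without any real data.

## Worked example

Simulate a 1329-day, 192-bed hospital with both artifact types, then run the
full pipeline:

```bash
censuswalk simulate --seed 6 --config sim.yaml --out panel.csv   # sim.yaml: inject_newyear_spike: true / inject_gap: [28, 9]
censuswalk full-run --in panel.csv --seed 6 --out report.json
censuswalk report --report report.json
```

which prints (abridged):

```
    series        Ds      s(Ds)
       adm   1.60776   2.70e-03
       dis   1.62290   2.82e-03
       inp   1.38396   2.79e-03
      dinp   1.59872   2.64e-03
     ddiad   1.60005   2.62e-03
        xi   1.38387   2.77e-03
  brownian   1.29085   3.83e-02  (M=100 ensemble)
     white   1.59854   1.00e-02  (M=100 ensemble)

pairwise dimension comparisons (one-tailed V-P bound):
                 dis       inp      dinp     ddiad        xi  brownian     white
       inp       ...       ... 7.11e-05* 6.96e-05*   [1/6,1] 3.78e-02* 5.21e-04*
      dinp       ...       ...       ...   [1/6,1] 7.05e-05* 3.46e-03*   [1/6,1]

occupancy: median 153.0 beds (152-154), 79.7% of 192 beds, range 65.1-96.4%
runs about the median (inp): 61 runs over 1286 usable days, P(R<=obs) = 5.48e-232
classification ddiad: white_like (slope 0.09, Ds 1.6001)
classification inp: brownian_like (slope -1.87, Ds 1.3840)
```

Reading it: the census (`inp`, D_s ≈ 1.384) sits far below the white band and
is indistinguishable from its reconstruction `xi` (corollary regime,
`[1/6,1]`) — the lag mechanism alone rebuilds the census walk.  The daily
variation `dinp` is indistinguishable from white noise, the census produces
only 61 runs where an independent sequence of that length would produce
~644 (hence the astronomically small run probability), and the spectral
classifier labels the census Brownian-like (log-log slope ≈ −2) and the
admissions−discharges difference white-like (slope ≈ 0).

The same analysis runs on real command-panel exports: the canonical CSV
(`day,adm,dis,inp`, empty cell = missing) or a spreadsheet workbook with a
column map (`load_panel(path, dialect="workbook", column_map=...)`).

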