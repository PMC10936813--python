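# Methods

## The model

`dsbmap` simulates meiotic Spo11-DSB formation cell by cell under a
primed-domain model with three ingredients.

**Prophase window.** Each cell draws an exit time `T`.  With Ndt80
present, `T` is truncated-normal on `[0, t_max]` with genotype-dependent
mean (defaults: 7.0 h for TEL1+, 5.5 h for *tel1Δ*, SD 0.5 h — encoding
the accelerated prophase exit of Tel1-deficient cells; configurable, not
claimed as measured).  Without Ndt80 the cell arrests and `T = t_max`
(default 10 h).  Sampling uses the inverse-CDF of the truncated normal,
so one uniform per cell regardless of parameters.

**Domain priming.** Hotspots are partitioned into contiguous priming
domains by maximal runs whose end-to-end midpoint span is at most
`max_domain_span` (default 15 kb, the scale of the inferred activation
zones).  Each domain has a mean priming time `tau_d` following a linear
spatial gradient anchored at the centromere (default 2 h at the
centromere rising by 4 h to the most distal point, emulating the early
pericentromeric association of pro-DSB factors).  Per cell and domain,
`t_d = max(0, tau_d + N(0, jitter_sd))`; hotspots may only fire during
`[t_d, T)`.  The domain's expected association time (`rec114_time`) is a
deterministic function of the gradient, exposed so comparisons against a
timing track have a planted truth.

**Cutting and suppression.** Four chromatids are simulated independently
(the assays count broken chromatids; no sister/homologue coupling).  In
discrete steps of `Δt` (default 0.1 h), each uncut, primed
hotspot-chromatid fires with probability `w·Δt·σ`, where `w` is the
hotspot's intrinsic hourly rate and `σ` is the Tel1 interference factor:
the product over previously committed cuts at midpoint distance `d` of
`(1 − s·exp(−d/λ))`, clamped at 0.  Suppression acts in cis (same
chromatid) by default; a `trans_suppression` switch extends it across
chromatids of the cell, since the data do not resolve cis vs trans.  The
strength `s` and decay length `λ` are not quantitatively known;
defaults (`s = 0.8–0.9`, `λ = 10–20 kb` in the bundled scenarios) are
illustrative and chosen so suppression is visible at a 5 kb hotspot
spacing without saturating the hazard.

### Exact event-driven sampling

The discrete-hazard process is sampled by geometric waiting times rather
than stepping through time: each hotspot-chromatid draws its
first-success step at hazard `w·Δt·σ`; the earliest scheduled fire
commits, `σ` is updated for affected neighbours, and their waiting times
are redrawn from the current step — valid because the geometric
distribution is memoryless.  Runtime therefore scales with the number of
cuts, not the number of time steps.  Ties within a step commit one cut
at a time in (chromatid, hotspot) order, with suppression applied
immediately to pending same-step fires; under total suppression
(`s = 1`, large `λ`) coincident same-chromatid cutting is therefore
exactly abolished.  Discretisation bias relative to the continuous-time
model is O(`w·Δt`) (≲ 2.5 % at the default rates).

Randomness uses one root seed with per-cell substreams
`SeedSequence([seed, cell_index])`, so enlarging the population never
reshuffles earlier cells, and identical seeds give bit-identical
populations.  Draw order within a cell: exit time, domain jitters,
per-chromatid schedules, event-loop redraws, then cut-position jitters.
Cut positions are the hotspot midpoint plus a uniform integer within
± width/2 (1-based coordinates throughout).

### Closed-form primed fraction

`primed_fraction` returns `P(t_d < T)` using untruncated normal tails:
`Φ((μ_T − τ_d)/√(σ_T² + σ_j²))`, with the arrest case as `σ_T = 0`.  It
is exact when the exit distribution's mass lies inside `[0, t_max]` and
`τ_d` is well above 0 relative to the jitter SD; zero-variance boundary
cases resolve by the strict inequality (`τ_d = T` counts as unprimed).

### Read-outs

`breaks_to_fullmap` gives the sequencing-style read-out: each cut
contributes one Watson read at its position and one Crick read at
position + 1 (the two covalently bound break ends).  Uniform background
is parameterised as `β` HpM per bp: the declared library total is solved
as `signal/(1 − β·L/10⁶)` (or taken from `library_reads` for
background-only maps) so that the expected background density in HpM
units equals `β` exactly, then per-position background counts are
Poisson.

`breaks_to_assay` gives the blot-style read-out as fractions of
chromatids.  `ideal` mode counts every cut; `blot` mode reproduces the
technique's occlusion: a single-DSB probe sees only the *nearest* cut on
its side, and a double-cut band requires no intervening cut.  This makes
the correction identity `blot(distal) + DC(proximal, distal) =
ideal(distal)` an exact bookkeeping statement on two-hotspot layouts —
the rationale for correcting distal hotspot frequencies by adding the
double-cut frequency.  Optional census times gate cut visibility by
`min(t, T)`, emulating timepoints.

## Interference statistics

Frequencies are fractions internally (percentages only at I/O).  The
pipeline per repeat: average the configured timepoints (default 6 and
8 h, unweighted; repeats missing a timepoint are flagged, never silently
dropped), apply the multi-copy correction (`raw × copies`, capped at 1
with an overflow flag) and optionally the occlusion correction, form
`expected = f₁·f₂`, and report `−log2(observed/expected)`.  Repeats where
either side is ≤ ε are excluded with a flag rather than reported as ±∞;
ε defaults to 10⁻⁴ in fraction units, a threshold chosen here because
the source analyses excluded near-zero cases only qualitatively.
Interference is averaged across repeats *after* the −log2 transform.
Genotypes are compared by a pooled-variance two-tailed t-test on the
per-repeat values; with zero pooled variance the p-value degenerates to
1 (equal means) or 0 (different), flagged as such.

## Hotspot calling

Strand-combined per-bp HpM is smoothed with a 201 bp Hann window
(weights normalised to sum 1; the raw window sums to 100, so an impulse
of mass m peaks at m/100).  Chromosome ends are zero-padded and total
signal is conserved on the padded domain.  Rule order: threshold the
smoothed profile at 0.193 HpM → merge candidate runs separated by
< 200 bp (gap = next.start − prev.end − 1) → apply the 25 bp minimum
length and 25-read minimum raw mass.  Merging before filtering makes
merged composites eligible as single hotspots.  The cutoff applies to
the smoothed profile (the natural reading of smoothing-then-cutoff), and
the read minimum is raw mass in the supplied map — HpM mass for pooled
HpM-normalised maps — both recorded choices, as the original recipe does
not pin them down.  Per-library templates combine by interval union with
per-source presence flags.  The rDNA exclusion interval is interpreted
in bp (the printed "kb" reads as a typo) and is configurable.

Background is the mean HpM per bp in the 47 longest ORFs exceeding
5.5 kb (fewer qualifying ORFs are used with a warning).  Strength per
hotspot: `corrected = max(0, ΣHpM − background × length)` (negative
values floored and flagged), and `NormHpM = corrected / Σcorrected ×
10⁶`, which sums to 10⁶ per library by construction.

## Comparative maps

Correlations pair NormHpM over the shared template, excluding (and
counting) zero-flagged hotspots.  Log2 ratios use no pseudocount — zeros
are flagged-excluded.  Smoothing of fold changes along chromosomes, and
of timing tracks, uses degree-1 local regression with tricube weights
over the nearest `ceil(span·n)` points (the classical loess recipe,
`it = 0`); an independent brute-force weighted-least-squares oracle
bounds it in the tests to 1e−8.  Ratios are unweighted by strength
before smoothing (a recorded choice).  Ratio heatmap bins anchor at the
centromere (50 kb, index k covering `[cen + 50 000·k, cen + 50 000·(k+1))`,
partial terminal bins retained, rows ordered by chromosome size rank);
timing tracks are confidence-filtered, loess-smoothed per chromosome
with span `80/N` clamped to (0, 1], and binned at 50 kb anchored at
position 0 — for correlation the timing bins are re-anchored onto the
centromere grid by overlap-weighted averaging so pairs align.  Spearman
p-values use the large-sample approximation, or exact permutation when
n < 10.  The raw sign convention is reported explicitly (positive r =
fold change rises with later association time); display conventions that
reverse the time axis flip the printed sign, so the coefficient is
reported, not asserted.

## Canonical scenarios and problem sizes

The bundled scenarios (in `dsbmap.scenarios`) fix the study conditions:

* **Coincidence law** — one domain, two hotspots 5 kb apart, rate
  0.25/h, no suppression, 20 000 cells.  The primed fraction f = 0.5 is
  realised *all-or-none*: `tau_d = t_max` under arrest with a very large
  priming jitter SD, so exactly half the cells prime (at time ~0, with
  the full window) and half never do.  This makes f exact and the
  per-chromatid cut probability essentially constant among primed cells
  — the regime in which population frequencies factorise as `f·p` and
  `CoC → 1/f`.  Residual partial-window cells bias interference by
  ≈ −0.01 at these settings.
* **Four genotypes** — same geometry, rate 0.1/h (a strong natural
  hotspot, ~0.5 cut probability per chromatid), suppression s = 0.9,
  λ = 20 kb for TEL1+; arrest vs a finite window with all-or-none
  priming; 5000 cells per scenario.
* **Priming gradient** — four 600 kb chromosomes (centromere at
  150 kb), ~780 hotspots at 3 kb spacing, rates calibrated to 150
  expected breaks per cell at a 7 h window, priming from 2 h
  (centromere) to 8 h (distal); a short prophase (mean exit 5 h) vs
  arrest, 5000 cells each, no suppression.
* **Null control** — a 500 kb hotspot-free map at β = 0.15 HpM/bp with
  a declared 3×10⁷-read library.  At that depth the smoothed background
  SD is ≈ 0.009 HpM, putting the 0.193 cutoff ≈ 5 SD above the mean
  (no calls) and the 0.125 cutoff below it (essentially the whole
  chromosome calls as one merged interval) — the lowered-cutoff
  behaviour of a catalytically dead control.  These depths were chosen
  from that variance argument.

These sizes keep the full test suite and the acceptance script in the
tens of seconds on one CPU while leaving Monte-Carlo errors a factor of
several inside each stated tolerance.

## What the generator does and does not emulate

It emulates: stochastic per-cell priming with a spatial timing gradient,
genotype-dependent prophase windows, four independent chromatids,
distance-decaying suppression of subsequent cuts, hotspot-width cut
dispersion, uniform background reads, blot occlusion, and equal-weight
library pooling.  It does not emulate: resection or repair, homologue
engagement, Mec1, sister/homologue coupling, sequence-determined hotspot
strengths, gel-quantification noise (lane background, blot-to-blot
variation), or mappability artefacts.  Passing tests therefore show the
*analysis pipeline* is correct and the model's population laws hold —
not that real libraries are free of the excluded effects, and measured
percentages from real gels are not reproduction targets.

## Known limitations

* The t-test type-I calibration band (0.05 ± 0.01 over 2000 replicates)
  is about two binomial SDs wide, so a small fraction of seeds will land
  outside it by chance.
* The closed-form primed fraction ignores truncation; it degrades when
  the exit distribution presses against 0 or `t_max`.
* Suppression distances use hotspot midpoints, not realised cut
  positions (differences are bounded by the hotspot width, which is tiny
  relative to the decay length).
* Loess here is the classical tricube/degree-1 recipe; it is not
  guaranteed to match any particular reference implementation's
  interpolation shortcuts, only the definition (enforced by the oracle
  tests).
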