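# dsbmap

Simulation and population-level analysis of meiotic Spo11 double-strand
break (DSB) landscapes in budding yeast.

During meiotic prophase, Spo11 catalyses 100–200 DSBs per cell across
~4000 potential hotspots, under two opposing layers of regulation: the
Tel1 (ATM) kinase locally suppresses further cutting near an existing
break (*DSB interference*), while sub-chromosomal "primed domains"
(< 15 kb) mature to a DSB-competent state at different times in different
cells, so that a short prophase leaves only part of the population able
to cut a given region.  Population assays mix these layers: the measured
coefficient of coincidence between two hotspots reflects both true
suppression and the primed fraction *f* of cells.

`dsbmap` provides, as a tested Python library:

* **a per-cell stochastic simulator** of the primed-domain model —
  discrete-time hazard `w·Δt·σ` per hotspot and chromatid, with
  `σ = Π (1 − s·exp(−d/λ))` over prior cuts, genotype-dependent prophase
  windows (finite for NDT80+, arrest for *ndt80Δ*), a spatial
  priming-time gradient, and blot-style or sequencing-style read-outs;
* **double-cut interference statistics** — expected DC = product of
  single-cut frequencies, CoC = observed/expected, interference
  `−log2(CoC)`, with multi-copy and occlusion corrections, 6+8 h
  timepoint averaging, per-repeat aggregation and equal-variance t-tests;
* **hotspot calling** from per-base break maps — 201 bp Hann smoothing,
  0.193 HpM cutoff, 25 bp / 25 read minima, < 200 bp merging, background
  calibration from the 47 longest ORFs (> 5.5 kb), and NormHpM strengths
  (background-corrected signal per million, summing to 10⁶ per library);
* **genome-wide comparisons** — strength correlations, per-hotspot log2
  fold changes, loess-style smoothing, 50 kb centromere-centred binning,
  and rank correlation against an association-time track.

## The statistic at the core

For two hotspots with single-cut frequencies *f₁*, *f₂* and observed
double-cut frequency *DC*:

```
expected DC = f1 · f2          (independence)
CoC         = DC / (f1 · f2)
interference = −log2(CoC)
```

Positive interference means fewer coincident cuts than chance, ~0 means
independence, negative means clustering.  Under the primed-domain model
with no suppression, `CoC → 1/f` as the number of cells grows, so
measured interference equals true within-domain interference plus
`log2(f)` — heterogeneous priming masquerades as clustering.

## Worked example

```
$ python examples/02_interference_four_genotypes.py
Coincidence law (no suppression): interference -> log2(f)
  primed fraction 1.0: obs DC 0.7551, exp DC 0.7551, interference -0.000 (analytic +0.0)
  primed fraction 0.5: obs DC 0.3728, exp DC 0.1859, interference -1.004 (analytic -1.0)

Four genotype scenarios (5000 cells each):
  tel1_arrest   f=1.00 interference +0.903
  tel1_short    f=0.50 interference +0.029
  tel1d_arrest  f=1.00 interference -0.004
  tel1d_short   f=0.50 interference -1.025
```

With every cell primed (arrest) and no Tel1, cuts are independent
(interference ≈ 0); halving the primed fraction shifts interference to
`log2(0.5) = −1` with no change in the underlying cutting; Tel1
suppression under arrest shows as clearly positive interference, and a
short prophase cancels it back towards zero.  The other examples print a
population summary (`01`), a hotspot-calling run recovering 100 % of
planted hotspots with the background rate estimated at 0.018 vs 0.02
planted (`03`), and a genome-wide fold-change analysis where binned
log2(short/arrest) tracks the planted priming-time gradient with
Spearman r = −0.86, p ≈ 3e−15 over 48 bins (`04`).

A thin CLI wraps the same stages:

```
dsbmap simulate --config cfg.yaml --seed 1 --out run/
dsbmap call-hotspots --fullmap run/fullmap.tsv --cutoff-hpm 0.193 --out hs/
dsbmap interference --frequencies freq.tsv --dc-assay dc --single1 s1 --single2 s2 --out int/
dsbmap compare --numerator a.tsv --denominator b.tsv --bin-kb 50 --out cmp/
```

## Layout

```
src/dsbmap/
  layout.py      synthetic genome: chromosomes, hotspots, priming domains
  simulate.py    per-cell simulator, assays, FullMap generation
  interference.py corrections, CoC, -log2 transform, t-tests
  hotspots.py    smoothing, calling, background, NormHpM, overlaps
  compare.py     correlations, ratios, binning, timing tracks
  maps.py        FullMap container and equal-weight pooling
  io.py          TSV/BED/bedGraph/YAML readers and writers
  pipeline.py    config-driven stage runner with manifests
  cli.py         `dsbmap` command group
docs/methods.md  model description, parameters, numerical choices
examples/        one narrative script per capability
tests/           pytest suite (unit, property and end-to-end)
```
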