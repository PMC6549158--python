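# Methods

## The replication model

`mfaterm` assumes a steady-state exponentially growing population of cells
with circular replicons, each replicated bidirectionally from one or more
origins at a uniform fork speed `v` (bp/min) with doubling time `τ` (min).
The probability that a random cell has replicated locus `x` decays
exponentially with the locus' replication age, so the expected marker
frequency is `MF(x) ∝ 2^(−age(x)/τ)` with

```
age(x) = min over origins i and fork directions d of (offset_i + arc_d(i→x)/v).
```

For equal fork speeds this minimum encodes fork meeting exactly: the fork
that arrives first is the one that replicates the locus.  Consequences used
throughout:

- `log2 MF` is piecewise linear with slope magnitude `b = 1/(v·τ)` per bp,
  descending from each origin to the fork convergence point (fcp) of its
  segment;
- with synchronous origins the fcp of a segment is its midpoint; a firing
  offset `Δ` between the flanking origins shifts it by `v·Δ/2` toward the
  later origin;
- a dependent origin (chr2's oriC2) licensed by replication of a locus on
  another replicon (chr1's crtS) is modelled as an origin with firing
  offset `age(crtS) + extra_delay`, so `MF(oriC2) = MF(crtS)·2^(−delay/τ)`.

Cell-to-cell variability of the convergence position is a Gaussian of width
σ centred on the fcp.  Conditioning on the convergence point `p`, a locus
at arc position `s` is replicated by the left arm's fork when `s < p`,
giving the population mixture

```
MF(s) = Φ((fcp−s)/σ)·2^L(s) + (1−Φ((fcp−s)/σ))·2^R(s),
```

`L`/`R` being the two arms' log2 lines extended across the segment.  Note
the mixture *deepens* the valley near the fcp (for `s` just left of the
fcp, cells that already converged have the locus replicated by the slower
right arm), which is the signature the width fit exploits.  The reported
termination-zone size is `S95 = 2·z₀.₉₇₅·σ = 3.919928·σ`; the 95%
two-sided normal convention was chosen and is asserted to 1e−9 in tests.

## Inference

**Breakpoint stage** (per inter-origin segment, log2 space).  Candidates
are the unmasked bin centres strictly inside the clockwise arc, excluding 5
bins adjacent to each origin (origin-proximal initiation transients).  For
each candidate two *independent* OLS lines are fit (the candidate bin
belongs to both sides); the candidate minimising the summed SSE is the fcp,
ties broken toward the smallest arc coordinate.  The scan is O(n) via
prefix sums of centred moments, and a test asserts exact agreement with a
naive per-candidate polyfit scan.  No sub-bin interpolation is applied: bin
noise dominates below the bin scale.  Regression is unweighted; after the
log transform at near-uniform depth the residual variance is nearly
constant.

**Width stage** (linear space).  σ is found by minimising the linear-scale
SSE against the mixture, with σ bounded in `[bin_size/10, arc/4]`.  Two
numerical points matter:

- *Arm-line re-estimation.*  The breakpoint-stage lines are contaminated by
  the smoothed shoulder (they are fit through it), which biases σ low by
  tens of percent even on noise-free data.  The width fit therefore
  alternates: fit σ, re-fit each arm line using only bins farther than 3σ
  from the fcp, repeat until σ moves < 1%.  On noise-free in-model data
  this recovers σ to < 0.5%.
- *Global 1-D search.*  The SSE-in-σ landscape can have a boundary minimum
  at σ→0 in addition to an interior one, so a 32-point log-spaced scan
  brackets the minimum before bounded Brent refinement.  Non-convergence
  reports the boundary value with a `sigma_converged=False` flag.

An optional joint local re-optimisation of the fcp together with σ
(`refit_breakpoint=True`) is off by default: the breakpoint definition
stays the log-space SSE argmin.

**Origin localisation.**  The same two-line machinery applied to the
inverted V around the profile maximum, within a window (≥ 20 bins; run at
two or more window sizes and compare).  The reported apex is the
*intersection* of the fitted ascending/descending lines rather than the
argmin split candidate: on noise-free data both coincide to within half a
bin, but under Poisson noise the split candidate wanders by roughly
`(12·σ_n²·h/(2b)²)^(1/3)` (~12 kb at 217×-equivalent depth, 1 kb bins)
while the intersection error scales as `σ_n·√(8/n)/(2b)` (~3 kb), which is
what makes the 0.5%-of-replicon validation bound hold in ≥19/20 seeded
runs.

**Reports.**  `segment_report` emits one row per segment — fcp (1-based),
midpoint, signed fcp−mp in bp and |fcp−mp| as % of the arc, slopes, σ,
S95, SSE, and shortest distances from the fcp to every named locus.
`termination_synchrony` classifies chr2 relative to a chr1 fcp from
`Δ = log2MF(fcp2) − log2MF(fcp1)` with a ±0.05 log2 tolerance (≈3.5% copy
number, below which binned profiles at these depths cannot discriminate).
`slope_asymmetry` compares the |slope| of the two arms leaving an origin
and flags ratios strictly outside `[1/1.25, 1.25]`.

## Statistical precision limits (what recovery tests can and cannot show)

Poisson counts with mean λ per bin give per-bin log2 noise
`σ_n ≈ 1/(ln2·√λ)` (0.10 at 200 reads/bin; 0.027 at the ~2900 read starts
per 1 kb bin implied by 217× coverage of 75 bp reads).  Because the true
model is continuous at the fcp, the only information about its position is
where the two arm lines intersect; for 1 Mb arms and slope `b ≈ 8.3e−7`
log2/bp the resulting bound is se(fcp) ≈ 8 kb at 200 reads/bin and ≈ 1.5 kb
at 217×-equivalent depth — no estimator beats this, and the exhaustive SSE
argmin is 2–3× noisier than the bound.  Similarly the Gaussian-width
signature has relative amplitude ≈ `0.16·(2b)·σ`, i.e. ~0.4% of the local
MF for σ = 20 kb, an aggregate SNR < 1 per dataset at these depths: σ of
that magnitude is not identifiable per experiment, and the global SSE
minimum then sits at the lower bound (a near-zero reported S95).  Wide
termination zones (σ of 10⁵ bp, as produced by perturbed, multi-origin
geometries) are identifiable.  The parameter-recovery tests therefore
document the measured errors at the simulated depths; the tight (2 kb /
25%) recovery bounds hold only in the noise-free limit.

## The simulator and its defaults

`simulate` generates binned counts directly — counts are
`Poisson(mean_depth · MF/min MF)` per bin, independent across bins — not
per-read alignments; bin counts are the unit the method consumes (a tiny
BAM writer exists in the tests solely to exercise `depth_from_alignments`).
Defaults define the simulated study conditions:

| parameter | default | why |
| --- | --- | --- |
| τ | 40 min | slow (minimal-medium-like) growth |
| v | 30 kb/min (500 bp/s) | typical bacterial replisome speed; gives b = 8.3e−7 log2/bp, an ori/ter ratio ≈ 2.3 on chr1 |
| bin size | 1 kb | resolves kb-scale S95 while keeping ≥10² reads/bin |
| mean depth | 2000 reads/bin at the profile minimum | ≈217× coverage equivalent for 75 bp single reads |
| σ (WT) | 1 kb | near-deterministic WT termination (S95 ≈ 4 kb) |
| σ (ectopic) | 20 kb | broadened termination with extra origins |
| crtS delay | tuned so WT chr1/chr2 co-terminate | the coupling's biological setpoint |

The fixture geometry is a two-chromosome genome (chr1 2,961,149 bp, chr2
1,072,315 bp) with stand-in landmark coordinates: oriC1 at 0, crtS 695 kb
counterclockwise (left replichore), ectopic origins 650 kb left (45 kb from
crtS) or 1,190 kb right of oriC1, dif1/dif2 placed ~45 kb and ~30 kb from
the respective antipodes.  These are *approximate, clearly-labelled
stand-ins* — real coordinates enter via the genome config.  Head-on
rRNA-operon conflicts are modelled as a multiplicative depression
`1 − magnitude·(1 − d/extent)` applied to bins within `extent` downstream
of the operon, only when the replicating fork travels against the
transcription direction; the linear ramp is a modelling choice (the
phenomenon is qualitative in real data) and makes the head-on arm's fitted
slope shallower, which trips the asymmetry flag.

What the simulator deliberately does **not** emulate: GC/mappability bias,
sequencing error, overdispersion beyond Poisson (an option exists to
stress-test trimming), fork stalling/restart dynamics, per-arm fork speeds,
and the replication-start asymmetry reported for synchronised cultures.
Passing recovery tests therefore demonstrate correctness of the inference
under the model's own assumptions, not robustness to real-data artefacts
beyond the outlier trim.

## Input handling

bedGraph input is 0-based half-open, single replicon per file, uniform
interval width (a final partial bin is allowed); absent intervals are
zero-count bins.  Alignment input must be coordinate-sorted and indexed;
counts are read *starts* per bin (Poisson-like, matching the sampling
model), ignoring unmapped/secondary/supplementary records.  Trimming masks
zero-count bins and Tukey-fence outliers at `Q1/Q3 ± 3·IQR` per replicon
(factor configurable; the rule is a robust stand-in and deliberately
parameter-light).  Normalisation divides by the grand total of unmasked
counts across all replicons, then anchors the scale so the minimum unmasked
log2 MF on the reference replicon (chr1 by convention) is exactly 0 —
keeping the chr2/chr1 copy ratio meaningful.  Masked bins never enter
totals, minima or fits.

## Known limitations

- fcp precision is depth-limited (see above); at routine depths the
  breakpoint argmin carries a ~10–25 kb statistical error on Mb-scale arcs.
- Small σ (S95 ≲ 20 kb) is reported as the search lower bound rather than
  an unbiased estimate; treat such values as "below resolution".
- Firing offsets are deterministic per origin; initiation stochasticity is
  subsumed into σ.
- Linear replicons are supported in the geometry layer but the termination
  machinery targets circular replicons with ≥1 origin per replicon.
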