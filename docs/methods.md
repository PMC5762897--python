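# Methods

## The assay model

The chip is modelled as two mirrored arrays of straight migration channels
(defaults: 450 per side, 30 µm wide, 1 mm long, 40 µm pitch) flanking a
central channel (200 µm wide band in the rendered layout). Channel heights
(5 µm migration, 40 µm main) are carried as metadata only: all analysis
operates on 2-D top-view micrographs, as the assay's imaging does. Because
the migration channel is shallower than a cancer cell's diameter
(10–15 µm), cells cannot stack; a channel is faithfully summarised by the
positions of its cells along the channel axis.

The chemoattractant profile along a channel is the steady-state 1-D
diffusion solution between fixed boundary concentrations, i.e. exactly
linear: `c(x) = c_side + (c_central − c_side)·x/L` for `x ∈ [0, L]`.

## Synthetic scenes and rendering

`sample_scene` places cells in uniformly random channels with a chosen
distance distribution (`point_mass_at_entrance`, `uniform`, truncated
`exponential`, or `two_component`, which sends a configurable migratory
fraction exactly to the channel exit and spreads the rest uniformly). The
number of migratory-component draws is recorded so detection output can be
scored against it. Placement is rejection-sampled so footprints within a
channel keep a 3-px clearance (bounded retries, explicit error when
packing is infeasible). All randomness flows from one `numpy` generator
seeded by the caller; identical parameters and seed give bit-identical
scenes and rendered planes (render noise uses `seed + 1`).

Cells are drawn as hard disks (radius 5–7.5 µm, peak intensity 150–255)
with a 1-px anti-aliased rim; live cells appear in the FITC plane, dead
cells in the TRITC plane **and** at the same peak in the FITC plane,
emulating the residual green signal of dying cells — this is what makes
TRITC-based exclusion a real, testable filtering step rather than a no-op.
Debris is defined operationally: small spots (2 µm radius, peak 60–140)
whose supra-threshold footprint stays below the cell-calling minimum.
The bright-field plane renders the channel layout (so template
registration has structure to lock onto) with cells and debris
superimposed. Gaussian read noise is added per plane and clipped to
[0, 255] at 8 bits.

What the generator does **not** emulate: optics (PSF, depth of field),
photobleaching, uneven illumination, bright-field texture, cell shape
irregularity, or time-lapse dynamics (the assay is end-point scored at
24 h). Passing tests therefore demonstrate correctness of the measurement
chain — segmentation, thresholding, component calling, exclusion rules,
frontier arithmetic — under controlled imaging, not robustness to every
microscope artefact.

## Detection pipeline choices

- **"Bright pixel"** is strictly `value > threshold` (default 50 on both
  fluorescence planes).
- **"Block"** is an 8-connected component (4-connectivity configurable).
  A block is a valid cell when it holds at least `min_bright_pixels = 20`
  bright pixels: at 1 µm/px a 10 µm cell covers ~78 px, so 20 rejects
  debris and single-pixel noise while keeping dim cells. These defaults
  are package choices (exposed in `QuantConfig`), since only the rule —
  not the values — is fixed by the assay's description.
- **Dead-cell rule:** any overlap between a detected object's footprint
  and a supra-threshold TRITC pixel marks it dead (the most conservative
  overlap rule).
- **Frontier:** the along-axis displacement of the farthest live cell's
  *centroid* from the entrance line, clamped to [0, L]. Empty channels
  score 0 — cells remained at the loading position — with
  `reached_central`/`used_in_analysis` flags preserving the distinction
  for auditing. Frontiers within `reach_tolerance_um = 1` of the exit are
  snapped to L and flagged as having reached the central channel; this
  absorbs sub-pixel centroid quantisation at the boundary and matches the
  retrieval semantics (cells past the exit are migratory by definition).
- **Segmentation** is template placement from the known geometry, with
  optional translation registration: the integer shift maximising circular
  cross-correlation between the channel-template mask and the bright-field
  plane. Free-form channel detection is deliberately out of scope — the
  device layout is known by design. Channel ROIs extend 8 px past the exit
  so a cell sitting exactly at the exit is still assigned to its channel.
- **Central window:** analysis restricts to the `central_window = 300`
  channels per side nearest the array midline, where loading is uniform.

### Accuracy of the measurement

Binary-mask centroids of sub-pixel-placed spots carry an inherent
quantisation error of up to ~0.1 px, so exact agreement with ground truth
is only possible for pixel-aligned placements. The zero-error oracle tests
use `sample_scene(snap_to_grid=True)` (exact equality, verified); the
noisy validation benchmark uses continuous placements, so discretisation
is part of the measured discrepancy. The benchmark
(`migchip.benchmarks.frontier_accuracy_benchmark`) uses a 240-channel
device with ~4 cells per channel, 10% migratory fraction, 10% dead cells,
debris, and read-noise sd 10 — roughly half the published device scale,
enough for >200 scored channels — and reports the median relative frontier
error over channels with a true frontier ≥ 50 µm. Typical values are
~0.003%, far below the 3% manual-vs-automated validation bound quoted for
the original software.

## Statistics

Mann–Whitney U uses joint midranks; the exact null distribution is
enumerated when `n1 + n2 ≤ 12` with no ties (≤ 924 arrangements),
otherwise the normal approximation with tie and continuity corrections.
The two modes agree within 0.01 wherever exact p ≤ 0.2; at mid-range p
(0.3–0.5) the gap can reach 0.0155 at n = 6/6 (full enumeration), which is
immaterial for significance calls. Box summaries use linear interpolation
between order statistics (numpy's default quantile convention,
documented because plotting software defaults vary). The sphere-rate
t-test is the pooled (Student's) two-sample test. Stars use strict
inequalities: *** p<0.001, ** p<0.01, * p<0.05.

## Limiting-dilution analysis

Single-hit Poisson model: `P(take | dose d) = 1 − exp(−f·d)`. One dose
group has the closed-form MLE `f = −ln(1 − k/n)/d`; several groups are
fitted by Newton iteration on `ln f` (the complementary-log-log binomial
GLM with offset `ln d`; tolerance 1e-10, ≤ 100 iterations, damped steps).
The 95% CI is Wald on `ln f` from the observed information — for a single
group this reduces to the delta-method form
`SE(ln f) = SE(p̂)/((1−p̂)·d·f̂)` — and is reported on the reciprocal
scale, upper bound (fewer stem cells) first, the convention of
limiting-dilution tables. Note that observed and expected (Fisher)
information differ under the non-canonical cloglog link; this package uses
observed information throughout (tests cross-check against a
finite-difference Hessian and a statsmodels GLM fit for the point
estimate).

Reproducibility note: for 4 takes of 10 implants at dose 100 this method
gives reciprocal 195.8 with interval (527.2, 72.69), matching the
published table to printed precision. For 9 of 10 it gives 43.43 with
interval (97.4, 19.4); the published upper bound for that arm (94.4) is
reproduced by neither the Wald nor the profile-likelihood interval
(101.0, 19.5) and its provenance is unclear, so only the 4-of-10 interval
is asserted in the acceptance checks.

Degenerate arms: all-negative outcomes report frequency 0 with a flag
(a boundary MLE, as in the published table's 0/10 row); all-positive
outcomes have no finite MLE and raise unless a continuity-corrected
(k → n − ½) one-sided bound is explicitly requested. The
likelihood-ratio arm comparison uses the convention that a boundary arm
contributes log-likelihood 0, keeping the statistic finite.

## Gene prioritization

Per-line significance is strict: p < 0.01 and |log2FC| > 1 (fold change
> 2); raw p-values are used, as no multiple-testing adjustment is
specified for this filter. Cross-line overlap keeps only genes changed in
the same direction in both lines. The survival screen splits patients at
the median expression (ties to the low group, kmplot-style), builds
Kaplan–Meier curves per group (lifelines), and computes the log-rank
statistic and a Mantel–Haenszel hazard ratio `HR = (O₁/E₁)/(O₂/E₂)` over
distinct event times — self-contained O/E machinery rather than a Cox
fit, matching the log-rank computation exactly. Concordance keeps a
down-regulated gene only when the low-expression group fares
significantly worse (HR_low > 1, log-rank p < 0.05, configurable), and
symmetrically for up-regulated genes. Survival data are user-supplied or
simulated; there is no online retrieval.

The packaged cross-line table carries the published per-line log2 fold
changes without p-values (the source table prints none); its genes are
significant by construction, so per-line sets are built from table
membership and fold-change sign. The packaged ordering is preserved as
printed; no ranking rule is asserted.

## Problem sizes

Default test and benchmark scenes use 10–30 channels per side; the
accuracy benchmark uses 120 per side (240 channels, ~960 cells). These
sizes give exact or tightly-bounded oracle comparisons at interactive
runtimes; the geometry scales to the full 900-channel device by changing
one constructor argument (covered by a channel-count test on the full
layout).

## Known limitations

- Registration handles translation only; rotation/scale drift is out of
  scope (stage-mounted chips justify this, but bent mounts would break it).
- Frontier uses the centroid, not the leading edge, of the farthest cell;
  the two differ by up to one cell radius (documented choice, the
  published description does not specify).
- The O/E hazard ratio is mildly conservative relative to a Cox estimate
  for strong effects (HR 2 recovers as ~1.9 in simulation).
- Debris is distinguished by size alone; real debris may also be excluded
  by intensity, which the generator does not separately exercise.
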