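# Methods

This note documents the models, numerical conventions and design choices
behind `stereosim`, in the spirit of a simulation package's methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic tissue model

A simulated striatum is an axis-aligned box, by default
2800 × 2000 × 2400 µm (x medio-lateral, y dorso-ventral, z
anterior→posterior), giving 60 coronal sections at 40 µm. Published mouse
work does not report striatal bounding dimensions; the box was chosen to be
of realistic millimetre scale and to hold roughly 10⁶ neurons at plausible
density. Neurons are independent uniform points — a homogeneous spatial
model with no somatotopy, gradients or exclusion volumes.

**Between-animal counts.** The per-animal true count is lognormal with
matched mean and CV (counts are positive; at CV ≈ 0.1 the lognormal is
nearly symmetric, and no negative draws are possible). The default CV of
0.116 is calibrated from a published 12-week wild-type group: SEM 38483 at
n = 9 gives SD ≈ 115449 against a mean of 993891. `cv = 0` yields the
rounded mean exactly, which the validation harness uses to pin the truth.

**Cell-body volumes.** A two-component lognormal mixture: 95% "medium
spiny" component with median 580 µm³ (σ_log 0.38) and 5% interneuron
component with median 1150 µm³ (σ_log 0.28). No distributional parameters
are reported for real striatal volume data; the mixture was calibrated once
so the population spans roughly 150–1500 µm³, covers the 200–1050 µm³
analysis range, and places ≈ 49% of cells in the 550–1050 µm³ band. Volumes
are independent of position.

**Disease effect.** A per-cell process applied to a healthy tissue: removal
with probability `loss_probability(v)` and multiplicative shrinkage of
survivors by `atrophy_fraction(v)`. The default late-disease effect is
banded: 26% removal and a 0.85 shrink factor inside 550–1050 µm³, zero
outside. With the default mixture (band probability 0.490) the expected
whole-tissue loss is 0.26 × 0.490 ≈ 12.7% — the published 12-week deficit
scale. Atrophy additionally pushes surviving band cells into smaller bins,
reproducing the qualitative pattern of deficits inside the band with mild
(non-significant) increases below it.

## Virtual microscopy

Sections are half-open z-intervals `[z, z+t)` tiling the extent; the
counting point is the neuron's position point (an idealized nucleolus), so
section assignment is an exact partition. Every `period`-th section is kept
after a uniform random start. Counting frames sit at the origin corner of
each `g × g` grid tile; the whole pattern is translated by an offset drawn
uniformly in `[0, g)²` **once per animal** (a documented convention —
commercial systems vary between per-animal and per-section randomization).
Frame membership is open on the left/bottom (forbidden) edges and closed on
the right/top, matching the half-open tiling, so with ssf = asf = tsf = 1
every point is counted exactly once — asserted exactly by the tiling-oracle
tests. Tissue shrinkage, lost caps, optical blur and mounting artifacts are
not modelled.

## Estimator properties and precision

The fractionator factors are exact by construction (1/12 · 0.0064 · 0.5
with default geometry), and unbiasedness over the random start and offset
is verified by a 200-animal two-SEM test and exactly by the tiling oracle.

Precision deserves a note. With the default design each animal yields
ΣQ⁻ ≈ 265 counted cells, a Poisson floor of CV ≈ 6%. On top of that, the
box tissue spans 5.6 grid periods along x and every section shares the same
rectangular outline, so the frame-coverage fluctuation induced by the
random grid offset (CV ≈ 8.5%) is perfectly correlated across an animal's
sections. The resulting per-animal CE of N̂ is ≈ 10%, higher than the ~5%
typical of real fractionator runs, where section profiles vary and
decorrelate the coverage term. This is a known property of the idealized
box geometry, not of the estimator: means over replicate animals converge
to truth, but a 20-replicate mean still carries ≈ 2.3% standard error,
which should be kept in mind when interpreting recovery checks at that
scale.

**Dissector window.** The real protocol's dissector height and guard zones
are not reported; defaults are a 20 µm dissector inside 2 µm guard zones in
40 µm sections (tsf = 0.5). Estimates are invariant in expectation to this
choice, which the suite asserts through the unbiasedness tests.

**Nucleator.** Simulation ground truth stores a volume scalar per cell, not
a shape, so the measured profile is the equatorial disc of a sphere of the
cell's volume — the nucleator then returns that volume exactly, and the
measured-volume noise in downstream analyses comes from sampling which
cells are counted. Non-spherical behaviour is exercised separately: for
ellipsoid sections under isotropic central planes, `EllipseProfile.
spheroid_section` provides the geometry and the Monte-Carlo tests confirm
(4π/3)·E[l³] recovers the true volume within 1% at 10⁵ draws. "Five
isotropic uniform random sections per cell" is implemented as five
isotropic rays of the 2D nucleator.

## Population statistics

Size bins are half-open `[k·50, (k+1)·50)` µm³ anchored at 0. Per-bin
population numbers are `N̂ × (cells in bin)/(cells measured)`, conserving
N̂ exactly; bins with no measured cells inside the observed range are 0,
not missing. Group tests are pooled-variance Student's t (consistent with a
single reported SEM for both groups in the source analyses), two-sided by
default; no multiple-testing correction is applied across bins unless the
Benjamini–Hochberg switch is enabled. Degenerate zero-variance bins resolve
to t = 0, p = 1 on equal means and ±∞, p = 0 otherwise.

The scaled-down study simulations used in validation run at the
measurement level (true counts plus 350 measured cells per animal — the
real per-animal workload — with the virtual-microscopy stage bypassed,
since its calibration is established separately). The per-bin test's type-I
rate is checked on a single well-populated reference bin over 2000 null
studies; the banded-deficit pattern is aggregated over 20 replicate studies
because a single 25-bin study throws spurious α = 0.05 rejections with
appreciable probability.

## Kinetics and power

Kinetics is deliberately minimal: linear loss from a 60-day onset to an
84-day sacrifice (12 weeks; the conversion to days is a package default),
an 8-hour detectable-death window, and a uniform anterior–posterior density
by default — a non-uniform normalized density profile can be supplied
rather than reverse-engineering any particular level-specific weighting.
Each operation is homogeneous of degree 1 in its leading argument.

The sample-size solver iterates the noncentral-t power function
(df = 2n−2, noncentrality δ/√((s₁²+s₂²)/n)) for the smallest n reaching
target power; rescue is defined on the deficit above the affected baseline
(treated mean = baseline + rescue_fraction × deficit), and each group's SD
is cv × its own mean, so the treated group is slightly more variable. A
closed-form normal approximation is exposed as an independent cross-check;
the two agree within 2 animals for standardized differences ≥ 0.5, and
simulated pooled t-tests reproduce the noncentral-t power within
Monte-Carlo error.

## Determinism

All randomness flows from integer seeds through numpy `SeedSequence`
streams: each animal derives five independent substreams from
`(cohort seed, animal index, stage)`, so cohorts are reproducible and
order-independent, and a fixed study seed makes every output file
byte-identical across runs.

## Known limitations

- Homogeneous box tissue: no anatomy, no spatial structure in loss, and the
  coverage-variance inflation described above.
- Volume-scalar ground truth: nucleator shape error is validated on
  analytic ellipsoids, not on reconstructed neurons.
- The kinetics layer is an arithmetic identity on its assumptions (linear
  loss, fixed window), not a mechanistic death model.
- Passing tests demonstrate correctness of the estimators and statistics on
  the generative model above; real tissue adds shrinkage, staining and
  segmentation errors that are out of scope here.
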