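# Methods

This note documents the models implemented by each pipeline, the defaults
and why they were chosen, what the synthetic phantoms do and do not emulate,
and the numerical choices that matter.

## Conventions

Pixel/voxel coordinates are 0-based, `(z, y, x)` ordered, half-open; the
physical position of a voxel centre is `index × voxel_size`. z index 0 is
the lowest z — the substrate side, below the basement membrane — so cells
seeded on top of the membrane invade toward decreasing z. Positions and
lengths are in µm, forces in nN, moduli in Pa, bead displacements in nm.

## Q-Pi: percent volume invasion

**Segmentation.** The cell channel is smoothed with a Gaussian (σ = 1 px),
thresholded with Otsu's method, and closed with a 3 px disk applied slice by
slice (slice-wise closing avoids border erosion artifacts that a 3D closing
with zero padding would introduce). Otsu always returns *some* threshold, so
a contrast guard rejects the split unless foreground exceeds background by
at least 4 background standard deviations — this is what makes a blank or
pure-noise slice yield no cells instead of percolated noise blobs. Cell
identity across slices is defined by 3D connected components of the
thresholded volume, which avoids fragile per-slice contour matching. Cells
touching the lateral image border are excluded by default because their
hull volume would be truncated.

**Contour reduction.** Slice boundaries (subpixel, from marching squares at
the 0.5 level) are reduced to dominant points with the Teh–Chin (1989)
adaptive region-of-support method: each point grows its support while the
chord keeps lengthening and the arc-to-chord ratio strictly rises with a
consistent bending sign (a point collinear with its immediate neighbours
gets support 1 — this is what confines a straight run's support within its
corners); significance is the k-cosine over that support; non-maxima within
half the support are suppressed, exactly-straight survivors removed, and
adjacent runs collapsed to their best member. A final refinement pass
re-inserts the farthest chain point of any arc deviating more than
`max_deviation` (default 1 px) from its chord, which bounds the Hausdorff
distance between the polygon and the chain — so hull volumes cannot be
degraded by an over-aggressive approximation on smooth arcs, and the
rasterized-square case still reduces to exactly its 4 corners.

**Ellipses.** Regression ellipses (direct least-squares conic fit) are
computed per slice for QC and visualisation. The hull is built from the
dominant contour points by default, because the volume model is the hull;
building it from sampled ellipse outlines instead is available via
`hull_source="ellipse"` for users who prefer the smoothed-shape convention.
The two differ by well under a percentage point on ellipsoidal phantoms.

**Membrane plane.** The laminin bilayer appears as two peaks in the
per-slice mean intensity of the membrane channel. The reference plane is
the highest-z local maximum exceeding the profile median by 3 robust
(MAD-based) standard deviations; exact ties resolve to the higher z, which
is what "upper layer" means. The membrane is treated as a single horizontal
plane; tilt correction is out of scope.

**Clipped volume.** The fraction of hull volume below the plane is computed
exactly: the clipped region of a convex body is itself convex and its
vertex set is exactly {hull vertices on or below the plane} ∪ {edge–plane
intersections}, so its volume is one further convex-hull evaluation. This
is algebraically identical to clipping a tetrahedral decomposition
term-by-term, with no case table. It satisfies `below + above = total` to
1e-9 relative, is monotone in the plane position, and agrees with a
10⁶-sample Monte-Carlo point-in-hull oracle within 0.5 percentage points
(tested on random hulls).

**Cumulative counting.** Daily invaded-cell counts per ROI are averaged,
divided by the number of mesenteries in the well, and cumulated by running
summation of both means and standard errors (errors summed, not in
quadrature — the convention of the counting protocol this mirrors).

## Micropillar traction

Spring constant: `k = 3EI/L³` with `I = πd⁴/64` (Euler–Bernoulli cantilever
under lateral tip load; shear compliance is neglected, appropriate for
d/L = 0.2 slender pillars). For E = 2 MPa, L = 5 µm, d = 1 µm this gives
2.3562 nN/µm.

Tracking fits a 2D Gaussian to each pillar top over a window of side
2/3 pitch centred on the pillar's previous position (so slow drift cannot
unlock a pillar); an intensity-centroid fallback is used when the fit
diverges, and a pillar whose centre leaves its window is flagged lost
rather than aborting the run. The rest position is the frame-1 fitted
position ("zero force"); if a cell already pulls at frame 1 the measured
displacements are offset accordingly — a documented limitation of the
initial-position convention. Stage drift is the unweighted mean (median
optional) of the raw displacements of user-chosen cell-free reference
pillars, subtracted per frame. Forces are `k·|displacement|`; the per-cell
aggregate defaults to the mean of per-pillar peak forces
(`aggregate="peak_of_means"` gives the alternative reading), since peak
heat maps are per-pillar maxima.

## Magnetic tweezers

Pulse windows are arithmetic once the onset is known (pulse i spans
`[onset + i·7 s, … + 3 s)` at the 12 × 3 s/4 s default regime); an unknown
onset is estimated by correlating the trace derivative with the regime's
on/off template, exact to one sample on clean traces. Amplitude is
`max − start` within each window — the start subtraction is the drift
handling; no detrending is applied. The stiffening statistic uses pulses 1
and 12 only: `r₁₂ = A₁₂/A₁`, `decrease = 100(1 − r₁₂)`; a trace is included
iff `A₁₂ < A₁` (strictly). "No initial response" is declared when A₁ fails
to exceed 3× the MAD-based SD of the pre-onset baseline (the protocol
itself states no threshold; 3 robust SDs is the usual detection
convention), and beads moving against the force (A₁ ≤ 0) are excluded with
a reason code. Cohort statistics average per-bead ratios; computing the
ratio of cohort-averaged amplitudes is the alternative convention and gives
the same answer for narrow amplitude distributions.

Note that the `max − start` convention carries a small positive noise bias
(the maximum of signal + noise over a window), which partially cancels in
the ratio; at the default 2 nm noise it depresses a programmed 25% cohort
decrease by roughly 1.5 points. This is a property of the estimator as
defined, not of the implementation, and affects real traces identically.

## AFM compliance

Hertz spherical indenter: `F = (4/3)·E/(1−ν²)·√R·δ^{3/2}`, ν = 0.5 by
default (incompressible cell; exposed as a parameter). Indentation is
deflection-corrected: `δ = (z − z_c) − F/k` — at k = 0.03 N/m and 1 nN the
cantilever itself deflects 33 nm, a few percent of the indentation of a
~300 Pa cell, so skipping the correction would bias E upward. The contact
point minimises the joint residual of a flat pre-contact baseline and the
Hertz law post-contact: a coarse scan over sample positions brackets the
optimum and a bounded golden-section refinement localises it (xatol 1 nm).
Given the contact point, E has a closed-form linear least-squares solution
in `δ^{3/2}`. The fit uses the post-contact region up to the 1 nN set force
by default. Only approach curves are analysed; batch mode reports both the
mean and the median modulus of a dish's curves, since cohort moduli are
conventionally reported either way.

## Phantoms: what they emulate, and what they do not

All generators are pure functions of their spec including the seed
(bit-identical repeats). Defaults encode the experimental protocols:
0.2 µm z-step stacks; a laminin bilayer 0.8 µm apart (layer thickness
σ = 0.15 µm) — separation is not stated by the imaging protocol and is an
exposed assumption; pillar frames at 1 frame/s; the 12 × 1 nN × 3 s/4 s
pulse regime; curves with R = 7.5 µm, k = 0.03 N/m, 1 nN set force, 5 µm/s
approach.

Noise levels are not stated by the protocols and were chosen once as
field-realistic values: confocal additive noise SD 20 on cells of
intensity 1000 (SNR 50); pillar images with spot amplitude 1000 and noise
SD 10 (bright-field pillar imaging is high-SNR); bead traces with 2 nm RMS
position noise and 0.5 nm/s drift; force curves with 20 pN RMS noise.

The phantoms emulate geometry and noise statistics, not instrument optics:
the PSF is an isotropic Gaussian (no confocal axial elongation or spectral
bleed-through), noise is Gaussian (no Poisson photon statistics), cells are
ellipsoids (no filopodia or concavities — irrelevant to a convex-hull
readout, but real segmentation masks are rougher), pillar spots are ideal
Gaussians, and tweezer responses are exponential rise/relax creeps rather
than full viscoelastic power laws. Passing the phantom suites therefore
demonstrates correctness of the *computational* pipelines under realistic
noise, not robustness to every optical artifact of real microscopes.

## Problem sizes and tolerances used in validation

The invasion sweep uses 20 single-cell phantoms (96×96 lateral at 0.15 µm,
z adaptive at 0.2 µm, radii 2–3.2 µm) spanning analytic invasion fractions
0–100%; recovery is well inside the 3-point mean-absolute-error target
(measured ≈ 0.4 points) and the hemisphere case lands within 1.5 points of
50%. The clip-vs-Monte-Carlo check uses 10 random 30-point hulls at 10⁶
samples each. The pillar check uses a 6×6 lattice over 40 frames with 12
loaded pillars (0.1–0.425 µm) plus a random-walk stage drift. The tweezer
cohort uses 30 traces with programmed decreases evenly spaced 15–35%
(mean exactly 25%). Hertz round trips cover 50–5000 Pa. These sizes keep
the full validation suite under half a minute while leaving each statistic
well-resolved.

## Known limitations

- Deeply invaded cells whose top has passed below the membrane are still
  modelled by their full hull; cells that have fully transmigrated are
  invisible to Q-Pi (they no longer intersect the imaged membrane) — the
  cumulative counting assay is the complementary readout.
- Convex hulls overestimate the volume of concave cells by construction;
  the percent-invasion ratio is less sensitive than the absolute volume.
- Pillar rest positions from frame 1 assume no load at acquisition start.
- The tweezer statistic is a two-point ratio; it does not model creep
  dynamics within pulses.
- Membrane tilt and curvature are not corrected; the plane is horizontal.
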