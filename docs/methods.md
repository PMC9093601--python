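# Methods

This note documents the models, numerical choices and open design
decisions behind `pseudotract`, in the order data flows through the
pipeline.

## Tensor model and fit

Signals follow the monoexponential Stejskal–Tanner model
`S_k = S0 · exp(−b_k g_kᵀ D g_k)` with a single symmetric tensor `D`
per voxel. The fit is **ordinary (unweighted) log-linear least
squares** on `ln S_k`, solving for the six tensor components and
`ln S0` jointly; `S0` is therefore the fitted intercept rather than an
average of the b=0 volumes, which uses all volumes and is exact on
noise-free input. OLS was chosen over weighted or nonlinear variants
because it is deterministic, closed-form, and verifiable to 1e-9
mm²/s against forward-simulated signals; it is, however, not
guaranteed to match what a particular clinical toolbox estimates, and
a weighted fit would behave differently at low SNR. Signals are
floored at 1e-12 before the log. Gradient tables must contain at least
one b=0 volume and six non-collinear diffusion directions (checked by
the rank of the design matrix), otherwise the fit is refused.

Scalar metrics come from the sorted eigenvalues: MD (mean), L1
(largest), RD (mean of the two smaller — the two radial eigenvalues
are reported as one quantity throughout), FA (normalized eigenvalue
dispersion, clipped to [0, 1]). Negative eigenvalues — a noise
artefact — are clamped to zero before metric computation and counted
in a QC field. The FA of an all-zero tensor is defined as 0 so
background voxels never produce NaN.

## Coordinate conventions

Voxel indices are 0-based; world space is RAS+ millimetres; streamline
points are stored in world mm so tract selection is independent of the
grid. Anterior–posterior is world +y; every fractional ROI rule
("anterior 1/6 of the corpus callosum") is measured along the +y axis
of the named structure's bounding extent. Measuring along the callosal
arc instead of the bounding box would be an alternative reading of
such rules; the axis-aligned extent was chosen as the simpler, fully
specified convention and is applied consistently.

## Tractography

Deterministic fixed-step Euler integration along the principal
eigenvector (FACT-style). The direction at an off-grid point is the
trilinear blend of the eight surrounding voxels' principal
eigenvectors, each first sign-aligned to the incoming direction
(eigenvectors are axes, so the sign is arbitrary per voxel) and
weighted by the voxel's FA in addition to the trilinear weight, which
suppresses the meaningless eigenvectors of near-isotropic neighbours
at bundle edges. Tracking is bidirectional from every seed; seeds sit
at voxel centres (or on a fixed subvoxel grid for densities > 1), so
the output is fully deterministic and independent of seed order.

Termination: interpolated FA below threshold, per-step turning angle
above threshold, leaving the grid, or reaching the length cap;
streamlines shorter than the minimum length are dropped. Defaults —
step 0.5 × voxel, FA 0.2, angle 45°, density 1, min length 10 mm, max
300 mm — are conventional deterministic-tractography values; the
reference clinical workflow this mirrors does not publish its
termination settings, so these defaults are a documented choice, not a
reproduction, and are recorded in each tractogram's provenance.
Runge-Kutta integration was deliberately left out: at the 2.7 mm
resolutions targeted here, Euler at half-voxel steps converges to
within 2% in arc length against step halving.

## Tract recipes and gate logic

Each tract is an ordered list of AND/NOT gates. A streamline is kept
iff it intersects every AND mask and no NOT mask; intersection is
tested at streamline vertices after world→voxel rounding, which cannot
tunnel through a one-voxel-thick gate as long as the step size is at
most half a voxel (the default). A segment-based strict mode was
considered and rejected as unnecessary at the default step size.

Gate placements are anatomical rules resolved against named landmark
masks (fractional slabs, edge/centre/max-area slices, parasagittal
slices at a structure's lateral edge, the midsagittal plane), never
hard-coded slice indices — the same recipe file therefore works in
template, subject, or phantom space, and a rule citing a structure the
reference lacks fails loudly with the structure's name. The shipped
recipe file encodes the eight study tracts with the published gate
structure (gCC 2 gates, bCC 2, ATR 4, IFO 3, ILF 4, PLIC 3, PTR 4,
UF 4; 14 instances per subject after bilateral expansion). A tract
instance is "generated" if at least one streamline survives its
gates; success rates are generated/attempted with half-up rounding to
one decimal.

## Cross-subject propagation and alignment

The pseudo-atlas workflow resolves gates once on a template subject
and maps the masks into each subject grid with nearest-neighbour
resampling (masks stay binary; scalar maps are interpolated
trilinearly). Three transform sources are supported: identity (no
alignment), landmark ACPC alignment (AC to the origin, AC→PC along −y,
midsagittal plane to x = 0; rigid by construction), and affine FA→FA
registration. How the original clinical tool propagated template ROIs
across subjects is not disclosed; affine propagation is the minimal
faithful mechanism and is recorded in provenance. Likewise, "warping"
an atlas may well be nonlinear in existing tools; only affine warps
are implemented here, which the atlas comparator inherits.

Registration minimizes mean squared intensity difference over a
12-parameter affine (translation, rotation, scale, shear), optimized
by a **deterministic gradient-free pattern search** with a fixed
step-halving schedule over three resolution levels (×4, ×2, ×1
downsampling with Gaussian pre-smoothing). No random restarts, no
seed: identical inputs give identical transforms, and the
full-resolution cost is asserted non-increasing across levels (a
coarse level that overfits its own grid is reverted). Final step sizes
(0.1 mm / 0.1° / 0.002) bound the achievable precision; recovery of
synthetic transforms is tested to 0.5 mm and 0.5°. Mean squared
difference assumes same-modality registration (FA to FA); a
correlation cost for cross-modality use is a known omission.

## Evans' index

EI = maximal frontal-horn width of the lateral ventricles / maximal
internal cranial width, both measured along world x over axial slices
of ACPC-aligned masks. Widths count whole voxels ((i_max − i_min + 1)
× pitch), so a ventricle mask equal to the skull mask yields exactly
1.0 and the ratio is invariant under isotropic rescaling. The
frontal-horn compartment is taken as ventricle voxels anterior to the
AC plane — an automation heuristic replacing the manual slice choice a
human rater would make; an explicit horn mask can override it. Width
quantization at coarse grids means small enlargements can leave EI
unchanged; the default 2.7 mm grid resolves the phantom's graded
enlargement.

## Profiles and aggregation

Per-tract metrics are means of trilinearly sampled map values over
streamline vertices (tractography-weighted averaging; a visited-voxel
mode was considered and left out to keep one auditable definition).
Left/right metrics are averaged per subject; if exactly one side is
missing the present side is used and flagged (`single_side`) — the
alternative policy of excluding such subjects is stricter but discards
data, and the choice is surfaced in the output rather than hidden.
Radar profiles display FA×20 and MD/L1/RD×10⁴; the raw values are
carried alongside the scaled ones so descaling is exact by
construction. Along-tract profiles resample each streamline to
`n_nodes` (default 50) equidistant arc-length nodes, orienting
streamlines either along a caller-specified world axis or by endpoint
matching to the first streamline.

## Statistics

Method comparison uses pairwise deletion (subjects missing either
method are dropped per row, surviving n reported; fewer than 3 pairs
marks the row insufficient), Pearson r with its two-sided p, and the
two-sided paired t-test, all via closed-form-verified routines. The
printed mean difference is comparator − pseudo-atlas, so a negative
value means the pseudo-atlas metric is higher. Confidence ellipses are
the χ²(2)-quantile contours of the fitted bivariate normal (sample
covariance); metric-vs-EI association is OLS slope + Pearson r. No
multiple-testing correction is applied anywhere, and two-sided tests
are used throughout; rounding follows the comparison tables'
precision (percentages 1 decimal half-up, r 3 decimals, mean
differences 4 decimals). The bilateral averaging step induces
dependence that the correlation p-values do not correct for; this is
a documented limitation, not an oversight.

## The phantom: what it emulates, and what it does not

A subject is rendered on an axis-aligned grid (default 64³ at 2.7 mm,
matching the emulated acquisition) whose anatomy is posed by a random
rigid transform drawn within `pose_jitter` (default up to 10° / 5 mm —
ordinary head-position variation; the ACPC experiments raise it to
25°). The grid stays axis-aligned while the content rotates, exactly
like a non-ACPC-aligned scan. Geometry, in a canonical frame with the
AC at the origin: an inner-skull ellipsoid of isotropic 0.9e-3 mm²/s
tissue (grey-matter-like MD, deliberately above the bundles' MD so
that overspilling atlas labels raise MD); paired ventricles (ellipsoid
bodies plus frontal-horn protrusions anterior to the AC, isotropic
3.0e-3 mm²/s CSF) whose analytic horn width 2·(14 + 6·scale) mm makes
EI checkable by construction; and three bundle archetypes — a midline
corpus-callosum-like arch (radius-30 mm arc, eigenvalues
(1.7, 0.3, 0.3)e-3), vertical internal-capsule-like tubes lateral to
the ventricles ((1.6, 0.35, 0.35)e-3), and long anterior–posterior
fronto-occipital-like tubes ((1.5, 0.4, 0.4)e-3) — plus box-shaped
synthetic landmark regions (thalamus, pons, brainstem, cingulum,
lobes, parieto-occipital marker) sized so every shipped recipe
resolves. Overlapping bundles are resolved later-wins and flagged.
Noise is Rician (default σ = 0.02·S0, i.e. SNR 50, a typical DTI
acquisition), applied to the magnitude signal.

Graded ventriculomegaly cohorts scale the ventricle semi-axes linearly
across subjects (0.9–1.5) and couple the internal-capsule eigenvalues
to the enlargement (+0.25e-3 axial, −0.05e-3 radial per unit scale
excess): the compression pattern of periventricular tracts — FA and
MD both rise with EI. The mismatched-atlas comparator dilates the
template's bundle masks by two voxels and shifts them 4 mm, emulating
a population template that overspills into tissue and CSF.

What the phantom does **not** model: real anatomy, crossing or kissing
fibres (beyond simple overlap), partial-volume gradients at bundle
edges (voxels are all-or-nothing), susceptibility/eddy distortion, or
atrophy of the bundles themselves. Consequently, passing tests show
the *pipeline machinery* is correct — fit exactness, gate logic,
transform recovery, the direction and sign of method disagreements
that are built into the geometry — not that clinical effect sizes
would be reproduced on patient data. Three of the eight recipes (ATR,
PTR, UF) have no corresponding phantom bundle and legitimately report
missing tracts; they exercise the resolver and the missing-data
accounting. The ILF recipe selects from the fronto-occipital bundle
(the phantom's only temporal-occipital surrogate) and is the most
marginal under pose jitter.

## Problem sizes

Default test and acceptance runs use 64³ × 2.7 mm subjects (46
volumes), cohorts of 6 (pose-jitter experiment, 48³ × 3.6 mm) and 8
(ventriculomegaly, 64³), chosen as the smallest sizes at which every
geometric feature spans several voxels and cohort statistics have
stable signs across seeds.
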