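# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic data used to test them, and the
numerical choices made where the design was genuinely open.

## Staged fiducial transform (`coregmatch.transforms`)

**Model.** The EM-to-2P map is a composition of eight stages in four
groups, each fitted by least squares between the previous stage's output of
the source (EM) fiducials and the 2P targets:

1. *Global degree-2 polynomial* — 10 monomials per output axis; captures
   scale, rotation, shear and one global nonlinear term.
2. *Z-binned polynomials* (5 bins, then 21) — independent degree-2 fits per
   equal-width z bin of the stage input, correcting residual trends aligned
   with the EM sectioning axis (section-shape changes between knife
   cleanings). A bin with fewer than 10 pairs recruits members from a
   symmetrically widened window (10% of the bin width per step).
   Evaluation blends adjacent bin models linearly within a configurable
   half-width (default 5 um) of each edge; half-width 0 gives piecewise
   evaluation with a jump equal to the inter-bin model difference. The
   paper-gap choices here: equal-width bins on the source z axis, and
   linear edge blending so a transform meant to be smooth has no artificial
   discontinuities.
3. *Grid TPS* (n = 3, 5, 10, 12) — the stage's displacement field is the
   3D thin-plate interpolant through an even n x n x n lattice spanning the
   fiducial bounding box; the free parameters are the lattice-node
   displacements, solved by penalized least squares on the fiducial
   residuals. The kernel is the first-order polyharmonic phi(r) = r with an
   affine term (the standard 3D "thin-plate" choice). The penalty is an L2
   ridge on node displacements scaled to `regularization_weight x
   trace(L'L)/m` (default 1e-6, i.e. relative); it guarantees solvability
   when nodes outnumber fiducials. Because a constant displacement lies in
   the affine span, a pure translation residual is reproduced exactly.
4. *Exact TPS* — every fiducial becomes a control point; the interpolation
   system is solved directly, so control-point residuals drop to machine
   precision (reported mean 0 to ~1e-9 um on the synthetic sets). This
   stage is maximally sensitive to annotation error, which is why
   evaluation switches to leave-one-out.

Polynomial fits are performed on centred/scaled coordinates, making
diagnostics translation-equivariant to ~1e-12 and keeping the degree-2
design well conditioned over mm-scale boxes.

**Evaluation.** `residual_report` gives in-sample per-fiducial Euclidean
residuals (um). `loo_residuals` refits the entire stack once per held-out
fiducial and records the held-out residual — the package's estimate of
accuracy at a new point. A `subset` argument evaluates a random or strided
subsample of fiducials when a full O(n) sweep of refits is not warranted;
the tests use 20 held-out points at n = 500 and full sweeps at n = 21-120.

**Capacity at desk scale.** The n = 10 and n = 12 lattices carry 1,000 and
1,728 nodes. At the production scale this transform targets (~3,000
fiducials) they are over-determined; at a 500-fiducial desk scale they can
interpolate the annotation noise, which inflates leave-one-out error even
though in-sample residuals fall monotonically. The regression band on
warp recovery (LOO mean within 3x the annotation noise) is therefore
asserted with a capacity-matched schedule (grids n = 3, 5); the canonical
schedule is asserted for stage-wise monotonicity, exactness of the final
stage, and LOO >= pre-exact in-sample residual.

**Inversion.** The stack is fitted one way (EM->2P); the other direction is
damped fixed-point iteration `q <- q + 0.8 A^-1 (p - T(q))`, preconditioned
with the inverse affine part A of the global polynomial, to a caller-set
tolerance (default 1e-3 um, max 200 iterations; non-convergent points are
reported by index). Points outside the fitted bounding box are transformed
but flagged with an `ExtrapolationWarning` — edge regions are exactly where
an interpolating transform is least trustworthy.

## Soma matching (`coregmatch.matching`)

Units and transformed EM centroids are paired per scan by minimum-weight
bipartite matching on Euclidean distance (`scipy.optimize.
linear_sum_assignment`), the globally optimal one-to-one assignment;
surplus rows on the larger side stay unmatched. A configurable cap
(default 25 um) forbids absurd pairings; pairs costed above the cap are
dropped after the solve. Matching per scan is what lets one EM neuron
carry several functional units across scans.

Scores per match: *residual* = matched distance (um); *separation* =
distance to the nearest EM neuron other than the matched one, minus the
residual — positive exactly when the matched neuron is the unit's nearest
neighbour, negative when a nearer candidate was passed over. Percentiles
use the average-rank convention `pct = (rank - 0.5)/n x 100` within the
table (per-scan grouping available); filtering keeps
`residual_pct <= max` and `separation_pct >= min`. Hybrid agreement is an
inner join of two automatch tables on (session, scan_idx, field, unit_id,
em_id). Evaluation against manual matches first restricts both tables to
rows whose unit or neuron was attempted in both ("commonly attempted"),
then counts tp/fp/fn; undefined ratios are reported as NaN, never 0. With
an entirely empty side the restriction is vacuous and the other table
counts in full.

## Vessel-based registration (`coregmatch.vessels`)

Pipeline on isotropic 1-um volumes: (1) Meijering neurite filter
(Hessian-eigenvector ridge enhancement, max over scales — scales and
thresholds are data-dependent config, defaults logged in provenance);
(2) tube normalization — binarize, 3D skeletonize, drop components below
`min_component_voxels`, grow constant-radius tubes by Gaussian blur
(`tube_sigma_um`), and repeat (second round re-binarizes at half the
current peak), so vessel calibre and z-smearing differences between
modalities cannot bias the similarity; (3) translation initialization by
normalized cross-correlation template matching (translation-only);
(4) multi-scale cubic B-spline free-form deformation — control-point
spacings (64, 32, 16) um with smoothing (8, 4, 1) um by default, L-BFGS,
correlation similarity, 1% random sampling, 600 iterations — behind a
backend protocol whose shipped implementation delegates to SimpleITK, the
standard engine for this registration family; (5) the fitted transform is
exported as a dense forward displacement grid on the fixed lattice, with
the inverse obtained by fixed-point iteration on the grid (tolerance
0.1 um). `apply_field` transports points either way by trilinear
interpolation and resamples volumes into the fixed frame; transported
centroids feed `matching.assign_matches` unchanged.

On the 72^3 tube phantom with a planted ~10-um smooth warp, the pipeline
recovers the field to <2 um mean error on vessel voxels and reduces
held-out landmark error ~6x. The information content is anisotropic:
displacement components along a tube axis are only constrained where tubes
cross or bend (the aperture problem), so recovery degrades for warps with
strong along-tube components or very sparse vasculature, and the similarity
can fail entirely on phantoms dense enough for tubes to merge.

## Reliability statistics (`coregmatch.reliability`)

*Oracle score*: per clip, each repeat is Pearson-correlated with the mean
of the remaining repeats; correlations average over repeats, then clips
(per-clip-then-average order; Pearson on deconvolved traces). Constant
repeats are excluded with a warning; an all-constant block scores NaN. An
optional flag z-scores each repeat first (off by default). For the
signal-plus-noise model `trace_i = s + eps_i` the expected score is
`rho = ss / sqrt((ss + sn)(ss + sn/(R-1)))` (ss, sn the signal and noise
variances, R repeats) — `synth.expected_oracle_score` — and simulated
scores track this curve across an SNR sweep within Monte-Carlo error.

*Signal correlation*: Pearson correlation of two units' concatenated
trial-averaged clip responses. *Cross-scan validation*: for every EM neuron
matched in two scans, the matched-vs-matched signal correlation plus two
controls (each matched unit against the nearest unit in the other scan not
matched to that neuron).

*Consolidation*: greedy agglomeration of units from different scans.
Group-to-group distance is single linkage (closest cross-group member
pair, the "closest 2 cells" reading); a join requires distance
<= `min_separation` (10 um), disjoint member scans, and merged z extent
<= `max_z_extent` (20 um); ties break on lexicographic member keys for
deterministic runs. Single linkage with a closed boundary is the one
convention consistent with the worked three-cell trace this rule is
specified by (members at z = 0, 9, 19 um collapse to one group; the 9-19
pair sits at exactly 10 um).

## Parametric stimuli (`coregmatch.stimuli`)

**Monet2.** Seeded i.i.d. Gaussian noise video -> temporal low-pass
(linear-phase Hamming-window FIR, half-amplitude point at 4 Hz) -> spatial
Gaussian (sigma 3 deg). Each block splits into `n_directions` equal periods
(boundaries rounded to frames); within a period the field is advected at
42.8 deg/s along the period's direction by Fourier-shift (exact subpixel
translation on the periodic domain, so phase correlation recovers the
planted motion), and the period's angular filter
`G(phi - theta; c)` is applied to each frame's 2D spectrum with period-pi
wrapping of `phi - theta`, biasing *orientation* (not direction) energy
perpendicular to the motion; the sqrt(c) gain is kept as defined, without
power renormalization, and the DC gain is set to the kernel maximum.
Frames are globally min-max rescaled to [0, 1]; the pre-rescaling field
(Gaussian by construction) is available for spectral diagnostics. Defaults
(4 Hz, 3 deg, 16 directions, 15 s, 42.8 deg/s, c = 2.5) are the stimulus's
defining parameters; frame size and fps are free, with degrees-per-pixel
derived from the monitor geometry (3.8 deg/cm at the nearest point,
56.5 cm wide).

**Trippy.** Uniform phase noise on a coarse control grid (12 x 20 by
default), keyframed every `round(fps / (2 x bandwidth))` frames (8 at
60 fps / 4 Hz — the bandwidth/kernel spacing is not fully determined by
the stimulus definition; this choice places the kernel null at the
keyframe rate) and interpolated with the raised-cosine (Hann) kernel,
which is a partition of unity, so keyframes are reproduced exactly. A
linear trend of 8 pi rad/s is added, the grid is upsampled to the frame
with a normalized Gaussian kernel (sigma 22.5 deg), and frames are exactly
`1/2 + 1/2 cos(phase)`; the unwrapped phase movie is returned alongside,
making local orientation, frequency and drift analytically derivable. The
measured mean phase-increment rate of a block equals the drift to within
the noise contribution (~0.2%).

## Synthetic data (`coregmatch.synth`)

`make_deformation` composes a random modest affine (rotation < ~5 deg,
scale 0.95-1.1), a componentwise quadratic trend, sinusoidal z-dependent
offsets (2-4 cycles over the depth, emulating section-shape trends), and a
random Gaussian-bump field with correlation length `smoothness_um`
(default 300 um) — fractions 0.3/0.25/0.5 of `amplitude_um` (default
20 um). Everything is a pure function of (params, seed). The scene box
(1,300 x 870 x 820 um) mirrors the scale of the volumes this workflow
targets. Somata are placed with 15-um minimum spacing (above the 10-um
consolidation criterion, so planted duplicate groups are unambiguous at
the default 2-um jitter). Tube phantoms rasterize smooth random
centrelines at 1-um voxels with Gaussian radial profiles; the moving
volume is the pull-back `moving(x) = fixed(warp(x))`, and landmark truth
is placed by numerically inverting the (small) warp.

What the generators do *not* emulate: real annotation-error structure
(manual fiducial errors are not isotropic Gaussians), nucleus-detection
failure modes, calcium indicator dynamics and deconvolution artefacts in
the response traces, and real vascular topology (loops, branching
hierarchies). Passing tests therefore demonstrate correctness of the
algorithms under controlled conditions and calibrated statistical
behaviour — not performance on real annotation data.

## Problem sizes and tolerances

Test and acceptance runs use: 500 fiducials for stack fitting (seconds),
leave-one-out on 20-120 held-out refits, matching scenes of 150-250
neurons and up to 7x7 brute-force enumeration oracles, 72^3 1-um vessel
phantoms (registration well under a minute), 200-simulation Monte-Carlo
nulls, and 15-s stimulus blocks at reduced frame sizes (e.g. 64 x 96).
Key numeric tolerances: exact-TPS control-point residual 1e-6 um
(achieved: ~0), stage monotonicity slack 1e-9 um, inversion tolerance
1e-3 um, displacement-field inverse 0.1 um, field round-trip 1 um.
Degenerate inputs raise typed errors (coplanar fiducials, duplicate
control points, empty vessel masks, flat templates, anisotropic volumes);
extrapolation and out-of-domain queries warn rather than fail.

## Known limitations

- The exact-TPS stage has no outlier protection; a bad fiducial deforms
  the map locally (by design — flagged for leave-one-out evaluation).
- Grid-TPS solves are dense; lattices much finer than n = 12 or fiducial
  sets far beyond ~5,000 would want an iterative or compact-support
  solver.
- The vessel path assumes vessels are already segmented/labelled in both
  volumes; no segmentation from raw imagery is provided.
- Bipartite matching is per scan and distance-only; activity or morphology
  similarity terms are out of scope.
- The consolidation solver is the O(n^2)-per-join greedy exactly as
  specified; it is not meant for >10^4 units in one region.
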