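# Methods

## Physical model

ECT delivers a pulsed current (clinically 800–900 mA) through two scalp
electrodes. At the relevant frequencies tissue behaves as a purely resistive
volume conductor: capacitive and inductive effects are neglected
(quasi-static approximation), so the potential satisfies ∇·(σ∇V) = 0 with
isotropic, homogeneous conductivity per tissue compartment. Boundary
conditions: the anode disc carries the total injected current, the cathode
disc is the ground (V = 0), and every other external surface is insulated
(no normal current into air).

Conductivities (S/m) are the values standard in the transcranial-stimulation
literature: skin 0.465, skull (bone) 0.01, CSF 1.65, grey matter 0.276,
white matter 0.126, muscle 0.35, conductive gel 1.4, electrode metal
5.9·10⁷. The phantom's abstract torso and lower-body blocks take the muscle
value 0.35; published organ-level values (liver 0.221, kidney 0.403,
intestine 0.164, bladder wall 0.408, …) bracket it, and the experiment
itself shows sub-0.01 % sensitivity of brain metrics to anything below the
torso, so organ-resolved conductivity would not change the conclusions.
Air is excluded from the unknowns altogether, which is mathematically
identical to assigning it a vanishing conductivity but avoids poisoning the
conditioning of the linear system.

## Discretisation and boundary handling

The domain is a regular isotropic voxel grid (axis convention x left→right,
y posterior→anterior, z inferior→superior; default spacing 2 mm). A
cell-centred finite-volume scheme assigns each non-air voxel one unknown;
the conductance of the face between neighbours i, j is

    g_ij = 2 σ_i σ_j / (σ_i + σ_j) · A / d      (A = h², d = h in metres)

i.e. the harmonic mean of the two conductivities — the exact 1-D series
resistance of two half-voxels, which makes layered-slab solutions exact at
voxel centres and current conservation exact by construction (interior row
sums vanish). Faces towards air simply carry no conductance (insulation).

The metal electrode layer is seven orders of magnitude more conductive than
any tissue, so each disc is collapsed algebraically into a single
equipotential terminal (the graph-Laplacian rows of its voxels are summed;
internal metal–metal faces cancel exactly). The anode terminal receives the
total current I; every cathode voxel is grounded. The idealisation is
accurate to the metal's internal potential drop, a relative ~1e-7, and
removes a ~1e10 conductance contrast that would otherwise cap the attainable
true residual of a double-precision Krylov solve near 1e-5. A `conductive`
electrode model (metal voxels kept as unknowns, only the cathode's
exterior-face voxels grounded, uniform Neumann current over the anode's
exterior faces) is retained as an option; with an equipotential terminal the
spatial distribution of the injected Neumann current is immaterial.
Whether the anode condition is "uniform current density" or "floating
equipotential terminal" is physically near-equivalent at this σ contrast;
the terminal form is the better conditioned of the two and is the default.
Which disc is anode is itself immaterial for |E| and every reported metric:
the field magnitude is invariant under role swap (verified as a reciprocity
property test). Defaults: RUL vertex disc and BL right disc are anodes.

E = −∇V is recovered with central differences where both axis neighbours
are in the domain and one-sided differences at domain boundaries; a voxel
with no in-domain neighbour along an axis gets a zero component there and is
counted in the solution diagnostics.

## Linear solver

The reduced system is symmetric positive definite and is solved by
conjugate gradients with a smoothed-aggregation multigrid V-cycle
preconditioner built on the voxel structure: 2×2×2 blocks form the
aggregates at every level, the piecewise-constant tentative prolongator is
smoothed by one damped-Jacobi step (ω = 4/3 over a power-iteration estimate
of ρ(D⁻¹A)), coarse operators are Galerkin products, smoothing is one
damped-Jacobi sweep pre and post (symmetric, so the preconditioner is SPD),
and the coarsest level (≤1200 unknowns) is factorised densely. Below
40 000 unknowns plain Jacobi-CG is used instead. Everything is
deterministic — there is no randomness in setup, smoothing, or ordering — so
repeated runs are bit-identical.

The convergence criterion is the *true* relative residual ‖b − Ax‖/‖b‖ ≤
tol (default 1e-8). SciPy's CG stops on a recursively updated residual that
can drift from the true one, so the solver verifies the true residual and
restarts the iteration (up to three times) until it genuinely meets the
tolerance; `strict=False` returns a non-converged solution with its
diagnostics instead of raising. A full-body solve at 2 mm (~1.5 M unknowns)
converges in ~50 preconditioned iterations.

Current conservation is checked a posteriori: the current collected by the
grounded cathode voxels, summed from face fluxes, must match the injected
current (relative imbalance ≲1e-6 for converged solves).

## The phantom

The synthetic phantom stands in for an MRI-segmented head fused with a
full-body dataset, preserving the features the extent analysis depends on
while remaining fully parametric:

- five strictly nested ellipsoidal head shells — skin, skull, a *continuous*
  CSF layer, grey matter, white matter — with default semi-axes
  (75, 92, 88), (68, 85, 81), (62, 79, 75), (57, 74, 70), (44, 60, 55) mm,
  approximating an adult head;
- a neck cylinder (radius 50 mm, length 70 mm, muscle) overlapping the head
  base by 10 mm so there is a continuous conductive path;
- abstract soft-tissue torso (160×120×300 mm) and lower-body
  (120×100×280 mm) blocks. The default grid is 86×98×414 voxels at 2 mm.

The body-block cross-sections are deliberately modest: they are large enough
that the torso→full-body transition is numerically negligible (matching the
saturation the extent analysis predicts) while keeping the largest solve at
~1.5 M unknowns, i.e. the full 10-solve experiment completes in about a
minute on one CPU. These sizes are the package's study conditions; all
defaults were fixed before the experiment and are not tuned per run.

The phantom is exactly mirror-symmetric about the midsagittal plane (even
voxel count along x, analytic shapes evaluated on symmetric coordinates, the
left BL disc stamped as the voxel mirror of the right), which gives exact
reference values for the symmetry and laterality properties. Optional
Gaussian surface jitter (`jitter_mm`, default 0, seeded) breaks that
symmetry for robustness experiments.

Electrode placement translates the clinical landmarks to the ellipsoid:
the frontotemporal centre lies on the antero-lateral skin surface (azimuth
35° anterior of pure lateral) at 25 mm above the head equator — the
ellipsoid's analogue of "2.5 cm above the canthus–tragus midpoint" — and the
RUL vertex disc is centred 25 mm right of the apex in horizontal projection
(the surface-arc vs projection distinction is below the voxel size; the
offset is a parameter). Discs are 25 mm radius; gel and metal are each one
2 mm layer following the scalp, stamped via a Euclidean distance transform
of the body surface. Gel/metal thickness is not standardised in the
modelling literature; 2 mm (one voxel) is the package default and a config
parameter.

Field-of-view truncation clears every voxel below a cut plane recorded at
build time: upper head = one voxel below the inferior-most brain voxel (the
whole-brain extent — cutting into the brain is an error), full head = the
bottom of the head shells, neck = the base of the neck cylinder, torso = the
base of the torso block; full body keeps everything.

What the phantom does **not** emulate: gyral folding and cortical detail,
skull thickness variation (notably the thin temporal bone), brainstem and
cerebellum as distinct structures, organ-level torso anatomy, and
inter-individual variability. Consequently the *absolute* stimulation
metrics of MRI-derived models are not reproduced — published full-body
upper-head REs (~50 % for BL, ~5 % for RUL) are an order of magnitude above
the phantom's (~1.8 % and ~0.6 %), because the real inferior current path
through skull base foramina and facial tissue is much stronger than through
closed ellipsoid shells. What passing tests *do* establish is every
direction and ordering the analysis turns on: p99 strength non-increasing
with extent, BL more extent-sensitive than RUL, the upper-head→full-head
transition dominating BL's error, BL laterality ≈ 1 and RUL > 1 (phantom
≈1.44 vs published 1.49–1.59), and brief-threshold focality dominating
ultra-brief.

## Metrics

- Brain = grey ∪ white voxels (the phantom has no separate
  cerebellum/brainstem compartment).
- `E/E_th` uses E_th = 25 V/m (0.25 V/cm, converted once at configuration)
  for ultra-brief pulses and 21 V/m for brief-pulse BL; the robust threshold
  multiplies by 1.4 (applied to the ultra-brief threshold by default, the
  brief variant is available).
- The per-condition summary is the 99th percentile over brain voxels with
  linear interpolation between order statistics (the common default
  estimator; documented because the choice moves the value slightly at
  finite voxel counts).
- RE = (M_X − M_FB)/M_FB × 100 %, signed; the full-body row is zero by
  construction.
- Laterality = median right-hemisphere |E| / median left; voxels centred
  exactly on the midsagittal plane would be excluded (the default grids have
  none, by the even-voxel-count construction).
- Focality = 100 × (brain voxels with value ≥ threshold)/(brain voxels);
  the comparison is inclusive (≥) to avoid measure-zero ambiguity.
- Amplitude sweeps rescale one converged solve per geometry (field linear in
  current — verified to machine precision as a property test) rather than
  re-solving; laterality is amplitude-invariant and computed once.

## Degenerate inputs and tie-breaks

A white-matter shell with zero semi-axes yields a phantom with no white
voxels (all other shells intact). Truncation that would remove brain voxels,
electrode discs that overlap each other, hang past a truncation plane, or
find no scalp, missing conductivities, and non-nested shells are all
errors. In the experiment driver a failing condition is logged in the run
manifest and skipped; the remaining conditions still run.

## Known limitations

Voxel (staircase) electrode and surface geometry; isotropic conductivity
only (no white-matter tensors); no electrode–skin interface impedance; no
frequency dependence; single synthetic subject. The refinement property
test shows the discretisation is consistent (brain-median |E| changes shrink
as spacing halves 8→4→2 mm), but absolute convergence of peak values at
2 mm is not claimed — the analysis deliberately targets *differences and
orderings across extents*, which are far less sensitive to discretisation
than absolute peaks.
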