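# Methods

This note records the models, conventions and numerical choices behind
`zernsurf`, in the order the pipeline applies them, together with what the
synthetic fixtures do and do not establish about real data.

## Surface construction

**Atom subsets.** Four representations are extracted from a parsed
structure: `AASurf` (all heavy atoms), `CACNO` (Cα, C, N, O; the terminal
OXT counts as a main-chain oxygen), `CACN`, and `CA`. Only the first model
and the blank/'A' alternate location are read; hydrogens, waters and
hetero-residues are dropped (selenomethionine can be mapped to methionine
on request). Residues are renumbered sequentially per chain so geometry
never depends on author numbering.

**Probe-rolled surface on a grid.** The solvent-excluded surface is
approximated with two Euclidean distance transforms: the union of atom
spheres inflated by the probe radius is rasterized, then eroded back by
the probe (voxels whose distance to the inflated solid's complement is at
least the probe radius). The boundary voxels of the eroded solid form a
one-voxel-thick closed shell — the binary function f(x) that is expanded.
This reproduces the path of a rolling probe to voxel accuracy without an
analytic triangulated surface. Defaults: probe 1.5 Å (2.0 Å for the CA
trace, which needs extra smoothing over the 3.8 Å Cα gaps); van der Waals
radii C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, Se 1.90 Å (uniform 1.70 Å
for the CA representation); grid 64³, which resolves order-20 angular
detail. Voxelization refuses grids whose spacing exceeds the probe radius,
since the erosion step is then unresolved.

**Unit-sphere placement.** The descriptor is defined on the unit ball, so
the shell is centred on its centre of gravity and scaled so its farthest
extent sits at `fill_fraction × dim/2`, with `fill_fraction = 0.7` keeping
mass away from the sphere boundary where the radial polynomials oscillate
most. Protein size is deliberately discarded here; the optional 65–135%
sequence-length pre-filter reintroduces it at query time.

Two implementation points matter for accuracy:

* `surface_unit_grid` (used by `describe_atoms`) rasterizes the surface
  *directly* onto the unit-sphere-aligned grid. A coarse pass supplies the
  surface centroid (averaged over thousands of shell voxels, so its
  rotational jitter is negligible), and the physical extent is taken as
  max over atoms of (distance to centroid + vdW radius) — a quantity the
  eroded surface attains at exposed extreme atoms and that is exactly
  invariant under rotation. By default the solid is rasterized at a 2×
  subdivision of the same grid and reduced by majority vote before the
  shell is extracted; the output is still binary, but boundary
  quantization noise drops roughly from a half-voxel to a quarter-voxel.
  Measured over 20 uniform random rotations of 100-residue chain fixtures,
  the descriptor spread (max deviation from the mean, relative L2) is
  2.5–4%, against the 5% bound used in the acceptance checks.
* `scale_to_unit_sphere` (for grids that arrive as voxels: geometric
  fixtures, density bands) resamples binary shapes through a linear
  interpolation of the signed distance to the solid boundary, filling
  one-voxel shells first and re-extracting the boundary afterwards.
  Nearest-neighbour resampling would punch holes in thin shells when
  shrinking and thicken them when growing; the distance-field route keeps
  shells exactly one voxel thick at any zoom.

**Sensitivity, honestly stated.** Order-20 descriptors of binary shapes
are extremely sensitive to sub-voxel geometry: changing a rasterized
ball's radius by 0.1 voxel moves the normalized descriptor by about 2% in
L2. Consequently a shape rasterized at two sizes and regridded cannot be
expected to agree to better than several percent in L2 (5–8% measured for
well-resolved solids); descriptor *correlation* across such copies exceeds
0.99, and that is the robustness the test suite asserts. Translation
invariance, by contrast, is exact by construction. A related artefact:
even a perfectly centred one-voxel spherical *shell* carries ~1.3% of its
descriptor energy outside l = 0 purely from lattice anisotropy, while a
filled voxel ball stays below 0.1%; the spherical-symmetry check therefore
uses the filled ball.

## Moments, invariants, reconstruction

The basis follows the classical polynomial construction: solid harmonics
expanded to monomials (Condon–Shortley phase, normalized so the squared
harmonic integrates to 4π over the sphere) times radial polynomials

    R_nl(r) = Σ_ν q_kl^ν r^(2ν+l),   n = 2k + l,

with coefficients chosen so the basis is orthonormal under (3/4π)dx on the
unit ball (verified numerically: the Gram matrix up to order 6 on a 64³
ball grid is within 2% of identity). Moments are computed in one pass from
geometric moments M_abc = Σ f x^a y^b z^c ΔV via the precomputed monomial
coefficients of each Z_nlm — O(dim³) regardless of order — and agree with
direct per-voxel numerical integration of f·Z̄ (an independently coded
oracle using scipy spherical harmonics and exact-rational Gram–Schmidt
radial polynomials) to better than 1e-9 relative at order 8. Only m ≥ 0 is
stored; real input fixes the rest through Ω_nl,−m = (−1)^m Ω̄_nlm.
Coefficients use double precision with factorials from integer arithmetic;
beyond order 20 cancellation degrades them, so higher orders warn.
F_nl = ‖Ω_nl‖₂ in fixed (n asc, l asc) order; the vector is normalized to
unit L2 norm, which removes most of the dependence on voxel count and
resolution (descriptors of the same surface at 48³ and 64³ correlate
above 0.99).

Reconstruction evaluates the truncated series Σ Ω_nlm Z_nlm by collapsing
all terms into a single real polynomial and evaluating it with three
tensor contractions; the real part is returned and voxels outside the unit
sphere are zeroed. Truncation error decreases monotonically with the order
cap on every fixture tested, which is what makes low-order reconstructions
a visual proxy for low-resolution density maps.

## Shape features and the combined distance

* Radius of gyration: rg = sqrt(mean‖x−cog‖² + R²) over the atoms of the
  representation, with R = 1.5 Å as a finite-atom-size correction added in
  quadrature.
* Sphericity: 1 − rg/(sqrt(3/5)·RS), where RS is the radius of the sphere
  with the same volume as the filled all-atom surface (voxel count ×
  spacing³). A uniform ball scores 0 (rg of a ball is sqrt(3/5)RS),
  elongated shapes negative, compact centrally-concentrated shapes
  positive; > 0.15 classifies a query as spherical. The formula is a
  pluggable strategy so an alternative compactness score can be swapped in
  without touching callers.
* Tail detection: residues (Cα positions) farther than 2·rg from the
  centre of gravity, counted only in maximal consecutive runs longer than
  three residues.
* Query weights (w_AASurf, w_CACNO): (0.7, 0.3) for tailed queries,
  (0.3, 0.7) for spherical ones, (0.4, 0.6) otherwise. The combined
  distance w_S·d_AASurf + w_B·d_CACNO is intentionally asymmetric — the
  weights come from the query, not the candidate.

## EM density maps

Simulated maps place a normalized Gaussian (unit integrated mass,
FWHM = nominal resolution) on every heavy atom, on a 1 Å cubic grid padded
past the 4σ kernel cutoff so per-atom mass is complete and density is
additive. Because absolute density units are convention-dependent, bands
can be specified as percentiles of the positive values as well as absolute
ranges (inclusive ends). Band selections substantially larger than the
descriptor grid are max-pooled toward it; near-target maps go straight to
the unit-sphere scaler, which is gentler than pooling. MRC2014 files are
read and written through gemmi; axis-permuted files are canonicalized to
x,y,z order on read. No solvent-noise model is included — the maps are
noise-free by design, so retrieval results on them bound what noisy
experimental maps would give from above.

On simulated 10 Å maps of chain fixtures, high-density bands nest inside
the convex hull of low-density bands (core vs envelope) in every fixture
tested. The finer claim that the core band resembles the backbone surface
*more than* the all-atom surface is a small effect here — both reference
descriptors correlate ~0.84 with the band descriptor — and is asserted
only as a majority over a paired comparison (high↔backbone and
low↔all-atom against the crossed pairing) on eight fixtures.

## Retrieval evaluation

For each query the remaining entries are sorted by distance (ties broken
by identifier for determinism). Precision and recall are computed per
query at shared distance thresholds — the union of observed distances by
default — averaged across queries, and summarized by the trapezoidal area
under precision vs recall, with the curve extended horizontally from the
smallest achieved recall to recall 0. Precision of an empty retrieved set
is defined as 1 so averaging is well-defined at small thresholds; queries
whose group has no other member are skipped with a warning, and the recall
denominator excludes the query itself.

That empty-set convention has an exact, finite-size consequence worth
knowing: for random rankings with iid uniform distances the expected
averaged precision at recall t is prior + (1−prior)(1−t)^(N−1), where
prior is the positive fraction and N the database size, so the expected
PR-AUC is prior + (1−prior)/N. On thousands of entries the extra term is
negligible and "random AUC ≈ positive fraction" holds as usually quoted;
on the 80-entry synthetic benchmark it is ≈ +0.01 and the measured random
AUCs sit on the corrected value. The acceptance checks compare against
this exact permutation expectation.

## Synthetic fixtures

The generator provides analytic solids (balls, ellipsoids, dumbbells,
rasterized as one-voxel shells of implicit surfaces) and protein-like
chains: self-avoiding random walks with 3.8 Å Cα steps compacted into a
sphere of radius 3.1·N^(1/3) Å (protein-like packing), escaped from dead
ends by backtracking, with ideal-geometry backbone atoms (N–Cα 1.46,
Cα–C 1.52, C=O 1.23 Å) and a CB plus 0–3 coarse side-chain carbons per
residue in 1.5 Å steps. The side-chain bulk is calibrated so backbone and
all-atom descriptors of chain fixtures correlate at 0.90–0.96, the regime
reported for real proteins; without it the two surfaces are nearly
identical (r ≥ 0.97) and all-atom-vs-backbone comparisons become vacuous.
Tailed globules append a straight radial tail starting two steps outside
the globule so the tail run reliably clears twice the radius of gyration.
All randomness flows through explicit seeds; identical seeds reproduce
identical coordinates.

What the fixtures do not emulate: real secondary structure, side-chain
rotamers, Ramachandran-valid dihedrals, crystallographic artefacts, or
experimental map noise. Green tests on fixtures therefore establish the
correctness and invariances of the machinery and the qualitative orderings
(class separability, core/envelope structure, representation similarity),
not absolute retrieval accuracy on curated fold benchmarks, which requires
the external classification databases.

## Problem sizes and runtime

Default grids are 64³ (96³ where a tail stretches the extent so that 64³
would under-resolve the probe); the retrieval benchmark uses 4 classes ×
20 instances; EM checks use five 50-residue chains at 10 Å. On one CPU the
full test suite runs in ~2 minutes and the acceptance script in ~2
minutes.

## Known limitations

* Absolute density-band values are tied to this simulator's amplitude
  convention; use percentile bands when comparing across conventions.
* The spacing-vs-probe guard caps the protein size per grid dimension
  (~45 Å extent at 64³ with a 1.5 Å probe); larger structures need larger
  grids.
* Order > 20 is numerically unsupported (double-precision coefficient
  cancellation).
* Multi-chain assemblies are described chain-by-chain; there is no
  complex-level surface.
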