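# zernsurf

Rotation-invariant protein surface comparison with 3D Zernike descriptors
(3DZD), including query-adaptive combination of all-atom and backbone
surfaces and retrieval on simulated electron-microscopy (EM) density maps.

## The problem

Structure databases grow faster than pairwise alignment programs can search
them, and EM increasingly produces maps in which no atomic coordinates
exist at all. Both problems yield to the same idea: describe the *surface
shape* of a molecule by a short vector that does not change when the
molecule is rotated or translated, and compare vectors instead of aligning
structures. Database search then costs one Euclidean distance per entry,
and a density map can be compared with a crystal structure directly.

`zernsurf` is for structural bioinformaticians who want that machinery as
a library and command-line tool: PDB in, 121-number descriptor out, with
ranking, precision-recall evaluation, and density-map handling around it.

## The descriptor

A molecular surface is built from one of four atom subsets — all heavy
atoms (`AASurf`), the heavy-atom backbone Cα,C,N,O (`CACNO`), Cα,C,N
(`CACN`), or the Cα trace (`CA`) — by rolling a probe sphere (1.5 Å; 2.0 Å
for `CA`) over the atoms, marking surface voxels with 1 on a cubic grid,
and scaling the shape into the unit ball. The resulting indicator function
f(**x**) is expanded in the 3D Zernike basis

    Z_nlm(r, θ, φ) = R_nl(r) Y_lm(θ, φ),   0 ≤ l ≤ n,  (n−l) even,  |m| ≤ l,

whose radial polynomials R_nl make every Z_nlm a polynomial in x, y, z.
The moments Ω_nlm = (3/4π) ∫ f(x) Z̄_nlm(x) dx are collapsed over m into

    F_nl = ‖ Ω_nl ‖₂ ,

which is invariant under rotation. Up to order n = 20 this gives 121
invariants; the vector is normalized to unit length. Distance between two
shapes is the Euclidean distance of their descriptors; a combined distance
weights the AASurf and CACNO distances per query — (0.7, 0.3) for proteins
with a tail-like structure, (0.3, 0.7) for spherical ones (sphericity
> 0.15), (0.4, 0.6) otherwise — because the all-atom surface recognises
tailed proteins better and the backbone surface spherical ones. An
optional pre-filter discards database entries outside 65–135% of the query
sequence length, restoring the size information the unit sphere discards.

For EM maps, density is simulated from coordinates by Gaussian kernels
(FWHM = nominal resolution, 1 Å grid); voxels inside a density band form a
binary shape that feeds the same descriptor pipeline — high bands trace
the protein core, low bands the envelope.

## Worked example

```python
from zernsurf import (
    parse_structure, select_representation, describe_atoms,
    descriptor_correlation, compute_shape_features, query_weights, write_pdb,
)
from zernsurf.synthetic import FixtureSpec, make_chain

# an 80-residue globular chain with an 8-residue tail, via PDB round trip
spec = FixtureSpec(kind="tailed_globule", seed=7, n_residues=80,
                   params={"tail_len": 8})
atoms = parse_structure(write_pdb(make_chain(spec)))

descriptors = {
    kind: describe_atoms(select_representation(atoms, kind), dim=96)
    for kind in ("aasurf", "cacno", "cacn", "ca")
}
for i, a in enumerate(descriptors):
    for b in list(descriptors)[i + 1:]:
        r = descriptor_correlation(descriptors[a], descriptors[b])
        print(f"{a:>6s} vs {b:<6s} r = {r:.3f}")

features = compute_shape_features(atoms, dim=96)
print(f"rg = {features.rg:.1f} A, sphericity = {features.sphericity:.3f}, "
      f"tail residues = {features.tail_residues}")
print("weights (w_AASurf, w_CACNO):", query_weights(features))
```

prints

```
aasurf vs cacno  r = 0.954
aasurf vs cacn   r = 0.945
aasurf vs ca     r = 0.956
 cacno vs cacn   r = 0.997
 cacno vs ca     r = 0.996
  cacn vs ca     r = 0.997
rg = 14.2 A, sphericity = -0.573, tail residues = 5
weights (w_AASurf, w_CACNO): (0.7, 0.3)
```

The three backbone descriptors are nearly interchangeable (r ≥ 0.996)
while the all-atom descriptor differs visibly (r ≈ 0.95) — the side-chain
envelope hides backbone ruggedness. The elongated tail makes the
sphericity negative, five residues lie beyond twice the radius of
gyration, so a combined-distance query from this protein weights the
all-atom surface 0.7.

The same operations are exposed on the command line:

```sh
zernsurf fixtures --kind tailed_globule --n 80 --tail 8 --seed 7 --out fix.pdb
zernsurf describe --pdb fix.pdb --rep cacno --out fix.zd
zernsurf em-describe --mrc map.mrc --band 70:100 --band-mode percentile
zernsurf search --query fix.pdb --db mydb --mode combined
zernsurf eval --db mydb --mode cacno
```

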