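"""Probe-rolled molecular surface voxelization and unit-sphere scaling.

The solvent-excluded surface is approximated on a cubic grid with two
Euclidean distance transforms: the atom spheres are first inflated by the
probe radius (the union of balls a rolling probe centre cannot enter), then
the inflated solid is eroded back by the same probe radius. The boundary
voxels of the eroded solid trace the probe-rolled surface to voxel accuracy.

The resulting one-voxel-thick shell, scaled into the unit sphere, is the
binary 3D function f(x) expanded in the Zernike basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .structures import AtomSet, Representation

__all__ = [
    "VoxelGrid",
    "UnitSphereGrid",
    "VDW_RADII",
    "DEFAULT_PROBE",
    "atom_radii",
    "voxelize_surface",
    "scale_to_unit_sphere",
    "surface_unit_grid",
]

#: van der Waals radii (Angstrom) used to build the molecular surface.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}
_DEFAULT_VDW = 1.70

#: Probe sphere radius per representation (Angstrom). The C-alpha trace uses
#: a larger probe to smooth over the 3.8 A gaps between consecutive residues.
DEFAULT_PROBE = {
    Representation.AASURF: 1.5,
    Representation.CACNO: 1.5,
    Representation.CACN: 1.5,
    Representation.CA: 2.0,
}

#: Uniform atom radius for the C-alpha-only representation.
CA_UNIFORM_RADIUS = 1.70


@dataclass
class VoxelGrid:
    """Cubic voxel grid; binary for surfaces, non-negative for densities."""

    values: np.ndarray  # (dim, dim, dim)
    spacing: float  # Angstrom per voxel
    origin: np.ndarray  # position of voxel (0,0,0) centre, Angstrom

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3 or len(set(self.values.shape)) != 1:
            raise ValueError(f"grid must be cubic, got shape {self.values.shape}")
        if self.dim < 8:
            raise ValueError(f"grid too small: dim={self.dim} < 8")

    @property
    def dim(self) -> int:
        return self.values.shape[0]

    def nonzero_count(self) -> int:
        return int(np.count_nonzero(self.values))


@dataclass
class UnitSphereGrid(VoxelGrid):
    """Voxel grid whose occupied voxels lie inside the inscribed unit sphere.

    Voxel centre (i, j, k) maps to unit-ball coordinates
    ``((i + 0.5) - dim/2) * 2/dim`` per axis, so the cube spans [-1, 1].
    ``scale_factor`` (unit-ball units per Angstrom) and ``center`` (the
    centroid removed, in source-grid Angstrom) record the affine map so it
    can be inverted.
    """

    scale_factor: float = 1.0
    center: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        super().__post_init__()
        if self.center is None:
            self.center = np.zeros(3)
        self.center = np.asarray(self.center, dtype=float)

    def unit_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid of unit-ball coordinates for every voxel centre."""
        ax = (np.arange(self.dim) + 0.5 - self.dim / 2) * (2.0 / self.dim)
        return np.meshgrid(ax, ax, ax, indexing="ij")


def atom_radii(atoms: AtomSet) -> np.ndarray:
    """Per-atom van der Waals radii; the CA trace uses one uniform radius."""
    if atoms.representation is Representation.CA:
        return np.full(len(atoms), CA_UNIFORM_RADIUS)
    return np.array([VDW_RADII.get(a.element, _DEFAULT_VDW) for a in atoms.atoms])


def _stamp_balls(
    shape: tuple[int, int, int],
    centers_vox: np.ndarray,
    radii_vox: np.ndarray,
) -> np.ndarray:
    """Union of balls rasterized onto a boolean grid (centres in voxel units)."""
    occ = np.zeros(shape, dtype=bool)
    dim = shape[0]
    for (cx, cy, cz), r in zip(centers_vox, radii_vox):
        lo = [max(0, int(np.floor(c - r - 1))) for c in (cx, cy, cz)]
        hi = [min(dim, int(np.ceil(c + r + 2))) for c in (cx, cy, cz)]
        ix = np.arange(lo[0], hi[0])
        iy = np.arange(lo[1], hi[1])
        iz = np.arange(lo[2], hi[2])
        dx2 = (ix - cx) ** 2
        dy2 = (iy - cy) ** 2
        dz2 = (iz - cz) ** 2
        mask = (
            dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        ) <= r * r
        occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= mask
    return occ


def voxelize_surface(
    atoms: AtomSet,
    probe_radius: float | None = None,
    dim: int = 64,
    filled: bool = False,
    grid: tuple[np.ndarray, float] | None = None,
) -> VoxelGrid:
    """Rasterize the solvent-excluded surface of an atom set.

    Parameters
    ----------
    atoms : AtomSet
        Atoms defining the surface; radii follow their elements (uniform
        1.7 A for the CA representation).
    probe_radius : float, optional
        Rolling probe radius in Angstrom. Defaults to 1.5 A, or 2.0 A for
        the CA representation.
    dim : int
        Grid edge length in voxels (>= 32).
    filled : bool
        Return the filled solvent-excluded solid instead of the one-voxel
        boundary shell. The filled solid is what the sphericity volume uses.
    grid : (origin, spacing), optional
        Rasterize onto a prescribed grid instead of deriving one from the
        atom bounding box; used to place the surface directly onto a
        unit-sphere-aligned grid without resampling.

    Returns
    -------
    VoxelGrid
        Binary grid: the surface shell (default) or the filled solid.
    """
    if probe_radius is None:
        probe_radius = DEFAULT_PROBE[atoms.representation]
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if dim < 32:
        raise ValueError(f"dim={dim} too small; need >= 32")

    coords = atoms.coords
    radii = atom_radii(atoms)
    if len(coords) > 1 and np.ptp(coords, axis=0).max() == 0.0:
        raise ValueError("degenerate atom set: all atoms at one point")

    if grid is None:
        rmax = float(radii.max())
        pad = rmax + probe_radius + 2.0
        lo = coords.min(axis=0) - pad
        hi = coords.max(axis=0) + pad
        extent = float((hi - lo).max())
        spacing = extent / dim
        origin = (lo + hi) / 2 - (np.array([dim, dim, dim]) / 2 - 0.5) * spacing
    else:
        origin, spacing = np.asarray(grid[0], dtype=float), float(grid[1])
    if spacing > probe_radius:
        raise ValueError(
            f"grid too coarse: spacing {spacing:.2f} A exceeds probe radius "
            f"{probe_radius:.2f} A; increase dim"
        )

    centers_vox = (coords - origin) / spacing
    inflated = _stamp_balls((dim, dim, dim), centers_vox, (radii + probe_radius) / spacing)
    if not inflated.any():
        raise ValueError("no voxels covered; atom set degenerate")

    # erode by the probe: keep voxels at least probe_radius inside the
    # probe-inflated solid
    depth = ndimage.distance_transform_edt(inflated, sampling=spacing)
    solid = depth >= probe_radius
    if not solid.any():
        # probe erosion swallowed everything (thin input); fall back to the
        # deepest layer so small fixtures still yield a surface
        solid = depth >= depth.max() - spacing

    if filled:
        values = solid
    else:
        values = solid & ~ndimage.binary_erosion(solid)
    return VoxelGrid(values=values.astype(np.uint8), spacing=spacing, origin=origin)


def scale_to_unit_sphere(
    grid: VoxelGrid,
    fill_fraction: float = 0.7,
    dim: int | None = None,
) -> UnitSphereGrid:
    """Centre the occupied voxels and scale them into the unit sphere.

    The centre of gravity of the nonzero voxels moves to the grid centre and
    the farthest occupied point lands at radius ``fill_fraction * dim/2``,
    keeping shape mass away from the sphere boundary where the radial basis
    oscillates.

    Binary grids are resampled through a signed distance field rather than
    by nearest-neighbour lookup: one-voxel shells enclosing an interior are
    filled, the signed distance to the solid boundary is interpolated
    linearly on the output grid, and (for shell input) the one-voxel
    boundary is re-extracted there. This keeps shells exactly one output
    voxel thick at any zoom, so the same shape rasterized at two sizes maps
    to nearly identical unit-sphere grids. Real-valued grids are resampled
    with trilinear interpolation.
    """
    if not 0 < fill_fraction <= 1:
        raise ValueError("fill_fraction must be in (0, 1]")
    values = np.asarray(grid.values)
    occ = values != 0
    nz = np.argwhere(occ)
    if len(nz) == 0:
        raise ValueError("grid has no occupied voxels")
    out_dim = dim if dim is not None else grid.dim
    binary = values.dtype == np.uint8 or values.dtype == bool or (
        np.isin(np.unique(values), (0, 1)).all()
    )

    cog = (nz + 0.5).mean(axis=0)
    target = fill_fraction * out_dim / 2.0
    c_out = np.full(3, out_dim / 2.0)

    pts = nz + 0.5
    dmax = float(np.linalg.norm(pts - cog, axis=1).max())
    zoom = target / dmax if dmax > 0 else 1.0

    if binary:
        # a shell with an enclosed interior is resampled as its filled solid
        interior = ndimage.binary_erosion(occ)
        mask, reextract = occ, False
        if interior.sum() < 0.1 * occ.sum():
            filled = ndimage.binary_fill_holes(occ)
            if filled.sum() > 1.5 * occ.sum():
                mask, reextract = filled, True
        inner = ndimage.distance_transform_edt(mask)
        outer = ndimage.distance_transform_edt(~mask)
        sdist = inner - outer
        offset = (0.5 - c_out) / zoom + cog - 0.5
        sdist_t = ndimage.affine_transform(
            sdist,
            np.eye(3) / zoom,
            offset=offset,
            output_shape=(out_dim,) * 3,
            order=1,
            mode="constant",
            cval=float(sdist.min()),
            prefilter=False,
        )
        out = sdist_t > 0
        if reextract:
            out = out & ~ndimage.binary_erosion(out)
        resampled = out.astype(np.uint8)
    else:
        offset = (0.5 - c_out) / zoom + cog - 0.5
        resampled = ndimage.affine_transform(
            values.astype(float),
            np.eye(3) / zoom,
            offset=offset,
            output_shape=(out_dim,) * 3,
            order=1,
            mode="constant",
            cval=0.0,
            prefilter=False,
        )
        resampled = np.clip(resampled, 0.0, None)

    return UnitSphereGrid(
        values=resampled,
        spacing=grid.spacing / zoom,
        origin=grid.origin.copy(),
        scale_factor=zoom * (2.0 / out_dim) / grid.spacing,
        center=grid.origin + (cog - 0.5) * grid.spacing,
    )


def surface_unit_grid(
    atoms: AtomSet,
    dim: int = 64,
    fill_fraction: float = 0.7,
    probe_radius: float | None = None,
    estimate_dim: int = 80,
    supersample: int = 2,
) -> UnitSphereGrid:
    """Rasterize the molecular surface directly onto a unit-sphere grid.

    A coarse first pass locates the surface shell's centre of gravity in
    physical units (averaged over thousands of shell voxels, so its jitter
    under rotation is negligible). The farthest surface extent is taken
    from the atoms directly -- max over atoms of distance-to-centre plus
    van der Waals radius, which the probe-eroded surface attains at exposed
    extreme atoms -- making the grid scale exactly rotation invariant. The
    final surface is voxelized once onto a grid whose spacing places that
    extent at ``fill_fraction * dim/2``; avoiding both a resampling step
    and a discretized extent estimate keeps the rotational noise of the
    descriptors well below the tolerance of retrieval distances.

    With ``supersample`` > 1 the solid is rasterized on a finer subdivision
    of the same physical grid and reduced by majority vote before the
    boundary shell is extracted -- the output stays binary, but the
    boundary quantization noise drops markedly.
    """
    if probe_radius is None:
        probe_radius = DEFAULT_PROBE[atoms.representation]
    coarse = voxelize_surface(atoms, probe_radius=probe_radius, dim=estimate_dim, filled=True)
    solid = coarse.values != 0
    shell = solid & ~ndimage.binary_erosion(solid)
    pts = np.argwhere(shell) + 0.5
    cog_vox = pts.mean(axis=0)
    cog = coarse.origin + (cog_vox - 0.5) * coarse.spacing

    radii = atom_radii(atoms)
    dmax = float(np.max(np.linalg.norm(atoms.coords - cog, axis=1) + radii))

    spacing = dmax / (fill_fraction * dim / 2.0)
    origin = cog - (dim / 2 - 0.5) * spacing
    ss = max(1, int(supersample))
    if ss == 1:
        fine = voxelize_surface(
            atoms, probe_radius=probe_radius, dim=dim, grid=(origin, spacing)
        )
        values = fine.values
    else:
        # subvoxel centres tile each output voxel
        ss_origin = origin - spacing * (ss - 1) / (2.0 * ss)
        fine = voxelize_surface(
            atoms,
            probe_radius=probe_radius,
            dim=ss * dim,
            grid=(ss_origin, spacing / ss),
            filled=True,
        )
        blocks = fine.values.reshape(dim, ss, dim, ss, dim, ss).sum(axis=(1, 3, 5))
        solid = blocks >= (ss**3 + 1) // 2
        shell = solid & ~ndimage.binary_erosion(solid)
        values = shell.astype(np.uint8)
    return UnitSphereGrid(
        values=values,
        spacing=spacing,
        origin=origin,
        scale_factor=(2.0 / dim) / spacing,
        center=cog,
    )
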