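"""High-level convenience: atoms -> descriptor, and database entry assembly."""

from __future__ import annotations

from .features import ShapeFeatures, radius_of_gyration, sphericity, tail_residue_count
from .retrieval import DatabaseEntry
from .structures import AtomRecord, AtomSet, Representation, select_representation
from .surface import surface_unit_grid, voxelize_surface
from .zernike import Descriptor, describe_grid

__all__ = ["describe_atoms", "compute_shape_features", "build_entry"]


def describe_atoms(
    atoms: AtomSet,
    dim: int = 64,
    order: int = 20,
    fill_fraction: float = 0.7,
    probe_radius: float | None = None,
) -> Descriptor:
    """Full surface pipeline: voxelize, scale into the unit sphere, describe.

    Returns the unit-normalized rotation-invariant descriptor with metadata
    (representation tag and residue count) attached. The surface is
    rasterized directly onto the unit-sphere grid (no resampling step).
    """
    unit = surface_unit_grid(
        atoms, dim=dim, fill_fraction=fill_fraction, probe_radius=probe_radius
    )
    d = describe_grid(unit, order=order)
    d.meta.update({"rep": atoms.representation.value, "len": atoms.n_residues})
    return d


def compute_shape_features(
    atoms: list[AtomRecord] | AtomSet, dim: int = 64
) -> ShapeFeatures:
    """Shape features of a parsed structure.

    The radius of gyration and sphericity use the all-heavy-atom set (the
    sphericity volume is the filled all-atom solvent-excluded solid); tail
    detection runs on the per-residue C-alpha positions.
    """
    if isinstance(atoms, AtomSet):
        records = atoms.atoms
    else:
        records = atoms
    aasurf = select_representation(records, Representation.AASURF)
    ca = select_representation(records, Representation.CA)

    rg = radius_of_gyration(aasurf)
    solid = voxelize_surface(aasurf, dim=dim, filled=True)
    volume = solid.nonzero_count() * solid.spacing**3
    sp = sphericity(aasurf, surface_volume=volume)
    ca_pos = ca.ca_positions()
    tail = tail_residue_count(ca_pos, rg=radius_of_gyration(ca_pos))
    return ShapeFeatures(
        rg=rg,
        sphericity=sp,
        tail_residues=tail,
        n_residues=aasurf.n_residues,
    )


def build_entry(
    entry_id: str,
    atoms: list[AtomRecord],
    group: str = "NA",
    representations: tuple[str, ...] = ("aasurf", "cacno"),
    dim: int = 64,
    order: int = 20,
    with_features: bool = True,
) -> DatabaseEntry:
    """Assemble a database entry with descriptors for the requested reps."""
    descriptors = {}
    n_res = 0
    for rep in representations:
        subset = select_representation(atoms, rep)
        n_res = subset.n_residues
        d = describe_atoms(subset, dim=dim, order=order)
        d.meta["id"] = entry_id
        descriptors[Representation(rep).value] = d
    features = compute_shape_features(atoms, dim=dim) if with_features else None
    return DatabaseEntry(
        id=entry_id,
        length=n_res,
        group=group,
        descriptors=descriptors,
        features=features,
    )
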