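"""3D Zernike moments, rotation-invariant descriptors, and reconstruction.

The 3D Zernike basis on the unit ball is

    Z_nlm(r, theta, phi) = R_nl(r) Y_lm(theta, phi),

with order ``n``, degree ``0 <= l <= n`` restricted to ``(n - l)`` even, and
repetition ``-l <= m <= l``. The radial polynomials R_nl are chosen
(following the Canterakis / Novotni-Klein construction) so that every Z_nlm
is a polynomial in the Cartesian coordinates, and the basis is orthonormal
under the measure ``(3 / 4 pi) dx`` on the unit ball.

Moments of a voxelized shape f(x) are the expansion coefficients

    Omega_nlm = (3 / 4 pi) * integral of f(x) conj(Z_nlm(x)) dx,

computed here in a single pass through geometric (monomial) moments: each
Z_nlm is expanded once into monomials x^a y^b z^c, and the voxel sums are
shared by all (n, l, m). Collapsing each (2l+1)-vector Omega_nl to its
Euclidean norm gives the rotation-invariant descriptor components

    F_nl = || Omega_nl ||_2,

121 numbers at the standard order 20. The final descriptor is normalized to
unit length, which suppresses the dependence on the voxel count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb, factorial, pi, sqrt

import numpy as np

from .surface import UnitSphereGrid, VoxelGrid

__all__ = [
    "ZernikeMoments",
    "Descriptor",
    "count_invariants",
    "nl_pairs",
    "compute_moments",
    "invariants",
    "normalize_descriptor",
    "reconstruct",
    "descriptor_correlation",
    "describe_grid",
    "write_descriptor",
    "read_descriptor",
]

MAX_ACCURATE_ORDER = 20


# ---------------------------------------------------------------------------
# index bookkeeping

def nl_pairs(order: int) -> list[tuple[int, int]]:
    """(n, l) pairs with 0 <= l <= n <= order, (n - l) even, in fixed order."""
    if order < 0:
        raise ValueError("order must be non-negative")
    return [(n, l) for n in range(order + 1) for l in range(n + 1) if (n - l) % 2 == 0]


def count_invariants(order: int) -> int:
    """Number of rotation invariants F_nl up to the given order (121 at 20)."""
    return len(nl_pairs(order))


def _nlm_triplets(order: int) -> list[tuple[int, int, int]]:
    """(n, l, m) with m >= 0; negative m follows by conjugation symmetry."""
    return [(n, l, m) for (n, l) in nl_pairs(order) for m in range(l + 1)]


# ---------------------------------------------------------------------------
# basis polynomial coefficients (monomial expansion)

def _radial_coeff(k: int, l: int, nu: int) -> float:
    """Coefficient of r^(2 nu + l) in R_nl with n = 2k + l."""
    return (
        ((-1) ** k / 4.0**k)
        * sqrt((2 * l + 4 * k + 3) / 3.0)
        * comb(2 * k, k)
        * (-1) ** nu
        * comb(k, nu)
        * comb(2 * (k + l + nu) + 1, 2 * k)
        / comb(k + l + nu, k)
    )


def _solid_harmonic_monomials(l: int, m: int) -> dict[tuple[int, int, int], complex]:
    """Monomial coefficients of sqrt(4 pi) r^l Y_lm (Condon-Shortley), m >= 0."""
    pref = (-1) ** m * sqrt((2 * l + 1) * factorial(l + m) * factorial(l - m))
    out: dict[tuple[int, int, int], complex] = {}
    for b in range((l - m) // 2 + 1):
        c0 = (
            pref
            * (-1) ** b
            / (2 ** (2 * b + m) * factorial(m + b) * factorial(b) * factorial(l - m - 2 * b))
        )
        p, q, zpow = m + b, b, l - m - 2 * b
        # expand (x + iy)^p (x - iy)^q
        for al in range(p + 1):
            for be in range(q + 1):
                coef = (
                    c0
                    * comb(p, al)
                    * comb(q, be)
                    * (1j) ** (p - al)
                    * (-1j) ** (q - be)
                )
                key = (al + be, (p - al) + (q - be), zpow)
                out[key] = out.get(key, 0) + coef
    return out


def _zernike_monomials(n: int, l: int, m: int) -> dict[tuple[int, int, int], complex]:
    """Monomial coefficients of Z_nlm = R_nl(r) * sqrt(4 pi) Y_lm, m >= 0."""
    k = (n - l) // 2
    harm = _solid_harmonic_monomials(l, m)
    out: dict[tuple[int, int, int], complex] = {}
    for nu in range(k + 1):
        q = _radial_coeff(k, l, nu)
        for i in range(nu + 1):
            for j in range(nu - i + 1):
                kk = nu - i - j
                mult = q * factorial(nu) / (factorial(i) * factorial(j) * factorial(kk))
                for (a, b, c), hc in harm.items():
                    key = (a + 2 * i, b + 2 * j, c + 2 * kk)
                    out[key] = out.get(key, 0) + mult * hc
    return out


@lru_cache(maxsize=4)
def _basis_table(order: int):
    """Dense monomial-coefficient matrix for all (n, l, m >= 0) up to order.

    Returns (nlms, monomials, chi) with chi[row, col] the coefficient of
    monomial x^a y^b z^c (col) in Z_nlm (row).
    """
    monos = [
        (a, b, c)
        for a in range(order + 1)
        for b in range(order + 1 - a)
        for c in range(order + 1 - a - b)
    ]
    mono_idx = {mn: i for i, mn in enumerate(monos)}
    nlms = _nlm_triplets(order)
    chi = np.zeros((len(nlms), len(monos)), dtype=complex)
    for row, (n, l, m) in enumerate(nlms):
        for key, co in _zernike_monomials(n, l, m).items():
            chi[row, mono_idx[key]] = co
    return nlms, monos, chi


# ---------------------------------------------------------------------------
# moments and invariants

@dataclass
class ZernikeMoments:
    """Complex moments Omega_nlm of a real voxel function.

    Only m >= 0 is stored; for real input the missing half follows from the
    conjugation symmetry Omega_nl(-m) = (-1)^m conj(Omega_nlm), which
    :meth:`value` applies transparently.
    """

    order: int
    values: np.ndarray  # complex, aligned with _nlm_triplets(order)

    def __post_init__(self):
        expected = len(_nlm_triplets(self.order))
        if len(self.values) != expected:
            raise ValueError(
                f"moment vector has {len(self.values)} entries, expected {expected}"
            )
        self._index = {t: i for i, t in enumerate(_nlm_triplets(self.order))}

    def value(self, n: int, l: int, m: int) -> complex:
        if abs(m) > l or l > n or (n - l) % 2:
            raise KeyError(f"invalid moment index (n={n}, l={l}, m={m})")
        if m >= 0:
            return complex(self.values[self._index[(n, l, m)]])
        return (-1) ** (-m) * np.conj(self.values[self._index[(n, l, -m)]])

    def vector_nl(self, n: int, l: int) -> np.ndarray:
        """The (2l+1)-vector Omega_nl, m from -l to l."""
        return np.array([self.value(n, l, m) for m in range(-l, l + 1)])


@dataclass
class Descriptor:
    """Rotation-invariant shape descriptor: F_nl in fixed (n, l) order."""

    order: int
    values: np.ndarray
    normalized: bool = False
    meta: dict = field(default_factory=dict)  # id, rep, len for file headers

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = count_invariants(self.order)
        if len(self.values) != expected:
            raise ValueError(
                f"descriptor has {len(self.values)} entries, expected {expected}"
            )
        if np.any(self.values < 0):
            raise ValueError("descriptor entries must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


def _unit_axis(dim: int) -> np.ndarray:
    return (np.arange(dim) + 0.5 - dim / 2) * (2.0 / dim)


def compute_moments(grid: UnitSphereGrid | np.ndarray, order: int = 20) -> ZernikeMoments:
    """3D Zernike moments of a unit-sphere voxel grid.

    The grid is reduced to geometric moments M_abc = sum f x^a y^b z^c dV in
    three tensor contractions, then projected onto the basis through the
    precomputed monomial coefficients. Deterministic for fixed input.
    """
    if order < 0:
        raise ValueError("order must be non-negative")
    if order > MAX_ACCURATE_ORDER:
        warnings.warn(
            f"order {order} > {MAX_ACCURATE_ORDER}: radial coefficients lose "
            "precision in double arithmetic",
            stacklevel=2,
        )
    values = grid.values if isinstance(grid, VoxelGrid) else np.asarray(grid)
    values = values.astype(float)
    if not values.any():
        raise ValueError("grid has no occupied voxels")
    dim = values.shape[0]
    ax = _unit_axis(dim)

    # guard the unit-ball contract: occupied voxels must lie inside r <= 1
    nz = np.argwhere(values != 0)
    pos = ax[nz]
    rmax = np.sqrt((pos**2).sum(axis=1)).max()
    if rmax > 1.0 + 1e-9:
        raise ValueError(
            f"occupied voxels outside the unit sphere (max radius {rmax:.3f}); "
            "scale the grid first"
        )

    powers = np.stack([ax**p for p in range(order + 1)], axis=1)  # (dim, order+1)
    t = np.tensordot(values, powers, axes=([2], [0]))
    t = np.tensordot(t, powers, axes=([1], [0]))
    t = np.tensordot(t, powers, axes=([0], [0]))
    geo = np.transpose(t, (2, 1, 0)) * (2.0 / dim) ** 3  # geo[a, b, c]

    nlms, monos, chi = _basis_table(order)
    mono_vals = geo[tuple(np.array(monos).T)]
    om = (3.0 / (4.0 * pi)) * (np.conj(chi) @ mono_vals)
    return ZernikeMoments(order=order, values=om)


def invariants(moments: ZernikeMoments) -> Descriptor:
    """Collapse moments to rotation invariants F_nl = ||Omega_nl||_2."""
    acc: dict[tuple[int, int], float] = {}
    for (n, l, m), v in zip(_nlm_triplets(moments.order), moments.values):
        w = 1.0 if m == 0 else 2.0  # negative m carries equal magnitude
        acc[(n, l)] = acc.get((n, l), 0.0) + w * float(np.abs(v)) ** 2
    vals = np.sqrt([acc[p] for p in nl_pairs(moments.order)])
    return Descriptor(order=moments.order, values=vals, normalized=False)


def normalize_descriptor(d: Descriptor) -> Descriptor:
    """Scale the descriptor to unit Euclidean norm."""
    norm = float(np.linalg.norm(d.values))
    if norm == 0.0:
        raise ValueError("cannot normalize a zero descriptor")
    return Descriptor(
        order=d.order, values=d.values / norm, normalized=True, meta=dict(d.meta)
    )


def describe_grid(grid: UnitSphereGrid | np.ndarray, order: int = 20) -> Descriptor:
    """Convenience pipeline: moments -> invariants -> unit normalization."""
    return normalize_descriptor(invariants(compute_moments(grid, order)))


def reconstruct(
    moments: ZernikeMoments, dim: int, order_cap: int | None = None
) -> VoxelGrid:
    """Evaluate the truncated Zernike expansion on a grid (real part).

    Collects the full expansion into a single real polynomial (the negative-m
    terms pair with the positive-m ones into 2 Re(Omega Z)), then evaluates
    it with three tensor contractions. Values outside the unit sphere are
    zeroed.
    """
    cap = moments.order if order_cap is None else order_cap
    if cap > moments.order:
        raise ValueError(f"order_cap {cap} exceeds moments order {moments.order}")
    nlms, monos, chi = _basis_table(moments.order)
    weights = np.array(
        [0.0 if n > cap else (1.0 if m == 0 else 2.0) for (n, l, m) in nlms]
    )
    poly = np.real((weights * moments.values) @ chi)  # coefficient per monomial

    coeff = np.zeros((moments.order + 1,) * 3)
    coeff[tuple(np.array(monos).T)] = poly

    ax = _unit_axis(dim)
    powers = np.stack([ax**p for p in range(moments.order + 1)], axis=1)
    t = np.tensordot(coeff, powers, axes=([2], [1]))  # (a, b, z)
    t = np.tensordot(t, powers, axes=([1], [1]))  # (a, z, y)
    out = np.tensordot(t, powers, axes=([0], [1]))  # (z, y, x)
    out = np.transpose(out, (2, 1, 0))

    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    out[x**2 + y**2 + z**2 > 1.0] = 0.0
    return VoxelGrid(values=out, spacing=2.0 / dim, origin=np.full(3, -1.0 + 1.0 / dim))


def descriptor_correlation(a: Descriptor, b: Descriptor) -> float:
    """Pearson correlation between two descriptors of equal length."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if np.std(a.values) == 0 or np.std(b.values) == 0:
        raise ValueError("zero-variance descriptor has no defined correlation")
    return float(np.corrcoef(a.values, b.values)[0, 1])


# ---------------------------------------------------------------------------
# flat-file format

def write_descriptor(d: Descriptor, path_or_buf) -> None:
    """Write the flat text format: one header line, then the invariants.

    Header: ``#3DZD order=20 rep=CACNO id=<id> len=<n_residues>``; values are
    printed with 17 significant digits so the round trip is bit-stable.
    """
    close = False
    if isinstance(path_or_buf, (str, bytes)):
        buf = open(path_or_buf, "w")
        close = True
    else:
        buf = path_or_buf
    try:
        rep = str(d.meta.get("rep", "NA")).upper()
        ident = d.meta.get("id", "NA")
        length = d.meta.get("len", 0)
        buf.write(f"#3DZD order={d.order} rep={rep} id={ident} len={length}\n")
        buf.write(" ".join(f"{v:.17g}" for v in d.values) + "\n")
    finally:
        if close:
            buf.close()


def read_descriptor(path_or_buf) -> Descriptor:
    """Read one descriptor written by :func:`write_descriptor`."""
    if isinstance(path_or_buf, (str, bytes)):
        with open(path_or_buf) as fh:
            return read_descriptor(fh)
    header = path_or_buf.readline()
    if not header.startswith("#3DZD"):
        raise ValueError(f"not a descriptor file (header {header!r})")
    fields = dict(tok.split("=", 1) for tok in header.split()[1:])
    values = np.array(path_or_buf.readline().split(), dtype=float)
    d = Descriptor(
        order=int(fields["order"]),
        values=values,
        normalized=bool(abs(np.linalg.norm(values) - 1.0) < 1e-9),
        meta={
            "rep": fields.get("rep", "NA").lower(),
            "id": fields.get("id", "NA"),
            "len": int(fields.get("len", 0)),
        },
    )
    return d
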