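"""Descriptor database, distances, and query ranking.

Retrieval compares unit-normalized descriptors by Euclidean (L2) distance.
The combined mode sums the all-atom-surface and backbone distances with
query-adaptive weights, making it deliberately asymmetric: the weights come
from the query's shape, not the candidate's. Because scaling into the unit
sphere discards protein size, an optional sequence-length pre-filter removes
candidates outside 65-135% of the query length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import ShapeFeatures, query_weights
from .structures import Representation
from .zernike import Descriptor, read_descriptor, write_descriptor

__all__ = [
    "DatabaseEntry",
    "RankedList",
    "descriptor_distance",
    "combined_distance",
    "length_prefilter",
    "rank_database",
    "write_database",
    "read_database",
]

LENGTH_FILTER_LO = 0.65
LENGTH_FILTER_HI = 1.35


@dataclass
class DatabaseEntry:
    """One protein in the searchable database."""

    id: str
    length: int  # residue count
    group: str  # classification label (fold / class / ...)
    descriptors: dict[str, Descriptor] = field(default_factory=dict)
    features: ShapeFeatures | None = None

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("length must be >= 1")
        self.descriptors = {
            Representation(k).value: v for k, v in self.descriptors.items()
        }
        for rep, d in self.descriptors.items():
            if not d.normalized:
                raise ValueError(f"descriptor for {rep!r} is not unit-normalized")

    def descriptor(self, rep: Representation | str) -> Descriptor:
        rep = Representation(rep).value
        if rep not in self.descriptors:
            raise KeyError(f"entry {self.id!r} has no {rep!r} descriptor")
        return self.descriptors[rep]


@dataclass
class RankedList:
    """Candidates sorted by ascending distance to the query."""

    query_id: str
    hits: list[tuple[str, float]]

    def ids(self) -> list[str]:
        return [h[0] for h in self.hits]

    def distances(self) -> np.ndarray:
        return np.array([h[1] for h in self.hits])


def descriptor_distance(a: Descriptor, b: Descriptor) -> float:
    """Euclidean distance between two descriptors."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return float(np.linalg.norm(a.values - b.values))


def combined_distance(
    query: DatabaseEntry,
    candidate: DatabaseEntry,
    weights: tuple[float, float] | None = None,
) -> float:
    """Weighted sum of the all-atom and backbone descriptor distances.

    ``weights = (w_S, w_B)`` applies w_S to the AASURF distance and w_B to
    the CACNO distance. When omitted, the weights follow from the *query's*
    shape features, which makes the measure asymmetric by design.
    """
    if weights is None:
        if query.features is None:
            raise ValueError(f"query {query.id!r} has no shape features")
        weights = query_weights(query.features)
    w_s, w_b = weights
    if abs(w_s + w_b - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    d_s = descriptor_distance(
        query.descriptor(Representation.AASURF),
        candidate.descriptor(Representation.AASURF),
    )
    d_b = descriptor_distance(
        query.descriptor(Representation.CACNO),
        candidate.descriptor(Representation.CACNO),
    )
    return w_s * d_s + w_b * d_b


def length_prefilter(query_length: int, candidate_length: int) -> bool:
    """Keep a candidate iff its length is within 65-135% of the query's."""
    if query_length < 1 or candidate_length < 1:
        raise ValueError("lengths must be >= 1")
    return (
        LENGTH_FILTER_LO * query_length
        <= candidate_length
        <= LENGTH_FILTER_HI * query_length
    )


def rank_database(
    query: DatabaseEntry,
    db: list[DatabaseEntry],
    mode: str = "cacno",
    use_length_filter: bool = False,
) -> RankedList:
    """Sort database entries by distance to the query.

    ``mode`` is a representation tag for single-representation search, or
    ``"combined"`` for the weighted two-representation distance. Ties are
    broken by id so results are deterministic.
    """
    if not db:
        raise ValueError("empty database")
    scored = []
    for entry in db:
        if entry.id == query.id:
            continue
        if use_length_filter and not length_prefilter(query.length, entry.length):
            continue
        if mode == "combined":
            dist = combined_distance(query, entry)
        else:
            rep = Representation(mode)
            dist = descriptor_distance(query.descriptor(rep), entry.descriptor(rep))
        scored.append((entry.id, dist))
    if not scored:
        warnings.warn(
            f"no candidates remain for query {query.id!r} after filtering",
            stacklevel=2,
        )
    scored.sort(key=lambda t: (t[1], t[0]))
    return RankedList(query_id=query.id, hits=scored)


# ---------------------------------------------------------------------------
# database files: concatenated descriptor blocks + a TSV index

def write_database(entries: list[DatabaseEntry], desc_path: str, index_path: str) -> None:
    """Persist a database as descriptor flat-file blocks plus a TSV index."""
    with open(desc_path, "w") as fh:
        for entry in entries:
            for rep in sorted(entry.descriptors):
                d = entry.descriptors[rep]
                d.meta.update({"id": entry.id, "rep": rep, "len": entry.length})
                write_descriptor(d, fh)
    rows = []
    for entry in entries:
        feats = entry.features
        rows.append(
            {
                "id": entry.id,
                "length": entry.length,
                "group": entry.group,
                "sp": feats.sphericity if feats else np.nan,
                "tail": feats.tail_residues if feats else 0,
                "rg": feats.rg if feats else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(index_path, sep="\t", index=False)


def read_database(desc_path: str, index_path: str) -> list[DatabaseEntry]:
    """Load a database written by :func:`write_database`."""
    index = pd.read_csv(index_path, sep="\t", dtype={"id": str, "group": str})
    descriptors: dict[str, dict[str, Descriptor]] = {}
    with open(desc_path) as fh:
        while True:
            pos = fh.tell()
            if not fh.readline().strip():
                break
            fh.seek(pos)
            d = read_descriptor(fh)
            descriptors.setdefault(d.meta["id"], {})[d.meta["rep"]] = d

    entries = []
    for row in index.itertuples():
        feats = None
        if np.isfinite(row.rg):
            feats = ShapeFeatures(
                rg=float(row.rg),
                sphericity=float(row.sp),
                tail_residues=int(row.tail),
                n_residues=int(row.length),
            )
        entries.append(
            DatabaseEntry(
                id=row.id,
                length=int(row.length),
                group=row.group,
                descriptors=descriptors.get(row.id, {}),
                features=feats,
            )
        )
    return entries
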