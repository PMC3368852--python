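"""Pairwise genetic distances between aligned variants and clone-level matrices.

Distances are simple pairwise differences (Hamming counts) on the alignment,
with two gap conventions: ``fifth_state`` treats ``-`` as a fifth character
state (gap vs base is a difference, gap vs gap a match), ``ignore`` skips any
column containing a gap in either sequence. The square-root transform is
applied only where matrices are routed into the multifactor partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import CloneLibrary, SequenceVariant

__all__ = [
    "DistanceMatrix",
    "pairwise_differences",
    "variant_distance_matrix",
    "sqrt_transform",
    "clone_distance_matrix",
]

GAP = "-"
GAP_MODES = ("fifth_state", "ignore")


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with a metric tag.

    ``metric`` is ``raw_differences`` (integer Hamming counts) or
    ``sqrt_differences`` (element-wise square root of the former).
    """

    labels: list[str]
    values: np.ndarray
    metric: str = "raw_differences"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("distance matrix contains negative values")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix diagonal is not zero")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in distance matrix") from None

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.index(a), self.index(b)])


def pairwise_differences(seq_a: str, seq_b: str, gap_mode: str = "fifth_state") -> int:
    """Count of aligned positions at which two sequences differ.

    ``fifth_state``: a gap is just another symbol. ``ignore``: columns with a
    gap in either sequence are skipped entirely.
    """
    if gap_mode not in GAP_MODES:
        raise ValueError(f"gap_mode must be one of {GAP_MODES}, got {gap_mode!r}")
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"unequal aligned lengths: {len(seq_a)} vs {len(seq_b)}"
        )
    a = seq_a.upper()
    b = seq_b.upper()
    if gap_mode == "fifth_state":
        return sum(x != y for x, y in zip(a, b))
    return sum(x != y for x, y in zip(a, b) if x != GAP and y != GAP)


def variant_distance_matrix(
    variants: Sequence[SequenceVariant] | Mapping[str, SequenceVariant],
    gap_mode: str = "fifth_state",
) -> DistanceMatrix:
    """Raw-differences matrix over a set of aligned variants (label order preserved)."""
    if isinstance(variants, Mapping):
        vlist = list(variants.values())
    else:
        vlist = list(variants)
    if len(vlist) < 2:
        raise ValueError("need at least 2 variants for a distance matrix")
    labels = [v.label for v in vlist]
    n = len(vlist)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_differences(vlist[i].sequence, vlist[j].sequence, gap_mode)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values, metric="raw_differences")


def sqrt_transform(matrix: DistanceMatrix) -> DistanceMatrix:
    """Element-wise square root; guards against double application via the metric tag."""
    if matrix.metric != "raw_differences":
        raise ValueError(
            f"sqrt_transform expects metric 'raw_differences', got {matrix.metric!r}"
        )
    return DistanceMatrix(
        labels=list(matrix.labels),
        values=np.sqrt(matrix.values),
        metric="sqrt_differences",
    )


def clone_distance_matrix(
    libraries: Sequence[CloneLibrary],
    variant_matrix: DistanceMatrix,
) -> tuple[DistanceMatrix, "pd.DataFrame"]:
    """Expand per-variant distances to per-clone distances.

    Every clone is one unit; the distance between two clones is the distance
    between their variants. Returns the clone matrix together with a metadata
    frame (one row per clone: sample_id, colony_id, site, year, life_stage,
    morphology, variant), aligned with the matrix rows.
    """
    import pandas as pd

    if not libraries:
        raise ValueError("no libraries supplied")
    rows = []
    idx: list[int] = []
    for lib in libraries:
        if lib.is_empty():
            raise ValueError(f"library {lib.sample_id!r} is empty after screening")
        for label in sorted(lib.counts):
            vi = variant_matrix.index(label)
            for _ in range(lib.counts[label]):
                idx.append(vi)
                rows.append(
                    {
                        "sample_id": lib.sample_id,
                        "colony_id": lib.colony_id,
                        "site": lib.site,
                        "year": lib.year,
                        "life_stage": lib.life_stage,
                        "morphology": lib.morphology,
                        "variant": label,
                    }
                )
    idx_arr = np.asarray(idx)
    values = variant_matrix.values[np.ix_(idx_arr, idx_arr)]
    labels = [f"{r['sample_id']}:{r['variant']}:{k}" for k, r in enumerate(rows)]
    meta = pd.DataFrame(rows)
    return (
        DistanceMatrix(labels=labels, values=values, metric=variant_matrix.metric),
        meta,
    )
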