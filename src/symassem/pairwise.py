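"""Per-colony adult-vs-egg statistics: percent similarity index and two-group AMOVA.

PSI (Wolda/Renkonen) is the sum over shared variant labels of the minimum
relative abundance in the two libraries: 1 for identical composition, 0 for
disjoint label sets. It is reported as a proportion.

The two-group AMOVA follows the distance formulation of Excoffier et al.
(1992) on squared clone-to-clone distances:

    SS_total  = (1/N) sum_{i<j} d_ij^2            over all clones,
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2,
    SS_among  = SS_total - SS_within,

with variance components from the usual expectations (n0 = (N - sum n_g^2/N)
/ (k-1)) and Phi = sigma2_among / (sigma2_among + sigma2_within). Phi may be
negative; it is never truncated. Significance comes from permuting clones
between the groups with group sizes fixed, with the add-one rule so p is
never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .io import CloneLibrary

__all__ = ["PsiResult", "TwoGroupAmova", "TwoGroupAmovaResults", "psi", "pairwise_phi", "permutation_test"]


@dataclass
class PsiResult:
    colony_id: str
    psi: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.psi <= 1 + 1e-12:
            raise ValueError(f"PSI out of [0, 1]: {self.psi}")
        self.psi = float(min(max(self.psi, 0.0), 1.0))

    @property
    def rounded(self) -> float:
        """PSI to 2 decimals with conventional half-up rounding (report scale)."""
        return round_half_up(self.psi)


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half away from zero, the convention of printed summary tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def psi(library_a: CloneLibrary, library_b: CloneLibrary) -> PsiResult:
    """Percent similarity index between two screened, non-empty libraries."""
    for lib in (library_a, library_b):
        if lib.is_empty():
            raise ValueError(
                f"cannot compute PSI on empty library {lib.sample_id!r}"
            )
    ta, tb = library_a.total, library_b.total
    shared = library_a.labels & library_b.labels
    value = sum(
        min(library_a.counts[l] / ta, library_b.counts[l] / tb) for l in shared
    )
    return PsiResult(colony_id=library_a.colony_id, psi=float(value))


class TwoGroupAmova:
    """Two-group distance AMOVA model over a clone distance matrix.

    Parameters
    ----------
    clone_distances
        Clone-by-clone :class:`DistanceMatrix` covering both groups
        (raw differences; squared internally).
    groups
        Sequence of group labels, one per clone, aligned with the matrix.
        Exactly two distinct labels required for the per-colony use, though
        the SS formulas accept k groups.
    """

    def __init__(self, clone_distances: DistanceMatrix, groups: Sequence) -> None:
        self.d2 = np.asarray(clone_distances.values, dtype=float) ** 2
        self.groups = np.asarray(groups)
        n = self.d2.shape[0]
        if len(self.groups) != n:
            raise ValueError(f"{len(self.groups)} group labels for {n} clones")
        self.levels, self.codes = np.unique(self.groups, return_inverse=True)
        sizes = np.bincount(self.codes)
        if np.any(sizes == 0) or len(self.levels) < 2:
            raise ValueError("each group must contain at least one clone")
        self.sizes = sizes

    # -- statistic ---------------------------------------------------------
    def _components(self, codes: np.ndarray) -> tuple[float, float, float]:
        """(sigma2_among, sigma2_within, phi) for a given group coding."""
        n = self.d2.shape[0]
        k = len(self.levels)
        ones = np.ones(n)
        ss_total = float(ones @ self.d2 @ ones) / (2.0 * n)
        ss_within = 0.0
        for g in range(k):
            mask = codes == g
            ng = int(mask.sum())
            block = self.d2[np.ix_(mask, mask)]
            ss_within += block.sum() / (2.0 * ng)
        ss_among = ss_total - ss_within
        df_within = n - k
        sigma_w = ss_within / df_within if df_within > 0 else 0.0
        n0 = (n - float((self.sizes**2).sum()) / n) / (k - 1)
        ms_among = ss_among / (k - 1)
        sigma_a = (ms_among - sigma_w) / n0
        denom = sigma_a + sigma_w
        phi = sigma_a / denom if denom > 0 else 0.0
        return sigma_a, sigma_w, phi

    def fit(self, n_perm: int = 0, seed: int | None = None) -> "TwoGroupAmovaResults":
        """Compute Phi and, if ``n_perm >= 1``, its permutation p-value."""
        sigma_a, sigma_w, phi = self._components(self.codes)
        p_value = float("nan")
        if n_perm:
            if n_perm < 1:
                raise ValueError("n_perm must be >= 1")
            rng = np.random.default_rng(seed)
            count = 0
            codes = self.codes.copy()
            for _ in range(int(n_perm)):
                rng.shuffle(codes)
                if self._components(codes)[2] >= phi - 1e-12:
                    count += 1
            p_value = (1 + count) / (1 + int(n_perm))
        return TwoGroupAmovaResults(
            phi=float(phi),
            sigma2_among=float(sigma_a),
            sigma2_within=float(sigma_w),
            p_value=p_value,
            n_permutations=int(n_perm),
            seed=seed,
        )


@dataclass
class TwoGroupAmovaResults:
    """Estimates from a two-group distance AMOVA fit."""

    phi: float
    sigma2_among: float
    sigma2_within: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    colony_id: str = ""

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"quantity": "phi", "value": self.phi},
                {"quantity": "sigma2_among", "value": self.sigma2_among},
                {"quantity": "sigma2_within", "value": self.sigma2_within},
                {"quantity": "p_value", "value": self.p_value},
                {"quantity": "n_permutations", "value": self.n_permutations},
            ]
        )


def _model_for_pair(
    library_a: CloneLibrary,
    library_b: CloneLibrary,
    clone_distances: DistanceMatrix,
    clone_meta: pd.DataFrame,
) -> TwoGroupAmova:
    mask = clone_meta["sample_id"].isin([library_a.sample_id, library_b.sample_id]).to_numpy()
    if not mask.any():
        raise ValueError("clone distance matrix covers neither library")
    sub = DistanceMatrix(
        labels=[l for l, m in zip(clone_distances.labels, mask) if m],
        values=clone_distances.values[np.ix_(mask, mask)],
        metric=clone_distances.metric,
    )
    groups = clone_meta.loc[mask, "sample_id"].to_numpy()
    for lib in (library_a, library_b):
        if (groups == lib.sample_id).sum() != lib.total:
            raise ValueError(
                f"clone matrix does not cover all clones of {lib.sample_id!r}"
            )
    return TwoGroupAmova(sub, groups)


def pairwise_phi(
    library_a: CloneLibrary,
    library_b: CloneLibrary,
    clone_distances: DistanceMatrix,
    clone_meta: pd.DataFrame,
) -> TwoGroupAmovaResults:
    """Two-group AMOVA Phi between two libraries (statistic only, no permutations)."""
    res = _model_for_pair(library_a, library_b, clone_distances, clone_meta).fit(n_perm=0)
    res.colony_id = library_a.colony_id
    return res


def permutation_test(
    library_a: CloneLibrary,
    library_b: CloneLibrary,
    clone_distances: DistanceMatrix,
    clone_meta: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> TwoGroupAmovaResults:
    """Two-group AMOVA with a permutation p-value (clones shuffled between groups)."""
    res = _model_for_pair(library_a, library_b, clone_distances, clone_meta).fit(
        n_perm=n_perm, seed=seed
    )
    res.colony_id = library_a.colony_id
    return res
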