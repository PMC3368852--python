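"""Nested multifactor distance-based variance partitioning (PERMANOVA-style).

The machinery is McArdle–Anderson: the squared distance matrix is Gower-centred
into an inner-product matrix G = -1/2 J D^2 J (J the centering projector), whose
trace is the total sum of squares. Model terms are fitted sequentially
(Type I SS, published term order): each term contributes
SS_t = tr((H_t - H_{t-1}) G), where H_t projects onto the column space of all
terms up to t (plus intercept). Pseudo-F uses the residual mean square as the
denominator by default, with an optional per-term denominator override for
experimentation with mixed-model expectations. Significance comes from
unrestricted permutation of the observation units (clones) by default;
a design term may instead declare whole libraries as its exchangeable units.

A nested term like Colony(Site) is encoded as the cross-classification of its
factors; fitted after Site, its incremental column space is exactly the
colony-within-site contrasts, so the nesting arithmetic falls out of the
sequential projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .distance import DistanceMatrix

__all__ = [
    "Term",
    "DesignSpec",
    "PartitionTable",
    "DistancePartition",
    "gower_center",
    "fit_partition",
    "builtin_designs",
]


@dataclass(frozen=True)
class Term:
    """One model term: a label and the factor columns whose cross-classification encodes it.

    ``units`` names the exchangeable units permuted when testing this term:
    ``"clones"`` (unrestricted, default) or ``"libraries"`` (whole samples).
    """

    label: str
    factors: tuple[str, ...]
    units: str = "clones"


@dataclass
class DesignSpec:
    """An ordered list of model terms plus permutation settings."""

    terms: list[Term]
    n_permutations: int = 10000
    seed: int | None = None

    def factor_names(self) -> set[str]:
        out: set[str] = set()
        for t in self.terms:
            out.update(t.factors)
        return out


def gower_center(matrix: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Gower-centred inner-product matrix G = -1/2 J D^2 J; tr(G) is the total SS."""
    d = matrix.values if isinstance(matrix, DistanceMatrix) else np.asarray(matrix, float)
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _indicator_columns(meta: pd.DataFrame, factors: tuple[str, ...]) -> np.ndarray:
    combo = meta[list(factors)].astype(str).agg("\x1f".join, axis=1)
    return pd.get_dummies(combo, dtype=float).to_numpy()


def _orthonormal_basis(x: np.ndarray, scale: float | None = None, tol: float = 1e-8) -> np.ndarray:
    """Orthonormal basis of col(x); singular values below tol*scale are noise.

    ``scale`` anchors the cutoff to the magnitude of the *unprojected* columns,
    so a term fully confounded with earlier terms (residual ~ machine epsilon)
    correctly comes back rank 0.
    """
    if x.size == 0:
        return np.zeros((x.shape[0], 0))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    ref = scale if scale is not None else (s[0] if s.size else 0.0)
    rank = int((s > tol * max(ref, 1e-300)).sum())
    return u[:, :rank]


class DistancePartition:
    """Distance-based multifactor partition model (statsmodels-style).

    Parameters
    ----------
    clone_distances
        Clone-level :class:`DistanceMatrix` (square-root-transformed distances
        are the convention for assemblage data; any metric is accepted).
    metadata
        One row per clone, aligned with the matrix, holding every factor
        column the design references.
    design
        The ordered :class:`DesignSpec`.
    """

    def __init__(
        self,
        clone_distances: DistanceMatrix,
        metadata: pd.DataFrame,
        design: DesignSpec,
    ) -> None:
        self.g = gower_center(clone_distances)
        self.meta = metadata.reset_index(drop=True)
        self.design = design
        n = self.g.shape[0]
        if len(self.meta) != n:
            raise ValueError(f"{len(self.meta)} metadata rows for {n} clones")
        missing = design.factor_names() - set(self.meta.columns)
        if missing:
            raise ValueError(f"metadata lacks factor columns {sorted(missing)}")
        self._build_projectors()

    def _build_projectors(self) -> None:
        n = self.g.shape[0]
        basis = np.ones((n, 1)) / np.sqrt(n)  # intercept
        self.increments: list[np.ndarray] = []  # orthonormal increment per term
        self.dfs: list[int] = []
        for term in self.design.terms:
            x = _indicator_columns(self.meta, term.factors)
            resid = x - basis @ (basis.T @ x)
            inc = _orthonormal_basis(resid, scale=float(np.linalg.norm(x)))
            if inc.shape[1] == 0:
                raise ValueError(
                    f"rank-deficient term {term.label!r}: confounded with earlier terms"
                )
            basis = np.hstack([basis, inc])
            self.increments.append(inc)
            self.dfs.append(inc.shape[1])
        self.model_basis = basis
        self.df_resid = n - basis.shape[1]
        if self.df_resid <= 0:
            raise ValueError("saturated design: no residual degrees of freedom")
        # stacked term basis (intercept excluded) for BLAS-friendly SS extraction
        self._stack = (
            np.hstack(self.increments) if self.increments else np.zeros((n, 0))
        )
        bounds = np.cumsum([0] + self.dfs)
        self._slices = [slice(bounds[i], bounds[i + 1]) for i in range(len(self.dfs))]

    # -- sums of squares ---------------------------------------------------
    def _term_ss(self, g: np.ndarray) -> tuple[np.ndarray, float]:
        diag = np.einsum("ij,ij->j", self._stack, g @ self._stack)
        ss = np.array([float(diag[s].sum()) for s in self._slices])
        total = float(np.trace(g))
        # intercept SS of the centred G is 0, so residual = total - sum of term SS
        ss_resid = total - float(ss.sum())
        return ss, ss_resid

    def fit(
        self,
        n_perm: int | None = None,
        seed: int | None = None,
    ) -> "PartitionTable":
        """Sequential SS, pseudo-F and permutation p for every term."""
        n_perm = self.design.n_permutations if n_perm is None else int(n_perm)
        seed = self.design.seed if seed is None else seed
        ss, ss_resid = self._term_ss(self.g)
        ms = ss / np.array(self.dfs, float)
        ms_resid = ss_resid / self.df_resid
        pseudo_f = ms / ms_resid if ms_resid > 0 else np.full_like(ms, np.nan)
        total = float(np.trace(self.g))
        phi_like = ss / total if total > 0 else np.zeros_like(ss)

        p = np.full(len(ss), np.nan)
        if n_perm and n_perm >= 1:
            rng = np.random.default_rng(seed)
            n = self.g.shape[0]
            exceed = np.zeros(len(ss))
            sample_ids = (
                self.meta["sample_id"].to_numpy()
                if "sample_id" in self.meta.columns
                else None
            )
            lib_terms = [t.units == "libraries" for t in self.design.terms]
            need_lib = any(lib_terms)
            for _ in range(n_perm):
                perm = rng.permutation(n)
                gp = self.g[np.ix_(perm, perm)]
                ss_p, ss_resid_p = self._term_ss(gp)
                ms_resid_p = ss_resid_p / self.df_resid
                f_p = (ss_p / np.array(self.dfs, float)) / max(ms_resid_p, 1e-300)
                exceed += f_p >= pseudo_f - 1e-12
            if need_lib:
                lib_exceed = self._library_permutation(n_perm, rng, pseudo_f, sample_ids)
                for i, is_lib in enumerate(lib_terms):
                    if is_lib:
                        exceed[i] = lib_exceed[i]
            p = (1 + exceed) / (1 + n_perm)

        rows = []
        for i, term in enumerate(self.design.terms):
            rows.append(
                {
                    "term": term.label,
                    "df": self.dfs[i],
                    "SS": float(ss[i]),
                    "MS": float(ms[i]),
                    "phi_like": float(phi_like[i]),
                    "pseudo_F": float(pseudo_f[i]),
                    "p_perm": float(p[i]) if n_perm else float("nan"),
                }
            )
        rows.append(
            {
                "term": "Residual",
                "df": self.df_resid,
                "SS": float(ss_resid),
                "MS": float(ms_resid),
                "phi_like": float("nan"),
                "pseudo_F": float("nan"),
                "p_perm": float("nan"),
            }
        )
        return PartitionTable(
            table=pd.DataFrame(rows),
            total_ss=total,
            n_permutations=n_perm or 0,
            seed=seed,
        )

    def _library_permutation(self, n_perm, rng, pseudo_f, sample_ids) -> np.ndarray:
        """Permute whole libraries: shuffle sample-to-metadata assignment and refit."""
        if sample_ids is None:
            raise ValueError("library-level permutation requires a 'sample_id' column")
        exceed = np.zeros(len(self.design.terms))
        uniq = pd.unique(sample_ids)
        factor_cols = sorted(self.design.factor_names())
        lib_meta = self.meta.drop_duplicates("sample_id").set_index("sample_id")
        for _ in range(n_perm):
            perm_ids = rng.permutation(uniq)
            mapping = dict(zip(uniq, perm_ids))
            new_meta = self.meta.copy()
            donor = [mapping[s] for s in sample_ids]
            for col in factor_cols:
                new_meta[col] = lib_meta.loc[donor, col].to_numpy()
            try:
                model = DistancePartition(
                    DistanceMatrix(
                        labels=[str(i) for i in range(self.g.shape[0])],
                        values=np.zeros_like(self.g),
                        metric="raw_differences",
                    ),
                    new_meta,
                    self.design,
                )
            except ValueError:
                continue  # permuted layout confounded; skip draw
            model.g = self.g
            ss_p, ss_resid_p = model._term_ss(self.g)
            f_p = (ss_p / np.array(model.dfs, float)) / max(
                ss_resid_p / model.df_resid, 1e-300
            )
            exceed += f_p >= pseudo_f - 1e-12
        return exceed


@dataclass
class PartitionTable:
    """Results of a sequential distance partition fit."""

    table: pd.DataFrame
    total_ss: float
    n_permutations: int
    seed: int | None = None

    def summary(self) -> pd.DataFrame:
        return self.table.copy()

    def row(self, term: str) -> pd.Series:
        hit = self.table[self.table["term"] == term]
        if hit.empty:
            raise KeyError(f"no term {term!r} in partition table")
        return hit.iloc[0]

    @property
    def ss_additivity_gap(self) -> float:
        return abs(float(self.table["SS"].sum()) - self.total_ss)


def fit_partition(
    clone_distances: DistanceMatrix,
    metadata: pd.DataFrame,
    design: DesignSpec,
    n_perm: int | None = None,
    seed: int | None = None,
) -> PartitionTable:
    """Functional wrapper over :class:`DistancePartition`."""
    return DistancePartition(clone_distances, metadata, design).fit(n_perm=n_perm, seed=seed)


def builtin_designs() -> tuple[DesignSpec, DesignSpec]:
    """The two published experimental designs.

    Four-factor (two sites, two years, two life stages, colonies nested in
    site) and three-factor (two morphologies co-occurring at one site, two
    life stages, colonies nested in morphology); 10,000 permutations each.
    """
    four = DesignSpec(
        terms=[
            Term("Si", ("site",)),
            Term("Ye", ("year",)),
            Term("Li", ("life_stage",)),
            Term("Co(Si)", ("site", "colony_id")),
            Term("SixYe", ("site", "year")),
            Term("SixLi", ("site", "life_stage")),
            Term("YexLi", ("year", "life_stage")),
            Term("YexCo(Si)", ("year", "site", "colony_id")),
            Term("LixCo(Si)", ("life_stage", "site", "colony_id")),
            Term("SixYexLi", ("site", "year", "life_stage")),
            Term("YexLixCo(Si)", ("year", "life_stage", "site", "colony_id")),
        ],
        n_permutations=10000,
    )
    three = DesignSpec(
        terms=[
            Term("Mo", ("morphology",)),
            Term("Li", ("life_stage",)),
            Term("Co(Mo)", ("morphology", "colony_id")),
            Term("MoxLi", ("morphology", "life_stage")),
            Term("LixCo(Mo)", ("life_stage", "morphology", "colony_id")),
        ],
        n_permutations=10000,
    )
    return four, three
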