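"""Hierarchical diploid AMOVA on host nuclear-intron genotypes, plus exact tests.

The AMOVA partitions squared allele distances over the 2N allele copies into
four strata: among groups, among samples within groups, among individuals
within samples, and within individuals. Sums of squares use the distance
formulation (within-cluster SS = sum of squared pairwise distances divided by
cluster size); variance components come from the standard nested expectations,
computed for arbitrary unbalanced layouts by solving the triangular system of
expected sums of squares. Phi statistics are ratios of cumulative components
(the F-statistic analogues for molecular data); negative components are
reported as-is, never truncated.

The exact test of non-differentiation (Raymond & Rousset) works on an
allele-by-population contingency table: for small tables the null distribution
is enumerated completely over all tables with the observed margins; larger
tables use a Markov chain over 2x2 switch proposals with Metropolis
acceptance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .distance import pairwise_differences
from .io import GenotypeTable

__all__ = [
    "HierAmovaResult",
    "ExactTestResult",
    "HierarchicalDiploidAmova",
    "hier_amova",
    "exact_test",
]

_LEVELS = [
    "among_groups",
    "among_samples_within_groups",
    "among_individuals_within_samples",
    "within_individuals",
]
_PHI_LABELS = ["Phi_AM", "Phi_AS(AM)", "Phi_AI(AS(AM))", "Phi_WI"]

ENUMERATION_CUTOFF = 12  # total table count at or below which the test is exact


# ---------------------------------------------------------------------------
# core SS machinery over allele copies


def _allele_distance_matrix(genotypes: GenotypeTable) -> tuple[list[str], np.ndarray]:
    labels = sorted(genotypes.allele_labels)
    if genotypes.allele_distances is not None:
        tab = genotypes.allele_distances
        missing = [l for l in labels if l not in tab.index or l not in tab.columns]
        if missing:
            raise ValueError(f"allele distance matrix lacks alleles {missing}")
        d = tab.loc[labels, labels].to_numpy(dtype=float)
    elif genotypes.allele_sequences is not None:
        missing = [l for l in labels if l not in genotypes.allele_sequences]
        if missing:
            raise ValueError(f"allele sequences lack alleles {missing}")
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pairwise_differences(
                    genotypes.allele_sequences[labels[i]],
                    genotypes.allele_sequences[labels[j]],
                )
    else:
        raise ValueError("genotype table has neither allele sequences nor a distance matrix")
    return labels, d


def _within_ss(d2: np.ndarray, allele_idx: np.ndarray, clusters: np.ndarray, n_alleles: int) -> float:
    """Sum over clusters of (pairwise squared distances within cluster) / cluster size."""
    ss = 0.0
    for c in np.unique(clusters):
        mask = clusters == c
        counts = np.bincount(allele_idx[mask], minlength=n_alleles).astype(float)
        n_c = counts.sum()
        ss += float(counts @ d2 @ counts) / (2.0 * n_c)
    return ss


def _amova_copies(
    d2: np.ndarray,
    allele_idx: np.ndarray,
    ind: np.ndarray,
    samp: np.ndarray,
    grp: np.ndarray,
):
    """Four-level nested AMOVA over allele copies; returns (df, SS, components).

    Components with zero degrees of freedom come back as 0 (collapsed strata),
    which lets the same machinery serve haploid/flat special cases.
    """
    n_alleles = d2.shape[0]
    n_tot = len(allele_idx)
    counts_all = np.bincount(allele_idx, minlength=n_alleles).astype(float)
    ss_total = float(counts_all @ d2 @ counts_all) / (2.0 * n_tot)
    w_ind = _within_ss(d2, allele_idx, ind, n_alleles)
    w_samp = _within_ss(d2, allele_idx, samp, n_alleles)
    w_grp = _within_ss(d2, allele_idx, grp, n_alleles)

    n_ind = len(np.unique(ind))
    n_samp = len(np.unique(samp))
    n_grp = len(np.unique(grp))
    df = np.array([n_grp - 1, n_samp - n_grp, n_ind - n_samp, n_tot - n_ind])
    ss = np.array([ss_total - w_grp, w_grp - w_samp, w_samp - w_ind, w_ind])

    def sizes(clusters: np.ndarray) -> np.ndarray:
        return np.array([np.sum(clusters == c) for c in np.unique(clusters)], float)

    def k_within(inner: np.ndarray, outer: np.ndarray) -> float:
        # sum over outer clusters of (sum of squared inner-cluster sizes)/outer size
        tot = 0.0
        for c in np.unique(outer):
            mask = outer == c
            inner_sizes = sizes(inner[mask])
            tot += float((inner_sizes**2).sum()) / mask.sum()
        return tot

    # expected-SS coefficients: rows = strata (AG, AS, AI, WI), cols = components
    # (sigma2_a groups, sigma2_b samples, sigma2_c individuals, sigma2_e within)
    k_ind_tot = float((sizes(ind) ** 2).sum()) / n_tot
    k_samp_tot = float((sizes(samp) ** 2).sum()) / n_tot
    k_grp_tot = float((sizes(grp) ** 2).sum()) / n_tot
    k_ind_in_samp = k_within(ind, samp)
    k_ind_in_grp = k_within(ind, grp)
    k_samp_in_grp = k_within(samp, grp)

    coef = np.zeros((4, 4))
    coef[0] = [n_tot - k_grp_tot, k_samp_in_grp - k_samp_tot, k_ind_in_grp - k_ind_tot, df[0]]
    coef[1] = [0.0, n_tot - k_samp_in_grp, k_ind_in_samp - k_ind_in_grp, df[1]]
    coef[2] = [0.0, 0.0, n_tot - k_ind_in_samp, df[2]]
    coef[3] = [0.0, 0.0, 0.0, df[3]]

    comp = np.zeros(4)  # a, b, c, e
    for stratum in (3, 2, 1, 0):
        col = 3 - stratum  # WI->e(3) ... AG->a(0); coef row `stratum` solves comp[stratum]
        if df[stratum] <= 0:
            comp[stratum] = 0.0
            continue
        known = sum(coef[stratum, k] * comp[k] for k in range(stratum + 1, 4))
        comp[stratum] = (ss[stratum] - known) / coef[stratum, stratum]
    return df, ss, comp


def _phi_stats(comp: np.ndarray) -> np.ndarray:
    a, b, c, e = comp
    total = a + b + c + e
    with np.errstate(invalid="ignore"):
        phi = np.array(
            [
                a / total if total != 0 else 0.0,
                b / (b + c + e) if (b + c + e) != 0 else 0.0,
                c / (c + e) if (c + e) != 0 else 0.0,
                (a + b + c) / total if total != 0 else 0.0,
            ]
        )
    return phi


# ---------------------------------------------------------------------------
# model / results


class HierarchicalDiploidAmova:
    """Four-level AMOVA model: groups / samples / individuals / allele copies.

    Built from a :class:`~symassem.io.GenotypeTable`; ``fit`` returns a
    :class:`HierAmovaResult` with components, Phi statistics and per-level
    permutation p-values (exchangeable units chosen per level: samples among
    groups, individuals among samples within groups, alleles among individuals
    within samples, alleles globally).
    """

    def __init__(self, genotypes: GenotypeTable) -> None:
        self.genotypes = genotypes
        for ind_id, a, b in genotypes.individuals:
            if not a or not b or str(a) == "nan" or str(b) == "nan":
                raise ValueError(f"individual {ind_id!r} has a missing allele")
        labels, d = _allele_distance_matrix(genotypes)
        self.allele_labels = labels
        self.d2 = d.astype(float) ** 2
        lab_idx = {l: i for i, l in enumerate(labels)}

        allele_idx, ind, samp, grp = [], [], [], []
        self.flags: list[str] = []
        samp_of_ind: dict[str, str] = {}
        for ind_id, a, b in genotypes.individuals:
            if not a or not b or str(a) == "nan" or str(b) == "nan":
                raise ValueError(f"individual {ind_id!r} has a missing allele")
            group, sample = genotypes.groupings[ind_id]
            samp_key = f"{group}\x1f{sample}"
            samp_of_ind[ind_id] = samp_key
            for allele in (a, b):
                allele_idx.append(lab_idx[allele])
                ind.append(ind_id)
                samp.append(samp_key)
                grp.append(group)
        self.allele_idx = np.asarray(allele_idx)
        self.ind, self.ind_codes = np.unique(np.asarray(ind), return_inverse=True)
        self.samp, self.samp_codes = np.unique(np.asarray(samp), return_inverse=True)
        self.grp, self.grp_codes = np.unique(np.asarray(grp), return_inverse=True)
        if len(self.grp) < 2:
            raise ValueError("need at least 2 groups for hierarchical AMOVA")
        for s in self.samp:
            n_in_sample = len({i for i, k in samp_of_ind.items() if k == s})
            if n_in_sample == 1:
                self.flags.append(f"sample {s.split(chr(31))[-1]!r} has a single individual")

    def _stat(self, ind, samp, grp) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        df, ss, comp = _amova_copies(self.d2, self.allele_idx, ind, samp, grp)
        return df, ss, comp, _phi_stats(comp)

    def fit(self, n_perm: int = 999, seed: int | None = None) -> "HierAmovaResult":
        df, ss, comp, phi = self._stat(self.ind_codes, self.samp_codes, self.grp_codes)
        degenerate = bool(np.all(np.abs(ss) < 1e-12))
        if degenerate:
            phi = np.zeros(4)
        p = np.full(4, np.nan)
        if n_perm and not degenerate:
            rng = np.random.default_rng(seed)
            exceed = np.zeros(4)
            for _ in range(int(n_perm)):
                perm_phi = self._permuted_phis(rng)
                exceed += perm_phi >= phi - 1e-12
            p = (1 + exceed) / (1 + int(n_perm))
        total = comp.sum()
        pct = 100 * comp / total if total != 0 else np.zeros(4)
        rows = []
        for i, level in enumerate(_LEVELS):
            rows.append(
                {
                    "level": level,
                    "df": int(df[i]),
                    "SS": float(ss[i]),
                    "variance_component": float(comp[i]),
                    "pct_variation": float(pct[i]),
                    "phi_label": _PHI_LABELS[i],
                    "phi": float(phi[i]),
                    "p_perm": float(p[i]),
                }
            )
        return HierAmovaResult(
            table=pd.DataFrame(rows),
            degenerate=degenerate,
            flags=list(self.flags),
            n_permutations=int(n_perm),
            seed=seed,
        )

    def _permuted_phis(self, rng: np.random.Generator) -> np.ndarray:
        """One draw of the four level statistics under their exchangeable units."""
        out = np.empty(4)
        # among groups: permute samples among groups (per-group sample counts fixed)
        samp_grp = np.empty(len(self.samp), dtype=int)
        for s in range(len(self.samp)):
            samp_grp[s] = self.grp_codes[self.samp_codes == s][0]
        perm = rng.permutation(samp_grp)
        grp_perm = perm[self.samp_codes]
        out[0] = self._stat(self.ind_codes, self.samp_codes, grp_perm)[3][0]
        # among samples within groups: permute individuals among samples within group
        samp_perm = self.samp_codes.copy()
        ind_samp = np.empty(len(self.ind), dtype=int)
        ind_grp = np.empty(len(self.ind), dtype=int)
        for i in range(len(self.ind)):
            ind_samp[i] = self.samp_codes[self.ind_codes == i][0]
            ind_grp[i] = self.grp_codes[self.ind_codes == i][0]
        new_ind_samp = ind_samp.copy()
        for g in range(len(self.grp)):
            members = np.where(ind_grp == g)[0]
            new_ind_samp[members] = rng.permutation(ind_samp[members])
        samp_perm = new_ind_samp[self.ind_codes]
        out[1] = self._stat(self.ind_codes, samp_perm, self.grp_codes)[3][1]
        # among individuals within samples: permute allele copies among
        # individuals within each sample
        ind_perm = self.ind_codes.copy()
        for s in range(len(self.samp)):
            members = np.where(self.samp_codes == s)[0]
            ind_perm[members] = self.ind_codes[rng.permutation(members)]
        out[2] = self._stat(ind_perm, self.samp_codes, self.grp_codes)[3][2]
        # within individuals: permute allele copies globally
        glob = rng.permutation(len(self.allele_idx))
        out[3] = self._stat(self.ind_codes[glob], self.samp_codes[glob], self.grp_codes[glob])[3][3]
        return out


@dataclass
class HierAmovaResult:
    """Four-stratum AMOVA table with components, Phi statistics and p-values."""

    table: pd.DataFrame
    degenerate: bool
    flags: list[str] = field(default_factory=list)
    n_permutations: int = 0
    seed: int | None = None

    def summary(self) -> pd.DataFrame:
        return self.table.copy()

    def row(self, level: str) -> pd.Series:
        hit = self.table[self.table["level"] == level]
        if hit.empty:
            raise KeyError(f"no level {level!r}")
        return hit.iloc[0]

    @property
    def pct_sum(self) -> float:
        return float(self.table["pct_variation"].sum())


def hier_amova(
    genotypes: GenotypeTable,
    n_perm: int = 999,
    seed: int | None = None,
) -> HierAmovaResult:
    """Functional wrapper over :class:`HierarchicalDiploidAmova`."""
    return HierarchicalDiploidAmova(genotypes).fit(n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# exact test of non-differentiation


@dataclass
class ExactTestResult:
    p_value: float
    method: str  # "enumeration" or "markov_chain"
    chain_steps: int
    seed: int | None
    table_dimensions: tuple[int, int]

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p-value out of (0, 1]: {self.p_value}")


def _log_table_prob(table: np.ndarray, log_margin_const: float) -> float:
    return log_margin_const - sum(math.lgamma(v + 1) for v in table.flat)


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)
    table = np.zeros((r, c), dtype=int)

    def fill(i: int, remaining_cols: np.ndarray):
        if i == r - 1:
            if np.all(remaining_cols >= 0):
                table[i] = remaining_cols
                yield table
            return
        target = row_sums[i]

        def fill_row(j: int, left: int):
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    table[i, j] = left
                    yield True
                return
            hi = min(left, remaining_cols[j])
            for v in range(hi + 1):
                table[i, j] = v
                yield from fill_row(j + 1, left - v)

        for _ in fill_row(0, target):
            new_remaining = remaining_cols - table[i]
            yield from fill(i + 1, new_remaining)

    yield from fill(0, np.asarray(col_sums, dtype=int).copy())


def exact_test(
    allele_by_population: np.ndarray | pd.DataFrame,
    chain_steps: int = 10000,
    seed: int | None = None,
    burn_in: int = 1000,
) -> ExactTestResult:
    """Exact (or Markov-chain) test of homogeneity of an allele x population table.

    The p-value is the null probability, conditional on the margins, of tables
    no more probable than the observed one. Tables with total count at or below
    12 are enumerated completely; larger tables use the 2x2 switch chain with
    Metropolis acceptance, seeded for reproducibility.
    """
    table = (
        allele_by_population.to_numpy()
        if isinstance(allele_by_population, pd.DataFrame)
        else np.asarray(allele_by_population)
    )
    table = table.astype(int)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need a 2-dimensional table with at least 2 rows and 2 columns")
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    if np.any(row_sums < 1) or np.any(col_sums < 1):
        raise ValueError("every row and column margin must be >= 1")
    n = int(table.sum())
    log_margin_const = (
        sum(math.lgamma(v + 1) for v in row_sums)
        + sum(math.lgamma(v + 1) for v in col_sums)
        - math.lgamma(n + 1)
    )
    log_p_obs = _log_table_prob(table, log_margin_const)
    eps = 1e-9

    if n <= ENUMERATION_CUTOFF:
        p = 0.0
        for t in _enumerate_tables(row_sums, col_sums):
            lp = _log_table_prob(t, log_margin_const)
            if lp <= log_p_obs + eps:
                p += math.exp(lp)
        return ExactTestResult(
            p_value=min(p, 1.0),
            method="enumeration",
            chain_steps=0,
            seed=seed,
            table_dimensions=table.shape,
        )

    rng = np.random.default_rng(seed)
    cur = table.copy()
    log_cur = log_p_obs
    r, c = table.shape
    hits = 0
    for step in range(burn_in + int(chain_steps)):
        i, k = rng.choice(r, size=2, replace=False)
        j, l = rng.choice(c, size=2, replace=False)
        # switch: cur[i,j]--, cur[i,l]++, cur[k,j]++, cur[k,l]--
        if cur[i, j] > 0 and cur[k, l] > 0:
            ratio = (cur[i, j] * cur[k, l]) / ((cur[i, l] + 1) * (cur[k, j] + 1))
            if ratio >= 1.0 or rng.random() < ratio:
                cur[i, j] -= 1
                cur[k, l] -= 1
                cur[i, l] += 1
                cur[k, j] += 1
                log_cur = _log_table_prob(cur, log_margin_const)
        if step >= burn_in and log_cur <= log_p_obs + eps:
            hits += 1
    return ExactTestResult(
        p_value=max(hits / int(chain_steps), 1.0 / int(chain_steps)),
        method="markov_chain",
        chain_steps=int(chain_steps),
        seed=seed,
        table_dimensions=table.shape,
    )
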