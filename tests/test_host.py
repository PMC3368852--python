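"""Hierarchical diploid AMOVA against a brute-force oracle; exact tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from symassem.host import (
    HierarchicalDiploidAmova,
    _amova_copies,
    exact_test,
    hier_amova,
)
from symassem.io import GenotypeTable
from symassem.pairwise import TwoGroupAmova
from symassem.distance import DistanceMatrix


# ---------------------------------------------------------------------------
# brute-force oracle: explicit loops over allele copies, independent EMS solve


def oracle_hier_amova(d: np.ndarray, alleles, ind, samp, grp):
    alleles = np.asarray(alleles)
    ind = np.asarray(ind)
    samp = np.asarray(samp)
    grp = np.asarray(grp)
    d2 = d.astype(float) ** 2
    n = len(alleles)

    def w(partition):
        total = 0.0
        for c in set(partition):
            idx = [i for i in range(n) if partition[i] == c]
            acc = 0.0
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    acc += d2[alleles[idx[a]], alleles[idx[b]]]
            total += acc / len(idx)
        return total

    ss_total = 0.0
    for a in range(n):
        for b in range(a + 1, n):
            ss_total += d2[alleles[a], alleles[b]]
    ss_total /= n

    w_ind, w_samp, w_grp = w(ind), w(samp), w(grp)
    ss = np.array([ss_total - w_grp, w_grp - w_samp, w_samp - w_ind, w_ind])
    n_i, n_s, n_g = len(set(ind)), len(set(samp)), len(set(grp))
    df = np.array([n_g - 1, n_s - n_g, n_i - n_s, n - n_i])

    def sizes(p):
        return {c: np.sum(p == c) for c in set(p)}

    def k_tot(p):
        return sum(v**2 for v in sizes(p).values()) / n

    def k_in(inner, outer):
        tot = 0.0
        for c in set(outer):
            mask = outer == c
            tot += sum(v**2 for v in sizes(inner[mask]).values()) / mask.sum()
        return tot

    coef = np.array(
        [
            [n - k_tot(grp), k_in(samp, grp) - k_tot(samp), k_in(ind, grp) - k_tot(ind), df[0]],
            [0, n - k_in(samp, grp), k_in(ind, samp) - k_in(ind, grp), df[1]],
            [0, 0, n - k_in(ind, samp), df[2]],
            [0, 0, 0, df[3]],
        ]
    )
    keep = df > 0
    comp = np.zeros(4)
    comp[keep] = np.linalg.solve(coef[np.ix_(keep, keep)], ss[keep])
    return df, ss, comp


def _random_toy(rng, n_ind=12):
    n_alleles = 5
    d = np.zeros((n_alleles, n_alleles))
    iu = np.triu_indices(n_alleles, 1)
    d[iu] = rng.integers(1, 7, size=len(iu[0]))
    d = d + d.T
    alleles = rng.integers(0, n_alleles, size=2 * n_ind)
    ind = np.repeat(np.arange(n_ind), 2)
    samp = np.repeat(rng.integers(0, 4, size=n_ind), 2)
    # samples nested in groups: group = sample // 2
    grp = samp // 2
    samp = samp + 10 * grp  # make sample codes unique within group
    return d, alleles, ind, samp, grp


def test_components_match_bruteforce_on_random_toys(rng):
    for _ in range(25):
        d, alleles, ind, samp, grp = _random_toy(rng)
        if len(set(grp)) < 2:
            continue
        df, ss, comp = _amova_copies(d.astype(float) ** 2, alleles, ind, samp, grp)
        df_o, ss_o, comp_o = oracle_hier_amova(d, alleles, ind, samp, grp)
        assert np.array_equal(df, df_o)
        assert np.allclose(ss, ss_o, atol=1e-10)
        assert np.allclose(comp, comp_o, atol=1e-10)


def _geno(individuals, groupings, seqs):
    return GenotypeTable(individuals=individuals, groupings=groupings, allele_sequences=seqs)


def test_all_homozygous_single_allele_is_degenerate():
    seqs = {"a1": "AAAA"}
    inds = [(f"i{k}", "a1", "a1") for k in range(6)]
    groupings = {f"i{k}": ("g1" if k < 3 else "g2", f"s{k % 2}") for k in range(6)}
    res = hier_amova(_geno(inds, groupings, seqs), n_perm=49, seed=0)
    assert res.degenerate
    assert np.allclose(res.table["phi"], 0)
    assert np.allclose(res.table["SS"], 0)


def test_alternate_fixation_puts_all_variance_among_groups():
    seqs = {"a1": "AAAA", "a2": "TTTT"}
    inds = [(f"x{k}", "a1", "a1") for k in range(4)] + [
        (f"y{k}", "a2", "a2") for k in range(4)
    ]
    groupings = {f"x{k}": ("g1", f"s{k % 2}") for k in range(4)}
    groupings |= {f"y{k}": ("g2", f"t{k % 2}") for k in range(4)}
    res = hier_amova(_geno(inds, groupings, seqs), n_perm=0, seed=0)
    tab = res.table.set_index("level")
    assert tab.loc["among_groups", "pct_variation"] == pytest.approx(100.0)
    assert res.pct_sum == pytest.approx(100.0, abs=1e-6)
    assert tab.loc["among_groups", "phi"] == pytest.approx(1.0)


def test_pct_variation_sums_to_100_and_perm_reproducible(rng):
    seqs = {f"a{k}": "".join(rng.choice(list("ACGT"), 8)) for k in range(1, 5)}
    pool = list(seqs)
    inds, groupings = [], {}
    for k in range(12):
        a, b = rng.choice(pool, 2)
        inds.append((f"i{k}", a, b))
        groupings[f"i{k}"] = ("g1" if k < 6 else "g2", f"s{k // 3}")
    g = _geno(inds, groupings, seqs)
    r1 = hier_amova(g, n_perm=99, seed=11)
    r2 = hier_amova(g, n_perm=99, seed=11)
    assert r1.pct_sum == pytest.approx(100.0, abs=1e-6)
    assert np.array_equal(
        r1.table["p_perm"].to_numpy(), r2.table["p_perm"].to_numpy()
    )


def test_missing_allele_and_single_group_rejected():
    seqs = {"a1": "AAAA"}
    with pytest.raises(ValueError, match="missing allele"):
        HierarchicalDiploidAmova(
            _geno([("i1", "a1", "")], {"i1": ("g1", "s1")}, seqs)
        )
    with pytest.raises(ValueError, match="2 groups"):
        HierarchicalDiploidAmova(
            _geno([("i1", "a1", "a1"), ("i2", "a1", "a1")],
                  {"i1": ("g1", "s1"), "i2": ("g1", "s1")}, seqs)
        )


def test_single_individual_sample_flagged():
    seqs = {"a1": "AAAA", "a2": "AAAT"}
    inds = [("i1", "a1", "a2"), ("i2", "a1", "a1"), ("i3", "a2", "a2")]
    groupings = {"i1": ("g1", "s1"), "i2": ("g1", "s1"), "i3": ("g2", "s2")}
    model = HierarchicalDiploidAmova(_geno(inds, groupings, seqs))
    assert any("single individual" in f for f in model.flags)


def test_haploid_flat_hierarchy_collapses_to_two_group_amova(rng):
    """One copy per individual, one sample per group: Phi_AM equals the
    two-group AMOVA Phi on the same distances."""
    n_var = 3
    base = np.zeros((n_var, n_var))
    iu = np.triu_indices(n_var, 1)
    base[iu] = rng.integers(1, 9, size=len(iu[0]))
    base = base + base.T
    vidx = rng.integers(0, n_var, size=14)
    grp = np.array([0] * 6 + [1] * 8)
    df, ss, comp = _amova_copies(base.astype(float) ** 2, vidx, np.arange(14), grp, grp)
    total = comp.sum()
    phi_am = comp[0] / total
    d = base[np.ix_(vidx, vidx)]
    res = TwoGroupAmova(
        DistanceMatrix(labels=[str(i) for i in range(14)], values=d),
        ["A"] * 6 + ["B"] * 8,
    ).fit()
    assert phi_am == pytest.approx(res.phi, abs=1e-10)


# ---------------------------------------------------------------------------
# exact test


def test_identical_columns_give_p_one():
    res = exact_test(np.array([[3, 3], [3, 3]]))
    assert res.method == "enumeration"
    assert res.p_value == pytest.approx(1.0)
    # larger identical-column table goes through the chain; p stays near 1
    big = exact_test(np.array([[5, 5], [5, 5]]), chain_steps=20_000, seed=1)
    assert big.method == "markov_chain"
    assert big.p_value > 0.9


def test_diagonal_table_matches_hypergeometric_tail():
    # [[5,0],[0,5]]: only the two extreme tables are as improbable;
    # p = 2 / C(10,5) = 2/252
    res = exact_test(np.array([[5, 0], [0, 5]]))
    assert res.method == "enumeration"
    assert res.p_value == pytest.approx(2 / 252, abs=1e-12)


def test_zero_margin_and_degenerate_shape_rejected():
    with pytest.raises(ValueError, match="margin"):
        exact_test(np.array([[0, 0], [3, 2]]))
    with pytest.raises(ValueError, match="2 rows"):
        exact_test(np.array([[1, 2, 3]]))


def test_chain_agrees_with_enumeration_on_small_tables(rng):
    from symassem import host

    tables = [
        np.array([[3, 1], [1, 4]]),
        np.array([[2, 2, 1], [1, 3, 2]]),
        np.array([[4, 1], [2, 3]]),
    ]
    for t in tables:
        exact = exact_test(t).p_value
        # force the chain path by dropping the enumeration cutoff
        old = host.ENUMERATION_CUTOFF
        host.ENUMERATION_CUTOFF = 0
        try:
            chain = exact_test(t, chain_steps=100_000, seed=17).p_value
        finally:
            host.ENUMERATION_CUTOFF = old
        assert chain == pytest.approx(exact, abs=0.02)


def test_chain_reproducible_given_seed():
    t = np.array([[8, 3, 2], [2, 6, 5], [4, 1, 7]])
    r1 = exact_test(t, chain_steps=20_000, seed=3)
    r2 = exact_test(t, chain_steps=20_000, seed=3)
    assert r1.method == "markov_chain"
    assert r1.p_value == r2.p_value
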