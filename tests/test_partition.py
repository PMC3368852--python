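"""Gower centring, sequential SS partition, built-in designs and calibration."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from symassem.distance import DistanceMatrix, clone_distance_matrix, sqrt_transform, variant_distance_matrix
from symassem.pairwise import TwoGroupAmova
from symassem.partition import (
    DesignSpec,
    DistancePartition,
    Term,
    builtin_designs,
    fit_partition,
    gower_center,
)
from symassem.screening import apply_screen, screen_variants
from symassem.simulate import SimConfig, simulate_bundle


def _random_distance(rng, n):
    vals = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    vals[iu] = rng.uniform(0.5, 5, size=len(iu[0]))
    vals = vals + vals.T
    return DistanceMatrix(labels=[str(i) for i in range(n)], values=vals)


def test_gower_center_zero_and_two_point():
    z = gower_center(np.zeros((4, 4)))
    assert np.allclose(z, 0)
    g = gower_center(np.array([[0.0, 2.0], [2.0, 0.0]]))
    assert np.trace(g) == pytest.approx(2.0)


def test_gower_trace_equals_mean_squared_distances(rng):
    for n in (3, 5, 9):
        m = _random_distance(rng, n)
        g = gower_center(m)
        acc = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                acc += m.values[i, j] ** 2
        assert np.trace(g) == pytest.approx(acc / n, abs=1e-10)


def test_one_way_partition_equals_two_group_amova(rng):
    n = 14
    m = _random_distance(rng, n)
    groups = np.array(["A"] * 6 + ["B"] * 8)
    meta = pd.DataFrame({"grp": groups})
    table = fit_partition(m, meta, DesignSpec(terms=[Term("grp", ("grp",))]), n_perm=0)
    amova = TwoGroupAmova(m, groups).fit()
    # identical SS decomposition implies identical F ratio
    row = table.row("grp")
    res = table.row("Residual")
    d2 = m.values**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = sum(
        d2[np.ix_(groups == g, groups == g)].sum() / (2 * (groups == g).sum())
        for g in "AB"
    )
    assert row["SS"] == pytest.approx(ss_total - ss_within, abs=1e-8)
    assert res["SS"] == pytest.approx(ss_within, abs=1e-8)
    f_amova = (ss_total - ss_within) / 1 / (ss_within / (n - 2))
    assert row["pseudo_F"] == pytest.approx(f_amova, abs=1e-8)
    # and the among component sign agrees with the AMOVA fit
    assert (row["SS"] > 0) == (amova.sigma2_among + amova.sigma2_within > 0)


def test_ss_additivity_on_random_fits(rng):
    n = 24
    m = _random_distance(rng, n)
    meta = pd.DataFrame(
        {
            "site": rng.choice(["BTN", "GL"], n),
            "life_stage": rng.choice(["adult", "egg"], n),
        }
    )
    design = DesignSpec(
        terms=[Term("Si", ("site",)), Term("Li", ("life_stage",)), Term("SixLi", ("site", "life_stage"))]
    )
    table = fit_partition(m, meta, design, n_perm=0)
    assert table.ss_additivity_gap < 1e-8
    dfs = table.table["df"].sum()
    assert dfs == n - 1


def test_builtin_designs_have_published_term_lists():
    four, three = builtin_designs()
    assert [t.label for t in four.terms] == [
        "Si", "Ye", "Li", "Co(Si)", "SixYe", "SixLi", "YexLi",
        "YexCo(Si)", "LixCo(Si)", "SixYexLi", "YexLixCo(Si)",
    ]
    assert [t.label for t in three.terms] == ["Mo", "Li", "Co(Mo)", "MoxLi", "LixCo(Mo)"]
    assert four.n_permutations == 10000 and three.n_permutations == 10000


def test_builtin_designs_fit_full_synthetic_layout():
    config = SimConfig(seed=5, n_colonies=3, sites=("BTN", "GL"))
    bundle, _ = simulate_bundle(config)
    report = screen_variants(bundle.libraries, bundle.variants)
    screened = [apply_screen(l, report) for l in bundle.libraries]
    screened = [l for l in screened if not l.is_empty()]
    vmat = variant_distance_matrix(
        [v for v in bundle.variants.values() if v.label in report.retained]
    )
    cmat, meta = clone_distance_matrix(screened, vmat)
    four, _ = builtin_designs()
    table = fit_partition(sqrt_transform(cmat), meta, four, n_perm=0)
    assert table.ss_additivity_gap < 1e-8
    assert len(table.table) == 12  # 11 terms + residual

    # three-factor design on a mixed-morphology site
    pr = SimConfig(
        seed=6, n_colonies=4, sites=("PR",), years=(2008,),
        site_morphology={"PR": "branching"},
    )
    bundle2, _ = simulate_bundle(pr)
    for i, lib in enumerate(bundle2.libraries):
        if int(lib.colony_id.split("-")[-1]) % 2 == 0:
            lib.morphology = "plating"
    report2 = screen_variants(bundle2.libraries, bundle2.variants)
    screened2 = [apply_screen(l, report2) for l in bundle2.libraries]
    screened2 = [l for l in screened2 if not l.is_empty()]
    vmat2 = variant_distance_matrix(
        [v for v in bundle2.variants.values() if v.label in report2.retained]
    )
    cmat2, meta2 = clone_distance_matrix(screened2, vmat2)
    _, three = builtin_designs()
    table2 = fit_partition(sqrt_transform(cmat2), meta2, three, n_perm=0)
    assert table2.ss_additivity_gap < 1e-8
    assert len(table2.table) == 6


def test_rank_deficient_term_is_named(rng):
    n = 12
    m = _random_distance(rng, n)
    site = np.array(["BTN"] * 6 + ["GL"] * 6)
    meta = pd.DataFrame({"site": site, "alias": site})  # perfectly confounded
    design = DesignSpec(terms=[Term("Si", ("site",)), Term("Alias", ("alias",))])
    with pytest.raises(ValueError, match="Alias"):
        fit_partition(m, meta, design, n_perm=0)


def test_site_effect_detected_and_null_stage_not():
    config = SimConfig(seed=42, n_colonies=4, years=(2007,), egg_model="faithful")
    bundle, _ = simulate_bundle(config)
    report = screen_variants(bundle.libraries, bundle.variants)
    screened = [l for l in (apply_screen(x, report) for x in bundle.libraries) if not l.is_empty()]
    vmat = variant_distance_matrix(
        [v for v in bundle.variants.values() if v.label in report.retained]
    )
    cmat, meta = clone_distance_matrix(screened, vmat)
    design = DesignSpec(terms=[Term("Si", ("site",)), Term("Li", ("life_stage",))])
    table = fit_partition(sqrt_transform(cmat), meta, design, n_perm=199, seed=0)
    assert table.row("Si")["p_perm"] < 0.05
    assert table.row("Li")["p_perm"] > 0.05


def test_permutation_p_reproducible(rng):
    n = 16
    m = _random_distance(rng, n)
    meta = pd.DataFrame({"site": rng.choice(["a", "b"], n)})
    design = DesignSpec(terms=[Term("Si", ("site",))])
    t1 = fit_partition(m, meta, design, n_perm=99, seed=3)
    t2 = fit_partition(m, meta, design, n_perm=99, seed=3)
    assert t1.row("Si")["p_perm"] == t2.row("Si")["p_perm"]


def test_library_unit_permutation_runs(rng):
    n_lib, per = 6, 4
    n = n_lib * per
    m = _random_distance(rng, n)
    meta = pd.DataFrame(
        {
            "sample_id": np.repeat([f"s{i}" for i in range(n_lib)], per),
            "site": np.repeat(["a", "b"], n // 2),
        }
    )
    design = DesignSpec(terms=[Term("Si", ("site",), units="libraries")])
    table = fit_partition(m, meta, design, n_perm=49, seed=1)
    assert 0 < table.row("Si")["p_perm"] <= 1
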