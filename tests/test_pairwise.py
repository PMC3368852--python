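"""PSI and two-group AMOVA: printed-table examples, brute-force oracle, permutations."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symassem.distance import DistanceMatrix, clone_distance_matrix, variant_distance_matrix
from symassem.pairwise import TwoGroupAmova, permutation_test, psi
from symassem.screening import apply_screen

from conftest import make_library, make_variant


def brute_force_amova(d: np.ndarray, groups: np.ndarray):
    """Explicit double-loop evaluation of the two-group AMOVA SS formulas."""
    d2 = d.astype(float) ** 2
    n = len(groups)
    levels = sorted(set(groups))
    k = len(levels)
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d2[i, j]
    ss_total /= n
    ss_within = 0.0
    for g in levels:
        idx = [i for i in range(n) if groups[i] == g]
        acc = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                acc += d2[idx[a], idx[b]]
        ss_within += acc / len(idx)
    ss_among = ss_total - ss_within
    sizes = [sum(groups == g) for g in levels]
    sigma_w = ss_within / (n - k)
    n0 = (n - sum(s**2 for s in sizes) / n) / (k - 1)
    sigma_a = (ss_among / (k - 1) - sigma_w) / n0
    denom = sigma_a + sigma_w
    phi = sigma_a / denom if denom > 0 else 0.0
    return sigma_a, sigma_w, phi


def _fit(d: np.ndarray, groups):
    labels = [str(i) for i in range(d.shape[0])]
    return TwoGroupAmova(DistanceMatrix(labels=labels, values=d), np.asarray(groups)).fit()


# ---------------------------------------------------------------------------
# PSI


def test_psi_matches_printed_rows(published_bundle, published_screen):
    libs = {l.sample_id: l for l in published_bundle.libraries}

    def screened_psi(colony_key):
        a = apply_screen(libs[f"{colony_key}-adult"], published_screen)
        e = apply_screen(libs[f"{colony_key}-egg"], published_screen)
        return psi(a, e).rounded

    assert screened_psi("BTN-1-2007") == 0.50  # only via C32.2 exclusion
    assert screened_psi("BTN-11-2007") == 0.72  # all clade D
    assert screened_psi("GL-35-2007") == 0.86
    assert screened_psi("BTN-10-2007") == 0.00  # disjoint after screening


def test_psi_identity_and_disjoint_limits():
    a = make_library("a", {"C31": 4, "C21": 4})
    b = make_library("b", {"C31": 1, "C21": 1})
    assert psi(a, b).psi == pytest.approx(1.0)
    c = make_library("c", {"D1": 5})
    assert psi(a, c).psi == 0.0


def test_psi_rejects_empty_library():
    a = make_library("a", {"C31": 4})
    with pytest.raises(ValueError, match="empty"):
        psi(a, make_library("b", {}))


@settings(deadline=None, max_examples=50)
@given(
    counts_a=st.dictionaries(
        st.sampled_from(["v1", "v2", "v3", "v4"]),
        st.integers(min_value=1, max_value=9),
        min_size=1,
    ),
    counts_b=st.dictionaries(
        st.sampled_from(["v2", "v3", "v4", "v5"]),
        st.integers(min_value=1, max_value=9),
        min_size=1,
    ),
    scale=st.integers(min_value=2, max_value=6),
)
def test_psi_symmetry_and_scale_invariance(counts_a, counts_b, scale):
    a = make_library("a", counts_a)
    b = make_library("b", counts_b)
    assert psi(a, b).psi == pytest.approx(psi(b, a).psi)
    scaled = make_library("a2", {k: v * scale for k, v in counts_a.items()})
    assert psi(scaled, b).psi == pytest.approx(psi(a, b).psi)


# ---------------------------------------------------------------------------
# two-group AMOVA


def test_alternate_fixation_gives_phi_one():
    d = np.zeros((8, 8))
    d[:4, 4:] = 5
    d[4:, :4] = 5
    res = _fit(d, ["A"] * 4 + ["B"] * 4)
    assert res.phi == pytest.approx(1.0)


def test_identical_multisets_give_near_zero_phi():
    # both groups {h1 x2, h2 x2}, d(h1,h2)=2 -> oracle pins the value
    variant_idx = np.array([0, 0, 1, 1, 0, 0, 1, 1])
    base = np.array([[0, 2], [2, 0]], float)
    d = base[np.ix_(variant_idx, variant_idx)]
    groups = np.array(["A"] * 4 + ["B"] * 4)
    res = _fit(d, groups)
    _, _, phi_oracle = brute_force_amova(d, groups)
    assert res.phi == pytest.approx(phi_oracle, abs=1e-12)
    # SS_among is exactly 0 here, so the unbiased component estimate is
    # mildly negative (sigma_a = -sigma_w/n0), never truncated
    assert res.phi == pytest.approx(-1 / 3)
    assert res.sigma2_among < 0


def test_unbalanced_example_matches_oracle():
    # A = {h1 x3, h2 x1}, B = {h3 x4}; d(h1,h2)=1, d(.,h3)=10
    vidx = [0, 0, 0, 1, 2, 2, 2, 2]
    base = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0]], float)
    d = base[np.ix_(vidx, vidx)]
    groups = np.array(["A"] * 4 + ["B"] * 4)
    res = _fit(d, groups)
    sigma_a, sigma_w, phi = brute_force_amova(d, groups)
    assert res.sigma2_among == pytest.approx(sigma_a, abs=1e-12)
    assert res.sigma2_within == pytest.approx(sigma_w, abs=1e-12)
    assert res.phi == pytest.approx(phi, abs=1e-12)


def test_degenerate_all_identical_returns_zero():
    d = np.zeros((6, 6))
    res = _fit(d, ["A"] * 3 + ["B"] * 3)
    assert res.phi == 0.0


def test_single_clone_group_allowed_but_zero_size_rejected():
    d = np.zeros((3, 3))
    d[0, 1:] = d[1:, 0] = 4
    res = _fit(d, ["A", "B", "B"])
    assert np.isfinite(res.phi)
    with pytest.raises(ValueError):
        _fit(d, ["A", "A", "A"])


def test_permutation_p_reproducible_and_separation_significant():
    v = [make_variant("C1", "A" * 8), make_variant("D1", "T" * 8)]
    vmat = variant_distance_matrix(v)
    a = make_library("a", {"C1": 8}, life_stage="adult")
    b = make_library("b", {"D1": 8}, life_stage="egg", colony_id="a")
    cmat, meta = clone_distance_matrix([a, b], vmat)
    r1 = permutation_test(a, b, cmat, meta, n_perm=999, seed=5)
    r2 = permutation_test(a, b, cmat, meta, n_perm=999, seed=5)
    assert r1.p_value == r2.p_value
    assert r1.phi == pytest.approx(1.0)
    assert r1.p_value < 0.05


def test_permutation_p_near_one_for_identical_groups():
    v = [make_variant("C1", "AAAA"), make_variant("C2", "AAAT")]
    vmat = variant_distance_matrix(v)
    a = make_library("a", {"C1": 4, "C2": 4})
    b = make_library("b", {"C1": 4, "C2": 4}, colony_id="a", life_stage="egg")
    cmat, meta = clone_distance_matrix([a, b], vmat)
    res = permutation_test(a, b, cmat, meta, n_perm=499, seed=2)
    assert res.p_value > 0.5


def test_p_invariant_under_distance_preserving_relabeling(rng):
    """Swapping variant identities that carry identical distances leaves p unchanged."""
    base = np.array([[0, 3], [3, 0]], float)
    vidx = rng.integers(0, 2, size=12)
    d = base[np.ix_(vidx, vidx)]
    groups = np.array(["A"] * 6 + ["B"] * 6)
    labels = [str(i) for i in range(12)]
    m1 = TwoGroupAmova(DistanceMatrix(labels=labels, values=d), groups).fit(n_perm=299, seed=9)
    swapped = base[np.ix_(1 - vidx, 1 - vidx)]  # relabel h1<->h2: same matrix
    m2 = TwoGroupAmova(DistanceMatrix(labels=labels, values=swapped), groups).fit(n_perm=299, seed=9)
    assert m1.p_value == m2.p_value


@settings(deadline=None, max_examples=60)
@given(st.data())
def test_phi_matches_bruteforce_on_random_small_libraries(data):
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    n_var = rng.integers(2, 5)
    base = np.zeros((n_var, n_var))
    iu = np.triu_indices(n_var, 1)
    base[iu] = rng.integers(1, 12, size=len(iu[0]))
    base = base + base.T
    na, nb = rng.integers(2, 11, size=2)
    vidx = rng.integers(0, n_var, size=na + nb)
    d = base[np.ix_(vidx, vidx)]
    groups = np.array(["A"] * na + ["B"] * nb)
    res = _fit(d, groups)
    sigma_a, sigma_w, phi = brute_force_amova(d, groups)
    assert res.phi == pytest.approx(phi, abs=1e-10)
    assert res.sigma2_among == pytest.approx(sigma_a, abs=1e-10)
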