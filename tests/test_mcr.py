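import itertools

import numpy as np
import pytest
from sklearn.base import clone

from hsifuse.mcr import (
    MCRALS,
    ComponentDeathError,
    ConstraintSet,
    als_update_C,
    als_update_S,
    component_maps,
    estimate_rank,
    lof,
    normalize_components,
    r2,
    run_mcr_als,
    simplisma_init,
)
from hsifuse.phantom import balanced_truth_spectra, match_components


# ------------------------------------------------------------------ lof / r2
def test_lof_r2_perfect_fit(rng):
    M = rng.random((5, 4))
    assert lof(M, M) == 0.0
    assert r2(M, M) == 1.0


def test_lof_r2_zero_model(rng):
    M = rng.random((5, 4))
    assert lof(M, np.zeros_like(M)) == pytest.approx(100.0)
    assert r2(M, np.zeros_like(M)) == pytest.approx(0.0)


def test_lof_r2_hand_computed_example():
    M = np.array([[1.0, 2.0], [3.0, 4.0]])
    Mhat = np.array([[1.0, 2.0], [3.0, 0.0]])
    assert lof(M, Mhat) == pytest.approx(100 * np.sqrt(16 / 30), abs=1e-10)
    assert lof(M, Mhat) == pytest.approx(73.0297, abs=1e-3)
    assert r2(M, Mhat) == pytest.approx(1 - 16 / 30, abs=1e-12)


def test_r2_equals_one_minus_squared_lof(rng):
    """r2 == 1 - (LOF/100)^2 identically, for arbitrary model matrices."""
    for _ in range(20):
        M = rng.normal(size=(6, 5))
        Mhat = rng.normal(size=(6, 5))
        assert r2(M, Mhat) == pytest.approx(1 - (lof(M, Mhat) / 100) ** 2, abs=1e-12)


def test_lof_all_zero_data_raises():
    with pytest.raises(ValueError):
        lof(np.zeros((2, 2)), np.zeros((2, 2)))


# -------------------------------------------------------------- estimate_rank
def test_estimate_rank_exact_low_rank(rng):
    M = rng.random((30, 3)) @ rng.random((3, 20))
    tab = estimate_rank(M, 6)
    s = tab["singular_value"].to_numpy()
    assert s[3] < 1e-8 * s[0]


def test_estimate_rank_cumvar_monotone_to_100(rng):
    M = rng.random((10, 8))
    tab = estimate_rank(M)
    cv = tab["cumulative_variance_pct"].to_numpy()
    assert np.all(np.diff(cv) >= -1e-12)
    assert cv[-1] == pytest.approx(100.0)


def test_estimate_rank_elbow_at_true_component_count(rng):
    K = 5
    M = rng.random((200, K)) @ rng.random((K, 40)) + 1e-4 * rng.normal(size=(200, 40))
    s = estimate_rank(M, 10)["singular_value"].to_numpy()
    drops = s[:-1] / s[1:]
    assert np.argmax(drops) + 1 == K


def test_estimate_rank_bad_max_k(rng):
    with pytest.raises(ValueError):
        estimate_rank(rng.random((4, 4)), 0)


# ------------------------------------------------------------------ simplisma
def _pure_fixture():
    S = np.array(
        [[1.0, 0.0, 0.0, 0.2], [0.0, 1.0, 0.0, 0.2], [0.0, 0.0, 1.0, 0.2]]
    )
    C = np.array(
        [
            [0.5, 0.5, 0.0],
            [1.0, 0.0, 0.0],  # pure in 0
            [0.2, 0.3, 0.5],
            [0.0, 1.0, 0.0],  # pure in 1
            [0.3, 0.3, 0.4],
            [0.0, 0.0, 1.0],  # pure in 2
        ]
    )
    return C @ S, {1, 3, 5}


def test_simplisma_selects_pure_rows():
    M, pure_rows = _pure_fixture()
    St = simplisma_init(M, 3, noise_alpha=1.0)
    picked = {int(np.where((M == row).all(axis=1))[0][0]) for row in St}
    assert picked == pure_rows


def test_simplisma_k1_matches_direct_purity_evaluation(rng):
    M = rng.random((30, 12)) + 0.1
    alpha = 5.0
    St = simplisma_init(M, 1, noise_alpha=alpha)
    mu, sd = M.mean(axis=1), M.std(axis=1)
    purity = sd / (mu + alpha / 100 * mu.max())
    np.testing.assert_array_equal(St[0], M[np.argmax(purity)])


def test_simplisma_duplicated_purest_row():
    """A duplicated purest row is selected once (first occurrence) and the
    collinear duplicate is rejected by the determinant weight."""
    pure = np.array([1.0, 0.0, 0.0])
    other = np.array([0.1, 0.8, 0.1])
    M = np.vstack([pure, pure, other, [0.3, 0.3, 0.3]])
    St = simplisma_init(M, 2, noise_alpha=1.0)
    np.testing.assert_array_equal(St[0], pure)
    np.testing.assert_array_equal(St[1], other)  # duplicate skipped
    # deterministic across calls
    np.testing.assert_array_equal(St, simplisma_init(M, 2, noise_alpha=1.0))


def test_simplisma_too_many_components_raises(rng):
    with pytest.raises(ValueError):
        simplisma_init(rng.random((3, 4)), 5)


# ------------------------------------------------------------------ ALS steps
def test_als_update_c_exact_on_noiseless_data(rng):
    C0 = rng.random((20, 3))
    S0 = rng.random((3, 15))
    C = als_update_C(C0 @ S0, S0)
    np.testing.assert_allclose(C, C0, atol=1e-10)


def test_als_update_s_zero_mask_is_exact(rng):
    C = rng.random((20, 3))
    M = C @ rng.random((3, 30))
    zero = np.zeros((3, 30), dtype=bool)
    zero[2, 10:21] = True
    St = als_update_S(M, C, zero=zero)
    assert (St[2, 10:21] == 0.0).all()


def _active_set_oracle(A, b):
    """Exhaustive NNLS for tiny systems: try every active set."""
    n = A.shape[1]
    best, best_val = None, np.inf
    for active in itertools.product([0, 1], repeat=n):
        free = [i for i in range(n) if not active[i]]
        x = np.zeros(n)
        if free:
            sol, *_ = np.linalg.lstsq(A[:, free], b, rcond=None)
            x[free] = sol
        if (x < -1e-10).any():
            continue
        val = np.sum((A @ x - b) ** 2)
        if val < best_val - 1e-12:
            best, best_val = x, val
    return best


def test_nonneg_solution_matches_active_set_oracle(rng):
    for _ in range(25):
        A = rng.normal(size=(3, 3))
        b = rng.normal(size=3)
        x = als_update_C(b[None, :], A.T, nonneg=np.ones((1, 3), dtype=bool))[0]
        oracle = _active_set_oracle(A, b)
        np.testing.assert_allclose(
            np.sum((A @ x - b) ** 2), np.sum((A @ oracle - b) ** 2), atol=1e-8
        )
        assert (x >= 0).all()


def test_normalize_components_unit_norm_and_invariant_product(rng):
    C = rng.random((10, 3))
    St = rng.random((3, 8))
    Cn, Stn = normalize_components(C, St)
    np.testing.assert_allclose(np.linalg.norm(Stn, axis=1), 1.0, rtol=1e-12)
    np.testing.assert_allclose(Cn @ Stn, C @ St, rtol=1e-12)


def test_normalize_components_death_raises():
    C = np.ones((4, 2))
    St = np.vstack([np.ones(5), np.zeros(5)])
    with pytest.raises(ComponentDeathError, match="component 1"):
        normalize_components(C, St)


# ------------------------------------------------------------------ full runs
def test_noiseless_phantom_recovery(clean_multiset, clean_phantom, clean_unmix):
    """Noiseless congruent multiset: near-zero lack of fit and matched
    augmented spectra essentially identical to the ground truth."""
    res = clean_unmix
    assert res.lof_final < 0.1
    S_true = balanced_truth_spectra(clean_phantom["truth"], clean_multiset)
    perm, corr = match_components(res.St, S_true)
    assert (corr > 0.999).all()
    assert sorted(perm.tolist()) == [0, 1, 2, 3]


def test_zero_block_constraint_is_exact(clean_multiset):
    """A component declared undetectable in one platform has an exactly
    zero sub-signature in the result."""
    cs = (
        ConstraintSet(4)
        .set_nonneg("C")
        .set_nonneg("S")
        .set_zero("S", component=1, block="raman")
        .set_zero("S", component=0, block="fluorescence", ranges=[(420.0, 625.0)])
    )
    res = run_mcr_als(clean_multiset, 4, constraints=cs)
    cols = clean_multiset.col_slice("raman")
    assert (res.St[1, cols] == 0.0).all()
    fl = clean_multiset.col_slice("fluorescence")
    ax = clean_multiset.axes["fluorescence"]
    sel = (ax >= 420) & (ax <= 625)
    assert (res.St[0, fl][sel] == 0.0).all()


def test_unconstrained_lof_trace_is_nonincreasing(rng):
    C0 = rng.random((25, 3))
    S0 = rng.random((3, 18))
    M = C0 @ S0 + 0.05 * rng.normal(size=(25, 18))
    res = run_mcr_als(M, 3, max_iter=20)
    trace = np.asarray(res.lof_trace)
    assert np.all(np.diff(trace) <= 1e-10)


def test_constraints_for_different_k_raise(clean_multiset):
    with pytest.raises(ValueError):
        run_mcr_als(clean_multiset, 4, constraints=ConstraintSet(3))


def test_component_fully_zeroed_everywhere_rejected(clean_multiset):
    cs = ConstraintSet(4).set_zero("S", component=2)  # all blocks
    with pytest.raises(ValueError, match="every spectral block"):
        run_mcr_als(clean_multiset, 4, constraints=cs)


def test_component_death_from_zero_init(clean_multiset):
    St0 = np.zeros((4, clean_multiset.M.shape[1]))
    St0[:3] = clean_multiset.M[[10, 50, 90]]  # fourth spectrum left all-zero
    with pytest.raises(ComponentDeathError):
        run_mcr_als(clean_multiset, 4, init=St0)


# -------------------------------------------------------------- component maps
def test_component_maps_shapes_and_fill(clean_unmix, clean_multiset):
    maps = component_maps(clean_unmix, clean_multiset, "s1")
    ny, nx = clean_multiset.shapes["s1"]
    assert maps.shape == (4, ny, nx)
    assert not np.isnan(maps).any()  # full mask in the clean phantom


def test_component_maps_unknown_sample_raises(clean_unmix, clean_multiset):
    with pytest.raises(KeyError):
        component_maps(clean_unmix, clean_multiset, "nope")


def test_component_maps_match_ground_truth(
    clean_unmix, clean_multiset, clean_phantom
):
    truth = clean_phantom["truth"]
    S_true = balanced_truth_spectra(truth, clean_multiset)
    perm, _ = match_components(clean_unmix.St, S_true)
    maps = component_maps(clean_unmix, clean_multiset, "s1", fill=0.0)
    gt = truth["maps_mod"][("s1", "ftir")]
    for i, k in enumerate(perm):
        c = np.corrcoef(maps[i].ravel(), gt[k].ravel())[0, 1]
        assert abs(c) > 0.999


# ----------------------------------------------------- parameter recovery
def test_parameter_recovery_over_seeds_at_snr50():
    """Median matched-spectrum correlation >= 0.99 and matched-map
    correlation >= 0.98 across 20 independent noisy phantoms."""
    from hsifuse.io import unfold
    from hsifuse.multiset import assemble, balance
    from hsifuse.phantom import PhantomSpec, generate_phantom

    s_meds, m_meds = [], []
    for seed in range(20):
        ph = generate_phantom(PhantomSpec.clean(n_px=16, seed=seed, snr=50.0))
        blocks = {k: unfold(c) for k, c in ph["cubes"].items()}
        ms = assemble(dict(zip(blocks, balance(list(blocks.values())))))
        cs = ConstraintSet(4).set_nonneg("C").set_nonneg("S")
        res = run_mcr_als(ms, 4, constraints=cs)
        S_true = balanced_truth_spectra(ph["truth"], ms)
        perm, corr = match_components(res.St, S_true)
        s_meds.append(np.median(corr))
        mc = []
        maps = component_maps(res, ms, "s1", fill=0.0)
        gt = ph["truth"]["maps_mod"][("s1", "ftir")]
        for i, k in enumerate(perm):
            mc.append(abs(np.corrcoef(maps[i].ravel(), gt[k].ravel())[0, 1]))
        m_meds.append(np.median(mc))
    assert np.median(s_meds) >= 0.99
    assert np.median(m_meds) >= 0.98


# ------------------------------------------------------------ estimator API
def test_mcrals_sklearn_interface(rng):
    C0 = rng.random((30, 2))
    S0 = rng.random((2, 10))
    M = C0 @ S0
    est = MCRALS(n_components=2, max_iter=10)
    assert clone(est).get_params() == est.get_params()
    Cfit = est.fit_transform(M)
    assert Cfit.shape == (30, 2)
    np.testing.assert_array_equal(Cfit, est.C_)
    assert est.lof_ < 1e-6
    assert est.r2_ == pytest.approx(1.0, abs=1e-10)
    # transform reproduces the fitted concentrations on the same data
    np.testing.assert_allclose(est.transform(M), est.C_, atol=1e-8)
    est.set_params(max_iter=5)
    assert est.get_params()["max_iter"] == 5


def test_mcrals_rejects_bad_inputs(rng):
    with pytest.raises(ValueError):
        MCRALS(n_components=10).fit(rng.random((4, 4)))
    with pytest.raises(ValueError):
        MCRALS(n_components=2).fit(np.full((4, 4), np.nan))
    with pytest.raises(ValueError):
        MCRALS(n_components=2, init=np.ones((3, 4))).fit(rng.random((6, 4)))
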