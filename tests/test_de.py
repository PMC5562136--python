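import numpy as np
import pytest
from scipy import special, stats

import stardiff.de as de
from stardiff.io import CountMatrix


# ---------------------------------------------------------------------------
# conditional log-likelihood
# ---------------------------------------------------------------------------

def test_conditional_loglik_all_zero_is_zero():
    for phi in (0.01, 0.5, 5.0):
        assert de.conditional_loglik(np.array([0, 0]), phi)[0] == pytest.approx(0.0)


def test_conditional_loglik_matches_direct_evaluation():
    y = np.array([3, 3])
    phi = 0.1
    r = 1 / phi
    n, z = 2, 6
    expected = (
        special.gammaln(3 + r) * 2
        + special.gammaln(n * r)
        - special.gammaln(z + n * r)
        - n * special.gammaln(r)
    )
    assert de.conditional_loglik(y, phi)[0] == pytest.approx(expected, rel=1e-12)


def test_conditional_loglik_permutation_invariant():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 40, size=8)
    for phi in (0.05, 0.3):
        a = de.conditional_loglik(y, phi)[0]
        b = de.conditional_loglik(rng.permutation(y), phi)[0]
        assert a == pytest.approx(b, rel=1e-12)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def _nb_matrix(rng, G, n, mu, phi):
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size=(G, n))


def test_common_dispersion_poisson_boundary():
    rng = np.random.default_rng(1)
    y = rng.poisson(60.0, size=(1500, 10)).astype(float)
    groups = [np.arange(5), np.arange(5, 10)]
    assert de.estimate_common_dispersion(y, groups) <= 1e-3


def test_common_dispersion_recovery():
    rng = np.random.default_rng(2)
    y = _nb_matrix(rng, 2000, 10, 80.0, 0.2).astype(float)
    groups = [np.arange(5), np.arange(5, 10)]
    est = de.estimate_common_dispersion(y, groups)
    assert 0.15 <= est <= 0.25


def test_common_dispersion_fragment_order_invariant():
    rng = np.random.default_rng(3)
    y = _nb_matrix(rng, 300, 8, 40.0, 0.1).astype(float)
    groups = [np.arange(4), np.arange(4, 8)]
    a = de.estimate_common_dispersion(y, groups)
    b = de.estimate_common_dispersion(y[rng.permutation(300)], groups)
    assert a == pytest.approx(b, rel=1e-6)


def test_tagwise_limits_and_monotone_shrinkage():
    rng = np.random.default_rng(4)
    G = 200
    phis = 0.15 * np.exp(rng.normal(0, 0.6, G))
    y = np.empty((G, 10))
    for g in range(G):
        y[g] = _nb_matrix(rng, 1, 10, 60.0, phis[g])[0]
    groups = [np.arange(5), np.arange(5, 10)]
    phi_c = de.estimate_common_dispersion(y, groups)
    ml = de.estimate_tagwise_dispersion(y, groups, phi_c, 0.0)
    huge = de.estimate_tagwise_dispersion(y, groups, phi_c, 1e7)
    assert np.allclose(np.log(huge), np.log(phi_c), atol=0.15)
    w_small = de.estimate_tagwise_dispersion(y, groups, phi_c, 0.5)
    w_big = de.estimate_tagwise_dispersion(y, groups, phi_c, 5.0)
    # larger prior weight pulls every estimate closer to the common value
    d_small = np.abs(np.log(w_small) - np.log(phi_c))
    d_big = np.abs(np.log(w_big) - np.log(phi_c))
    assert np.all(d_big <= d_small + 0.05)
    assert np.mean(d_big) < np.mean(np.abs(np.log(ml) - np.log(phi_c)))


def test_tagwise_rejects_negative_weight():
    y = np.ones((5, 4))
    with pytest.raises(ValueError):
        de.estimate_tagwise_dispersion(y, [np.arange(2), np.arange(2, 4)], 0.1, -1.0)


# ---------------------------------------------------------------------------
# pseudo-count equalization
# ---------------------------------------------------------------------------

def test_equalize_identity_for_equal_sizes():
    rng = np.random.default_rng(5)
    y = rng.integers(0, 50, size=(30, 4))
    sizes = np.full(4, 1e5)
    pseudo, common = de.equalize_libraries(y, sizes, [np.arange(2), np.arange(2, 4)], 0.1)
    assert common == pytest.approx(1e5)
    assert np.array_equal(pseudo, y)


def test_equalize_scales_like_direct_ratio():
    # one library at twice the size: its pseudo-counts shrink by ~ size ratio
    rng = np.random.default_rng(6)
    G = 200
    lam = rng.lognormal(-4, 0.6, G)
    sizes = np.array([2e4, 1e4, 1e4, 1e4])
    phi = 0.05
    r = 1 / phi
    mu = lam[:, None] * sizes[None, :]
    y = rng.negative_binomial(r, r / (r + mu)).astype(float)
    pseudo, common = de.equalize_libraries(y, sizes, [np.arange(4)], phi)
    expected = y * (common / sizes)[None, :]
    big = y.max(axis=1) > 5  # rounding dominates at tiny counts
    assert np.median(np.abs(pseudo - expected)[big]) <= 1.0


def test_equalize_column_sums_near_common_size():
    rng = np.random.default_rng(7)
    G = 300
    lam = rng.lognormal(-5, 0.8, G)
    lam /= lam.sum()
    sizes = np.array([5e4, 8e4, 1e5, 6e4])
    mu = lam[:, None] * sizes[None, :]
    y = rng.poisson(mu).astype(float)
    pseudo, common = de.equalize_libraries(y, sizes, [np.arange(4)], 0.01)
    assert np.allclose(pseudo.sum(axis=0), common, rtol=0.05)


# ---------------------------------------------------------------------------
# exact conditional test
# ---------------------------------------------------------------------------

def enum_exact_pvalue(z_a, Z, n_a, n_b, phi):
    """Independent oracle: brute-force enumeration of the conditional law of
    the group sum in 40-digit arithmetic (product of NB pmfs, renormalized)."""
    import mpmath as mp

    mp.mp.dps = 40
    r_a, r_b = mp.mpf(n_a) / mp.mpf(phi), mp.mpf(n_b) / mp.mpf(phi)
    lg = mp.loggamma
    probs = [
        mp.e ** (lg(z + r_a) - lg(z + 1) + lg(Z - z + r_b) - lg(Z - z + 1))
        for z in range(Z + 1)
    ]
    tot = sum(probs)
    probs = [p / tot for p in probs]
    obs = probs[z_a]
    return float(sum(p for p in probs if p <= obs * (1 + mp.mpf("1e-10"))))


def test_exact_test_modal_symmetry():
    p = de.exact_test_pvalues(np.array([7]), np.array([7]), 4, 4, np.array([0.2]))
    assert p[0] == pytest.approx(1.0)


def test_exact_test_zero_total():
    p = de.exact_test_pvalues(np.array([0]), np.array([0]), 5, 5, np.array([0.1]))
    assert p[0] == 1.0


def test_exact_test_matches_enumeration_oracle():
    rng = np.random.default_rng(8)
    for _ in range(60):
        n_a, n_b = rng.integers(2, 7, size=2)
        Z = int(rng.integers(1, 201))
        z_a = int(rng.integers(0, Z + 1))
        phi = float(10 ** rng.uniform(-4, np.log10(2)))
        mine = de.exact_test_pvalues(
            np.array([z_a]), np.array([Z - z_a]), n_a, n_b, np.array([phi])
        )[0]
        assert mine == pytest.approx(enum_exact_pvalue(z_a, Z, n_a, n_b, phi), abs=1e-12)


def test_exact_test_poisson_limit_matches_binomial():
    rng = np.random.default_rng(9)
    for _ in range(25):
        n_a, n_b = rng.integers(2, 7, size=2)
        Z = int(rng.integers(1, 201))
        z_a = int(rng.integers(0, Z + 1))
        mine = de.exact_test_pvalues(
            np.array([z_a]), np.array([Z - z_a]), n_a, n_b, np.array([1e-8])
        )[0]
        ref = stats.binomtest(z_a, Z, n_a / (n_a + n_b)).pvalue
        assert mine == pytest.approx(ref, abs=1e-4)


def test_exact_test_label_swap_symmetry(ambient_contrast):
    matrix, wild, ins, _ = ambient_contrast
    fwd = de.two_group_de(matrix, wild, ins)
    rev = de.two_group_de(matrix, ins, wild)
    assert np.allclose(fwd["pvalue"], rev["pvalue"], rtol=1e-9)
    assert np.allclose(fwd["logFC"], -rev["logFC"], atol=1e-9)


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

def test_bh_single_p():
    assert de.bh_fdr(np.array([0.03]))[0] == pytest.approx(0.03)


def test_bh_hand_stepup():
    q = de.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(10)
    p = rng.uniform(1e-8, 1, 500)
    q = de.bh_fdr(p)
    ref = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(q, ref, atol=1e-12)


def test_bh_monotone_in_sorted_order():
    rng = np.random.default_rng(11)
    p = np.sort(rng.uniform(1e-6, 1, 100))
    q = de.bh_fdr(p)
    assert np.all(np.diff(q) >= -1e-15)


def test_bh_rejects_invalid():
    with pytest.raises(ValueError):
        de.bh_fdr(np.array([0.0, 0.5]))
    with pytest.raises(ValueError):
        de.bh_fdr(np.array([1.5]))


# ---------------------------------------------------------------------------
# paired LRT
# ---------------------------------------------------------------------------

def _paired_design(rng, G, n_ind, mu, phi, treat_log2fc=0.0, affected=None):
    import pandas as pd

    from stardiff.io import LibraryMeta

    rows = []
    for k in range(n_ind):
        for tr in ("ambient", "elevated"):
            rows.append((f"ind{k}_{tr}", f"ind{k}", "wild", tr))
    meta = LibraryMeta(
        pd.DataFrame(rows, columns=["library_id", "individual_id", "genotype", "treatment"])
    )
    ind_eff = rng.lognormal(0, 0.1, n_ind)
    counts = np.empty((G, 2 * n_ind), dtype=np.int64)
    fc = np.ones(G)
    if affected is not None:
        fc[affected] = 2.0 ** treat_log2fc
    r = 1 / phi
    for j, (_, row) in enumerate(meta.table.iterrows()):
        k = int(row["individual_id"][3:])
        m = np.broadcast_to(mu * ind_eff[k] * (fc if row["treatment"] == "elevated" else 1.0), G)
        counts[:, j] = rng.negative_binomial(r, r / (r + m))
    frag_ids = tuple(f"f{i}" for i in range(G))
    return CountMatrix(frag_ids, tuple(meta.table["library_id"]), counts), meta


def test_paired_lrt_null_calibration():
    rng = np.random.default_rng(12)
    matrix, meta = _paired_design(rng, 2500, 10, 70.0, 0.15)
    res = de.paired_lrt(matrix, meta, np.full(2500, 0.15))
    rate = float((res["pvalue"] < 0.05).mean())
    assert 0.03 <= rate <= 0.07


def test_paired_lrt_detects_planted_effect():
    rng = np.random.default_rng(13)
    affected = np.arange(40)
    matrix, meta = _paired_design(rng, 400, 10, 70.0, 0.15, treat_log2fc=2.0, affected=affected)
    res = de.paired_lrt(matrix, meta, np.full(400, 0.15))
    hit = res.iloc[affected]
    assert (hit["fdr"] < 0.05).mean() > 0.5
    assert hit["logFC"].median() == pytest.approx(2.0, abs=0.4)


def test_paired_lrt_deviance_nesting():
    rng = np.random.default_rng(14)
    matrix, meta = _paired_design(rng, 150, 5, 50.0, 0.2)
    from stardiff.norm import tmm_factors

    sub = matrix
    factors = tmm_factors(sub)
    eff = factors.effective_sizes(sub)
    offsets = np.log(eff)
    table = meta.table
    inds = list(dict.fromkeys(table["individual_id"]))
    X_null = np.zeros((len(table), len(inds)))
    for j, (_, row) in enumerate(table.iterrows()):
        X_null[j, inds.index(row["individual_id"])] = 1.0
    treat = (table["treatment"] == "elevated").to_numpy(float)[:, None]
    X_full = np.hstack([X_null, treat])
    phi = np.full(150, 0.2)
    y = sub.counts.astype(float)
    _, dev_full, _ = de._irls_nb(y, X_full, offsets, phi)
    _, dev_null, _ = de._irls_nb(y, X_null, offsets, phi)
    assert np.all(dev_full <= dev_null + 1e-6)


def test_paired_lrt_rejects_unpaired():
    rng = np.random.default_rng(15)
    matrix, meta = _paired_design(rng, 20, 4, 50.0, 0.2)
    broken = meta.subset([l for l in meta.table["library_id"] if l != "ind0_elevated"])
    sub = matrix.select_libraries(list(broken.table["library_id"]))
    with pytest.raises(ValueError, match="unpaired"):
        de.paired_lrt(sub, broken, np.full(20, 0.2))
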