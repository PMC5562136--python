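"""Negative-binomial differential expression engine.

The two-class test follows the classic count-DE recipe: counts are
quantile-adjusted ("pseudo-counts") to a common effective library size so
that a conditional test applies; a common NB dispersion is estimated by
conditional maximum likelihood on the pseudo-counts; per-fragment
("tagwise") dispersions shrink the per-fragment likelihood toward the
common one with an empirical-Bayes prior weight; and an exact two-sided
test conditions on the total pseudo-count of each fragment.

NB parameterization throughout: variance = mu + phi * mu^2, size r = 1/phi.
For two groups sharing the per-library mean, the distribution of one
group's sum given the total Z is beta-binomial(Z, n_A/phi, n_B/phi), which
the exact test evaluates in closed form.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io import CountMatrix
from .norm import NormFactors, tmm_factors

PHI_MIN = 1e-6
PHI_MAX = 10.0
DEFAULT_PRIOR_DF = 10.0


@dataclasses.dataclass(frozen=True)
class DispersionEstimates:
    """Common and per-fragment NB dispersions with the shrinkage weight used."""

    common: float
    tagwise: np.ndarray
    prior_weight: float


# ---------------------------------------------------------------------------
# conditional likelihood and dispersion estimation
# ---------------------------------------------------------------------------

def conditional_loglik(group_counts: np.ndarray, phi: float) -> np.ndarray:
    """Conditional NB log-likelihood of a group given its total, per fragment.

    ``group_counts`` is (G, n) or (n,) of equal-size-library (pseudo)
    counts; constant terms not involving phi are dropped.  Returns a
    length-G vector (scalar input gives a length-1 vector).
    """
    y = np.atleast_2d(np.asarray(group_counts, dtype=float))
    phi = max(float(phi), PHI_MIN / 100)
    r = 1.0 / phi
    n = y.shape[1]
    z = y.sum(axis=1)
    return (
        special.gammaln(y + r).sum(axis=1)
        + special.gammaln(n * r)
        - special.gammaln(z + n * r)
        - n * special.gammaln(r)
    )


def _groups_loglik(pseudo: np.ndarray, group_cols: list[np.ndarray], phi: float) -> np.ndarray:
    """Sum of per-group conditional log-likelihoods, per fragment."""
    total = np.zeros(pseudo.shape[0])
    for cols in group_cols:
        if len(cols):
            total += conditional_loglik(pseudo[:, cols], phi)
    return total


def estimate_common_dispersion(pseudo: np.ndarray, group_cols: list[np.ndarray]) -> float:
    """Maximize the summed conditional log-likelihood over phi in [1e-6, 10]."""
    if not np.any(pseudo > 0):
        raise ValueError("all-zero matrix: cannot estimate dispersion")
    for cols in group_cols:
        if len(cols) < 2:
            raise ValueError("each group needs at least 2 libraries")

    def neg(logphi: float) -> float:
        return -float(_groups_loglik(pseudo, group_cols, 10.0 ** logphi).sum())

    res = optimize.minimize_scalar(
        neg, bounds=(np.log10(PHI_MIN), np.log10(PHI_MAX)), method="bounded",
        options={"xatol": 1e-4},
    )
    return float(10.0 ** res.x)


def _dispersion_grid(n_points: int = 25) -> np.ndarray:
    return np.logspace(np.log10(PHI_MIN), np.log10(PHI_MAX), n_points)


def estimate_tagwise_dispersion(
    pseudo: np.ndarray,
    group_cols: list[np.ndarray],
    phi_common: float,
    prior_weight: float,
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted-likelihood empirical-Bayes per-fragment dispersions.

    Maximizes l_g(phi) + W * lbar(phi) per fragment, lbar being the mean
    conditional log-likelihood over all fragments; W -> 0 gives per-fragment
    conditional ML, W -> inf collapses every estimate onto the common value.
    Maximization is a log-spaced grid search refined by quadratic
    interpolation in log-phi.
    """
    if prior_weight < 0:
        raise ValueError("prior weight must be non-negative")
    if grid is None:
        grid = _dispersion_grid()
    G = pseudo.shape[0]
    L = np.empty((G, grid.size))
    for k, phi in enumerate(grid):
        L[:, k] = _groups_loglik(pseudo, group_cols, phi)
    if np.isinf(prior_weight):
        return np.full(G, phi_common)
    obj = L + prior_weight * L.mean(axis=0)[None, :]
    best = np.argmax(obj, axis=1)
    logphi = _quadratic_refine(np.log10(grid), obj, best)
    return 10.0 ** logphi


def _quadratic_refine(x: np.ndarray, obj: np.ndarray, best: np.ndarray) -> np.ndarray:
    """Vertex of the parabola through the argmax grid point and neighbours."""
    i = np.clip(best, 1, x.size - 2)
    g = np.arange(obj.shape[0])
    y0, y1, y2 = obj[g, i - 1], obj[g, i], obj[g, i + 1]
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    denom = (y0 - y1) * (x1 - x2) - (y1 - y2) * (x0 - x1)
    num = (y0 - y1) * (x1 + x2) * (x1 - x2) - (y1 - y2) * (x0 + x1) * (x0 - x1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vertex = 0.5 * num / denom
    bad = ~np.isfinite(vertex) | (vertex < np.minimum(x0, x2)) | (vertex > np.maximum(x0, x2))
    vertex = np.where(bad, x[best], vertex)
    # boundary argmax stays on the boundary
    vertex = np.where((best == 0) | (best == x.size - 1), x[best], vertex)
    return vertex


def default_prior_weight(group_sizes: list[int], prior_df: float = DEFAULT_PRIOR_DF) -> float:
    """prior_df / residual_df with residual_df = sum_k (n_k - 1)."""
    residual_df = sum(n - 1 for n in group_sizes)
    if residual_df <= 0:
        raise ValueError("no residual degrees of freedom")
    return prior_df / residual_df


# ---------------------------------------------------------------------------
# pseudo-counts (quantile adjustment to a common library size)
# ---------------------------------------------------------------------------

def _fit_group_rate(y: np.ndarray, sizes: np.ndarray, phi: float) -> np.ndarray:
    """Per-fragment NB rate lambda maximizing the one-group likelihood.

    Solves sum_j (y_gj - lambda*N_j) / (1 + phi*lambda*N_j) = 0 by Newton
    iteration on log(lambda); lambda = 0 for all-zero rows.
    """
    tot = y.sum(axis=1)
    N = sizes[None, :]
    lam = tot / sizes.sum()
    pos = lam > 0
    loglam = np.where(pos, np.log(np.where(pos, lam, 1.0)), -np.inf)
    for _ in range(30):
        mu = np.exp(loglam)[:, None] * N
        denom = 1.0 + phi * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.where(pos & (info > 0), score / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -5, 5)
        loglam = loglam + step
        if not pos.any() or np.max(np.abs(step[pos])) < 1e-10:
            break
    return np.where(pos, np.exp(loglam), 0.0)


def q2qnbinom(x: np.ndarray, input_mean: np.ndarray, output_mean: np.ndarray,
              dispersion: float) -> np.ndarray:
    """Quantile-to-quantile map of NB counts between mean regimes.

    Averages a normal and a gamma quantile transform matched to the NB
    mean/variance at the input and output means (a smooth surrogate for the
    integer NB quantile map, keeping pseudo-counts continuous).
    """
    x = np.asarray(x, dtype=float)
    input_mean = np.where(input_mean < 1e-14, input_mean + 0.25, input_mean)
    output_mean = np.where(output_mean < 1e-14, output_mean + 0.25, output_mean)
    vin = input_mean * (1.0 + dispersion * input_mean)
    vout = output_mean * (1.0 + dispersion * output_mean)
    upper = x >= input_mean

    out = np.empty_like(x)
    for mask, tail in ((upper, "upper"), (~upper, "lower")):
        if not mask.any():
            continue
        xm, im, om = x[mask], input_mean[mask], output_mean[mask]
        vi, vo = vin[mask], vout[mask]
        if tail == "upper":
            p_norm = stats.norm.sf(xm, loc=im, scale=np.sqrt(vi))
            q_norm = stats.norm.isf(p_norm, loc=om, scale=np.sqrt(vo))
            p_gam = stats.gamma.sf(xm, a=im**2 / vi, scale=vi / im)
            q_gam = stats.gamma.isf(p_gam, a=om**2 / vo, scale=vo / om)
        else:
            p_norm = stats.norm.cdf(xm, loc=im, scale=np.sqrt(vi))
            q_norm = stats.norm.ppf(p_norm, loc=om, scale=np.sqrt(vo))
            p_gam = stats.gamma.cdf(xm, a=im**2 / vi, scale=vi / im)
            q_gam = stats.gamma.ppf(p_gam, a=om**2 / vo, scale=vo / om)
        out[mask] = 0.5 * (q_norm + q_gam)
    # far-tail counts can underflow the survival probability to 0 (isf -> inf);
    # fall back to plain mean-ratio scaling there
    bad = ~np.isfinite(out)
    if bad.any():
        out[bad] = (x * output_mean / input_mean)[bad]
    return np.maximum(out, 0.0)


def equalize_libraries(
    counts: np.ndarray,
    effective_sizes: np.ndarray,
    group_cols: list[np.ndarray],
    dispersion: float,
) -> tuple[np.ndarray, float]:
    """Quantile-adjust counts to the geometric-mean effective size.

    Per group, a one-group NB fit gives each fragment's rate; counts are
    then mapped through matched NB quantiles from their library's mean to
    the mean at the common size.  With equal effective sizes the map is the
    identity.  Returns (pseudo_counts, common_size).
    """
    effective_sizes = np.asarray(effective_sizes, dtype=float)
    common_size = float(np.exp(np.mean(np.log(effective_sizes))))
    if np.allclose(effective_sizes, common_size, rtol=1e-12):
        return counts.astype(float), common_size
    pseudo = np.empty(counts.shape, dtype=float)
    for cols in group_cols:
        if not len(cols):
            continue
        y = counts[:, cols].astype(float)
        sizes = effective_sizes[cols]
        lam = _fit_group_rate(y, sizes, dispersion)
        input_mean = lam[:, None] * sizes[None, :]
        output_mean = np.broadcast_to((lam * common_size)[:, None], y.shape)
        pseudo[:, cols] = q2qnbinom(y, input_mean, output_mean, dispersion)
    return pseudo, common_size


# ---------------------------------------------------------------------------
# exact conditional test
# ---------------------------------------------------------------------------

_TIE_TOL = 1e-10  # log-space slack so the observed outcome always counts
_SMALL_Z = 600    # totals up to this use exact prefix-sum log-probabilities


def _bb_logpmf(z, Z, r_a, r_b, logfact, const):
    """log pmf of beta-binomial(Z, r_a, r_b) at z (aligned integer arrays)."""
    return (
        const
        - logfact[z]
        - logfact[Z - z]
        + special.gammaln(z + r_a)
        + special.gammaln(Z - z + r_b)
    )


def _range_sum(lo, hi, Z, r_a, r_b, logfact, const, minlength):
    """Sum of pmf over [lo, hi] per fragment (empty where lo > hi)."""
    lengths = np.maximum(hi - lo + 1, 0)
    if not lengths.any():
        return np.zeros(minlength)
    offsets = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    idx = np.repeat(np.arange(lo.size), lengths)
    z = np.arange(int(lengths.sum())) - offsets[idx] + lo[idx]
    lp = _bb_logpmf(z, Z[idx], r_a[idx], r_b[idx], logfact, const[idx])
    return np.bincount(idx, weights=np.exp(lp), minlength=minlength)


def exact_test_pvalues(
    z_a: np.ndarray, z_b: np.ndarray, n_a: int, n_b: int, phi: np.ndarray
) -> np.ndarray:
    """Two-sided exact conditional p-values for rounded group pseudo-sums.

    Given totals Z = z_a + z_b, the null conditional law of z_a is
    beta-binomial(Z, n_a/phi, n_b/phi); the two-sided p sums the
    probabilities of all outcomes no more likely than the observed one.
    For the usual log-concave case (both shape parameters >= 1) only the
    smaller of {more-likely window, complementary tails} is enumerated,
    bracketing the window by bisection around the mode; this avoids
    cancellation for small p because small p-values are summed directly.
    """
    z_a = np.asarray(z_a, dtype=np.int64)
    z_b = np.asarray(z_b, dtype=np.int64)
    phi = np.maximum(np.asarray(phi, dtype=float), 1e-10)
    Z = z_a + z_b
    G = Z.size
    r_a = np.broadcast_to(n_a / phi, (G,)).astype(float)
    r_b = np.broadcast_to(n_b / phi, (G,)).astype(float)

    pvals = np.ones(G)
    live = Z > 0
    if not live.any():
        return pvals

    maxz = int(Z.max())
    logfact = np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, maxz + 1)))))
    const = (
        logfact[Z]
        + special.gammaln(r_a + r_b)
        - special.gammaln(r_a)
        - special.gammaln(r_b)
        - special.gammaln(Z + r_a + r_b)
    )
    log_obs = _bb_logpmf(z_a, Z, r_a, r_b, logfact, const)
    thr = log_obs + _TIE_TOL

    small = live & (Z <= _SMALL_Z)
    if small.any():
        isml = np.flatnonzero(small)
        pvals[isml] = _small_exact_pvalues(z_a[isml], Z[isml], r_a[isml], r_b[isml])

    concave = live & ~small & (np.minimum(r_a, r_b) >= 1.0)
    brute = live & ~small & ~concave
    if brute.any():
        ib = np.flatnonzero(brute)
        lengths = Z[ib] + 1
        offsets = np.concatenate(([0], np.cumsum(lengths)[:-1]))
        idx = np.repeat(np.arange(ib.size), lengths)
        z = np.arange(int(lengths.sum())) - offsets[idx]
        lpv = _bb_logpmf(z, Z[ib][idx], r_a[ib][idx], r_b[ib][idx], logfact, const[ib][idx])
        keep = lpv <= thr[ib][idx]
        p = np.bincount(idx[keep], weights=np.exp(lpv[keep]), minlength=ib.size)
        pvals[ib] = np.clip(p, np.finfo(float).tiny, 1.0)

    if concave.any():
        ic = np.flatnonzero(concave)
        Zc, rac, rbc = Z[ic], r_a[ic], r_b[ic]
        cc, thrc = const[ic], thr[ic]
        # mode of the log-concave pmf
        mode = np.clip(
            np.floor(Zc * (rac - 1.0) / np.maximum(rac + rbc - 2.0, 1e-8)).astype(np.int64),
            0, Zc,
        )
        lp_mode = _bb_logpmf(mode, Zc, rac, rbc, logfact, cc)
        lp_next = _bb_logpmf(np.minimum(mode + 1, Zc), Zc, rac, rbc, logfact, cc)
        mode = np.where(lp_next > lp_mode, np.minimum(mode + 1, Zc), mode)

        # largest z in [0, mode] with pmf <= threshold (-1 if none):
        lo = _bisect_edge(Zc, rac, rbc, cc, thrc, mode, logfact, side="left")
        # smallest z in [mode, Z] with pmf <= threshold (Z+1 if none):
        hi = _bisect_edge(Zc, rac, rbc, cc, thrc, mode, logfact, side="right")

        all_below = lo >= hi  # window empty: every outcome is <= threshold
        tails = (lo + 1) + (Zc - hi + 1)
        window = np.maximum(hi - lo - 1, 0)
        use_tails = (~all_below) & (tails <= window)
        use_window = (~all_below) & ~use_tails

        p = np.ones(ic.size)
        if use_tails.any():
            it = np.flatnonzero(use_tails)
            left = _range_sum(np.zeros(it.size, np.int64), lo[it], Zc[it], rac[it],
                              rbc[it], logfact, cc[it], it.size)
            right = _range_sum(hi[it], Zc[it], Zc[it], rac[it], rbc[it],
                               logfact, cc[it], it.size)
            p[it] = left + right
        if use_window.any():
            iw = np.flatnonzero(use_window)
            s = _range_sum(lo[iw] + 1, hi[iw] - 1, Zc[iw], rac[iw], rbc[iw],
                           logfact, cc[iw], iw.size)
            p[iw] = 1.0 - s
        pvals[ic] = np.clip(p, np.finfo(float).tiny, 1.0)
    return pvals


def _small_exact_pvalues(z_a, Z, r_a, r_b) -> np.ndarray:
    """Full enumeration with prefix-sum log terms (high accuracy at any phi).

    Uses lgamma(z + r) - lgamma(r) = sum_{j<z} log(r + j) computed by
    segmented cumulative sums, avoiding the cancellation that the gammaln
    difference suffers when r is enormous (near-Poisson dispersions).
    """
    lengths = Z + 1
    offsets = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    idx = np.repeat(np.arange(Z.size), lengths)
    zrel = np.arange(int(lengths.sum())) - offsets[idx]

    # extended precision keeps the accumulated log-term error below the
    # p-value comparison noise floor
    ld = np.longdouble

    def prefix(r):
        # value at flat position with zrel=k is sum_{j<k} log(r + j)
        v = np.where(zrel > 0, np.log(ld(r)[idx] + np.maximum(zrel - 1, 0)), ld(0.0))
        cs = np.cumsum(v)
        return cs - cs[offsets][idx]

    A = prefix(r_a)
    B = prefix(r_b)
    C = prefix(r_a + r_b)
    D = C[offsets + Z]  # sum_{j<Z} log(r_a + r_b + j)
    B_at = B[offsets[idx] + (Z[idx] - zrel)]
    lfz = np.cumsum(np.log(np.maximum(np.arange(int(Z.max()) + 1), 1).astype(ld)))
    logpmf = lfz[Z[idx]] - lfz[zrel] - lfz[Z[idx] - zrel] + A + B_at - D[idx]
    log_obs = logpmf[offsets + z_a]
    keep = logpmf <= log_obs[idx] + _TIE_TOL
    p = np.bincount(idx[keep], weights=np.exp(logpmf[keep]).astype(float),
                    minlength=Z.size)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _bisect_edge(Z, r_a, r_b, const, thr, mode, logfact, side: str) -> np.ndarray:
    """Boundary of {pmf <= thr} on one monotone flank of a log-concave pmf.

    side='left': largest z in [0, mode] with log-pmf <= thr, or -1.
    side='right': smallest z in [mode, Z] with log-pmf <= thr, or Z + 1.
    """
    if side == "left":
        lo = np.zeros(Z.size, dtype=np.int64)
        hi = mode.copy()
        # pmf increasing on [0, mode]; answer = last index below threshold
        below0 = _bb_logpmf(lo, Z, r_a, r_b, logfact, const) <= thr
        ans = np.where(below0, np.int64(0), np.int64(-1))
        lo = np.where(below0, lo, hi + 1)  # empty range when even z=0 is above
        while True:
            active = lo < hi
            if not active.any():
                break
            mid = (lo + hi + 1) // 2
            ok = _bb_logpmf(np.minimum(mid, Z), Z, r_a, r_b, logfact, const) <= thr
            take = active & ok
            ans = np.where(take, mid, ans)
            lo = np.where(active & ok, mid, lo)
            hi = np.where(active & ~ok, mid - 1, hi)
        return np.where(lo <= hi, np.maximum(ans, -1), ans)
    else:
        lo = mode.copy()
        hi = Z.copy()
        belowZ = _bb_logpmf(hi, Z, r_a, r_b, logfact, const) <= thr
        ans = np.where(belowZ, Z, Z + 1)
        hi = np.where(belowZ, hi, lo - 1)
        while True:
            active = lo < hi
            if not active.any():
                break
            mid = (lo + hi) // 2
            ok = _bb_logpmf(np.maximum(mid, 0), Z, r_a, r_b, logfact, const) <= thr
            take = active & ok
            ans = np.where(take, mid, ans)
            hi = np.where(active & ok, mid, hi)
            lo = np.where(active & ~ok, mid + 1, lo)
        return ans


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


# ---------------------------------------------------------------------------
# the assembled two-class pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TwoGroupFit:
    """Intermediate state of a two-class run (pseudo-counts and dispersions)."""

    matrix: CountMatrix
    cols_a: np.ndarray
    cols_b: np.ndarray
    factors: NormFactors
    pseudo: np.ndarray
    common_size: float
    dispersions: DispersionEstimates


def fit_two_group(
    matrix: CountMatrix,
    libs_a: list[str],
    libs_b: list[str],
    prior_df: float = DEFAULT_PRIOR_DF,
    factors: NormFactors | None = None,
) -> TwoGroupFit:
    """Normalize, equalize and estimate dispersions for one two-class contrast.

    One round of pseudo-count/dispersion alternation: equalize at a starting
    dispersion of 0.01, estimate the common dispersion, re-equalize at the
    estimate, re-estimate, stop.
    """
    lib_order = list(libs_a) + list(libs_b)
    sub = matrix.select_libraries(lib_order)
    if factors is None:
        factors = tmm_factors(sub)
    eff = factors.effective_sizes(sub)
    cols_a = np.arange(len(libs_a))
    cols_b = np.arange(len(libs_a), len(lib_order))
    groups = [cols_a, cols_b]

    pseudo, _ = equalize_libraries(sub.counts, eff, groups, dispersion=0.01)
    phi1 = estimate_common_dispersion(pseudo, groups)
    pseudo, common_size = equalize_libraries(sub.counts, eff, groups, dispersion=phi1)
    phi_common = estimate_common_dispersion(pseudo, groups)

    W = default_prior_weight([len(libs_a), len(libs_b)], prior_df)
    tagwise = estimate_tagwise_dispersion(pseudo, groups, phi_common, W)
    disp = DispersionEstimates(common=phi_common, tagwise=tagwise, prior_weight=W)
    return TwoGroupFit(sub, cols_a, cols_b, factors, pseudo, common_size, disp)


def exact_test(fit: TwoGroupFit, dispersion: str = "tagwise") -> pd.DataFrame:
    """Exact conditional test on a fitted two-class contrast.

    Returns one row per fragment: fragment_id, logFC (log2 class-B over
    class-A), logCPM (log2 mean CPM, prior count 0.25), pvalue, fdr.
    """
    if dispersion == "tagwise":
        phi = fit.dispersions.tagwise
    elif dispersion == "common":
        phi = np.full(fit.matrix.n_fragments, fit.dispersions.common)
    else:
        raise ValueError("dispersion must be 'tagwise' or 'common'")
    n_a, n_b = len(fit.cols_a), len(fit.cols_b)
    z_a = np.rint(fit.pseudo[:, fit.cols_a].sum(axis=1)).astype(np.int64)
    z_b = np.rint(fit.pseudo[:, fit.cols_b].sum(axis=1)).astype(np.int64)
    pvals = exact_test_pvalues(z_a, z_b, n_a, n_b, phi)
    logfc = np.log2(((z_b + 0.5) / n_b) / ((z_a + 0.5) / n_a))
    logfc[(z_a + z_b) == 0] = 0.0
    mean_pseudo = fit.pseudo.mean(axis=1)
    logcpm = np.log2((mean_pseudo + 0.25) / fit.common_size * 1e6)
    return pd.DataFrame(
        {
            "fragment_id": list(fit.matrix.fragment_ids),
            "logFC": logfc,
            "logCPM": logcpm,
            "pvalue": pvals,
            "fdr": bh_fdr(pvals),
        }
    )


def two_group_de(
    matrix: CountMatrix,
    libs_a: list[str],
    libs_b: list[str],
    prior_df: float = DEFAULT_PRIOR_DF,
    dispersion: str = "tagwise",
) -> pd.DataFrame:
    """Full two-class DE: TMM -> equalize -> dispersions -> exact test -> BH."""
    return exact_test(fit_two_group(matrix, libs_a, libs_b, prior_df), dispersion)


# ---------------------------------------------------------------------------
# paired likelihood-ratio test
# ---------------------------------------------------------------------------

def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB residual deviance per fragment (rows), phi per fragment."""
    r = 1.0 / np.maximum(phi, 1e-10)[:, None]
    mu = np.maximum(mu, 1e-10)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
    term2 = (y + r) * np.log((y + r) / (mu + r))
    return 2.0 * (term1 - term2).sum(axis=1)


def _irls_nb(
    y: np.ndarray, X: np.ndarray, offsets: np.ndarray, phi: np.ndarray,
    max_iter: int = 50, tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized NB IRLS at fixed per-fragment dispersion.

    Returns (beta (G,p), deviance (G,), converged (G,) bool).
    """
    G, n = y.shape
    p = X.shape[1]
    z0 = np.log(y + 0.5) - offsets[None, :]
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (G, p)
    eta = beta @ X.T + offsets[None, :]
    mu = np.exp(np.clip(eta, -30, 30))
    dev = _nb_deviance(y, mu, phi)
    converged = np.zeros(G, dtype=bool)
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        w = mu / (1.0 + phi[:, None] * mu)
        zz = (eta - offsets[None, :]) + (y - mu) / np.maximum(mu, 1e-10)
        A = np.einsum("ji,gj,jk->gik", X, w, X)
        b = np.einsum("ji,gj->gi", X, w * zz)
        A = A + 1e-8 * np.eye(p)[None, :, :]
        new_beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        step = new_beta - beta
        # damped update: halve until deviance does not increase
        scale = np.ones(G)
        for _half in range(12):
            trial = beta + scale[:, None] * step
            eta_t = np.clip(trial @ X.T + offsets[None, :], -30, 30)
            mu_t = np.exp(eta_t)
            dev_t = _nb_deviance(y, mu_t, phi)
            worse = active & (dev_t > dev + 1e-10)
            if not worse.any():
                break
            scale = np.where(worse, scale * 0.5, scale)
        beta = beta + scale[:, None] * step
        eta = np.clip(beta @ X.T + offsets[None, :], -30, 30)
        mu = np.exp(eta)
        new_dev = _nb_deviance(y, mu, phi)
        converged = converged | (np.abs(dev - new_dev) < tol * (np.abs(dev) + 1.0))
        dev = new_dev
    return beta, dev, converged


def paired_lrt(
    matrix: CountMatrix,
    meta,
    dispersions: np.ndarray,
    factors: NormFactors | None = None,
) -> pd.DataFrame:
    """Paired-design treatment test: NB log-linear model with individual blocks.

    log mu = log(effective size) + individual + treatment, fitted by IRLS at
    fixed per-fragment dispersion; p-values from the likelihood-ratio
    statistic against the no-treatment model (chi-square, 1 df); BH FDR.
    Every individual must have both treatments.
    """
    table = meta.table
    lib_order = list(table["library_id"])
    sub = matrix.select_libraries(lib_order)
    inds = list(dict.fromkeys(table["individual_id"]))
    per_ind = table.groupby("individual_id")["treatment"].nunique()
    unpaired = per_ind[per_ind < 2]
    if len(unpaired):
        raise ValueError(f"unpaired individuals: {list(unpaired.index)}")

    if factors is None:
        factors = tmm_factors(sub)
    eff = factors.effective_sizes(sub)
    offsets = np.log(eff)

    n = len(lib_order)
    ind_idx = {ind: k for k, ind in enumerate(inds)}
    X_null = np.zeros((n, len(inds)))
    for j, (_, row) in enumerate(table.iterrows()):
        X_null[j, ind_idx[row["individual_id"]]] = 1.0
    treat = (table["treatment"] == "elevated").to_numpy(dtype=float)[:, None]
    X_full = np.hstack([X_null, treat])

    y = sub.counts.astype(float)
    phi = np.asarray(dispersions, dtype=float)
    if phi.shape != (sub.n_fragments,):
        raise ValueError("one dispersion per fragment required")

    beta_full, dev_full, conv_full = _irls_nb(y, X_full, offsets, phi)
    _, dev_null, conv_null = _irls_nb(y, X_null, offsets, phi)

    lrt = np.maximum(dev_null - dev_full, 0.0)
    pvals = stats.chi2.sf(lrt, df=1)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    flagged = ~(conv_full & conv_null)
    pvals[flagged] = 1.0

    logfc = beta_full[:, -1] / np.log(2.0)
    logcpm = np.log2((y / eff[None, :] * 1e6).mean(axis=1) + 0.25)
    return pd.DataFrame(
        {
            "fragment_id": list(sub.fragment_ids),
            "logFC": logfc,
            "logCPM": logcpm,
            "pvalue": pvals,
            "fdr": bh_fdr(pvals),
            "converged": ~flagged,
        }
    )
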