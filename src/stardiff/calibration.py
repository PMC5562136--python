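"""Seeded calibration experiments: the package's own evaluation battery.

Each function regenerates its inputs from a seed, runs the relevant part of
the pipeline, and returns summary numbers.  These are the experiments the
test suite and the reproduction script run; problem sizes are scaled-down
versions of the study design (documented in the methods note).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import behavior, contrasts, de, permtest
from .norm import filter_expressed
from .simulate import SimulationParams, simulate_experiment, simulate_righting


def _spawn_ints(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) from one base seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# exact-test oracle agreement
# ---------------------------------------------------------------------------

def _mp_enum_pvalue(z_a: int, Z: int, n_a: int, n_b: int, phi: float) -> float:
    """Brute-force enumeration of the conditional two-sided p in 40-digit
    arithmetic (independent of the package's closed-form route)."""
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


def exact_test_oracle_errors(seed: int, n_instances: int = 200) -> dict:
    """Max |p - oracle| over random small instances, plus the Poisson limit.

    Instances: total Z <= 200, group sizes 2..6, phi in [1e-4, 2].  The
    Poisson-limit check compares phi = 1e-8 against the exact binomial test.
    """
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_instances):
        n_a, n_b = rng.integers(2, 7, size=2)
        Z = int(rng.integers(1, 201))
        z_a = int(rng.integers(0, Z + 1))
        phi = float(10 ** rng.uniform(-4, np.log10(2.0)))
        mine = de.exact_test_pvalues(
            np.array([z_a]), np.array([Z - z_a]), int(n_a), int(n_b), np.array([phi])
        )[0]
        max_err = max(max_err, abs(mine - _mp_enum_pvalue(z_a, Z, int(n_a), int(n_b), phi)))
    poisson_err = 0.0
    for _ in range(50):
        n_a, n_b = rng.integers(2, 7, size=2)
        Z = int(rng.integers(1, 201))
        z_a = int(rng.integers(0, Z + 1))
        mine = de.exact_test_pvalues(
            np.array([z_a]), np.array([Z - z_a]), int(n_a), int(n_b), np.array([1e-8])
        )[0]
        ref = stats.binomtest(z_a, Z, n_a / (n_a + n_b)).pvalue
        poisson_err = max(poisson_err, abs(mine - ref))
    return {"max_abs_err": max_err, "poisson_max_abs_err": poisson_err, "n": n_instances}


# ---------------------------------------------------------------------------
# null calibration (false calls and permutation uniformity)
# ---------------------------------------------------------------------------

def null_calibration(seed: int, n_seeds: int = 50, n_fragments: int = 2000,
                     K: int = 20) -> dict:
    """Null simulations: false-call counts and unsorted-permutation PIT.

    For each seed, simulates an effect-free experiment, counts fragments at
    FDR < 0.01 in the genotype contrast, and runs an unsorted permutation
    test (K random splits) recording the randomized-PIT percentile of the
    observed DE count; the PIT is uniform under exchangeability, which a
    Kolmogorov-Smirnov test checks across seeds.
    """
    child = _spawn_ints(seed, 2 * n_seeds)
    counts, pits = [], []
    for k in range(n_seeds):
        params = SimulationParams(seed=child[k], pi_de=0.0, k_wild=0, k_ins=0,
                                  n_fragments=n_fragments)
        matrix, meta, _ = simulate_experiment(params)
        filt = filter_expressed(matrix)
        res = permtest.unsorted_permutation_test(filt, meta, K=K, seed=child[n_seeds + k])
        counts.append(res.observed_stat)
        pits.append(res.pit)
    counts = np.array(counts)
    ks = stats.kstest(np.array(pits) / 100.0, "uniform")
    return {
        "false_call_counts": counts.tolist(),
        "near_zero_fraction": float((counts <= 1).mean()),
        "zero_fraction": float((counts == 0).mean()),
        "pit_ks_pvalue": float(ks.pvalue),
        "n": n_seeds,
    }


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def dispersion_recovery(seed: int, true_phi: float = 0.2, n_fragments: int = 2000) -> dict:
    """Common-dispersion recovery on a homogeneous-dispersion simulation."""
    params = SimulationParams(seed=seed, pi_de=0.0, k_wild=0, k_ins=0,
                              dispersion=true_phi, dispersion_log_sd=0.0,
                              n_fragments=n_fragments)
    matrix, meta, _ = simulate_experiment(params)
    filt = filter_expressed(matrix)
    wild = meta.libraries(genotype="wild", treatment="ambient")
    ins = meta.libraries(genotype="ins", treatment="ambient")
    fit = de.fit_two_group(filt.select_libraries(wild + ins), wild, ins)
    est = fit.dispersions.common
    return {"estimate": est, "true": true_phi,
            "rel_err": abs(est - true_phi) / true_phi, "n": n_fragments}


def shrinkage_mse(seed: int, n_seeds: int = 20, n_fragments: int = 800) -> dict:
    """Tagwise (empirical Bayes) vs per-fragment ML dispersion MSE.

    Simulates heterogeneous true dispersions (lognormal spread), estimates
    both ways, and compares mean squared error on phi itself — the scale on
    which the estimates feed the exact test.
    """
    child = _spawn_ints(seed, n_seeds)
    mse_tag, mse_ml = [], []
    for s in child:
        params = SimulationParams(seed=s, pi_de=0.0, k_wild=0, k_ins=0,
                                  dispersion=0.2, dispersion_log_sd=0.5,
                                  n_fragments=n_fragments,
                                  library_size_log_mean=float(np.log(1e5)))
        matrix, meta, truth = simulate_experiment(params)
        filt = filter_expressed(matrix)
        wild = meta.libraries(genotype="wild", treatment="ambient")
        ins = meta.libraries(genotype="ins", treatment="ambient")
        fit = de.fit_two_group(filt.select_libraries(wild + ins), wild, ins)
        groups = [fit.cols_a, fit.cols_b]
        ml = de.estimate_tagwise_dispersion(fit.pseudo, groups, fit.dispersions.common, 0.0)
        true_phi = truth.dispersion.loc[list(fit.matrix.fragment_ids)].to_numpy()
        mse_tag.append(float(np.mean((fit.dispersions.tagwise - true_phi) ** 2)))
        mse_ml.append(float(np.mean((ml - true_phi) ** 2)))
    return {
        "mse_tagwise": float(np.mean(mse_tag)),
        "mse_ml": float(np.mean(mse_ml)),
        "ratio": float(np.mean(mse_tag) / np.mean(mse_ml)),
        "n": n_seeds,
    }


# ---------------------------------------------------------------------------
# outlier (recombinant-library) study
# ---------------------------------------------------------------------------

def outlier_study(seed: int, n_seeds: int = 20, n_fragments: int = 1000) -> dict:
    """Sorted-permutation and influence diagnostics with a planted outlier.

    Each replicate plants genotype effects (|log2FC| = 2) plus one
    wild-labelled library with an ins-like profile, runs the exhaustive
    sorted reassignment test, and the exclude/reassign influence analyses.
    """
    child = _spawn_ints(seed, n_seeds)
    involve, excl_gt, reass_ge = [], [], []
    observed, excluded, reassigned = [], [], []
    for s in child:
        params = SimulationParams(seed=s, n_fragments=n_fragments,
                                  library_size_log_mean=float(np.log(1e5)),
                                  outlier_library=True)
        matrix, meta, truth = simulate_experiment(params)
        filt = filter_expressed(matrix)
        res = permtest.sorted_permutation_test(filt, meta)
        out_lib = truth.outlier_library_id
        exceed = [p for p, c in res.entries if c > res.observed_stat]
        involve.append(all(out_lib in p.moved for p in exceed) if exceed else True)
        n_ex = contrasts.influence_analysis(filt, meta, out_lib, "exclude")[1]
        n_ex = n_ex.per_threshold[0.01]["n_total_DE"]
        n_re = contrasts.influence_analysis(filt, meta, out_lib, "reassign")[1]
        n_re = n_re.per_threshold[0.01]["n_total_DE"]
        observed.append(res.observed_stat)
        excluded.append(n_ex)
        reassigned.append(n_re)
        excl_gt.append(n_ex > res.observed_stat)
        reass_ge.append(n_re >= n_ex)
    return {
        "exceeding_all_involve_outlier_fraction": float(np.mean(involve)),
        "exclude_gt_observed_fraction": float(np.mean(excl_gt)),
        "reassign_ge_exclude_fraction": float(np.mean(reass_ge)),
        "observed": observed,
        "excluded": excluded,
        "reassigned": reassigned,
        "n": n_seeds,
    }


# ---------------------------------------------------------------------------
# direction asymmetry
# ---------------------------------------------------------------------------

def asymmetry_recovery(seed: int, n_seeds: int = 20) -> dict:
    """Fraction of genotype-DE fragments higher in ins at default conditions
    (planted: 85% of affected fragments lower in heterozygotes)."""
    child = _spawn_ints(seed, n_seeds)
    fracs = []
    for s in child:
        matrix, meta, _ = simulate_experiment(SimulationParams(seed=s))
        filt = filter_expressed(matrix)
        _, summary = contrasts.genotype_contrast(filt, meta)
        d = summary.per_threshold[0.01]
        if d["n_total_DE"]:
            fracs.append(d["n_higher_in_B"] / d["n_total_DE"])
    return {"mean_fraction_higher_in_ins": float(np.mean(fracs)),
            "per_seed": [float(f) for f in fracs], "n": n_seeds}


# ---------------------------------------------------------------------------
# righting response
# ---------------------------------------------------------------------------

def righting_recovery(seed: int, n_seeds: int = 40) -> dict:
    """Recomputes the wild/ins righting-time ratio through the behavior
    module on synthetic trials generated at the study conditions (five
    individuals per genotype, heterozygotes 1.8x faster on average)."""
    child = _spawn_ints(seed, n_seeds)
    ratios, pvals = [], []
    for s in child:
        table, geno = simulate_righting(5, 5, seed=s)
        kept, _ = behavior.filter_unresponsive(table)
        if kept["individual_id"].nunique() < 4:
            continue
        summary = behavior.righting_summary(kept)
        try:
            _, p, ratio = behavior.genotype_compare(summary, geno)
        except ValueError:
            continue
        ratios.append(ratio)
        pvals.append(p)
    return {"mean_ratio_wild_over_ins": float(np.mean(ratios)),
            "reject_fraction_alpha05": float(np.mean(np.array(pvals) < 0.05)),
            "n": len(ratios)}


# ---------------------------------------------------------------------------
# headline run at default conditions
# ---------------------------------------------------------------------------

def default_experiment(seed: int) -> dict:
    """One full analysis of a default synthetic experiment: genotype DE
    counts, direction split, temperature-responder counts, and the unsorted
    permutation percentile of the genotype partition."""
    matrix, meta, truth = simulate_experiment(SimulationParams(seed=seed))
    filt = filter_expressed(matrix)
    _, summary = contrasts.genotype_contrast(filt, meta, thresholds=(0.01, 1e-4))
    rw, sw = contrasts.temperature_response(filt, meta, "wild")
    ri, si = contrasts.temperature_response(filt, meta, "ins")
    un = permtest.unsorted_permutation_test(filt, meta, K=100, seed=seed)
    d01 = summary.per_threshold[0.01]
    return {
        "genotype_de_fdr01": d01["n_total_DE"],
        "genotype_de_fdr1e4": summary.per_threshold[1e-4]["n_total_DE"],
        "higher_in_ins_fdr01": d01["n_higher_in_B"],
        "temp_responders_wild_fdr01": sw.per_threshold[0.01]["n_total_DE"],
        "temp_responders_ins_fdr01": si.per_threshold[0.01]["n_total_DE"],
        "unsorted_percentile": un.percentile,
        "n_planted": int(len(truth.affected)),
    }
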