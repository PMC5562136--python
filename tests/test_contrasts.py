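import numpy as np
import pandas as pd
import pytest

import stardiff as sd
from stardiff import contrasts


@pytest.fixture(scope="module")
def genotype_run(ambient_contrast):
    matrix, wild, ins, truth = ambient_contrast
    meta_full = None
    return matrix, wild, ins, truth


def test_genotype_contrast_threshold_nesting(planted_sim):
    matrix, meta, _ = planted_sim
    filt = sd.filter_expressed(matrix)
    result, summary = contrasts.genotype_contrast(filt, meta, thresholds=(0.1, 0.01, 1e-4))
    ids = {t: contrasts.significant_ids(result, t) for t in (0.1, 0.01, 1e-4)}
    assert ids[1e-4] <= ids[0.01] <= ids[0.1]
    for t, d in summary.per_threshold.items():
        assert d["n_higher_in_A"] + d["n_higher_in_B"] == d["n_total_DE"]


def test_genotype_contrast_direction_asymmetry(planted_sim):
    matrix, meta, truth = planted_sim
    filt = sd.filter_expressed(matrix)
    result, summary = contrasts.genotype_contrast(filt, meta)
    d = summary.per_threshold[0.01]
    # planted: 85% of affected fragments lower in ins -> most DE higher in wild
    assert d["n_higher_in_A"] > d["n_higher_in_B"]


def test_positive_class_flip(planted_sim):
    matrix, meta, _ = planted_sim
    filt = sd.filter_expressed(matrix)
    r_ins, _ = contrasts.genotype_contrast(filt, meta)
    r_wild, _ = contrasts.genotype_contrast(filt, meta, positive_class="wild")
    assert np.allclose(r_ins["logFC"], -r_wild["logFC"])
    assert np.allclose(r_ins["pvalue"], r_wild["pvalue"])


def test_abundance_asymmetry_recovered():
    # plant down-in-ins fragments at high abundance: the higher-in-wild side
    # of the DE set should be the more abundant one
    params = sd.SimulationParams(n_fragments=500, seed=31, pi_de=0.06, asymmetry=1.0,
                                 library_size_log_mean=float(np.log(5e4)))
    matrix, meta, truth = sd.simulate_experiment(params)
    filt = sd.filter_expressed(matrix)
    result, summary = contrasts.genotype_contrast(filt, meta, thresholds=(0.05,))
    d = summary.per_threshold[0.05]
    if d["n_higher_in_B"] and d["n_higher_in_A"]:
        assert d["max_logCPM_higher_in_A"] >= d["max_logCPM_higher_in_B"] - 2.0


def test_temperature_nesting_and_counts(planted_sim):
    matrix, meta, truth = planted_sim
    filt = sd.filter_expressed(matrix)
    rw, sw = contrasts.temperature_response(filt, meta, "wild")
    ri, si = contrasts.temperature_response(filt, meta, "ins")
    for s in (sw, si):
        assert s.per_threshold[0.1]["n_total_DE"] >= s.per_threshold[0.01]["n_total_DE"]
    assert sw.per_threshold[0.01]["n_total_DE"] > si.per_threshold[0.01]["n_total_DE"]


def test_temperature_paired_variant(planted_sim):
    matrix, meta, _ = planted_sim
    filt = sd.filter_expressed(matrix)
    unpaired, su = contrasts.temperature_response(filt, meta, "wild")
    paired, sp = contrasts.temperature_response(filt, meta, "wild", paired=True)
    assert len(paired) == filt.n_fragments
    assert set(paired.columns) >= {"fragment_id", "logFC", "pvalue", "fdr"}
    # both routes should find temperature responders in wild
    assert sp.per_threshold[0.1]["n_total_DE"] > 0
    assert su.per_threshold[0.1]["n_total_DE"] > 0


def test_temperature_sign_recovered():
    # strongly down-shifted wild responders: mean logFC over significant loci < 0
    params = sd.SimulationParams(n_fragments=600, seed=41, temp_down_frac_wild=0.85,
                                 k_wild=40, library_size_log_mean=float(np.log(6e4)))
    matrix, meta, _ = sd.simulate_experiment(params)
    filt = sd.filter_expressed(matrix)
    _, sw = contrasts.temperature_response(filt, meta, "wild")
    assert sw.logfc_mean_sd_significant is not None
    assert sw.logfc_mean_sd_significant[0] < 0


def test_overlap():
    assert contrasts.overlap({"a", "b", "c"}, {"b", "c", "d"}) == 2
    assert contrasts.overlap({"a"}, {"b"}) == 0
    assert contrasts.overlap({"a", "b"}, {"a", "b", "c"}) == 2


def test_influence_exclude_and_reinclude_reproduce(planted_sim):
    matrix, meta, _ = planted_sim
    filt = sd.filter_expressed(matrix)
    base1 = contrasts.genotype_contrast(filt, meta)[1].per_threshold[0.01]["n_total_DE"]
    base2 = contrasts.genotype_contrast(filt, meta)[1].per_threshold[0.01]["n_total_DE"]
    assert base1 == base2  # pure function of inputs


def test_influence_validates(planted_sim):
    matrix, meta, _ = planted_sim
    filt = sd.filter_expressed(matrix)
    with pytest.raises(KeyError):
        contrasts.influence_analysis(filt, meta, "nope", "exclude")
    with pytest.raises(ValueError, match="mode"):
        lib = meta.libraries(genotype="wild", treatment="ambient")[0]
        contrasts.influence_analysis(filt, meta, lib, "drop")


def test_influence_outlier_behaviour():
    params = sd.SimulationParams(n_fragments=500, seed=51, outlier_library=True,
                                 library_size_log_mean=float(np.log(6e4)))
    matrix, meta, truth = sd.simulate_experiment(params)
    filt = sd.filter_expressed(matrix)
    obs = contrasts.genotype_contrast(filt, meta, thresholds=(0.01,))[1]
    n_obs = obs.per_threshold[0.01]["n_total_DE"]
    n_ex = contrasts.influence_analysis(filt, meta, truth.outlier_library_id, "exclude")[1]
    n_ex = n_ex.per_threshold[0.01]["n_total_DE"]
    assert n_ex > n_obs  # outlier removal sharpens the genotype contrast


def test_locus_report_ordering():
    df = pd.DataFrame(
        {
            "fragment_id": ["a", "b", "c", "d"],
            "logFC": [1.0, -3.0, 2.0, 0.5],
            "logCPM": [1.0] * 4,
            "pvalue": [0.01, 0.001, 0.001, 0.5],
            "fdr": [0.02, 0.004, 0.004, 0.5],
        }
    )
    out = contrasts.locus_report(df)
    assert out["fragment_id"].tolist() == ["b", "c", "a", "d"]  # fdr ties: larger |logFC| first
    assert len(out) == len(df)
    assert "neg_log10_p" in out.columns
    out2 = contrasts.locus_report(df, annotations={"a": "gi:1"})
    assert out2.loc[out2["fragment_id"] == "a", "annotation"].iloc[0] == "gi:1"
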