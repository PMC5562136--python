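"""Synthetic experiment generator with ground truth for recovery tests.

Emulates the study design the pipeline targets: five individuals per EF1A
genotype (wild homozygote vs ins heterozygote), each sequenced at ambient
and after elevated (+3 degC) temperature, NB-distributed counts over a
log-normal baseline abundance profile, a small planted set of
genotype-affected fragments with strongly asymmetric direction (most lower
in heterozygotes), genotype-specific temperature responders, and an
optional "recombinant" individual labelled wild whose expression follows
the ins class (the Po5 mimic).

A single seed expands into per-stage substreams so that, e.g., the count
draw does not shift when only the righting table is regenerated.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .behavior import PERIODS
from .io import CountMatrix, LibraryMeta


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Generator settings; defaults emulate the study conditions."""

    n_per_genotype: int = 5
    n_fragments: int = 2000
    library_size_log_mean: float = float(np.log(2e5))
    library_size_log_sd: float = 0.15
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    dispersion: float = 0.15         # phi0: variance = mu + phi*mu^2
    dispersion_log_sd: float = 0.4   # lognormal spread of per-fragment phi
    pi_de: float = 0.02              # fraction of genotype-affected fragments
    asymmetry: float = 0.85          # fraction of affected lower in ins (rho)
    logfc_mean: float = 2.0          # |log2 FC| of genotype effects
    logfc_sd: float = 0.0
    k_wild: int = 46                 # temperature responders per genotype
    k_ins: int = 6
    temp_logfc: float = 2.0
    temp_down_frac_wild: float = 0.61
    temp_down_frac_ins: float = 0.43
    outlier_library: bool = False
    outlier_strength: float = 0.85  # fraction of the ins log-effect the outlier shows
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi_de <= 1.0 and 0.0 <= self.asymmetry <= 1.0):
            raise ValueError("pi_de and asymmetry must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_fragments < 1 or self.n_per_genotype < 2:
            raise ValueError("need >=1 fragment and >=2 individuals per genotype")
        for name in ("library_size_log_mean", "library_size_log_sd", "baseline_log_mean",
                     "baseline_log_sd", "logfc_mean", "logfc_sd", "temp_logfc"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclasses.dataclass(frozen=True)
class SimulationTruth:
    """Planted effects, for recovery tests against pipeline output."""

    affected: pd.DataFrame          # fragment_id, log2fc (ins over wild, signed)
    temp_wild: pd.DataFrame         # fragment_id, log2fc (elevated over ambient)
    temp_ins: pd.DataFrame
    outlier_individual_id: str | None
    outlier_library_id: str | None  # the outlier's ambient library
    dispersion: pd.Series | None = None  # true per-fragment phi, indexed by fragment id

    @property
    def affected_fragments(self) -> set[str]:
        return set(self.affected["fragment_id"])


def _library_id(individual: str, treatment: str) -> str:
    return f"{individual}_{treatment}"


def simulate_experiment(params: SimulationParams) -> tuple[CountMatrix, LibraryMeta, SimulationTruth]:
    """Draw one synthetic experiment (counts, metadata, ground truth)."""
    ss = np.random.SeedSequence(params.seed).spawn(4)
    rng_design, rng_effects, rng_counts, _ = (np.random.default_rng(s) for s in ss)
    G, n = params.n_fragments, params.n_per_genotype

    frag_ids = [f"TRINITY_DN{g}_c0_g1_i1" for g in range(G)]
    wild_inds = [f"w{k+1}" for k in range(n)]
    ins_inds = [f"i{k+1}" for k in range(n)]
    meta_rows = []
    for geno, inds in (("wild", wild_inds), ("ins", ins_inds)):
        for ind in inds:
            for tr in ("ambient", "elevated"):
                meta_rows.append((_library_id(ind, tr), ind, geno, tr))
    meta = LibraryMeta(pd.DataFrame(meta_rows,
                                    columns=["library_id", "individual_id", "genotype", "treatment"]))

    # baseline relative abundance and per-fragment dispersion
    base = rng_design.lognormal(params.baseline_log_mean, params.baseline_log_sd, size=G)
    props = base / base.sum()
    phi = params.dispersion * rng_design.lognormal(0.0, params.dispersion_log_sd, size=G)

    # planted genotype effects (multiplier applied to the ins class)
    n_aff = int(round(params.pi_de * G))
    aff_idx = rng_effects.choice(G, size=n_aff, replace=False)
    down = rng_effects.random(n_aff) < params.asymmetry
    mag = np.abs(params.logfc_mean + params.logfc_sd * rng_effects.standard_normal(n_aff))
    aff_log2fc = np.where(down, -mag, mag)
    geno_mult_ins = np.ones(G)
    geno_mult_ins[aff_idx] = 2.0 ** aff_log2fc

    # genotype-specific temperature responders (multiplier on elevated libraries)
    def _temp_set(k: int, down_frac: float) -> tuple[np.ndarray, np.ndarray]:
        idx = rng_effects.choice(G, size=min(k, G), replace=False)
        sign = np.where(rng_effects.random(idx.size) < down_frac, -1.0, 1.0)
        return idx, sign * params.temp_logfc

    tw_idx, tw_log2fc = _temp_set(params.k_wild, params.temp_down_frac_wild)
    ti_idx, ti_log2fc = _temp_set(params.k_ins, params.temp_down_frac_ins)
    temp_mult = {"wild": np.ones(G), "ins": np.ones(G)}
    temp_mult["wild"][tw_idx] = 2.0 ** tw_log2fc
    temp_mult["ins"][ti_idx] = 2.0 ** ti_log2fc

    outlier_ind = wild_inds[0] if params.outlier_library else None

    lib_ids = meta.table["library_id"].tolist()
    sizes = rng_counts.lognormal(params.library_size_log_mean, params.library_size_log_sd,
                                 size=len(lib_ids))
    counts = np.empty((G, len(lib_ids)), dtype=np.int64)
    for j, (_, row) in enumerate(meta.table.iterrows()):
        geno = row["genotype"]
        if geno == "ins":
            mult = geno_mult_ins
        elif outlier_ind is not None and row["individual_id"] == outlier_ind:
            # wild-labelled but ins-like at the genotype-effect fragments
            mult = geno_mult_ins ** params.outlier_strength
        else:
            mult = np.ones(G)
        tmult = temp_mult[geno] if row["treatment"] == "elevated" else 1.0
        mu = sizes[j] * props * mult * tmult
        r = 1.0 / phi
        counts[:, j] = rng_counts.negative_binomial(r, r / (r + np.maximum(mu, 1e-12)))

    matrix = CountMatrix(tuple(frag_ids), tuple(lib_ids), counts)
    truth = SimulationTruth(
        affected=pd.DataFrame({"fragment_id": [frag_ids[i] for i in aff_idx],
                               "log2fc": aff_log2fc}),
        temp_wild=pd.DataFrame({"fragment_id": [frag_ids[i] for i in tw_idx],
                                "log2fc": tw_log2fc}),
        temp_ins=pd.DataFrame({"fragment_id": [frag_ids[i] for i in ti_idx],
                               "log2fc": ti_log2fc}),
        outlier_individual_id=outlier_ind,
        outlier_library_id=_library_id(outlier_ind, "ambient") if outlier_ind else None,
        dispersion=pd.Series(phi, index=frag_ids),
    )
    return matrix, meta, truth


def simulate_righting(
    n_ins: int,
    n_wild: int,
    ratio: float = 1.8,
    noise_sd: float = 0.25,
    seed: int = 0,
    base_time_ins: float = 400.0,
    n_replicates: int = 3,
    unresponsive_prob: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic righting-response trials for both genotype classes.

    Wild times average ``ratio`` x the ins times (heterozygotes right
    faster); three trial periods with a mild slowdown at elevated
    temperature; log-normal noise of scale ``noise_sd``; occasional trials
    exceed the 1-h cutoff with probability ``unresponsive_prob``.  Returns
    (righting table, individual genotype table).
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
    period_mult = {"ambient_pre": 1.0, "elevated": 1.2, "ambient_post": 1.0}
    rows, geno_rows = [], []
    for geno, n_ind, base in (("ins", n_ins, base_time_ins),
                              ("wild", n_wild, ratio * base_time_ins)):
        for k in range(n_ind):
            ind = f"r{geno[0]}{k+1}"
            geno_rows.append({"individual_id": ind, "genotype": geno})
            ind_effect = float(np.exp(noise_sd * rng.standard_normal())) if noise_sd else 1.0
            for period in PERIODS:
                for rep in range(1, n_replicates + 1):
                    noise = float(np.exp(noise_sd * rng.standard_normal())) if noise_sd else 1.0
                    t = base * period_mult[period] * ind_effect * noise
                    if unresponsive_prob and rng.random() < unresponsive_prob:
                        t = 3600.0 * (1.1 + rng.random())
                    rows.append({"individual_id": ind, "period": period,
                                 "replicate": rep, "time_s": float(t)})
    return pd.DataFrame(rows), pd.DataFrame(geno_rows)


def make_feature_map(
    n_genes: int,
    isoforms_per_gene: int,
    homology_sharing: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Trinity-style feature map: transcripts -> clusters/genes/homology ids.

    Genes pair up into clusters (two genes per cluster where possible);
    a ``homology_sharing`` fraction of genes is grouped into shared
    homology ids (two genes per id) and a further fraction stays
    unannotated, so homology collapse strictly reduces the row count while
    keeping unannotated genes.
    """
    if n_genes < 1 or isoforms_per_gene < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    genes = []
    for g in range(n_genes):
        cluster = f"TRINITY_DN{g // 2}_c0"
        gene = f"{cluster}_g{g % 2 + 1}"
        genes.append((gene, cluster))
        for i in range(1, isoforms_per_gene + 1):
            rows.append({"transcript_id": f"{gene}_i{i}", "cluster_id": cluster,
                         "gene_id": gene, "homology_id": ""})
    n_shared = 2 * int(round(homology_sharing * n_genes / 2))
    shared = rng.choice(n_genes, size=n_shared, replace=False)
    fmap = pd.DataFrame(rows)
    for m in range(0, n_shared, 2):
        gid = f"gi:{1000 + m // 2}"
        for gsel in shared[m:m + 2]:
            fmap.loc[fmap["gene_id"] == genes[gsel][0], "homology_id"] = gid
    return fmap
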