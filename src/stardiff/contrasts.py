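"""Reported summaries: genotype DE counts, direction asymmetry, abundance of
DE sets, temperature-response contrasts, set overlap, and outlier-library
influence analyses.

Sign convention: class A = wild, class B = ins, so positive logFC means
higher expression in *ins* heterozygotes.  ``positive_class='wild'`` flips
the orientation for display.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import de
from .io import CountMatrix, LibraryMeta


@dataclasses.dataclass(frozen=True)
class ContrastSummary:
    """Per-threshold DE counts and direction/abundance breakdown."""

    thresholds: tuple[float, ...]
    per_threshold: dict[float, dict]
    logfc_mean_sd_significant: tuple[float, float] | None = None
    logfc_mean_sd_all: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "thresholds": list(self.thresholds),
            "per_threshold": {str(t): v for t, v in self.per_threshold.items()},
            "logfc_mean_sd_significant": self.logfc_mean_sd_significant,
            "logfc_mean_sd_all": self.logfc_mean_sd_all,
        }


def summarize_de(
    result: pd.DataFrame,
    thresholds,
    logfc_threshold_for_mean: float | None = None,
) -> ContrastSummary:
    """Direction split and per-side abundance at each FDR threshold.

    ``n_higher_in_B`` counts significant fragments with logFC > 0 (higher
    in ins under the default orientation).
    """
    thresholds = tuple(sorted(thresholds, reverse=True))
    per: dict[float, dict] = {}
    for t in thresholds:
        sig = result[result["fdr"] < t]
        up_b = sig[sig["logFC"] > 0]
        up_a = sig[sig["logFC"] <= 0]
        per[t] = {
            "n_total_DE": int(len(sig)),
            "n_higher_in_B": int(len(up_b)),
            "n_higher_in_A": int(len(up_a)),
            "mean_logCPM_higher_in_B": float(up_b["logCPM"].mean()) if len(up_b) else None,
            "mean_logCPM_higher_in_A": float(up_a["logCPM"].mean()) if len(up_a) else None,
            "max_logCPM_higher_in_B": float(up_b["logCPM"].max()) if len(up_b) else None,
            "max_logCPM_higher_in_A": float(up_a["logCPM"].max()) if len(up_a) else None,
        }
    t0 = logfc_threshold_for_mean if logfc_threshold_for_mean is not None else min(thresholds)
    sig = result[result["fdr"] < t0]
    mean_sd_sig = (
        (float(sig["logFC"].mean()), float(sig["logFC"].std(ddof=1))) if len(sig) else None
    )
    mean_sd_all = (float(result["logFC"].mean()), float(result["logFC"].std(ddof=1)))
    return ContrastSummary(thresholds, per, mean_sd_sig, mean_sd_all)


def genotype_contrast(
    matrix: CountMatrix,
    meta: LibraryMeta,
    thresholds=(0.01, 1e-4),
    treatment: str | None = "ambient",
    dispersion: str = "tagwise",
    positive_class: str = "ins",
) -> tuple[pd.DataFrame, ContrastSummary]:
    """Wild-vs-ins DE on one treatment's libraries (default: ambient).

    The default orientation reports logFC of ins over wild; pass
    ``positive_class='wild'`` to flip signs for display.
    """
    wild = meta.libraries(genotype="wild", treatment=treatment)
    ins = meta.libraries(genotype="ins", treatment=treatment)
    if not wild or not ins:
        raise ValueError("both genotypes must be present")
    result = de.two_group_de(matrix, wild, ins, dispersion=dispersion)
    if positive_class == "wild":
        result = result.assign(logFC=-result["logFC"])
    summary = summarize_de(result, thresholds)
    return result, summary


def temperature_response(
    matrix: CountMatrix,
    meta: LibraryMeta,
    genotype: str,
    thresholds=(0.01, 0.1),
    paired: bool = False,
    dispersion: str = "tagwise",
) -> tuple[pd.DataFrame, ContrastSummary]:
    """Ambient-vs-elevated DE within one genotype.

    Unpaired: the exact conditional test with treatment as the class label
    (positive logFC = higher at elevated temperature).  Paired: the NB
    likelihood-ratio test blocking on individual, with dispersions from the
    treatment grouping.
    """
    sub_meta = meta.subset(meta.libraries(genotype=genotype))
    amb = sub_meta.libraries(treatment="ambient")
    ele = sub_meta.libraries(treatment="elevated")
    if not amb or not ele:
        raise ValueError(f"genotype {genotype!r} lacks one of the treatments")
    if not paired:
        result = de.two_group_de(matrix, amb, ele, dispersion=dispersion)
    else:
        fit = de.fit_two_group(matrix, amb, ele)
        phi = (
            fit.dispersions.tagwise
            if dispersion == "tagwise"
            else np.full(matrix.n_fragments, fit.dispersions.common)
        )
        result = de.paired_lrt(matrix, sub_meta, phi)
    summary = summarize_de(result, thresholds, logfc_threshold_for_mean=min(thresholds))
    return result, summary


def overlap(ids_a, ids_b) -> int:
    """Size of the intersection of two fragment-id sets."""
    return len(set(ids_a) & set(ids_b))


def significant_ids(result: pd.DataFrame, alpha: float) -> set[str]:
    return set(result.loc[result["fdr"] < alpha, "fragment_id"])


def influence_analysis(
    matrix: CountMatrix,
    meta: LibraryMeta,
    library_id: str,
    mode: str,
    alpha: float = 0.01,
    treatment: str | None = "ambient",
    dispersion: str = "tagwise",
) -> tuple[pd.DataFrame, ContrastSummary]:
    """Genotype contrast with one library excluded or genotype-reassigned.

    ``exclude`` drops the library; ``reassign`` flips its genotype label.
    The DE counts are comparable with the observed-partition contrast.
    """
    if mode not in ("exclude", "reassign"):
        raise ValueError("mode must be 'exclude' or 'reassign'")
    all_libs = set(meta.table["library_id"])
    if library_id not in all_libs:
        raise KeyError(f"unknown library id {library_id!r}")
    if mode == "exclude":
        keep = [l for l in meta.table["library_id"] if l != library_id]
        new_meta = meta.subset(keep)
        geno = meta.genotype_of(library_id)
        if len(new_meta.libraries(genotype=geno, treatment=treatment)) < 2:
            raise ValueError("exclusion would leave fewer than 2 libraries in a class")
    else:
        current = meta.genotype_of(library_id)
        flipped = "ins" if current == "wild" else "wild"
        new_meta = meta.with_genotype(library_id, flipped)
    return genotype_contrast(
        matrix, new_meta, thresholds=(alpha,), treatment=treatment, dispersion=dispersion
    )


def locus_report(de_result: pd.DataFrame, annotations: dict | None = None) -> pd.DataFrame:
    """Plot-ready ranked table: sorted by FDR, ties broken by larger |logFC|."""
    out = de_result.copy()
    out["neg_log10_p"] = -np.log10(out["pvalue"])
    out["abs_logFC"] = out["logFC"].abs()
    out = out.sort_values(["fdr", "abs_logFC"], ascending=[True, False], kind="mergesort")
    out = out.drop(columns=["abs_logFC"]).reset_index(drop=True)
    if annotations:
        out["annotation"] = out["fragment_id"].map(annotations).fillna("")
    return out
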