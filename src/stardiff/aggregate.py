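"""Collapse transcript-level counts to cluster, gene, or homology level.

Trinity names transcripts hierarchically (``<prefix>_c<N>_g<N>_i<N>``):
isoforms nest in genes, genes in clusters.  Collapsing sums counts within
a group, so per-library totals are conserved at every level.  At the
homology level, rows without a homology annotation keep their gene id as
the row key, so unannotated genes survive the collapse.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .io import CountMatrix

_TRINITY_RE = re.compile(r"^(?P<cluster>.+_c\d+)_g(?P<gene>\d+)_i(?P<iso>\d+)$")
_GENE_RE = re.compile(r"^.+_c\d+_g\d+$")
_CLUSTER_RE = re.compile(r"^.+_c\d+$")

LEVELS = ("cluster", "gene", "homology")


class TrinityIdError(ValueError):
    """Transcript id does not follow the <prefix>_c<N>_g<N>_i<N> convention."""


def parse_trinity_id(transcript_id: str) -> tuple[str, str, int]:
    """Split a Trinity-style id into (cluster_id, gene_id, isoform_index)."""
    m = _TRINITY_RE.match(transcript_id)
    if m is None:
        raise TrinityIdError(f"not a Trinity-style transcript id: {transcript_id!r}")
    cluster = m.group("cluster")
    gene = f"{cluster}_g{m.group('gene')}"
    return cluster, gene, int(m.group("iso"))


def feature_map_from_ids(transcript_ids) -> pd.DataFrame:
    """Build a cluster/gene feature map by parsing Trinity ids (no homology)."""
    rows = []
    for t in transcript_ids:
        cluster, gene, _ = parse_trinity_id(t)
        rows.append((t, cluster, gene, ""))
    return pd.DataFrame(rows, columns=["transcript_id", "cluster_id", "gene_id", "homology_id"])


def collapse_counts(matrix: CountMatrix, fmap: pd.DataFrame | None, level: str) -> CountMatrix:
    """Sum counts within each group at the requested level.

    ``fmap`` maps transcript_id to cluster_id/gene_id/homology_id.  When it
    is None and level is cluster or gene, ids are derived by parsing the
    Trinity naming convention.  Output row order is first-appearance order
    of group ids.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    keys = _group_keys(matrix, fmap, level)
    order: dict[str, int] = {}
    idx = np.empty(matrix.n_fragments, dtype=np.intp)
    for i, key in enumerate(keys):
        if key not in order:
            order[key] = len(order)
        idx[i] = order[key]
    out = np.zeros((len(order), matrix.n_libraries), dtype=np.int64)
    np.add.at(out, idx, matrix.counts)
    return CountMatrix(tuple(order.keys()), matrix.library_ids, out)


def _group_keys(matrix: CountMatrix, fmap: pd.DataFrame | None, level: str) -> list[str]:
    if fmap is None:
        if level == "homology":
            raise ValueError("homology collapse requires a feature map")
        return [_derive_key(t, level) for t in matrix.fragment_ids]

    fmap = fmap.fillna("")
    lookup = fmap.set_index("transcript_id")
    missing = [t for t in matrix.fragment_ids if t not in lookup.index]
    if missing:
        if level == "gene":
            # fall back to Trinity parsing for unmapped rows
            pass
        else:
            raise KeyError(
                f"{len(missing)} fragment ids missing from feature map "
                f"(first offenders: {missing[:5]})"
            )
    keys = []
    for t in matrix.fragment_ids:
        if t in lookup.index:
            row = lookup.loc[t]
            if level == "cluster":
                key = str(row.get("cluster_id", "")) or parse_trinity_id(t)[0]
            elif level == "gene":
                key = str(row["gene_id"])
            else:
                hom = str(row.get("homology_id", ""))
                key = hom if hom else str(row["gene_id"])
        else:
            key = _derive_key(t, level)
        keys.append(key)
    return keys


def _derive_key(transcript_id: str, level: str) -> str:
    """Cluster/gene key from a Trinity-style id; already-collapsed ids map to
    themselves, which makes collapse idempotent at its own level."""
    try:
        cluster, gene, _ = parse_trinity_id(transcript_id)
    except TrinityIdError:
        if _GENE_RE.match(transcript_id):
            cluster = transcript_id.rsplit("_g", 1)[0]
            gene = transcript_id
        elif _CLUSTER_RE.match(transcript_id) and level == "cluster":
            return transcript_id
        else:
            raise
    return cluster if level == "cluster" else gene
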