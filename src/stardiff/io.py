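"""Tabular readers/writers and the pipeline's core containers.

All tables are tab-delimited UTF-8 text with '.' as the decimal mark,
matching the count-file idiom of upstream RNA-seq quantifiers.  Run
summaries are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("wild", "ins")
TREATMENTS = ("ambient", "elevated")


class FormatError(ValueError):
    """A file violated the expected tabular format."""


@dataclasses.dataclass(frozen=True)
class CountMatrix:
    """Fragments x libraries matrix of non-negative integer read counts.

    ``counts`` has one row per fragment and one column per library; row and
    column order is preserved from the source file and is significant
    (group partitions index into columns).
    """

    fragment_ids: tuple[str, ...]
    library_ids: tuple[str, ...]
    counts: np.ndarray  # shape (n_fragments, n_libraries)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.fragment_ids), len(self.library_ids)):
            raise FormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.fragment_ids)} fragments x {len(self.library_ids)} libraries"
            )
        if len(set(self.fragment_ids)) != len(self.fragment_ids):
            dup = _first_duplicate(self.fragment_ids)
            raise FormatError(f"duplicate fragment id {dup!r}")
        if len(set(self.library_ids)) != len(self.library_ids):
            dup = _first_duplicate(self.library_ids)
            raise FormatError(f"duplicate library id {dup!r}")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise FormatError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count at fragment {self.fragment_ids[i]!r}, "
                f"library {self.library_ids[j]!r}"
            )
        object.__setattr__(self, "counts", np.ascontiguousarray(counts, dtype=np.int64))
        object.__setattr__(self, "fragment_ids", tuple(self.fragment_ids))
        object.__setattr__(self, "library_ids", tuple(self.library_ids))

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_ids)

    @property
    def n_libraries(self) -> int:
        return len(self.library_ids)

    @property
    def library_sizes(self) -> np.ndarray:
        """Column sums (total counts per library)."""
        return self.counts.sum(axis=0)

    def library_index(self, library_ids: Iterable[str]) -> np.ndarray:
        pos = {lib: k for k, lib in enumerate(self.library_ids)}
        try:
            return np.array([pos[l] for l in library_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown library id {exc.args[0]!r}") from None

    def select_libraries(self, library_ids: Sequence[str]) -> "CountMatrix":
        idx = self.library_index(library_ids)
        return CountMatrix(self.fragment_ids, tuple(library_ids), self.counts[:, idx])

    def select_fragments(self, keep: np.ndarray) -> "CountMatrix":
        """Subset rows by a boolean mask or integer index, preserving order."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        frags = tuple(self.fragment_ids[i] for i in keep)
        return CountMatrix(frags, self.library_ids, self.counts[keep, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.fragment_ids), columns=list(self.library_ids)
        )


@dataclasses.dataclass(frozen=True)
class LibraryMeta:
    """Per-library annotations defining contrasts and pairing.

    One row per library: genotype in {wild, ins}, treatment in
    {ambient, elevated}, and the individual the library was sampled from.
    An individual contributes at most one library per treatment and keeps
    one genotype throughout.
    """

    table: pd.DataFrame  # columns: library_id, individual_id, genotype, treatment

    def __post_init__(self) -> None:
        t = self.table.copy()
        required = ["library_id", "individual_id", "genotype", "treatment"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        t = t[required].astype(str)
        t["genotype"] = t["genotype"].str.strip().str.lower()
        t["treatment"] = t["treatment"].str.strip().str.lower()
        bad = t.loc[~t["genotype"].isin(GENOTYPES), "genotype"]
        if len(bad):
            raise FormatError(f"unknown genotype {bad.iloc[0]!r} (expected one of {GENOTYPES})")
        bad = t.loc[~t["treatment"].isin(TREATMENTS), "treatment"]
        if len(bad):
            raise FormatError(f"unknown treatment {bad.iloc[0]!r} (expected one of {TREATMENTS})")
        if t["library_id"].duplicated().any():
            dup = t.loc[t["library_id"].duplicated(), "library_id"].iloc[0]
            raise FormatError(f"duplicate library id {dup!r}")
        dup_pair = t.duplicated(subset=["individual_id", "treatment"])
        if dup_pair.any():
            row = t.loc[dup_pair].iloc[0]
            raise FormatError(
                f"individual {row['individual_id']!r} has more than one "
                f"{row['treatment']!r} library"
            )
        geno_per_ind = t.groupby("individual_id")["genotype"].nunique()
        if (geno_per_ind > 1).any():
            ind = geno_per_ind[geno_per_ind > 1].index[0]
            raise FormatError(f"individual {ind!r} has inconsistent genotypes")
        t = t.reset_index(drop=True)
        object.__setattr__(self, "table", t)

    def libraries(self, genotype: str | None = None, treatment: str | None = None) -> list[str]:
        t = self.table
        if genotype is not None:
            t = t[t["genotype"] == genotype]
        if treatment is not None:
            t = t[t["treatment"] == treatment]
        return list(t["library_id"])

    def genotype_of(self, library_id: str) -> str:
        row = self.table[self.table["library_id"] == library_id]
        if row.empty:
            raise KeyError(f"unknown library id {library_id!r}")
        return row["genotype"].iloc[0]

    def individual_of(self, library_id: str) -> str:
        row = self.table[self.table["library_id"] == library_id]
        if row.empty:
            raise KeyError(f"unknown library id {library_id!r}")
        return row["individual_id"].iloc[0]

    def subset(self, library_ids: Sequence[str]) -> "LibraryMeta":
        t = self.table[self.table["library_id"].isin(set(library_ids))]
        return LibraryMeta(t)

    def with_genotype(self, library_id: str, genotype: str) -> "LibraryMeta":
        """Return a copy with one library's genotype label replaced."""
        if library_id not in set(self.table["library_id"]):
            raise KeyError(f"unknown library id {library_id!r}")
        t = self.table.copy()
        # Reassignment severs the library from its individual's other samples so
        # the genotype-constancy invariant still holds for diagnostics runs.
        mask = t["library_id"] == library_id
        t.loc[mask, "genotype"] = genotype
        t.loc[mask, "individual_id"] = t.loc[mask, "individual_id"] + "_reassigned"
        return LibraryMeta(t)


def read_counts(path: str | Path) -> CountMatrix:
    """Read a counts TSV: first column fragment id, header row of library ids."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse counts TSV: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate fragment id {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals)) | (vals < 0)
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-integer or negative count at fragment {row!r}, library {col!r}"
            )
        df[col] = vals.astype(np.int64)
    return CountMatrix(
        tuple(str(i) for i in df.index),
        tuple(str(c) for c in df.columns),
        df.to_numpy(dtype=np.int64),
    )


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="fragment_id")


def read_metadata(path: str | Path) -> LibraryMeta:
    """Read the library metadata TSV (library_id, individual_id, genotype, treatment)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse metadata TSV: {exc}") from exc
    return LibraryMeta(df)


def write_metadata(meta: LibraryMeta, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_feature_map(path: str | Path) -> pd.DataFrame:
    """Read a feature map TSV (transcript_id, gene_id, optional cluster_id/homology_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "transcript_id" not in df.columns or "gene_id" not in df.columns:
        raise FormatError(f"{path}: feature map needs transcript_id and gene_id columns")
    if df["transcript_id"].duplicated().any():
        dup = df.loc[df["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise FormatError(f"{path}: duplicate transcript id {dup!r}")
    return df


def write_feature_map(fmap: pd.DataFrame, path: str | Path) -> None:
    fmap.to_csv(path, sep="\t", index=False)


def read_righting(path: str | Path) -> pd.DataFrame:
    """Read a righting-response TSV (individual_id, period, replicate, time_s)."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "period": str})
    need = {"individual_id", "period", "replicate", "time_s"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: righting table needs columns {sorted(need)}")
    return df


def write_de_result(result: pd.DataFrame, path: str | Path) -> None:
    result.to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset, tuple)):
        return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _first_duplicate(items: Iterable[str]) -> str:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""
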