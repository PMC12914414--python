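"""Readers and writers for every on-disk format the pipeline touches.

All tabular formats are plain TSV (tab-separated, UTF-8, mandatory header
row, no quoting, ``NA`` for missing values, floats serialised at repr
precision) so that write→read→write round trips are byte-identical.
Single-cell count matrices use the MatrixMarket coordinate triplet
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``); genomic intervals
are BED-convention 0-based half-open.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """A file violates the format contract (names the offending record)."""


@dataclass
class CountMatrix:
    """Integer gene × unit count matrix with unit metadata.

    Units are bulk samples or single cells/nuclei. ``unit_meta`` is indexed
    by ``unit_ids`` and typically carries library / condition / schedule
    columns.
    """

    values: np.ndarray  # genes × units, non-negative integers
    gene_ids: np.ndarray  # unique strings
    unit_ids: np.ndarray  # unique strings
    unit_meta: pd.DataFrame = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.unit_ids = np.asarray(self.unit_ids, dtype=object)
        if self.values.ndim != 2:
            raise FormatError("count matrix must be 2-dimensional")
        if not np.issubdtype(self.values.dtype, np.integer):
            if np.any(self.values != np.floor(self.values)):
                bad = np.argwhere(self.values != np.floor(self.values))[0]
                raise FormatError(
                    f"non-integer count at gene {self.gene_ids[bad[0]]!r}, "
                    f"unit {self.unit_ids[bad[1]]!r}"
                )
            self.values = self.values.astype(np.int64)
        if self.values.size and self.values.min() < 0:
            g, u = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative count at gene {self.gene_ids[g]!r}, unit {self.unit_ids[u]!r}"
            )
        if self.values.shape != (len(self.gene_ids), len(self.unit_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} gene ids and {len(self.unit_ids)} unit ids"
            )
        for name, ids in (("gene", self.gene_ids), ("unit", self.unit_ids)):
            if len(set(ids)) != len(ids):
                seen, dup = set(), None
                for i in ids:
                    if i in seen:
                        dup = i
                        break
                    seen.add(i)
                raise FormatError(f"duplicate {name} id {dup!r}")
        if self.unit_meta is None:
            self.unit_meta = pd.DataFrame(index=pd.Index(self.unit_ids, name="unit_id"))
        else:
            self.unit_meta = self.unit_meta.loc[list(self.unit_ids)]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    def subset_units(self, keep: "list[str] | np.ndarray") -> "CountMatrix":
        keep = list(keep)
        pos = pd.Index(self.unit_ids).get_indexer(keep)
        if (pos < 0).any():
            missing = [k for k, p in zip(keep, pos) if p < 0]
            raise KeyError(f"unknown unit ids: {missing[:5]}")
        return CountMatrix(
            self.values[:, pos], self.gene_ids, np.asarray(keep, dtype=object),
            self.unit_meta.loc[keep],
        )

    def subset_genes(self, keep: "list[str] | np.ndarray") -> "CountMatrix":
        keep = list(keep)
        pos = pd.Index(self.gene_ids).get_indexer(keep)
        if (pos < 0).any():
            missing = [k for k, p in zip(keep, pos) if p < 0]
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        return CountMatrix(
            self.values[pos, :], np.asarray(keep, dtype=object), self.unit_ids,
            self.unit_meta,
        )


@dataclass
class GeneSignature:
    """A named, directed gene list scored by summed scaled expression."""

    name: str
    direction: str  # "induced" or "repressed"
    genes: frozenset

    def __post_init__(self) -> None:
        if self.direction not in ("induced", "repressed"):
            raise FormatError(
                f"unknown signature direction {self.direction!r} in {self.name!r}"
            )
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise FormatError(f"signature {self.name!r} is empty")


@dataclass
class EnhancerTable:
    """Enhancer intervals (0-based half-open) with per-condition tag densities."""

    table: pd.DataFrame  # chrom, start, end, enhancer_id, <mark>_<condition>...

    def __post_init__(self) -> None:
        t = self.table
        for col in ("chrom", "start", "end", "enhancer_id"):
            if col not in t.columns:
                raise FormatError(f"enhancer table missing column {col!r}")
        bad = t.index[t["start"] >= t["end"]]
        if len(bad):
            row = t.loc[bad[0]]
            raise FormatError(
                f"empty or inverted interval for enhancer {row['enhancer_id']!r}: "
                f"[{row['start']}, {row['end']})"
            )
        tag_cols = self.tag_columns
        if tag_cols and (t[tag_cols].to_numpy(dtype=float) < 0).any():
            raise FormatError("negative tag density in enhancer table")

    @property
    def tag_columns(self) -> list:
        return [c for c in self.table.columns
                if c not in ("chrom", "start", "end", "enhancer_id")]


@dataclass
class TssTable:
    """One TSS coordinate per gene (strand stored, unused in distances)."""

    table: pd.DataFrame  # gene_id, chrom, tss_pos, strand

    def __post_init__(self) -> None:
        for col in ("gene_id", "chrom", "tss_pos", "strand"):
            if col not in self.table.columns:
                raise FormatError(f"TSS table missing column {col!r}")
        if self.table["gene_id"].duplicated().any():
            dup = self.table["gene_id"][self.table["gene_id"].duplicated()].iloc[0]
            raise FormatError(f"duplicate gene id {dup!r} in TSS table")


DE_COLUMNS = ["gene_id", "base_mean", "log2fc", "se", "stat", "p", "padj"]


# ---------------------------------------------------------------------------
# MatrixMarket bundle


def write_mtx_bundle(m: CountMatrix, outdir: "str | Path") -> None:
    """Write ``matrix.mtx`` (genes × cells), ``features.tsv``, ``barcodes.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coo = scipy.sparse.coo_matrix(m.values)
    buf = _stdio.BytesIO()
    scipy.io.mmwrite(buf, coo, field="integer")
    (outdir / "matrix.mtx").write_bytes(buf.getvalue())
    (outdir / "features.tsv").write_text("".join(f"{g}\n" for g in m.gene_ids))
    (outdir / "barcodes.tsv").write_text("".join(f"{b}\n" for b in m.unit_ids))
    if len(m.unit_meta.columns):
        write_table(m.unit_meta.reset_index(names="unit_id"), outdir / "unit_meta.tsv")


def read_mtx_bundle(indir: "str | Path") -> CountMatrix:
    indir = Path(indir)
    try:
        mat = scipy.io.mmread(indir / "matrix.mtx")
    except Exception as e:  # scipy raises bare ValueError on malformed files
        raise FormatError(f"cannot parse {indir / 'matrix.mtx'}: {e}") from e
    mat = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
    genes = [ln.split("\t")[0] for ln in
             (indir / "features.tsv").read_text().splitlines() if ln]
    cells = [ln.split("\t")[0] for ln in
             (indir / "barcodes.tsv").read_text().splitlines() if ln]
    if len(genes) != mat.shape[0]:
        raise FormatError(
            f"features.tsv has {len(genes)} rows but matrix declares {mat.shape[0]} genes"
        )
    if len(cells) != mat.shape[1]:
        raise FormatError(
            f"barcodes.tsv has {len(cells)} rows but matrix declares {mat.shape[1]} columns"
        )
    meta = None
    if (indir / "unit_meta.tsv").exists():
        meta = pd.read_csv(indir / "unit_meta.tsv", sep="\t", dtype={"unit_id": str})
        meta = meta.set_index("unit_id")
    return CountMatrix(mat, np.asarray(genes, dtype=object),
                       np.asarray(cells, dtype=object), meta)


# ---------------------------------------------------------------------------
# TSV tables


def write_table(t: pd.DataFrame, path: "str | Path") -> None:
    """Bit-stable TSV writer: '\\t' sep, repr-precision floats, 'NA' missing."""
    t.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path: "str | Path", **kwargs) -> pd.DataFrame:
    """TSV reader matching :func:`write_table`; exact float round trips."""
    kwargs.setdefault("float_precision", "round_trip")
    return pd.read_csv(path, sep="\t", na_values=["NA"], **kwargs)


def write_bulk_tsv(m: CountMatrix, path: "str | Path") -> None:
    df = pd.DataFrame(m.values, columns=list(m.unit_ids))
    df.insert(0, "gene_id", list(m.gene_ids))
    write_table(df, path)


def read_bulk_tsv(path: "str | Path",
                  condition_table: "pd.DataFrame | None" = None) -> CountMatrix:
    df = read_table(path, dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: bulk counts must have a 'gene_id' column")
    genes = df["gene_id"].to_numpy(dtype=object)
    samples = np.asarray([c for c in df.columns if c != "gene_id"], dtype=object)
    vals = df[list(samples)].to_numpy()
    meta = None
    if condition_table is not None:
        meta = condition_table.set_index("sample_id")
    return CountMatrix(vals, genes, samples, meta)


def read_condition_table(path: "str | Path") -> pd.DataFrame:
    t = read_table(path, dtype=str)
    if "sample_id" not in t.columns:
        raise FormatError(f"{path}: condition table must have a 'sample_id' column")
    return t


def write_signature(sig: GeneSignature, path: "str | Path") -> None:
    df = pd.DataFrame({
        "signature": sig.name,
        "gene_id": sorted(sig.genes),
        "direction": sig.direction,
    })
    write_table(df, path)


def read_signature(path: "str | Path") -> GeneSignature:
    df = read_table(path, dtype=str)
    for col in ("signature", "gene_id", "direction"):
        if col not in df.columns:
            raise FormatError(f"{path}: signature file missing column {col!r}")
    names = df["signature"].unique()
    if len(names) != 1:
        raise FormatError(f"{path}: expected one signature, found {list(names)}")
    directions = df["direction"].unique()
    if len(directions) != 1:
        raise FormatError(f"{path}: mixed directions {list(directions)}")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate gene {dup!r}")
    return GeneSignature(str(names[0]), str(directions[0]), set(df["gene_id"]))


def write_bed_enhancers(enh: EnhancerTable, path: "str | Path") -> None:
    write_table(enh.table, path)


def read_bed_enhancers(path: "str | Path") -> EnhancerTable:
    df = read_table(path, dtype={"chrom": str, "enhancer_id": str})
    return EnhancerTable(df)


def write_tss(tss: TssTable, path: "str | Path") -> None:
    write_table(tss.table, path)


def read_tss(path: "str | Path") -> TssTable:
    df = read_table(path, dtype={"gene_id": str, "chrom": str, "strand": str})
    return TssTable(df)


def write_de_table(t: pd.DataFrame, path: "str | Path") -> None:
    write_table(t[DE_COLUMNS], path)


def read_de_table(path: "str | Path") -> pd.DataFrame:
    df = read_table(path, dtype={"gene_id": str})
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: DE table missing columns {missing}")
    for col in ("p", "padj"):
        v = df[col].to_numpy(dtype=float)
        v = v[~np.isnan(v)]
        if v.size and (v.min() < 0 or v.max() > 1):
            raise FormatError(f"{path}: column {col!r} outside [0, 1]")
    return df
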