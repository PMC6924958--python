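"""Readers and writers for the pipeline's plain-text and TIFF formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dge import CountMatrix

__all__ = [
    "read_counts", "write_counts",
    "read_sample_sheet", "write_sample_sheet",
    "read_count_matrix", "write_count_matrix",
    "read_dge_table", "write_dge_table",
    "read_transcript_table", "write_transcript_table",
    "read_image", "write_image", "read_mask", "write_mask",
    "read_gene_lists",
]


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    required = {"sample_id", "fraction", "compartment", "condition", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet.set_index("sample_id")


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index_label="sample_id")


def read_count_matrix(counts_path, sheet_path) -> CountMatrix:
    return CountMatrix(read_counts(counts_path), read_sample_sheet(sheet_path))


def write_count_matrix(cm: CountMatrix, counts_path, sheet_path) -> None:
    write_counts(cm.counts, counts_path)
    write_sample_sheet(cm.sample_sheet, sheet_path)


def read_dge_table(path) -> pd.DataFrame:
    """Read a DGE table; external tables need at least gene_id, log2fc, padj."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    required = {"log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DGE table missing columns: {sorted(missing)}")
    if "tested" not in df.columns:
        df["tested"] = df["padj"].notna()
    return df


def write_dge_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


def read_transcript_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_transcript_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_image(path) -> np.ndarray:
    import tifffile
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def write_image(image: np.ndarray, path) -> None:
    import tifffile
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def read_mask(path) -> np.ndarray:
    import tifffile
    return np.asarray(tifffile.imread(str(path))) > 0


def write_mask(mask: np.ndarray, path) -> None:
    import tifffile
    tifffile.imwrite(str(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_gene_lists(paths: dict[str, str | Path]) -> dict[str, set]:
    """Read named reference gene lists.

    Each file is either one gene id per line, or a two-column TSV
    (list_name, gene_id) — in the latter case the file may carry
    several lists and the mapping key is ignored in favor of column 1.
    """
    out: dict[str, set] = {}
    for name, path in paths.items():
        lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        if lines and "\t" in lines[0]:
            for ln in lines:
                list_name, gene = ln.split("\t")[:2]
                out.setdefault(list_name, set()).add(gene)
        else:
            out[name] = set(lines)
    return out
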