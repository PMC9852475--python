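"""Readers and writers for the plain-text formats the pipeline exchanges.

Fragments travel as BED6 with a structured name field ``cell|fraction|id``;
peaks as narrowPeak (BED6+4); matrices as TSV or MatrixMarket triplets.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_fragments_bed",
    "write_fragments_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_matrix_mtx",
    "read_matrix_mtx",
]

FRAGMENT_COLUMNS = ["Chromosome", "Start", "End", "cell", "fraction", "Strand"]

NARROWPEAK_COLUMNS = [
    "Chromosome", "Start", "End", "name", "score", "Strand",
    "fold_enrichment", "neg_log10_p", "neg_log10_q", "summit_offset",
]


def read_fragments_bed(path: str | Path) -> pd.DataFrame:
    """Load aligned fragments from BED6 (name = ``cell|fraction[|...]``)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["Chromosome", "Start", "End", "name", "score", "Strand"])
    parts = df["name"].astype(str).str.split("|")
    df["cell"] = parts.str[0]
    df["fraction"] = parts.str[1].fillna("RNA")
    return df[FRAGMENT_COLUMNS]


def write_fragments_bed(frags: pd.DataFrame, path: str | Path) -> None:
    out = frags.copy()
    extra = out["molecule"].astype(str) if "molecule" in out else None
    name = out["cell"].astype(str) + "|" + out["fraction"].astype(str)
    if extra is not None:
        name = name + "|" + extra
    bed = pd.DataFrame({
        0: out["Chromosome"], 1: out["Start"].astype(int), 2: out["End"].astype(int),
        3: name, 4: 0, 5: out.get("Strand", "+"),
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=NARROWPEAK_COLUMNS)
    return df


def write_narrowpeak(peaks: pd.DataFrame, path: str | Path) -> None:
    """Write peaks in narrowPeak column order, bit-exact."""
    out = peaks.copy()
    if "name" not in out:
        out["name"] = [f"peak_{i + 1}" for i in range(len(out))]
    if "score" not in out:
        out["score"] = np.minimum(1000, np.round(10 * out["neg_log10_q"]).astype(int))
    if "Strand" not in out:
        out["Strand"] = "."
    out = out[NARROWPEAK_COLUMNS]
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def write_matrix_mtx(matrix: pd.DataFrame, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` plus row/column label sidecars."""
    from scipy import io as spio
    from scipy import sparse

    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")),
                 sparse.csr_matrix(matrix.to_numpy()))
    prefix.with_suffix(".rows.txt").write_text("\n".join(map(str, matrix.index)) + "\n")
    prefix.with_suffix(".cols.txt").write_text("\n".join(map(str, matrix.columns)) + "\n")


def read_matrix_mtx(prefix: str | Path) -> pd.DataFrame:
    from scipy import io as spio

    prefix = Path(prefix)
    mat = spio.mmread(str(prefix.with_suffix(".mtx"))).toarray()
    rows = prefix.with_suffix(".rows.txt").read_text().splitlines()
    cols = prefix.with_suffix(".cols.txt").read_text().splitlines()
    return pd.DataFrame(mat, index=rows, columns=cols)
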