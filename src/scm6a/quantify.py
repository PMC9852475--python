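"""Per-gene counting, expression normalization and per-cell m6A levels.

Counting follows the unique-assignment convention: a fragment counts toward
the single gene whose exons it overlaps; fragments touching exons of two or
more genes are ambiguous and discarded; fragments touching none are
unassigned.  The per-cell relative m6A level is
``log2(IP / (IP + RNA + SUP))`` over deduplicated fragment counts of the
three fractions, which is always <= 0 and equals 0 only for a cell whose
every fragment was immunoprecipitated.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyranges as pr

from .annotation import GeneAnnotation

__all__ = [
    "Unit",
    "ExpressionMatrix",
    "count_fragments_per_gene",
    "counts_to_matrix",
    "normalize_expression",
    "cell_m6a_level",
    "cell_profiles",
    "common_modified_transcripts",
]

FRACTIONS = ("IP", "RNA", "SUP")


class Unit(str, enum.Enum):
    COUNTS = "COUNTS"
    FPKM = "FPKM"
    TPM = "TPM"
    CPM = "CPM"


@dataclass
class ExpressionMatrix:
    """genes x cells matrix with its unit and the gene lengths used."""

    values: pd.DataFrame
    unit: Unit
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        self.unit = Unit(self.unit)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")


def count_fragments_per_gene(
    fragments: pd.DataFrame, annotation: GeneAnnotation
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """featureCounts-style unique assignment of fragments to genes.

    ``fragments``: Chromosome/Start/End/cell/fraction table of deduplicated
    fragments.  Returns ``(counts, audit)`` where ``counts`` is a long table
    (cell, fraction, gene_id, count) and ``audit`` tallies
    assigned/ambiguous/unassigned per cell and fraction.
    """
    frags = fragments.reset_index(drop=True).copy()
    frags["_idx"] = np.arange(len(frags))
    gene_sets: dict[int, set] = {}
    if not frags.empty:
        joined = pr.PyRanges(frags[["Chromosome", "Start", "End", "_idx"]]).join(
            annotation.exon_ranges()
        ).df
        if not joined.empty:
            for idx, sub in joined.groupby("_idx"):
                gene_sets[idx] = set(sub["gene_id"])
    n_genes_hit = frags["_idx"].map(lambda i: len(gene_sets.get(i, ())))
    frags["fate"] = np.select(
        [n_genes_hit == 1, n_genes_hit > 1], ["assigned", "ambiguous"], "unassigned"
    )
    frags["gene_id"] = [
        next(iter(gene_sets[i])) if len(gene_sets.get(i, ())) == 1 else None
        for i in frags["_idx"]
    ]
    assigned = frags[frags["fate"] == "assigned"]
    counts = (
        assigned.groupby(["cell", "fraction", "gene_id"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    audit = (
        frags.groupby(["cell", "fraction", "fate"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return counts, audit


def counts_to_matrix(counts: pd.DataFrame, fraction: str | None = None,
                     genes: list[str] | None = None,
                     cells: list[str] | None = None) -> pd.DataFrame:
    """Pivot the long count table into a genes x cells matrix for one fraction."""
    sub = counts if fraction is None else counts[counts["fraction"] == fraction]
    mat = sub.pivot_table(index="gene_id", columns="cell", values="count",
                          aggfunc="sum", fill_value=0)
    if genes is not None:
        mat = mat.reindex(index=genes, fill_value=0)
    if cells is not None:
        mat = mat.reindex(columns=cells, fill_value=0)
    return mat.astype(float)


def normalize_expression(counts: pd.DataFrame, gene_lengths: pd.Series,
                         unit: Unit | str) -> ExpressionMatrix:
    """Depth/length normalization of a genes x cells count matrix.

    FPKM = count / (length_kb * mapped_millions); CPM = count /
    mapped_millions; TPM rescales the per-kb rate so each cell sums to 1e6.
    The library size is the column sum of uniquely assigned fragments.
    """
    unit = Unit(unit)
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"no length for gene {missing!r}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    lib = counts.sum(axis=0)
    if unit is Unit.COUNTS:
        return ExpressionMatrix(counts.astype(float), unit, lengths)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][0]
        raise ValueError(f"cell {bad!r} has zero library size")
    millions = lib / 1e6
    if unit is Unit.CPM:
        vals = counts / millions
    elif unit is Unit.FPKM:
        vals = counts.div(lengths / 1e3, axis=0) / millions
    else:  # TPM
        rate = counts.div(lengths / 1e3, axis=0)
        vals = rate / rate.sum(axis=0) * 1e6
    return ExpressionMatrix(vals, unit, lengths)


def cell_m6a_level(n_ip: int, n_rna: int, n_sup: int) -> float:
    """log2 fraction of a cell's fragments captured by the IP.

    Undefined (raises) when the cell has no IP fragments.  Scale-invariant:
    multiplying all three counts by a constant leaves the level unchanged.
    """
    if n_ip <= 0:
        raise ValueError("m6A level undefined for a cell with no IP fragments")
    total = n_ip + n_rna + n_sup
    return math.log2(n_ip / total)


def cell_profiles(counts_by_fraction: pd.DataFrame) -> pd.DataFrame:
    """Per-cell tri-fraction counts and derived m6A level.

    ``counts_by_fraction``: tidy table (cell, fraction, count) or the long
    per-gene count table (summed over genes).  Cells without IP fragments
    get ``m6a_level`` NaN and ``level_defined`` False — they are excluded
    from level-based clustering upstream.
    """
    total = (counts_by_fraction.groupby(["cell", "fraction"])["count"].sum()
             .unstack(fill_value=0))
    for frac in FRACTIONS:
        if frac not in total:
            total[frac] = 0
    prof = pd.DataFrame({
        "n_ip": total["IP"].astype(int),
        "n_rna": total["RNA"].astype(int),
        "n_sup": total["SUP"].astype(int),
    })
    defined = prof["n_ip"] > 0
    level = np.full(len(prof), np.nan)
    tot = prof[["n_ip", "n_rna", "n_sup"]].sum(axis=1)
    level[defined.to_numpy()] = np.log2(
        prof.loc[defined, "n_ip"] / tot[defined]
    )
    prof["m6a_level"] = level
    prof["level_defined"] = defined
    return prof.sort_index()


def common_modified_transcripts(
    per_cell_scores: list[pd.Series],
    top_n: int = 5000,
    min_cells: int = 6,
) -> list[str]:
    """Transcripts in the per-cell top-N enrichment scores of many cells.

    Each entry of ``per_cell_scores`` maps transcript -> enrichment score
    for one cell (a transcript's score is its best peak's fold enrichment).
    A transcript is kept iff it ranks within the top ``top_n`` scores
    (descending; ties broken by transcript id for determinism) in at least
    ``min_cells`` cells.
    """
    if top_n <= 0:
        raise ValueError("top_n must be > 0")
    if len(per_cell_scores) < min_cells:
        raise ValueError(f"need at least {min_cells} cells, got {len(per_cell_scores)}")
    hits: dict[str, int] = {}
    for scores in per_cell_scores:
        df = scores.rename("score").rename_axis("transcript").reset_index()
        df = df.sort_values(["score", "transcript"], ascending=[False, True],
                            kind="mergesort")
        for t in df["transcript"].head(top_n):
            hits[t] = hits.get(t, 0) + 1
    return sorted(t for t, n in hits.items() if n >= min_cells)
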