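"""Maternal / ZGA gene classification and reader-target distances.

Stage logic for the mouse oocyte-to-embryo transition: maternal genes are
those expressed in the MII oocyte (FPKM >= 1); maternal-decay genes are the
maternal genes significantly higher in MII than in the zygote; minor-wave
zygotic genes come up in the early or mid 2-cell embryo against the
previous stage, and major-wave genes in the late 2-cell or 4-cell embryo,
all at log2FC > 0.5 and adjusted p < 0.05.  DE tables are pluggable; a
rank-sum stand-in is provided so synthetic runs need no external fitter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Category",
    "StageDesign",
    "classify_gene_categories",
    "internal_de_standin",
    "reader_target_distance",
    "shuffle_intervals",
]

MATERNAL = "MATERNAL"
MATERNAL_DECAY = "MATERNAL_DECAY"
MINOR_ZGA = "MINOR_ZGA"
MAJOR_ZGA = "MAJOR_ZGA"
Category = str


@dataclass
class StageDesign:
    """Which stages and contrasts feed each label.

    Contrasts are (test, control) pairs keyed the same way in ``de_tables``;
    a contrast's log2fc is test-over-control.  ``decay_contrast`` defaults
    to MII-over-zygote (decay genes sit higher in the oocyte); the
    orientation is explicit because it is a modelling choice.
    """

    maternal_stage: str = "MII"
    decay_contrast: tuple[str, str] = ("MII", "zygote")
    minor_zga_contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("early2C", "zygote"), ("mid2C", "early2C")])
    major_zga_contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("late2C", "mid2C"), ("C4", "late2C")])


def _up_genes(de: pd.DataFrame, fc: float, padj: float) -> set[str]:
    hit = (de["log2fc"] > fc) & (de["padj"] < padj)
    return set(de.loc[hit, "gene"])


def classify_gene_categories(
    expr: pd.DataFrame,
    de_tables: dict[tuple[str, str], pd.DataFrame],
    design: StageDesign | None = None,
    fc_threshold: float = 0.5,
    padj_threshold: float = 0.05,
    maternal_fpkm: float = 1.0,
) -> pd.DataFrame:
    """Label genes as maternal / maternal-decay / minor-ZGA / major-ZGA.

    ``expr``: genes x stages FPKM matrix (must contain the maternal stage).
    ``de_tables``: (test, control) -> DataFrame(gene, log2fc, p, padj).
    Returns a boolean table per gene with an ``evidence`` column naming the
    supporting contrast(s).  A missing contrast only disables the labels
    depending on it (with a warning).
    """
    design = design or StageDesign()
    if design.maternal_stage not in expr.columns:
        raise ValueError(f"expression matrix lacks stage {design.maternal_stage!r}")
    genes = expr.index
    out = pd.DataFrame(
        {MATERNAL: expr[design.maternal_stage] >= maternal_fpkm,
         MATERNAL_DECAY: False, MINOR_ZGA: False, MAJOR_ZGA: False,
         "evidence": ""},
        index=genes,
    )

    def lookup(contrast):
        de = de_tables.get(contrast)
        if de is None:
            warnings.warn(f"contrast {contrast} missing; dependent label skipped")
        return de

    decay_de = lookup(design.decay_contrast)
    if decay_de is not None:
        up = _up_genes(decay_de, fc_threshold, padj_threshold)
        hits = out.index.isin(up) & out[MATERNAL]
        out.loc[hits, MATERNAL_DECAY] = True
        out.loc[hits, "evidence"] += f"{design.decay_contrast[0]}>{design.decay_contrast[1]};"
    for label, contrasts in ((MINOR_ZGA, design.minor_zga_contrasts),
                             (MAJOR_ZGA, design.major_zga_contrasts)):
        for contrast in contrasts:
            de = lookup(contrast)
            if de is None:
                continue
            up = _up_genes(de, fc_threshold, padj_threshold)
            hits = out.index.isin(up)
            out.loc[hits, label] = True
            out.loc[hits, "evidence"] += f"{contrast[0]}>{contrast[1]};"
    return out


def internal_de_standin(counts_a: pd.DataFrame, counts_b: pd.DataFrame,
                        pseudocount: float = 1.0) -> pd.DataFrame:
    """Simple two-group differential test on genes x cells count matrices.

    log2fc is the log2 ratio of group mean CPM (pseudocount added); p is a
    two-sided rank-sum test per gene on per-cell CPM; padj is
    Benjamini-Hochberg.  Meant as plumbing for synthetic runs, not a
    replacement for a dispersion-modelling DE fit.
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need at least 2 cells per group")
    for name, c in (("a", counts_a), ("b", counts_b)):
        if (c.sum(axis=0) <= 0).all():
            raise ValueError(f"group {name} has zero total counts")
    genes = counts_a.index.intersection(counts_b.index)
    cpm_a = counts_a.loc[genes] / counts_a.loc[genes].sum(axis=0) * 1e6
    cpm_b = counts_b.loc[genes] / counts_b.loc[genes].sum(axis=0) * 1e6
    log2fc = np.log2((cpm_a.mean(axis=1) + pseudocount)
                     / (cpm_b.mean(axis=1) + pseudocount))
    pvals = np.ones(len(genes))
    a_vals, b_vals = cpm_a.to_numpy(), cpm_b.to_numpy()
    for i in range(len(genes)):
        if np.ptp(np.concatenate([a_vals[i], b_vals[i]])) == 0:
            continue
        pvals[i] = stats.ranksums(a_vals[i], b_vals[i]).pvalue
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({"gene": genes, "log2fc": log2fc.to_numpy(),
                         "p": pvals, "padj": padj}).reset_index(drop=True)


def _closest_distance(p_start: int, p_end: int, t_starts: np.ndarray,
                      t_ends: np.ndarray) -> int:
    """Distance to the nearest target: 0 overlap, 1 bookended, else gap+1.

    When several targets tie on distance the nearest-by-start one is the
    conceptual winner; only the distance is returned so ties are moot here.
    """
    d = np.zeros(len(t_starts), dtype=np.int64)
    left = t_ends <= p_start      # entirely left of the peak (or bookended)
    right = t_starts >= p_end     # entirely right (or bookended)
    d[left] = p_start - t_ends[left] + 1
    d[right] = t_starts[right] - p_end + 1
    return int(d.min())


def reader_target_distance(
    peaks: pd.DataFrame,
    targets: pd.DataFrame,
    genome_sizes: dict[str, int],
    shuffle_n: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Observed peak-to-target distances plus a shuffled null.

    Distance convention follows interval-closest tools: 0 when overlapping,
    1 when bookended, gap+1 otherwise.  The null relocates every target
    uniformly within its own chromosome (length preserved) ``shuffle_n``
    times with a seeded generator and recomputes the distances.  Peaks on
    chromosomes without any target get distance -1 and are dropped from
    both observed and null returns.
    """
    for chrom in targets["Chromosome"].unique():
        if chrom not in genome_sizes:
            raise ValueError(f"chromosome {chrom!r} absent from genome sizes")
    rng = np.random.default_rng(seed)

    def distances(tgt: pd.DataFrame) -> np.ndarray:
        by_chrom = {}
        for chrom, sub in tgt.groupby("Chromosome"):
            order = np.argsort(sub["Start"].to_numpy(), kind="stable")
            by_chrom[chrom] = (sub["Start"].to_numpy()[order],
                               sub["End"].to_numpy()[order])
        out = np.empty(len(peaks), dtype=int)
        for n, rec in enumerate(peaks.itertuples(index=False)):
            arrs = by_chrom.get(rec.Chromosome)
            out[n] = -1 if arrs is None else _closest_distance(
                int(rec.Start), int(rec.End), *arrs)
        return out

    observed = distances(targets)
    valid = observed >= 0
    nulls = []
    for _ in range(shuffle_n):
        shuffled = shuffle_intervals(targets, genome_sizes, rng)
        nulls.append(distances(shuffled)[valid])
    return observed[valid], nulls


def shuffle_intervals(intervals: pd.DataFrame, genome_sizes: dict[str, int],
                      rng: np.random.Generator) -> pd.DataFrame:
    """Random relocation preserving each interval's chromosome and length."""
    out = intervals.copy()
    lengths = (out["End"] - out["Start"]).to_numpy()
    caps = out["Chromosome"].map(genome_sizes).to_numpy()
    slack = caps - lengths
    if (slack < 0).any():
        raise ValueError("interval longer than its chromosome")
    new_start = (rng.random(len(out)) * (slack + 1)).astype(int)
    out["Start"] = new_start
    out["End"] = new_start + lengths
    return out
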