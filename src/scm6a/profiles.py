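"""Metagene IP/input ratio profiles and sequencing-saturation curves.

Metagene profiling bins CPM-scaled fragment coverage into fixed-width bins
around a per-transcript anchor (TSS or stop codon), in transcript
orientation, and reports the per-bin mean of the per-region
(IP + pseudocount) / (input + pseudocount) ratio.  Saturation curves count
genes detected after seeded random subsampling of reads without
replacement, mirroring shuffle-based rarefaction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation

__all__ = [
    "Anchor",
    "MetageneResult",
    "SaturationCurve",
    "metagene_ratio_profile",
    "saturation_curve",
]


class Anchor(str, enum.Enum):
    TSS = "TSS"
    STOP_CODON = "STOP_CODON"


# windows copied from the reference-point profiling flags:
# stop codon -b 500 -a 500, TSS -b 50 -a 500
DEFAULT_WINDOWS = {Anchor.TSS: (50, 500), Anchor.STOP_CODON: (500, 500)}


@dataclass
class MetageneResult:
    """Per-bin mean ratio curve plus the per-region ratio matrix."""

    curve: np.ndarray
    ratio_matrix: pd.DataFrame  # regions x bins
    bin_size: int
    upstream: int
    downstream: int
    anchor: Anchor

    @property
    def bin_centers(self) -> np.ndarray:
        """Transcript-relative coordinate of each bin center (bp)."""
        n = len(self.curve)
        return -self.upstream + self.bin_size * (np.arange(n) + 0.5)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.bin_centers, "ratio": self.curve})


@dataclass
class SaturationCurve:
    table: pd.DataFrame  # depth, mean_genes, sd_genes
    replicates: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return self.table


def _coverage_arrays(frags: pd.DataFrame, chrom_sizes: dict[str, int],
                     cpm_scale: float) -> dict[str, np.ndarray]:
    """Per-bp coverage per chromosome, scaled to counts-per-million."""
    out = {}
    for chrom, size in chrom_sizes.items():
        diff = np.zeros(size + 1)
        sub = frags[frags["Chromosome"] == chrom]
        if not sub.empty:
            lo = np.clip(sub["Start"].to_numpy(int), 0, size)
            hi = np.clip(sub["End"].to_numpy(int), 0, size)
            np.add.at(diff, lo, 1.0)
            np.add.at(diff, hi, -1.0)
        out[chrom] = np.cumsum(diff[:-1]) * cpm_scale
    return out


def _binned(cov: np.ndarray, start: int, n_bins: int, bin_size: int) -> np.ndarray:
    window = cov[start:start + n_bins * bin_size]
    return window.reshape(n_bins, bin_size).mean(axis=1)


def metagene_ratio_profile(
    ip_fragments: pd.DataFrame,
    input_fragments: pd.DataFrame,
    annotation: GeneAnnotation,
    anchor: Anchor | str = Anchor.STOP_CODON,
    upstream: int | None = None,
    downstream: int | None = None,
    bin_size: int = 5,
    pseudocount: float = 1.0,
    ratio_of_means: bool = False,
    chrom_sizes: dict[str, int] | None = None,
) -> MetageneResult:
    """Mean IP/input coverage ratio around a per-transcript anchor.

    Coverage of each library is CPM-scaled before the ratio; the window runs
    from ``upstream`` bp 5' of the anchor to ``downstream`` bp 3' of it in
    transcript orientation (minus-strand regions are reversed), in
    ``bin_size``-bp bins.  Regions whose window is truncated by a
    chromosome edge are dropped; pass ``chrom_sizes`` to enforce real
    chromosome bounds (otherwise bounds are inferred from the data with a
    one-window margin, so only windows running off the left edge drop).
    ``ratio_of_means=True`` returns instead the ratio of the across-region
    mean coverages per bin.
    """
    anchor = Anchor(anchor)
    if upstream is None or downstream is None:
        d_up, d_down = DEFAULT_WINDOWS[anchor]
        upstream = d_up if upstream is None else upstream
        downstream = d_down if downstream is None else downstream
    if (upstream + downstream) % bin_size != 0:
        raise ValueError("window length must be a multiple of bin_size")
    n_bins = (upstream + downstream) // bin_size

    col = "tss" if anchor is Anchor.TSS else "stop_codon"
    anchors = annotation.anchors.dropna(subset=[col])
    if anchors.empty:
        raise ValueError(f"no region carries a {anchor.value} anchor")

    if chrom_sizes is not None:
        sizes = dict(chrom_sizes)
    else:
        sizes = annotation.chrom_extent()
        for frags in (ip_fragments, input_fragments):
            for chrom, end in frags.groupby("Chromosome")["End"].max().items():
                sizes[chrom] = max(sizes.get(chrom, 0), int(end))
        sizes = {c: s + upstream + downstream for c, s in sizes.items()}
    cov_ip = _coverage_arrays(ip_fragments, sizes, 1e6 / max(1, len(ip_fragments)))
    cov_in = _coverage_arrays(input_fragments, sizes, 1e6 / max(1, len(input_fragments)))

    rows_ip, rows_in, kept = [], [], []
    for gid, rec in anchors.sort_index().iterrows():
        pos = int(rec[col])
        chrom, strand = rec["Chromosome"], rec["Strand"]
        if chrom not in sizes:
            continue
        if strand == "+":
            lo = pos - upstream
        else:
            lo = pos - downstream + 1
        hi = lo + upstream + downstream
        if lo < 0 or hi > sizes[chrom]:
            continue  # truncated by a chromosome edge
        bi = _binned(cov_ip[chrom], lo, n_bins, bin_size)
        bn = _binned(cov_in[chrom], lo, n_bins, bin_size)
        if strand != "+":
            bi, bn = bi[::-1], bn[::-1]
        rows_ip.append(bi)
        rows_in.append(bn)
        kept.append(gid)
    if not kept:
        raise ValueError("every region was dropped (chromosome-edge truncation)")

    mat_ip = np.asarray(rows_ip)
    mat_in = np.asarray(rows_in)
    ratios = (mat_ip + pseudocount) / (mat_in + pseudocount)
    if ratio_of_means:
        curve = (mat_ip.mean(axis=0) + pseudocount) / (mat_in.mean(axis=0) + pseudocount)
    else:
        curve = ratios.mean(axis=0)
    matrix = pd.DataFrame(ratios, index=pd.Index(kept, name="gene_id"))
    return MetageneResult(curve=curve, ratio_matrix=matrix, bin_size=bin_size,
                          upstream=upstream, downstream=downstream, anchor=anchor)


def saturation_curve(
    gene_per_read: pd.Series | np.ndarray,
    depths: list[int],
    replicates: int = 20,
    seed: int = 0,
    min_reads_per_gene: int = 1,
) -> SaturationCurve:
    """Genes detected as a function of sampled read count.

    ``gene_per_read`` holds one gene label per assigned read.  For each
    depth, reads are drawn without replacement ``replicates`` times with a
    seeded generator and genes with at least ``min_reads_per_gene`` sampled
    reads are counted.  Identical seeds give identical curves.
    """
    genes = np.asarray(gene_per_read)
    total = len(genes)
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        if depth > total:
            raise ValueError(f"depth {depth} exceeds total reads {total}")
        detected = []
        for _ in range(replicates):
            idx = rng.choice(total, size=depth, replace=False)
            _, counts = np.unique(genes[idx], return_counts=True)
            detected.append(int((counts >= min_reads_per_gene).sum()))
        rows.append({"depth": depth, "mean_genes": float(np.mean(detected)),
                     "sd_genes": float(np.std(detected, ddof=0))})
    return SaturationCurve(table=pd.DataFrame(rows), replicates=replicates, seed=seed)
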