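"""Gene-model container shared by counting, peak annotation and profiling.

Coordinates are 0-based half-open throughout (BED convention); GTF input is
converted on read.  One transcript per gene is assumed for anchor lookup
(TSS, stop codon); multi-transcript GTFs use each gene's first transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = ["GeneAnnotation", "read_chrom_sizes", "write_chrom_sizes"]


@dataclass
class GeneAnnotation:
    """Exon structures plus per-transcript anchor coordinates.

    ``exons``: DataFrame with columns Chromosome, Start, End, Strand, gene_id
    (exons of one gene must not overlap each other).
    ``anchors``: DataFrame indexed by gene_id with columns Chromosome,
    Strand, tss, stop_codon — single genomic base positions; ``stop_codon``
    may hold NaN where no stop-codon feature is known.
    """

    exons: pd.DataFrame
    anchors: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        need = {"Chromosome", "Start", "End", "Strand", "gene_id"}
        if not need <= set(self.exons.columns):
            raise ValueError(f"exons missing columns {need - set(self.exons.columns)}")
        if self.exons.empty:
            raise ValueError("empty annotation")

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.exons["gene_id"].unique())

    def gene_lengths(self) -> pd.Series:
        """Summed exon length (bp) per gene."""
        lens = (self.exons["End"] - self.exons["Start"]).groupby(
            self.exons["gene_id"]
        ).sum()
        lens.name = "length"
        return lens

    def exon_ranges(self) -> pr.PyRanges:
        return pr.PyRanges(self.exons[["Chromosome", "Start", "End", "Strand", "gene_id"]].copy())

    def chrom_extent(self) -> dict[str, int]:
        return (self.exons.groupby("Chromosome", observed=True)["End"]
                .max().astype(int).to_dict())

    # ---------------------------------------------------------------- I/O

    @classmethod
    def from_gtf(cls, path: str | Path) -> "GeneAnnotation":
        gr = pr.read_gtf(str(path))
        df = gr.df
        exons = df[df.Feature == "exon"][
            ["Chromosome", "Start", "End", "Strand", "gene_id"]
        ].reset_index(drop=True)
        tx = df[df.Feature == "transcript"]
        if tx.empty:  # fall back to gene rows or exon spans
            tx = df[df.Feature == "gene"]
        if tx.empty:
            tx = (
                exons.groupby("gene_id")
                .agg(Chromosome=("Chromosome", "first"), Start=("Start", "min"),
                     End=("End", "max"), Strand=("Strand", "first"))
                .reset_index()
            )
        tx = tx.drop_duplicates("gene_id")
        tss = np.where(tx.Strand == "+", tx.Start, tx.End - 1)
        anchors = pd.DataFrame(
            {"Chromosome": tx.Chromosome.to_numpy(), "Strand": tx.Strand.to_numpy(),
             "tss": tss.astype(float), "stop_codon": np.nan},
            index=pd.Index(tx.gene_id, name="gene_id"),
        )
        stops = df[df.Feature == "stop_codon"].drop_duplicates("gene_id")
        if not stops.empty:
            pos = np.where(stops.Strand == "+", stops.Start, stops.End - 1)
            anchors.loc[stops.gene_id, "stop_codon"] = pos.astype(float)
        return cls(exons=exons, anchors=anchors)

    @classmethod
    def from_bed12(cls, path: str | Path) -> "GeneAnnotation":
        cols = ["Chromosome", "Start", "End", "name", "score", "Strand",
                "thickStart", "thickEnd", "rgb", "blockCount", "blockSizes", "blockStarts"]
        df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
        rows = []
        anchors = []
        for rec in df.itertuples(index=False):
            sizes = [int(x) for x in str(rec.blockSizes).rstrip(",").split(",")]
            offs = [int(x) for x in str(rec.blockStarts).rstrip(",").split(",")]
            for size, off in zip(sizes, offs):
                rows.append((rec.Chromosome, rec.Start + off, rec.Start + off + size,
                             rec.Strand, rec.name))
            tss = rec.Start if rec.Strand == "+" else rec.End - 1
            # thickEnd/thickStart bound the CDS; its last base approximates the stop
            stop = float(rec.thickEnd - 1 if rec.Strand == "+" else rec.thickStart) \
                if rec.thickEnd > rec.thickStart else np.nan
            anchors.append((rec.name, rec.Chromosome, rec.Strand, float(tss), stop))
        exons = pd.DataFrame(rows, columns=["Chromosome", "Start", "End", "Strand", "gene_id"])
        anc = pd.DataFrame(anchors, columns=["gene_id", "Chromosome", "Strand", "tss",
                                             "stop_codon"]).set_index("gene_id")
        return cls(exons=exons, anchors=anc)

    def to_gtf(self, path: str | Path, source: str = "scm6a") -> None:
        """Write gene/transcript/exon/stop_codon rows (1-based inclusive)."""
        with open(path, "w") as fh:
            for gid, sub in self.exons.groupby("gene_id", sort=True):
                sub = sub.sort_values("Start")
                chrom = sub.Chromosome.iloc[0]
                strand = sub.Strand.iloc[0]
                start, end = int(sub.Start.min()), int(sub.End.max())
                attrs = f'gene_id "{gid}"; transcript_id "{gid}.t1";'
                for feat in ("gene", "transcript"):
                    fh.write(f"{chrom}\t{source}\t{feat}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n")
                for ex in sub.itertuples(index=False):
                    fh.write(f"{chrom}\t{source}\texon\t{ex.Start + 1}\t{ex.End}\t.\t{strand}\t.\t{attrs}\n")
                if gid in self.anchors.index:
                    stop = self.anchors.loc[gid, "stop_codon"]
                    if pd.notna(stop):
                        s = int(stop)
                        lo, hi = (s, s + 3) if strand == "+" else (s - 2, s + 1)
                        fh.write(f"{chrom}\t{source}\tstop_codon\t{lo + 1}\t{hi}\t.\t{strand}\t.\t{attrs}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")
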