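"""Synthetic single-cell m6A-seq datasets with full ground truth.

The generator builds a toy genome annotation, draws per-cell gene counts
from a negative binomial (single-cell overdispersion), plants m6A peaks
near stop codons of methylated genes, routes each molecule to the IP,
RNA-seq or supernatant fraction according to its gene's methylation state,
and finally emits structured paired FASTQ (barcode + UMI + GGG anchor) with
geometric PCR duplication and optional barcode corruption.  Every read maps
back to exactly one truth molecule, so demultiplexing, counting, peak
calling and clustering can all be scored against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation
from .io import write_fragments_bed
from .scheme import BarcodeScheme

__all__ = [
    "PopulationSpec",
    "SimulationSpec",
    "TruthTables",
    "simulate_truth",
    "simulate_reads",
    "make_scheme",
    "simulate_dataset",
    "simulate_metagene_fragments",
    "simulate_level_contrast",
]

_BASES = np.array(list("ACGT"))


@dataclass
class PopulationSpec:
    """One cell population of the simulated experiment.

    ``methylated_fraction`` is the fraction of genes carrying an m6A peak
    in this population; ``pulldown_efficiency`` is the probability that a
    molecule of a methylated gene is captured by the IP, and
    ``background_pulldown`` the capture probability for unmethylated
    molecules (non-specific antibody binding).  Marker genes let
    populations differ in expression as well as methylation.
    """

    name: str
    n_cells: int
    methylated_fraction: float = 0.3
    pulldown_efficiency: float = 0.8
    background_pulldown: float = 0.05
    expr_scale: float = 1.0
    n_marker_genes: int = 0
    marker_log2fc: float = 2.0

    def __post_init__(self) -> None:
        for p in (self.methylated_fraction, self.pulldown_efficiency,
                  self.background_pulldown):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("population needs at least one cell")


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic dataset (all draws seeded)."""

    populations: list[PopulationSpec] = field(
        default_factory=lambda: [PopulationSpec("pop1", 10)])
    n_chromosomes: int = 2
    chrom_length: int = 100_000
    n_genes: int = 60
    exons_per_gene: int = 1
    exon_len_range: tuple[int, int] = (600, 1200)
    intron_len_range: tuple[int, int] = (100, 400)
    intergenic_range: tuple[int, int] = (200, 800)
    utr3_len: int = 300
    peak_halfwidth: int = 100
    mean_expression: float = 10.0
    dispersion: float = 5.0
    lognormal_sigma: float = 0.5
    fragment_length: int = 100
    read_length: int = 100
    duplication_rate: float = 0.0
    barcode_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.duplication_rate, self.barcode_error_rate):
            if not 0 <= p < 1:
                raise ValueError("rates must lie in [0, 1)")
        if self.utr3_len < self.peak_halfwidth:
            raise ValueError("utr3_len must be >= peak_halfwidth so the planted "
                             "peak stays inside the final exon")
        if self.exon_len_range[0] < self.utr3_len + self.peak_halfwidth:
            raise ValueError("final exon must accommodate the 3'UTR plus peak")
        if self.fragment_length > 2 * self.peak_halfwidth:
            raise ValueError("fragments must fit inside a planted peak")


@dataclass
class TruthTables:
    """Ground truth of one simulated dataset."""

    annotation: GeneAnnotation
    cells: pd.DataFrame        # cell_id, population, methylated_fraction
    genes: pd.DataFrame        # gene_id, Chromosome, Strand, Start, End, mean
    methylation: pd.DataFrame  # population, gene_id (methylated pairs)
    peaks: pd.DataFrame        # gene_id, Chromosome, Start, End
    molecules: pd.DataFrame    # molecule, cell, gene_id, fraction, coords
    spec: SimulationSpec

    def fragments(self) -> pd.DataFrame:
        """Deduplicated fragment table (one row per molecule)."""
        return self.molecules[
            ["Chromosome", "Start", "End", "cell", "fraction", "Strand"]
        ].reset_index(drop=True)

    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.spec.chrom_length
                for i in range(self.spec.n_chromosomes)}


def _place_genes(spec: SimulationSpec, rng: np.random.Generator):
    """Lay out non-overlapping genes round-robin across chromosomes."""
    cursors = {f"chr{i + 1}": 500 for i in range(spec.n_chromosomes)}
    exon_rows, gene_rows, anchor_rows, peak_rows = [], [], [], []
    for g in range(spec.n_genes):
        chrom = f"chr{g % spec.n_chromosomes + 1}"
        gid = f"gene{g:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = spec.exons_per_gene
        ex_lens = rng.integers(*spec.exon_len_range, size=n_ex)
        introns = rng.integers(*spec.intron_len_range, size=max(0, n_ex - 1))
        start = cursors[chrom] + int(rng.integers(*spec.intergenic_range))
        pos = start
        exons = []
        for i in range(n_ex):
            exons.append((pos, pos + int(ex_lens[i])))
            pos += int(ex_lens[i]) + (int(introns[i]) if i < n_ex - 1 else 0)
        end = exons[-1][1]
        if end > spec.chrom_length - 500:
            raise ValueError("genes too dense to place on the chromosome")
        cursors[chrom] = end
        L = int(ex_lens.sum())
        # transcript coordinate of the stop codon: utr3_len upstream of 3' end
        t_stop = L - spec.utr3_len
        if strand == "+":
            tss = start
            stop = _tx_to_genomic(exons, t_stop, "+")
            pk_lo = _tx_to_genomic(exons, t_stop - spec.peak_halfwidth, "+")
            pk_hi = _tx_to_genomic(exons, t_stop + spec.peak_halfwidth - 1, "+") + 1
        else:
            tss = end - 1
            stop = _tx_to_genomic(exons, t_stop, "-")
            pk_hi = _tx_to_genomic(exons, t_stop - spec.peak_halfwidth, "-") + 1
            pk_lo = _tx_to_genomic(exons, t_stop + spec.peak_halfwidth - 1, "-")
        for (lo, hi) in exons:
            exon_rows.append((chrom, lo, hi, strand, gid))
        gene_rows.append((gid, chrom, strand, start, end, L))
        anchor_rows.append((gid, chrom, strand, float(tss), float(stop)))
        peak_rows.append((gid, chrom, int(pk_lo), int(pk_hi)))
    exons_df = pd.DataFrame(exon_rows, columns=["Chromosome", "Start", "End",
                                                "Strand", "gene_id"])
    genes_df = pd.DataFrame(gene_rows, columns=["gene_id", "Chromosome", "Strand",
                                                "Start", "End", "length"])
    anchors = pd.DataFrame(anchor_rows, columns=["gene_id", "Chromosome", "Strand",
                                                 "tss", "stop_codon"]).set_index("gene_id")
    peaks_df = pd.DataFrame(peak_rows, columns=["gene_id", "Chromosome", "Start", "End"])
    return GeneAnnotation(exons=exons_df, anchors=anchors), genes_df, peaks_df


def _tx_to_genomic(exons: list[tuple[int, int]], t: int, strand: str) -> int:
    """Map a transcript offset (5'->3') to a genomic base position."""
    if strand == "-":
        total = sum(hi - lo for lo, hi in exons)
        t = total - 1 - t
    for lo, hi in exons:
        if t < hi - lo:
            return lo + t
        t -= hi - lo
    raise ValueError("transcript offset outside the transcript")


def simulate_truth(spec: SimulationSpec) -> TruthTables:
    """Draw annotation, per-cell counts, methylation states and molecules."""
    rng = np.random.default_rng(spec.seed)
    annotation, genes_df, all_peaks = _place_genes(spec, rng)
    n_genes = spec.n_genes
    base_mean = spec.mean_expression * rng.lognormal(0.0, spec.lognormal_sigma, n_genes)
    genes_df["mean"] = base_mean

    gene_ids = genes_df["gene_id"].to_numpy()
    marker_order = rng.permutation(n_genes)
    marker_cursor = 0

    cell_rows, meth_rows = [], []
    pop_means, pop_meth = {}, {}
    for pop in spec.populations:
        mu = base_mean * pop.expr_scale
        if pop.n_marker_genes:
            take = marker_order[marker_cursor:marker_cursor + pop.n_marker_genes]
            marker_cursor += pop.n_marker_genes
            mu = mu.copy()
            mu[take] = mu[take] * 2.0 ** pop.marker_log2fc
        pop_means[pop.name] = mu
        n_meth = int(round(pop.methylated_fraction * n_genes))
        meth_idx = rng.choice(n_genes, size=n_meth, replace=False)
        meth_set = set(gene_ids[meth_idx])
        pop_meth[pop.name] = meth_set
        for gid in sorted(meth_set):
            meth_rows.append((pop.name, gid))

    cell_idx = 0
    mol_rows = []
    mol_counter = 0
    exon_lookup = {
        gid: sorted((lo, hi) for _, lo, hi, _, g2 in
                    annotation.exons.itertuples(index=False) if g2 == gid)
        for gid in gene_ids
    }
    peak_lookup = all_peaks.set_index("gene_id")
    flen = spec.fragment_length
    for pop in spec.populations:
        mu = pop_means[pop.name]
        p_nb = spec.dispersion / (spec.dispersion + mu)
        for _ in range(pop.n_cells):
            cell = f"cell{cell_idx:03d}"
            cell_idx += 1
            cell_rows.append((cell, pop.name, pop.methylated_fraction))
            counts = rng.negative_binomial(spec.dispersion, p_nb)
            for gi in np.nonzero(counts)[0]:
                gid = gene_ids[gi]
                n = int(counts[gi])
                meth = gid in pop_meth[pop.name]
                p_ip = pop.pulldown_efficiency if meth else pop.background_pulldown
                n_ip = rng.binomial(n, p_ip)
                n_rna = rng.binomial(n - n_ip, 0.5)
                n_sup = n - n_ip - n_rna
                chrom = genes_df.iloc[gi]["Chromosome"]
                strand = genes_df.iloc[gi]["Strand"]
                exons = exon_lookup[gid]
                for frac, cnt in (("IP", n_ip), ("RNA", n_rna), ("SUP", n_sup)):
                    for _ in range(cnt):
                        if frac == "IP" and meth:
                            pk = peak_lookup.loc[gid]
                            s = int(rng.integers(pk["Start"], pk["End"] - flen + 1))
                        else:
                            s = _uniform_exonic_start(exons, flen, rng)
                        mol_rows.append(
                            (f"m{mol_counter:07d}", cell, gid, frac,
                             chrom, s, s + flen, strand))
                        mol_counter += 1
    cells_df = pd.DataFrame(cell_rows, columns=["cell_id", "population",
                                                "methylated_fraction"])
    meth_df = pd.DataFrame(meth_rows, columns=["population", "gene_id"])
    molecules = pd.DataFrame(mol_rows, columns=["molecule", "cell", "gene_id",
                                                "fraction", "Chromosome",
                                                "Start", "End", "Strand"])
    planted = all_peaks[all_peaks["gene_id"].isin(meth_df["gene_id"].unique())]
    return TruthTables(annotation=annotation, cells=cells_df, genes=genes_df,
                       methylation=meth_df, peaks=planted.reset_index(drop=True),
                       molecules=molecules, spec=spec)


def _uniform_exonic_start(exons: list[tuple[int, int]], flen: int,
                          rng: np.random.Generator) -> int:
    """Uniform fragment start over all exonic placements that fit."""
    weights = np.array([max(0, hi - lo - flen + 1) for lo, hi in exons], float)
    if weights.sum() == 0:
        lo, hi = exons[0]
        return lo
    i = rng.choice(len(exons), p=weights / weights.sum())
    lo, hi = exons[i]
    return int(rng.integers(lo, hi - flen + 1))


def make_scheme(cell_ids: list[str], seed: int = 0, barcode_len: int = 8,
                min_distance: int = 3, **scheme_kwargs) -> BarcodeScheme:
    """Barcode scheme with one well-separated barcode per cell.

    Barcodes are drawn at random subject to pairwise Hamming distance >=
    ``min_distance``, so any single corrupted base can never be mistaken
    for another cell under exact matching.
    """
    rng = np.random.default_rng(seed)
    probe = BarcodeScheme(barcode1_table={"A" * barcode_len: "probe"},
                          **scheme_kwargs)
    forbidden = {probe.tso_seq, *probe.extra_5p_seqs}
    barcodes: list[str] = []
    while len(barcodes) < len(cell_ids):
        cand = "".join(_BASES[rng.integers(0, 4, barcode_len)])
        if cand in forbidden:
            continue
        if all(sum(a != b for a, b in zip(cand, bc)) >= min_distance
               for bc in barcodes):
            barcodes.append(cand)
    table = {bc: cid for bc, cid in zip(barcodes, sorted(cell_ids))}
    return BarcodeScheme(barcode1_table=table, **scheme_kwargs)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def simulate_reads(
    truth: TruthTables,
    scheme: BarcodeScheme,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Turn truth molecules into structured FASTQ plus a truth fragment BED.

    Each molecule yields ``1 + Geometric(duplication_rate)`` read-pair
    copies sharing one molecular identity.  Read 1 is
    ``barcode1 + UMI random bases + anchor + payload``; payload sequences
    are random DNA drawn so every molecule's duplicate-collapsing key is
    unique within its cell under both dedup strategies.  Barcode corruption
    flips one barcode base at the configured rate.  Writes
    ``reads_R1.fastq``/``reads_R2.fastq`` and ``fragments.bed``
    (record-for-record consistent with the FASTQ) and returns the per-read
    truth table.
    """
    spec = truth.spec
    rng = np.random.default_rng(spec.seed + 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    label_to_bc = {lab: bc for bc, lab in scheme.barcode1_table.items()}
    missing = set(truth.cells["cell_id"]) - set(label_to_bc)
    if missing:
        raise ValueError(f"scheme lacks barcodes for cells {sorted(missing)[:3]}...")
    struct = scheme.barcode1_len + scheme.umi_random_len + len(scheme.anchor)
    p1_len = spec.read_length - struct
    if p1_len < 7:
        raise ValueError("read_length too short for the read-1 structure")

    from .demux import _adapter_hit

    def clean(seq: str) -> bool:
        """No chance 3'-adapter lookalike: trimming must be a no-op."""
        return all(_adapter_hit(seq, ad, scheme.min_adapter_overlap) is None
                   for ad in scheme.adapters_3p)

    seen_keys: dict[str, set] = {}
    reads = []
    for mol in truth.molecules.itertuples(index=False):
        cell_keys = seen_keys.setdefault(mol.cell, set())
        bc_true = label_to_bc[mol.cell]
        while True:
            umi = _random_dna(rng, scheme.umi_random_len)
            payload1 = _random_dna(rng, p1_len)
            payload2 = _random_dna(rng, spec.read_length)
            k1 = umi + payload2[:7]
            k2 = payload1[:7] + payload2[:7]
            if (k1 not in cell_keys and k2 not in cell_keys
                    and clean(bc_true + umi + scheme.anchor + payload1)
                    and clean(payload2)):
                cell_keys.update((k1, k2))
                break
        n_copies = 1 + (rng.geometric(1.0 - spec.duplication_rate) - 1
                        if spec.duplication_rate > 0 else 0)
        for copy_i in range(n_copies):
            bc = label_to_bc[mol.cell]
            corrupted = rng.random() < spec.barcode_error_rate
            if corrupted:
                pos = int(rng.integers(len(bc)))
                orig = bc[pos]
                repl = _BASES[(list("ACGT").index(orig) + 1 + int(rng.integers(3))) % 4]
                bc = bc[:pos] + repl + bc[pos + 1:]
            seq1 = bc + umi + scheme.anchor + payload1
            reads.append((mol.cell, mol.fraction, mol.molecule, copy_i, corrupted,
                          seq1, payload2, mol.Chromosome, mol.Start, mol.End,
                          mol.Strand))
    order = rng.permutation(len(reads))
    q = "I"

    read_rows = []
    with open(out_dir / "reads_R1.fastq", "w") as f1, \
         open(out_dir / "reads_R2.fastq", "w") as f2, \
         open(out_dir / "fragments.bed", "w") as fb:
        for out_i, idx in enumerate(order):
            (cell, frac, mol_id, copy_i, corrupted, seq1, seq2,
             chrom, s, e, strand) = reads[idx]
            name = f"rd{out_i:07d}"
            f1.write(f"@{name}\n{seq1}\n+\n{q * len(seq1)}\n")
            f2.write(f"@{name}\n{seq2}\n+\n{q * len(seq2)}\n")
            flag = "bc1err" if corrupted else "ok"
            fb.write(f"{chrom}\t{s}\t{e}\t{cell}|{frac}|{mol_id}|{flag}\t0\t{strand}\n")
            read_rows.append({"read": name, "cell": cell, "fraction": frac,
                              "molecule": mol_id, "copy": copy_i,
                              "corrupted": corrupted})
    return pd.DataFrame(read_rows)


def simulate_metagene_fragments(
    n_regions: int = 500,
    enrichment: float = 3.0,
    gene_len: int = 2_000,
    fragment_length: int = 100,
    depth: int = 600,
    utr3_len: int = 300,
    spacing: int = 3_000,
    peak_halfwidth: int = 100,
    seed: int = 0,
) -> tuple[GeneAnnotation, pd.DataFrame, pd.DataFrame]:
    """Plant a flat IP enrichment around every stop codon.

    Builds ``n_regions`` single-exon plus-strand genes; the input library is
    ``depth`` uniform fragments per gene, and the IP library swaps a
    computed number of them for fragments spanning exactly the
    ``+/- peak_halfwidth`` window at the stop codon so the expected
    CPM-scaled IP/input coverage ratio at the window center equals
    ``enrichment`` (flanks sit just below 1).  Returns
    (annotation, ip_fragments, input_fragments).
    """
    placements = gene_len - fragment_length + 1
    n_extra = int(round(depth * (enrichment - 1.0)
                        / (placements / fragment_length - 1.0)))
    if not 0 < n_extra < depth:
        raise ValueError("enrichment not representable at this depth")
    rng = np.random.default_rng(seed)
    exon_rows, anchor_rows = [], []
    ip_rows, in_rows = [], []
    for i in range(n_regions):
        start = 1_000 + i * spacing
        gid = f"g{i:04d}"
        stop = start + gene_len - utr3_len
        exon_rows.append(("chr1", start, start + gene_len, "+", gid))
        anchor_rows.append((gid, "chr1", "+", float(start), float(stop)))
        for s in rng.integers(start, start + placements, size=depth):
            in_rows.append(("chr1", int(s), int(s) + fragment_length, "c", "RNA"))
        for s in rng.integers(start, start + placements, size=depth - n_extra):
            ip_rows.append(("chr1", int(s), int(s) + fragment_length, "c", "IP"))
        ip_rows.extend([("chr1", stop - peak_halfwidth, stop + peak_halfwidth,
                         "c", "IP")] * n_extra)
    exons = pd.DataFrame(exon_rows, columns=["Chromosome", "Start", "End",
                                             "Strand", "gene_id"])
    anchors = pd.DataFrame(anchor_rows, columns=["gene_id", "Chromosome",
                                                 "Strand", "tss", "stop_codon"]
                           ).set_index("gene_id")
    cols = ["Chromosome", "Start", "End", "cell", "fraction"]
    ip = pd.DataFrame(ip_rows, columns=cols).assign(Strand="+")
    inp = pd.DataFrame(in_rows, columns=cols).assign(Strand="+")
    return GeneAnnotation(exons=exons, anchors=anchors), ip, inp


def simulate_level_contrast(
    n_per_pop: int = 25,
    level_a: float = -1.0,
    level_b: float = -3.0,
    level_sd: float = 0.1,
    n_genes: int = 80,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Two cell populations separable only by their m6A level.

    Every cell shares one expression profile, so embeddings built from the
    matrix carry no population signal; the per-cell m6A levels are drawn
    around ``level_a`` for the first population and ``level_b`` for the
    second.  Returns (genes x cells matrix, levels, true labels).
    """
    rng = np.random.default_rng(seed)
    profile = rng.poisson(20, size=n_genes).astype(float)
    n = 2 * n_per_pop
    matrix = pd.DataFrame(np.tile(profile[:, None], n),
                          index=[f"g{i}" for i in range(n_genes)],
                          columns=[f"cell{i:03d}" for i in range(n)])
    truth = np.repeat([0, 1], n_per_pop)
    levels = np.where(truth == 0, rng.normal(level_a, level_sd, n),
                      rng.normal(level_b, level_sd, n))
    return matrix, levels, truth


def simulate_dataset(spec: SimulationSpec, out_dir: str | Path,
                     scheme: BarcodeScheme | None = None
                     ) -> tuple[TruthTables, BarcodeScheme, pd.DataFrame]:
    """Full dataset on disk: GTF, truth TSVs, fragment BED and FASTQ pair."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth(spec)
    if scheme is None:
        scheme = make_scheme(list(truth.cells["cell_id"]), seed=spec.seed)
    truth.annotation.to_gtf(out_dir / "annotation.gtf")
    truth.cells.to_csv(out_dir / "truth_cells.tsv", sep="\t", index=False)
    truth.genes.to_csv(out_dir / "truth_genes.tsv", sep="\t", index=False)
    truth.peaks.to_csv(out_dir / "truth_peaks.tsv", sep="\t", index=False)
    truth.molecules.to_csv(out_dir / "truth_molecules.tsv", sep="\t", index=False)
    frags = truth.fragments().copy()
    frags["molecule"] = truth.molecules["molecule"].to_numpy()
    write_fragments_bed(frags, out_dir / "truth_fragments.bed")
    read_truth = simulate_reads(truth, scheme, out_dir)
    read_truth.to_csv(out_dir / "truth_reads.tsv", sep="\t", index=False)
    from .scheme import write_scheme_tsv

    write_scheme_tsv(scheme, out_dir / "scheme.tsv")
    return truth, scheme, read_truth
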