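import numpy as np
import pandas as pd
import pytest

from scm6a.annotation import GeneAnnotation
from scm6a.scheme import BarcodeScheme
from scm6a.synthdata import PopulationSpec, SimulationSpec, simulate_truth


def make_annotation(genes):
    """Annotation from (gene_id, chrom, start, end, strand) single-exon rows."""
    exons = pd.DataFrame(genes, columns=["gene_id", "Chromosome", "Start", "End",
                                         "Strand"])
    exons = exons[["Chromosome", "Start", "End", "Strand", "gene_id"]]
    anchors = pd.DataFrame({
        "Chromosome": exons["Chromosome"].to_numpy(),
        "Strand": exons["Strand"].to_numpy(),
        "tss": np.where(exons["Strand"] == "+", exons["Start"], exons["End"] - 1).astype(float),
        "stop_codon": np.nan,
    }, index=pd.Index(exons["gene_id"], name="gene_id"))
    return GeneAnnotation(exons=exons.reset_index(drop=True), anchors=anchors)


def make_fragments(rows):
    """Fragment table from (chrom, start, end, cell, fraction) tuples."""
    df = pd.DataFrame(rows, columns=["Chromosome", "Start", "End", "cell", "fraction"])
    df["Strand"] = "+"
    return df


@pytest.fixture
def simple_scheme():
    return BarcodeScheme(barcode1_table={"ACGTACGT": "c7", "TTTTCCCC": "c8"})


@pytest.fixture(scope="session")
def small_truth():
    """Two populations differing in methylation and markers; session-cached."""
    spec = SimulationSpec(
        populations=[
            PopulationSpec("hi", 6, methylated_fraction=0.5, n_marker_genes=5),
            PopulationSpec("lo", 6, methylated_fraction=0.1, n_marker_genes=5),
        ],
        n_genes=40, mean_expression=15, seed=11,
    )
    return simulate_truth(spec)
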