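"""Read-structure grammar for two-round-barcoded single-cell m6A-seq libraries.

A library read pair carries, on read 1, a cell barcode followed by a short
random stretch and a fixed ``GGG`` anchor left by template switching; the
rest of read 1 and all of read 2 are cDNA payload.  An optional second-round
cell barcode sits at the start of read 2 and an optional sample index lives
in the FASTQ header.  :class:`BarcodeScheme` holds all of this plus the
constant 5'/3' sequences to trim and the duplicate-collapsing strategy.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = [
    "DedupStrategy",
    "ReadStatus",
    "BarcodeScheme",
    "DecodedRead",
    "read_scheme_tsv",
    "write_scheme_tsv",
]

_VALID_BASES = set("ACGTN")


class DedupStrategy(str, enum.Enum):
    """How the per-molecule key is built from a decoded read pair.

    UMI_NNNN_READ2
        random UMI bases from read 1 + first 7 bases of the read-2 payload.
    PAYLOAD7_READ1_READ2
        first 7 bases of each mate's payload ("molecular barcode").
    """

    UMI_NNNN_READ2 = "UMI_NNNN_READ2"
    PAYLOAD7_READ1_READ2 = "PAYLOAD7_READ1_READ2"


class ReadStatus(str, enum.Enum):
    ASSIGNED = "ASSIGNED"
    TOO_SHORT = "TOO_SHORT"
    BARCODE1_MISMATCH = "BARCODE1_MISMATCH"
    BARCODE2_MISMATCH = "BARCODE2_MISMATCH"
    ANCHOR_MISSING = "ANCHOR_MISSING"
    INDEX_MISMATCH = "INDEX_MISMATCH"


def _check_table(name: str, table: Mapping[str, str]) -> None:
    if not table:
        return
    lengths = {len(seq) for seq in table}
    if len(lengths) != 1:
        raise ValueError(f"{name}: all barcodes must share one length, got {sorted(lengths)}")
    if 0 in lengths:
        raise ValueError(f"{name}: empty barcode sequence")
    for seq in table:
        if not set(seq) <= _VALID_BASES:
            raise ValueError(f"{name}: non-nucleotide barcode {seq!r}")


@dataclass
class BarcodeScheme:
    """Full description of the read structure of one library design."""

    tso_seq: str = "TCCGATCT"
    extra_5p_seqs: tuple[str, ...] = ("CACGTCTC",)
    adapters_3p: tuple[str, ...] = ("NNNNNNNAGATCGGA", "TCGGAAGAGCACAC")
    barcode1_table: dict[str, str] = field(default_factory=dict)
    barcode2_table: dict[str, str] = field(default_factory=dict)
    index_table: dict[str, str] = field(default_factory=dict)
    umi_random_len: int = 4
    anchor: str = "GGG"
    min_len_after_trim: int = 28
    max_tso_rounds: int = 5
    min_adapter_overlap: int = 8
    barcode_max_mismatch: int = 0
    dedup_strategy: DedupStrategy = DedupStrategy.UMI_NNNN_READ2

    def __post_init__(self) -> None:
        self.dedup_strategy = DedupStrategy(self.dedup_strategy)
        if self.umi_random_len < 0:
            raise ValueError("umi_random_len must be >= 0")
        if not self.anchor:
            raise ValueError("anchor must be non-empty")
        if self.barcode_max_mismatch not in (0, 1):
            raise ValueError("barcode_max_mismatch must be 0 or 1")
        for name, table in (
            ("barcode1", self.barcode1_table),
            ("barcode2", self.barcode2_table),
            ("index", self.index_table),
        ):
            _check_table(name, table)

    @property
    def barcode1_len(self) -> int:
        return len(next(iter(self.barcode1_table))) if self.barcode1_table else 0

    @property
    def barcode2_len(self) -> int:
        return len(next(iter(self.barcode2_table))) if self.barcode2_table else 0

    def min_read1_structure_len(self) -> int:
        return self.barcode1_len + self.umi_random_len + len(self.anchor)


@dataclass
class DecodedRead:
    """One read pair after structure decoding.

    ``molecular_key`` is the duplicate-collapsing key; it is deterministic
    given the payloads and the scheme's :class:`DedupStrategy`.
    """

    name: str
    status: ReadStatus
    cell_id: str | None = None
    umi: str = ""
    molecular_key: str = ""
    payload1: str = ""
    payload2: str = ""
    qual1: str = ""
    qual2: str = ""


def read_scheme_tsv(path: str | Path, **overrides) -> BarcodeScheme:
    """Load barcode tables from a 3-column TSV (table, sequence, label).

    ``table`` is one of ``barcode1``, ``barcode2``, ``index``.  Scalar scheme
    fields (UMI length, anchor, ...) keep their defaults unless passed as
    keyword overrides.
    """
    tables: dict[str, dict[str, str]] = {"barcode1": {}, "barcode2": {}, "index": {}}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            table, seq, label = parts
            if table not in tables:
                raise ValueError(f"{path}:{lineno}: unknown table {table!r}")
            seq = seq.upper()
            if seq in tables[table]:
                raise ValueError(f"{path}:{lineno}: duplicate sequence {seq} in {table}")
            tables[table][seq] = label
    return BarcodeScheme(
        barcode1_table=tables["barcode1"],
        barcode2_table=tables["barcode2"],
        index_table=tables["index"],
        **overrides,
    )


def write_scheme_tsv(scheme: BarcodeScheme, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, table in (
            ("barcode1", scheme.barcode1_table),
            ("barcode2", scheme.barcode2_table),
            ("index", scheme.index_table),
        ):
            for seq in sorted(table):
                fh.write(f"{name}\t{seq}\t{table[seq]}\n")
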