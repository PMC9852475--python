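"""Read trimming, structure decoding, duplicate collapsing, demultiplexing."""

import random

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scm6a.demux import (ReadPair, decode_read_pair, deduplicate_reads,
                         demultiplex, trim_read_pair)
from scm6a.scheme import BarcodeScheme, DecodedRead, DedupStrategy, ReadStatus
from scm6a.synthdata import PopulationSpec, SimulationSpec, simulate_dataset

PAYLOAD = "ACCTGATTGACCTGATTGACCTGATTGACCTGATTGACCT"  # 40 nt, adapter-free
Q = "I"


def pair(seq1, seq2="C" * 40):
    return ReadPair("r", seq1, Q * len(seq1), seq2, Q * len(seq2))


class TestTrim:
    def test_single_tso_prefix_removed(self):
        scheme = BarcodeScheme()
        out = trim_read_pair(pair("TCCGATCT" + PAYLOAD), scheme)
        assert out.seq1 == PAYLOAD
        assert out.seq2 == "C" * 40
        assert len(out.qual1) == len(out.seq1)

    def test_repeated_tso_prefix_removed_up_to_round_limit(self):
        scheme = BarcodeScheme()
        out = trim_read_pair(pair("TCCGATCT" * 2 + PAYLOAD), scheme)
        assert out.seq1 == PAYLOAD
        # six copies exceed the five-round cap: one survives
        out6 = trim_read_pair(pair("TCCGATCT" * 6 + PAYLOAD), scheme)
        assert out6.seq1 == "TCCGATCT" + PAYLOAD

    def test_extra_5p_sequence_also_stripped(self):
        out = trim_read_pair(pair("CACGTCTC" + PAYLOAD), BarcodeScheme())
        assert out.seq1 == PAYLOAD

    def test_too_short_after_trimming_rejected(self):
        # 27 nt left after the prefix: below the minimum of 28
        out = trim_read_pair(pair("TCCGATCT" + PAYLOAD[:27]), BarcodeScheme())
        assert out is None

    def test_3p_adapter_truncates_at_match(self):
        seq = PAYLOAD[:30] + "TCGGAAGAGCACAC" + "ACGT"
        out = trim_read_pair(pair(seq), BarcodeScheme())
        assert out.seq1 == PAYLOAD[:30]

    def test_3p_adapter_with_n_wildcards_needs_8_exact(self):
        # NNNNNNNAGATCGGA: the 7 Ns match anything, the 8 fixed bases count
        seq = PAYLOAD[:30] + "GGGGGGG" + "AGATCGGA"
        out = trim_read_pair(pair(seq), BarcodeScheme())
        assert out.seq1 == PAYLOAD[:30]

    def test_partial_adapter_at_3p_end(self):
        seq = PAYLOAD[:32] + "TCGGAAGA"  # 8-base prefix of the adapter
        out = trim_read_pair(pair(seq), BarcodeScheme())
        assert out.seq1 == PAYLOAD[:32]

    def test_adapter_applies_to_read2_as_well(self):
        seq2 = "C" * 35 + "TCGGAAGAGCACAC"
        out = trim_read_pair(pair(PAYLOAD, seq2), BarcodeScheme())
        assert out.seq2 == "C" * 35

    def test_malformed_record_raises(self):
        with pytest.raises(ValueError, match="r"):
            trim_read_pair(ReadPair("r", "ACGT", "II", "ACGT", "IIII"),
                           BarcodeScheme())


class TestDecode:
    def test_well_formed_read_assigned(self, simple_scheme):
        p = pair("ACGTACGT" + "TCAG" + "GGG" + PAYLOAD)
        rec = decode_read_pair(p, simple_scheme)
        assert rec.status is ReadStatus.ASSIGNED
        assert rec.cell_id == "c7"
        assert rec.umi == "TCAG" + "C" * 7
        assert rec.payload1 == PAYLOAD

    def test_single_mismatch_rejected_under_exact_matching(self, simple_scheme):
        rec = decode_read_pair(pair("ACGTACGA" + "TCAG" + "GGG" + PAYLOAD),
                               simple_scheme)
        assert rec.status is ReadStatus.BARCODE1_MISMATCH

    def test_anchor_mutation_rejected(self, simple_scheme):
        rec = decode_read_pair(pair("ACGTACGT" + "TCAG" + "GGA" + PAYLOAD),
                               simple_scheme)
        assert rec.status is ReadStatus.ANCHOR_MISSING

    def test_read_shorter_than_structure_is_anchor_missing(self, simple_scheme):
        rec = decode_read_pair(pair("ACGTACGT" + "TCAG" + "GG"), simple_scheme)
        assert rec.status is ReadStatus.ANCHOR_MISSING

    def test_hamming1_rescue_accepts_unique_neighbor(self):
        scheme = BarcodeScheme(barcode1_table={"ACGTACGT": "c7"},
                               barcode_max_mismatch=1)
        rec = decode_read_pair(pair("ACGTACGA" + "TCAG" + "GGG" + PAYLOAD), scheme)
        assert rec.status is ReadStatus.ASSIGNED

    def test_hamming1_rescue_rejects_ambiguous_barcode(self):
        scheme = BarcodeScheme(barcode1_table={"AAAAAAAA": "c1", "AAAAAAAT": "c2"},
                               barcode_max_mismatch=1)
        # distance 1 from both table entries
        rec = decode_read_pair(pair("AAAAAAAC" + "TCAG" + "GGG" + PAYLOAD), scheme)
        assert rec.status is ReadStatus.BARCODE1_MISMATCH

    def test_index_checked_before_barcode1(self):
        scheme = BarcodeScheme(barcode1_table={"ACGTACGT": "c7"},
                               index_table={"GATC": "s1"})
        p = ReadPair("r", "TTTTTTTT" + "TCAG" + "GGG" + PAYLOAD,
                     Q * (15 + len(PAYLOAD)), "C" * 40, Q * 40,
                     comment="1:N:0:AAAA")
        assert decode_read_pair(p, scheme).status is ReadStatus.INDEX_MISMATCH

    def test_barcode2_consumed_from_read2_start(self):
        scheme = BarcodeScheme(barcode1_table={"ACGTACGT": "c7"},
                               barcode2_table={"GGCCGGCC": "r1"})
        p = pair("ACGTACGT" + "TCAG" + "GGG" + PAYLOAD, "GGCCGGCC" + "A" * 30)
        rec = decode_read_pair(p, scheme)
        assert rec.status is ReadStatus.ASSIGNED
        assert rec.cell_id == "c7_r1"
        assert rec.payload2 == "A" * 30

    def test_molecular_key_strategies(self, simple_scheme):
        p = pair("ACGTACGT" + "TCAG" + "GGG" + PAYLOAD, "GTACCAT" + "A" * 30)
        rec = decode_read_pair(p, simple_scheme)
        assert rec.molecular_key == "TCAG" + "GTACCAT"
        scheme2 = BarcodeScheme(barcode1_table={"ACGTACGT": "c7"},
                                dedup_strategy=DedupStrategy.PAYLOAD7_READ1_READ2)
        rec2 = decode_read_pair(p, scheme2)
        assert rec2.molecular_key == PAYLOAD[:7] + "GTACCAT"


def _rec(key, cell="c1"):
    return DecodedRead(name="r", status=ReadStatus.ASSIGNED, cell_id=cell,
                       molecular_key=key)


class TestDedup:
    def test_identical_keys_collapse_to_first(self):
        kept, dups = deduplicate_reads([_rec("AAAA"), _rec("AAAA")])
        assert len(kept) == 1 and dups == 1

    def test_differing_read2_bases_kept_separately(self):
        kept, dups = deduplicate_reads([_rec("AAAACCCGTAC"), _rec("AAAACCCGTAA")])
        assert len(kept) == 2 and dups == 0

    def test_mixed_cells_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            deduplicate_reads([_rec("A", "c1"), _rec("C", "c2")])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.text(alphabet="ACGT", min_size=1, max_size=4)))
    def test_output_plus_duplicates_conserves_input(self, keys):
        kept, dups = deduplicate_reads([_rec(k) for k in keys])
        assert len(kept) + dups == len(keys)
        assert len({r.molecular_key for r in kept}) == len(kept)

    def test_matches_hash_set_oracle_on_random_records(self):
        rng = random.Random(7)
        keys = ["".join(rng.choices("ACGT", k=6)) for _ in range(10_000)]
        kept, dups = deduplicate_reads([_rec(k) for k in keys])
        distinct = len(set(keys))  # independent hash-set dedup
        assert len(kept) == distinct
        assert dups == len(keys) - distinct
        # first-occurrence order is preserved
        seen, order = set(), []
        for k in keys:
            if k not in seen:
                seen.add(k)
                order.append(k)
        assert [r.molecular_key for r in kept] == order


@pytest.fixture(scope="module")
def dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    spec = SimulationSpec(populations=[PopulationSpec("p", 4)],
                          n_genes=20, mean_expression=12, seed=3)
    truth, scheme, reads = simulate_dataset(spec, out)
    return out, truth, scheme, reads


class TestDemultiplex:

    def test_error_free_reads_assigned_to_true_cells(self, dataset, tmp_path):
        out, truth, scheme, reads = dataset
        summary = demultiplex(out / "reads_R1.fastq", out / "reads_R2.fastq",
                              scheme, tmp_path)
        got = summary[summary.status == "ASSIGNED"].set_index("cell")["count"]
        expected = reads.groupby("cell").size()
        pd.testing.assert_series_equal(got.sort_index(), expected.sort_index(),
                                       check_names=False, check_dtype=False)

    def test_conservation_and_reproducibility(self, dataset, tmp_path):
        out, truth, scheme, reads = dataset
        s1 = demultiplex(out / "reads_R1.fastq", out / "reads_R2.fastq",
                         scheme, tmp_path / "a")
        s2 = demultiplex(out / "reads_R1.fastq", out / "reads_R2.fastq",
                         scheme, tmp_path / "b")
        assert s1["count"].sum() == len(reads)
        for f in sorted(p.name for p in (tmp_path / "a").iterdir()):
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_demultiplexing_own_output_is_a_noop(self, dataset, tmp_path):
        out, truth, scheme, reads = dataset
        demultiplex(out / "reads_R1.fastq", out / "reads_R2.fastq",
                    scheme, tmp_path / "first")
        cell = truth.cells["cell_id"].iloc[0]
        r1 = tmp_path / "first" / f"{cell}_R1.fastq"
        r2 = tmp_path / "first" / f"{cell}_R2.fastq"
        summary = demultiplex(r1, r2, scheme, tmp_path / "second",
                              decode_structure=False, cell_id=cell)
        n_in = sum(1 for _ in open(r1)) // 4
        row = summary[summary.cell == cell].iloc[0]
        assert row["count"] == n_in and row["duplicates"] == 0
        assert (tmp_path / "second" / f"{cell}_R1.fastq").read_bytes() == r1.read_bytes()

    def test_empty_input_gives_empty_outputs(self, tmp_path, simple_scheme):
        r1, r2 = tmp_path / "e1.fastq", tmp_path / "e2.fastq"
        r1.write_text("")
        r2.write_text("")
        summary = demultiplex(r1, r2, simple_scheme, tmp_path / "out")
        assert summary["count"].sum() == 0

    def test_corrupted_barcodes_land_in_undetermined_only(self, tmp_path):
        spec = SimulationSpec(populations=[PopulationSpec("p", 4)],
                              n_genes=20, mean_expression=12,
                              barcode_error_rate=0.1, seed=4)
        truth, scheme, reads = simulate_dataset(spec, tmp_path / "sim")
        summary = demultiplex(tmp_path / "sim" / "reads_R1.fastq",
                              tmp_path / "sim" / "reads_R2.fastq",
                              scheme, tmp_path / "dx")
        n_corrupt = int(reads["corrupted"].sum())
        assert n_corrupt > 0
        rejected = summary[summary.cell == "*"]["count"].sum()
        assert rejected == n_corrupt
        undet = (tmp_path / "dx" / "undetermined_R1.fastq").read_text()
        names = {line[1:].split()[0] for line in undet.splitlines()[::4]}
        assert names == set(reads.loc[reads["corrupted"], "read"])
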