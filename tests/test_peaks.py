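"""Window caller calibration, high-confidence filter, reciprocal consensus,
gene annotation and writer-dependent peaks."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_annotation, make_fragments
from scm6a.peaks import (CallerParams, ConsensusParams,
                         annotate_peaks_to_transcripts, call_candidate_peaks,
                         filter_high_confidence, mettl3_dependent_peaks,
                         reciprocal_consensus)


def poisson_tail_oracle(k, lam):
    """Independent exact survival sum P(X >= k), term-by-term recurrence."""
    log_term = -lam + k * math.log(lam) - math.lgamma(k + 1)
    term = math.exp(log_term)
    total, i = 0.0, k
    while term > 0 and i < k + 10_000:
        total += term
        i += 1
        term *= lam / i
        if term < total * 1e-18:
            total += term
            break
    return total


def frag_block(chrom, start, end, n, cell="c", fraction="IP"):
    return make_fragments([(chrom, start, end, cell, fraction)] * n)


class TestCaller:
    def test_pvalues_match_exact_survival_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = int(rng.integers(1, 200))
            lam = float(rng.uniform(0.5, 50))
            ours = stats.poisson.sf(k - 1, lam)  # the caller's tail computation
            oracle = poisson_tail_oracle(k, lam)
            assert ours == pytest.approx(oracle, rel=1e-10)

    def test_no_enrichment_yields_no_peaks(self):
        rng = np.random.default_rng(1)
        starts = rng.integers(0, 9_900, size=300)
        frags = make_fragments([("chr1", s, s + 100, "c", "IP") for s in starts])
        peaks = call_candidate_peaks(frags, frags.copy())
        assert peaks.empty

    def test_single_enriched_window_fold_about_ten(self):
        # 100 IP fragments in one window; balanced libraries make the
        # scaled control expectation 10
        ip = pd.concat([frag_block("chr1", 0, 100, 100)])
        ctrl = pd.concat([frag_block("chr1", 0, 100, 10, fraction="RNA"),
                          frag_block("chr2", 5_000, 5_100, 90, fraction="RNA")])
        peaks = call_candidate_peaks(ip, ctrl,
                                     genome_sizes={"chr1": 10_000, "chr2": 10_000})
        hit = peaks[peaks.Chromosome == "chr1"]
        assert len(hit) == 1
        assert hit.iloc[0]["fold_enrichment"] == pytest.approx(10, rel=0.05)
        # peak p-value agrees with the independent tail oracle
        expect = poisson_tail_oracle(100, 10.0)
        assert 10 ** (-hit.iloc[0]["neg_log10_p"]) == pytest.approx(expect, rel=1e-6)

    def test_nearby_significant_windows_merge_into_one_peak(self):
        ip = pd.concat([frag_block("chr1", 0, 100, 60),
                        frag_block("chr1", 180, 280, 60),
                        frag_block("chr2", 0, 5_000, 1)])
        ctrl = frag_block("chr2", 0, 10_000, 121, fraction="RNA")
        params = CallerParams(merge_gap=100)
        peaks = call_candidate_peaks(ip, ctrl, params,
                                     genome_sizes={"chr1": 10_000, "chr2": 10_000})
        assert (peaks.Chromosome == "chr1").sum() == 1
        far = call_candidate_peaks(
            pd.concat([frag_block("chr1", 0, 100, 60),
                       frag_block("chr1", 2_000, 2_100, 60),
                       frag_block("chr2", 0, 5_000, 1)]),
            ctrl, params, genome_sizes={"chr1": 10_000, "chr2": 10_000})
        assert (far.Chromosome == "chr1").sum() == 2

    def test_empty_fraction_rejected(self):
        frags = frag_block("chr1", 0, 100, 5)
        with pytest.raises(ValueError):
            call_candidate_peaks(frags.iloc[0:0], frags)

    def test_planted_peaks_recovered_with_high_confidence_filter(self, small_truth):
        frags = small_truth.fragments()
        ip = frags[frags.fraction == "IP"]
        rna = frags[frags.fraction == "RNA"]
        called = filter_high_confidence(
            call_candidate_peaks(ip, rna, genome_sizes=small_truth.chrom_sizes()))
        planted = small_truth.peaks.drop_duplicates("gene_id")
        hits = 0
        for pk in planted.itertuples(index=False):
            ov = called[(called.Chromosome == pk.Chromosome)
                        & (called.Start < pk.End) & (called.End > pk.Start)]
            hits += int(len(ov) > 0)
        assert hits / len(planted) >= 0.9


def random_peaks(rng, n):
    starts = rng.integers(0, 100_000, size=n)
    return pd.DataFrame({
        "Chromosome": rng.choice(["chr1", "chr2"], size=n),
        "Start": starts,
        "End": starts + rng.integers(50, 500, size=n),
        "name": [f"p{i}" for i in range(n)],
        "fold_enrichment": rng.uniform(0, 6, size=n).round(2),
        "neg_log10_q": rng.uniform(0, 30, size=n).round(2),
        "neg_log10_p": rng.uniform(0, 40, size=n),
        "summit_offset": 0,
    })


class TestFilter:
    @pytest.mark.parametrize("fe,q10,kept", [
        (3.0, 12.0, True),
        (2.0, 50.0, False),   # fold exactly at the threshold fails the strict rule
        (5.0, 10.0, False),   # q exactly at the threshold fails too
        (2.01, 10.01, True),
    ])
    def test_boundary_cases(self, fe, q10, kept):
        df = pd.DataFrame({"fold_enrichment": [fe], "neg_log10_q": [q10]})
        assert (len(filter_high_confidence(df)) == 1) is kept

    def test_matches_brute_force_and_is_idempotent(self):
        peaks = random_peaks(np.random.default_rng(3), 1000)
        once = filter_high_confidence(peaks)
        expected = [i for i, r in peaks.iterrows()
                    if r["fold_enrichment"] > 2 and r["neg_log10_q"] > 10]
        assert list(once.index) == expected
        pd.testing.assert_frame_equal(filter_high_confidence(once), once)

    def test_missing_field_raises(self):
        with pytest.raises(ValueError, match="fold_enrichment"):
            filter_high_confidence(pd.DataFrame({"neg_log10_q": [1.0]}))


def brute_force_consensus(a, b, fa, fb):
    kept = []
    for i, ra in a.iterrows():
        for _, rb in b.iterrows():
            if ra.Chromosome != rb.Chromosome:
                continue
            ov = min(ra.End, rb.End) - max(ra.Start, rb.Start)
            if ov <= 0:
                continue
            if ov / (ra.End - ra.Start) >= fa and ov / (rb.End - rb.Start) >= fb:
                kept.append(i)
                break
    return kept


class TestConsensus:
    def test_overlap_51_of_100_retained(self):
        a = pd.DataFrame({"Chromosome": ["chr1"], "Start": [0], "End": [100]})
        b = pd.DataFrame({"Chromosome": ["chr1"], "Start": [49], "End": [149]})
        assert len(reciprocal_consensus(a, b)) == 1

    def test_overlap_50_of_100_dropped(self):
        a = pd.DataFrame({"Chromosome": ["chr1"], "Start": [0], "End": [100]})
        b = pd.DataFrame({"Chromosome": ["chr1"], "Start": [50], "End": [150]})
        assert len(reciprocal_consensus(a, b)) == 0

    def test_matches_quadratic_oracle_on_random_intervals(self):
        rng = np.random.default_rng(4)
        a = random_peaks(rng, 500)
        b = random_peaks(rng, 500)
        got = reciprocal_consensus(a, b)
        assert list(got.index) == brute_force_consensus(a, b, 0.51, 0.51)

    def test_monotone_under_shrinking_subject_set(self):
        rng = np.random.default_rng(5)
        a = random_peaks(rng, 200)
        b = random_peaks(rng, 200)
        full = set(reciprocal_consensus(a, b).index)
        half = set(reciprocal_consensus(a, b.iloc[:100]).index)
        assert half <= full


class TestAnnotate:
    ann = None

    def setup_method(self):
        self.ann = make_annotation([
            ("gA", "chr1", 1_000, 2_000, "+"),
            ("gB", "chr1", 3_000, 4_000, "-"),
        ])

    def _peaks(self, rows):
        return pd.DataFrame(rows, columns=["Chromosome", "Start", "End", "name"])

    def test_peak_inside_one_exon_assigned(self):
        out = annotate_peaks_to_transcripts(
            self._peaks([("chr1", 1_100, 1_300, "p1")]), self.ann)
        assert out.iloc[0]["gene"] == "gA" and not out.iloc[0]["tie"]

    def test_low_overlap_left_unassigned(self):
        out = annotate_peaks_to_transcripts(
            self._peaks([("chr1", 1_900, 2_400, "p1")]), self.ann)
        assert pd.isna(out.iloc[0]["gene"])  # only 20% inside gA

    def test_equal_overlap_on_two_genes_reports_tie(self):
        ann = make_annotation([("gA", "chr1", 0, 1_000, "+"),
                               ("gB", "chr1", 0, 1_000, "-")])
        out = annotate_peaks_to_transcripts(
            self._peaks([("chr1", 100, 300, "p1")]), ann)
        assert sorted(out["gene"]) == ["gA", "gB"]
        assert out["tie"].all()


class TestWriterDependent:
    def _annotated(self, rows):
        df = pd.DataFrame(rows, columns=["Chromosome", "Start", "End", "name", "gene"])
        return df

    def test_control_only_peak_in_expressed_gene_is_dependent(self):
        ctrl = self._annotated([("chr1", 0, 100, "p1", "gA")])
        cko = pd.DataFrame(columns=["Chromosome", "Start", "End"])
        fpkm = pd.Series({"gA": 1.2})
        assert len(mettl3_dependent_peaks(ctrl, cko, fpkm)) == 1

    def test_peak_matched_in_knockout_is_not_dependent(self):
        ctrl = self._annotated([("chr1", 0, 100, "p1", "gA")])
        cko = pd.DataFrame({"Chromosome": ["chr1"], "Start": [0], "End": [100]})
        assert len(mettl3_dependent_peaks(ctrl, cko, pd.Series({"gA": 5.0}))) == 0

    def test_low_expression_gene_excluded(self):
        ctrl = self._annotated([("chr1", 0, 100, "p1", "gA")])
        cko = pd.DataFrame(columns=["Chromosome", "Start", "End"])
        assert len(mettl3_dependent_peaks(ctrl, cko, pd.Series({"gA": 0.5}))) == 0

    def test_gene_missing_from_expression_warns_and_excludes(self):
        ctrl = self._annotated([("chr1", 0, 100, "p1", "gA")])
        cko = pd.DataFrame(columns=["Chromosome", "Start", "End"])
        with pytest.warns(UserWarning, match="gA"):
            out = mettl3_dependent_peaks(ctrl, cko, pd.Series({"gB": 2.0}))
        assert len(out) == 0
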