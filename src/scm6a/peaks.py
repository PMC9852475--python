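"""m6A peak calling, filtering and consensus.

The internal caller scores sliding windows by an exact Poisson upper-tail
test of the IP fragment count against a library-size-scaled control
expectation, corrects across windows by Benjamini–Hochberg, and merges
significant windows into peaks.  Downstream, peaks are reduced to a
high-confidence set by the enrichment/q-value filter, to a dual-control
consensus by reciprocal overlap, annotated to genes by exonic overlap, and —
given a writer-knockout peak set — to writer-dependent peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneAnnotation
from .io import NARROWPEAK_COLUMNS

__all__ = [
    "CallerParams",
    "ConsensusParams",
    "call_candidate_peaks",
    "filter_high_confidence",
    "reciprocal_consensus",
    "annotate_peaks_to_transcripts",
    "mettl3_dependent_peaks",
]


@dataclass
class CallerParams:
    """Tuning knobs of the sliding-window caller.

    window/step in bp; ``min_lambda`` floors the per-window control
    expectation so unsampled control regions cannot produce infinite
    enrichment; ``q_threshold`` is the BH cutoff for window significance.
    """

    window: int = 100
    step: int = 50
    merge_gap: int = 50
    min_lambda: float = 1.0
    q_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not (self.window >= self.step > 0):
            raise ValueError("require window >= step > 0")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if self.min_lambda <= 0:
            raise ValueError("min_lambda must be > 0")


@dataclass
class ConsensusParams:
    """Minimum reciprocal overlap fractions (query side, subject side)."""

    frac_a: float = 0.51
    frac_b: float = 0.51

    def __post_init__(self) -> None:
        for f in (self.frac_a, self.frac_b):
            if not 0 < f <= 1:
                raise ValueError("overlap fractions must be in (0, 1]")


def _sorted_arrays(frags: pd.DataFrame, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    sub = frags[frags["Chromosome"] == chrom]
    return (np.sort(sub["Start"].to_numpy(int)), np.sort(sub["End"].to_numpy(int)))


def _overlap_counts(starts: np.ndarray, ends: np.ndarray,
                    win_start: np.ndarray, win_end: np.ndarray) -> np.ndarray:
    """Fragments overlapping each half-open window: start < we and end > ws."""
    return (np.searchsorted(starts, win_end, side="left")
            - np.searchsorted(ends, win_start, side="right"))


def call_candidate_peaks(
    ip: pd.DataFrame,
    control: pd.DataFrame,
    params: CallerParams | None = None,
    genome_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Call enrichment peaks of IP over control fragment coverage.

    Both inputs are fragment tables (Chromosome/Start/End).  Windows of
    ``params.window`` bp every ``params.step`` bp with at least one IP
    fragment are tested: p = P(Poisson(lambda) >= k) with k the IP count and
    lambda = max(min_lambda, control count x libIP/libCtrl).  BH q-values
    are computed over all tested windows of the run; windows with
    q < q_threshold are merged when closer than ``merge_gap``.  Deterministic.

    Returns a narrowPeak-shaped DataFrame sorted by (Chromosome, Start).
    """
    params = params or CallerParams()
    if ip.empty or control.empty:
        raise ValueError("both IP and control fragment sets must be non-empty")
    lib_ip, lib_ctrl = float(len(ip)), float(len(control))
    scale = lib_ip / lib_ctrl

    chroms = sorted(set(ip["Chromosome"]).union(control["Chromosome"]))
    win_rows = []
    for chrom in chroms:
        ip_s, ip_e = _sorted_arrays(ip, chrom)
        ct_s, ct_e = _sorted_arrays(control, chrom)
        if genome_sizes is not None:
            extent = genome_sizes.get(chrom, 0)
        else:
            extent = int(max(ip_e.max(initial=0), ct_e.max(initial=0)))
        if extent <= 0:
            raise ValueError(f"zero-length extent for chromosome {chrom!r}")
        ws = np.arange(0, extent, params.step)
        we = np.minimum(ws + params.window, extent)
        k_ip = _overlap_counts(ip_s, ip_e, ws, we)
        k_ct = _overlap_counts(ct_s, ct_e, ws, we)
        mask = k_ip > 0
        if not mask.any():
            continue
        lam = np.maximum(params.min_lambda, k_ct[mask] * scale)
        pvals = stats.poisson.sf(k_ip[mask] - 1, lam)
        win_rows.append(pd.DataFrame({
            "Chromosome": chrom, "Start": ws[mask], "End": we[mask],
            "k_ip": k_ip[mask], "p": pvals,
        }))
    if not win_rows:
        return _empty_peaks()
    windows = pd.concat(win_rows, ignore_index=True)
    windows["q"] = multipletests(windows["p"].to_numpy(), method="fdr_bh")[1]
    sig = windows[windows["q"] < params.q_threshold]
    if sig.empty:
        return _empty_peaks()

    peaks = []
    for chrom, sub in sig.groupby("Chromosome", sort=True):
        sub = sub.sort_values("Start")
        ip_s, ip_e = _sorted_arrays(ip, chrom)
        ct_s, ct_e = _sorted_arrays(control, chrom)
        cur_s, cur_e, cur_q = None, None, np.inf
        intervals = []
        for row in sub.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e, cur_q = row.Start, row.End, row.q
            elif row.Start - cur_e <= params.merge_gap:
                cur_e = max(cur_e, row.End)
                cur_q = min(cur_q, row.q)
            else:
                intervals.append((cur_s, cur_e, cur_q))
                cur_s, cur_e, cur_q = row.Start, row.End, row.q
        intervals.append((cur_s, cur_e, cur_q))
        for s, e, qmin in intervals:
            k_ip = int(_overlap_counts(ip_s, ip_e, np.array([s]), np.array([e]))[0])
            k_ct = int(_overlap_counts(ct_s, ct_e, np.array([s]), np.array([e]))[0])
            lam = max(params.min_lambda * (e - s) / params.window, k_ct * scale)
            p = float(stats.poisson.sf(k_ip - 1, lam))
            fe = k_ip / lam
            summit = _summit(ip_s, ip_e, s, e)
            peaks.append({
                "Chromosome": chrom, "Start": int(s), "End": int(e),
                "fold_enrichment": fe,
                "neg_log10_p": _neg_log10(p),
                "neg_log10_q": _neg_log10(qmin),
                "summit_offset": summit - int(s),
            })
    out = pd.DataFrame(peaks).sort_values(["Chromosome", "Start"]).reset_index(drop=True)
    out["name"] = [f"peak_{i + 1}" for i in range(len(out))]
    out["score"] = np.minimum(1000, np.round(10 * out["neg_log10_q"]).astype(int))
    out["Strand"] = "."
    return out[NARROWPEAK_COLUMNS]


def _neg_log10(p: float, cap: float = 323.0) -> float:
    if p <= 0:
        return cap
    return float(min(cap, -np.log10(p)))


def _summit(starts: np.ndarray, ends: np.ndarray, s: int, e: int) -> int:
    """Leftmost position of maximum IP per-base coverage inside [s, e)."""
    cov = np.zeros(e - s + 1, dtype=np.int64)
    lo = np.clip(starts, s, e) - s
    hi = np.clip(ends, s, e) - s
    keep = hi > lo
    np.add.at(cov, lo[keep], 1)
    np.add.at(cov, hi[keep], -1)
    depth = np.cumsum(cov[:-1])
    return s + int(np.argmax(depth))


def _empty_peaks() -> pd.DataFrame:
    return pd.DataFrame(columns=NARROWPEAK_COLUMNS)


def filter_high_confidence(peaks: pd.DataFrame,
                           min_fold: float = 2.0,
                           min_neg_log10_q: float = 10.0) -> pd.DataFrame:
    """Keep peaks with fold_enrichment > 2 and -log10(q) > 10 (both strict)."""
    for col in ("fold_enrichment", "neg_log10_q"):
        if col not in peaks.columns:
            raise ValueError(f"peak table lacks required column {col!r}")
        if peaks[col].isna().any():
            bad = peaks.index[peaks[col].isna()][0]
            raise ValueError(f"peak record {bad!r} has missing {col}")
    keep = (peaks["fold_enrichment"] > min_fold) & (peaks["neg_log10_q"] > min_neg_log10_q)
    return peaks[keep]


def reciprocal_consensus(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame,
                         params: ConsensusParams | None = None) -> pd.DataFrame:
    """Subset of ``peaks_a`` reciprocally overlapped by some peak of ``peaks_b``.

    A query peak survives iff a subject peak covers >= frac_a of the query
    AND the shared span is >= frac_b of that subject peak (bedtools
    ``-f/-F`` semantics with both fractions required).  Order of ``peaks_a``
    is preserved.
    """
    params = params or ConsensusParams()
    if peaks_a.empty or peaks_b.empty:
        return peaks_a.iloc[0:0]
    a = peaks_a[["Chromosome", "Start", "End"]].copy()
    a["_idx"] = np.arange(len(a))
    b = peaks_b[["Chromosome", "Start", "End"]].copy()
    joined = pr.PyRanges(a).join(pr.PyRanges(b)).df
    if joined.empty:
        return peaks_a.iloc[0:0]
    ov = (np.minimum(joined["End"], joined["End_b"])
          - np.maximum(joined["Start"], joined["Start_b"]))
    len_a = joined["End"] - joined["Start"]
    len_b = joined["End_b"] - joined["Start_b"]
    ok = (ov / len_a >= params.frac_a) & (ov / len_b >= params.frac_b)
    kept = np.sort(joined.loc[ok, "_idx"].unique())
    return peaks_a.iloc[kept]


def annotate_peaks_to_transcripts(peaks: pd.DataFrame, annotation: GeneAnnotation,
                                  min_frac: float = 0.5) -> pd.DataFrame:
    """Assign each peak to the gene with the largest exonic overlap.

    Requires the winning overlap to be >= ``min_frac`` of the peak length;
    ties report every tied gene (one row each, ``tie=True``).  Unassigned
    peaks appear once with ``gene`` NaN.  Returns columns
    (name, gene, overlap_bp, overlap_frac, gene_strand, tie).
    """
    if peaks.empty:
        return pd.DataFrame(columns=["name", "gene", "overlap_bp", "overlap_frac",
                                     "gene_strand", "tie"])
    p = peaks[["Chromosome", "Start", "End", "name"]].copy()
    p["_idx"] = np.arange(len(p))
    joined = pr.PyRanges(p).join(annotation.exon_ranges(), apply_strand_suffix=False).df
    assignments = {}
    if not joined.empty:
        joined["ov"] = (np.minimum(joined["End"], joined["End_b"])
                        - np.maximum(joined["Start"], joined["Start_b"]))
        per_gene = (joined.groupby(["_idx", "gene_id"])
                    .agg(ov=("ov", "sum"), strand=("Strand", "first"))
                    .reset_index())
        for idx, sub in per_gene.groupby("_idx"):
            best = sub["ov"].max()
            plen = int(peaks.iloc[idx]["End"] - peaks.iloc[idx]["Start"])
            if best / plen < min_frac:
                continue
            winners = sub[sub["ov"] == best].sort_values("gene_id")
            assignments[idx] = winners
    rows = []
    for idx in range(len(peaks)):
        name = peaks.iloc[idx]["name"]
        plen = int(peaks.iloc[idx]["End"] - peaks.iloc[idx]["Start"])
        if idx in assignments:
            winners = assignments[idx]
            tie = len(winners) > 1
            for rec in winners.itertuples(index=False):
                rows.append({"name": name, "gene": rec.gene_id,
                             "overlap_bp": int(rec.ov),
                             "overlap_frac": rec.ov / plen,
                             "gene_strand": rec.strand, "tie": tie})
        else:
            rows.append({"name": name, "gene": np.nan, "overlap_bp": 0,
                         "overlap_frac": 0.0, "gene_strand": ".", "tie": False})
    return pd.DataFrame(rows)


def mettl3_dependent_peaks(
    control_peaks: pd.DataFrame,
    cko_peaks: pd.DataFrame,
    expression: pd.Series,
    consensus: ConsensusParams | None = None,
    min_fpkm: float = 1.0,
) -> pd.DataFrame:
    """Writer-dependent peaks: in control, absent from the knockout, expressed.

    ``control_peaks`` must carry a ``gene`` column (from
    :func:`annotate_peaks_to_transcripts`); ``expression`` maps gene ->
    control FPKM.  A control peak is dependent iff no knockout peak matches
    it under the reciprocal-overlap rule and its gene has FPKM >= 1.
    """
    matched = reciprocal_consensus(control_peaks, cko_peaks, consensus) \
        if not cko_peaks.empty else control_peaks.iloc[0:0]
    only = control_peaks.loc[~control_peaks.index.isin(matched.index)]
    if "gene" not in only.columns:
        raise ValueError("control peaks need a 'gene' column; annotate them first")
    keep = []
    for idx, rec in only.iterrows():
        gene = rec["gene"]
        if pd.isna(gene):
            continue
        if gene not in expression.index:
            warnings.warn(f"gene {gene!r} missing from expression table; "
                          f"peak {rec.get('name', idx)!r} excluded")
            continue
        if expression.loc[gene] >= min_fpkm:
            keep.append(idx)
    return only.loc[keep]
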