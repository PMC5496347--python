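"""Fragment-to-feature assignment, TPM normalization, expression tiers,
per-base coverage and UTR plateau detection.

The assignment mimics a two-pass mapping strategy: any fragment touching a
ribosomal RNA feature by at least one nucleotide goes to the rRNA category
first; remaining fragments go to the annotated feature with the largest
overlap, provided that overlap covers at least half the fragment, and are
intergenic otherwise.  Counting is unstranded by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    CoverageTrack,
    FeatureTable,
    FragmentPlacement,
    FragmentSet,
    RegionCall,
    TxscapeError,
    merge_intervals,
)

logger = logging.getLogger(__name__)

#: integer codes for per-fragment categories
CAT_RRNA, CAT_CDS, CAT_OTHER_FEATURE, CAT_UTR, CAT_INTERGENIC = range(5)

CATEGORY_NAMES = {
    CAT_RRNA: "rRNA",
    CAT_CDS: "CDS",
    CAT_OTHER_FEATURE: "other_feature",
    CAT_UTR: "UTR",
    CAT_INTERGENIC: "other_intergenic",
}


@dataclass
class FragmentAssignment:
    """Result of partitioning fragments among rRNA/feature/intergenic."""

    counts: dict[str, int]
    category: np.ndarray  # per-fragment category code
    feature_index: np.ndarray  # per-fragment index into the feature table, -1 if none
    coverage: CoverageTrack
    n_fragments: int

    def category_sets(self) -> dict[str, np.ndarray]:
        return {
            name: np.flatnonzero(self.category == code)
            for code, name in CATEGORY_NAMES.items()
        }


class ExpressionTable:
    """Per-feature counts and TPM for one condition.

    Wraps a DataFrame with columns ``feature_id, length, count, tpm, tier``.
    ``average_tpm`` and ``median_tpm`` are computed over CDS records only,
    matching the convention of excluding rRNA and other non-coding features
    from the genome-wide averages.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        condition: str = "",
        category_fractions: Optional[dict[str, float]] = None,
    ):
        required = {"feature_id", "length", "count", "tpm"}
        if not required <= set(df.columns):
            raise TxscapeError(f"expression table missing {required - set(df.columns)}")
        if "tier" not in df.columns:
            df = df.assign(tier="")
        if "is_cds" not in df.columns:
            df = df.assign(is_cds=True)
        self.df = df.reset_index(drop=True)
        self.condition = condition
        self.category_fractions = category_fractions
        self.p10_count_threshold: Optional[float] = None
        self.frac_above_p10: Optional[float] = None

    def __len__(self) -> int:
        return len(self.df)

    @property
    def cds_df(self) -> pd.DataFrame:
        return self.df[self.df["is_cds"]]

    @property
    def average_tpm(self) -> float:
        return float(self.cds_df["tpm"].mean())

    @property
    def median_tpm(self) -> float:
        return float(self.cds_df["tpm"].median())

    @property
    def total_tpm(self) -> float:
        return float(self.df["tpm"].sum())

    def feature_ids(self) -> list[str]:
        return list(self.df["feature_id"])

    def tpm_series(self) -> pd.Series:
        return self.df.set_index("feature_id")["tpm"]

    def to_tsv(self, path: str | Path) -> None:
        out = self.df[["feature_id", "length", "count", "tpm", "tier"]].copy()
        out["tpm"] = out["tpm"].map(lambda v: f"{v:.6g}")
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

def _interval_mask_cumsum(
    intervals: Sequence[tuple[int, int]], genome_length: int
) -> np.ndarray:
    """Cumulative count of masked bases; overlap of [s,e) = cum[e]-cum[s]."""
    diff = np.zeros(genome_length + 1, dtype=np.int64)
    for s, e in merge_intervals(intervals):
        diff[s] += 1
        diff[e] -= 1
    mask = np.cumsum(diff[:-1]) > 0
    cum = np.zeros(genome_length + 1, dtype=np.int64)
    np.cumsum(mask, out=cum[1:])
    return cum


def assign_fragments(
    placements: Sequence[FragmentPlacement],
    feature_table: FeatureTable,
    genome_length: int,
    rrna_first: bool = True,
    stranded: bool = False,
) -> FragmentAssignment:
    """Partition fragments among rRNA / annotated features / intergenic.

    Rules, applied per fragment:

    1. overlaps an rRNA feature by >= 1 nt -> rRNA category (two-pass mimic);
    2. else the feature with the largest overlap wins, if that overlap is at
       least 50% of the fragment length (ties broken by leftmost feature
       start);
    3. else intergenic.

    Coverage accumulates every retained fragment, including rRNA.
    """
    fs = FragmentSet.from_placements(placements)
    n = len(fs)
    if n == 0:
        warnings.warn("empty placement list: zero expression table")
    rrna_feats = feature_table.rrna
    if rrna_first and not rrna_feats:
        raise TxscapeError("rRNA-first assignment requested but no rRNA features")

    frag_start = fs.starts
    frag_end = fs.ends
    frag_len = frag_end - frag_start
    frag_strand = fs.strand_codes

    category = np.full(n, CAT_INTERGENIC, dtype=np.int8)
    feature_index = np.full(n, -1, dtype=np.int64)

    # coverage from all retained fragments
    cov_diff = np.bincount(frag_start, minlength=genome_length + 1) - np.bincount(
        frag_end, minlength=genome_length + 1
    )
    coverage = CoverageTrack(np.cumsum(cov_diff[:-1]))

    # pass 1: rRNA catch-all
    assignable = np.ones(n, dtype=bool)
    if rrna_first and rrna_feats and n:
        cum = _interval_mask_cumsum(
            [(f.start, f.end) for f in rrna_feats], genome_length
        )
        rrna_ov = cum[frag_end] - cum[frag_start]
        is_rrna = rrna_ov >= 1
        category[is_rrna] = CAT_RRNA
        assignable &= ~is_rrna

    all_start = np.array([f.start for f in feature_table], dtype=np.int64)
    all_end = np.array([f.end for f in feature_table], dtype=np.int64)
    all_strand = np.array(
        [1 if f.strand == "+" else -1 for f in feature_table], dtype=np.int8
    )
    all_is_cds = np.array([f.ftype == "CDS" for f in feature_table], dtype=bool)

    # pass 2: largest-overlap feature assignment
    feats = [
        (i, f)
        for i, f in enumerate(feature_table)
        if not (rrna_first and f.ftype == "rRNA")
    ]
    if feats and assignable.any() and n:
        cand_idx = np.flatnonzero(assignable)
        cs, ce = frag_start[cand_idx], frag_end[cand_idx]
        order = np.argsort(cs, kind="stable")
        cand_idx, cs, ce = cand_idx[order], cs[order], ce[order]
        max_frag = int(frag_len.max())

        feat_idx = np.array([fi for fi, _ in feats], dtype=np.int64)
        lo = np.searchsorted(cs, all_start[feat_idx] - max_frag, side="left")
        hi = np.searchsorted(cs, all_end[feat_idx], side="left")
        cnt = np.maximum(0, hi - lo)
        total = int(cnt.sum())
        pos = pt = np.empty(0, dtype=np.int64)
        if total:
            cum_cnt = np.concatenate([[0], np.cumsum(cnt)])
            pt = np.repeat(feat_idx, cnt)
            pos = (
                np.arange(total) - np.repeat(cum_cnt[:-1], cnt) + np.repeat(lo, cnt)
            )
            keep0 = ce[pos] > all_start[pt]
            pos, pt = pos[keep0], pt[keep0]
        if pos.size:
            pf = cand_idx[pos]
            f_start = all_start[pt]
            f_end = all_end[pt]
            ov = np.minimum(f_end, frag_end[pf]) - np.maximum(f_start, frag_start[pf])
            keep = 2 * ov >= frag_len[pf]
            if stranded:
                keep &= (frag_strand[pf] == 0) | (frag_strand[pf] == all_strand[pt])
            pf, pt, ov, f_start = pf[keep], pt[keep], ov[keep], f_start[keep]
            if pf.size:
                # best per fragment: max overlap, ties -> leftmost feature start
                sort = np.lexsort((f_start, -ov, pf))
                pf_s, pt_s = pf[sort], pt[sort]
                first = np.ones(pf_s.size, dtype=bool)
                first[1:] = pf_s[1:] != pf_s[:-1]
                winners_frag = pf_s[first]
                winners_feat = pt_s[first]
                feature_index[winners_frag] = winners_feat
                category[winners_frag] = np.where(
                    all_is_cds[winners_feat], CAT_CDS, CAT_OTHER_FEATURE
                ).astype(np.int8)

    counts = {f.feature_id: 0 for f in feature_table}
    if n:
        assigned = feature_index >= 0
        idx, cnt = np.unique(feature_index[assigned], return_counts=True)
        for i, c in zip(idx, cnt):
            counts[feature_table[int(i)].feature_id] = int(c)
        # rRNA-category fragments count toward the rRNA feature they touch most
        if rrna_first and rrna_feats:
            rr_idx = np.flatnonzero(category == CAT_RRNA)
            if rr_idx.size:
                best_ov = np.zeros(rr_idx.size, dtype=np.int64)
                best_feat = np.full(rr_idx.size, -1, dtype=np.int64)
                for k, f in enumerate(rrna_feats):
                    o = np.minimum(f.end, frag_end[rr_idx]) - np.maximum(
                        f.start, frag_start[rr_idx]
                    )
                    better = o > best_ov
                    best_ov[better] = o[better]
                    best_feat[better] = k
                for k, f in enumerate(rrna_feats):
                    counts[f.feature_id] += int(np.count_nonzero(best_feat == k))

    return FragmentAssignment(
        counts=counts,
        category=category,
        feature_index=feature_index,
        coverage=coverage,
        n_fragments=n,
    )


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def compute_tpm(
    counts: Mapping[str, int],
    feature_table: FeatureTable,
    denominator: str = "cds_only",
    condition: str = "",
    category_fractions: Optional[dict[str, float]] = None,
) -> ExpressionTable:
    """Length-normalized TPM over the chosen denominator feature set.

    tpm_i = 1e6 * (count_i / len_i) / sum_j (count_j / len_j) with j ranging
    over CDS only (default) or over all annotated features.
    """
    if denominator == "cds_only":
        feats = feature_table.cds
    elif denominator == "all_features":
        feats = list(feature_table)
    else:
        raise TxscapeError(f"unknown denominator {denominator!r}")
    if not feats:
        raise TxscapeError("no features in denominator set")

    ids = [f.feature_id for f in feats]
    lengths = np.array([f.length for f in feats], dtype=np.int64)
    cvec = np.array([counts.get(i, 0) for i in ids], dtype=np.float64)
    if (cvec < 0).any():
        raise TxscapeError("negative counts")
    rate = cvec / lengths
    total = rate.sum()
    if total == 0:
        warnings.warn(f"all-zero counts for condition {condition!r}: TPM set to 0")
        tpm = np.zeros_like(rate)
    else:
        tpm = 1e6 * rate / total
    df = pd.DataFrame(
        {
            "feature_id": ids,
            "length": lengths,
            "count": cvec.astype(np.int64),
            "tpm": tpm,
            "is_cds": [f.ftype == "CDS" for f in feats],
        }
    )
    return ExpressionTable(df, condition=condition, category_fractions=category_fractions)


def classify_tiers(table: ExpressionTable) -> ExpressionTable:
    """Attach expression tiers relative to the table's mean CDS TPM.

    silent: zero count; sub_tpm: TPM < 1; ge10x/ge5x/ge2.5x: TPM >= k * mean
    (highest applicable); avg: TPM >= mean; below_avg otherwise.  Also records
    the 10th-percentile read-count threshold and the fraction of CDS above it.
    """
    avg = table.average_tpm
    tpm = table.df["tpm"].to_numpy()
    cnt = table.df["count"].to_numpy()
    tier = np.full(len(table.df), "below_avg", dtype=object)
    tier[tpm >= avg] = "avg"
    for k, name in ((2.5, "ge2.5x"), (5, "ge5x"), (10, "ge10x")):
        tier[tpm >= k * avg] = name
    tier[tpm < 1] = "sub_tpm"
    tier[cnt == 0] = "silent"
    table.df["tier"] = tier
    cds_counts = table.cds_df["count"].to_numpy()
    if cds_counts.size:
        p10 = float(np.percentile(cds_counts, 10))
        table.p10_count_threshold = p10
        table.frac_above_p10 = float(np.mean(cds_counts > p10))
    return table


# ---------------------------------------------------------------------------
# UTRs and category fractions
# ---------------------------------------------------------------------------

def _leading_true(mask: np.ndarray) -> int:
    """Length of the leading all-True run."""
    if mask.size == 0:
        return 0
    nz = np.flatnonzero(~mask)
    return int(nz[0]) if nz.size else int(mask.size)


def detect_utrs(
    coverage: CoverageTrack,
    feature_table: FeatureTable,
    expression: ExpressionTable,
    min_cov: Optional[float] = None,
    max_extent: int = 500,
) -> list[RegionCall]:
    """Call UTR plateaus flanking expressed CDS.

    From each boundary of a CDS with nonzero count, extend outward while the
    per-base depth stays at or above ``min_cov`` (default: max(5, 10% of the
    flanking gene's mean coverage)), stopping at the nearest annotated feature
    or after ``max_extent`` nt.  Overlapping calls are merged.
    """
    if min_cov is not None and min_cov < 1:
        raise TxscapeError("min_cov must be >= 1")
    vals = coverage.values
    L = len(vals)
    counts = expression.df.set_index("feature_id")["count"]
    feats = feature_table.features
    nf = len(feats)
    starts = np.array([f.start for f in feats])
    ends = np.array([f.end for f in feats])
    # nearest annotated neighbour boundaries (features are sorted by start)
    prev_end = np.zeros(nf, dtype=np.int64)  # max end among features before i
    if nf > 1:
        prev_end[1:] = np.maximum.accumulate(ends[:-1])
    next_start = np.full(nf, L, dtype=np.int64)
    if nf > 1:
        next_start[:-1] = starts[1:]
    # cumulative depth for O(1) mean-depth queries
    cum = np.concatenate([[0], np.cumsum(vals, dtype=np.int64)])

    raw: list[tuple[int, int, str]] = []
    for i, f in enumerate(feats):
        if f.ftype != "CDS" or counts.get(f.feature_id, 0) == 0:
            continue
        thr = min_cov if min_cov is not None else max(
            5.0, 0.1 * (cum[f.end] - cum[f.start]) / f.length
        )
        # upstream (left of start): stop at the closest feature end to the left
        left_lim = max(0, f.start - max_extent, min(int(prev_end[i]), f.start))
        seg = vals[left_lim: f.start][::-1]
        run = _leading_true(seg >= thr)
        if run > 0:
            raw.append((f.start - run, f.start, f.feature_id))
        # downstream (right of end)
        right_lim = min(L, f.end + max_extent, max(int(next_start[i]), f.end))
        seg = vals[f.end: right_lim]
        run = _leading_true(seg >= thr)
        if run > 0:
            raw.append((f.end, f.end + run, f.feature_id))

    merged = merge_intervals([(s, e) for s, e, _ in raw])
    raw.sort()
    calls = []
    j = 0
    for s, e in merged:
        members = set()
        while j < len(raw) and raw[j][0] < e:
            if raw[j][1] > s:
                members.add(raw[j][2])
            j += 1
        calls.append(
            RegionCall(
                kind="utr",
                start=s,
                end=e,
                score=float(vals[s:e].mean()),
                members=tuple(sorted(members)),
            )
        )
    return calls


def apply_utr_category(
    assignment: FragmentAssignment,
    placements: Sequence[FragmentPlacement],
    utr_calls: Sequence[RegionCall],
    genome_length: int,
) -> FragmentAssignment:
    """Re-label intergenic fragments overlapping a UTR by >=50% as UTR."""
    if not utr_calls:
        return assignment
    fs = FragmentSet.from_placements(placements)
    cum = _interval_mask_cumsum([(u.start, u.end) for u in utr_calls], genome_length)
    inter = np.flatnonzero(assignment.category == CAT_INTERGENIC)
    if inter.size:
        s = fs.starts[inter]
        e = fs.ends[inter]
        is_utr = 2 * (cum[e] - cum[s]) >= (e - s)
        assignment.category[inter[is_utr]] = CAT_UTR
    return assignment


def category_fractions(assignment: FragmentAssignment) -> dict[str, float]:
    """Fraction of retained fragments per category; sums to 1."""
    n = assignment.n_fragments
    out = {}
    for code, name in CATEGORY_NAMES.items():
        out[name] = (
            float(np.count_nonzero(assignment.category == code)) / n if n else 0.0
        )
    return out


__all__ = [
    "FragmentAssignment",
    "ExpressionTable",
    "assign_fragments",
    "compute_tpm",
    "classify_tiers",
    "detect_utrs",
    "apply_utr_category",
    "category_fractions",
    "CATEGORY_NAMES",
]
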