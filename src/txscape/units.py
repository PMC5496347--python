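"""Polycistronic transcription-unit inference and intergenic transcribed
islands (putative small non-coding RNAs).

Units are maximal runs of same-strand consecutive CDS whose intergenic gaps
are short (overlaps count as gaps <= 0), optionally split where per-gene
coverage becomes uneven — an operon is expected to show a more or less even
read distribution over its members.  Islands are intervals of high coverage
lying entirely outside annotated features and called UTRs, in the size range
of small RNAs.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    CoverageTrack,
    FeatureTable,
    RegionCall,
    merge_intervals,
)


def _cv(values: list[float]) -> float:
    """Sample coefficient of variation (ddof=1); 0 for a single value."""
    if len(values) < 2:
        return 0.0
    arr = np.asarray(values, dtype=float)
    m = arr.mean()
    if m == 0:
        return float("inf") if arr.std(ddof=1) > 0 else 0.0
    return float(arr.std(ddof=1) / m)


def infer_units(
    feature_table: FeatureTable,
    coverage: Optional[CoverageTrack] = None,
    gap_max: int = 30,
    evenness_cv_max: float = 1.0,
) -> list[RegionCall]:
    """Group CDS into transcription units.

    Adjacency rule: consecutive CDS on the same strand with an intergenic gap
    of at most ``gap_max`` nt (gap <= 0 for overlapping genes) belong to one
    candidate unit; the boundary gap is compared inclusively.  When coverage
    is given, a candidate unit is split before any gene whose addition pushes
    the coefficient of variation of member mean coverages above
    ``evenness_cv_max``.  Singleton genes become monocistronic units.
    """
    cds = feature_table.cds
    units: list[list] = []
    for f in cds:
        if units:
            prev = units[-1][-1]
            gap = f.start - prev.end
            if f.strand == prev.strand and gap <= gap_max:
                if coverage is None:
                    units[-1].append(f)
                    continue
                means = [coverage.mean_depth(g.start, g.end) for g in units[-1]]
                if _cv(means + [coverage.mean_depth(f.start, f.end)]) <= evenness_cv_max:
                    units[-1].append(f)
                    continue
        units.append([f])
    calls = []
    for members in units:
        score = (
            float(np.mean([coverage.mean_depth(g.start, g.end) for g in members]))
            if coverage is not None
            else float(len(members))
        )
        calls.append(
            RegionCall(
                kind="transcription_unit",
                start=members[0].start,
                end=max(g.end for g in members),
                score=score,
                members=tuple(g.feature_id for g in members),
            )
        )
    return calls


def unit_evidence_table(
    units: Sequence[RegionCall],
    feature_table: FeatureTable,
    coverage: Optional[CoverageTrack],
) -> pd.DataFrame:
    """Per-unit member coverage statistics (evidence table)."""
    by_id = {f.feature_id: f for f in feature_table}
    rows = []
    for i, u in enumerate(units):
        means = (
            [coverage.mean_depth(by_id[m].start, by_id[m].end) for m in u.members]
            if coverage is not None
            else []
        )
        rows.append(
            {
                "unit_id": f"TU{i + 1:04d}",
                "start": u.start,
                "end": u.end,
                "n_genes": len(u.members),
                "members": "+".join(u.members),
                "mean_coverage": float(np.mean(means)) if means else float("nan"),
                "coverage_cv": _cv(means) if means else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def call_islands(
    coverage: CoverageTrack,
    feature_table: FeatureTable,
    utr_calls: Sequence[RegionCall] = (),
    min_len: int = 30,
    max_len: int = 500,
    min_depth_factor: float = 5.0,
) -> list[RegionCall]:
    """Intergenic transcribed islands: candidate small non-coding RNAs.

    Maximal intervals with per-base depth >= ``min_depth_factor`` times the
    median mean-depth of expressed CDS, lying entirely outside annotated
    features and called UTRs, retained if their length is within
    [min_len, max_len].  A candidate run that directly abuts covered
    annotated/UTR sequence is a clipped continuation of that signal, not a
    detached island, and is discarded.  Score = mean depth.
    """
    vals = coverage.values
    if vals.sum() == 0:
        warnings.warn("all-zero coverage: no islands")
        return []
    cds_depths = [
        coverage.mean_depth(f.start, f.end) for f in feature_table.cds
    ]
    expressed = [d for d in cds_depths if d > 0]
    if not expressed:
        warnings.warn("no expressed CDS: no islands")
        return []
    threshold = min_depth_factor * float(np.median(expressed))

    excluded = merge_intervals(
        [(f.start, f.end) for f in feature_table]
        + [(u.start, u.end) for u in utr_calls]
    )
    excl_mask = np.zeros(len(vals), dtype=bool)
    for s, e in excluded:
        excl_mask[s:e] = True

    ok = (vals >= threshold) & ~excl_mask
    edges = np.flatnonzero(np.diff(np.concatenate([[0], ok.view(np.int8), [0]])))
    calls = []
    for s, e in zip(edges[::2], edges[1::2]):
        s, e = int(s), int(e)
        if not (min_len <= e - s <= max_len):
            continue
        # discard clipped continuations of covered annotated/UTR signal
        if s > 0 and excl_mask[s - 1] and vals[s - 1] >= threshold:
            continue
        if e < len(vals) and excl_mask[e] and vals[e] >= threshold:
            continue
        calls.append(
            RegionCall(
                kind="transcribed_island",
                start=s,
                end=e,
                score=float(vals[s:e].mean()),
            )
        )
    for c in calls:  # post-hoc invariant: islands never overlap exclusions
        assert not excl_mask[c.start: c.end].any()
    return calls


def annotate_islands(
    islands: Sequence[RegionCall], ncrna_bed: Sequence[RegionCall]
) -> pd.DataFrame:
    """Overlap report of islands against a user-supplied ncRNA BED."""
    rows = []
    for isl in islands:
        hits = [
            r
            for r in ncrna_bed
            if r.start < isl.end and r.end > isl.start
        ]
        rows.append(
            {
                "start": isl.start,
                "end": isl.end,
                "length": isl.length,
                "mean_depth": isl.score,
                "overlap_hint": ",".join(
                    f"{r.start}-{r.end}" for r in hits
                ),
            }
        )
    return pd.DataFrame(rows)


__all__ = ["infer_units", "call_islands", "unit_evidence_table", "annotate_islands"]
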