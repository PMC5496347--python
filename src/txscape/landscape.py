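"""Positional genome tracks and region calls.

Sliding-window GC deviation, hypothetical-gene density, low-expression
region calling, genome half/quartile TPM shares and per-arCOG expression
summaries.

Window statistics are estimates centered at the window midpoint; merged
region calls therefore span the *centers* of the flagged windows rather
than their full extents, which removes the half-window smearing a union of
overlapping windows would add at region boundaries.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    FeatureTable,
    Genome,
    RegionCall,
    TxscapeError,
    WindowStat,
)
from .quantify import ExpressionTable

LOG_PSEUDOCOUNT = 0.1  # TPM added before every log10 transform


# ---------------------------------------------------------------------------
# GC track
# ---------------------------------------------------------------------------

def gc_track(genome: Genome, window: int = 5000, step: int = 1000) -> list[WindowStat]:
    """GC fraction in sliding windows, with z-scores against the track.

    N bases are excluded from both numerator and denominator.  z is computed
    against the mean and SD of all window values; a zero-SD track gets z = 0
    everywhere.
    """
    if window < 50:
        raise TxscapeError("window < 50 nt is statistically meaningless")
    if window > genome.length:
        raise TxscapeError("window exceeds genome length")
    seq = np.frombuffer(genome.sequence.encode(), dtype="S1")
    is_gc = ((seq == b"G") | (seq == b"C")).astype(np.int64)
    is_n = (seq == b"N").astype(np.int64)
    cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cum_n = np.concatenate([[0], np.cumsum(is_n)])
    starts = np.arange(0, genome.length - window + 1, step)
    gc = cum_gc[starts + window] - cum_gc[starts]
    nn = cum_n[starts + window] - cum_n[starts]
    denom = window - nn
    with np.errstate(invalid="ignore"):
        vals = np.where(denom > 0, gc / np.maximum(denom, 1), np.nan)
    mean = float(np.nanmean(vals))
    sd = float(np.nanstd(vals))
    z = (vals - mean) / sd if sd > 0 else np.zeros_like(vals)
    return [
        WindowStat(int(s), int(s + window), float(v), float(zz))
        for s, v, zz in zip(starts, vals, z)
    ]


def call_deviant_regions(
    track: Sequence[WindowStat], z_threshold: float = 2.5
) -> list[RegionCall]:
    """Merge windows with |z| > threshold into GC-deviant region calls.

    Overlapping or adjacent flagged windows form one region spanning their
    centers (a lone flagged window spans half a window-step either side of
    its center); the score is the maximum |z| in the region.
    """
    flagged = [w for w in track if abs(w.z) > z_threshold]
    if not flagged:
        return []
    step = track[1].start - track[0].start if len(track) > 1 else (
        track[0].end - track[0].start
    )
    regions: list[list[WindowStat]] = [[flagged[0]]]
    for w in flagged[1:]:
        if w.start <= regions[-1][-1].end:
            regions[-1].append(w)
        else:
            regions.append([w])
    calls = []
    for group in regions:
        centers = [(w.start + w.end) // 2 for w in group]
        start, end = centers[0], centers[-1]
        if start == end:
            start, end = start - step // 2, end + step // 2
        calls.append(
            RegionCall(
                kind="gc_deviant",
                start=max(0, start),
                end=end,
                score=max(abs(w.z) for w in group),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Gene-window tracks
# ---------------------------------------------------------------------------

def hypothetical_density(
    feature_table: FeatureTable, gene_window: int = 100
) -> list[WindowStat]:
    """Percent hypothetical proteins in a sliding window of consecutive CDS.

    The window steps one gene at a time; its coordinates are the genomic span
    of the member genes.  With fewer CDS than the window, one window covers
    all of them.
    """
    cds = feature_table.cds
    if not cds:
        raise TxscapeError("no CDS in feature table")
    hyp = np.array([f.is_hypothetical for f in cds], dtype=np.float64)
    n = len(cds)
    w = min(gene_window, n)
    cum = np.concatenate([[0.0], np.cumsum(hyp)])
    starts_idx = np.arange(0, n - w + 1)
    vals = 100.0 * (cum[starts_idx + w] - cum[starts_idx]) / w
    mean, sd = float(vals.mean()), float(vals.std())
    z = (vals - mean) / sd if sd > 0 else np.zeros_like(vals)
    return [
        WindowStat(cds[i].start, cds[i + w - 1].end, float(v), float(zz))
        for i, v, zz in zip(starts_idx, vals, z)
    ]


def low_expression_regions(
    expression: ExpressionTable,
    feature_table: FeatureTable,
    gene_window: int = 100,
    quantile: float = 0.10,
) -> list[RegionCall]:
    """Flag runs of gene windows whose median TPM falls below the given
    quantile of all window medians (strictly below, so a flat expression
    profile yields no calls).

    Runs of flagged windows are merged; the reported region spans the
    *center* genes of the first and last flagged window, which recovers the
    boundaries of a low-expression gene block without half-window smearing
    (a window median flips when just over half its genes are low).
    The score is the lowest window median in the region.
    """
    cds = feature_table.cds
    tpm = expression.tpm_series()
    gene_tpm = np.array([tpm.get(f.feature_id, 0.0) for f in cds])
    n = len(cds)
    if n == 0:
        raise TxscapeError("no CDS in feature table")
    w = min(gene_window, n)
    medians = np.array(
        [float(np.median(gene_tpm[i: i + w])) for i in range(n - w + 1)]
    )
    cutoff = float(np.quantile(medians, quantile))
    flagged_idx = np.flatnonzero(medians < cutoff)
    if flagged_idx.size == 0:
        return []
    groups: list[list[int]] = [[int(flagged_idx[0])]]
    for i in flagged_idx[1:]:
        if i <= groups[-1][-1] + w:  # windows overlap in gene space
            groups[-1].append(int(i))
        else:
            groups.append([int(i)])
    calls = []
    half = w // 2
    for g in groups:
        lo = min(g[0] + half, n - 1)
        hi = min(g[-1] + half, n - 1)
        members = tuple(f.feature_id for f in cds[lo: hi + 1])
        calls.append(
            RegionCall(
                kind="low_expression",
                start=cds[lo].start,
                end=cds[hi].end,
                score=float(min(medians[i] for i in g)),
                members=members,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Positional shares and functional groups
# ---------------------------------------------------------------------------

def positional_shares(
    expression: ExpressionTable,
    feature_table: FeatureTable,
    parts: int,
    genome_length: int,
    min_tpm: Optional[float] = None,
    max_tpm: Optional[float] = None,
    exclude_top: Optional[int] = None,
) -> list[float]:
    """Share of summed TPM per equal-length genome part, as percentages.

    Genes are assigned to parts by start coordinate.  The optional filters
    restrict the gene subset: ``min_tpm``/``max_tpm`` bound the TPM and
    ``exclude_top`` drops the k highest-expressed genes first.
    """
    if parts < 2:
        raise TxscapeError("parts must be >= 2")
    cds = feature_table.cds
    if parts > len(cds):
        warnings.warn("more parts than genes")
    tpm = expression.tpm_series()
    rows = [(f.start, float(tpm.get(f.feature_id, 0.0))) for f in cds]
    if exclude_top:
        drop = set(
            sorted(range(len(rows)), key=lambda i: -rows[i][1])[:exclude_top]
        )
        rows = [r for i, r in enumerate(rows) if i not in drop]
    if min_tpm is not None:
        rows = [r for r in rows if r[1] >= min_tpm]
    if max_tpm is not None:
        rows = [r for r in rows if r[1] <= max_tpm]
    shares = np.zeros(parts)
    for start, t in rows:
        p = min(parts - 1, start * parts // genome_length)
        shares[p] += t
    total = shares.sum()
    if total == 0:
        return [0.0] * parts
    return [float(100.0 * s / total) for s in shares]


def arcog_summary(
    expression: ExpressionTable,
    feature_table: FeatureTable,
    top_n: Optional[int] = None,
    pseudocount: float = LOG_PSEUDOCOUNT,
    min_members: int = 3,
) -> pd.DataFrame:
    """Per-arCOG-category summary of log10(TPM + pseudocount) over CDS.

    With ``top_n``, only the top-n genes by TPM are considered and categories
    with fewer than ``min_members`` members are dropped (mirroring a
    "more than 2 representatives" filter on a top-gene analysis).
    """
    tpm = expression.tpm_series()
    rows = [
        (f.arcog, float(tpm.get(f.feature_id, 0.0)))
        for f in feature_table.cds
        if f.arcog
    ]
    if not rows:
        raise TxscapeError("no arCOG-annotated CDS")
    df = pd.DataFrame(rows, columns=["arcog", "tpm"])
    if top_n is not None:
        df = df.nlargest(top_n, "tpm")
    df["log_tpm"] = np.log10(df["tpm"] + pseudocount)
    out = (
        df.groupby("arcog")["log_tpm"]
        .agg(
            n="size",
            median="median",
            q1=lambda s: float(np.percentile(s, 25)),
            q3=lambda s: float(np.percentile(s, 75)),
        )
        .reset_index()
    )
    if top_n is not None:
        out = out[out["n"] >= min_members].reset_index(drop=True)
    return out.sort_values("median", ascending=False).reset_index(drop=True)


def windows_to_tsv(track: Sequence[WindowStat], path) -> None:
    pd.DataFrame(
        [(w.start, w.end, w.value, w.z) for w in track],
        columns=["start", "end", "value", "z"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


__all__ = [
    "gc_track",
    "call_deviant_regions",
    "hypothetical_density",
    "low_expression_regions",
    "positional_shares",
    "arcog_summary",
    "windows_to_tsv",
    "LOG_PSEUDOCOUNT",
]
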