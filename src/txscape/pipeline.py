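"""End-to-end pipeline: quantify -> compare -> CAI -> landscape -> units.

Produces a consolidated report (JSON) mirroring the general-statistics and
top-genes tables of a transcriptome study, plus all tracks and region calls
as TSV/BED/bedGraph files.  Reruns with the same configuration are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from . import cai as cai_mod
from . import compare as compare_mod
from . import io as gio
from . import landscape as land
from . import units as units_mod
from .model import (
    CoverageTrack,
    Feature,
    FeatureTable,
    FragmentPlacement,
    FragmentSet,
    TxscapeError,
    merge_intervals,
)
from .quantify import (
    ExpressionTable,
    apply_utr_category,
    assign_fragments,
    category_fractions,
    classify_tiers,
    compute_tpm,
    detect_utrs,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and tunables for one full run."""

    genome: str
    annotation: str
    fragments: dict[str, str]  # condition name -> TSV or SAM/BAM path
    out_dir: str
    fragment_format: str = "tsv"
    seed: int = 0  # recorded in the report; the pipeline itself is deterministic
    denominator: str = "cds_only"
    stranded: bool = False
    rrna_first: bool = True
    utr_max_extent: int = 500
    utr_min_cov: Optional[float] = None
    gc_window: int = 5000
    gc_step: int = 1000
    gc_z_threshold: float = 2.5
    gene_window: int = 100
    low_quantile: float = 0.10
    compare_pseudocount: float = 0.1
    compare_z_threshold: float = 2.5
    compare_log2fc_threshold: float = 1.0
    cai_n_reference: int = 40
    unit_gap_max: int = 30
    unit_evenness_cv_max: float = 1.0
    island_min_len: int = 30
    island_max_len: int = 500
    island_min_depth_factor: float = 5.0

    def hash(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _round(x: float, nd: int = 6) -> float:
    return float(round(float(x), nd))


def intergenic_table(
    placements: Sequence[FragmentPlacement],
    feature_table: FeatureTable,
    genome_length: int,
    condition: str = "",
    min_len: int = 50,
) -> ExpressionTable:
    """Expression over intergenic gaps (fragment midpoint binning).

    Used for the intergenic-region condition comparison; gaps shorter than
    ``min_len`` are skipped.
    """
    occupied = merge_intervals([(f.start, f.end) for f in feature_table])
    gaps = []
    prev = 0
    for s, e in occupied:
        if s - prev >= min_len:
            gaps.append((prev, s))
        prev = max(prev, e)
    if genome_length - prev >= min_len:
        gaps.append((prev, genome_length))
    feats = [
        Feature(f"IG{i + 1:05d}", "other", s, e, "+", "intergenic region")
        for i, (s, e) in enumerate(gaps)
    ]
    table = FeatureTable(feats, genome_id=feature_table.genome_id)
    fs = FragmentSet.from_placements(placements)
    bounds = np.array([s for s, _ in gaps] + [genome_length])
    mids = (fs.starts + fs.ends) // 2
    idx = np.searchsorted(bounds, mids, side="right") - 1
    ends = np.array([e for _, e in gaps])
    counts: dict[str, int] = {f.feature_id: 0 for f in feats}
    valid = (idx >= 0) & (idx < len(gaps))
    hit = idx[valid][mids[valid] < ends[idx[valid]]]
    for i, c in zip(*np.unique(hit, return_counts=True)):
        counts[feats[int(i)].feature_id] = int(c)
    et = compute_tpm(counts, table, denominator="all_features", condition=condition)
    et.df["is_cds"] = True  # treat gaps as first-class records for stats
    return et


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle; returns the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = gio.read_fasta(config.genome)
    features = gio.read_gff3(config.annotation, genome)

    report: dict = {
        "tool": "txscape",
        "version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "genome": {
            "id": genome.id,
            "length": genome.length,
            "gc_percent": _round(100 * genome.gc_fraction(), 2),
            "n_cds": len(features.cds),
        },
        "conditions": {},
    }

    tables: dict[str, ExpressionTable] = {}
    coverages: dict[str, CoverageTrack] = {}
    utrs_by_cond = {}
    placements_by_cond = {}
    for cond, path in sorted(config.fragments.items()):
        placements = gio.read_fragments(path, config.fragment_format, genome)
        placements_by_cond[cond] = placements
        assignment = assign_fragments(
            placements,
            features,
            genome.length,
            rrna_first=config.rrna_first,
            stranded=config.stranded,
        )
        table = compute_tpm(
            assignment.counts, features, config.denominator, condition=cond
        )
        table = classify_tiers(table)
        utr_calls = detect_utrs(
            assignment.coverage,
            features,
            table,
            min_cov=config.utr_min_cov,
            max_extent=config.utr_max_extent,
        )
        assignment = apply_utr_category(
            assignment, placements, utr_calls, genome.length
        )
        fracs = category_fractions(assignment)
        table.category_fractions = fracs
        tables[cond] = table
        coverages[cond] = assignment.coverage
        utrs_by_cond[cond] = utr_calls

        table.to_tsv(out / f"expression_{cond}.tsv")
        gio.write_bedgraph(
            assignment.coverage, out / f"coverage_{cond}.bedgraph", genome.id
        )
        gio.write_bed(utr_calls, out / f"utrs_{cond}.bed", genome.id)

        cds_counts = table.cds_df["count"].to_numpy()
        report["conditions"][cond] = {
            "total_fragments": assignment.n_fragments,
            "category_percent": {
                k: _round(100 * v, 4) for k, v in fracs.items()
            },
            "mean_coverage_per_nt": _round(assignment.coverage.values.mean(), 4),
            "average_count_per_cds": _round(cds_counts.mean(), 4),
            "median_count_per_cds": _round(float(np.median(cds_counts)), 4),
            "average_tpm_per_cds": _round(table.average_tpm, 4),
            "median_tpm_per_cds": _round(table.median_tpm, 4),
            "percent_cds_expressed": _round(100 * float((cds_counts > 0).mean()), 4),
            "p10_count_threshold": _round(table.p10_count_threshold or 0.0, 4),
            "percent_cds_above_p10": _round(100 * (table.frac_above_p10 or 0.0), 4),
            "n_utr_calls": len(utr_calls),
        }

    conds = sorted(tables)
    if len(conds) == 2:
        a, b = conds
        comparison = compare_mod.compare_conditions(
            tables[a],
            tables[b],
            pseudocount=config.compare_pseudocount,
            z_threshold=config.compare_z_threshold,
            log2fc_threshold=config.compare_log2fc_threshold,
        )
        compare_mod.write_comparison_tsv(comparison, out / "comparison_cds.tsv")
        ig_a = intergenic_table(
            placements_by_cond[a], features, genome.length, condition=a
        )
        ig_b = intergenic_table(
            placements_by_cond[b], features, genome.length, condition=b
        )
        ig_cmp = compare_mod.compare_conditions(
            ig_a,
            ig_b,
            pseudocount=config.compare_pseudocount,
            z_threshold=config.compare_z_threshold,
            log2fc_threshold=config.compare_log2fc_threshold,
        )
        compare_mod.write_comparison_tsv(ig_cmp, out / "comparison_intergenic.tsv")
        mean_table = compare_mod.average_conditions(tables[a], tables[b])
        report["comparison"] = {
            "conditions": [a, b],
            "n_sd_outliers_cds": int(comparison["is_sd_outlier"].sum()),
            "n_fc_flagged_cds": int(comparison["is_fc_flagged"].sum()),
            "n_sd_outliers_intergenic": int(ig_cmp["is_sd_outlier"].sum()),
            "sd_outlier_fraction_cds": _round(
                float(comparison["is_sd_outlier"].mean()), 6
            ),
        }
    elif len(conds) == 1:
        warnings.warn("single condition: comparison stage skipped")
        mean_table = tables[conds[0]]
        report["comparison"] = None
    else:
        raise TxscapeError("pipeline expects 1 or 2 conditions")
    mean_table.to_tsv(out / "expression_mean.tsv")

    # CAI
    cai_df = cai_mod.genome_cai(genome, features, config.cai_n_reference)
    cai_df.to_csv(out / "cai.tsv", sep="\t", index=False, float_format="%.6g")
    report["cai"] = {
        "n_genes": int(len(cai_df)),
        "mean": _round(cai_df["cai"].mean(), 6),
        "median": _round(cai_df["cai"].median(), 6),
    }

    # landscape
    track = land.gc_track(genome, config.gc_window, config.gc_step)
    land.windows_to_tsv(track, out / "gc_track.tsv")
    gc_regions = land.call_deviant_regions(track, config.gc_z_threshold)
    gio.write_bed(gc_regions, out / "gc_deviant.bed", genome.id)
    hyp_track = land.hypothetical_density(features, config.gene_window)
    land.windows_to_tsv(hyp_track, out / "hypothetical_density.tsv")
    low_regions = land.low_expression_regions(
        mean_table, features, config.gene_window, config.low_quantile
    )
    gio.write_bed(low_regions, out / "low_expression.bed", genome.id)
    halves = land.positional_shares(mean_table, features, 2, genome.length)
    quarters = land.positional_shares(mean_table, features, 4, genome.length)
    high_quarters = land.positional_shares(
        mean_table, features, 4, genome.length,
        min_tpm=2.5 * mean_table.average_tpm,
    )
    report["landscape"] = {
        "n_gc_deviant_regions": len(gc_regions),
        "n_low_expression_regions": len(low_regions),
        "low_expression_spans": [[r.start, r.end] for r in low_regions],
        "half_tpm_shares_percent": [_round(s, 4) for s in halves],
        "quarter_tpm_shares_percent": [_round(s, 4) for s in quarters],
        "quarter_shares_high_genes_percent": [_round(s, 4) for s in high_quarters],
    }
    try:
        arcog = land.arcog_summary(mean_table, features)
        arcog.to_csv(out / "arcog_summary.tsv", sep="\t", index=False,
                     float_format="%.6g")
        report["landscape"]["n_arcog_categories"] = int(len(arcog))
    except TxscapeError:
        report["landscape"]["n_arcog_categories"] = 0

    # units and islands (pooled coverage over conditions)
    pooled = CoverageTrack(sum(c.values for c in coverages.values()))
    units = units_mod.infer_units(
        features, pooled, config.unit_gap_max, config.unit_evenness_cv_max
    )
    gio.write_bed(units, out / "units.bed", genome.id)
    units_mod.unit_evidence_table(units, features, pooled).to_csv(
        out / "units_evidence.tsv", sep="\t", index=False, float_format="%.6g"
    )
    all_utrs = [u for calls in utrs_by_cond.values() for u in calls]
    islands = units_mod.call_islands(
        pooled,
        features,
        all_utrs,
        config.island_min_len,
        config.island_max_len,
        config.island_min_depth_factor,
    )
    gio.write_bed(islands, out / "islands.bed", genome.id)
    report["units"] = {
        "n_units": len(units),
        "n_polycistronic": sum(1 for u in units if len(u.members) > 1),
        "largest_unit": max((len(u.members) for u in units), default=0),
        "n_transcribed_islands": len(islands),
    }

    # top-genes table (>= 10x average, sorted by TPM)
    top = mean_table.df[mean_table.df["tier"] == "ge10x"].sort_values(
        "tpm", ascending=False
    )
    products = {f.feature_id: f.product for f in features}
    top = top.assign(product=top["feature_id"].map(products))
    top[["feature_id", "tpm", "count", "product"]].to_csv(
        out / "top_genes.tsv", sep="\t", index=False, float_format="%.4f"
    )
    report["top_genes"] = {
        "n_ge10x": int(len(top)),
        "highest": (
            {
                "feature_id": str(top.iloc[0]["feature_id"]),
                "tpm": _round(top.iloc[0]["tpm"], 2),
            }
            if len(top)
            else None
        ),
    }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
    return report


__all__ = ["PipelineConfig", "run_pipeline", "intergenic_table"]
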