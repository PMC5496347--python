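"""Seeded generator of synthetic genomes, annotations and fragment
placements with the statistical structure the analysis pipeline assumes.

The generator emulates a halophilic-archaeon-like transcriptome experiment:

* a single chromosome (~47.9% GC) carrying two ribosomal RNA operon
  clusters that attract the large majority (default 79%) of fragments;
* protein-coding genes organised in operons (short or overlapping
  intergenic gaps within an operon, >100 nt between operons), with
  negative-binomial fragment counts shared per operon;
* two planted low-expression gene blocks that are enriched in hypothetical
  proteins and co-locate with planted GC-shifted regions;
* UTR coverage plateaus flanking expressed genes (fragments fall uniformly
  in the gene plus short untranslated margins);
* intergenic transcribed islands of 30-500 nt at high depth (planted small
  non-coding RNAs), placed well away from genes;
* two conditions drawn from identical per-gene means (the null the study
  observed between light and dark).

Everything is reproducible from the config seed, and the machine-readable
ground truth for every planted structure is returned alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as gio
from .cai import SYNONYMOUS_FAMILIES
from .model import (
    CoverageTrack,
    Feature,
    FeatureTable,
    FragmentPlacement,
    FragmentSet,
    Genome,
    TxscapeError,
)
from .quantify import ExpressionTable, compute_tpm

ARCOG_LETTERS = "CDEGHIJKLMNOPQRTUV"


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Negative-binomial counts are parameterised by (mean, dispersion) with
    variance = mean + mean^2 / dispersion.  The default dispersion of 50 is
    the near-technical-replicate regime: two libraries from one culture a
    few hours apart, consistent with the absence of any differential
    expression between conditions.
    """

    seed: int = 0
    genome_len: int = 2_400_000
    gc_background: float = 0.479
    n_genes: int = 2000
    hypothetical_frac: float = 0.30
    low_block_hypothetical_frac: float = 0.80
    n_ribosomal: int = 50
    rrna_positions: Optional[tuple[tuple[int, int], ...]] = None
    rrna_read_frac: float = 0.79
    planted_gc_islands: Optional[list[tuple[int, int, float]]] = None
    gc_island_len: int = 30_000
    gc_island_shift: float = 0.05
    planted_low_expr_blocks: Optional[list[tuple[int, int, float]]] = None
    operon_spec: Optional[list[tuple[int, tuple[int, ...]]]] = None
    nb_mean: float = 80.0
    nb_dispersion: float = 50.0
    # log-normal spread of per-operon expression; 1.3 reproduces the ~2.4
    # mean/median TPM ratio typical of a bulk prokaryotic transcriptome
    expression_sigma: float = 1.3
    fragment_len: int = 200
    utr_len_range: tuple[int, int] = (150, 400)
    utr_read_ratio: float = 5.0
    n_islands: int = 12
    island_len_range: tuple[int, int] = (30, 500)
    island_depth_factor: float = 30.0
    gene_len_range: tuple[int, int] = (300, 1500)
    intergenic_gap_range: tuple[int, int] = (250, 600)
    codon_bias: float = 0.7
    min_feature_len_emitted: Optional[int] = None
    conditions: tuple[str, str] = ("light", "dark")

    def __post_init__(self) -> None:
        for name in ("gc_background", "hypothetical_frac", "rrna_read_frac",
                     "low_block_hypothetical_frac", "codon_bias"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise TxscapeError(f"{name}={v} outside [0, 1]")
        if self.fragment_len < 30:
            raise TxscapeError("fragment_len too short")

    # -- resolved defaults ---------------------------------------------------

    def resolved_rrna_positions(self) -> list[tuple[int, int]]:
        if self.rrna_positions is not None:
            return [tuple(p) for p in self.rrna_positions]
        L = self.genome_len
        return [
            (int(0.05 * L), int(0.05 * L) + 5300),
            (int(0.55 * L), int(0.55 * L) + 5300),
        ]

    def resolved_low_blocks(self) -> list[tuple[int, int, float]]:
        if self.planted_low_expr_blocks is not None:
            return [tuple(b) for b in self.planted_low_expr_blocks]
        n = self.n_genes
        size = max(1, n // 20)
        return [
            (int(0.40 * n), size, 0.02),
            (int(0.78 * n), size, 0.02),
        ]

    def resolved_operon_spec(self) -> list[tuple[int, tuple[int, ...]]]:
        if self.operon_spec is not None:
            return [(int(n), tuple(g)) for n, g in self.operon_spec]
        return [
            (1, ()),
            (2, (-3,)),
            (3, (-13, -3)),
            (1, ()),
            (4, (-3, 2, 10)),
            (2, (10,)),
            (1, ()),
            (5, (-13, -3, 2, 24)),
            (3, (0, 1)),
            (1, ()),
        ]


@dataclass
class GroundTruth:
    """Machine-readable truth for every planted structure."""

    rrna_intervals: list[tuple[int, int]]
    gc_islands: list[tuple[int, int]]
    low_expression_blocks: list[dict]
    island_coords: list[tuple[int, int]]
    units: list[list[str]]
    gene_lambda: dict[str, float]
    expected_tpm: dict[str, float]
    counts: dict[str, dict[str, int]]
    utr_extents: dict[str, tuple[int, int]]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, sort_keys=True, indent=1)


@dataclass
class SimResult:
    genome: Genome
    features: FeatureTable
    fragments: dict[str, list[FragmentPlacement]]
    truth: GroundTruth
    config: SimConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "genome.fasta",
            "gff3": out / "annotation.gff3",
            "truth": out / "truth.json",
            "config": out / "config.json",
        }
        gio.write_fasta(self.genome, paths["fasta"])
        gio.write_gff3(self.features, paths["gff3"])
        self.truth.to_json(paths["truth"])
        with open(paths["config"], "w") as fh:
            json.dump(asdict(self.config), fh, sort_keys=True, indent=1)
        for cond, placements in self.fragments.items():
            p = out / f"fragments_{cond}.tsv"
            gio.write_fragments_tsv(placements, p)
            paths[f"fragments_{cond}"] = p
            cov = _coverage_of(placements, self.genome.length)
            cp = out / f"coverage_{cond}.bedgraph"
            gio.write_bedgraph(cov, cp, genome_id=self.genome.id)
            paths[f"coverage_{cond}"] = cp
        return paths


def _coverage_of(placements: Sequence[FragmentPlacement], L: int) -> CoverageTrack:
    fs = FragmentSet.from_placements(placements)
    diff = np.zeros(L + 1, dtype=np.int64)
    np.add.at(diff, fs.starts, 1)
    np.add.at(diff, fs.ends, -1)
    return CoverageTrack(np.cumsum(diff[:-1]))


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

def _layout(cfg: SimConfig, rng: np.random.Generator):
    """Place operons, genes, island slots along the chromosome."""
    rrna = cfg.resolved_rrna_positions()
    blocks = cfg.resolved_low_blocks()
    boundaries = sorted(
        {b[0] for b in blocks} | {b[0] + b[1] for b in blocks} | {cfg.n_genes}
    )
    spec = cfg.resolved_operon_spec()
    lo3, hi3 = cfg.gene_len_range[0] // 3, cfg.gene_len_range[1] // 3

    genes: list[tuple[int, int, str]] = []  # (start, end, strand)
    units: list[list[int]] = []
    island_coords: list[tuple[int, int]] = []
    island_every = max(1, cfg.n_genes // max(1, cfg.n_islands))
    island_margin = 600

    cursor = 500
    gi = 0
    spec_i = 0
    max_operon_span = 5 * cfg.gene_len_range[1] + 200
    while gi < cfg.n_genes:
        for rs, re in rrna:
            if cursor + max_operon_span > rs - 300 and cursor < re + 300:
                cursor = re + 300
        m, gaps = spec[spec_i % len(spec)]
        spec_i += 1
        next_boundary = min(b for b in boundaries if b > gi)
        m = min(m, cfg.n_genes - gi, next_boundary - gi)
        strand = "+" if rng.random() < 0.5 else "-"
        members = []
        end = cursor
        for k in range(m):
            glen = 3 * int(rng.integers(lo3, hi3 + 1))
            start = cursor
            end = start + glen
            genes.append((start, end, strand))
            members.append(gi)
            gi += 1
            if k < m - 1:
                gap = gaps[k] if k < len(gaps) else int(rng.integers(0, 21))
                cursor = end + gap
        units.append(members)
        cursor = end + int(rng.integers(*cfg.intergenic_gap_range))
        if len(island_coords) < cfg.n_islands and gi >= (len(island_coords) + 1) * island_every:
            ilen = int(rng.integers(cfg.island_len_range[0], cfg.island_len_range[1] + 1))
            istart = cursor + island_margin
            island_coords.append((istart, istart + ilen))
            cursor = istart + ilen + island_margin
    if cursor > cfg.genome_len - 500:
        raise TxscapeError(
            f"infeasible gene packing: layout needs {cursor} nt, genome is "
            f"{cfg.genome_len} nt"
        )
    return genes, units, island_coords, rrna, blocks


# ---------------------------------------------------------------------------
# Sequence
# ---------------------------------------------------------------------------

def _sample_sequence(
    cfg: SimConfig, rng: np.random.Generator, gc_islands: Sequence[tuple[int, int]]
) -> np.ndarray:
    L = cfg.genome_len
    p = np.full(L, cfg.gc_background)
    for s, e in gc_islands:
        p[s:e] = np.clip(p[s:e] + cfg.gc_island_shift, 0.05, 0.95)
    is_gc = rng.random(L) < p
    pick = rng.random(L) < 0.5
    seq = np.where(is_gc, np.where(pick, b"G", b"C"), np.where(pick, b"A", b"T"))
    return seq.astype("S1")


def _preferred_codons(gc_target: float = 0.479) -> dict[str, str]:
    """One deterministic preferred codon per family.

    The codon whose GC content is closest to the genome background is chosen
    (ties alphabetical), so the planted codon preference of the reference
    genes does not double as a GC anomaly — the GC track must see only the
    explicitly planted GC islands.
    """
    target = 3.0 * gc_target
    pref = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        pref[aa] = min(
            codons, key=lambda c: (abs((c.count("G") + c.count("C")) - target), c)
        )
    return pref


def _write_biased_cds(
    seq: np.ndarray,
    start: int,
    end: int,
    strand: str,
    bias: float,
    rng: np.random.Generator,
    gc_target: float = 0.479,
) -> None:
    """Overwrite a gene with a start codon, biased sense codons and a stop.

    Amino-acid sampling weights are exponentially tilted so the expected GC
    of the biased gene matches ``gc_target``: the planted codon preference
    must not double as a GC anomaly on the genome track.
    """
    pref = _preferred_codons(gc_target)
    aas = sorted(SYNONYMOUS_FAMILIES)

    def _gc(codon: str) -> float:
        return (codon.count("G") + codon.count("C")) / 3.0

    g_a = np.array(
        [
            bias * _gc(pref[aa])
            + (1 - bias) * np.mean([_gc(c) for c in SYNONYMOUS_FAMILIES[aa]])
            for aa in aas
        ]
    )

    def mean_gc(theta: float) -> float:
        w = np.exp(theta * g_a)
        return float((w * g_a).sum() / w.sum())

    lo, hi = -30.0, 30.0
    for _ in range(60):  # bisection: mean_gc is increasing in theta
        mid = (lo + hi) / 2
        if mean_gc(mid) < gc_target:
            lo = mid
        else:
            hi = mid
    w = np.exp(lo * g_a)
    w /= w.sum()

    n_codons = (end - start) // 3
    aa_draws = rng.choice(len(aas), size=max(0, n_codons - 2), p=w)
    use_pref = rng.random(max(0, n_codons - 2)) < bias
    parts = ["ATG"]
    for aa_i, pr in zip(aa_draws, use_pref):
        aa = aas[int(aa_i)]
        fam = SYNONYMOUS_FAMILIES[aa]
        if pr:
            parts.append(pref[aa])
        else:
            parts.append(fam[int(rng.integers(len(fam)))])
    parts.append("TAA")
    cds = "".join(parts)
    if strand == "-":
        cds = cds.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    seq[start:end] = np.frombuffer(cds.encode(), dtype="S1")


# ---------------------------------------------------------------------------
# Generate
# ---------------------------------------------------------------------------

def generate(cfg: SimConfig, out_dir: Optional[str | Path] = None) -> SimResult:
    """Generate the full synthetic experiment; optionally write all files."""
    rng = np.random.default_rng(cfg.seed)
    genes, unit_idx, island_coords, rrna, blocks = _layout(cfg, rng)
    n = cfg.n_genes

    in_block = np.zeros(n, dtype=bool)
    block_scale = np.ones(n)
    block_records = []
    for bs, bn, scale in blocks:
        in_block[bs: bs + bn] = True
        block_scale[bs: bs + bn] = scale
        block_records.append(
            {
                "gene_start": bs,
                "n_genes": bn,
                "tpm_scale": scale,
                "start": genes[bs][0],
                "end": genes[bs + bn - 1][1],
            }
        )

    if cfg.planted_gc_islands is not None:
        gc_islands = [(int(p), int(p) + int(l)) for p, l, _ in cfg.planted_gc_islands]
    else:
        gc_islands = []
        for rec in block_records:
            c = (rec["start"] + rec["end"]) // 2
            s = max(0, c - cfg.gc_island_len // 2)
            gc_islands.append((s, min(cfg.genome_len, s + cfg.gc_island_len)))
    for s, e in gc_islands:
        if not (0 <= s < e <= cfg.genome_len):
            raise TxscapeError(f"planted GC island ({s}, {e}) out of bounds")
    merged = sorted(gc_islands)
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        if s2 < e1:
            raise TxscapeError("planted GC islands overlap")

    # -- annotation ---------------------------------------------------------
    # reference (ribosomal) genes must not overlap their neighbours: their
    # codons are rewritten in place and an overlapping rewrite would corrupt
    # the adjacent reading frame
    def _overlaps_neighbour(i: int) -> bool:
        s, e, _ = genes[i]
        if i > 0 and genes[i - 1][1] > s:
            return True
        if i + 1 < n and genes[i + 1][0] < e:
            return True
        return False

    eligible = [
        i for i in range(n) if not in_block[i] and not _overlaps_neighbour(i)
    ]
    ribo_idx = set(
        int(i)
        for i in rng.choice(eligible, size=min(cfg.n_ribosomal, len(eligible)),
                            replace=False)
    )
    gene_ids = [f"G{i + 1:04d}" for i in range(n)]
    features: list[Feature] = []
    ribo_counter = 0
    for i, (s, e, strand) in enumerate(genes):
        if i in ribo_idx:
            ribo_counter += 1
            subunit = "50S" if ribo_counter % 2 else "30S"
            letter = "L" if subunit == "50S" else "S"
            product = f"{subunit} ribosomal protein {letter}{ribo_counter}"
            hyp, arcog = False, "J"
        else:
            p_hyp = (
                cfg.low_block_hypothetical_frac if in_block[i] else cfg.hypothetical_frac
            )
            hyp = bool(rng.random() < p_hyp)
            if hyp:
                product = "hypothetical protein"
                arcog = "S" if rng.random() < 0.3 else None
            else:
                product = f"conserved protein {gene_ids[i]}"
                arcog = ARCOG_LETTERS[int(rng.integers(len(ARCOG_LETTERS)))]
        features.append(
            Feature(gene_ids[i], "CDS", s, e, strand, product, hyp, arcog)
        )
    for k, (rs, re) in enumerate(rrna, start=1):
        if re - rs >= 5000:
            features.append(
                Feature(f"rrna16S_{k}", "rRNA", rs + 200, rs + 1700, "+",
                        "16S ribosomal RNA")
            )
            features.append(
                Feature(f"rrna23S_{k}", "rRNA", rs + 2000, rs + 4900, "+",
                        "23S ribosomal RNA")
            )
        else:
            features.append(
                Feature(f"rrna_{k}", "rRNA", rs, re, "+", "ribosomal RNA operon")
            )
    table = FeatureTable(features, genome_id="synth_chr")

    # -- sequence -----------------------------------------------------------
    seq = _sample_sequence(cfg, rng, gc_islands)
    for i in sorted(ribo_idx):
        s, e, strand = genes[i]
        _write_biased_cds(seq, s, e, strand, cfg.codon_bias, rng, cfg.gc_background)
    genome = Genome(id="synth_chr", sequence=seq.tobytes().decode())

    # -- expression ---------------------------------------------------------
    operon_rel = np.exp(rng.normal(0.0, cfg.expression_sigma, size=len(unit_idx)))
    lam = np.empty(n)
    for u, members in enumerate(unit_idx):
        for i in members:
            lam[i] = cfg.nb_mean * operon_rel[u] * block_scale[i]
    glen = np.array([e - s for s, e, _ in genes], dtype=np.int64)
    rate = lam / glen
    expected_tpm = 1e6 * rate / rate.sum()

    med_depth = float(np.median(lam * cfg.fragment_len / glen))
    island_target = cfg.island_depth_factor * med_depth

    gene_strand_code = np.array(
        [1 if st == "+" else -1 for _, _, st in genes], dtype=np.int8
    )
    gstart = np.array([s for s, _, _ in genes], dtype=np.int64)
    gend = np.array([e for _, e, _ in genes], dtype=np.int64)

    # UTR geometry: untranslated margins exist only at transcription-unit
    # boundaries (a polycistronic message has a single 5' UTR); each margin
    # is capped so UTR fragments never touch the neighbouring occupied
    # interval, and a UTR fragment overlaps its gene by less than half a
    # fragment so it is never counted to the CDS.
    frag = cfg.fragment_len
    max_ov = frag // 2 - 1  # largest gene overlap still below the 50% rule
    min_utr = frag - max_ov + 9
    unit_spans = [
        (int(gstart[members[0]]), int(max(gend[i] for i in members)))
        for members in unit_idx
    ]
    items = (
        [(s, e, "unit", ui) for ui, (s, e) in enumerate(unit_spans)]
        + [(s, e, "rrna", -1) for s, e in rrna]
        + [(s, e, "island", -1) for s, e in island_coords]
    )
    items.sort()
    utr5 = np.zeros(n, dtype=np.int64)
    utr3 = np.zeros(n, dtype=np.int64)
    raw5 = rng.integers(cfg.utr_len_range[0], cfg.utr_len_range[1] + 1, size=n)
    raw3 = rng.integers(cfg.utr_len_range[0], cfg.utr_len_range[1] + 1, size=n)
    for k, (s, e, kind, ui) in enumerate(items):
        if kind != "unit":
            continue
        prev_end = items[k - 1][1] if k > 0 else 0
        next_start = items[k + 1][0] if k + 1 < len(items) else cfg.genome_len
        first, last = unit_idx[ui][0], unit_idx[ui][-1]
        u5 = min(int(raw5[first]), s - prev_end - 60)
        u3 = min(int(raw3[last]), next_start - e - 60)
        if u5 >= min_utr:
            utr5[first] = u5
        if u3 >= min_utr:
            utr3[last] = u3

    r = cfg.nb_dispersion
    fragments: dict[str, list[FragmentPlacement]] = {}
    counts_truth: dict[str, dict[str, int]] = {}
    emit_min = cfg.min_feature_len_emitted or 0
    for cond in cfg.conditions:
        counts = rng.negative_binomial(r, r / (r + lam)).astype(np.int64)
        isl_counts = np.maximum(
            1,
            rng.negative_binomial(r, r / (r + island_target), size=len(island_coords)),
        ).astype(np.int64)

        emit_counts = np.where(glen >= emit_min, counts, 0)
        # CDS fragments: strictly inside the gene
        width = np.repeat(glen - frag + 1, emit_counts)
        g_starts = np.repeat(gstart, emit_counts) + (
            rng.random(int(emit_counts.sum())) * width
        ).astype(np.int64)
        g_ends = g_starts + frag
        g_strands = np.repeat(gene_strand_code, emit_counts)

        # UTR fragments: mostly outside the gene, within the UTR margin
        utr_mean = cfg.utr_read_ratio * lam / 2.0
        c5 = np.where(
            (utr5 > 0) & (glen >= emit_min),
            rng.negative_binomial(r, r / (r + utr_mean)),
            0,
        ).astype(np.int64)
        c3 = np.where(
            (utr3 > 0) & (glen >= emit_min),
            rng.negative_binomial(r, r / (r + utr_mean)),
            0,
        ).astype(np.int64)
        lo5 = gstart - utr5
        hi5 = gstart + max_ov - frag  # fragment end overlaps gene by <= max_ov
        w5 = np.repeat(np.maximum(1, hi5 - lo5 + 1), c5)
        u5_starts = np.repeat(lo5, c5) + (rng.random(int(c5.sum())) * w5).astype(
            np.int64
        )
        lo3 = gend - max_ov
        hi3u = gend + utr3 - frag
        w3 = np.repeat(np.maximum(1, hi3u - lo3 + 1), c3)
        u3_starts = np.repeat(lo3, c3) + (rng.random(int(c3.sum())) * w3).astype(
            np.int64
        )
        u_starts = np.concatenate([u5_starts, u3_starts])
        u_ends = u_starts + frag
        u_strands = np.concatenate(
            [np.repeat(gene_strand_code, c5), np.repeat(gene_strand_code, c3)]
        )

        if island_coords:
            i_starts = np.repeat([s for s, _ in island_coords], isl_counts)
            i_ends = np.repeat([e for _, e in island_coords], isl_counts)
        else:
            i_starts = i_ends = np.empty(0, dtype=np.int64)

        n_other = g_starts.size + u_starts.size + i_starts.size
        f = cfg.rrna_read_frac
        n_rrna = int(round(n_other * f / (1.0 - f))) if f < 1 else 0
        rrna_feats = table.rrna
        weights = np.array([ft.length for ft in rrna_feats], dtype=float)
        alloc = rng.multinomial(n_rrna, weights / weights.sum())
        r_starts = np.concatenate(
            [
                ft.start
                + (rng.random(int(c)) * (ft.end - ft.start - cfg.fragment_len + 1)).astype(
                    np.int64
                )
                for ft, c in zip(rrna_feats, alloc)
            ]
        ) if n_rrna else np.empty(0, dtype=np.int64)
        r_ends = r_starts + cfg.fragment_len

        starts = np.concatenate([g_starts, u_starts, i_starts, r_starts]).astype(
            np.int64
        )
        ends = np.concatenate([g_ends, u_ends, i_ends, r_ends]).astype(np.int64)
        strand_codes = np.concatenate(
            [
                g_strands,
                u_strands,
                np.ones(i_starts.size, dtype=np.int8),
                np.ones(r_starts.size, dtype=np.int8),
            ]
        )
        fragments[cond] = FragmentSet(
            starts, ends, strand_codes, id_prefix=cond,
            genome_length=cfg.genome_len,
        )
        counts_truth[cond] = {gene_ids[i]: int(counts[i]) for i in range(n)}

    truth = GroundTruth(
        rrna_intervals=[(int(s), int(e)) for s, e in rrna],
        gc_islands=[(int(s), int(e)) for s, e in gc_islands],
        low_expression_blocks=block_records,
        island_coords=[(int(s), int(e)) for s, e in island_coords],
        units=[[gene_ids[i] for i in members] for members in unit_idx],
        gene_lambda={gene_ids[i]: float(lam[i]) for i in range(n)},
        expected_tpm={gene_ids[i]: float(expected_tpm[i]) for i in range(n)},
        counts=counts_truth,
        utr_extents={
            gene_ids[i]: (int(utr5[i]), int(utr3[i])) for i in range(n)
        },
    )
    result = SimResult(genome, table, fragments, truth, cfg)
    if out_dir is not None:
        result.write(out_dir)
    return result


# ---------------------------------------------------------------------------
# Null pairs for comparison calibration
# ---------------------------------------------------------------------------

def null_feature_table(cfg: SimConfig, rng: np.random.Generator) -> FeatureTable:
    lo3, hi3 = cfg.gene_len_range[0] // 3, cfg.gene_len_range[1] // 3
    feats = []
    cursor = 0
    for i in range(cfg.n_genes):
        glen = 3 * int(rng.integers(lo3, hi3 + 1))
        feats.append(Feature(f"G{i + 1:04d}", "CDS", cursor, cursor + glen, "+"))
        cursor += glen + 100
    return FeatureTable(feats, genome_id="null")


def null_pair(
    cfg: SimConfig, out_dir: Optional[str | Path] = None
) -> tuple[ExpressionTable, ExpressionTable]:
    """Two expression tables drawn from one shared negative-binomial model.

    Every gene has the same mean (``nb_mean``) in both draws, so the pair is
    an exchangeable null for the standardized log-ratio screen.  With
    ``out_dir`` the equivalent fragment TSVs (uniform placements within each
    gene) are also written.
    """
    rng = np.random.default_rng(cfg.seed)
    table = null_feature_table(cfg, rng)
    r = cfg.nb_dispersion
    lam = np.full(cfg.n_genes, cfg.nb_mean)
    out = []
    for cond in cfg.conditions:
        counts = rng.negative_binomial(r, r / (r + lam))
        cmap = {f.feature_id: int(c) for f, c in zip(table, counts)}
        out.append(compute_tpm(cmap, table, condition=cond))
        if out_dir is not None:
            path = Path(out_dir) / f"null_fragments_{cond}.tsv"
            placements = []
            fid = 0
            for f, c in zip(table, counts):
                span = max(1, f.length - cfg.fragment_len)
                starts = f.start + rng.integers(0, span, size=int(c))
                for st in starts:
                    placements.append(
                        FragmentPlacement(
                            f"{cond}_{fid}",
                            int(st),
                            int(st) + min(cfg.fragment_len, f.length),
                            "+",
                        )
                    )
                    fid += 1
            gio.write_fragments_tsv(placements, path)
    return out[0], out[1]


__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimResult",
    "generate",
    "null_pair",
    "null_feature_table",
]
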