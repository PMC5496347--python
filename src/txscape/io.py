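"""Readers and writers for the standard formats the pipeline consumes.

FASTA is read through Bio.SeqIO, GFF3 through gffutils (in-memory db),
SAM/BAM through pysam.  Writing the tabular/interval outputs (GFF3, BED,
bedGraph, TSV) is plain formatting and is done here directly.

Coordinate conventions: internal intervals are 0-based half-open; GFF3 is
converted from/to 1-based inclusive at this boundary; BED and bedGraph are
already 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence
from urllib.parse import quote, unquote

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    CoverageTrack,
    Feature,
    FeatureTable,
    FragmentPlacement,
    FragmentSet,
    Genome,
    RegionCall,
    TxscapeError,
)

logger = logging.getLogger(__name__)

_GFF_TYPE_MAP = {
    "CDS": "CDS",
    "rRNA": "rRNA",
    "ncRNA": "ncRNA",
    "tRNA": "tRNA",
}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, circular: bool = False) -> Genome:
    """Read a single-record FASTA into a :class:`Genome`.

    The sequence is uppercased; anything outside {A,C,G,T,N} is rejected.
    Multi-record files are rejected: the pipeline models one replicon per run.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise TxscapeError(f"{path}: empty FASTA, no records found")
    if len(records) > 1:
        raise TxscapeError(
            f"{path}: {len(records)} records found; single chromosome expected"
        )
    rec = records[0]
    return Genome(id=rec.id, sequence=str(rec.seq).upper(), circular=circular)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")
    _ = width  # Bio.SeqIO uses its own 60-col wrapping; kept for signature stability


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_bool(text: str) -> bool:
    return text.strip().lower() in ("true", "1", "yes")


def read_gff3(path: str | Path, genome: Optional[Genome] = None) -> FeatureTable:
    """Read a GFF3 annotation into a :class:`FeatureTable`.

    ``product`` containing the substring "hypothetical" (case-insensitive)
    marks a feature as hypothetical; an explicit ``hypothetical=true/false``
    attribute overrides the substring rule.  A single-letter ``arcog``
    attribute is carried through when present.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[Feature] = []
    genome_id = genome.id if genome is not None else ""
    for gf in db.all_features():
        if gf.featuretype in ("region", "chromosome"):
            continue
        ftype = _GFF_TYPE_MAP.get(gf.featuretype, "other")
        if gf.start > gf.end:
            raise TxscapeError(
                f"{path}: feature {gf.id} has end < start ({gf.end} < {gf.start})"
            )
        start = gf.start - 1  # GFF3 1-based inclusive -> 0-based half-open
        end = gf.end
        product = unquote(gf.attributes.get("product", [""])[0])
        hyp = "hypothetical" in product.lower()
        if "hypothetical" in gf.attributes:
            hyp = _parse_bool(gf.attributes["hypothetical"][0])
        arcog = gf.attributes.get("arcog", [None])[0]
        fid = gf.attributes.get("ID", [gf.id])[0]
        features.append(
            Feature(
                feature_id=fid,
                ftype=ftype,
                start=start,
                end=end,
                strand=gf.strand if gf.strand in ("+", "-") else "+",
                product=product,
                is_hypothetical=hyp,
                arcog=arcog,
            )
        )
        if not genome_id:
            genome_id = gf.seqid
    table = FeatureTable(features, genome_id=genome_id)
    if genome is not None:
        table.validate_bounds(genome.length)
    return table


def write_gff3(table: FeatureTable, path: str | Path) -> None:
    """Write a FeatureTable as GFF3 (inverse of :func:`read_gff3`)."""
    inv_type = {v: k for k, v in _GFF_TYPE_MAP.items()}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in table:
            attrs = [f"ID={quote(f.feature_id, safe='')}"]
            if f.product:
                attrs.append(f"product={quote(f.product, safe=' ')}")
            attrs.append(f"hypothetical={'true' if f.is_hypothetical else 'false'}")
            if f.arcog:
                attrs.append(f"arcog={f.arcog}")
            gtype = inv_type.get(f.ftype, f.ftype if f.ftype != "other" else "gene")
            fh.write(
                "\t".join(
                    [
                        table.genome_id or "genome",
                        "txscape",
                        gtype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Fragment placements
# ---------------------------------------------------------------------------

def read_fragments(
    path: str | Path,
    format: str = "tsv",
    genome: Optional[Genome] = None,
) -> list[FragmentPlacement]:
    """Read paired-fragment placements from a TSV or a SAM/BAM file.

    TSV columns: ``fragment_id<TAB>start<TAB>end<TAB>strand`` with a header
    row.  For SAM/BAM, one placement is produced per properly paired fragment,
    spanning the leftmost mate start to the rightmost mate end; unmapped and
    secondary/supplementary records are dropped and their counts logged.
    """
    glen = genome.length if genome is not None else None
    if format == "tsv":
        return _read_fragments_tsv(path, glen)
    if format in ("sam_bam", "sam", "bam"):
        placements = _read_fragments_sam(path)
        for p in placements:
            p.validate(glen)
        return placements
    raise TxscapeError(f"unknown fragment format {format!r}")


def _read_fragments_tsv(
    path: str | Path, genome_length: Optional[int] = None
) -> FragmentSet:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"fragment_id": str, "start": int, "end": int, "strand": str},
    )
    required = {"fragment_id", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise TxscapeError(f"{path}: missing fragment TSV columns {sorted(missing)}")
    bad = set(df["strand"].unique()) - {"+", "-", "unknown"}
    if bad:
        raise TxscapeError(f"{path}: bad strand values {sorted(bad)}")
    codes = df["strand"].map({"+": 1, "-": -1, "unknown": 0}).to_numpy(dtype="int8")
    return FragmentSet(
        df["start"].to_numpy(),
        df["end"].to_numpy(),
        codes,
        ids=df["fragment_id"].tolist(),
        genome_length=genome_length,
    )


def _read_fragments_sam(path: str | Path) -> list[FragmentPlacement]:
    mode = "rb" if str(path).endswith(".bam") else "r"
    n_unmapped = 0
    n_secondary = 0
    mates: dict[str, list[tuple[int, int, bool]]] = {}
    with pysam.AlignmentFile(str(path), mode) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped:
                n_unmapped += 1
                continue
            if read.is_secondary or read.is_supplementary:
                n_secondary += 1
                continue
            mates.setdefault(read.query_name, []).append(
                (read.reference_start, read.reference_end, read.is_reverse)
            )
    if n_unmapped or n_secondary:
        logger.info(
            "%s: dropped %d unmapped and %d secondary/supplementary records",
            path,
            n_unmapped,
            n_secondary,
        )
    placements = []
    for name in mates:  # insertion order: first-mate appearance in the file
        spans = mates[name]
        start = min(s for s, _, _ in spans)
        end = max(e for _, e, _ in spans)
        if len(spans) == 2:
            # strand of the fragment = strand of the leftmost (first) mate
            strand = "-" if sorted(spans)[0][2] else "+"
        else:
            strand = "-" if spans[0][2] else "+"
        placements.append(FragmentPlacement(name, start, end, strand))
    return placements


def write_fragments_tsv(
    placements: Iterable[FragmentPlacement], path: str | Path
) -> None:
    if isinstance(placements, FragmentSet):
        code_map = {1: "+", -1: "-", 0: "unknown"}
        pd.DataFrame(
            {
                "fragment_id": placements.all_ids(),
                "start": placements.starts,
                "end": placements.ends,
                "strand": [code_map[int(c)] for c in placements.strand_codes],
            }
        ).to_csv(path, sep="\t", index=False)
        return
    with open(path, "w") as fh:
        fh.write("fragment_id\tstart\tend\tstrand\n")
        for p in placements:
            fh.write(f"{p.fragment_id}\t{p.start}\t{p.end}\t{p.strand}\n")


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def write_bed(
    regions: Sequence[RegionCall], path: str | Path, genome_id: str = "genome"
) -> None:
    """Write region calls as BED6; name = kind or joined member ids."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.start, r.end)):
            name = "+".join(r.members) if r.members else r.kind
            fh.write(
                f"{genome_id}\t{r.start}\t{r.end}\t{name}\t{r.score:.4g}\t.\n"
            )


def read_bed(path: str | Path, kind: str = "gc_deviant") -> list[RegionCall]:
    """Read a BED file into RegionCalls of the given kind (cols 1-5 used)."""
    calls = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            start, end = int(parts[1]), int(parts[2])
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            calls.append(RegionCall(kind=kind, start=start, end=end, score=score))
    return calls


def write_bedgraph(
    coverage: CoverageTrack, path: str | Path, genome_id: str = "genome"
) -> None:
    """Write per-base depth as run-length-compressed bedGraph."""
    vals = coverage.values
    with open(path, "w") as fh:
        if len(vals) == 0:
            return
        run_start = 0
        for i in range(1, len(vals) + 1):
            if i == len(vals) or vals[i] != vals[run_start]:
                fh.write(f"{genome_id}\t{run_start}\t{i}\t{int(vals[run_start])}\n")
                run_start = i


def read_bedgraph(path: str | Path, genome_length: int) -> CoverageTrack:
    import numpy as np

    vals = np.zeros(genome_length, dtype=np.int64)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            _, s, e, v = line.split("\t")
            vals[int(s): int(e)] = int(float(v))
    return CoverageTrack(vals)


__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_fragments",
    "write_fragments_tsv",
    "write_bed",
    "read_bed",
    "write_bedgraph",
    "read_bedgraph",
]
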