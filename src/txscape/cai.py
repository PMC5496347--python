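"""Codon usage and the codon adaptation index (CAI).

CAI follows Sharp & Li (1987): relative adaptiveness w_c of each sense codon
is its usage count in a highly-expressed reference gene set divided by the
count of the most-used synonymous codon; a gene's CAI is the geometric mean
of w over its sense codons.  Unobserved reference codons get a pseudo-count
of 0.5 so no w is ever zero.  Stop codons and codons containing N are
excluded from both the usage table and gene scoring.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

from Bio.Data import CodonTable

from .model import Feature, FeatureTable, Genome, TxscapeError

_TABLE = CodonTable.unambiguous_dna_by_id[11]  # bacterial/archaeal code

STOP_CODONS = frozenset(_TABLE.stop_codons)

#: codon -> amino acid for the 61 sense codons
SENSE_CODONS: dict[str, str] = dict(_TABLE.forward_table)

#: amino acid -> tuple of synonymous codons
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(SENSE_CODONS.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

START_CODONS = frozenset(_TABLE.start_codons)

PSEUDO_COUNT = 0.5


@dataclass
class CodonUsageTable:
    """Codon counts over a reference gene set and within-family frequencies."""

    counts: dict[str, float]
    frequencies: dict[str, float]
    n_excluded: int = 0

    def family_frequency_sums(self) -> dict[str, float]:
        return {
            aa: sum(self.frequencies[c] for c in codons)
            for aa, codons in SYNONYMOUS_FAMILIES.items()
        }


@dataclass
class AdaptivenessTable:
    """Relative adaptiveness w_c in (0, 1] for each sense codon."""

    w: dict[str, float]

    def __post_init__(self) -> None:
        for aa, codons in SYNONYMOUS_FAMILIES.items():
            fam_max = max(self.w[c] for c in codons)
            if not math.isclose(fam_max, 1.0):
                raise TxscapeError(f"family {aa}: max w is {fam_max}, expected 1")
            if any(self.w[c] <= 0 for c in codons):
                raise TxscapeError(f"family {aa}: non-positive w")


def _codons(seq: str) -> Iterable[str]:
    for i in range(0, len(seq) - len(seq) % 3, 3):
        yield seq[i: i + 3]


def build_usage(reference_cds: Sequence[str]) -> CodonUsageTable:
    """Count codon usage over a reference CDS set.

    Sequences must have length divisible by 3; a non-start first codon or an
    internal stop only triggers a warning (the codons are still counted).
    Stop codons and N-containing codons are excluded; zero-count sense codons
    receive a pseudo-count of 0.5 before family frequencies are computed.
    """
    if not reference_cds:
        raise TxscapeError("empty reference gene set")
    counts = {c: 0.0 for c in SENSE_CODONS}
    n_excluded = 0
    for k, seq in enumerate(reference_cds):
        seq = seq.upper()
        if len(seq) % 3:
            raise TxscapeError(f"reference sequence {k} length not divisible by 3")
        codon_list = list(_codons(seq))
        if codon_list and codon_list[0] not in START_CODONS:
            warnings.warn(f"reference sequence {k} does not start with a start codon")
        if any(c in STOP_CODONS for c in codon_list[:-1]):
            warnings.warn(f"reference sequence {k} contains an internal stop codon")
        for c in codon_list:
            if c in SENSE_CODONS:
                counts[c] += 1
            else:
                n_excluded += 1
    for c in counts:
        if counts[c] == 0:
            counts[c] = PSEUDO_COUNT
    frequencies = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        fam_total = sum(counts[c] for c in codons)
        for c in codons:
            frequencies[c] = counts[c] / fam_total
    return CodonUsageTable(counts=counts, frequencies=frequencies, n_excluded=n_excluded)


def relative_adaptiveness(usage: CodonUsageTable) -> AdaptivenessTable:
    """w_c = count_c / max count within the codon's synonymous family."""
    w = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        fam_max = max(usage.counts[c] for c in codons)
        for c in codons:
            w[c] = usage.counts[c] / fam_max
    return AdaptivenessTable(w=w)


def cai_of(seq: str, adaptiveness: AdaptivenessTable) -> tuple[float, int]:
    """CAI of one CDS: exp(mean log w) over its sense codons.

    Computed in the log domain so long genes do not underflow.  Returns the
    CAI and the number of codons actually scored (stop and N-containing
    codons are skipped).
    """
    seq = seq.upper()
    if len(seq) % 3:
        raise TxscapeError("CDS length not divisible by 3")
    if len(seq) < 6:
        raise TxscapeError("CDS too short for CAI (need at least 2 codons)")
    log_sum = 0.0
    n_used = 0
    for c in _codons(seq):
        if c in SENSE_CODONS:
            log_sum += math.log(adaptiveness.w[c])
            n_used += 1
    if n_used == 0:
        raise TxscapeError("no scorable sense codons in CDS")
    return math.exp(log_sum / n_used), n_used


# ---------------------------------------------------------------------------
# Reference set selection and genome-wide scoring
# ---------------------------------------------------------------------------

def extract_cds_sequence(genome: Genome, feature: Feature) -> str:
    """Strand-aware CDS sequence for a feature."""
    seq = genome.sequence[feature.start: feature.end]
    if feature.strand == "-":
        comp = str.maketrans("ACGTN", "TGCAN")
        seq = seq.translate(comp)[::-1]
    return seq


def ribosomal_reference(
    feature_table: FeatureTable, genome: Genome, n_reference: int = 40
) -> list[Feature]:
    """Pick the reference gene set: ribosomal-protein CDS, the ``n_reference``
    longest when more are annotated."""
    ribo = [
        f
        for f in feature_table.cds
        if "ribosomal protein" in f.product.lower()
    ]
    if not ribo:
        raise TxscapeError("no ribosomal-protein CDS found for the CAI reference set")
    ribo.sort(key=lambda f: (-f.length, f.feature_id))
    return ribo[:n_reference]


def genome_cai(
    genome: Genome,
    feature_table: FeatureTable,
    n_reference: int = 40,
) -> "pd.DataFrame":
    """Per-CDS CAI against a ribosomal-protein reference usage table.

    Returns a DataFrame with feature_id, cai, n_codons.  CDS whose length is
    not divisible by 3 are skipped with a warning.
    """
    import pandas as pd

    ref_feats = ribosomal_reference(feature_table, genome, n_reference)
    usage = build_usage([extract_cds_sequence(genome, f) for f in ref_feats])
    adapt = relative_adaptiveness(usage)
    rows = []
    for f in feature_table.cds:
        seq = extract_cds_sequence(genome, f)
        if len(seq) % 3 or len(seq) < 6:
            warnings.warn(f"skipping {f.feature_id}: length {len(seq)} unsuitable for CAI")
            continue
        value, n_codons = cai_of(seq, adapt)
        rows.append((f.feature_id, value, n_codons))
    return pd.DataFrame(rows, columns=["feature_id", "cai", "n_codons"])


def write_usage_table(usage: CodonUsageTable, path: str | Path) -> None:
    """Write the reference usage in a cusp-style text layout
    (codon, amino acid, family fraction, per-1000 frequency, count)."""
    total = sum(usage.counts.values())
    with open(path, "w") as fh:
        fh.write("#Codon AA Fraction Frequency Number\n")
        for codon in sorted(SENSE_CODONS):
            aa = SENSE_CODONS[codon]
            fh.write(
                f"{codon} {aa} {usage.frequencies[codon]:.3f} "
                f"{1000 * usage.counts[codon] / total:.3f} "
                f"{usage.counts[codon]:.1f}\n"
            )


__all__ = [
    "CodonUsageTable",
    "AdaptivenessTable",
    "build_usage",
    "relative_adaptiveness",
    "cai_of",
    "genome_cai",
    "ribosomal_reference",
    "extract_cds_sequence",
    "write_usage_table",
    "SENSE_CODONS",
    "SYNONYMOUS_FAMILIES",
    "STOP_CODONS",
]
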