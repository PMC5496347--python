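"""Core data model shared by all analysis stages.

All coordinates are 0-based, half-open ``[start, end)`` on a single linear
replicon.  File formats that use other conventions (GFF3: 1-based inclusive)
are converted at the I/O boundary only.
"""

from __future__ import annotations

from collections.abc import Sequence as SequenceABC
from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple, Optional, Sequence

import numpy as np

VALID_ALPHABET = frozenset("ACGTN")

FEATURE_TYPES = ("CDS", "rRNA", "ncRNA", "tRNA", "other")

#: expression tiers, from silent to >=10x the mean CDS TPM
TIERS = ("silent", "sub_tpm", "below_avg", "avg", "ge2.5x", "ge5x", "ge10x")

REGION_KINDS = (
    "gc_deviant",
    "low_expression",
    "utr",
    "transcribed_island",
    "transcription_unit",
)


class TxscapeError(ValueError):
    """Raised on contract violations (malformed input, bad parameters)."""


@dataclass(frozen=True)
class Genome:
    """A single linear chromosome (circularity is recorded, not modelled)."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise TxscapeError("empty genome sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise TxscapeError(
                f"non-nucleotide characters in genome sequence: {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gc_fraction(self) -> float:
        """GC fraction over non-N bases."""
        seq = np.frombuffer(self.sequence.encode(), dtype="S1")
        n_n = int(np.count_nonzero(seq == b"N"))
        gc = int(np.count_nonzero((seq == b"G") | (seq == b"C")))
        denom = self.length - n_n
        return gc / denom if denom else float("nan")


@dataclass(frozen=True)
class Feature:
    feature_id: str
    ftype: str
    start: int
    end: int
    strand: str
    product: str = ""
    is_hypothetical: bool = False
    arcog: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise TxscapeError(f"unknown feature type {self.ftype!r}")
        if not (0 <= self.start < self.end):
            raise TxscapeError(
                f"bad feature interval [{self.start}, {self.end}) for {self.feature_id}"
            )
        if self.strand not in ("+", "-"):
            raise TxscapeError(f"bad strand {self.strand!r} for {self.feature_id}")

    @property
    def length(self) -> int:
        return self.end - self.start


class FeatureTable:
    """Ordered collection of features on one genome, sorted by (start, end)."""

    def __init__(self, features: Sequence[Feature], genome_id: str = ""):
        feats = sorted(features, key=lambda f: (f.start, f.end))
        ids = [f.feature_id for f in feats]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TxscapeError(f"duplicate feature ids: {dupes[:5]}")
        self.features: list[Feature] = feats
        self.genome_id = genome_id

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def __getitem__(self, i: int) -> Feature:
        return self.features[i]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, FeatureTable)
            and self.genome_id == other.genome_id
            and self.features == other.features
        )

    def of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.ftype == ftype]

    @property
    def cds(self) -> list[Feature]:
        return self.of_type("CDS")

    @property
    def rrna(self) -> list[Feature]:
        return self.of_type("rRNA")

    def validate_bounds(self, genome_length: int) -> None:
        for f in self.features:
            if f.end > genome_length:
                raise TxscapeError(
                    f"feature {f.feature_id} ends at {f.end} beyond genome "
                    f"length {genome_length}"
                )


class FragmentPlacement(NamedTuple):
    """One sequenced cDNA fragment placed on the genome (mate-pair union).

    A lightweight tuple: simulations create millions of these.  Use
    :meth:`validate` at parse boundaries.
    """

    fragment_id: str
    start: int
    end: int
    strand: str = "unknown"

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate(self, genome_length: Optional[int] = None) -> "FragmentPlacement":
        if self.start < 0 or self.start >= self.end:
            raise TxscapeError(
                f"bad fragment interval [{self.start}, {self.end}) "
                f"for {self.fragment_id}"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise TxscapeError(f"bad fragment strand {self.strand!r}")
        if genome_length is not None and self.end > genome_length:
            raise TxscapeError(
                f"fragment {self.fragment_id} [{self.start}, {self.end}) beyond "
                f"genome length {genome_length}"
            )
        return self


_STRAND_TO_CODE = {"+": 1, "-": -1, "unknown": 0}
_CODE_TO_STRAND = {1: "+", -1: "-", 0: "unknown"}


class FragmentSet(SequenceABC):
    """Columnar collection of fragment placements.

    Stores starts/ends/strand codes as numpy arrays for vectorised
    processing; indexing materialises individual
    :class:`FragmentPlacement` tuples on demand, so a FragmentSet can be
    used anywhere a sequence of placements is expected.
    """

    def __init__(
        self,
        starts: np.ndarray,
        ends: np.ndarray,
        strand_codes: Optional[np.ndarray] = None,
        ids: Optional[Sequence[str]] = None,
        id_prefix: str = "frag",
        genome_length: Optional[int] = None,
    ):
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        n = self.starts.size
        if self.ends.size != n:
            raise TxscapeError("starts/ends length mismatch")
        self.strand_codes = (
            np.zeros(n, dtype=np.int8)
            if strand_codes is None
            else np.asarray(strand_codes, dtype=np.int8)
        )
        self._ids = list(ids) if ids is not None else None
        self.id_prefix = id_prefix
        if n:
            if (self.starts < 0).any() or (self.starts >= self.ends).any():
                raise TxscapeError("invalid fragment interval in set")
            if genome_length is not None and int(self.ends.max()) > genome_length:
                raise TxscapeError(
                    f"fragment beyond genome length {genome_length}"
                )

    @classmethod
    def from_placements(
        cls, placements: Sequence["FragmentPlacement"]
    ) -> "FragmentSet":
        if isinstance(placements, cls):
            return placements
        n = len(placements)
        starts = np.fromiter((p.start for p in placements), dtype=np.int64, count=n)
        ends = np.fromiter((p.end for p in placements), dtype=np.int64, count=n)
        codes = np.fromiter(
            (_STRAND_TO_CODE[p.strand] for p in placements), dtype=np.int8, count=n
        )
        return cls(starts, ends, codes, ids=[p.fragment_id for p in placements])

    def id_of(self, i: int) -> str:
        return self._ids[i] if self._ids is not None else f"{self.id_prefix}_{i}"

    def all_ids(self) -> list[str]:
        if self._ids is not None:
            return list(self._ids)
        return [f"{self.id_prefix}_{i}" for i in range(len(self))]

    def __len__(self) -> int:
        return int(self.starts.size)

    def __getitem__(self, i):
        if isinstance(i, slice):
            idx = range(*i.indices(len(self)))
            return [self[j] for j in idx]
        return FragmentPlacement(
            self.id_of(i),
            int(self.starts[i]),
            int(self.ends[i]),
            _CODE_TO_STRAND[int(self.strand_codes[i])],
        )

    def __iter__(self) -> Iterator["FragmentPlacement"]:
        for i in range(len(self)):
            yield self[i]

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts


@dataclass
class CoverageTrack:
    """Per-nucleotide fragment depth over the whole genome."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 1:
            raise TxscapeError("coverage must be a 1-D array")
        if (self.values < 0).any():
            raise TxscapeError("negative coverage")

    def __len__(self) -> int:
        return len(self.values)

    def mean_depth(self, start: int, end: int) -> float:
        return float(self.values[start:end].mean())


@dataclass(frozen=True)
class WindowStat:
    start: int
    end: int
    value: float
    z: float


@dataclass(frozen=True)
class RegionCall:
    kind: str
    start: int
    end: int
    score: float
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise TxscapeError(f"unknown region kind {self.kind!r}")
        if not self.start < self.end:
            raise TxscapeError(f"bad region interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent half-open intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def interval_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def jaccard(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> float:
    """Jaccard index between two sets of half-open intervals (by nt)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    inter = sum(
        interval_overlap(s1, e1, s2, e2) for s1, e1 in a for s2, e2 in b
    )
    len_a = sum(e - s for s, e in a)
    len_b = sum(e - s for s, e in b)
    union = len_a + len_b - inter
    return inter / union if union else 1.0


__all__ = [
    "Genome",
    "Feature",
    "FeatureTable",
    "FragmentPlacement",
    "FragmentSet",
    "CoverageTrack",
    "WindowStat",
    "RegionCall",
    "TxscapeError",
    "TIERS",
    "FEATURE_TYPES",
    "REGION_KINDS",
    "merge_intervals",
    "interval_overlap",
    "jaccard",
    "replace",
    "field",
]
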