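"""Core genomic data containers shared across the toolkit.

All internal coordinates are 0-based half-open; conversion to the 1-based
conventions of GTF and VCF happens only at format boundaries (see
:mod:`lofkit.reference_io`).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}; "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` and ``cds_intervals`` are ordered 5'->3' in transcript
    orientation: ascending genomic coordinates on the plus strand,
    descending on the minus strand.  The CDS is required to be non-empty
    and contained within the exons; a CDS whose length is not a multiple
    of three is retained but flagged incomplete.
    """

    transcript_id: str
    gene_id: str
    gene_symbol: str
    strand: str
    exons: Tuple[GenomicInterval, ...]
    cds_intervals: Tuple[GenomicInterval, ...]
    canonical: bool = False

    def __post_init__(self) -> None:
        self.exons = tuple(self.exons)
        self.cds_intervals = tuple(self.cds_intervals)
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        starts = [e.start for e in self.exons]
        expected = sorted(starts, reverse=self.strand == "-")
        if starts != expected:
            raise ValueError(
                f"{self.transcript_id}: exons not in transcript (5'->3') order"
            )
        asc = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(asc, asc[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        for c in self.cds_intervals:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ValueError(
                    f"{self.transcript_id}: CDS {c.start}-{c.end} outside exons"
                )
        if self.cds_length == 0:
            raise ValueError(f"{self.transcript_id}: empty CDS")

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds_intervals)

    @property
    def cds_incomplete(self) -> bool:
        """True when the CDS length is not a multiple of three."""
        return self.cds_length % 3 != 0

    @property
    def span(self) -> GenomicInterval:
        start = min(e.start for e in self.exons)
        end = max(e.end for e in self.exons)
        return GenomicInterval(self.contig, start, end, self.strand)

    @property
    def exons_genomic(self) -> Tuple[GenomicInterval, ...]:
        """Exons sorted by ascending genomic coordinate."""
        return tuple(sorted(self.exons, key=lambda e: e.start))

    def cds_genomic_positions(self) -> np.ndarray:
        """Genomic positions of every CDS base, in transcript (5'->3') order."""
        chunks = []
        for c in self.cds_intervals:
            if self.strand == "+":
                chunks.append(np.arange(c.start, c.end))
            else:
                chunks.append(np.arange(c.end - 1, c.start - 1, -1))
        return np.concatenate(chunks)

    @property
    def last_junction_cds_offset(self) -> int:
        """CDS offset of the first coding base of the 3'-most CDS exon.

        Coding bases at offsets >= this value lie downstream of the final
        exon-exon junction of the coding region.  Zero for a single-interval
        CDS (no junction; the whole CDS counts as terminal for the NMD rule).
        """
        if len(self.cds_intervals) < 2:
            return 0
        return self.cds_length - len(self.cds_intervals[-1])

    def introns(self) -> List[GenomicInterval]:
        """Introns between consecutive exons, in transcript order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append(GenomicInterval(self.contig, a.end, b.start, "+"))
            else:
                out.append(GenomicInterval(self.contig, b.end, a.start, "-"))
        return out


@dataclass(frozen=True)
class VariantRecord:
    """A single bi-allelic cohort allele with site-level counts.

    ``pos`` is 1-based as in VCF; ``ref``/``alt`` are minimally represented
    (shared prefix/suffix trimmed, at least one base each).
    """

    contig: str
    pos: int
    ref: str
    alt: str
    allele_count: int
    allele_number: int
    n_homalt: int = 0
    site_filters: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not (0 <= self.allele_count <= self.allele_number):
            raise ValueError(
                f"{self.key}: AC={self.allele_count} outside [0, AN={self.allele_number}]"
            )
        if 2 * self.n_homalt > self.allele_count:
            raise ValueError(f"{self.key}: 2*nhomalt exceeds AC")
        if self.ref == self.alt:
            raise ValueError(f"{self.key}: ref equals alt")

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def allele_frequency(self) -> float:
        return self.allele_count / self.allele_number

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def passes_filters(self) -> bool:
        return not self.site_filters or self.site_filters == {"PASS"}


class CoverageTrack:
    """Per-base median coverage, backed by one array per contig.

    Positions outside the track return NaN, the "uncovered" sentinel.
    """

    def __init__(self) -> None:
        self._arrays: Dict[str, np.ndarray] = {}

    def set_interval(self, contig: str, start: int, end: int, value: float) -> None:
        if value < 0:
            raise ValueError("median coverage must be non-negative")
        arr = self._arrays.get(contig)
        if arr is None or len(arr) < end:
            new = np.full(max(end, 0 if arr is None else len(arr)), np.nan)
            if arr is not None:
                new[: len(arr)] = arr
            self._arrays[contig] = arr = new
        arr[start:end] = value

    def get(self, contig: str, pos: int) -> float:
        arr = self._arrays.get(contig)
        if arr is None or not (0 <= pos < len(arr)):
            return math.nan
        return float(arr[pos])

    def get_array(self, contig: str, positions: np.ndarray) -> np.ndarray:
        arr = self._arrays.get(contig)
        out = np.full(len(positions), np.nan)
        if arr is None:
            return out
        ok = (positions >= 0) & (positions < len(arr))
        out[ok] = arr[positions[ok]]
        return out

    def contigs(self) -> List[str]:
        return list(self._arrays)

    def intervals(self) -> Iterable[Tuple[str, int, int, float]]:
        """Run-length encoded (contig, start, end, value) records."""
        for contig, arr in self._arrays.items():
            if len(arr) == 0:
                continue
            same = (arr[1:] == arr[:-1]) | (np.isnan(arr[1:]) & np.isnan(arr[:-1]))
            breaks = np.flatnonzero(~same) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [len(arr)]])
            for s, e in zip(starts, ends):
                if not np.isnan(arr[s]):
                    yield contig, int(s), int(e), float(arr[s])


class PositionTrack:
    """Sparse per-base real-valued annotation (e.g. CpG methylation)."""

    def __init__(self, default: float = 0.0) -> None:
        self.default = default
        self._values: Dict[Tuple[str, int], float] = {}

    def set(self, contig: str, pos: int, value: float) -> None:
        self._values[(contig, pos)] = value

    def get(self, contig: str, pos: int) -> float:
        return self._values.get((contig, pos), self.default)

    def items(self) -> Iterable[Tuple[str, int, float]]:
        for (contig, pos), v in sorted(self._values.items()):
            yield contig, pos, v

    def __len__(self) -> int:
        return len(self._values)
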