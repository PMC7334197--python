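"""Readers and writers for the standard formats the toolkit consumes.

FASTA access goes through :mod:`pyfaidx`, transcript models through
:mod:`gffutils`, and cohort variant calls through :mod:`cyvcf2`.  All
coordinates are converted to the internal 0-based half-open convention at
this boundary and nowhere else.
"""
from __future__ import annotations

import logging
from collections import defaultdict

from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from pyfaidx import Fasta

from .models import (
    CoverageTrack,
    GenomicInterval,
    PositionTrack,
    TranscriptModel,
    VariantRecord,
    revcomp,
)

logger = logging.getLogger(__name__)


class ReferenceSequence:
    """Random-access view of an (indexed) FASTA reference.

    Substring queries use 0-based half-open intervals and return uppercase
    sequence; minus-strand queries return the reverse complement.
    """

    def __init__(self, path) -> None:
        self._fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        names = list(self._fasta.keys())
        if len(set(names)) != len(names):  # pragma: no cover - pyfaidx rejects first
            raise ValueError("duplicate contig names in FASTA")
        self._lengths = {name: len(self._fasta[name]) for name in names}
        self._seq_cache: Dict[str, str] = {}

    @property
    def contigs(self) -> List[str]:
        return list(self._lengths)

    def contig_length(self, contig: str) -> int:
        try:
            return self._lengths[contig]
        except KeyError:
            raise KeyError(f"contig {contig!r} not in reference") from None

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)`` on ``contig``; reverse-complemented for '-'."""
        length = self.contig_length(contig)
        if not (0 <= start <= end <= length):
            raise ValueError(
                f"query {contig}:{start}-{end} outside contig bounds [0, {length})"
            )
        seq = str(self._fasta[contig][start:end])
        return revcomp(seq) if strand == "-" else seq

    def contig_sequence(self, contig: str) -> str:
        cached = self._seq_cache.get(contig)
        if cached is None:
            cached = self.fetch(contig, 0, self.contig_length(contig))
            self._seq_cache[contig] = cached
        return cached


def write_fasta(sequences: Dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Transcript models (GTF)
# ---------------------------------------------------------------------------

def read_transcripts(
    path,
    canonical_tag: Tuple[str, str] = ("tag", "canonical"),
) -> List[TranscriptModel]:
    """Parse transcript models from a GTF file.

    One :class:`TranscriptModel` is built per ``transcript_id`` from its
    exon and CDS features.  GTF 1-based inclusive coordinates become
    internal 0-based half-open.  The canonical flag is read from the
    attribute named ``canonical_tag[0]`` when it contains the value
    ``canonical_tag[1]``; if no transcript of a gene carries the tag, the
    longest-CDS transcript is designated canonical (ties broken by
    lexicographic transcript_id).

    Transcripts with CDS outside any exon are rejected with a logged
    reason; an input yielding zero transcripts is an error.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except gffutils.exceptions.EmptyInputError as exc:
        raise ValueError(f"no usable transcripts in {path}") from exc
    exons: Dict[str, list] = defaultdict(list)
    cds: Dict[str, list] = defaultdict(list)
    meta: Dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        symbol = feat.attributes.get("gene_name", [gid])[0]
        tagged = canonical_tag[1] in feat.attributes.get(canonical_tag[0], [])
        info = meta.setdefault(
            tid,
            {"gene_id": gid, "gene_symbol": symbol, "strand": feat.strand, "canonical": False},
        )
        info["canonical"] = info["canonical"] or tagged
        iv = (feat.seqid, feat.start - 1, feat.end)
        (exons if feat.featuretype == "exon" else cds)[tid].append(iv)

    transcripts: List[TranscriptModel] = []
    for tid, info in meta.items():
        strand = info["strand"]
        rev = strand == "-"
        exon_ivs = [
            GenomicInterval(c, s, e, strand)
            for c, s, e in sorted(exons.get(tid, []), key=lambda x: x[1], reverse=rev)
        ]
        cds_ivs = [
            GenomicInterval(c, s, e, strand)
            for c, s, e in sorted(cds.get(tid, []), key=lambda x: x[1], reverse=rev)
        ]
        try:
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=info["gene_id"],
                    gene_symbol=info["gene_symbol"],
                    strand=strand,
                    exons=tuple(exon_ivs),
                    cds_intervals=tuple(cds_ivs),
                    canonical=info["canonical"],
                )
            )
        except ValueError as exc:
            logger.warning("rejecting transcript %s: %s", tid, exc)
    if not transcripts:
        raise ValueError(f"no usable transcripts in {path}")

    # fallback canonical designation per gene
    by_gene: Dict[str, List[TranscriptModel]] = defaultdict(list)
    for t in transcripts:
        by_gene[t.gene_id].append(t)
    for gene_transcripts in by_gene.values():
        if not any(t.canonical for t in gene_transcripts):
            best = sorted(
                gene_transcripts, key=lambda t: (-t.cds_length, t.transcript_id)
            )[0]
            best.canonical = True
    return transcripts


def write_gtf(transcripts: Sequence[TranscriptModel], path, source: str = "lofkit") -> None:
    """Write transcript models as GTF (1-based inclusive coordinates)."""

    def attrs(t: TranscriptModel) -> str:
        parts = [
            f'gene_id "{t.gene_id}"',
            f'transcript_id "{t.transcript_id}"',
            f'gene_name "{t.gene_symbol}"',
        ]
        if t.canonical:
            parts.append('tag "canonical"')
        return "; ".join(parts) + ";"

    with open(path, "w") as fh:
        for t in transcripts:
            a = attrs(t)
            span = t.span
            fh.write(
                f"{t.contig}\t{source}\ttranscript\t{span.start + 1}\t{span.end}\t.\t{t.strand}\t.\t{a}\n"
            )
            for e in t.exons_genomic:
                fh.write(
                    f"{t.contig}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{t.strand}\t.\t{a}\n"
                )
            for c in sorted(t.cds_intervals, key=lambda x: x.start):
                fh.write(
                    f"{t.contig}\t{source}\tCDS\t{c.start + 1}\t{c.end}\t.\t{t.strand}\t0\t{a}\n"
                )


# ---------------------------------------------------------------------------
# Variants (VCF)
# ---------------------------------------------------------------------------

def minimal_representation(pos: int, ref: str, alt: str) -> Tuple[int, str, str]:
    """Trim shared suffix then prefix, keeping at least one base of each allele.

    ``pos`` is 1-based and is advanced as leading shared bases are removed.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _as_tuple(value, n: int):
    if value is None:
        return (0,) * n
    if isinstance(value, (tuple, list, np.ndarray)):
        return tuple(value)
    return (value,)


def read_variants(path) -> List[VariantRecord]:
    """Read cohort alleles from a VCF.

    Multi-allelic records are split into bi-allelic minimal-representation
    records.  INFO keys AC and AN are required, nhomalt is optional
    (default 0).  Records with AC > AN are rejected with a logged reason.
    """
    out: List[VariantRecord] = []
    vcf = VCF(str(path))
    for v in vcf:
        n_alt = len(v.ALT)
        ac = _as_tuple(v.INFO.get("AC"), n_alt)
        nhom = _as_tuple(v.INFO.get("nhomalt"), n_alt)
        an = v.INFO.get("AN")
        if an is None:
            logger.warning("skipping %s:%s: missing AN", v.CHROM, v.POS)
            continue
        filters = frozenset() if v.FILTER is None else frozenset(v.FILTER.split(";"))
        for i, alt in enumerate(v.ALT):
            pos, ref, alt_min = minimal_representation(v.POS, v.REF, alt)
            try:
                out.append(
                    VariantRecord(
                        contig=v.CHROM,
                        pos=pos,
                        ref=ref,
                        alt=alt_min,
                        allele_count=int(ac[i]),
                        allele_number=int(an),
                        n_homalt=int(nhom[i]) if i < len(nhom) else 0,
                        site_filters=filters,
                    )
                )
            except ValueError as exc:
                logger.warning("rejecting record: %s", exc)
    return out


def variants_to_frame(variants: Iterable[VariantRecord]) -> pd.DataFrame:
    rows = [
        (
            v.contig,
            v.pos,
            v.ref,
            v.alt,
            v.allele_count,
            v.allele_number,
            v.n_homalt,
            v.passes_filters,
        )
        for v in variants
    ]
    return pd.DataFrame(
        rows,
        columns=["contig", "pos", "ref", "alt", "AC", "AN", "nhomalt", "pass"],
    )


def write_vcf(
    variants: Sequence[VariantRecord],
    contig_lengths: Dict[str, int],
    path,
) -> None:
    """Write bi-allelic records as a sorted VCF v4.2 with AC/AN/nhomalt INFO."""
    order = {c: i for i, c in enumerate(contig_lengths)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lofkit\n")
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">\n')
        fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Total allele number">\n')
        fh.write(
            '##INFO=<ID=nhomalt,Number=A,Type=Integer,Description="Number of homozygous-alternate individuals">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda x: (order.get(x.contig, 1 << 30), x.pos, x.ref, x.alt)):
            filt = "PASS" if v.passes_filters else ";".join(sorted(v.site_filters))
            fh.write(
                f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{filt}\t"
                f"AC={v.allele_count};AN={v.allele_number};nhomalt={v.n_homalt}\n"
            )


# ---------------------------------------------------------------------------
# Coverage and methylation tracks (TSV)
# ---------------------------------------------------------------------------

def read_coverage(path) -> CoverageTrack:
    """BED-like TSV with columns contig, start (0-based), end, median_coverage."""
    track = CoverageTrack()
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["contig", "start", "end", "median_coverage"])
    for row in df.itertuples(index=False):
        track.set_interval(row.contig, int(row.start), int(row.end), float(row.median_coverage))
    return track


def write_coverage(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for contig, start, end, value in track.intervals():
            fh.write(f"{contig}\t{start}\t{end}\t{value:g}\n")


def read_methylation(path) -> PositionTrack:
    """TSV with columns contig, pos (0-based), methylation value in [0, 1]."""
    track = PositionTrack(default=0.0)
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["contig", "pos", "value"])
    for row in df.itertuples(index=False):
        track.set(row.contig, int(row.pos), float(row.value))
    return track


def write_methylation(track: PositionTrack, path) -> None:
    with open(path, "w") as fh:
        for contig, pos, value in track.items():
            fh.write(f"{contig}\t{pos}\t{value:g}\n")


def coding_sequence(transcript: TranscriptModel, reference: ReferenceSequence) -> str:
    """Concatenated CDS sequence in 5'->3' transcript orientation.

    Minus-strand transcripts are reverse-complemented.  An incomplete CDS
    (length not a multiple of three) is returned as-is; callers consult
    :attr:`TranscriptModel.cds_incomplete`.
    """
    parts = []
    for c in transcript.cds_intervals:
        parts.append(reference.fetch(c.contig, c.start, c.end, transcript.strand))
    return "".join(parts)
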