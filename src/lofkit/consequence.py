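"""Variant consequence annotation and LOFTEE-style pLoF classification.

The annotator assigns a single most-severe consequence per
(variant, transcript) pair using the standard codon table; the classifier
sorts putative loss-of-function calls (stop-gained, frameshift, essential
splice) into high-confidence (HC), low-confidence (LC, with named
filters) and other-splice (OS) following first-principles rules:

* END_TRUNC - premature stops/frameshifts in the last coding exon or
  within the NMD-escape window (50 coding bases by default) upstream of
  the 3'-most exon-exon junction are predicted to escape
  nonsense-mediated decay and are filtered.
* SMALL_INTRON - essential-splice disruptions of very short introns.
* SPLICE_RESCUE - a frame-preserving cryptic GT/AG within a configurable
  window can rescue splicing.
* NON_CANONICAL_INTRON - the disrupted intron does not use GT..AG.
* INCOMPLETE_CDS - the transcript's CDS length is not a multiple of 3.

Splice-affecting substitutions outside the two essential intronic bases
(intronic positions 3-8 and the final exonic base of an internal exon)
are reported as splice_region and classified OS.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple


from Bio.Data.CodonTable import unambiguous_dna_by_id

from .models import GenomicInterval, TranscriptModel, VariantRecord, complement
from .reference_io import ReferenceSequence

_TABLE = unambiguous_dna_by_id[1]
AMINO_ACIDS: Dict[str, str] = dict(_TABLE.forward_table)
for _codon in _TABLE.stop_codons:
    AMINO_ACIDS[_codon] = "*"

#: Most-severe-first consequence ordering (fixed, deterministic).
SEVERITY_ORDER: Tuple[str, ...] = (
    "stop_gained",
    "frameshift",
    "splice_donor",
    "splice_acceptor",
    "stop_lost",
    "start_lost",
    "missense",
    "inframe_indel",
    "splice_region",
    "synonymous",
    "intron",
    "utr",
    "other",
)
_SEVERITY = {c: i for i, c in enumerate(SEVERITY_ORDER)}

PLOF_CONSEQUENCES = frozenset(
    {"stop_gained", "frameshift", "splice_donor", "splice_acceptor"}
)


@dataclass
class LofteeConfig:
    """Tunable thresholds of the pLoF classifier."""

    nmd_escape_window: int = 50        # coding bases upstream of the last junction
    min_intron_length: int = 15        # introns shorter than this -> SMALL_INTRON
    rescue_window: int = 15            # +/- bases scanned for cryptic GT/AG
    splice_region_intron_start: int = 3
    splice_region_intron_end: int = 8
    max_indel_length: int = 50         # larger events are structural, rejected


DEFAULT_LOFTEE_CONFIG = LofteeConfig()


@dataclass
class ConsequenceCall:
    variant: VariantRecord
    transcript_id: str
    consequence: str
    cds_position: Optional[int] = None
    intron_index: Optional[int] = None
    out_of_range: bool = False


@dataclass
class LofteeVerdict:
    call: ConsequenceCall
    verdict: str                      # HC | LC | OS | not_pLoF
    filters: frozenset = frozenset()


class _Intron:
    """Precomputed splice architecture of one intron (transcript order)."""

    __slots__ = (
        "interval",
        "length",
        "seq",
        "canonical",
        "donor_positions",
        "acceptor_positions",
        "donor_region",
        "acceptor_region",
        "donor_rescue",
        "acceptor_rescue",
    )

    def __init__(self, interval: GenomicInterval, seq: str):
        self.interval = interval
        self.length = len(interval)
        self.seq = seq  # transcript-oriented
        self.canonical = len(seq) >= 4 and seq[:2] == "GT" and seq[-2:] == "AG"


class TranscriptFrame:
    """Cached per-transcript coordinate/sequence scaffolding.

    Maps genomic positions to CDS offsets, catalogues essential splice and
    splice-region bases, and precomputes the cryptic-site rescue scan for
    each intron end.
    """

    def __init__(
        self,
        transcript: TranscriptModel,
        reference: ReferenceSequence,
        config: LofteeConfig = DEFAULT_LOFTEE_CONFIG,
    ):
        self.transcript = transcript
        self.config = config
        t = transcript
        rev = t.strand == "-"
        self.cds_positions = t.cds_genomic_positions()
        self.cds_seq = "".join(
            reference.fetch(c.contig, c.start, c.end, t.strand) for c in t.cds_intervals
        )
        self.pos_to_cds: Dict[int, int] = {
            int(g): i for i, g in enumerate(self.cds_positions)
        }
        self.introns: List[_Intron] = []
        self.essential: Dict[int, Tuple[str, int]] = {}
        self.region: Dict[int, int] = {}
        self.exonic_last_bases: Set[int] = set()

        w = config.rescue_window
        exons = t.exons  # transcript order
        for idx, iv in enumerate(t.introns()):
            seq = reference.fetch(iv.contig, iv.start, iv.end, t.strand)
            intron = _Intron(iv, seq)
            # genomic position of intron offset k (from the 5' end, transcript sense)
            def at(k: int) -> int:
                return iv.start + k if not rev else iv.end - 1 - k

            # genomic position of offset j from the 3' end (j=1 is the last base)
            def at_end(j: int) -> int:
                return iv.end - j if not rev else iv.start + j - 1

            L = intron.length
            for k in (0, 1):
                if k < L:
                    self.essential[at(k)] = ("splice_donor", idx)
            for j in (1, 2):
                if L - j >= 2:  # do not double-book donor bases in tiny introns
                    self.essential.setdefault(at_end(j), ("splice_acceptor", idx))
            for p in range(config.splice_region_intron_start - 1, config.splice_region_intron_end):
                if p < L and at(p) not in self.essential:
                    self.region.setdefault(at(p), idx)
            for j in range(config.splice_region_intron_start, config.splice_region_intron_end + 1):
                if L - j >= 2 and at_end(j) not in self.essential:
                    self.region.setdefault(at_end(j), idx)

            upstream_exon = exons[idx]
            last_base = upstream_exon.end - 1 if not rev else upstream_exon.start
            self.exonic_last_bases.add(last_base)

            # cryptic-site rescue scans (reference sequence approximation)
            up_flank = reference.fetch(
                iv.contig,
                upstream_exon.end - min(w, len(upstream_exon)) if not rev else upstream_exon.start,
                upstream_exon.end if not rev else upstream_exon.start + min(w, len(upstream_exon)),
                t.strand,
            )
            donor_local = up_flank + seq[: w + 2]
            origin = len(up_flank)
            intron.donor_rescue = _scan_rescue(donor_local, origin, "GT", w)

            down_exon = exons[idx + 1]
            down_flank = reference.fetch(
                iv.contig,
                down_exon.start if not rev else down_exon.end - min(w, len(down_exon)),
                down_exon.start + min(w, len(down_exon)) if not rev else down_exon.end,
                t.strand,
            )
            tail = seq[-(w + 2):]
            acceptor_local = tail + down_flank
            origin_a = len(tail) - 2
            intron.acceptor_rescue = _scan_rescue(acceptor_local, origin_a, "AG", w)

            self.introns.append(intron)


def _scan_rescue(local_seq: str, origin: int, motif: str, window: int) -> bool:
    """True when a frame-preserving cryptic ``motif`` lies within ``window``.

    ``origin`` is the index of the original essential dinucleotide within
    ``local_seq`` (transcript orientation); offsets divisible by 3 preserve
    frame.
    """
    for delta in range(-window, window + 1):
        if delta == 0 or delta % 3 != 0:
            continue
        i = origin + delta
        if 0 <= i and i + 2 <= len(local_seq) and local_seq[i : i + 2] == motif:
            return True
    return False


def get_frame(
    transcript: TranscriptModel,
    reference: ReferenceSequence,
    config: LofteeConfig = DEFAULT_LOFTEE_CONFIG,
) -> TranscriptFrame:
    """Return (and cache on the transcript) its :class:`TranscriptFrame`."""
    cached = getattr(transcript, "_lofkit_frame", None)
    if cached is not None and cached[0] is reference and cached[1] is config:
        return cached[2]
    frame = TranscriptFrame(transcript, reference, config)
    transcript._lofkit_frame = (reference, config, frame)
    return frame


_codon_memo: Dict[Tuple[str, int, str, bool], str] = {}


def codon_change_consequence(
    ref_codon: str, within: int, alt_base: str, is_first_codon: bool
) -> str:
    """Consequence of substituting ``alt_base`` at ``within`` of ``ref_codon``.

    All sequences are in transcript orientation.  Codons containing N are
    unscorable and return "other".
    """
    key = (ref_codon, within, alt_base, is_first_codon)
    hit = _codon_memo.get(key)
    if hit is not None:
        return hit
    if "N" in ref_codon or alt_base == "N" or len(ref_codon) != 3:
        cons = "other"
    else:
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
        ref_aa = AMINO_ACIDS[ref_codon]
        alt_aa = AMINO_ACIDS[alt_codon]
        if alt_aa == ref_aa:
            cons = "synonymous"
        elif alt_aa == "*":
            cons = "stop_gained"
        elif ref_aa == "*":
            cons = "stop_lost"
        elif is_first_codon and ref_codon == "ATG":
            cons = "start_lost"
        else:
            cons = "missense"
    _codon_memo[key] = cons
    return cons


def _most_severe(candidates) -> str:
    return min(candidates, key=lambda c: _SEVERITY[c])


def annotate_variant(
    variant: VariantRecord,
    transcript: TranscriptModel,
    reference: ReferenceSequence,
    config: LofteeConfig = DEFAULT_LOFTEE_CONFIG,
    flank: int = 200,
) -> ConsequenceCall:
    """Assign the single most-severe consequence of ``variant`` on ``transcript``.

    SNVs get codon-level calls; indels inside the CDS are frameshift when
    the length change is not a multiple of three, inframe otherwise.
    Events longer than ``config.max_indel_length`` are rejected as
    structural (ValueError).
    """
    frame = get_frame(transcript, reference, config)
    t = transcript
    pos0 = variant.pos - 1
    span = t.span

    if max(len(variant.ref), len(variant.alt)) > config.max_indel_length + 1:
        raise ValueError(
            f"{variant.key}: event larger than {config.max_indel_length} bp is structural"
        )

    if not (span.start - flank <= pos0 < span.end + flank):
        return ConsequenceCall(variant, t.transcript_id, "other", out_of_range=True)

    if variant.is_snv:
        return _annotate_snv(variant, frame, pos0)
    return _annotate_indel(variant, frame, pos0)


def _annotate_snv(variant: VariantRecord, frame: TranscriptFrame, pos0: int) -> ConsequenceCall:
    t = frame.transcript
    hit = frame.essential.get(pos0)
    if hit is not None:
        kind, idx = hit
        return ConsequenceCall(variant, t.transcript_id, kind, intron_index=idx)

    cds_off = frame.pos_to_cds.get(pos0)
    if cds_off is not None:
        alt_t = variant.alt if t.strand == "+" else complement(variant.alt)
        codon_i = cds_off // 3
        within = cds_off % 3
        ref_codon = frame.cds_seq[3 * codon_i : 3 * codon_i + 3]
        cons = codon_change_consequence(ref_codon, within, alt_t, codon_i == 0)
        if pos0 in frame.exonic_last_bases:
            cons = _most_severe([cons, "splice_region"])
        return ConsequenceCall(variant, t.transcript_id, cons, cds_position=cds_off)

    if pos0 in frame.region:
        return ConsequenceCall(
            variant, t.transcript_id, "splice_region", intron_index=frame.region[pos0]
        )
    for intron in frame.introns:
        if intron.interval.contains(pos0):
            return ConsequenceCall(variant, t.transcript_id, "intron")
    if any(e.contains(pos0) for e in t.exons):
        return ConsequenceCall(variant, t.transcript_id, "utr")
    return ConsequenceCall(variant, t.transcript_id, "other")


def _annotate_indel(variant: VariantRecord, frame: TranscriptFrame, pos0: int) -> ConsequenceCall:
    t = frame.transcript
    size = abs(len(variant.ref) - len(variant.alt))
    if len(variant.ref) > len(variant.alt):  # deletion: bases after the anchor
        affected = range(pos0 + 1, pos0 + len(variant.ref))
    else:  # insertion between pos0 and pos0+1
        affected = [p for p in (pos0, pos0 + 1) if p in frame.pos_to_cds]

    candidates = []
    cds_hits = [frame.pos_to_cds[p] for p in affected if p in frame.pos_to_cds]
    intron_idx = None
    for p in affected:
        hit = frame.essential.get(p)
        if hit is not None:
            candidates.append(hit[0])
            intron_idx = hit[1]
        elif p in frame.region:
            candidates.append("splice_region")
            intron_idx = intron_idx if intron_idx is not None else frame.region[p]
    if len(variant.ref) > len(variant.alt):
        if cds_hits:
            candidates.append("frameshift" if size % 3 else "inframe_indel")
    else:
        # insertion is coding only when both flanking bases are coding
        if len(cds_hits) == 2:
            candidates.append("frameshift" if size % 3 else "inframe_indel")
    if not candidates:
        if any(intron.interval.contains(pos0 + 1) for intron in frame.introns):
            candidates.append("intron")
        elif any(e.contains(pos0 + 1) for e in t.exons):
            candidates.append("utr")
        else:
            candidates.append("other")
    cons = _most_severe(candidates)
    return ConsequenceCall(
        variant,
        t.transcript_id,
        cons,
        cds_position=min(cds_hits) if cds_hits else None,
        intron_index=intron_idx,
    )


def classify_plof(
    call: ConsequenceCall,
    transcript: TranscriptModel,
    reference: ReferenceSequence,
    config: LofteeConfig = DEFAULT_LOFTEE_CONFIG,
) -> LofteeVerdict:
    """Classify a consequence call as HC / LC (with filters) / OS / not_pLoF."""
    if call.transcript_id != transcript.transcript_id:
        raise ValueError(
            f"call on {call.transcript_id} classified against {transcript.transcript_id}"
        )
    cons = call.consequence
    if cons == "splice_region":
        return LofteeVerdict(call, "OS")
    if cons not in PLOF_CONSEQUENCES:
        return LofteeVerdict(call, "not_pLoF")

    frame = get_frame(transcript, reference, config)
    filters: Set[str] = set()
    if transcript.cds_incomplete:
        filters.add("INCOMPLETE_CDS")

    if cons in ("stop_gained", "frameshift"):
        if call.cds_position is not None:
            junction = transcript.last_junction_cds_offset
            if call.cds_position >= junction - config.nmd_escape_window:
                filters.add("END_TRUNC")
    else:  # essential splice
        if call.intron_index is None:
            raise ValueError("splice call lacks intron information")
        intron = frame.introns[call.intron_index]
        if intron.length < config.min_intron_length:
            filters.add("SMALL_INTRON")
        if not intron.canonical:
            filters.add("NON_CANONICAL_INTRON")
        rescued = (
            intron.donor_rescue if cons == "splice_donor" else intron.acceptor_rescue
        )
        if rescued:
            filters.add("SPLICE_RESCUE")

    verdict = "LC" if filters else "HC"
    return LofteeVerdict(call, verdict, frozenset(filters))
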