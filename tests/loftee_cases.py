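"""Constructed rule-matrix cases for the pLoF classifier.

Each case is a hand-built gene whose sequence is controlled so exactly
one classification rule is exercised: exons are AAC-repeats (no stray
GT/AG dinucleotides), introns are GT + C-runs + AG with cryptic sites
placed only where a case wants them.  Every case carries its expected
consequence, verdict and filter set, and can be built on either strand
(the minus-strand build mirrors the genome and the variant).
"""
from dataclasses import dataclass
from typing import List, Optional, Tuple

from lofkit.models import complement

EXON1 = "ATG" + "AAC" * 9          # 30 bp, starts the CDS
EXON2 = "AAC" * 9 + "TAA"          # 30 bp, ends the CDS
FLANK5 = "CCACCACCAC"
FLANK3 = "CACCACCACC"


def plain_intron(length: int) -> str:
    assert length >= 4
    return "GT" + "C" * (length - 4) + "AG"


@dataclass
class SpliceCase:
    id: str
    intron: str
    offset: int                    # intron offset of the variant (from 5' end)
    alt_sense: str
    consequence: str
    verdict: str
    filters: frozenset = frozenset()
    exon2: str = EXON2


def splice_cases() -> List[SpliceCase]:
    cases = [
        # SMALL_INTRON threshold at 14/15/16 bp (minimum 15)
        SpliceCase("small_intron_14", plain_intron(14), 0, "A",
                   "splice_donor", "LC", frozenset({"SMALL_INTRON"})),
        SpliceCase("small_intron_15", plain_intron(15), 0, "A",
                   "splice_donor", "HC"),
        SpliceCase("small_intron_16", plain_intron(16), 0, "A",
                   "splice_donor", "HC"),
        # SPLICE_RESCUE: cryptic GT at +3 preserves frame, at +4 breaks it
        SpliceCase("donor_rescue_in_frame", "GTC" + "GT" + "C" * 23 + "AG", 0, "A",
                   "splice_donor", "LC", frozenset({"SPLICE_RESCUE"})),
        SpliceCase("donor_rescue_frame_broken", "GTCC" + "GT" + "C" * 22 + "AG", 0, "A",
                   "splice_donor", "HC"),
        # acceptor-side rescue: cryptic AG three bases upstream of the real AG
        SpliceCase("acceptor_rescue_in_frame", "GT" + "C" * 23 + "AG" + "C" + "AG", 29, "T",
                   "splice_acceptor", "LC", frozenset({"SPLICE_RESCUE"})),
        SpliceCase("acceptor_rescue_frame_broken", "GT" + "C" * 22 + "AG" + "CC" + "AG", 29, "T",
                   "splice_acceptor", "HC"),
        # non-GT..AG intron disrupted at the (positional) essential site
        SpliceCase("non_canonical_intron", "CT" + "C" * 26 + "AG", 0, "A",
                   "splice_donor", "LC", frozenset({"NON_CANONICAL_INTRON"})),
        # second essential donor base
        SpliceCase("donor_plus2", plain_intron(30), 1, "A", "splice_donor", "HC"),
        # essential acceptor bases
        SpliceCase("acceptor_minus2", plain_intron(30), 28, "C", "splice_acceptor", "HC"),
        # other-splice: intronic positions +3 .. +8 from the donor
        *[
            SpliceCase(f"os_donor_plus{k + 1}", plain_intron(30), k, "A",
                       "splice_region", "OS")
            for k in range(2, 8)
        ],
        # intronic +9 is past the splice region
        SpliceCase("intron_plus9", plain_intron(30), 8, "A", "intron", "not_pLoF"),
        # acceptor-side splice region at -3
        SpliceCase("os_acceptor_minus3", plain_intron(30), 27, "A", "splice_region", "OS"),
        # incomplete CDS flags any essential-splice pLoF
        SpliceCase("incomplete_cds_donor", plain_intron(30), 0, "A",
                   "splice_donor", "LC", frozenset({"INCOMPLETE_CDS"}),
                   exon2="AAC" * 9 + "TA"),
    ]
    return cases


def build_splice_case(case: SpliceCase, strand: str):
    """(GeneCase, VariantRecord) for a case on the requested strand."""
    from genebuild import build_gene

    gene = build_gene([EXON1, case.exon2], [case.intron], FLANK5, FLANK3, strand=strand)
    pos_sense = len(FLANK5) + len(EXON1) + case.offset
    if strand == "+":
        pos0, alt = pos_sense, case.alt_sense
    else:
        pos0 = len(gene.contig_seq) - 1 - pos_sense
        alt = complement(case.alt_sense)
    return gene, gene.snv(pos0, alt)


# END_TRUNC boundary: 3 exons of 60 coding bases, last junction at CDS 120,
# NMD-escape window 50 -> positions >= 70 escape.
END_TRUNC_CASES: List[Tuple[str, int, str, Optional[frozenset]]] = [
    ("five_prime_stop_kept", 0, "HC", None),
    ("just_outside_window_69", 69, "HC", None),
    ("window_boundary_70", 70, "LC", frozenset({"END_TRUNC"})),
    ("inside_window_71", 71, "LC", frozenset({"END_TRUNC"})),
    ("last_base_before_junction", 119, "LC", frozenset({"END_TRUNC"})),
    ("last_exon_130", 130, "LC", frozenset({"END_TRUNC"})),
]
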