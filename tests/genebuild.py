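"""Hand-built single-gene genomes for annotation tests."""
from __future__ import annotations

from dataclasses import dataclass
from typing import List

from lofkit.models import GenomicInterval, TranscriptModel, VariantRecord, revcomp
from lofkit.simulate import InMemoryReference


@dataclass
class GeneCase:
    """A hand-built single-gene test genome."""

    reference: InMemoryReference
    transcript: TranscriptModel
    contig_seq: str

    def snv(self, pos0: int, alt: str, ac: int = 1, an: int = 1000) -> VariantRecord:
        return VariantRecord(
            contig="chrT",
            pos=pos0 + 1,
            ref=self.contig_seq[pos0],
            alt=alt,
            allele_count=ac,
            allele_number=an,
        )


def build_gene(
    exon_seqs: List[str],
    intron_seqs: List[str],
    flank5: str = "CCACCACCAC",
    flank3: str = "CACCACCACC",
    strand: str = "+",
    contig: str = "chrT",
) -> GeneCase:
    """Assemble a fully coding gene; minus-strand genes are mirrored.

    ``exon_seqs``/``intron_seqs`` are given in transcript (sense)
    orientation; for the minus strand the stored contig is the reverse
    complement and intervals are remapped, so the transcript reads the
    same sense sequence either way.
    """
    assert len(intron_seqs) == len(exon_seqs) - 1
    parts = [flank5]
    ivs = []
    offset = len(flank5)
    for i, ex in enumerate(exon_seqs):
        ivs.append((offset, offset + len(ex)))
        parts.append(ex)
        offset += len(ex)
        if i < len(intron_seqs):
            parts.append(intron_seqs[i])
            offset += len(intron_seqs[i])
    parts.append(flank3)
    sense = "".join(parts)

    if strand == "+":
        seq = sense
    else:
        seq = revcomp(sense)
        L = len(sense)
        ivs = [(L - e, L - s) for s, e in ivs]
    order = sorted(ivs, reverse=strand == "-")
    exons = tuple(GenomicInterval(contig, s, e, strand) for s, e in order)
    transcript = TranscriptModel(
        transcript_id="TX1",
        gene_id="GENE1",
        gene_symbol="GENE1",
        strand=strand,
        exons=exons,
        cds_intervals=exons,
        canonical=True,
    )
    return GeneCase(
        reference=InMemoryReference({contig: seq}),
        transcript=transcript,
        contig_seq=seq,
    )
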