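"""Synthetic cohorts with known per-gene pLoF depletion.

The generator builds a toy genome (one contig per gene), fully coding
multi-exon transcripts with canonical GT..AG introns, a CpG methylation
track, a trinucleotide mutation-rate table, heterogeneous sequencing
coverage and a cohort VCF, all deterministic under a seed.

The population-genetic model is deliberately minimal and matches what
the constraint machinery consumes - independent sites, no linkage, no
recurrent mutation:

* a site with rate mu segregates with probability d * (1 - exp(-theta0 * mu)),
  where the depletion d < 1 applies only to high-confidence pLoF sites of
  genes in a depleted group: a fraction 1 - d of would-be-segregating pLoF
  sites is purged by selection, so d is exactly the o/e ratio the
  constraint pipeline should recover, independent of how saturated the
  site's mutation rate is;
* observation is additionally thinned at low-coverage bases by
  min(1, log10(cov)/log10(c_high)), the effect the coverage model corrects;
* segregating sites draw allele counts from the neutral 1/k spectrum
  truncated at AN haplotypes, thinned towards singletons per functional
  class (AC -> 1 + Binomial(AC - 1, f)) to give deleterious classes the
  rare-shifted spectra that MAPS detects;
* homozygote counts follow Hardy-Weinberg at the realised frequency.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import (
    CoverageTrack,
    GenomicInterval,
    PositionTrack,
    TranscriptModel,
    VariantRecord,
    revcomp,
)
from .mutation_model import MutationRateTable, enumerate_possible_all
from .reference_io import (
    write_coverage,
    write_fasta,
    write_gtf,
    write_methylation,
    write_vcf,
)

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


class InMemoryReference:
    """Duck-typed stand-in for ReferenceSequence backed by a dict of strings."""

    def __init__(self, sequences: Dict[str, str]):
        self._seqs = dict(sequences)

    @property
    def contigs(self) -> List[str]:
        return list(self._seqs)

    def contig_length(self, contig: str) -> int:
        try:
            return len(self._seqs[contig])
        except KeyError:
            raise KeyError(f"contig {contig!r} not in reference") from None

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        length = self.contig_length(contig)
        if not (0 <= start <= end <= length):
            raise ValueError(f"query {contig}:{start}-{end} outside [0, {length})")
        seq = self._seqs[contig][start:end]
        return revcomp(seq) if strand == "-" else seq

    def contig_sequence(self, contig: str) -> str:
        return self.fetch(contig, 0, self.contig_length(contig))


@dataclass
class SimulationConfig:
    """Study conditions of one synthetic cohort.

    Defaults describe the reference simulation: 300 genes with widely
    dispersed coding lengths split into a strongly constrained minority
    (15% of genes, pLoF depletion 0.1), moderately constrained genes
    (35%, depletion 0.5) and an unconstrained majority (50%, depletion
    1.0), sequenced in a cohort of 20,000 haplotypes with
    CpG-methylation-stratified mutation rates and 10% low-coverage
    sequence.
    """

    seed: int = 0
    n_genes: int = 300
    exons_per_gene: Tuple[int, int] = (2, 5)
    cds_length: Tuple[int, int] = (900, 6000)   # bases, forced to multiples of 3
    intron_length: Tuple[int, int] = (60, 300)
    flank: int = 25
    min_exon: int = 60
    n_haplotypes: int = 20000
    theta0: float = 1.5e7  # per-site segregation intensity multiplier
    #: gene group -> depletion d applied to HC pLoF segregation (and AC)
    depletion_by_class: Dict[str, float] = field(
        default_factory=lambda: {"strong": 0.1, "intermediate": 0.5, "neutral": 1.0}
    )
    group_fractions: Dict[str, float] = field(
        default_factory=lambda: {"strong": 0.15, "intermediate": 0.35, "neutral": 0.5}
    )
    #: functional-class allele-count thinning towards singletons
    frequency_depletion: Dict[str, float] = field(
        default_factory=lambda: {
            "hc": 0.25,
            "lc": 0.5,
            "os": 0.5,
            "missense": 0.7,
            "synonymous": 1.0,
        }
    )
    cpg_rate_multiplier: float = 16 / 3  # methylated CpG transition vs transition
    mu_transversion: float = 2e-9
    mu_transition: float = 6e-9
    context_spread: float = 0.25  # deterministic flanking-base modulation of mu
    fraction_low_coverage: float = 0.10
    fraction_zero_coverage: float = 0.005
    coverage_block: int = 50
    c_high: float = 40.0
    frameshift_indels_per_gene: float = 0.0

    def validate(self) -> None:
        for name in ("exons_per_gene", "cds_length", "intron_length"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"infeasible range {name}={lo, hi}")
        if self.cds_length[0] < 9:
            raise ValueError("cds_length must allow start + one codon + stop")
        if abs(sum(self.group_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("group fractions must sum to 1")
        for group, d in self.depletion_by_class.items():
            if not (0.0 <= d <= 1.0):
                raise ValueError(f"depletion for {group} outside [0, 1]")
            if group not in self.group_fractions:
                raise ValueError(f"group {group} missing from group_fractions")
        if self.n_haplotypes < 2:
            raise ValueError("need at least 2 haplotypes")


def default_rate_table(config: Optional[SimulationConfig] = None) -> MutationRateTable:
    """Build the full collapsed-context mutation-rate table.

    Transitions exceed transversions; CpG C>T rates rise with methylation
    level (level 2 = ``cpg_rate_multiplier`` times the base transition
    rate); a deterministic flanking-base factor spreads mu within each
    mutation type so the calibration has a non-degenerate design.
    """
    cfg = config or SimulationConfig()
    tv, ts = cfg.mu_transversion, cfg.mu_transition
    cpg_level = {
        0: 0.25 * ts * cfg.cpg_rate_multiplier,
        1: 0.50 * ts * cfg.cpg_rate_multiplier,
        2: 1.00 * ts * cfg.cpg_rate_multiplier,
    }
    idx = {b: i for i, b in enumerate("ACGT")}
    transitions = {("A", "G"), ("C", "T")}
    rates: Dict[Tuple[str, str, int], float] = {}
    for left in "ACGT":
        for centre in "AC":
            for right in "ACGT":
                ctx = left + centre + right
                spread = 1.0 + cfg.context_spread * ((idx[left] + idx[right]) - 3) / 3
                is_cpg = centre == "C" and right == "G"
                for alt in "ACGT":
                    if alt == centre:
                        continue
                    levels = (0, 1, 2) if is_cpg else (0,)
                    for level in levels:
                        if (centre, alt) in transitions:
                            base = cpg_level[level] if is_cpg else ts
                        else:
                            base = tv
                        rates[(ctx, alt, level)] = base * spread
    return MutationRateTable(rates)


@dataclass
class ReferenceBundle:
    sequences: Dict[str, str]
    transcripts: List[TranscriptModel]
    methylation: PositionTrack
    truth_genes: pd.DataFrame

    @property
    def reference(self) -> InMemoryReference:
        return InMemoryReference(self.sequences)


@dataclass
class CohortBundle:
    variants: List[VariantRecord]
    coverage: CoverageTrack
    possible: pd.DataFrame


def _split_lengths(total: int, parts: int, minimum: int, rng: np.random.Generator) -> List[int]:
    if total < parts * minimum:
        raise ValueError(f"cannot split {total} into {parts} parts of >= {minimum}")
    extra = total - parts * minimum
    weights = rng.dirichlet(np.ones(parts))
    sizes = [minimum + int(extra * w) for w in weights]
    sizes[0] += total - sum(sizes)
    return sizes


def generate_reference_and_transcripts(config: SimulationConfig) -> ReferenceBundle:
    """Generate the toy genome, transcript models, methylation and gene truth."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))

    groups = sorted(config.group_fractions)
    counts = {g: int(config.group_fractions[g] * config.n_genes) for g in groups}
    short = config.n_genes - sum(counts.values())
    for g in groups[:short]:
        counts[g] += 1
    assignment = rng.permutation(
        np.concatenate([np.full(counts[g], i) for i, g in enumerate(groups)])
    )

    sequences: Dict[str, str] = {}
    transcripts: List[TranscriptModel] = []
    methylation = PositionTrack(default=0.0)
    truth_rows = []

    for gi in range(config.n_genes):
        contig = f"g{gi:04d}"
        gene_id = f"GENE{gi:04d}"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        cds_len = 3 * int(rng.integers(config.cds_length[0] // 3, config.cds_length[1] // 3 + 1))
        n_codons = cds_len // 3
        body = "".join(
            _NON_STOP_CODONS[i] for i in rng.integers(0, len(_NON_STOP_CODONS), n_codons - 2)
        )
        cds = "ATG" + body + "TAA"
        exon_sizes = _split_lengths(cds_len, n_exons, config.min_exon, rng)
        intron_seqs = []
        for _ in range(n_exons - 1):
            ilen = int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
            interior = "".join(
                "ACGT"[i] for i in rng.integers(0, 4, max(ilen - 4, 0))
            )
            intron_seqs.append(("GT" + interior + "AG")[:ilen])
        flank5 = "".join("ACGT"[i] for i in rng.integers(0, 4, config.flank))
        flank3 = "".join("ACGT"[i] for i in rng.integers(0, 4, config.flank))

        parts = [flank5]
        exon_ivs_sense = []
        offset = len(flank5)
        cds_cursor = 0
        for ei, size in enumerate(exon_sizes):
            exon_ivs_sense.append((offset, offset + size))
            parts.append(cds[cds_cursor : cds_cursor + size])
            cds_cursor += size
            offset += size
            if ei < n_exons - 1:
                parts.append(intron_seqs[ei])
                offset += len(intron_seqs[ei])
        parts.append(flank3)
        sense = "".join(parts)

        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            contig_seq = sense
            ivs = exon_ivs_sense
        else:
            contig_seq = revcomp(sense)
            L = len(sense)
            ivs = [(L - e, L - s) for s, e in exon_ivs_sense]
        order = sorted(ivs, key=lambda x: x[0], reverse=strand == "-")
        exons = tuple(GenomicInterval(contig, s, e, strand) for s, e in order)

        sequences[contig] = contig_seq
        transcripts.append(
            TranscriptModel(
                transcript_id=f"TX{gi:04d}",
                gene_id=gene_id,
                gene_symbol=gene_id,
                strand=strand,
                exons=exons,
                cds_intervals=exons,
                canonical=True,
            )
        )

        pos = contig_seq.find("CG")
        while pos != -1:
            u = rng.random()
            if u < 0.70:
                value = rng.uniform(0.65, 0.98)
            elif u < 0.85:
                value = rng.uniform(0.25, 0.55)
            else:
                value = rng.uniform(0.0, 0.15)
            methylation.set(contig, pos, value)
            methylation.set(contig, pos + 1, value)
            pos = contig_seq.find("CG", pos + 1)

        group = groups[int(assignment[gi])]
        truth_rows.append(
            {
                "gene_id": gene_id,
                "contig": contig,
                "group": group,
                "depletion": config.depletion_by_class[group],
                "strand": strand,
                "cds_length": cds_len,
            }
        )

    return ReferenceBundle(
        sequences=sequences,
        transcripts=transcripts,
        methylation=methylation,
        truth_genes=pd.DataFrame(truth_rows),
    )


def _coverage_track(config: SimulationConfig, sequences: Dict[str, str],
                    rng: np.random.Generator) -> CoverageTrack:
    track = CoverageTrack()
    lo_cut = config.fraction_zero_coverage
    mid_cut = lo_cut + config.fraction_low_coverage
    for contig, seq in sequences.items():
        for start in range(0, len(seq), config.coverage_block):
            end = min(start + config.coverage_block, len(seq))
            u = rng.random()
            if u < lo_cut:
                value = 0.5
            elif u < mid_cut:
                value = rng.uniform(2.0, config.c_high - 1.0)
            else:
                value = rng.uniform(config.c_high + 2.0, 60.0)
            track.set_interval(contig, start, end, round(value, 2))
    return track


def _coverage_thinning(cov: np.ndarray, c_high: float) -> np.ndarray:
    """True observation thinning at low coverage (what the pipeline re-fits)."""
    out = np.zeros(cov.shape)
    ok = cov >= 1.0
    out[ok] = np.minimum(1.0, np.log10(cov[ok]) / np.log10(c_high))
    return out


def _class_key(verdict: str, consequence: str) -> str:
    if verdict == "HC":
        return "hc"
    if verdict == "LC":
        return "lc"
    if verdict == "OS":
        return "os"
    if consequence == "synonymous":
        return "synonymous"
    if consequence in ("missense", "stop_lost", "start_lost"):
        return "missense"
    return "neutral"


def simulate_cohort_vcf(
    config: SimulationConfig,
    bundle: ReferenceBundle,
    rates: MutationRateTable,
) -> CohortBundle:
    """Simulate cohort allele counts for every possible SNV of the genome."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    reference = bundle.reference
    coverage = _coverage_track(config, bundle.sequences, rng)

    possible = enumerate_possible_all(
        bundle.transcripts,
        reference,
        coverage=coverage,
        rates=rates,
        methylation=bundle.methylation,
    )

    depletion = bundle.truth_genes.set_index("gene_id")["depletion"]
    gene_d = possible["gene_id"].map(depletion).to_numpy(dtype=float)
    verdict = possible["verdict"].astype(str).to_numpy()
    consequence = possible["consequence"].astype(str).to_numpy()
    mu = possible["mu"].to_numpy()
    cov = possible["coverage"].to_numpy()

    is_hc = verdict == "HC"
    d_seg = np.where(is_hc, gene_d, 1.0)
    p_seg = d_seg * (1.0 - np.exp(-config.theta0 * mu))
    syn_sat = p_seg[consequence == "synonymous"]
    if syn_sat.size and syn_sat.max() > 0.99:
        warnings.warn("neutral synonymous sites approaching saturation (p > 0.99)")
    p_obs = p_seg * _coverage_thinning(cov, config.c_high)
    segregating = rng.random(len(possible)) < p_obs

    an = config.n_haplotypes
    k_values = np.arange(1, an + 1)
    sfs_p = 1.0 / k_values
    sfs_p /= sfs_p.sum()
    n_seg = int(segregating.sum())
    k = rng.choice(an, size=n_seg, p=sfs_p) + 1

    class_factor = np.array(
        [
            config.frequency_depletion.get(_class_key(v, c), 1.0)
            for v, c in zip(verdict[segregating], consequence[segregating])
        ]
    )
    d_freq = class_factor * np.where(is_hc[segregating], gene_d[segregating], 1.0)
    d_freq = np.clip(d_freq, 1e-12, 1.0)
    ac = 1 + rng.binomial(k - 1, d_freq)
    nhom = np.minimum(rng.binomial(an // 2, (ac / an) ** 2), ac // 2)

    seg_rows = possible[segregating]
    variants = [
        VariantRecord(
            contig=row.contig,
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            allele_count=int(a),
            allele_number=an,
            n_homalt=int(h),
        )
        for row, a, h in zip(seg_rows.itertuples(index=False), ac, nhom)
    ]

    if config.frameshift_indels_per_gene > 0:
        variants.extend(_plant_frameshifts(config, bundle, rng))

    return CohortBundle(variants=variants, coverage=coverage, possible=possible)


def _plant_frameshifts(
    config: SimulationConfig, bundle: ReferenceBundle, rng: np.random.Generator
) -> List[VariantRecord]:
    """Plant 1-bp coding deletions (pLoF-class indels) for classifier tests."""
    an = config.n_haplotypes
    k_values = np.arange(1, an + 1)
    sfs_p = 1.0 / k_values
    sfs_p /= sfs_p.sum()
    out = []
    thin = config.frequency_depletion.get("hc", 1.0)
    for t in bundle.transcripts:
        n = rng.poisson(config.frameshift_indels_per_gene)
        if n == 0:
            continue
        seq = bundle.sequences[t.contig]
        cds_pos = np.sort(t.cds_genomic_positions())
        for g in rng.choice(cds_pos[3:-3], size=n, replace=False):
            pos0 = int(g) - 1  # anchor base before the deleted one
            k = int(rng.choice(an, p=sfs_p)) + 1
            ac = 1 + int(rng.binomial(k - 1, thin))
            out.append(
                VariantRecord(
                    contig=t.contig,
                    pos=pos0 + 1,
                    ref=seq[pos0 : pos0 + 2],
                    alt=seq[pos0],
                    allele_count=ac,
                    allele_number=an,
                )
            )
    return out


def analytic_singleton_proportion(an: int, thinning: float = 1.0) -> float:
    """Exact singleton proportion under the truncated 1/k spectrum.

    With allele-count thinning AC -> 1 + Binomial(AC - 1, thinning), a
    site initially at count k stays a singleton with probability
    (1 - thinning)^(k-1).
    """
    k = np.arange(1, an + 1)
    p = 1.0 / k
    p /= p.sum()
    return float(np.sum(p * (1.0 - thinning) ** (k - 1)))


def simulate_to_dir(config: SimulationConfig, outdir) -> Dict[str, Path]:
    """Run the full generator and write every input file the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = generate_reference_and_transcripts(config)
    rates = default_rate_table(config)
    cohort = simulate_cohort_vcf(config, bundle, rates)

    paths = {
        "fasta": outdir / "ref.fa",
        "gtf": outdir / "genes.gtf",
        "methylation": outdir / "meth.tsv",
        "rates": outdir / "rates.tsv",
        "coverage": outdir / "cov.tsv",
        "vcf": outdir / "cohort.vcf",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(bundle.sequences, paths["fasta"])
    write_gtf(bundle.transcripts, paths["gtf"])
    write_methylation(bundle.methylation, paths["methylation"])
    rates.to_tsv(paths["rates"])
    write_coverage(cohort.coverage, paths["coverage"])
    contig_lengths = {c: len(s) for c, s in bundle.sequences.items()}
    write_vcf(cohort.variants, contig_lengths, paths["vcf"])
    bundle.truth_genes.to_csv(paths["truth"], sep="\t", index=False)
    return paths
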