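"""End-to-end gene constraint pipeline.

Wires the modules together: enumerate possible variants, join the cohort
VCF, calibrate the mutational model on synonymous sites, fit the
coverage correction, and emit the per-gene constraint table with
observed/expected ratios, confidence bounds (LOEUF), deciles, aggregate
pLoF frequency and homozygote tallies.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from collections import defaultdict
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from . import constraint as cm
from .consequence import (
    DEFAULT_LOFTEE_CONFIG,
    LofteeConfig,
    annotate_variant,
    classify_plof,
)
from .models import TranscriptModel, VariantRecord
from .mutation_model import (
    CalibrationModel,
    CoverageModel,
    MutationRateTable,
    enumerate_possible_all,
    fit_calibration,
    fit_coverage_model,
    mark_observed,
    per_site_expectation,
)
from .reference_io import (
    ReferenceSequence,
    read_coverage,
    read_methylation,
    read_transcripts,
    read_variants,
    variants_to_frame,
)

logger = logging.getLogger(__name__)

HC_LOF_SNV_CONSEQUENCES = ("stop_gained", "splice_donor", "splice_acceptor")


@dataclass
class ConstraintResult:
    table: pd.DataFrame
    calibration: CalibrationModel
    coverage_model: CoverageModel
    possible: pd.DataFrame           # possible-variant table with observed join
    indel_lof: pd.DataFrame          # HC pLoF indels annotated outside the SNV model

    @property
    def observed(self) -> pd.DataFrame:
        """Observed (pass-filter, frequency-eligible) rows of the possible table."""
        return self.possible[self.possible["observed"]]


def run_constraint(
    reference,
    transcripts: Sequence[TranscriptModel],
    variants: Sequence[VariantRecord],
    coverage,
    rates: MutationRateTable,
    methylation=None,
    max_af: float = cm.DEFAULT_MAX_AF,
    alpha: float = cm.DEFAULT_ALPHA,
    c_high: float = 40.0,
    well_powered_threshold: float = 10.0,
    loftee_config: LofteeConfig = DEFAULT_LOFTEE_CONFIG,
) -> ConstraintResult:
    """Compute the per-gene constraint table from in-memory inputs.

    The allele-frequency cutoff ``max_af`` is applied consistently to the
    observed counts of every class *and* to the synonymous calibration,
    so expectation and observation describe the same frequency stratum.
    Pass ``max_af=1.0`` to count all segregating variants.
    """
    canonical = [t for t in transcripts if t.canonical]
    possible = enumerate_possible_all(
        canonical,
        reference,
        coverage=coverage,
        rates=rates,
        methylation=methylation,
        config=loftee_config,
    )
    obs_df = variants_to_frame(variants)
    po = mark_observed(possible, obs_df)
    if max_af < 1.0:
        af = po["AC"].to_numpy() / po["AN"].to_numpy()
        po["observed"] &= np.nan_to_num(af, nan=1.0) < max_af

    calibration = fit_calibration(po, coverage_threshold=c_high)
    coverage_model = fit_coverage_model(po, calibration, c_high=c_high)
    po["exp_p"] = per_site_expectation(po, calibration, coverage_model)

    indel_lof = _annotate_indel_lof(reference, canonical, variants, loftee_config)

    table = _gene_table(
        po, indel_lof, max_af, alpha, well_powered_threshold
    )
    return ConstraintResult(
        table=table,
        calibration=calibration,
        coverage_model=coverage_model,
        possible=po,
        indel_lof=indel_lof,
    )


def _annotate_indel_lof(
    reference,
    transcripts: Sequence[TranscriptModel],
    variants: Sequence[VariantRecord],
    loftee_config: LofteeConfig,
) -> pd.DataFrame:
    """Classify indels (absent from the SNV possible table) for pLoF tallies."""
    by_contig: Dict[str, List[TranscriptModel]] = defaultdict(list)
    for t in transcripts:
        by_contig[t.contig].append(t)
    rows = []
    for v in variants:
        if v.is_snv or not v.passes_filters:
            continue
        for t in by_contig.get(v.contig, []):
            try:
                call = annotate_variant(v, t, reference, config=loftee_config)
            except ValueError as exc:
                logger.warning("skipping structural event: %s", exc)
                continue
            verdict = classify_plof(call, t, reference, config=loftee_config)
            if verdict.verdict in ("HC", "LC"):
                rows.append(
                    {
                        "contig": v.contig,
                        "pos": v.pos,
                        "ref": v.ref,
                        "alt": v.alt,
                        "gene_id": t.gene_id,
                        "transcript_id": t.transcript_id,
                        "consequence": call.consequence,
                        "verdict": verdict.verdict,
                        "AC": v.allele_count,
                        "AN": v.allele_number,
                        "nhomalt": v.n_homalt,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", "ref", "alt", "gene_id", "transcript_id",
            "consequence", "verdict", "AC", "AN", "nhomalt",
        ],
    )


def _gene_table(
    po: pd.DataFrame,
    indel_lof: pd.DataFrame,
    max_af: float,
    alpha: float,
    well_powered_threshold: float,
) -> pd.DataFrame:
    hc_lof = (po["verdict"] == "HC") & po["consequence"].isin(HC_LOF_SNV_CONSEQUENCES)
    classes = {
        "lof": hc_lof,
        "syn": po["consequence"] == "synonymous",
        "mis": po["consequence"] == "missense",
    }
    genes = po[["gene_id", "transcript_id"]].drop_duplicates().set_index("gene_id")
    table = pd.DataFrame(index=genes.index)
    table["transcript_id"] = genes["transcript_id"]
    table["canonical"] = True
    observed = po["observed"].to_numpy()
    for name, mask in classes.items():
        m = mask.to_numpy()
        obs = po.loc[m & observed].groupby("gene_id", observed=True).size()
        exp = po.loc[m].groupby("gene_id", observed=True)["exp_p"].sum(min_count=1)
        table[f"obs_{name}"] = obs.reindex(table.index).fillna(0).astype(int)
        table[f"exp_{name}"] = exp.reindex(table.index).fillna(0.0)

    # HC frameshift indels count as observed pLoF (expectation stays SNV-based)
    if not indel_lof.empty:
        hc_indels = indel_lof[indel_lof["verdict"] == "HC"]
        af_ok = hc_indels["AC"] / hc_indels["AN"] < max_af
        extra = hc_indels[af_ok].groupby("gene_id").size()
        table["obs_lof"] = (
            table["obs_lof"] + extra.reindex(table.index).fillna(0).astype(int)
        )

    for name in classes:
        with np.errstate(divide="ignore", invalid="ignore"):
            table[f"oe_{name}"] = table[f"obs_{name}"] / table[f"exp_{name}"]

    lowers, uppers = [], []
    for obs, exp in zip(table["obs_lof"], table["exp_lof"]):
        if exp > 0:
            lo, hi = cm.oe_confidence_interval(int(obs), float(exp), alpha=alpha)
        else:
            lo, hi = np.nan, np.nan
        lowers.append(lo)
        uppers.append(hi)
    table["oe_lof_lower"] = lowers
    table["oe_lof_upper"] = uppers
    table["well_powered"] = table["exp_lof"] >= well_powered_threshold

    # aggregate pLoF frequency and homozygote tallies over all HC pLoF alleles
    hc_obs = po[(po["verdict"] == "HC")
                & po["consequence"].isin(HC_LOF_SNV_CONSEQUENCES)
                & po["AC"].notna() & po["pass"]]
    frames = [hc_obs[["gene_id", "AC", "AN", "nhomalt"]]]
    if not indel_lof.empty:
        frames.append(
            indel_lof.loc[indel_lof["verdict"] == "HC", ["gene_id", "AC", "AN", "nhomalt"]]
        )
    hc_all = pd.concat(frames, ignore_index=True)
    if not hc_all.empty:
        af = hc_all["AC"] / hc_all["AN"]
        agg = (
            pd.DataFrame({"gene_id": hc_all["gene_id"], "log1m": np.log1p(-af)})
            .groupby("gene_id", observed=True)["log1m"].sum()
        )
        table["agg_plof_freq"] = (
            (1.0 - np.exp(agg)).reindex(table.index).fillna(0.0)
        )
        hom = hc_all.groupby("gene_id", observed=True)["nhomalt"].sum()
        table["n_homalt"] = hom.reindex(table.index).fillna(0).astype(int)
    else:
        table["agg_plof_freq"] = 0.0
        table["n_homalt"] = 0

    table = table.reset_index()
    eligible = table["exp_lof"] > 0
    table["decile"] = pd.NA
    if eligible.sum() >= 10:
        binned = cm.assign_deciles(table[eligible], loeuf_col="oe_lof_upper")
        table.loc[eligible, "decile"] = binned["decile"]
    return table


def run_constraint_files(
    fasta,
    gtf,
    vcf,
    coverage_tsv,
    rates_tsv,
    methylation_tsv=None,
    **kwargs,
) -> ConstraintResult:
    """File-based wrapper around :func:`run_constraint`."""
    reference = ReferenceSequence(fasta)
    transcripts = read_transcripts(gtf)
    variants = read_variants(vcf)
    coverage = read_coverage(coverage_tsv)
    rates = MutationRateTable.from_tsv(rates_tsv)
    methylation = read_methylation(methylation_tsv) if methylation_tsv else None
    return run_constraint(
        reference, transcripts, variants, coverage, rates, methylation=methylation, **kwargs
    )
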