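"""Trinucleotide mutational model and coverage-corrected expected counts.

Every possible SNV in a transcript's coding and splice space is
enumerated with its strand-collapsed trinucleotide context, CpG
methylation stratum and relative mutation rate mu.  A calibration fitted
on synonymous sites maps mu to the proportion of possible sites expected
to be observed at the cohort's size; a base-level coverage model scales
that expectation down where sequencing depth is limiting.  Expected
variant counts per gene/class are sums of per-site predictions.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .consequence import (
    DEFAULT_LOFTEE_CONFIG,
    LofteeConfig,
    codon_change_consequence,
    get_frame,
)
from .models import PositionTrack, CoverageTrack, TranscriptModel, revcomp
from .reference_io import ReferenceSequence

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_ALTS = {b: tuple(a for a in "ACGT" if a != b) for b in "ACGT"}

#: methylation discretization cut points: < cuts[0] -> 0, < cuts[1] -> 1, else 2
DEFAULT_METHYLATION_CUTS: Tuple[float, float] = (0.2, 0.6)


@dataclass(frozen=True)
class MutationContext:
    """Strand-collapsed mutational context of one possible SNV.

    ``context`` is the 3-mer reference window centred on the site with the
    central base collapsed into {A, C}; ``alt`` is the alternate central
    base after the same collapse.  ``methylation_level`` is non-zero only
    at CpG dinucleotides (2 = highly methylated).
    """

    context: str
    alt: str
    methylation_level: int = 0

    def __post_init__(self) -> None:
        if len(self.context) != 3 or self.context[1] not in "AC":
            raise ValueError(f"invalid collapsed context {self.context!r}")
        if self.methylation_level and not self.is_cpg:
            raise ValueError("methylation level > 0 at a non-CpG site")

    @property
    def is_cpg(self) -> bool:
        return self.context[1] == "C" and self.context[2] == "G"


def collapse_context(context: str, alt: str) -> Tuple[str, str]:
    """Collapse a plus-strand (3-mer, alt) pair so the central base is A or C."""
    if context[1] in "GT":
        return revcomp(context), _COMP[alt]
    return context, alt


def discretize_methylation(
    value: float, cuts: Tuple[float, float] = DEFAULT_METHYLATION_CUTS
) -> int:
    if value < cuts[0]:
        return 0
    if value < cuts[1]:
        return 1
    return 2


def attach_context(
    contig: str,
    pos0: int,
    alt: str,
    reference: ReferenceSequence,
    methylation: Optional[PositionTrack] = None,
    cuts: Tuple[float, float] = DEFAULT_METHYLATION_CUTS,
) -> MutationContext:
    """Mutational context of the site at 0-based ``pos0`` with alternate ``alt``.

    The 3-mer window must lie inside the contig; N-containing windows are
    unscorable and raise ValueError.  Methylation is read from the track
    at CpG sites and forced to zero elsewhere.
    """
    if pos0 - 1 < 0 or pos0 + 2 > reference.contig_length(contig):
        raise ValueError(f"context window out of bounds at {contig}:{pos0}")
    window = reference.fetch(contig, pos0 - 1, pos0 + 2)
    if "N" in window or alt == "N":
        raise ValueError(f"unscorable context {window!r} at {contig}:{pos0}")
    ctx, alt_c = collapse_context(window, alt)
    level = 0
    if ctx[1] == "C" and ctx[2] == "G" and methylation is not None:
        level = discretize_methylation(methylation.get(contig, pos0), cuts)
    return MutationContext(ctx, alt_c, level)


class MutationRateTable:
    """mu per (collapsed context, alt, methylation level)."""

    def __init__(self, rates: Dict[Tuple[str, str, int], float]):
        for key, mu in rates.items():
            if mu <= 0:
                raise ValueError(f"non-positive mu for {key}")
        self._rates = dict(rates)

    def mu(self, context: str, alt: str, methylation_level: int = 0) -> float:
        try:
            return self._rates[(context, alt, methylation_level)]
        except KeyError:
            raise KeyError(
                f"no mutation rate for context={context} alt={alt} "
                f"methylation={methylation_level}"
            ) from None

    def mu_of(self, ctx: MutationContext) -> float:
        return self.mu(ctx.context, ctx.alt, ctx.methylation_level)

    def items(self):
        return self._rates.items()

    def __len__(self) -> int:
        return len(self._rates)

    def map_arrays(
        self, contexts: Sequence[str], alts: Sequence[str], levels: Sequence[int]
    ) -> np.ndarray:
        r = self._rates
        return np.array(
            [r[(c, a, m)] for c, a, m in zip(contexts, alts, levels)], dtype=float
        )

    @classmethod
    def from_tsv(cls, path) -> "MutationRateTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            {
                (row.context, row.alt, int(row.methylation_level)): float(row.mu)
                for row in df.itertuples(index=False)
            }
        )

    def to_tsv(self, path) -> None:
        rows = [
            {"context": c, "alt": a, "methylation_level": m, "mu": mu}
            for (c, a, m), mu in sorted(self._rates.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Possible-variant enumeration
# ---------------------------------------------------------------------------

POSSIBLE_COLUMNS = [
    "contig", "pos", "ref", "alt", "gene_id", "transcript_id", "canonical",
    "consequence", "verdict", "lof_filters", "cds_position",
    "context", "alt_collapsed", "methylation", "mu", "coverage",
]


def enumerate_possible(
    transcript: TranscriptModel,
    reference: ReferenceSequence,
    coverage: Optional[CoverageTrack] = None,
    rates: Optional[MutationRateTable] = None,
    methylation: Optional[PositionTrack] = None,
    include_splice_region: bool = True,
    config: LofteeConfig = DEFAULT_LOFTEE_CONFIG,
    methylation_cuts: Tuple[float, float] = DEFAULT_METHYLATION_CUTS,
) -> pd.DataFrame:
    """Enumerate all possible SNVs of a transcript as a DataFrame.

    Three alternate alleles are emitted for every scorable CDS base and
    every essential splice base (and, by default, splice-region bases at
    intronic positions 3-8).  Consequences and LOFTEE verdicts are
    computed identically to observed-variant annotation.  Sites whose
    3-mer context contains N are skipped; the skip count is stored in
    ``df.attrs["n_unscorable"]``.
    """
    if transcript.cds_length == 0:
        raise ValueError(f"{transcript.transcript_id}: empty CDS")
    frame = get_frame(transcript, reference, config)
    t = transcript
    contig = t.contig
    seq = reference.contig_sequence(contig)
    rev = t.strand == "-"
    nmd_cut = t.last_junction_cds_offset - config.nmd_escape_window
    incomplete = t.cds_incomplete

    pos_l: List[int] = []
    ref_l: List[str] = []
    alt_l: List[str] = []
    cons_l: List[str] = []
    verdict_l: List[str] = []
    filt_l: List[str] = []
    cdsp_l: List[int] = []
    ctx_l: List[str] = []
    altc_l: List[str] = []
    meth_l: List[int] = []
    skipped = 0

    def emit(g: int, alt: str, cons: str, verdict: str, filters: str, cds_off: int) -> bool:
        ctx = seq[g - 1 : g + 2] if g >= 1 else ""
        if len(ctx) != 3 or "N" in ctx:
            return False
        ctx_c, alt_c = collapse_context(ctx, alt)
        level = 0
        if ctx_c[1] == "C" and ctx_c[2] == "G" and methylation is not None:
            level = discretize_methylation(methylation.get(contig, g), methylation_cuts)
        pos_l.append(g + 1)
        ref_l.append(ctx[1])
        alt_l.append(alt)
        cons_l.append(cons)
        verdict_l.append(verdict)
        filt_l.append(filters)
        cdsp_l.append(cds_off)
        ctx_l.append(ctx_c)
        altc_l.append(alt_c)
        meth_l.append(level)
        return True

    base_filter = "INCOMPLETE_CDS" if incomplete else ""

    # --- CDS bases ---------------------------------------------------------
    cds_positions = frame.cds_positions
    cds_seq = frame.cds_seq
    for t_off in range(len(cds_positions)):
        g = int(cds_positions[t_off])
        ref_base = seq[g]
        if ref_base == "N" or g < 1 or g + 2 > len(seq) or "N" in seq[g - 1 : g + 2]:
            skipped += 3
            continue
        codon_i = t_off // 3
        within = t_off % 3
        ref_codon = cds_seq[3 * codon_i : 3 * codon_i + 3]
        is_last_exonic = g in frame.exonic_last_bases
        for alt in _ALTS[ref_base]:
            alt_t = alt if not rev else _COMP[alt]
            if len(ref_codon) == 3:
                cons = codon_change_consequence(ref_codon, within, alt_t, codon_i == 0)
            else:  # trailing partial codon of an incomplete CDS
                cons = "other"
            if is_last_exonic and cons in ("synonymous", "missense", "other"):
                if cons != "missense":
                    cons = "splice_region"
            if cons == "stop_gained":
                filters = base_filter
                if t_off >= nmd_cut:
                    filters = (filters + ";END_TRUNC").lstrip(";")
                verdict = "LC" if filters else "HC"
            elif cons == "splice_region":
                verdict, filters = "OS", ""
            else:
                verdict, filters = "not_pLoF", ""
            emit(g, alt, cons, verdict, filters, t_off)

    # --- essential splice bases -------------------------------------------
    for g, (kind, idx) in frame.essential.items():
        ref_base = seq[g]
        if ref_base == "N":
            skipped += 3
            continue
        intron = frame.introns[idx]
        filters = set()
        if incomplete:
            filters.add("INCOMPLETE_CDS")
        if intron.length < config.min_intron_length:
            filters.add("SMALL_INTRON")
        if not intron.canonical:
            filters.add("NON_CANONICAL_INTRON")
        if intron.donor_rescue if kind == "splice_donor" else intron.acceptor_rescue:
            filters.add("SPLICE_RESCUE")
        verdict = "LC" if filters else "HC"
        filt = ";".join(sorted(filters))
        for alt in _ALTS[ref_base]:
            if not emit(g, alt, kind, verdict, filt, -1):
                skipped += 1

    # --- splice-region bases (intronic 3..8) -------------------------------
    if include_splice_region:
        for g in frame.region:
            ref_base = seq[g]
            if ref_base == "N":
                skipped += 3
                continue
            for alt in _ALTS[ref_base]:
                if not emit(g, alt, "splice_region", "OS", "", -1):
                    skipped += 1

    df = pd.DataFrame(
        {
            "contig": contig,
            "pos": np.asarray(pos_l, dtype=np.int64),
            "ref": pd.Categorical(ref_l, categories=list("ACGT")),
            "alt": pd.Categorical(alt_l, categories=list("ACGT")),
            "gene_id": t.gene_id,
            "transcript_id": t.transcript_id,
            "canonical": t.canonical,
            "consequence": pd.Categorical(cons_l),
            "verdict": pd.Categorical(verdict_l, categories=["HC", "LC", "OS", "not_pLoF"]),
            "lof_filters": pd.Categorical(filt_l),
            "cds_position": np.asarray(cdsp_l, dtype=np.int64),
            "context": pd.Categorical(ctx_l),
            "alt_collapsed": pd.Categorical(altc_l, categories=list("ACGT")),
            "methylation": np.asarray(meth_l, dtype=np.int8),
        }
    )
    if rates is not None:
        df["mu"] = rates.map_arrays(ctx_l, altc_l, meth_l)
    else:
        df["mu"] = np.nan
    if coverage is not None:
        df["coverage"] = coverage.get_array(contig, df["pos"].to_numpy() - 1)
    else:
        df["coverage"] = np.nan
    df.attrs["n_unscorable"] = skipped
    return df


def enumerate_possible_all(
    transcripts: Iterable[TranscriptModel],
    reference: ReferenceSequence,
    **kwargs,
) -> pd.DataFrame:
    """Concatenate :func:`enumerate_possible` over many transcripts."""
    frames = [enumerate_possible(t, reference, **kwargs) for t in transcripts]
    skipped = sum(f.attrs.get("n_unscorable", 0) for f in frames)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["n_unscorable"] = skipped
    return out


def mark_observed(possible: pd.DataFrame, observed: pd.DataFrame) -> pd.DataFrame:
    """Left-join observed cohort alleles onto the possible-variant table.

    Adds columns AC/AN/nhomalt/pass and a boolean ``observed``.  Observed
    variants absent from the possible table (e.g. indels) are ignored
    here; they are handled by direct annotation elsewhere.
    """
    obs = observed[["contig", "pos", "ref", "alt", "AC", "AN", "nhomalt", "pass"]]
    merged = possible.merge(
        obs,
        on=["contig", "pos", "ref", "alt"],
        how="left",
        validate="many_to_one",
    )
    merged["pass"] = merged["pass"].astype("boolean").fillna(False).astype(bool)
    merged["observed"] = merged["AC"].notna() & merged["pass"]
    return merged


def proportion_observed(
    possible_observed: pd.DataFrame,
    consequences: Optional[Sequence[str]] = None,
    verdicts: Optional[Sequence[str]] = None,
) -> Tuple[int, int, float]:
    """(n_observed, n_possible, fraction observed) for a variant class."""
    df = possible_observed
    mask = np.ones(len(df), dtype=bool)
    if consequences is not None:
        mask &= df["consequence"].isin(consequences).to_numpy()
    if verdicts is not None:
        mask &= df["verdict"].isin(verdicts).to_numpy()
    n_possible = int(mask.sum())
    n_observed = int((mask & df["observed"].to_numpy()).sum())
    frac = n_observed / n_possible if n_possible else 0.0
    return n_observed, n_possible, frac


# ---------------------------------------------------------------------------
# Calibration: mu -> proportion of possible sites observed
# ---------------------------------------------------------------------------

def _weighted_linfit(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> Tuple[float, float]:
    """Weighted least squares y ~ a + b*x; intercept-only on degenerate input."""
    if len(np.unique(x)) < 2:
        warnings.warn("degenerate design: falling back to intercept-only fit")
        return float(np.average(y, weights=w)), 0.0
    W = np.sqrt(w)
    A = np.column_stack([np.ones_like(x), x]) * W[:, None]
    try:
        coef, *_ = np.linalg.lstsq(A, y * W, rcond=None)
    except np.linalg.LinAlgError:  # pragma: no cover
        warnings.warn("singular fit: falling back to intercept-only")
        return float(np.average(y, weights=w)), 0.0
    return float(coef[0]), float(coef[1])


@dataclass
class CalibrationModel:
    """Linear map mu -> expected proportion of possible sites observed.

    One (intercept, slope) pair per methylation stratum, fitted by
    weighted least squares on synonymous high-coverage sites; predictions
    are clamped to [0, 1].
    """

    params: Dict[int, Tuple[float, float]]
    fallback: Tuple[float, float]
    n_training_contexts: int = 0

    def predict(self, mu: np.ndarray, methylation: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        methylation = np.asarray(methylation)
        out = np.empty_like(mu)
        for level in np.unique(methylation):
            a, b = self.params.get(int(level), self.fallback)
            m = methylation == level
            out[m] = a + b * mu[m]
        return np.clip(out, 0.0, 1.0)

    def predict_one(self, mu: float, methylation_level: int = 0) -> float:
        return float(self.predict(np.array([mu]), np.array([methylation_level]))[0])

    def to_json(self, path) -> None:
        payload = {
            "params": {str(k): list(v) for k, v in self.params.items()},
            "fallback": list(self.fallback),
            "n_training_contexts": self.n_training_contexts,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            params={int(k): tuple(v) for k, v in payload["params"].items()},
            fallback=tuple(payload["fallback"]),
            n_training_contexts=payload.get("n_training_contexts", 0),
        )


def fit_calibration(
    possible_observed: pd.DataFrame,
    coverage_threshold: float = 40.0,
) -> CalibrationModel:
    """Fit the mu -> proportion-observed calibration on synonymous sites.

    Only synonymous sites at coverage >= ``coverage_threshold`` are used.
    Per (context, alt, methylation) cell the proportion of possible sites
    observed is regressed on mu, weighted by the number of possible
    sites, separately per methylation stratum.
    """
    df = possible_observed
    train = df[
        (df["consequence"] == "synonymous")
        & (df["coverage"] >= coverage_threshold)
    ]
    if train.empty:
        raise ValueError("empty calibration training set")
    cells = (
        train.groupby(["context", "alt_collapsed", "methylation"], observed=True)
        .agg(n=("observed", "size"), k=("observed", "sum"), mu=("mu", "first"))
        .reset_index()
    )
    cells["prop"] = cells["k"] / cells["n"]
    params: Dict[int, Tuple[float, float]] = {}
    for level, grp in cells.groupby("methylation"):
        params[int(level)] = _weighted_linfit(
            grp["mu"].to_numpy(), grp["prop"].to_numpy(), grp["n"].to_numpy()
        )
    fallback = _weighted_linfit(
        cells["mu"].to_numpy(), cells["prop"].to_numpy(), cells["n"].to_numpy()
    )
    return CalibrationModel(
        params=params, fallback=fallback, n_training_contexts=len(cells)
    )


# ---------------------------------------------------------------------------
# Coverage correction
# ---------------------------------------------------------------------------

@dataclass
class CoverageModel:
    """Observation-probability correction for low-coverage sites.

    factor = 1 for coverage >= ``c_high``; clamp(a + b*log10(cov), 0, 1)
    for 1 <= cov < c_high; NaN (excluded-site sentinel) below 1.
    """

    c_high: float = 40.0
    intercept: float = 0.0
    slope: float = 0.625  # 1/log10(40): factor reaching 1 at c_high

    def factor(self, coverage: np.ndarray) -> np.ndarray:
        cov = np.asarray(coverage, dtype=float)
        if np.any(cov < 0):
            raise ValueError("negative coverage")
        out = np.full(cov.shape, np.nan)
        high = cov >= self.c_high
        out[high] = 1.0
        low = (cov >= 1.0) & ~high
        out[low] = np.clip(self.intercept + self.slope * np.log10(cov[low]), 0.0, 1.0)
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"c_high": self.c_high, "intercept": self.intercept, "slope": self.slope},
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "CoverageModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


def coverage_correction_factor(median_coverage: float, model: CoverageModel) -> float:
    """Scalar correction factor; NaN marks an excluded (coverage < 1) site."""
    return float(model.factor(np.array([median_coverage]))[0])


def fit_coverage_model(
    possible_observed: pd.DataFrame,
    calibration: CalibrationModel,
    c_high: float = 40.0,
) -> CoverageModel:
    """Fit the low-coverage correction on synonymous sites below ``c_high``.

    Sites are binned by integer coverage; each bin's ratio of observed to
    calibration-predicted counts is regressed on log10(coverage), weighted
    by the predicted count.
    """
    df = possible_observed
    low = df[
        (df["consequence"] == "synonymous")
        & (df["coverage"] >= 1.0)
        & (df["coverage"] < c_high)
    ]
    if low.empty:
        warnings.warn("no low-coverage synonymous sites; coverage correction disabled")
        return CoverageModel(c_high=c_high, intercept=1.0, slope=0.0)
    pred = calibration.predict(low["mu"].to_numpy(), low["methylation"].to_numpy())
    tmp = pd.DataFrame(
        {
            "bin": np.floor(low["coverage"].to_numpy()).astype(int),
            "obs": low["observed"].to_numpy().astype(float),
            "pred": pred,
            "cov": low["coverage"].to_numpy(),
        }
    )
    grp = tmp.groupby("bin").agg(
        obs=("obs", "sum"), pred=("pred", "sum"), cov=("cov", "mean")
    )
    grp = grp[grp["pred"] > 0]
    a, b = _weighted_linfit(
        np.log10(grp["cov"].to_numpy()),
        (grp["obs"] / grp["pred"]).to_numpy(),
        grp["pred"].to_numpy(),
    )
    return CoverageModel(c_high=c_high, intercept=a, slope=b)


# ---------------------------------------------------------------------------
# Expected counts
# ---------------------------------------------------------------------------

def expected_counts(
    possible: pd.DataFrame,
    calibration: CalibrationModel,
    coverage_model: CoverageModel,
    consequences: Optional[Sequence[str]] = None,
    verdicts: Optional[Sequence[str]] = None,
) -> float:
    """Expected number of observed variants for a class of possible sites.

    Sum over sites of predicted proportion observed times the coverage
    factor; coverage < 1 sites are excluded.  An empty class returns 0
    with a warning.
    """
    df = possible
    mask = np.ones(len(df), dtype=bool)
    if consequences is not None:
        mask &= df["consequence"].isin(consequences).to_numpy()
    if verdicts is not None:
        mask &= df["verdict"].isin(verdicts).to_numpy()
    sub = df[mask]
    if sub.empty:
        warnings.warn("no possible sites in class; expected = 0")
        return 0.0
    pred = calibration.predict(sub["mu"].to_numpy(), sub["methylation"].to_numpy())
    factor = coverage_model.factor(sub["coverage"].to_numpy())
    return float(np.nansum(pred * factor))


def per_site_expectation(
    possible: pd.DataFrame,
    calibration: CalibrationModel,
    coverage_model: CoverageModel,
) -> np.ndarray:
    """Per-site expected observation probability (NaN at excluded sites)."""
    pred = calibration.predict(
        possible["mu"].to_numpy(), possible["methylation"].to_numpy()
    )
    return pred * coverage_model.factor(possible["coverage"].to_numpy())
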