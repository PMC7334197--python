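"""Observed/expected constraint metrics.

The central statistic is the observed/expected (o/e) ratio of rare
high-confidence pLoF variants to the mutational-model expectation, with a
Poisson-likelihood confidence interval computed on a ratio grid.  The 90%
upper bound of that interval (alpha = 0.05) is the LOEUF score: low
values flag genes confidently depleted of loss-of-function variation,
while keeping small genes (little expectation, wide interval) honestly
uncertain instead of spuriously constrained.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import poisson

from .consequence import LofteeVerdict
from .models import VariantRecord

DEFAULT_MAX_AF = 1e-3
DEFAULT_ALPHA = 0.05
DEFAULT_GRID_MAX = 2.0
DEFAULT_GRID_STEP = 1e-3


def oe_confidence_interval(
    n_observed: int,
    n_expected: float,
    alpha: float = DEFAULT_ALPHA,
    grid_max: float = DEFAULT_GRID_MAX,
    grid_step: float = DEFAULT_GRID_STEP,
) -> Tuple[float, float]:
    """Poisson-likelihood confidence interval for the o/e ratio.

    The Poisson probability of ``n_observed`` is evaluated at mean
    ``r * n_expected`` over the ratio grid r in {step, 2*step, ..., grid_max};
    the cumulative sum normalised by its total defines the interval:
    ci_upper is the smallest grid ratio whose normalised cumulative
    reaches 1 - alpha, ci_lower the largest one still below alpha (zero
    when n_observed is zero, where the likelihood peaks at r = 0).

    The grid includes ``grid_max`` itself; together with two-decimal
    truncation for display this reproduces the reference worked examples
    (0 observed, 2 expected -> 1.34; 0 observed, 100 expected -> 0.03).
    """
    if n_expected <= 0:
        raise ValueError("n_expected must be positive")
    if n_observed < 0:
        raise ValueError("n_observed must be non-negative")
    n_points = int(round(grid_max / grid_step))
    grid = np.arange(1, n_points + 1) * grid_step
    pmf = poisson.pmf(n_observed, grid * n_expected)
    cum = np.cumsum(pmf)
    cum /= cum[-1]

    if n_observed / n_expected > grid_max:
        warnings.warn(
            f"o/e ratio {n_observed / n_expected:.3f} exceeds grid maximum "
            f"{grid_max}; upper bound clamped"
        )
        ci_upper = float(grid_max)
    else:
        upper_idx = int(np.searchsorted(cum, 1.0 - alpha, side="left"))
        ci_upper = float(grid[min(upper_idx, n_points - 1)])

    if n_observed == 0:
        ci_lower = 0.0
    else:
        below = np.nonzero(cum < alpha)[0]
        ci_lower = float(grid[below[-1]]) if len(below) else 0.0
    return ci_lower, ci_upper


def loeuf(n_observed: int, n_expected: float, alpha: float = DEFAULT_ALPHA) -> float:
    """LoF observed/expected upper bound fraction (the 90% CI upper bound)."""
    return oe_confidence_interval(n_observed, n_expected, alpha=alpha)[1]


def format_oe(value: float, decimals: int = 2) -> str:
    """Display formatting: truncation toward zero (full precision elsewhere)."""
    scale = 10 ** decimals
    return f"{math.trunc(value * scale) / scale:.{decimals}f}"


@dataclass
class GeneConstraintRecord:
    gene_id: str
    transcript_id: str
    n_observed: int
    n_expected: float
    oe: float
    ci_lower: float
    ci_upper: float
    decile: Optional[int] = None
    well_powered: bool = False
    agg_plof_frequency: float = 0.0
    n_homozygous_individuals: int = 0

    @classmethod
    def from_counts(
        cls,
        gene_id: str,
        transcript_id: str,
        n_observed: int,
        n_expected: float,
        alpha: float = DEFAULT_ALPHA,
        well_powered_threshold: float = 10.0,
        **kwargs,
    ) -> "GeneConstraintRecord":
        lo, hi = oe_confidence_interval(n_observed, n_expected, alpha=alpha)
        return cls(
            gene_id=gene_id,
            transcript_id=transcript_id,
            n_observed=n_observed,
            n_expected=n_expected,
            oe=n_observed / n_expected,
            ci_lower=lo,
            ci_upper=hi,
            well_powered=n_expected >= well_powered_threshold,
            **kwargs,
        )


def observed_counts(
    verdicts: Iterable[LofteeVerdict],
    consequences: Optional[Sequence[str]] = None,
    max_af: float = DEFAULT_MAX_AF,
) -> int:
    """Count distinct high-confidence variants of a class below ``max_af``.

    Only HC verdicts on variants passing site filters contribute; the
    allele-frequency cutoff keeps constraint focused on rare, plausibly
    deleterious variation.
    """
    seen = set()
    for v in verdicts:
        if v.verdict != "HC":
            continue
        if consequences is not None and v.call.consequence not in consequences:
            continue
        var = v.call.variant
        if not var.passes_filters or var.allele_frequency >= max_af:
            continue
        seen.add(var.key)
    return len(seen)


def assign_deciles(table: pd.DataFrame, loeuf_col: str = "oe_lof_upper") -> pd.DataFrame:
    """Bin genes into LOEUF deciles (1 = most constrained).

    Rows are ranked by LOEUF ascending with ties broken by expected count
    descending then gene_id; the ranking is split into 10 near-equal bins
    whose sizes differ by at most one, larger bins first.
    """
    if len(table) < 10:
        raise ValueError(f"need at least 10 genes to assign deciles, got {len(table)}")
    order = table.sort_values(
        by=[loeuf_col, "exp_lof", "gene_id"], ascending=[True, False, True]
    ).index
    n = len(order)
    base, rem = divmod(n, 10)
    sizes = [base + 1] * rem + [base] * (10 - rem)
    deciles = np.empty(n, dtype=int)
    start = 0
    for d, size in enumerate(sizes, start=1):
        deciles[start : start + size] = d
        start += size
    out = table.copy()
    out.loc[order, "decile"] = deciles
    out["decile"] = out["decile"].astype(int)
    return out


def aggregate_plof_frequency(allele_frequencies: Iterable[float]) -> float:
    """Estimated fraction of haplotypes carrying >= 1 pLoF allele of a gene.

    Assumes independent sites: p = 1 - prod(1 - AF).
    """
    p_none = 1.0
    for af in allele_frequencies:
        p_none *= 1.0 - af
    return 1.0 - p_none


def homozygote_tally(variants: Iterable[VariantRecord]) -> Tuple[int, int]:
    """(number of variants homozygous in >= 1 individual, total homozygotes)."""
    n_variants = 0
    total = 0
    for v in variants:
        if v.n_homalt > 0:
            n_variants += 1
            total += v.n_homalt
    return n_variants, total


# ---------------------------------------------------------------------------
# Downsampling discovery curves
# ---------------------------------------------------------------------------

@dataclass
class DiscoveryCurve:
    """Expected distinct variants discovered at each subsample size."""

    sizes: np.ndarray
    expected: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_haplotypes": self.sizes, "expected_variants": self.expected})


def _prob_sampled(ac: np.ndarray, an: int, n: int) -> np.ndarray:
    """P(>= 1 alternate allele in a subsample of n haplotypes), hypergeometric.

    1 - C(AN - AC, n) / C(AN, n), computed with log-factorials for
    numerical stability.
    """
    ac = np.asarray(ac, dtype=np.int64)

    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    miss = np.full(ac.shape, -np.inf)
    ok = an - ac >= n
    miss[ok] = logc(an - ac[ok], n) - logc(an, n)
    return 1.0 - np.exp(miss)


def discovery_curve(
    allele_counts: Sequence[int],
    allele_number: int,
    sizes: Sequence[int],
) -> DiscoveryCurve:
    """Expected distinct-variant discovery as a function of sample size.

    For each subsample of n haplotypes (without replacement from the
    cohort of AN), each variant contributes its hypergeometric probability
    of being sampled at least once.  Growth is monotone and concave,
    approximately square-root in n for a neutral frequency spectrum.
    """
    ac = np.asarray(allele_counts, dtype=np.int64)
    sizes_arr = np.asarray(sizes, dtype=np.int64)
    if np.any(sizes_arr > allele_number):
        raise ValueError("subsample size exceeds cohort allele number")
    if np.any(sizes_arr < 0):
        raise ValueError("negative subsample size")
    expected = np.array(
        [float(_prob_sampled(ac, allele_number, int(n)).sum()) for n in sizes_arr]
    )
    return DiscoveryCurve(sizes=sizes_arr, expected=expected)
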