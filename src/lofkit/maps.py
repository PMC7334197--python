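"""Mutability-adjusted proportion of singletons (MAPS).

The raw singleton proportion of a variant class confounds selection with
mutability: highly mutable sites (e.g. methylated CpG transitions) recur
and are less often singletons regardless of selection.  MAPS removes the
mutability component by calibrating the expected singleton proportion
against mu on synonymous variants and reporting the excess:

    MAPS = ps_observed - ps_predicted

Positive values indicate a rarer-than-neutral frequency spectrum, i.e. a
more deleterious variant class.  By construction MAPS of the synonymous
training set is zero (weighted-regression residual identity).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import VariantRecord
from .mutation_model import _weighted_linfit


def singleton_proportion(variants: Sequence[VariantRecord]) -> float:
    """Fraction of variants with allele count 1; empty input is an error."""
    if len(variants) == 0:
        raise ValueError("singleton proportion of an empty variant list")
    return sum(1 for v in variants if v.allele_count == 1) / len(variants)


@dataclass
class MapsCalibration:
    """Fitted mu -> expected singleton proportion, per methylation stratum."""

    params: Dict[int, Tuple[float, float]]
    fallback: Tuple[float, float]
    n_training_variants: int = 0
    mu_range: Tuple[float, float] = (0.0, 0.0)

    def predict(self, mu: np.ndarray, methylation: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        methylation = np.asarray(methylation)
        out = np.empty_like(mu)
        for level in np.unique(methylation):
            a, b = self.params.get(int(level), self.fallback)
            m = methylation == level
            out[m] = a + b * mu[m]
        return np.clip(out, 0.0, 1.0)


@dataclass
class MapsResult:
    label: str
    n_variants: int
    ps_observed: float
    ps_predicted: float
    maps: float
    se: float


def fit_maps_calibration(variants: pd.DataFrame) -> MapsCalibration:
    """Calibrate expected singleton proportion on synonymous variants.

    ``variants`` carries one row per observed synonymous variant with
    columns AC, mu, context, alt_collapsed and methylation.  Per
    (context, alt, methylation) cell, the singleton proportion is
    regressed on mu by weighted least squares (weights = variant counts),
    one stratum per methylation level; a degenerate design falls back to
    an intercept-only fit with a warning.
    """
    if variants.empty:
        raise ValueError("empty MAPS training set")
    df = variants.copy()
    df["singleton"] = (df["AC"] == 1).astype(float)
    cells = (
        df.groupby(["context", "alt_collapsed", "methylation"], observed=True)
        .agg(n=("singleton", "size"), ps=("singleton", "mean"), mu=("mu", "first"))
        .reset_index()
    )
    params: Dict[int, Tuple[float, float]] = {}
    for level, grp in cells.groupby("methylation"):
        params[int(level)] = _weighted_linfit(
            grp["mu"].to_numpy(), grp["ps"].to_numpy(), grp["n"].to_numpy()
        )
    fallback = _weighted_linfit(
        cells["mu"].to_numpy(), cells["ps"].to_numpy(), cells["n"].to_numpy()
    )
    return MapsCalibration(
        params=params,
        fallback=fallback,
        n_training_variants=int(len(df)),
        mu_range=(float(df["mu"].min()), float(df["mu"].max())),
    )


def compute_maps(
    variants: pd.DataFrame,
    calibration: MapsCalibration,
    label: str = "",
) -> MapsResult:
    """MAPS for one variant class.

    ``variants`` has one row per observed variant with AC, mu and
    methylation columns.  The binomial standard error on the observed
    singleton proportion is reported; calibration uncertainty is ignored.
    """
    if variants.empty:
        raise ValueError(f"empty variant class {label!r}")
    n = len(variants)
    ps_obs = float((variants["AC"] == 1).mean())
    ps_pred = float(
        calibration.predict(
            variants["mu"].to_numpy(), variants["methylation"].to_numpy()
        ).mean()
    )
    se = float(np.sqrt(ps_obs * (1.0 - ps_obs) / n))
    return MapsResult(
        label=label,
        n_variants=n,
        ps_observed=ps_obs,
        ps_predicted=ps_pred,
        maps=ps_obs - ps_pred,
        se=se,
    )


def maps_by_class(
    observed: pd.DataFrame,
    calibration: Optional[MapsCalibration] = None,
    classes: Optional[Dict[str, pd.Series]] = None,
) -> pd.DataFrame:
    """MAPS across standard variant classes of an annotated cohort table.

    ``observed`` is the possible-variant table restricted to observed
    variants (it must carry consequence, verdict, AC, mu, methylation).
    Default classes: synonymous, missense, pLoF HC / LC, other-splice.
    The calibration is fitted on the synonymous class when not supplied.
    """
    df = observed
    if classes is None:
        classes = {
            "synonymous": df["consequence"] == "synonymous",
            "missense": df["consequence"] == "missense",
            "splice_region_OS": df["verdict"] == "OS",
            "pLoF_LC": df["verdict"] == "LC",
            "pLoF_HC": df["verdict"] == "HC",
        }
    if calibration is None:
        calibration = fit_maps_calibration(df[classes["synonymous"]])
    rows = []
    for label, mask in classes.items():
        sub = df[mask]
        if sub.empty:
            warnings.warn(f"no variants in class {label}; skipped")
            continue
        r = compute_maps(sub, calibration, label=label)
        rows.append(
            {
                "class": r.label,
                "n": r.n_variants,
                "ps_observed": r.ps_observed,
                "ps_predicted": r.ps_predicted,
                "maps": r.maps,
                "se": r.se,
            }
        )
    return pd.DataFrame(rows)
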