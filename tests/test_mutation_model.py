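"""Context handling, possible-variant enumeration, calibration, coverage."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from genebuild import build_gene
from loftee_cases import EXON1, EXON2, plain_intron
from lofkit.models import CoverageTrack, PositionTrack, revcomp
from lofkit.mutation_model import (
    CalibrationModel,
    CoverageModel,
    MutationContext,
    attach_context,
    collapse_context,
    coverage_correction_factor,
    enumerate_possible,
    expected_counts,
    fit_calibration,
    fit_coverage_model,
    proportion_observed,
)
from lofkit.simulate import InMemoryReference


class TestContextCollapse:
    def test_central_g_collapses_to_c(self):
        assert collapse_context("CGT", "A") == ("ACG", "T")

    def test_central_c_unchanged(self):
        assert collapse_context("ACG", "T") == ("ACG", "T")

    @given(
        ctx=st.text(alphabet="ACGT", min_size=3, max_size=3),
        alt=st.sampled_from("ACGT"),
    )
    @settings(max_examples=200, derandomize=True)
    def test_collapse_is_strand_invariant(self, ctx, alt):
        """Collapsing a context and its reverse complement agree."""
        from lofkit.models import complement

        if alt == ctx[1]:
            return
        a = collapse_context(ctx, alt)
        b = collapse_context(revcomp(ctx), complement(alt))
        assert a == b
        assert a[0][1] in "AC"

    def test_methylation_forbidden_outside_cpg(self):
        with pytest.raises(ValueError):
            MutationContext("ACA", "T", methylation_level=2)


class TestAttachContext:
    def test_cpg_reads_methylation_track(self):
        ref = InMemoryReference({"c": "AACGT"})
        meth = PositionTrack()
        meth.set("c", 2, 0.9)
        ctx = attach_context("c", 2, "T", ref, methylation=meth)
        assert ctx == MutationContext("ACG", "T", 2)

    def test_central_g_site_is_mirrored_cpg(self):
        # CGT centred on G: reverse complement of the ACG context
        ref = InMemoryReference({"c": "ACGTA"})
        meth = PositionTrack()
        meth.set("c", 2, 0.9)
        ctx = attach_context("c", 2, "A", ref, methylation=meth)
        assert ctx == MutationContext("ACG", "T", 2)

    def test_non_cpg_methylation_forced_to_zero(self):
        ref = InMemoryReference({"c": "AACAT"})
        meth = PositionTrack()
        meth.set("c", 2, 0.9)
        assert attach_context("c", 2, "T", ref, methylation=meth).methylation_level == 0

    def test_window_out_of_bounds_errors(self):
        ref = InMemoryReference({"c": "ACGT"})
        with pytest.raises(ValueError):
            attach_context("c", 0, "T", ref)

    def test_n_in_window_unscorable(self):
        ref = InMemoryReference({"c": "ANCGT"})
        with pytest.raises(ValueError):
            attach_context("c", 2, "T", ref)


class TestEnumeratePossible:
    def test_nine_base_single_exon_gives_27(self):
        gene = build_gene(["ATGAAATAA"], [])
        df = enumerate_possible(gene.transcript, gene.reference)
        assert len(df) == 27
        assert (df.groupby("pos").size() == 3).all()

    def test_two_exon_transcript_adds_12_essential_splice(self):
        single = build_gene(["ATG" + "AAC" * 9 + "AAC" * 9 + "TAA"], [])
        double = build_gene([EXON1, EXON2], [plain_intron(30)])
        n_single = len(
            enumerate_possible(single.transcript, single.reference, include_splice_region=False)
        )
        n_double = len(
            enumerate_possible(double.transcript, double.reference, include_splice_region=False)
        )
        assert n_double - n_single == 12

    def test_unscorable_context_skipped_with_count(self):
        gene = build_gene(["ATGAAATAA"], [], flank5="CCACCACCAN")
        df = enumerate_possible(gene.transcript, gene.reference)
        assert df.attrs["n_unscorable"] == 3
        assert len(df) == 24

    def test_strand_mirrored_enumeration_identical(self):
        """A mirrored minus-strand gene yields the same call multiset."""
        plus = build_gene([EXON1, EXON2], [plain_intron(30)])
        minus = build_gene([EXON1, EXON2], [plain_intron(30)], strand="-")
        cols = ["consequence", "verdict", "lof_filters", "context", "alt_collapsed"]
        a = (
            enumerate_possible(plus.transcript, plus.reference)[cols]
            .value_counts().sort_index()
        )
        b = (
            enumerate_possible(minus.transcript, minus.reference)[cols]
            .value_counts().sort_index()
        )
        pd.testing.assert_series_equal(a, b)

    def test_empty_cds_errors(self):
        gene = build_gene(["ATGAAATAA"], [])
        gene.transcript.cds_intervals = ()
        with pytest.raises(ValueError):
            enumerate_possible(gene.transcript, gene.reference)


def test_proportion_observed_counts():
    df = pd.DataFrame(
        {
            "consequence": ["synonymous"] * 10,
            "verdict": ["not_pLoF"] * 10,
            "observed": [True] * 3 + [False] * 7,
        }
    )
    assert proportion_observed(df, consequences=["synonymous"]) == (3, 10, 0.3)
    df["observed"] = False
    assert proportion_observed(df)[2] == 0.0
    df["observed"] = True
    assert proportion_observed(df)[2] == 1.0


def _training_frame(mus, props, n_per_context=1000, rng=None):
    """Synthetic synonymous training table with exact per-context proportions."""
    rows = []
    contexts = [(l + "C" + r) for l in "ACGT" for r in "ACT"]
    for i, (mu, p) in enumerate(zip(mus, props)):
        ctx = contexts[i % len(contexts)]
        k = int(round(p * n_per_context))
        rows.append(
            pd.DataFrame(
                {
                    "consequence": "synonymous",
                    "coverage": 50.0,
                    "context": ctx,
                    "alt_collapsed": "T" if i < len(contexts) else "G",
                    "methylation": 0,
                    "mu": mu,
                    "observed": [True] * k + [False] * (n_per_context - k),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestCalibration:
    def test_constant_proportion_gives_flat_fit(self):
        df = _training_frame([1e-9, 2e-9, 4e-9], [0.5, 0.5, 0.5])
        model = fit_calibration(df)
        a, b = model.params[0]
        assert a == pytest.approx(0.5, abs=1e-9)
        assert b * 4e-9 == pytest.approx(0.0, abs=1e-9)

    def test_generate_and_refit_recovers_slope(self):
        """Data built as proportion = 100*mu (linear region) refits the slope."""
        rng = np.random.default_rng(42)
        mus = np.linspace(1e-3, 5e-3, 12)
        props = np.minimum(1.0, 100 * mus)
        noisy = rng.binomial(2000, props) / 2000
        df = _training_frame(mus, noisy, n_per_context=2000)
        model = fit_calibration(df)
        assert model.params[0][1] == pytest.approx(100.0, rel=0.05)

    def test_predictions_clamped_to_unit_interval(self):
        model = CalibrationModel(params={0: (0.9, 1e12)}, fallback=(0.9, 1e12))
        assert model.predict(np.array([1.0]), np.array([0]))[0] == 1.0
        model = CalibrationModel(params={0: (-0.5, 0.0)}, fallback=(-0.5, 0.0))
        assert model.predict(np.array([1.0]), np.array([0]))[0] == 0.0

    def test_empty_training_set_errors(self):
        df = _training_frame([1e-9], [0.5])
        df["coverage"] = 10.0  # everything below the high-coverage threshold
        with pytest.raises(ValueError):
            fit_calibration(df)

    def test_json_round_trip(self, tmp_path):
        model = CalibrationModel(params={0: (0.1, 2e6), 2: (0.3, 1e6)}, fallback=(0.2, 1.5e6))
        path = tmp_path / "cal.json"
        model.to_json(path)
        back = CalibrationModel.from_json(path)
        assert back.params == model.params
        assert back.fallback == model.fallback


class TestCoverageModel:
    def test_high_coverage_factor_is_one(self):
        model = CoverageModel(c_high=40.0, intercept=0.0, slope=0.625)
        assert coverage_correction_factor(45.0, model) == 1.0

    def test_below_one_excluded_sentinel(self):
        model = CoverageModel()
        assert np.isnan(coverage_correction_factor(0.5, model))

    def test_negative_coverage_errors(self):
        with pytest.raises(ValueError):
            CoverageModel().factor(np.array([-1.0]))

    def test_fitted_line_closed_form_at_coverage_10(self):
        """At coverage 10, the factor equals a + b (log10(10) = 1)."""
        rng = np.random.default_rng(7)
        true = CoverageModel(c_high=40.0, intercept=0.0, slope=0.625)
        rows = []
        for cov in (2.0, 5.0, 10.0, 20.0, 30.0):
            p = 0.4 * float(true.factor(np.array([cov]))[0])
            obs = rng.random(4000) < p
            rows.append(
                pd.DataFrame(
                    {
                        "consequence": "synonymous",
                        "coverage": cov,
                        "context": "ACA",
                        "alt_collapsed": "T",
                        "methylation": 0,
                        "mu": 1e-8,
                        "observed": obs,
                    }
                )
            )
        df = pd.concat(rows, ignore_index=True)
        calibration = CalibrationModel(params={0: (0.4, 0.0)}, fallback=(0.4, 0.0))
        fitted = fit_coverage_model(df, calibration, c_high=40.0)
        a, b = fitted.intercept, fitted.slope
        assert coverage_correction_factor(10.0, fitted) == pytest.approx(
            np.clip(a + b, 0, 1)
        )
        assert a + b == pytest.approx(true.intercept + true.slope, abs=0.08)


class TestExpectedCounts:
    def _possible(self, n, coverage):
        return pd.DataFrame(
            {
                "consequence": "synonymous",
                "verdict": "not_pLoF",
                "mu": 1e-8,
                "methylation": 0,
                "coverage": coverage,
            },
            index=range(n),
        )

    def test_sum_of_predicted_proportions(self):
        cal = CalibrationModel(params={0: (0.2, 0.0)}, fallback=(0.2, 0.0))
        cov = CoverageModel(c_high=40.0)
        df = self._possible(10, 50.0)
        assert expected_counts(df, cal, cov) == pytest.approx(2.0)

    def test_low_coverage_sites_downweighted(self):
        cal = CalibrationModel(params={0: (0.2, 0.0)}, fallback=(0.2, 0.0))
        cov = CoverageModel(c_high=40.0, intercept=0.5, slope=0.0)
        df = pd.concat(
            [self._possible(5, 50.0), self._possible(5, 10.0)], ignore_index=True
        )
        assert expected_counts(df, cal, cov) == pytest.approx(1.5)

    def test_empty_class_warns_and_returns_zero(self):
        cal = CalibrationModel(params={0: (0.2, 0.0)}, fallback=(0.2, 0.0))
        cov = CoverageModel()
        df = self._possible(5, 50.0)
        with pytest.warns(UserWarning):
            assert expected_counts(df, cal, cov, consequences=["missense"]) == 0.0

    def test_expected_monotone_in_coverage_and_mu(self):
        cal = CalibrationModel(params={0: (0.0, 2e7)}, fallback=(0.0, 2e7))
        cov = CoverageModel(c_high=40.0, intercept=0.0, slope=0.625)
        base = expected_counts(self._possible(10, 20.0), cal, cov)
        higher_cov = expected_counts(self._possible(10, 35.0), cal, cov)
        df_mu = self._possible(10, 20.0)
        df_mu["mu"] = 2e-8
        higher_mu = expected_counts(df_mu, cal, cov)
        assert base < higher_cov
        assert base < higher_mu
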