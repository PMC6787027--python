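"""Underdetermined-variable detection, pinning and site comparisons."""

import numpy as np
import pytest

import fsthermo as ft
from fsthermo.identifiability import (
    _choose_representative,
    flag_underdetermined,
    iterative_pinning,
    pin_and_refit,
    sample_correlations,
    site_comparison,
)
from fsthermo.inference import PosteriorSummary, metropolis_run, summarize

from conftest import make_design


def _summary(labels, sds):
    n = len(labels)
    return PosteriorSummary(
        variable_labels=list(labels),
        mean=np.zeros(n),
        sd=np.asarray(sds, dtype=float),
        histograms=[(np.array([0.0, 1.0]), np.array([1.0]))] * n,
        pooled_chains=False,
    )


class TestFlagging:
    def test_study_fit_flags_exactly_six(self, study_summary):
        under = flag_underdetermined(study_summary)
        assert sorted(under) == [
            "A1 A·U→C·U",
            "A1 A·U→G·U",
            "A1 U·A→C·A",
            "A1 U·A→G·A",
            "P3 C·G→U·G",
            "P3 G·S→A·S",
        ]

    def test_identifiable_low_noise_design_flags_none(self):
        d = make_design(np.eye(3, dtype=int), ["x", "y", "z"])
        fs = ft.fs_from_dg(np.array([1.0, -2.0, 0.5]))
        cfg = ft.FitConfig(n_steps=5_000, n_chains=1, rng_seed=3)
        chain = metropolis_run(fs, np.full(3, 0.01), d, cfg)
        assert flag_underdetermined(summarize([chain], cfg)) == []

    def test_zero_sigma_summary_flags_none(self):
        assert flag_underdetermined(_summary(["x", "y"], [0.0, 0.0])) == []

    def test_empty_summary_rejected(self):
        with pytest.raises(ValueError):
            flag_underdetermined(_summary([], []))


class TestCorrelations:
    def test_sum_identified_pair_anticorrelated(self):
        d = make_design([[1, 1]], ["x", "y"])
        cfg = ft.FitConfig(n_steps=30_000, n_chains=1, rng_seed=4)
        chain = metropolis_run([0.3], [0.02], d, cfg)
        corr = sample_correlations([chain], 0.2)
        assert corr[0, 1] < -0.9
        assert corr[0, 0] == corr[1, 1] == 1.0

    def test_independent_variables_weakly_correlated(self):
        d = make_design(np.eye(2, dtype=int), ["x", "y"])
        fs = ft.fs_from_dg(np.array([1.0, -1.0]))
        cfg = ft.FitConfig(n_steps=20_000, n_chains=1, rng_seed=5)
        chain = metropolis_run(fs, np.full(2, 0.01), d, cfg)
        corr = sample_correlations([chain], 0.2)
        assert abs(corr[0, 1]) < 0.3

    def test_degenerate_series_reported_as_zero(self, study):
        cfg = ft.FitConfig(
            n_steps=500, n_chains=1, rng_seed=6,
            pinned_variables=frozenset({"P3 G·S→A·S"}),
        )
        chain = metropolis_run(study["fs"], study["sigma"], study["design"], cfg)
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = sample_correlations([chain], 0.2)
        j = chain.variable_labels.index("P3 G·S→A·S")
        off_diag = np.delete(corr[j], j)
        assert np.all(off_diag == 0.0) and corr[j, j] == 1.0

    def test_representative_is_the_shared_sum_variable(
        self, study_chains, study_summary, study_config
    ):
        corr = sample_correlations(study_chains, study_config.burn_in_fraction)
        labels = study_summary.variable_labels
        g_cluster = ["P3 G·S→A·S", "A1 A·U→G·U", "A1 U·A→G·A"]
        c_cluster = ["P3 C·G→U·G", "A1 A·U→C·U", "A1 U·A→C·A"]
        assert _choose_representative(corr, labels, g_cluster) == "P3 G·S→A·S"
        assert _choose_representative(corr, labels, c_cluster) == "P3 C·G→U·G"


class TestPinning:
    def test_double_pin_determines_all_fourteen(self, study, study_summary):
        cfg = ft.FitConfig(n_steps=8_000, n_chains=1, rng_seed=7)
        _, combos, refit = pin_and_refit(
            study["fs"],
            study["sigma"],
            study["design"],
            ["P3 G·S→A·S", "P3 C·G→U·G"],
            cfg,
            baseline=study_summary,
        )
        assert flag_underdetermined(refit) == []
        # the four coupled A1 variables surface as pinned-pair combinations
        assert {c.member for c in combos} == {
            "A1 A·U→G·U",
            "A1 U·A→G·A",
            "A1 A·U→C·U",
            "A1 U·A→C·A",
        }

    def test_combination_values_recover_truth_sums(self, study, study_summary):
        cfg = ft.FitConfig(n_steps=8_000, n_chains=1, rng_seed=8)
        truth = dict(
            zip(study["design"].col_labels, study["truth"].dg_bp_true)
        )
        _, combos, _ = pin_and_refit(
            study["fs"], study["sigma"], study["design"],
            ["P3 G·S→A·S"], cfg, baseline=study_summary,
        )
        by_member = {c.member: c for c in combos}
        for member in ("A1 A·U→G·U", "A1 U·A→G·A"):
            c = by_member[member]
            expected = truth["P3 G·S→A·S"] + truth[member]
            assert abs(c.mean - expected) <= 3 * c.sd

    def test_pin_nothing_matches_plain_run(self, study):
        cfg = ft.FitConfig(n_steps=300, n_chains=1, rng_seed=9)
        chains, _, _ = pin_and_refit(
            study["fs"], study["sigma"], study["design"], [], cfg
        )
        plain = metropolis_run(study["fs"], study["sigma"], study["design"], cfg)
        np.testing.assert_array_equal(chains[0].dg_samples, plain.dg_samples)

    def test_sum_identified_toy_pin_one_recovers_sum(self):
        truth_sum = float(ft.dg_from_fs(0.3))
        d = make_design([[1, 1]], ["x", "y"])
        cfg = ft.FitConfig(n_steps=10_000, n_chains=1, rng_seed=10)
        _, _, refit = pin_and_refit([0.3], [0.02], d, ["x"], cfg)
        mean_y, sd_y = refit["y"]
        assert abs(mean_y - truth_sum) <= 3 * sd_y

    def test_unknown_pin_label_rejected(self, study):
        cfg = ft.FitConfig(n_steps=10)
        with pytest.raises(ValueError, match="not in design"):
            pin_and_refit(
                study["fs"], study["sigma"], study["design"], ["bogus"], cfg
            )

    def test_pinning_determined_variable_warns(self, study, study_summary):
        cfg = ft.FitConfig(n_steps=200, n_chains=1, rng_seed=11)
        with pytest.warns(UserWarning, match="already-determined"):
            pin_and_refit(
                study["fs"], study["sigma"], study["design"],
                ["A3 G·S→A·S"], cfg, baseline=study_summary,
            )


class TestIterativePinning:
    def test_study_protocol(self, study):
        cfg = ft.FitConfig(n_steps=30_000, n_chains=1, rng_seed=5)
        report = iterative_pinning(
            study["fs"], study["sigma"], study["design"], cfg
        )
        assert len(report.underdetermined) == 6
        assert len(report.pin_history[0]["determined"]) == 10
        pinned_final = report.pin_history[-1]["pinned"]
        assert sorted(pinned_final) == ["P3 C·G→U·G", "P3 G·S→A·S"]
        assert report.pin_history[-1]["underdetermined"] == []
        assert {c.member for c in report.combinations} == {
            "A1 A·U→G·U",
            "A1 U·A→G·A",
            "A1 A·U→C·U",
            "A1 U·A→C·A",
        }

    def test_fully_identifiable_design_terminates_immediately(self):
        d = make_design(np.eye(2, dtype=int), ["x", "y"])
        fs = ft.fs_from_dg(np.array([0.5, -0.5]))
        cfg = ft.FitConfig(n_steps=4_000, n_chains=1, rng_seed=12)
        report = iterative_pinning(fs, np.full(2, 0.01), d, cfg)
        assert report.underdetermined == []
        assert len(report.pin_history) == 1
        assert report.combinations == []


class TestSiteComparison:
    def test_degenerate_posterior_exact_arithmetic(self):
        labels = [
            "P1 A·U→C·U", "P1 U·A→C·A", "P1 A·U→G·U", "P1 U·A→G·A",
            "P3 C·G→U·G", "A1 A·U→C·U", "A1 U·A→C·A",
            "P3 G·S→A·S", "A1 A·U→G·U", "A1 U·A→G·A",
        ]
        values = np.array([[6.0, 4.5, 5.1, 2.0, 1.7, 6.2, 4.1, 1.5, 1.8, 2.2]])
        chain = ft.ChainSamples(
            dg_samples=values,
            variable_labels=labels,
            seed=0,
            accept_counts=np.zeros(len(labels), dtype=int),
        )
        table = site_comparison([chain], burn_in_fraction=0.0)
        row = table.set_index(["change", "site"])
        assert row.loc[("C·A→C·U", "P"), "mean"] == pytest.approx(6.0 - 4.5)
        assert row.loc[("C·A→C·U", "A"), "mean"] == pytest.approx(6.2 - 4.1)
        assert row.loc[("G·A→G·U", "P"), "mean"] == pytest.approx(5.1 - 2.0)
        assert row.loc[("G·A→G·U", "A"), "mean"] == pytest.approx(1.8 - 2.2)
        assert (table["sd"] == 0.0).all()

    def test_recovers_truth_differences(self, study, study_chains, study_config):
        truth = dict(zip(study["design"].col_labels, study["truth"].dg_bp_true))
        table = site_comparison(
            study_chains, study_config.burn_in_fraction
        ).set_index(["change", "site"])
        expected = {
            ("C·A→C·U", "P"): truth["P1 A·U→C·U"] - truth["P1 U·A→C·A"],
            ("C·A→C·U", "A"): truth["A1 A·U→C·U"] - truth["A1 U·A→C·A"],
            ("G·A→G·U", "P"): truth["P1 A·U→G·U"] - truth["P1 U·A→G·A"],
            ("G·A→G·U", "A"): truth["A1 A·U→G·U"] - truth["A1 U·A→G·A"],
        }
        for key, val in expected.items():
            mean, sd = table.loc[key, "mean"], table.loc[key, "sd"]
            assert abs(mean - val) <= 3 * sd
            assert sd < 2.0  # derived differences are determined

    def test_missing_label_is_explicit(self, study_chains):
        with pytest.raises(KeyError, match="nope"):
            site_comparison(
                study_chains, recipe={("q", "P"): (["nope"], ["P1 A·U→C·U"])}
            )
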