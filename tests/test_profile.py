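"""Population fits, dwell-time fits, pooling and condition summaries."""

import math

import numpy as np
import pytest

import synpore as sp
from synpore.detect import EventRecord, EventTable
from synpore.profile import (
    DegenerateFitError,
    GaussianComponent,
    PopulationFit,
    build_blockade_histogram,
    fit_dwell_time,
    fit_population_model,
    pool_replicates,
    profile_replicate,
    summarize_condition,
)


def table_from_arrays(amps, dwells=None, condition="c", replicate=0):
    amps = np.asarray(amps, float)
    dwells = np.ones(amps.size) if dwells is None else np.asarray(dwells, float)
    recs = [
        EventRecord(i * 1000, i * 1000 + 10, i * 0.01, float(d), float(a))
        for i, (a, d) in enumerate(zip(amps, dwells))
    ]
    return EventTable(recs, {"condition": condition, "replicate": replicate})


@pytest.fixture(scope="module")
def two_class_amps():
    # alpha-syn-alone-like mixture: 66:24 renormalized at -85 / -30 pA
    rng = np.random.default_rng(123)
    n = 2000
    labels = rng.random(n) < 66 / 90
    return np.where(labels, rng.normal(-85, 5, n), rng.normal(-30, 3, n)), labels


class TestHistogram:
    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        amps = rng.normal(-85, 5, 100)
        for bw in (2.0, 1.0, 5.0):
            assert build_blockade_histogram(amps, bw).counts.sum() == 100

    def test_identical_amplitudes_single_bin(self):
        h = build_blockade_histogram(np.full(40, -30.0), 2.0)
        assert (h.counts > 0).sum() == 1

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ValueError):
            build_blockade_histogram(np.array([-30.0]), 0.0)


class TestFitPopulationModel:
    def test_single_component_peak_matches_sample_mean(self):
        rng = np.random.default_rng(1)
        amps = rng.normal(-85, 5, 1000)
        fit = fit_population_model(amps, k=1)
        assert fit.components[0].peak_pA == pytest.approx(-85.0, abs=1.0)
        # fitted peak agrees with the sample mean within 2 SE
        se = 5 / math.sqrt(1000)
        assert fit.components[0].peak_pA == pytest.approx(float(amps.mean()), abs=2 * se)

    @pytest.mark.parametrize("method", ["mle", "histogram_ls"])
    def test_two_component_population_recovery(self, two_class_amps, method):
        amps, labels = two_class_amps
        fit = fit_population_model(amps, k=2, method=method)
        trans = fit.component("translocation")
        bump = fit.component("bumping")
        true_trans_pct = 100 * labels.mean()
        assert trans.peak_pA == pytest.approx(-85.0, abs=1.0)
        assert bump.peak_pA == pytest.approx(-30.0, abs=1.0)
        assert trans.population_pct == pytest.approx(true_trans_pct, abs=5.0)

    def test_bic_selects_two_components(self, two_class_amps):
        amps, _ = two_class_amps
        fit = fit_population_model(amps, k="auto")
        assert fit.k == 2

    def test_population_plus_unclassified_conserved(self, two_class_amps):
        amps, _ = two_class_amps
        fit = fit_population_model(amps, k="auto")
        total = sum(c.population_pct for c in fit.components) + fit.unclassified_pct
        assert total == pytest.approx(100.0, abs=0.1)

    def test_too_few_events_refused(self):
        with pytest.raises(ValueError, match=">= 50"):
            fit_population_model(np.full(30, -85.0) + np.random.default_rng(0).normal(0, 1, 30))


class TestAssignEventClasses:
    def _fit(self, comps):
        return PopulationFit(comps, 2.0, 0.0, "mle", 0.0, {}, 100)

    def test_deep_event_is_translocation(self):
        comps = [
            GaussianComponent("translocation", -85.0, 5.0, 70.0, 0.7),
            GaussianComponent("bumping", -30.0, 3.0, 28.0, 0.3),
        ]
        table = table_from_arrays([-85.0, -30.0, -2.0])
        sp.assign_event_classes(table, self._fit(comps))
        assert table.labels() == ["translocation", "bumping", None]

    def test_exact_zscore_tie_goes_to_deeper_component(self):
        comps = [
            GaussianComponent("translocation", -85.0, 5.0, 50.0, 0.5),
            GaussianComponent("bumping", -35.0, 5.0, 50.0, 0.5),
        ]
        table = table_from_arrays([-60.0])  # 5 sigma from both peaks -> unclassified
        sp.assign_event_classes(table, self._fit(comps), z_max=6.0)
        assert table.labels() == ["translocation"]

    def test_three_components_middle_is_intercalation(self):
        rng = np.random.default_rng(5)
        amps = np.concatenate(
            [rng.normal(-85, 4, 500), rng.normal(-50, 4, 400), rng.normal(-25, 3, 400)]
        )
        fit = fit_population_model(amps, k=3)
        labels = [c.class_label for c in fit.components]
        assert labels == ["translocation", "intercalation", "bumping"]

    def test_identical_peaks_rejected(self):
        comps = [
            GaussianComponent("translocation", -85.0, 5.0, 50.0, 0.5),
            GaussianComponent("bumping", -85.0, 3.0, 50.0, 0.5),
        ]
        with pytest.raises(DegenerateFitError):
            sp.assign_event_classes(table_from_arrays([-85.0]), self._fit(comps))

    def test_single_shallow_component_labeled_bumping(self):
        rng = np.random.default_rng(6)
        fit = fit_population_model(rng.normal(-30, 3, 500), k=1)
        assert fit.components[0].class_label == "bumping"


class TestFitDwellTime:
    def test_mle_recovers_scale(self):
        rng = np.random.default_rng(7)
        d = rng.exponential(0.5, 5000)
        fit = fit_dwell_time(d, "translocation")
        assert abs(fit.tau_ms - 0.5) / 0.5 < 0.05

    def test_mle_is_the_sample_mean(self):
        d = np.full(25, 0.3)
        assert fit_dwell_time(d).tau_ms == pytest.approx(0.3, abs=1e-12)

    def test_mle_and_histogram_agree(self):
        rng = np.random.default_rng(8)
        d = rng.exponential(0.5, 5000)
        mle = fit_dwell_time(d, method="mle").tau_ms
        hist = fit_dwell_time(d, method="histogram_ls").tau_ms
        assert abs(mle - hist) / mle < 0.10

    def test_truncated_mle_unbiased(self):
        # left-truncation at c: tau = mean(d | d >= c) - c recovers the scale
        rng = np.random.default_rng(9)
        d = rng.exponential(0.05, 20000)
        fit = fit_dwell_time(d, method="mle", min_dwell_ms=0.02)
        assert abs(fit.tau_ms - 0.05) / 0.05 < 0.05
        assert fit.n_events == int(np.sum(d >= 0.02))

    def test_too_few_events_refused_with_count(self):
        with pytest.raises(ValueError, match="only 5"):
            fit_dwell_time(np.full(5, 0.3))


class TestPoolingAndSummaries:
    def test_pooled_count_is_sum(self):
        tables = [
            table_from_arrays(np.full(n, -85.0), condition="c", replicate=i)
            for i, n in enumerate([400, 500, 600])
        ]
        pooled = pool_replicates(tables)
        assert len(pooled) == 1500
        assert pooled.meta["n_replicates"] == 3

    def test_identical_replicates_preserve_fractions(self):
        rng = np.random.default_rng(11)
        amps = np.concatenate([rng.normal(-85, 5, 700), rng.normal(-30, 3, 300)])
        tables = [table_from_arrays(amps, condition="c", replicate=i) for i in range(3)]
        pooled = pool_replicates(tables)
        fit_one = fit_population_model(table_from_arrays(amps), k=2)
        fit_pool = fit_population_model(pooled, k=2)
        for lbl in ("translocation", "bumping"):
            assert fit_pool.component(lbl).population_pct == pytest.approx(
                fit_one.component(lbl).population_pct, abs=0.1
            )

    def test_mismatched_conditions_rejected(self):
        with pytest.raises(ValueError, match="different conditions"):
            pool_replicates(
                [table_from_arrays([-85.0], condition="a"),
                 table_from_arrays([-85.0], condition="b")]
            )

    def test_sem_formula(self):
        # per-replicate populations (66, 64, 68) -> SEM = SD / sqrt(3)
        rng = np.random.default_rng(13)
        profiles = []
        for i, pct in enumerate([66, 64, 68]):
            n = 1000
            n_t = int(round(n * pct / 100))
            amps = np.concatenate(
                [rng.normal(-85, 5, n_t), rng.normal(-30, 3, n - n_t)]
            )
            profiles.append(profile_replicate(table_from_arrays(amps, replicate=i), k=2))
        summary = summarize_condition(profiles, "c")
        pops = summary.per_replicate["translocation"]["population_pct"]
        expected_sem = float(np.std(pops, ddof=1) / math.sqrt(3))
        assert summary.classes["translocation"].population.sem == pytest.approx(expected_sem)
        hand = [66.0, 64.0, 68.0]
        assert float(np.std(hand, ddof=1) / math.sqrt(3)) == pytest.approx(2 / math.sqrt(3))

    def test_single_replicate_has_no_sem(self):
        rng = np.random.default_rng(14)
        prof = profile_replicate(table_from_arrays(rng.normal(-85, 5, 500)), k=1)
        summary = summarize_condition([prof], "c")
        assert summary.classes["translocation"].population.sem is None

    def test_identical_replicates_zero_sem(self):
        rng = np.random.default_rng(15)
        amps = rng.normal(-85, 5, 500)
        profiles = [profile_replicate(table_from_arrays(amps, replicate=i), k=1) for i in range(3)]
        summary = summarize_condition(profiles, "c")
        assert summary.classes["translocation"].population.sem == pytest.approx(0.0, abs=1e-9)

    def test_summary_json_round_trip(self):
        rng = np.random.default_rng(16)
        amps = np.concatenate([rng.normal(-85, 5, 700), rng.normal(-30, 3, 300)])
        profiles = [profile_replicate(table_from_arrays(amps, replicate=i), k=2) for i in range(3)]
        summary = summarize_condition(profiles, "c", construct="full_length")
        back = sp.ConditionSummary.from_dict(summary.to_dict())
        assert back.condition == "c"
        assert back.construct == "full_length"
        assert back.classes.keys() == summary.classes.keys()
        assert back.classes["translocation"].population.mean == pytest.approx(
            summary.classes["translocation"].population.mean
        )


class TestPeakErrorScaling:
    def test_peak_error_shrinks_as_sqrt_n(self):
        # |peak error| ~ n^(-1/2): regression of log error on log n over seeds
        rng = np.random.default_rng(17)
        ns = [100, 400, 1600, 6400]
        mean_err = []
        for n in ns:
            errs = []
            for _ in range(40):
                amps = rng.normal(-85, 5, n)
                fit = fit_population_model(amps, k=1)
                errs.append(abs(fit.components[0].peak_pA + 85.0))
            mean_err.append(np.mean(errs))
        slope = np.polyfit(np.log(ns), np.log(mean_err), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.15)
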