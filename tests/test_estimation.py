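"""Baseline and transition-matrix estimation from longitudinal panels."""

import numpy as np
import pytest

from hivcea import (
    GeneratorSpec,
    Observation,
    PanelDataset,
    PatientRecord,
    count_transitions,
    estimate_baseline,
    estimate_transitions,
    simulate_panel,
)


def _record(pid, cd4_by_year, **kwargs):
    obs = [Observation(t, c) for t, c in cd4_by_year]
    return PatientRecord(patient_id=pid, observations=obs, **kwargs)


class TestPanelValidation:
    def test_duplicate_ids_rejected(self):
        r = _record("a", [(0, 100)])
        with pytest.raises(ValueError, match="unique"):
            PanelDataset([r, _record("a", [(0, 600)])])

    def test_years_strictly_increasing(self):
        with pytest.raises(ValueError, match="increasing"):
            _record("a", [(0, 100), (0, 200)])


class TestEstimateBaseline:
    def test_one_patient_per_stage_gives_uniform(self):
        panel = PanelDataset(
            [
                _record("a", [(0, 150)]),
                _record("b", [(0, 250)]),
                _record("c", [(0, 400)]),
                _record("d", [(0, 900)]),
            ]
        )
        np.testing.assert_allclose(estimate_baseline(panel).p, 0.25)

    def test_excludes_art_experienced(self):
        panel = PanelDataset(
            [
                _record("a", [(0, 150)]),
                _record("b", [(0, 900)], art_naive=False),
            ]
        )
        np.testing.assert_array_equal(estimate_baseline(panel).p, [1, 0, 0, 0])

    def test_empty_panel_errors(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_baseline(PanelDataset([]))

    def test_missing_year0_errors(self):
        panel = PanelDataset([_record("a", [(1, 150)])])
        with pytest.raises(ValueError, match="year-0"):
            estimate_baseline(panel)

    def test_large_synthetic_panel_recovers_truth(self):
        panel = simulate_panel(GeneratorSpec(n_patients=10_000, years=0, seed=42))
        est = estimate_baseline(panel).p
        np.testing.assert_allclose(est, [0.39, 0.22, 0.16, 0.23], atol=0.02)


class TestCountTransitions:
    def test_hand_counted_trajectory(self):
        panel = PanelDataset([_record("a", [(0, 150), (1, 250), (2, 400)])])
        counts = count_transitions(panel, max_year=2)
        assert counts.counts[1][0, 1] == 1
        assert counts.counts[1].sum() == 1
        assert counts.counts[2][1, 2] == 1
        assert counts.counts[2].sum() == 1

    def test_gap_produces_no_counts(self):
        panel = PanelDataset([_record("a", [(0, 150), (2, 400)])])
        counts = count_transitions(panel, max_year=2)
        assert all(c.sum() == 0 for c in counts.counts.values())

    def test_count_conservation(self):
        """Total cell count at year t equals the number of observed pairs."""
        panel = simulate_panel(GeneratorSpec(n_patients=500, years=3, seed=5))
        counts = count_transitions(panel, max_year=3)
        for t in (1, 2, 3):
            assert counts.counts[t].sum() == 500  # no dropout: every pair observed

    def test_max_year_validated(self):
        with pytest.raises(ValueError):
            count_transitions(PanelDataset([]), max_year=0)


class TestEstimateTransitions:
    def test_row_proportions_match_hand_division(self):
        panel_records = []
        # 101 patients leaving stage <200: 38/36/20/7 to each destination
        dests = [150] * 38 + [250] * 36 + [400] * 20 + [900] * 7
        for k, d in enumerate(dests):
            panel_records.append(_record(f"p{k}", [(0, 100), (1, d)]))
        counts = count_transitions(PanelDataset(panel_records), max_year=1)
        sched = estimate_transitions(counts, carry_forward_from=1)
        np.testing.assert_allclose(
            sched.matrix_for(1)[0], [38 / 101, 36 / 101, 20 / 101, 7 / 101]
        )

    def test_zero_row_without_smoothing_becomes_identity(self):
        panel = PanelDataset([_record("a", [(0, 150), (1, 150)])])
        counts = count_transitions(panel, max_year=1)
        with pytest.warns(UserWarning, match="remain in stage"):
            sched = estimate_transitions(counts, carry_forward_from=1)
        np.testing.assert_array_equal(sched.matrix_for(1)[2], [0, 0, 1, 0])

    def test_all_zero_row_with_smoothing_is_uniform(self):
        panel = PanelDataset([_record("a", [(0, 150), (1, 150)])])
        counts = count_transitions(panel, max_year=1)
        sched = estimate_transitions(counts, carry_forward_from=1, smoothing=1.0)
        np.testing.assert_allclose(sched.matrix_for(1)[3], 0.25)

    def test_carry_forward_lookup(self):
        panel = simulate_panel(GeneratorSpec(n_patients=300, years=3, seed=9))
        counts = count_transitions(panel, max_year=3)
        sched = estimate_transitions(counts, carry_forward_from=3)
        np.testing.assert_array_equal(sched.matrix_for(5), sched.matrix_for(3))

    def test_invalid_carry_forward(self):
        with pytest.raises(ValueError):
            estimate_transitions(
                count_transitions(PanelDataset([]), 1), carry_forward_from=0
            )


class TestParameterRecovery:
    def test_error_decreases_with_sample_size(self, table2):
        errors = []
        for n, seed in ((500, 1), (5_000, 2), (50_000, 3)):
            panel = simulate_panel(GeneratorSpec(n_patients=n, years=3, seed=seed))
            counts = count_transitions(panel, max_year=3)
            sched = estimate_transitions(counts, carry_forward_from=3)
            err = max(
                np.abs(sched.matrix_for(t) - table2.matrix_for(t)).max()
                for t in (1, 2, 3)
            )
            errors.append(err)
        assert errors[0] > errors[2]
        assert errors[2] < 0.01

    def test_estimates_within_binomial_envelope(self, table2):
        """Each estimated cell sits inside its own 3-sigma sampling band."""
        panel = simulate_panel(GeneratorSpec(n_patients=5_000, years=3, seed=2))
        counts = count_transitions(panel, max_year=3)
        sched = estimate_transitions(counts, carry_forward_from=3)
        for t in (1, 2, 3):
            truth = table2.matrix_for(t)
            row_tot = counts.counts[t].sum(axis=1, keepdims=True).astype(float)
            se = np.sqrt(truth * (1 - truth) / np.maximum(row_tot, 1))
            assert np.all(np.abs(sched.matrix_for(t) - truth) <= 3 * se + 1e-12)

    def test_recovery_robust_to_missingness(self, table2):
        from hivcea import degrade_panel

        panel = simulate_panel(GeneratorSpec(n_patients=5_000, years=3, seed=13))
        thinned = degrade_panel(panel, missing_rate=0.3, seed=14)
        counts = count_transitions(thinned, max_year=3)
        sched = estimate_transitions(counts, carry_forward_from=3)
        for t in (1, 2, 3):
            assert np.abs(sched.matrix_for(t) - table2.matrix_for(t)).max() < 0.05
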