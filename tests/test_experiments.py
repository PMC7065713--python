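"""Experiments: lattice maps, seeded trial sampling, masking sweep."""

import csv
import math

import numpy as np
import pandas as pd
import pytest

import hoss
from hoss import GridSpec, ModelSpec
from hoss.experiments import summarize_by_report, sweep_to_frame, trials_to_frame


@pytest.fixture(scope="module")
def near_grid(near_threshold_spec) -> pd.DataFrame:
    return hoss.grid_map(near_threshold_spec, GridSpec(-1, 3, 0.1, -1, 3, 0.1))


class TestGridMap:
    def test_row_at_equidistant_point(self, near_grid):
        row = near_grid[(near_grid.x1 == 1.0) & (near_grid.x2 == 1.0)].iloc[0]
        assert row.p_presence == pytest.approx(0.5, abs=1e-12)
        assert row.kl_w == pytest.approx(0.0, abs=1e-12)
        assert row.kl_a == pytest.approx(0.0, abs=1e-12)
        assert bool(row.on_contour)

    def test_presence_rises_along_main_diagonal(self, near_grid):
        diag = near_grid[np.isclose(near_grid.x1, near_grid.x2)].sort_values("x1")
        assert np.all(np.diff(diag.p_presence.to_numpy()) > 0)

    def test_presence_higher_upper_right_than_lower_left(self, near_grid):
        at = lambda x1, x2: near_grid[
            np.isclose(near_grid.x1, x1) & np.isclose(near_grid.x2, x2)
        ].iloc[0]
        assert at(2.5, 2.5).p_presence > at(0.0, 0.0).p_presence

    def test_confidence_grows_towards_off_diagonal_corners(self, near_grid):
        at = lambda x1, x2: near_grid[
            np.isclose(near_grid.x1, x1) & np.isclose(near_grid.x2, x2)
        ].iloc[0]
        center = at(1.0, 1.0).confidence
        assert at(2.5, -0.5).confidence > center
        assert at(-0.5, 2.5).confidence > center

    def test_contour_flags_trace_the_boundary(self, near_grid):
        flagged = near_grid[near_grid.on_contour]
        assert len(flagged) > 0
        # every flagged point is close to the 0.5 level relative to the lattice pitch
        assert np.all(np.abs(flagged.p_presence - 0.5) < 0.05)
        # and the true boundary crossing lies inside the flagged band
        unflagged = near_grid[~near_grid.on_contour]
        assert np.abs(unflagged.p_presence - 0.5).min() > np.abs(flagged.p_presence - 0.5).min()

    def test_graded_confidence_in_unseen_region(self, near_grid):
        unseen = near_grid[near_grid.p_presence < 0.5]
        assert unseen.confidence.max() - unseen.confidence.min() > 0.2

    def test_rejects_non_2d_spec(self):
        spec1d = ModelSpec(
            means=[[0.0, 2.0]],
            covariance=[[1.0]],
            prior_presence=0.5,
            prior_content_given_presence=[1.0],
        )
        with pytest.raises(ValueError, match="2D"):
            hoss.grid_map(spec1d, GridSpec(-1, 1, 0.5, -1, 1, 0.5))

    def test_grid_validation(self):
        with pytest.raises(ValueError, match="step"):
            GridSpec(0, 1, -0.1, 0, 1, 0.1)
        with pytest.raises(ValueError, match="upper bound"):
            GridSpec(1, 0, 0.1, 0, 1, 0.1)
        with pytest.raises(ValueError, match="1e6"):
            GridSpec(0, 1000, 0.0001, 0, 1000, 0.1)


class TestSampleTrials:
    def test_seeded_runs_are_identical(self, gratings_spec):
        a = hoss.sample_trials(gratings_spec, 50, seed=42)
        b = hoss.sample_trials(gratings_spec, 50, seed=42)
        assert all(np.array_equal(ta.x, tb.x) for ta, tb in zip(a, b))
        assert all(ta.bundle.report == tb.bundle.report for ta, tb in zip(a, b))

    def test_counts_and_labels(self, gratings_spec):
        trials = hoss.sample_trials(gratings_spec, 1, seed=0)
        assert len(trials) == 3
        assert [t.true_class for t in trials] == ["absent", "grating_1", "grating_2"]

    def test_class_subsetting_preserves_draws(self, gratings_spec):
        """Each class keeps its own substream, so dropping a class does
        not perturb the draws of the classes kept."""
        full = hoss.sample_trials(gratings_spec, 20, seed=9)
        only_present = hoss.sample_trials(gratings_spec, 20, seed=9, classes=[1, 2])
        full_present = [t for t in full if t.true_class != "absent"]
        assert all(np.array_equal(a.x, b.x) for a, b in zip(full_present, only_present))

    def test_empirical_means_match_generative_means(self, gratings_spec):
        trials = hoss.sample_trials(gratings_spec, 2000, seed=13)
        se = 1.0 / math.sqrt(2000)
        for c, label in enumerate(gratings_spec.state_labels):
            xs = np.array([t.x for t in trials if t.true_class == label])
            assert np.all(np.abs(xs.mean(axis=0) - gratings_spec.means[:, c]) < 3 * se)

    def test_invalid_inputs(self, gratings_spec):
        with pytest.raises(ValueError, match="n_per_class"):
            hoss.sample_trials(gratings_spec, 0, seed=1)
        with pytest.raises(ValueError, match="class indices"):
            hoss.sample_trials(gratings_spec, 5, seed=1, classes=[7])


class TestSummarize:
    def test_simple_arithmetic_mean(self, gratings_spec):
        trials = hoss.sample_trials(gratings_spec, 4, seed=2)
        seen = [t for t in trials if t.bundle.report == "seen"][:2]
        table = summarize_by_report(seen)
        seen_row = table[table.report == "seen"].iloc[0]
        assert seen_row.mean_kl_w == pytest.approx(
            (seen[0].update.kl_w + seen[1].update.kl_w) / 2, abs=1e-12
        )
        unseen_row = table[table.report == "unseen"].iloc[0]
        assert unseen_row.n == 0 and math.isnan(unseen_row.mean_kl_w)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            summarize_by_report([])

    def test_matches_independent_tabulation_of_trial_csv(self, gratings_spec, tmp_path):
        """Report-conditioned means recomputed by a plain csv-module
        group-by over the written trial table."""
        trials = hoss.sample_trials(gratings_spec, 300, seed=21, lam=0.3)
        path = tmp_path / "trials.csv"
        hoss.write_table(trials_to_frame(trials), path, schema="trials")
        sums: dict[str, list[float]] = {"seen": [], "unseen": []}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                sums[row["report"]].append(float(row["kl_w"]))
        table = summarize_by_report(trials)
        for report in ("seen", "unseen"):
            expected = sum(sums[report]) / len(sums[report])
            got = float(table[table.report == report].mean_kl_w.iloc[0])
            assert got == pytest.approx(expected, rel=1e-9)


@pytest.fixture(scope="module")
def sweep(gratings_spec):
    return hoss.masking_sweep(gratings_spec, n_per_class=2000, seed=1)


class TestMaskingSweep:
    def test_seen_rate_for_present_classes_rises_with_precision(self, gratings_spec):
        results = hoss.masking_sweep(gratings_spec, n_per_class=2000, seed=1, classes=[1, 2])
        rates = [r.p_seen for r in results]
        # non-decreasing within binomial error at n = 4000 per level
        tol = 2.0 * math.sqrt(0.25 / 4000)
        assert all(b - a > -tol for a, b in zip(rates, rates[1:]))

    def test_w_level_ignition_asymmetry_grows(self, sweep):
        for r in sweep:
            assert r.mean_kl_w_seen > r.mean_kl_w_unseen
        gaps = [r.asym_w for r in sweep]
        assert all(b >= a for a, b in zip(gaps, gaps[1:]))

    def test_a_level_updates_more_symmetric_than_w_level(self, sweep):
        for r in sweep:
            assert abs(r.asym_a) < abs(r.asym_w)

    def test_counts_partition_trials(self, sweep):
        for r in sweep:
            assert r.n_seen + r.n_unseen == 3 * r.n_per_class
            assert 0.0 <= r.p_seen <= 1.0

    def test_high_precision_limits(self, gratings_spec):
        r = hoss.masking_sweep(gratings_spec, [100.0], n_per_class=2000, seed=1)[0]
        assert r.mean_kl_w_seen == pytest.approx(math.log(4.0), rel=0.05)
        assert r.mean_kl_w_unseen == pytest.approx(math.log(2.0), rel=0.05)
        assert r.mean_kl_a_seen == pytest.approx(math.log(2.0), rel=0.05)
        assert r.mean_kl_a_unseen == pytest.approx(math.log(2.0), rel=0.05)

    def test_empty_report_category_flagged_not_zero(self, gratings_spec):
        # present classes only at very high precision: nothing is unseen
        r = hoss.masking_sweep(gratings_spec, [100.0], n_per_class=50, seed=1, classes=[1, 2])[0]
        assert r.n_unseen == 0
        assert math.isnan(r.mean_kl_w_unseen)
        assert math.isnan(r.asym_w)

    def test_flat_comparator_asymmetry_smaller_at_high_precision(self, gratings_spec, sweep):
        flat = hoss.load_packaged_spec("gratings_2d_flat")
        flat_results = hoss.masking_sweep(flat, n_per_class=2000, seed=1)
        assert abs(flat_results[-1].asym_w) < abs(sweep[-1].asym_w)

    def test_per_node_mode_runs_and_differs(self, gratings_spec):
        joint = hoss.masking_sweep(gratings_spec, [0.5], n_per_class=200, seed=4)[0]
        per_node = hoss.masking_sweep(
            gratings_spec, [0.5], n_per_class=200, seed=4, kl_w_mode="per_node_sum"
        )[0]
        assert per_node.mean_kl_w_seen > joint.mean_kl_w_seen

    def test_invalid_precision_rejected(self, gratings_spec):
        with pytest.raises(ValueError, match="positive"):
            hoss.masking_sweep(gratings_spec, [0.5, -1.0], n_per_class=10, seed=0)

    def test_frames_have_declared_schemas(self, gratings_spec, sweep):
        frame = sweep_to_frame(sweep)
        assert list(frame.columns)[:4] == ["lambda", "n_seen", "n_unseen", "p_seen"]
        trials = hoss.sample_trials(gratings_spec, 3, seed=0)
        tf = trials_to_frame(trials)
        assert list(tf.columns) == [
            "trial_id", "lambda", "true_class", "x1", "x2",
            "p_presence", "confidence", "report", "kl_w", "kl_a",
        ]
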