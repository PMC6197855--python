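import math

import numpy as np
import pytest

from kinfret import presets
from kinfret.dwell_analysis import (
    DwellRecord,
    LifetimeEstimate,
    classify_traces,
    dwell_table,
    extract_dwells,
    first_binding_times,
    fit_lifetime,
    fret_histogram,
    postsynchronized_histogram,
    transition_density,
)
from kinfret.idealization import IdealizedPath
from kinfret.kinetic_models import ExperimentCondition
from kinfret.synthetic_data import generate_dataset, truth_idealized_paths
from kinfret.trace_processing import FretTrace


def path_from_labels(labels, dt=0.1, mol="m0", right_censored=True):
    """Build a canonical IdealizedPath directly from per-frame labels."""
    labels = np.asarray(labels, float)
    levels = np.unique(labels[np.isfinite(labels)])
    lut = {lv: i for i, lv in enumerate(levels)}
    states = np.array([lut.get(x, 0) for x in labels])
    return IdealizedPath(
        state_per_frame=states,
        fitted_means=levels,
        fitted_sds=np.full(levels.size, 1e-3),
        n_states=levels.size,
        model_score=0.0,
        frame_time=dt,
        molecule_id=mol,
        right_censored=right_censored,
        canonical_per_frame=labels,
        assignment={i: float(lv) for i, lv in enumerate(levels)},
    )


class TestExtractDwells:
    def test_interior_dwell(self):
        path = path_from_labels([0, 0, 0.4, 0.4, 0.4, 0])
        dwells = extract_dwells(path)
        assert len(dwells) == 3
        mid = dwells[1]
        assert mid.state == 0.4
        assert mid.duration == pytest.approx(0.3)
        assert mid.prev_state == 0.0 and mid.next_state == 0.0
        assert not mid.left_censored and not mid.right_censored

    def test_boundary_dwells_censored(self):
        dwells = extract_dwells(path_from_labels([0, 0, 0.4, 0.4]))
        assert dwells[0].left_censored and dwells[0].next_state == 0.4
        assert dwells[-1].right_censored and dwells[-1].next_state is None
        assert dwells[0].prev_state is None

    def test_single_state_path(self):
        dwells = extract_dwells(path_from_labels([0.7] * 10))
        assert len(dwells) == 1
        assert dwells[0].left_censored and dwells[0].right_censored

    def test_durations_cover_trace_exactly(self):
        rng = np.random.default_rng(0)
        labels = rng.choice([0.0, 0.4, 0.7], size=500)
        dwells = extract_dwells(path_from_labels(labels))
        assert sum(d.duration for d in dwells) == pytest.approx(500 * 0.1)

    def test_merge_pools_states(self):
        dwells = extract_dwells(
            path_from_labels([0, 0.2, 0.4, 0.2, 0]), merge={0.2: 0.4}
        )
        assert [d.state for d in dwells] == [0.0, 0.4, 0.0]
        assert dwells[1].duration == pytest.approx(0.3)

    def test_matches_ground_truth_sojourns(self, contact_scheme, emission):
        cond = ExperimentCondition(30e-9, 0.1, 1000)
        ds = generate_dataset(contact_scheme, cond, emission, 60, seed=5)
        paths = truth_idealized_paths(ds)
        est = sorted(
            d.duration
            for p in paths
            for d in extract_dwells(p)
            if d.state == 0.4 and not d.right_censored and not d.left_censored
        )
        truth = []
        for sp, b in zip(ds.paths, ds.bleach_times):
            horizon = min(b.donor, cond.duration)
            for start, stop, state in sp.segments():
                if state == "P" and stop < horizon:
                    truth.append(stop - start)
        truth = sorted(truth)
        # frame discretization: counts agree closely, mean within a frame
        assert abs(len(est) - len(truth)) <= max(3, 0.1 * len(truth))
        if est:
            assert abs(np.mean(est) - np.mean(truth)) < 0.15


class TestFitLifetime:
    def test_parametric_recovery(self, rng):
        d = rng.exponential(3.6, 1000)
        est = fit_lifetime(d)
        assert abs(est.tau - 3.6) < 2 * est.uncertainty

    def test_histogram_method(self, rng):
        d = rng.exponential(3.6, 2000)
        est = fit_lifetime(d, method="histogram")
        assert est.tau == pytest.approx(3.6, rel=0.25)

    def test_degenerate_double_mixture_equals_tau(self):
        est = LifetimeEstimate(
            tau=5.0, uncertainty=0.1, n_dwells=100, model="double",
            components=(5.0, 0.5, 5.0, 0.5),
        )
        assert est.weighted_average == pytest.approx(5.0)

    def test_weighted_average_formula(self):
        est = LifetimeEstimate(
            tau=0.0, uncertainty=0.0, n_dwells=0, model="double",
            components=(3.9, 0.46, 15.7, 0.54),
        )
        assert est.weighted_average == pytest.approx(10.272, abs=1e-3)

    def test_double_fit_separates_mixture(self, rng):
        d = np.concatenate([rng.exponential(1.0, 1500), rng.exponential(12.0, 1500)])
        est = fit_lifetime(d, model="double")
        t1, a1, t2, a2 = est.components
        assert t1 == pytest.approx(1.0, rel=0.3)
        assert t2 == pytest.approx(12.0, rel=0.3)
        assert a1 == pytest.approx(0.5, abs=0.1)

    def test_censoring_aware_beats_naive(self, rng):
        # dwells tau=20 censored by bleach mean 70
        true = rng.exponential(20.0, 4000)
        bleach = rng.exponential(70.0, 4000)
        observed = np.minimum(true, bleach)
        censored = bleach < true
        dwells = [
            DwellRecord("m", 0.4, t, None, None, False, bool(c))
            for t, c in zip(observed, censored)
        ]
        est = fit_lifetime(dwells)
        naive = observed[~censored].mean()
        assert abs(est.tau - 20.0) / 20.0 < 0.10
        assert naive < 20.0  # directional: naive truncation underestimates

    def test_too_few_dwells_flagged(self):
        est = fit_lifetime([1.0, 2.0, 3.0], min_dwells=20)
        assert not est.reliable

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fit_lifetime([])


class TestFretHistogram:
    def _traces(self, level, n=40, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        return [
            FretTrace(rng.normal(level, noise, 200), 0.1, (0, 200), f"m{i}")
            for i in range(n)
        ]

    def test_single_peak_recovered(self):
        hist = fret_histogram(self._traces(0.7), n_peaks=1)
        assert hist.peaks[0]["mean"] == pytest.approx(0.70, abs=0.01)

    def test_two_equal_peaks(self):
        traces = self._traces(0.4, n=25, seed=1) + self._traces(0.7, n=25, seed=2)
        hist = fret_histogram(traces, n_peaks=2)
        means = [p["mean"] for p in hist.peaks]
        weights = [p["weight"] for p in hist.peaks]
        assert means[0] == pytest.approx(0.4, abs=0.02)
        assert means[1] == pytest.approx(0.7, abs=0.02)
        assert weights[0] == pytest.approx(0.5, abs=0.05)

    def test_ligand_free_single_zero_peak(self):
        hist = fret_histogram(self._traces(0.0, seed=3), n_peaks=1)
        assert abs(hist.peaks[0]["mean"]) < 0.01

    def test_empty_rejected(self):
        ft = FretTrace(np.full(10, np.nan), 0.1, (0, 10), "m")
        with pytest.raises(ValueError):
            fret_histogram([ft])


class TestTransitionDensity:
    def test_two_state_mass_only_off_diagonal_pair(self):
        labels = [0, 0, 0.4, 0.4, 0, 0.4, 0, 0]
        dwells = extract_dwells(path_from_labels(labels))
        hist, bins = transition_density(dwells, use_fitted_means=False)
        nz = np.nonzero(hist)
        centers = np.round(bins[:-1] + 0.01, 2)
        coords = {(centers[i], centers[j]) for i, j in zip(*nz)}
        assert coords == {(0.0, 0.4), (0.4, 0.0)}

    def test_single_dwell_traces_empty(self):
        dwells = extract_dwells(path_from_labels([0.4] * 5))
        hist, _ = transition_density(dwells)
        assert hist.sum() == 0

    def test_branched_scheme_reachable_transitions(self, branched_scheme, emission):
        cond = ExperimentCondition(100e-9, 0.1, 1000)
        ds = generate_dataset(branched_scheme, cond, emission, 80, seed=9)
        dwells = [
            d for p in truth_idealized_paths(ds) for d in extract_dwells(p)
        ]
        pairs = {
            (d.state, d.next_state)
            for d in dwells
            if not d.right_censored and d.next_state is not None
        }
        # dominant interconversions of the branched scheme must be present
        assert {(0.2, 0.4), (0.4, 0.2), (0.4, 0.7), (0.7, 0.4)} <= pairs
        # unbinding happens only from the relaxed partially bound state
        assert (0.4, 0.0) not in pairs and (0.7, 0.0) not in pairs


class TestClassifyTraces:
    def test_stable_trace(self):
        tf = classify_traces([path_from_labels([0, 0.4, 0.7, 0.7])])
        assert tf.fraction_stable == 1.0

    def test_excursion_trace(self):
        tf = classify_traces([path_from_labels([0, 0.7, 0.4, 0.7])])
        assert tf.fraction_excursion == 1.0

    def test_partial_only_trace(self):
        tf = classify_traces([path_from_labels([0, 0.4, 0.4, 0])])
        assert tf.fraction_partial_only == 1.0

    def test_never_bound_excluded(self):
        paths = [path_from_labels([0, 0, 0]), path_from_labels([0, 0.7, 0.7])]
        tf = classify_traces(paths)
        assert tf.n_bound == 1

    def test_fractions_sum_to_one_and_order_invariant(self):
        rng = np.random.default_rng(4)
        paths = []
        for i in range(30):
            labels = rng.choice([0.0, 0.4, 0.7], size=50)
            paths.append(path_from_labels(labels, mol=f"m{i}"))
        tf = classify_traces(paths)
        total = tf.fraction_stable + tf.fraction_excursion + tf.fraction_partial_only
        assert total == pytest.approx(1.0)
        tf_rev = classify_traces(paths[::-1])
        assert tf_rev.fraction_stable == tf.fraction_stable

    def test_no_bound_traces_rejected(self):
        with pytest.raises(ValueError):
            classify_traces([path_from_labels([0, 0, 0])])


class TestPostsynchronized:
    def test_fast_docking_reaches_top_band_quickly(self, emission):
        scheme = presets.two_step_scheme()  # k_dock = 10 s^-1
        cond = ExperimentCondition(30e-9, 0.1, 1000)
        ds = generate_dataset(scheme, cond, emission, 150, seed=14)
        paths = truth_idealized_paths(ds)
        fts = [
            FretTrace(p.canonical_per_frame, 0.1, (0, p.n_frames), p.molecule_id)
            for p in paths
        ]
        counts, bins, n = postsynchronized_histogram(fts, paths, n_frames=10)
        assert n > 10
        # within 2 frames of sync the 0.7 band dominates the bound density
        top = (bins[:-1] >= 0.55).nonzero()[0]
        mid = ((bins[:-1] >= 0.3) & (bins[:-1] < 0.55)).nonzero()[0]
        row = counts[5 + 2]  # pre_frames=5 -> sync+2
        assert row[top].sum() > row[mid].sum()

    def test_docking_dead_never_enters_top_band(self, contact_scheme, emission):
        cond = ExperimentCondition(30e-9, 0.1, 1000)
        ds = generate_dataset(contact_scheme, cond, emission, 60, seed=15)
        paths = truth_idealized_paths(ds)
        fts = [
            FretTrace(p.canonical_per_frame, 0.1, (0, p.n_frames), p.molecule_id)
            for p in paths
        ]
        counts, bins, _ = postsynchronized_histogram(fts, paths, n_frames=20)
        top = (bins[:-1] >= 0.55).nonzero()[0]
        assert counts[:, top].sum() == 0

    def test_deterministic_single_trace_equals_indicator(self):
        labels = np.array([0, 0, 0.4, 0.4, 0.7, 0.7, 0.7, 0.7])
        path = path_from_labels(labels)
        ft = FretTrace(labels.astype(float), 0.1, (0, labels.size), "m0")
        counts, bins, n = postsynchronized_histogram(
            [ft], [path], n_frames=4, pre_frames=2
        )
        assert n == 1
        assert counts.sum() == 6  # 2 pre + 4 post frames, all in range
        for row in counts:
            assert row.sum() == 1

    def test_no_qualifying_trace_rejected(self):
        path = path_from_labels([0.7, 0.7])
        ft = FretTrace(np.array([0.7, 0.7]), 0.1, (0, 2), "m0")
        with pytest.raises(ValueError):
            postsynchronized_histogram([ft], [path])


def test_dwell_table_and_first_binding_times():
    paths = [
        path_from_labels([0, 0, 0.4, 0.7], mol="a"),
        path_from_labels([0.7, 0.7], mol="b"),  # starts bound: no wait
        path_from_labels([0, 0, 0, 0], mol="c"),  # never binds
    ]
    waits = first_binding_times(paths)
    assert waits.tolist() == [pytest.approx(0.2)]
    df = dwell_table(d for p in paths for d in extract_dwells(p))
    assert {"molecule_id", "state", "duration"} <= set(df.columns)
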