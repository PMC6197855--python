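"""Ground-truthed synthetic smFRET datasets.

Trajectories are simulated exactly (Gillespie) from a kinetic scheme, then
rendered as two-channel frame-integrated intensity traces with Gaussian
channel noise, donor->acceptor bleed-through, and independent exponential
photobleaching of either fluorophore.  Frame values integrate the FRET
efficiency over the exposure window (time-weighted average), which is what
makes sub-frame sojourns appear as intermediate FRET values — the behaviour
responsible for missed short dwells at finite time resolution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kinetic_models import (
    ExperimentCondition,
    KineticScheme,
    build_generator,
)

__all__ = [
    "StatePath",
    "IntensityTrace",
    "EmissionModel",
    "BleachTimes",
    "SimulatedDataset",
    "gillespie_path",
    "apply_photobleaching",
    "render_trace",
    "footprint_detected",
    "generate_dataset",
]


@dataclass(frozen=True)
class StatePath:
    """A piecewise-constant state trajectory.

    Segment ``i`` occupies ``[event_times[i], event_times[i+1])`` in state
    ``states[i]``; the final segment extends to ``end_time``.
    """

    event_times: np.ndarray  # segment start times, event_times[0] == 0
    states: tuple[str, ...]
    end_time: float

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", t)
        object.__setattr__(self, "states", tuple(self.states))
        if t.size == 0 or t[0] != 0.0:
            raise ValueError("event_times must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("event_times must be strictly increasing")
        if len(self.states) != t.size:
            raise ValueError("one state per segment required")
        if self.end_time < t[-1]:
            raise ValueError("end_time must be >= last event time")

    def state_at(self, t: float) -> str:
        idx = int(np.searchsorted(self.event_times, t, side="right")) - 1
        return self.states[idx]

    def segments(self):
        """Yield (start, stop, state) triples covering [0, end_time]."""
        stops = np.append(self.event_times[1:], self.end_time)
        for start, stop, state in zip(self.event_times, stops, self.states):
            yield float(start), float(stop), state

    def dwell_times(self, state: str) -> np.ndarray:
        """Durations of completed sojourns in ``state`` (the final, truncated
        segment is excluded)."""
        durations = np.diff(self.event_times)
        return np.array(
            [d for d, s in zip(durations, self.states[:-1]) if s == state]
        )


@dataclass(frozen=True)
class EmissionModel:
    """Forward model parameters for rendering intensity traces."""

    total_intensity: float = 1000.0
    noise_sd: float = 50.0
    bleedthrough_fraction: float = 0.1
    baseline_donor: float = 0.0
    baseline_acceptor: float = 0.0
    donor_bleach_rate: float = 0.0
    acceptor_bleach_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.total_intensity < 0:
            raise ValueError("total_intensity must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.bleedthrough_fraction < 1:
            raise ValueError("bleedthrough_fraction must be in [0, 1)")
        if self.donor_bleach_rate < 0 or self.acceptor_bleach_rate < 0:
            raise ValueError("bleach rates must be >= 0")


@dataclass(frozen=True)
class BleachTimes:
    donor: float
    acceptor: float


@dataclass
class IntensityTrace:
    """Per-frame donor/acceptor intensities for one molecule."""

    donor: np.ndarray
    acceptor: np.ndarray
    frame_time: float
    molecule_id: str = "mol"
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape or self.donor.ndim != 1:
            raise ValueError("donor and acceptor must be 1-D and equal length")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be > 0")

    @property
    def n_frames(self) -> int:
        return self.donor.size


# ----------------------------------------------------------------- simulate
def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gillespie_path(
    scheme: KineticScheme,
    condition: ExperimentCondition,
    t_max: float,
    seed,
    start_state: str | None = None,
) -> StatePath:
    """Exact stochastic simulation of the scheme up to ``t_max`` seconds.

    Waiting times are exponential with the current state's total exit rate
    and the next state is chosen proportionally to the outgoing rates.  In
    flow mode (``condition.injection_time`` set) the clock is held in the
    starting state until injection, since all association steps require
    ligand.
    """
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    rng = _as_rng(seed)
    Q = build_generator(scheme, condition)
    labels = scheme.state_labels
    current = scheme.index(start_state if start_state else scheme.unbound_state)

    times = [0.0]
    states = [labels[current]]
    t = condition.injection_time or 0.0
    while t < t_max:
        exit_rate = -Q[current, current]
        if exit_rate <= 0:
            break  # absorbing: single remaining segment
        t += rng.exponential(1.0 / exit_rate)
        if t >= t_max:
            break
        probs = Q[current].copy()
        probs[current] = 0.0
        probs /= probs.sum()
        current = int(rng.choice(len(labels), p=probs))
        times.append(t)
        states.append(labels[current])
    return StatePath(np.array(times), tuple(states), float(t_max))


def apply_photobleaching(
    path: StatePath, model: EmissionModel, seed
) -> BleachTimes:
    """Draw independent exponential bleach times for donor and acceptor.

    A zero rate yields an infinite bleach time.  The path argument is part of
    the interface for symmetry with the renderer; bleaching is independent of
    the kinetic state.
    """
    del path
    rng = _as_rng(seed)
    donor = (
        rng.exponential(1.0 / model.donor_bleach_rate)
        if model.donor_bleach_rate > 0
        else math.inf
    )
    acceptor = (
        rng.exponential(1.0 / model.acceptor_bleach_rate)
        if model.acceptor_bleach_rate > 0
        else math.inf
    )
    return BleachTimes(donor=donor, acceptor=acceptor)


def _piecewise_frame_means(
    breaks: np.ndarray, values: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Frame-wise means of a piecewise-constant function.

    ``breaks`` (len m+1) delimit segments with ``values`` (len m); ``edges``
    are frame boundaries.  Uses the cumulative integral so cost is
    O(m + n_frames).
    """
    cum = np.concatenate([[0.0], np.cumsum(np.diff(breaks) * values)])
    integral = np.interp(edges, breaks, cum)
    return np.diff(integral) / np.diff(edges)


def _zero_after(
    breaks: np.ndarray, values: np.ndarray, t_cut: float
) -> tuple[np.ndarray, np.ndarray]:
    """Clamp a piecewise-constant function to zero for t >= t_cut."""
    end = breaks[-1]
    if t_cut >= end:
        return breaks, values
    keep = breaks[:-1] < t_cut
    return (
        np.concatenate([breaks[:-1][keep], [t_cut, end]]),
        np.concatenate([values[keep], [0.0]]),
    )


def render_trace(
    path: StatePath,
    scheme: KineticScheme,
    model: EmissionModel,
    condition: ExperimentCondition,
    seed,
    bleach: BleachTimes | None = None,
    molecule_id: str = "mol",
) -> IntensityTrace:
    """Render a state path as a noisy two-channel frame-integrated trace.

    Per frame: E is the time-weighted mean FRET level over the exposure
    (zero after acceptor bleach); donor = total*(alive - E~) + baseline +
    noise and acceptor = total*E~ + bleedthrough*donor_signal + baseline +
    noise, where ``alive`` is the within-frame fraction before donor bleach.
    """
    window = condition.duration
    if path.end_time < window - 1e-9:
        raise ValueError("path must cover the full acquisition window")
    rng = _as_rng(seed)
    if bleach is None:
        bleach = apply_photobleaching(path, model, rng)

    breaks = np.append(path.event_times, path.end_time)
    values = np.array([scheme.fret_of(s) for s in path.states])
    # acceptor bleach zeroes FRET from that instant on; donor bleach kills
    # all signal, so both the FRET and the total-emission series are masked
    db, ab = bleach.donor, bleach.acceptor
    e_breaks, e_values = _zero_after(breaks, values, ab)
    e_breaks, e_values = _zero_after(e_breaks, e_values, db)
    a_breaks, a_values = _zero_after(
        breaks, np.ones_like(values), db
    )

    edges = np.arange(condition.acquisition_frames + 1) * condition.frame_time
    e_alive = _piecewise_frame_means(e_breaks, e_values, edges)
    alive = _piecewise_frame_means(a_breaks, a_values, edges)

    donor_signal = model.total_intensity * (alive - e_alive)
    acceptor_signal = model.total_intensity * e_alive

    n = alive.size
    noise_d = rng.normal(0.0, model.noise_sd, n) if model.noise_sd else 0.0
    noise_a = rng.normal(0.0, model.noise_sd, n) if model.noise_sd else 0.0
    donor = donor_signal + model.baseline_donor + noise_d
    acceptor = (
        acceptor_signal
        + model.bleedthrough_fraction * donor_signal
        + model.baseline_acceptor
        + noise_a
    )
    truth = {
        "bleach_donor": db,
        "bleach_acceptor": ab,
        "path_times": path.event_times.tolist(),
        "path_states": list(path.states),
    }
    return IntensityTrace(donor, acceptor, condition.frame_time, molecule_id, truth)


def footprint_detected(
    path: StatePath,
    window: float,
    donor_bleach_time: float = math.inf,
    unbound_state: str = "U",
) -> bool:
    """True iff any bound (non-unbound) segment overlaps the observable
    window ``[0, min(window, donor bleach))``."""
    if window <= 0:
        raise ValueError("window must be > 0")
    horizon = min(window, donor_bleach_time)
    for start, stop, state in path.segments():
        if state == unbound_state:
            continue
        if start < horizon and stop > start:
            return True
        if start >= horizon:
            break
    return False


# ------------------------------------------------------------------ dataset
@dataclass
class SimulatedDataset:
    """Rendered traces plus the full ground-truth ledger."""

    traces: list[IntensityTrace]
    paths: list[StatePath]
    bleach_times: list[BleachTimes]
    scheme: KineticScheme
    condition: ExperimentCondition
    model: EmissionModel
    seed: int
    frame_state_truth: list[np.ndarray] = field(default_factory=list)

    @property
    def n_molecules(self) -> int:
        return len(self.traces)

    def ledger(self) -> dict:
        """JSON-serializable ground truth: per-molecule paths, bleach times
        and per-frame majority-state labels, plus the true rate constants."""
        return {
            "seed": self.seed,
            "scheme": self.scheme.to_dict(),
            "condition": {
                "ligand_concentration_M": self.condition.ligand_concentration,
                "frame_time_s": self.condition.frame_time,
                "acquisition_frames": self.condition.acquisition_frames,
                "injection_time_s": self.condition.injection_time,
            },
            "emission": {
                "total_intensity": self.model.total_intensity,
                "noise_sd": self.model.noise_sd,
                "bleedthrough_fraction": self.model.bleedthrough_fraction,
                "donor_bleach_rate": self.model.donor_bleach_rate,
                "acceptor_bleach_rate": self.model.acceptor_bleach_rate,
            },
            "molecules": [
                {
                    "molecule_id": tr.molecule_id,
                    "event_times": p.event_times.tolist(),
                    "states": list(p.states),
                    "bleach_donor": b.donor if math.isfinite(b.donor) else None,
                    "bleach_acceptor": (
                        b.acceptor if math.isfinite(b.acceptor) else None
                    ),
                    "frame_states": fs.tolist(),
                }
                for tr, p, b, fs in zip(
                    self.traces, self.paths, self.bleach_times, self.frame_state_truth
                )
            ],
        }

    def write_ledger(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.ledger(), fh)


def _frame_majority_states(
    path: StatePath, scheme: KineticScheme, condition: ExperimentCondition
) -> np.ndarray:
    """Index of the state occupying the largest share of each frame."""
    edges = np.arange(condition.acquisition_frames + 1) * condition.frame_time
    breaks = np.append(path.event_times, path.end_time)
    occ = np.zeros((scheme.n_states, condition.acquisition_frames))
    for k, label in enumerate(scheme.state_labels):
        indicator = np.array([1.0 if s == label else 0.0 for s in path.states])
        occ[k] = _piecewise_frame_means(breaks, indicator, edges)
    return occ.argmax(axis=0)


def truth_idealized_paths(dataset: "SimulatedDataset"):
    """Oracle idealized paths built from the ground-truth ledger.

    Frames up to the donor bleach (or acquisition end) carry the true
    majority-state canonical level.  Useful for testing downstream dwell and
    rate analysis independently of the HMM.
    """
    from .idealization import IdealizedPath

    scheme = dataset.scheme
    cond = dataset.condition
    levels = np.asarray(scheme.fret_levels)
    paths = []
    for trace, fs, bleach in zip(
        dataset.traces, dataset.frame_state_truth, dataset.bleach_times
    ):
        n = min(
            cond.acquisition_frames,
            int(min(bleach.donor, cond.duration) / cond.frame_time),
        )
        n = max(n, 1)
        states = fs[:n]
        paths.append(
            IdealizedPath(
                state_per_frame=states,
                fitted_means=levels.copy(),
                fitted_sds=np.full(levels.size, 1e-3),
                n_states=levels.size,
                model_score=float("nan"),
                frame_time=cond.frame_time,
                molecule_id=trace.molecule_id,
                right_censored=bleach.donor >= cond.duration,
                canonical_per_frame=levels[states].astype(float),
                assignment={i: float(lv) for i, lv in enumerate(levels)},
            )
        )
    return paths


def generate_dataset(
    scheme: KineticScheme,
    condition: ExperimentCondition,
    model: EmissionModel,
    n_molecules: int,
    seed: int,
    start_state: str | None = None,
) -> SimulatedDataset:
    """Simulate ``n_molecules`` independent molecules under one condition.

    Each molecule consumes a deterministic substream of the master seed, so
    datasets are reproducible and insensitive to generation order.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_molecules)
    traces, paths, bleaches, frame_truth = [], [], [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        path = gillespie_path(scheme, condition, condition.duration, rng, start_state)
        bleach = apply_photobleaching(path, model, rng)
        trace = render_trace(
            path, scheme, model, condition, rng, bleach, molecule_id=f"mol{i:04d}"
        )
        traces.append(trace)
        paths.append(path)
        bleaches.append(bleach)
        frame_truth.append(_frame_majority_states(path, scheme, condition))
    return SimulatedDataset(
        traces, paths, bleaches, scheme, condition, model, seed, frame_truth
    )
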