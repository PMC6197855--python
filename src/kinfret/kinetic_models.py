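"""Continuous-time Markov schemes for multi-step ligand binding.

A :class:`KineticScheme` holds a labelled state space, a mean FRET efficiency
per state, and directed rate constants between states.  Association steps are
stored as second-order rate constants (M^-1 s^-1) and are converted to
pseudo-first-order rates at generator-build time using the ligand
concentration of an :class:`ExperimentCondition`, so the same scheme serves
steady-state and flow-injection experiments.

Photobleaching is deliberately *not* a state of the scheme: it is an
independent censoring process handled by the trace simulator, which keeps the
analytic solutions below (matrix exponential occupancy, mean exit and
first-passage times) usable as oracles for the stochastic simulator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm, null_space

__all__ = [
    "Rate",
    "KineticScheme",
    "ExperimentCondition",
    "build_generator",
    "occupancy_at_time",
    "mean_exit_time",
    "mean_first_passage_time",
    "stationary_distribution",
    "load_config",
]


@dataclass(frozen=True)
class Rate:
    """A directed rate constant.

    ``order == 1`` means a first-order rate in s^-1; ``order == 2`` means a
    second-order rate in M^-1 s^-1 that is multiplied by the ligand
    concentration when the generator matrix is built.
    """

    value: float
    order: int = 1

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"rate constant must be >= 0, got {self.value}")
        if self.order not in (1, 2):
            raise ValueError(f"rate order must be 1 or 2, got {self.order}")

    def first_order(self, concentration: float) -> float:
        """Pseudo-first-order rate in s^-1 at the given ligand concentration."""
        if self.order == 2:
            return self.value * concentration
        return self.value


@dataclass(frozen=True)
class ExperimentCondition:
    """Acquisition metadata for one measurement.

    Parameters
    ----------
    ligand_concentration : float
        Free ligand concentration in M.
    frame_time : float
        Camera exposure per frame in seconds.
    acquisition_frames : int
        Number of frames recorded.
    injection_time : float or None
        For flow experiments, time (s) at which ligand is injected; before
        this the effective ligand concentration is zero.  ``None`` means the
        ligand is present from the start (steady state).
    """

    ligand_concentration: float
    frame_time: float = 0.1
    acquisition_frames: int = 1500
    injection_time: float | None = None

    def __post_init__(self) -> None:
        if self.ligand_concentration < 0:
            raise ValueError("ligand_concentration must be >= 0")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be > 0")
        if self.acquisition_frames < 1:
            raise ValueError("acquisition_frames must be >= 1")
        if self.injection_time is not None and self.injection_time < 0:
            raise ValueError("injection_time must be >= 0")

    @property
    def duration(self) -> float:
        """Total acquisition time in seconds."""
        return self.frame_time * self.acquisition_frames


def _normalize_rate_key(key) -> tuple[str, str]:
    if isinstance(key, str):
        src, _, dst = key.partition("->")
        if not dst:
            raise ValueError(f"rate key {key!r} is not of the form 'A->B'")
        return src.strip(), dst.strip()
    src, dst = key
    return str(src), str(dst)


def _coerce_rate(value) -> Rate:
    if isinstance(value, Rate):
        return value
    if isinstance(value, Mapping):
        return Rate(float(value["value"]), int(value.get("order", 1)))
    return Rate(float(value))


@dataclass(frozen=True)
class KineticScheme:
    """Labelled state space with per-state FRET levels and a rate matrix."""

    state_labels: tuple[str, ...]
    fret_levels: tuple[float, ...]
    rates: dict[tuple[str, str], Rate] = field(default_factory=dict)
    photobleach_rate: float = 0.0

    def __init__(self, state_labels, fret_levels, rates=None, photobleach_rate=0.0):
        labels = tuple(str(s) for s in state_labels)
        levels = tuple(float(e) for e in fret_levels)
        if len(labels) != len(levels):
            raise ValueError("state_labels and fret_levels must have equal length")
        if len(set(labels)) != len(labels):
            raise ValueError("state labels must be unique")
        for e in levels:
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"FRET level {e} outside [0, 1]")
        norm: dict[tuple[str, str], Rate] = {}
        for key, val in (rates or {}).items():
            src, dst = _normalize_rate_key(key)
            if src not in labels or dst not in labels:
                raise ValueError(f"rate {src}->{dst} references unknown state")
            if src == dst:
                raise ValueError("self-transitions are not allowed")
            norm[(src, dst)] = _coerce_rate(val)
        if photobleach_rate < 0:
            raise ValueError("photobleach_rate must be >= 0")
        object.__setattr__(self, "state_labels", labels)
        object.__setattr__(self, "fret_levels", levels)
        object.__setattr__(self, "rates", norm)
        object.__setattr__(self, "photobleach_rate", float(photobleach_rate))

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def index(self, label: str) -> int:
        return self.state_labels.index(label)

    def fret_of(self, label: str) -> float:
        return self.fret_levels[self.index(label)]

    @property
    def unbound_state(self) -> str:
        """The first state whose FRET level is 0 (ligand-free by convention)."""
        for label, e in zip(self.state_labels, self.fret_levels):
            if e == 0.0:
                return label
        raise ValueError("scheme has no zero-FRET (unbound) state")

    def rate(self, src: str, dst: str) -> Rate:
        return self.rates.get((src, dst), Rate(0.0))

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return {
            "states": list(self.state_labels),
            "fret_levels": list(self.fret_levels),
            "rates": {
                f"{s}->{d}": {"value": r.value, "order": r.order}
                for (s, d), r in sorted(self.rates.items())
            },
            "photobleach_rate": self.photobleach_rate,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "KineticScheme":
        return cls(
            d["states"],
            d["fret_levels"],
            d.get("rates", {}),
            d.get("photobleach_rate", 0.0),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "KineticScheme":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def load_config(source) -> tuple[KineticScheme, ExperimentCondition]:
    """Load a combined scheme + condition JSON config.

    ``source`` may be a path or an already-parsed mapping.  Recognized keys
    beyond the scheme fields: ``ligand_concentration_M``, ``frame_time_s``,
    ``acquisition_frames``, ``injection_time_s``.
    """
    if isinstance(source, Mapping):
        d = source
    else:
        with open(source) as fh:
            d = json.load(fh)
    scheme = KineticScheme.from_dict(d)
    condition = ExperimentCondition(
        ligand_concentration=float(d.get("ligand_concentration_M", 0.0)),
        frame_time=float(d.get("frame_time_s", 0.1)),
        acquisition_frames=int(d.get("acquisition_frames", 1500)),
        injection_time=d.get("injection_time_s"),
    )
    return scheme, condition


# --------------------------------------------------------------------- math
def build_generator(
    scheme: KineticScheme, condition: ExperimentCondition
) -> np.ndarray:
    """Build the CTMC generator matrix over ``scheme.state_labels``.

    Off-diagonal entry (i, j) is the first-order rate i -> j in s^-1, with
    second-order (association) entries multiplied by the ligand
    concentration.  Rows sum to zero.
    """
    n = scheme.n_states
    Q = np.zeros((n, n))
    for (src, dst), rate in scheme.rates.items():
        Q[scheme.index(src), scheme.index(dst)] = rate.first_order(
            condition.ligand_concentration
        )
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def occupancy_at_time(
    generator: np.ndarray, initial: Sequence[float], t: float
) -> np.ndarray:
    """State distribution ``initial . exp(Q t)``.

    Raises ``ValueError`` for ``t < 0`` or a non-stochastic initial vector.
    """
    p0 = np.asarray(initial, dtype=float)
    if t < 0:
        raise ValueError("t must be >= 0")
    if p0.ndim != 1 or p0.shape[0] != generator.shape[0]:
        raise ValueError("initial distribution has wrong length")
    if np.any(p0 < 0) or not math.isclose(p0.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("initial vector is not a probability distribution")
    if t == 0:
        return p0.copy()
    p = p0 @ expm(generator * t)
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def mean_exit_time(generator: np.ndarray, state: int) -> float:
    """Mean sojourn time of ``state``: 1 / (total exit rate).

    Returns ``inf`` for an absorbing state.
    """
    exit_rate = -generator[state, state]
    if exit_rate <= 0:
        return math.inf
    return 1.0 / exit_rate

def mean_first_passage_time(generator: np.ndarray, start: int, target: int) -> float:
    """Expected time to first reach ``target`` from ``start``.

    Solves Q_TT tau = -1 over the transient set (all states except the
    target).  Returns ``inf`` if the target is unreachable.
    """
    n = generator.shape[0]
    transient = [i for i in range(n) if i != target]
    Qtt = generator[np.ix_(transient, transient)]
    try:
        tau = np.linalg.solve(Qtt, -np.ones(len(transient)))
    except np.linalg.LinAlgError:
        return math.inf
    if np.any(tau < 0):
        return math.inf
    return float(tau[transient.index(start)])


def stationary_distribution(generator: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible generator (pi Q = 0)."""
    ns = null_space(generator.T)
    if ns.shape[1] != 1:
        raise ValueError("generator is not irreducible; stationary law not unique")
    pi = ns[:, 0]
    pi = np.abs(pi)
    return pi / pi.sum()
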