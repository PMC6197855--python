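"""Dwell times, lifetime fits, histograms and trace typing.

Dwells are maximal runs of identical canonical labels in an idealized path.
The first and last run of every trace are censored (by the start of the
acquisition and by photobleaching or the end of the acquisition).  The
default lifetime estimator is censoring-aware exponential maximum
likelihood; a histogram least-squares fit with offset is available for
parity with legacy analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize
from sklearn.mixture import GaussianMixture

from .idealization import IdealizedPath

__all__ = [
    "DwellRecord",
    "LifetimeEstimate",
    "extract_dwells",
    "fit_lifetime",
    "fret_histogram",
    "transition_density",
    "classify_traces",
    "postsynchronized_histogram",
    "dwell_table",
    "first_binding_times",
]


@dataclass(frozen=True)
class DwellRecord:
    """One sojourn in one canonical state."""

    molecule_id: str
    state: float
    duration: float
    prev_state: float | None
    next_state: float | None
    left_censored: bool
    right_censored: bool
    state_mean: float = math.nan  # fitted emission mean of the model state


@dataclass
class LifetimeEstimate:
    """An exponential (or bi-exponential) lifetime with uncertainty."""

    tau: float
    uncertainty: float
    n_dwells: int
    model: str = "single"  # single | double
    method: str = "mle"  # mle | histogram | mean
    components: tuple[float, float, float, float] | None = None  # t1, A1, t2, A2
    reliable: bool = True

    @property
    def weighted_average(self) -> float:
        """Population-weighted mean lifetime (A1*t1 + A2*t2) / (A1 + A2)."""
        if self.components is None:
            return self.tau
        t1, a1, t2, a2 = self.components
        return (a1 * t1 + a2 * t2) / (a1 + a2)


def extract_dwells(
    path: IdealizedPath, merge: dict[float, float] | None = None
) -> list[DwellRecord]:
    """Split an idealized path into maximal constant-state runs.

    ``merge`` optionally maps canonical labels onto pooled labels before run
    extraction (e.g. treating two partially bound conformations as one bound
    class).  Leading/trailing unassigned (NaN) frames are dropped; interior
    NaN frames inherit the previous label.
    """
    if path.canonical_per_frame is None:
        raise ValueError("path has no canonical labels; run map_to_canonical first")
    labels = path.canonical_per_frame.copy()
    finite = np.isfinite(labels)
    if not finite.any():
        return []
    lo, hi = np.nonzero(finite)[0][[0, -1]]
    labels = labels[lo : hi + 1]
    bad = ~np.isfinite(labels)
    if bad.any():
        idx = np.arange(labels.size)
        labels = labels[np.maximum.accumulate(np.where(~bad, idx, 0))]
    if merge:
        labels = np.array([merge.get(x, x) for x in labels])

    means = path.frame_means()[lo : hi + 1]
    changes = np.nonzero(np.diff(labels) != 0)[0] + 1
    starts = np.concatenate([[0], changes])
    stops = np.concatenate([changes, [labels.size]])
    dwells = []
    for i, (a, b) in enumerate(zip(starts, stops)):
        dwells.append(
            DwellRecord(
                molecule_id=path.molecule_id,
                state=float(labels[a]),
                duration=(b - a) * path.frame_time,
                prev_state=float(labels[starts[i - 1]]) if i > 0 else None,
                next_state=float(labels[stops[i]]) if i < len(starts) - 1 else None,
                left_censored=i == 0,
                right_censored=i == len(starts) - 1,
                state_mean=float(np.mean(means[a:b])),
            )
        )
    return dwells


def _censored_mle(
    durations: np.ndarray, uncensored: np.ndarray, resolution: float | None
) -> tuple[float, float, int]:
    """Exponential MLE under right censoring: tau = sum(t) / n_uncensored.

    ``resolution`` optionally corrects for the detection floor of frame-
    quantized dwells (observed dwells are truncated below ~resolution, so
    the memoryless shift t - resolution restores the unconditional mean).
    """
    n_unc = int(uncensored.sum())
    if n_unc == 0:
        return math.nan, math.nan, 0
    d = durations - (resolution or 0.0)
    tau = float(np.sum(np.clip(d, 0.0, None)) / n_unc)
    return tau, tau / math.sqrt(n_unc), n_unc


def _double_mle(
    durations: np.ndarray, uncensored: np.ndarray, resolution: float | None
) -> tuple[float, float, float] | None:
    """Right-censored two-component exponential mixture MLE.

    Returns (w1, t1, t2) or None if the optimizer fails.
    """
    d = np.clip(durations - (resolution or 0.0), 1e-9, None)
    mean = float(np.mean(d))

    def nll(params):
        logit_w, log_t1, log_t2 = params
        w = 1.0 / (1.0 + np.exp(-logit_w))
        t1, t2 = np.exp(log_t1), np.exp(log_t2)
        pdf = w / t1 * np.exp(-d / t1) + (1 - w) / t2 * np.exp(-d / t2)
        sf = w * np.exp(-d / t1) + (1 - w) * np.exp(-d / t2)
        ll = np.where(uncensored, np.log(pdf + 1e-300), np.log(sf + 1e-300))
        return -float(np.sum(ll))

    x0 = np.array([0.0, math.log(mean * 0.5), math.log(mean * 2.0)])
    res = minimize(nll, x0, method="Nelder-Mead", options={"maxiter": 2000})
    if not res.success:
        return None
    w = 1.0 / (1.0 + math.exp(-res.x[0]))
    t1, t2 = math.exp(res.x[1]), math.exp(res.x[2])
    if t1 > t2:
        t1, t2, w = t2, t1, 1.0 - w
    return w, t1, t2


def _histogram_fit(durations: np.ndarray) -> tuple[float, float]:
    """Legacy estimator: least-squares A*exp(-t/tau) + y0 on the dwell-time
    histogram (uncensored dwells only)."""
    n_bins = max(8, int(math.sqrt(durations.size)))
    counts, edges = np.histogram(durations, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def decay(t, amp, tau, y0):
        return amp * np.exp(-t / tau) + y0

    p0 = (counts.max(), max(float(np.mean(durations)), 1e-3), 0.0)
    popt, pcov = curve_fit(decay, centers, counts, p0=p0, maxfev=10000)
    tau = abs(popt[1])
    err = math.sqrt(abs(pcov[1][1])) if np.isfinite(pcov[1][1]) else math.nan
    return tau, err


def fit_lifetime(
    dwells: Iterable[DwellRecord] | Sequence[float],
    model: str = "single",
    method: str = "mle",
    min_dwells: int = 20,
    resolution: float | None = None,
) -> LifetimeEstimate:
    """Fit an exponential lifetime to a set of dwells.

    Accepts either :class:`DwellRecord` objects (censoring flags honoured)
    or plain durations (treated as uncensored).  ``method='histogram'``
    reproduces the binned least-squares fit with offset; the default
    censoring-aware MLE uses all dwells.  For ``model='double'`` a two-
    component mixture is fitted and the population-weighted mean lifetime is
    reported, falling back to the single fit when the mixture does not
    converge.
    """
    items = list(dwells)
    if items and isinstance(items[0], DwellRecord):
        durations = np.array([d.duration for d in items])
        uncensored = np.array([not d.right_censored for d in items])
    else:
        durations = np.asarray(items, dtype=float)
        uncensored = np.ones(durations.size, dtype=bool)
    if durations.size == 0:
        raise ValueError("no dwells to fit")
    reliable = int(uncensored.sum()) >= min_dwells

    if model == "double":
        fit = _double_mle(durations, uncensored, resolution)
        if fit is not None:
            w, t1, t2 = fit
            est = LifetimeEstimate(
                tau=w * t1 + (1 - w) * t2,
                uncertainty=(w * t1 + (1 - w) * t2) / math.sqrt(max(uncensored.sum(), 1)),
                n_dwells=durations.size,
                model="double",
                method="mle",
                components=(t1, w, t2, 1.0 - w),
                reliable=reliable,
            )
            return est
        # fall through to single with a warning flag
        model = "single"

    if method == "histogram":
        tau, err = _histogram_fit(durations[uncensored])
        n_unc = int(uncensored.sum())
    else:
        tau, err, n_unc = _censored_mle(durations, uncensored, resolution)
    return LifetimeEstimate(
        tau=tau,
        uncertainty=err,
        n_dwells=int(durations.size),
        model="single",
        method=method,
        reliable=bool(reliable and np.isfinite(tau)),
    )


# ------------------------------------------------------------- histograms
@dataclass
class FretHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    peaks: list[dict]  # {"mean", "sd", "weight"} sorted by mean


def fret_histogram(
    fret_traces,
    bins=None,
    n_peaks: int | None = None,
    seed: int = 0,
) -> FretHistogram:
    """Pooled frame histogram with Gaussian peak fits.

    ``n_peaks`` fixes the mixture component count (default 1); peaks are
    fitted on the pooled per-frame efficiencies by a Gaussian mixture.
    """
    pooled = np.concatenate([ft.valid_efficiency for ft in fret_traces])
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise ValueError("no valid frames to histogram")
    if bins is None:
        bins = np.arange(-0.2, 1.21, 0.02)
    counts, edges = np.histogram(pooled, bins=bins)
    k = n_peaks or 1
    gmm = GaussianMixture(n_components=k, random_state=seed, n_init=3)
    gmm.fit(pooled[:, None])
    order = np.argsort(gmm.means_.ravel())
    peaks = [
        {
            "mean": float(gmm.means_.ravel()[i]),
            "sd": float(np.sqrt(gmm.covariances_.reshape(-1)[i])),
            "weight": float(gmm.weights_[i]),
        }
        for i in order
    ]
    return FretHistogram(edges, counts, peaks)


def transition_density(
    dwells: Iterable[DwellRecord],
    bins=None,
    use_fitted_means: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """2-D histogram of (E before, E after) over all uncensored transitions.

    Transitions are dwell boundaries where the following dwell exists (the
    dwell is not right-censored).  Uses fitted emission means when available
    so the plot reflects the data, not the canonical grid.
    """
    pre, post = [], []
    items = list(dwells)
    by_mol: dict[str, list[DwellRecord]] = {}
    for d in items:
        by_mol.setdefault(d.molecule_id, []).append(d)
    for mol_dwells in by_mol.values():
        for a, b in zip(mol_dwells[:-1], mol_dwells[1:]):
            e_a = a.state_mean if use_fitted_means and np.isfinite(a.state_mean) else a.state
            e_b = b.state_mean if use_fitted_means and np.isfinite(b.state_mean) else b.state
            pre.append(e_a)
            post.append(e_b)
    if bins is None:
        # offset grid so canonical levels fall on bin centers
        bins = np.arange(-0.11, 1.02, 0.02)
    hist, _, _ = np.histogram2d(pre, post, bins=[bins, bins])
    return hist, np.asarray(bins)


# ---------------------------------------------------------------- typing
@dataclass
class TraceTypeFractions:
    """Partition of bound traces into the three qualitative types."""

    n_bound: int
    fraction_stable: float  # reaches the full level, never back-steps
    fraction_excursion: float  # reaches the full level with >=1 back-step
    fraction_partial_only: float  # samples partial level(s) only
    se_stable: float
    se_excursion: float
    se_partial_only: float


def classify_traces(
    paths: Iterable[IdealizedPath],
    full_level: float = 0.7,
    unbound_level: float = 0.0,
) -> TraceTypeFractions:
    """Classify bound traces by their sampling of the fully bound level.

    Traces that never leave the unbound level are excluded from the
    denominator.  Standard errors are binomial.
    """
    n = {"stable": 0, "excursion": 0, "partial": 0}
    for path in paths:
        labels = path.canonical_per_frame
        if labels is None:
            raise ValueError("paths must carry canonical labels")
        labels = labels[np.isfinite(labels)]
        bound = labels[labels != unbound_level]
        if bound.size == 0:
            continue
        reaches_full = np.any(labels == full_level)
        if not reaches_full:
            n["partial"] += 1
            continue
        first_full = int(np.argmax(labels == full_level))
        after = labels[first_full:]
        back = np.any((after != full_level) & (after != unbound_level))
        n["excursion" if back else "stable"] += 1
    total = sum(n.values())
    if total == 0:
        raise ValueError("no bound traces to classify")

    def frac_se(count):
        p = count / total
        return p, math.sqrt(p * (1 - p) / total)

    fs, ses = frac_se(n["stable"])
    fe, see = frac_se(n["excursion"])
    fp, sep_ = frac_se(n["partial"])
    return TraceTypeFractions(total, fs, fe, fp, ses, see, sep_)


def postsynchronized_histogram(
    fret_traces,
    paths: Sequence[IdealizedPath],
    n_frames: int = 50,
    pre_frames: int = 5,
    fret_bins=None,
    unbound_level: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Time-evolved FRET density aligned at the first binding transition.

    Each qualifying trace (at least one unbound frame followed by a bound
    frame) contributes its raw efficiencies from ``pre_frames`` before to
    ``n_frames`` after the synchronization point.  Returns (density array of
    shape [n_time, n_fret_bins], fret bin edges, number of traces).
    """
    if fret_bins is None:
        fret_bins = np.arange(-0.2, 1.21, 0.05)
    fret_bins = np.asarray(fret_bins)
    n_time = pre_frames + n_frames
    counts = np.zeros((n_time, fret_bins.size - 1))
    n_traces = 0
    for ft, path in zip(fret_traces, paths):
        labels = path.canonical_per_frame
        if labels is None or labels.size == 0:
            continue
        finite = np.isfinite(labels)
        is_bound = finite & (labels != unbound_level)
        was_unbound = np.concatenate([[False], (labels == unbound_level)[:-1]])
        sync_candidates = np.nonzero(is_bound & was_unbound)[0]
        if sync_candidates.size == 0:
            continue
        sync = int(sync_candidates[0])
        e = ft.valid_efficiency
        n_traces += 1
        for row, frame in enumerate(range(sync - pre_frames, sync + n_frames)):
            if 0 <= frame < e.size and np.isfinite(e[frame]):
                b = int(np.searchsorted(fret_bins, e[frame], side="right")) - 1
                if 0 <= b < counts.shape[1]:
                    counts[row, b] += 1
    if n_traces == 0:
        raise ValueError("no trace satisfies the synchronization rule")
    return counts, fret_bins, n_traces


# ----------------------------------------------------------------- tables
def dwell_table(dwells: Iterable[DwellRecord]) -> pd.DataFrame:
    """One row per dwell, all fields (for delimited-text export)."""
    return pd.DataFrame([vars(d) for d in dwells])


def first_binding_times(
    paths: Iterable[IdealizedPath], unbound_level: float = 0.0
) -> np.ndarray:
    """Waiting time (s) from trace start to the first departure from the
    unbound level, for traces that start unbound and eventually bind."""
    waits = []
    for path in paths:
        labels = path.canonical_per_frame
        if labels is None:
            continue
        finite = np.isfinite(labels)
        if not finite.any():
            continue
        labels = labels[finite]
        if labels[0] != unbound_level:
            continue
        bound = np.nonzero(labels != unbound_level)[0]
        if bound.size == 0:
            continue
        waits.append(bound[0] * path.frame_time)
    return np.asarray(waits)
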