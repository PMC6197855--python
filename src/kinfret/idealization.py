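"""Hidden-Markov idealization of FRET traces.

Each trace is fitted independently with Gaussian-emission HMMs over a range
of candidate state counts; the count is chosen by the Bayesian information
criterion and the most likely path is obtained by Viterbi decoding.  Fitted
emission means are then snapped onto the canonical FRET levels of the
experiment, merging model states that land on the same level.

This is a deliberate stand-in for variational-Bayes idealization: same
contract (per-trace fit, automatic state-count selection, hard state path),
fewer free hyperparameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM

# per-trace EM on short traces routinely stops on the iteration cap; the
# monitor's warning is noise at this granularity
logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

__all__ = ["IdealizedPath", "fit_hmm", "map_to_canonical"]

#: Fitted means farther than this from every canonical level are flagged
#: unassigned instead of being snapped.
DEFAULT_ASSIGNMENT_CUTOFF = 0.15


@dataclass
class IdealizedPath:
    """Discrete state labels per analyzable frame of one FRET trace.

    ``state_per_frame`` indexes into ``fitted_means``/``fitted_sds``.  After
    :func:`map_to_canonical`, ``canonical_per_frame`` holds the canonical
    FRET level of each frame (NaN where the fitted state could not be
    assigned) and ``assignment`` maps model-state index -> canonical level.
    """

    state_per_frame: np.ndarray
    fitted_means: np.ndarray
    fitted_sds: np.ndarray
    n_states: int
    model_score: float
    frame_time: float
    start_frame: int = 0
    molecule_id: str = "mol"
    right_censored: bool = True
    canonical_per_frame: np.ndarray | None = None
    assignment: dict[int, float] = field(default_factory=dict)
    unassigned: tuple[int, ...] = ()

    @property
    def n_frames(self) -> int:
        return self.state_per_frame.size

    def frame_means(self) -> np.ndarray:
        """Fitted emission mean of each frame's state."""
        return self.fitted_means[self.state_per_frame]


def _single_state_path(e: np.ndarray, fret, molecule_id, right_censored, start):
    return IdealizedPath(
        state_per_frame=np.zeros(e.size, dtype=int),
        fitted_means=np.array([float(np.mean(e))]),
        fitted_sds=np.array([max(float(np.std(e)), 1e-6)]),
        n_states=1,
        model_score=float("nan"),
        frame_time=fret.frame_time,
        start_frame=start,
        molecule_id=molecule_id,
        right_censored=right_censored,
    )


def fit_hmm(
    fret,
    candidate_state_counts=(1, 2, 3, 4),
    seed: int = 0,
    n_restarts: int = 1,
    n_iter: int = 100,
    min_frames: int = 10,
    init_means=None,
) -> IdealizedPath:
    """Idealize one FRET trace with a Gaussian-emission HMM.

    For each candidate state count an HMM is trained by expectation-
    maximization (with ``n_restarts`` differently seeded restarts); the best
    count is chosen by BIC and the path by Viterbi decoding.  Degenerate
    traces (no variance) yield a single-state path.  Deterministic for a
    fixed ``seed``.

    ``init_means`` optionally lists expected emission levels; every
    candidate whose state count does not exceed ``len(init_means)`` gets one
    extra EM run seeded from each size-k subset midpoint-free combination of
    those levels, which protects against k-means merging nearby levels.
    """
    lo, hi = fret.valid_range
    e = fret.efficiency[lo:hi]
    # interior invalid frames: carry the previous finite value so the frame
    # grid stays contiguous for dwell bookkeeping
    if np.isnan(e).any():
        idx = np.arange(e.size)
        finite = np.isfinite(e)
        e = np.interp(idx, idx[finite], e[finite])
    if e.size < min_frames:
        raise ValueError(
            f"trace {fret.molecule_id}: only {e.size} valid frames (< {min_frames})"
        )
    if float(np.std(e)) < 1e-9:
        return _single_state_path(e, fret, fret.molecule_id, fret.right_censored, lo)

    X = e[:, None]
    rng = np.random.default_rng(seed)
    best = None  # (bic, model)
    for k in candidate_state_counts:
        if k > len(np.unique(np.round(e, 9))) or k > e.size // 2:
            continue
        starts: list[np.ndarray | None] = [None] * max(1, n_restarts)
        if init_means is not None and k <= len(init_means):
            from itertools import combinations

            starts.extend(
                np.asarray(c, dtype=float)
                for c in combinations(sorted(init_means), k)
            )
        for mu0 in starts:
            model = GaussianHMM(
                n_components=k,
                covariance_type="diag",
                n_iter=n_iter,
                random_state=int(rng.integers(2**31 - 1)),
                min_covar=1e-5,
                init_params="stc" if mu0 is not None else "stmc",
            )
            if mu0 is not None:
                model.means_ = mu0[:, None]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(X)
                    bic = model.bic(X)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if np.isfinite(bic) and (best is None or bic < best[0]):
                best = (bic, model)
    if best is None:
        return _single_state_path(e, fret, fret.molecule_id, fret.right_censored, lo)

    bic, model = best
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, states = model.decode(X)
    means = model.means_.ravel().copy()
    sds = np.sqrt(model.covars_.reshape(-1)).copy()
    # drop states never visited by the decoded path
    used = np.unique(states)
    remap = {old: new for new, old in enumerate(used)}
    states = np.array([remap[s] for s in states], dtype=int)
    return IdealizedPath(
        state_per_frame=states,
        fitted_means=means[used],
        fitted_sds=np.maximum(sds[used], 1e-6),
        n_states=used.size,
        model_score=float(bic),
        frame_time=fret.frame_time,
        start_frame=lo,
        molecule_id=fret.molecule_id,
        right_censored=fret.right_censored,
    )


def map_to_canonical(
    path: IdealizedPath,
    canonical_levels,
    cutoff: float = DEFAULT_ASSIGNMENT_CUTOFF,
) -> IdealizedPath:
    """Assign each fitted emission mean to the nearest canonical FRET level.

    Ties break toward the lower level (conservative against overcalling the
    bound state).  Fitted means farther than ``cutoff`` from every level are
    flagged unassigned and their frames set to NaN.  States mapping to the
    same level are merged implicitly by sharing a label.
    """
    levels = np.asarray(sorted(canonical_levels), dtype=float)
    if levels.size != np.unique(levels).size:
        raise ValueError("canonical levels must be distinct")
    assignment: dict[int, float] = {}
    unassigned: list[int] = []
    for i, mu in enumerate(path.fitted_means):
        dist = np.abs(levels - mu)
        best = float(np.min(dist))
        if best > cutoff + 1e-9:
            unassigned.append(i)
            continue
        # ties (within float fuzz) break toward the lower level
        tied = np.nonzero(dist <= best + 1e-9)[0]
        assignment[i] = float(levels[int(tied[0])])
    canonical = np.array(
        [assignment.get(s, np.nan) for s in path.state_per_frame], dtype=float
    )
    return IdealizedPath(
        state_per_frame=path.state_per_frame,
        fitted_means=path.fitted_means,
        fitted_sds=path.fitted_sds,
        n_states=path.n_states,
        model_score=path.model_score,
        frame_time=path.frame_time,
        start_frame=path.start_frame,
        molecule_id=path.molecule_id,
        right_censored=path.right_censored,
        canonical_per_frame=canonical,
        assignment=assignment,
        unassigned=tuple(unassigned),
    )
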