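"""Raw two-channel traces -> FRET-efficiency time series.

Covers bleed-through/baseline correction, per-frame FRET computation with an
intensity floor, photobleach truncation by change-point detection on the
total intensity, trace selection emulating acceptor maximum-intensity-
projection spot picking, and the two-column-per-molecule delimited text
format (donor column then acceptor column for each molecule).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synthetic_data import IntensityTrace

__all__ = [
    "FretTrace",
    "SelectionResult",
    "correct_channels",
    "compute_fret",
    "truncate_at_photobleach",
    "select_traces",
    "write_traces",
    "read_traces",
    "qc_table",
]

#: Fraction of the pre-bleach median total intensity below which a frame is
#: considered dark (no analyzable signal).
INTENSITY_FLOOR_FRACTION = 0.1


@dataclass
class FretTrace:
    """Per-frame FRET efficiency with an analyzable frame range.

    ``efficiency`` holds NaN at frames whose total intensity fell below the
    floor.  ``valid_range`` is a half-open frame interval; after photobleach
    truncation its end marks the bleach point and ``right_censored`` records
    whether the trace ended by bleaching (False) or by the end of the
    acquisition (True).
    """

    efficiency: np.ndarray
    frame_time: float
    valid_range: tuple[int, int]
    molecule_id: str = "mol"
    right_censored: bool = True

    def __post_init__(self) -> None:
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        lo, hi = self.valid_range
        if not (0 <= lo <= hi <= self.efficiency.size):
            raise ValueError("valid_range outside trace bounds")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be > 0")

    @property
    def n_valid(self) -> int:
        lo, hi = self.valid_range
        return hi - lo

    @property
    def length_s(self) -> float:
        """Analyzable trace length in seconds (for trace-lifetime fits)."""
        return self.n_valid * self.frame_time

    @property
    def valid_efficiency(self) -> np.ndarray:
        lo, hi = self.valid_range
        return self.efficiency[lo:hi]


def correct_channels(
    trace: IntensityTrace,
    bleedthrough_fraction: float,
    baseline_donor: float = 0.0,
    baseline_acceptor: float = 0.0,
) -> IntensityTrace:
    """Subtract baselines and remove donor bleed-through from the acceptor.

    acceptor' = acceptor - baseline_a - bt * (donor - baseline_d);
    donor' = donor - baseline_d.
    """
    if not 0 <= bleedthrough_fraction < 1:
        raise ValueError("bleedthrough_fraction must be in [0, 1)")
    donor = trace.donor - baseline_donor
    acceptor = trace.acceptor - baseline_acceptor - bleedthrough_fraction * donor
    return IntensityTrace(
        donor, acceptor, trace.frame_time, trace.molecule_id, trace.truth
    )


def _intensity_floor(total: np.ndarray) -> float:
    # median of the brighter part of the trace approximates the pre-bleach
    # level without needing the bleach point first
    bright = total[total >= 0.5 * np.percentile(total, 90)]
    ref = np.median(bright) if bright.size else np.median(total)
    return INTENSITY_FLOOR_FRACTION * max(ref, 0.0)


def compute_fret(trace: IntensityTrace, floor: float | None = None) -> FretTrace:
    """Per-frame E = acceptor / (donor + acceptor).

    Frames whose total intensity is below ``floor`` (default: a fixed
    fraction of the pre-bleach median total) are marked invalid (NaN) rather
    than divided.  Raises if no frame is analyzable.
    """
    total = trace.donor + trace.acceptor
    if floor is None:
        floor = _intensity_floor(total)
    valid = total > floor
    if not valid.any():
        raise ValueError(
            f"trace {trace.molecule_id}: no frame above the intensity floor"
        )
    eff = np.full(total.shape, np.nan)
    eff[valid] = trace.acceptor[valid] / total[valid]
    idx = np.nonzero(valid)[0]
    return FretTrace(
        eff,
        trace.frame_time,
        (int(idx[0]), int(idx[-1]) + 1),
        trace.molecule_id,
    )


def _bleach_changepoint(total: np.ndarray) -> int | None:
    """Frame index of the largest sustained drop in mean total intensity.

    Returns None when no split leaves the post-split mean far below the
    pre-split mean (no bleach within the acquisition).
    """
    n = total.size
    if n < 4:
        return None
    cum = np.cumsum(total)
    k = np.arange(1, n)
    mean_before = cum[:-1] / k
    mean_after = (cum[-1] - cum[:-1]) / (n - k)
    split = int(np.argmax(mean_before - mean_after)) + 1
    before = cum[split - 1] / split
    after = (cum[-1] - cum[split - 1]) / (n - split)
    if before <= 0 or after > 0.25 * before:
        return None
    return split


def truncate_at_photobleach(fret: FretTrace, raw: IntensityTrace) -> FretTrace:
    """End the valid range at the donor-photobleach change point.

    The bleach point is the largest sustained drop in total intensity; if no
    such drop exists the trace is right-censored at the acquisition end.
    """
    if raw.n_frames != fret.efficiency.size:
        raise ValueError("raw trace and FRET trace are not aligned")
    total = raw.donor + raw.acceptor
    split = _bleach_changepoint(total)
    lo, hi = fret.valid_range
    if split is None or split <= lo:
        return replace(fret, right_censored=True)
    return replace(fret, valid_range=(lo, min(hi, split)), right_censored=split >= hi)


@dataclass
class SelectionResult:
    """Traces passing the acceptor-projection detection contract."""

    selected: list[IntensityTrace]
    n_total: int
    threshold: float

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    @property
    def fraction(self) -> float:
        return self.n_selected / self.n_total if self.n_total else 0.0


def select_traces(
    traces: list[IntensityTrace],
    threshold: float,
    window_s: float | None = None,
) -> SelectionResult:
    """Select traces whose acceptor channel exceeds ``threshold`` in at least
    one frame of the observation window (maximum-intensity-projection spot
    picking emulated at the trace level).

    ``n_total`` counts every input trace (the donor-visible molecule count
    used as the denominator of normalized detection fractions).
    """
    if not traces:
        raise ValueError("empty trace collection")
    selected = []
    for tr in traces:
        acceptor = tr.acceptor
        if window_s is not None:
            acceptor = acceptor[: max(1, int(round(window_s / tr.frame_time)))]
        if np.any(acceptor > threshold):
            selected.append(tr)
    return SelectionResult(selected, len(traces), threshold)


# ----------------------------------------------------------------------- IO
def write_traces(traces: list[IntensityTrace], path, sep: str = "\t") -> None:
    """Write traces as delimited text, two columns per molecule (donor then
    acceptor), with a header row carrying molecule ids."""
    columns = {}
    n = max(tr.n_frames for tr in traces)
    for tr in traces:
        donor = np.full(n, np.nan)
        acceptor = np.full(n, np.nan)
        donor[: tr.n_frames] = tr.donor
        acceptor[: tr.n_frames] = tr.acceptor
        columns[f"{tr.molecule_id}_donor"] = donor
        columns[f"{tr.molecule_id}_acceptor"] = acceptor
    pd.DataFrame(columns).to_csv(path, sep=sep, index=False, float_format="%.4f")


def read_traces(path, frame_time: float, sep: str = "\t") -> list[IntensityTrace]:
    """Read the two-column-per-molecule delimited format.

    Raises a parse error naming the file when the column count is odd.
    """
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] % 2 != 0:
        raise ValueError(
            f"{path}: expected an even number of columns "
            f"(donor/acceptor pairs), got {df.shape[1]}"
        )
    traces = []
    for i in range(0, df.shape[1], 2):
        donor = df.iloc[:, i].to_numpy(dtype=float)
        acceptor = df.iloc[:, i + 1].to_numpy(dtype=float)
        ok = ~(np.isnan(donor) & np.isnan(acceptor))
        stop = int(np.nonzero(ok)[0][-1]) + 1 if ok.any() else 0
        name = str(df.columns[i])
        mol_id = name[: -len("_donor")] if name.endswith("_donor") else name
        traces.append(
            IntensityTrace(donor[:stop], acceptor[:stop], frame_time, mol_id)
        )
    return traces


def qc_table(
    traces: list[IntensityTrace],
    fret_traces: list[FretTrace],
    selection: SelectionResult | None = None,
) -> pd.DataFrame:
    """Per-trace QC summary: length, mean intensity, censoring, selection."""
    selected_ids = (
        {tr.molecule_id for tr in selection.selected} if selection else None
    )
    rows = []
    for raw, ft in zip(traces, fret_traces):
        rows.append(
            {
                "molecule_id": raw.molecule_id,
                "n_frames": raw.n_frames,
                "length_s": ft.length_s,
                "right_censored": ft.right_censored,
                "mean_total_intensity": float(np.mean(raw.donor + raw.acceptor)),
                "selected": (
                    raw.molecule_id in selected_ids if selected_ids is not None else True
                ),
            }
        )
    return pd.DataFrame(rows)
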