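"""Raw dual-channel FRET traces -> background-corrected, normalized ratio traces with QC.

The ratiometric cGMP indicator emits in two channels: cGMP binding increases
CFP emission (F480) and decreases YFP emission (F535), so the CFP/YFP ratio R
tracks the intracellular cGMP concentration.  This module implements the
standard offline processing chain:

1. subtract the background fluorescence measured in a cell-free ROI,
2. compute the per-frame CFP/YFP ratio,
3. normalize the ratio to its pre-stimulus baseline (first 20-30 frames),
4. validate candidate responses by antiparallel channel movement, and
5. discard low-quality traces (peak smaller than twice the baseline noise,
   or erratic baseline movement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .protocol import StimulusEvent, nonresponse_frames, validate_protocol

__all__ = [
    "TraceSet",
    "RatioTrace",
    "QCStatus",
    "background_correct",
    "compute_ratio",
    "normalize_baseline",
    "validate_antiparallel",
    "qc_trace",
    "process_traceset",
]

#: Floor applied to background-corrected fluorescence to keep ratios finite.
SIGNAL_FLOOR = 1e-9

#: Smallest normalized-ratio change treated as a real signal (0.5% of
#: baseline).  Guards the instability and antiparallel-downgrade rules
#: against numerical ripple in effectively noiseless traces.
MIN_RATIO_CHANGE = 0.005


class QCStatus(str, Enum):
    PASS = "PASS"
    REJECT_LOW_SIGNAL = "REJECT_LOW_SIGNAL"
    REJECT_BASELINE = "REJECT_BASELINE"
    REJECT_NO_ANTIPARALLEL = "REJECT_NO_ANTIPARALLEL"


@dataclass
class TraceSet:
    """Per-ROI dual-channel fluorescence time series with a stimulation protocol.

    ``cfp`` and ``yfp`` map ROI id -> 1-D array of mean fluorescence per
    frame (arbitrary units); ``background_roi`` names the cell-free ROI used
    for background correction.
    """

    frame_period: float
    cfp: dict[str, np.ndarray]
    yfp: dict[str, np.ndarray]
    background_roi: str
    protocol: list[StimulusEvent]

    def __post_init__(self) -> None:
        if self.background_roi not in self.cfp:
            raise ValueError(f"background ROI {self.background_roi!r} missing")
        lengths = {len(v) for v in self.cfp.values()} | {
            len(v) for v in self.yfp.values()
        }
        if len(lengths) != 1:
            raise ValueError("all channel series must have equal length")
        if set(self.cfp) != set(self.yfp):
            raise ValueError("CFP and YFP must cover the same ROIs")
        validate_protocol(self.protocol)

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.cfp.values())))

    @property
    def rois(self) -> list[str]:
        """Cell ROIs, excluding the background ROI."""
        return [r for r in self.cfp if r != self.background_roi]


@dataclass
class RatioTrace:
    """Baseline-normalized CFP/YFP ratio series for one ROI, with QC annotations."""

    roi: str
    r: np.ndarray
    baseline_window: tuple[int, int]
    baseline_noise_sd: float
    qc_status: QCStatus = QCStatus.PASS
    #: per-event antiparallel validity flags, parallel to the protocol
    valid_events: list[bool] = field(default_factory=list)
    #: per-event antiparallel correlation scores
    event_scores: list[float] = field(default_factory=list)


def background_correct(
    traces: TraceSet, mode: str = "scalar", floor: float = SIGNAL_FLOOR
) -> TraceSet:
    """Subtract the cell-free-ROI background from every channel of every ROI.

    ``mode="scalar"`` (default) subtracts the time-mean of the background
    series from each channel; ``mode="perframe"`` subtracts the background
    series frame-wise.  Corrected values are clipped at a small positive
    floor so downstream ratios stay finite.
    """
    if mode not in ("scalar", "perframe"):
        raise ValueError(f"unknown background mode {mode!r}")
    bg_cfp = np.asarray(traces.cfp[traces.background_roi], dtype=float)
    bg_yfp = np.asarray(traces.yfp[traces.background_roi], dtype=float)
    if not (np.all(np.isfinite(bg_cfp)) and np.all(np.isfinite(bg_yfp))):
        raise ValueError("background series contains non-finite values")

    sub_cfp = bg_cfp.mean() if mode == "scalar" else bg_cfp
    sub_yfp = bg_yfp.mean() if mode == "scalar" else bg_yfp

    # A background exceeding every cell signal means the background ROI was
    # mis-specified; reject the whole set rather than emit negative traces.
    cell_rois = traces.rois
    if cell_rois:
        min_cell_cfp = min(np.mean(traces.cfp[r]) for r in cell_rois)
        min_cell_yfp = min(np.mean(traces.yfp[r]) for r in cell_rois)
        if bg_cfp.mean() >= min_cell_cfp and bg_yfp.mean() >= min_cell_yfp:
            raise ValueError(
                "background ROI is at least as bright as every cell ROI; "
                "background mis-specified"
            )

    cfp = {}
    yfp = {}
    for roi in traces.cfp:
        if roi == traces.background_roi:
            cfp[roi] = np.asarray(traces.cfp[roi], dtype=float) - sub_cfp
            yfp[roi] = np.asarray(traces.yfp[roi], dtype=float) - sub_yfp
        else:
            cfp[roi] = np.maximum(
                np.asarray(traces.cfp[roi], dtype=float) - sub_cfp, floor
            )
            yfp[roi] = np.maximum(
                np.asarray(traces.yfp[roi], dtype=float) - sub_yfp, floor
            )
    return TraceSet(
        frame_period=traces.frame_period,
        cfp=cfp,
        yfp=yfp,
        background_roi=traces.background_roi,
        protocol=list(traces.protocol),
    )


def compute_ratio(traces: TraceSet) -> dict[str, np.ndarray]:
    """Per-ROI raw CFP/YFP ratio series (background-corrected input expected).

    ROIs with any non-positive YFP frame get an all-NaN series; callers flag
    them ``REJECT_BASELINE``.
    """
    out: dict[str, np.ndarray] = {}
    for roi in traces.rois:
        yfp = np.asarray(traces.yfp[roi], dtype=float)
        cfp = np.asarray(traces.cfp[roi], dtype=float)
        if np.any(yfp <= 0):
            out[roi] = np.full_like(yfp, np.nan)
        else:
            out[roi] = cfp / yfp
    return out


def normalize_baseline(
    r: np.ndarray,
    baseline_window: tuple[int, int],
    roi: str = "",
    protocol: Sequence[StimulusEvent] = (),
) -> RatioTrace:
    """Normalize a raw ratio series to its pre-stimulus baseline mean.

    ``baseline_window`` is a half-open frame interval that must lie before
    the first stimulus.  The baseline noise (SD of the normalized ratio over
    the window, population SD) is recorded for the 2x QC rule downstream.
    """
    r = np.asarray(r, dtype=float)
    lo, hi = baseline_window
    if not (0 <= lo < hi <= len(r)):
        raise ValueError("baseline window outside series")
    for ev in protocol:
        if ev.start_frame < hi:
            raise ValueError(
                f"baseline window [{lo},{hi}) overlaps stimulus starting at "
                f"frame {ev.start_frame}"
            )
    if np.any(np.isnan(r)):
        return RatioTrace(
            roi=roi,
            r=r,
            baseline_window=(lo, hi),
            baseline_noise_sd=np.nan,
            qc_status=QCStatus.REJECT_BASELINE,
        )
    base = float(np.mean(r[lo:hi]))
    if base <= 0:
        raise ValueError("non-positive baseline mean")
    rn = r / base
    noise = float(np.std(rn[lo:hi]))
    return RatioTrace(
        roi=roi, r=rn, baseline_window=(lo, hi), baseline_noise_sd=noise
    )


def _local_pre_baseline(x: np.ndarray, start: int, fallback: tuple[int, int]) -> float:
    """Mean of the last few frames before *start* (pre-event channel level)."""
    lo = max(0, start - 5)
    if lo == start:
        lo, hi = fallback
        return float(np.mean(x[lo:hi]))
    return float(np.mean(x[lo:start]))


def validate_antiparallel(
    traces: TraceSet,
    roi: str,
    event: StimulusEvent,
    tail: int = 10,
    rho_min: float = 0.5,
    baseline_window: tuple[int, int] = (0, 25),
) -> tuple[bool, float]:
    """Validate a candidate cGMP response by antiparallel channel movement.

    A ratio change counts as a genuine cGMP change only if CFP rises while
    YFP falls.  Over the event window extended by *tail* frames, both
    channels are linearly detrended (removing common bleaching drift) and
    their Pearson correlation computed; the event is valid iff the
    correlation is <= ``-rho_min`` and the CFP excursion is positive.

    Returns ``(valid, score)`` where score is the correlation.
    """
    from scipy.signal import detrend
    from scipy.stats import pearsonr

    n = traces.n_frames
    lo = event.start_frame
    hi = min(n, event.end_frame + tail)
    if not (0 <= lo < hi <= n):
        raise ValueError("event window outside series")
    if hi - lo < 3:
        raise ValueError("event window too short (<3 frames)")
    cfp = np.asarray(traces.cfp[roi], dtype=float)[lo:hi]
    yfp = np.asarray(traces.yfp[roi], dtype=float)[lo:hi]
    if np.std(cfp) == 0 or np.std(yfp) == 0:
        return False, 0.0
    dc = detrend(cfp)
    dy = detrend(yfp)
    if np.std(dc) == 0 or np.std(dy) == 0:
        # perfectly linear channels: no transient to correlate
        return False, 0.0
    score = float(pearsonr(dc, dy).statistic)
    pre = _local_pre_baseline(
        np.asarray(traces.cfp[roi], dtype=float), event.start_frame, baseline_window
    )
    cfp_change = float(np.max(cfp) - pre)
    valid = (score <= -rho_min) and (cfp_change > 0)
    return valid, score


def max_event_peak(
    r: np.ndarray, protocol: Sequence[StimulusEvent], tail: int = 20
) -> float:
    """Highest signal (normalized ratio - 1) over all event windows + tails."""
    n = len(r)
    peak = -np.inf
    for ev in protocol:
        hi = min(n, ev.end_frame + tail)
        seg = r[ev.start_frame:hi]
        if seg.size:
            peak = max(peak, float(np.max(seg) - 1.0))
    if not np.isfinite(peak):
        peak = float(np.max(r) - 1.0)
    return peak


def qc_trace(
    rt: RatioTrace,
    protocol: Sequence[StimulusEvent],
    tail: int = 20,
    instability_factor: float = 3.0,
) -> QCStatus:
    """Quality-control a normalized ratio trace.

    * ``REJECT_LOW_SIGNAL`` if the highest signal over all event windows
      (extended by *tail*) is smaller than twice the baseline noise.
    * ``REJECT_BASELINE`` if the baseline moves erratically: the SD of the
      first difference of the ratio outside event windows exceeds
      ``instability_factor`` x baseline noise.
    * ``PASS`` otherwise.  A zero-noise trace passes with any positive peak.
    """
    if rt.qc_status is QCStatus.REJECT_BASELINE:
        return QCStatus.REJECT_BASELINE
    r = rt.r
    n = len(r)
    peak = max_event_peak(r, protocol, tail=tail)
    if peak < 2.0 * rt.baseline_noise_sd:
        return QCStatus.REJECT_LOW_SIGNAL

    # "extreme random movements of the baseline": frame-to-frame jumps of the
    # ratio on non-response frames, computed within each quiet segment (not
    # across the gaps the event windows leave), compared against the baseline
    # noise with a small absolute floor for effectively noiseless traces.
    quiet = nonresponse_frames(protocol, n, tail=tail)
    diffs: list[np.ndarray] = []
    idx = np.flatnonzero(quiet)
    if idx.size >= 3:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for seg in np.split(idx, breaks + 1):
            if len(seg) >= 2:
                diffs.append(np.diff(r[seg]))
    if diffs:
        jump_sd = float(np.std(np.concatenate(diffs)))
        threshold = instability_factor * max(rt.baseline_noise_sd, MIN_RATIO_CHANGE)
        if jump_sd > threshold:
            return QCStatus.REJECT_BASELINE
    return QCStatus.PASS


def process_traceset(
    traces: TraceSet,
    baseline_window: tuple[int, int] = (0, 25),
    background_mode: str = "scalar",
    tail: int = 20,
    antiparallel_tail: int = 10,
    rho_min: float = 0.5,
) -> dict[str, RatioTrace]:
    """Full processing chain: background -> ratio -> normalize -> validate -> QC.

    Returns one annotated :class:`RatioTrace` per cell ROI.  A trace that
    passes signal/baseline QC but has no antiparallel-valid event is marked
    ``REJECT_NO_ANTIPARALLEL`` unless its signal is below the 2x-noise floor
    anyway (then ``REJECT_LOW_SIGNAL`` takes precedence: a flat trace is a
    non-responder, not an artifact).
    """
    corrected = background_correct(traces, mode=background_mode)
    ratios = compute_ratio(corrected)
    out: dict[str, RatioTrace] = {}
    for roi, r in ratios.items():
        rt = normalize_baseline(r, baseline_window, roi=roi, protocol=traces.protocol)
        if rt.qc_status is QCStatus.REJECT_BASELINE:
            rt.valid_events = [False] * len(traces.protocol)
            rt.event_scores = [float("nan")] * len(traces.protocol)
            out[roi] = rt
            continue
        flags, scores = [], []
        for ev in traces.protocol:
            try:
                ok, score = validate_antiparallel(
                    corrected,
                    roi,
                    ev,
                    tail=antiparallel_tail,
                    rho_min=rho_min,
                    baseline_window=baseline_window,
                )
            except ValueError:
                ok, score = False, float("nan")
            flags.append(ok)
            scores.append(score)
        rt.valid_events = flags
        rt.event_scores = scores
        status = qc_trace(rt, traces.protocol, tail=tail)
        # A trace with a clear response (well above what the noise maximum
        # reaches by chance) but no antiparallel-confirmed event is an
        # artifact, e.g. focus drift; a merely noisy flat trace is a
        # non-responder and is not downgraded here.
        peak = max_event_peak(rt.r, traces.protocol, tail=tail)
        if (
            status is QCStatus.PASS
            and not any(flags)
            and peak >= max(4.0 * rt.baseline_noise_sd, MIN_RATIO_CHANGE)
        ):
            status = QCStatus.REJECT_NO_ANTIPARALLEL
        rt.qc_status = status
        out[roi] = rt
    return out
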