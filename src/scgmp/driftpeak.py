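"""Baseline drift correction and per-stimulus peak quantification.

Ratio traces often drift slowly (residual differential photobleaching,
focus creep).  The drift is corrected by fitting an exponential
``r_base(t) = a*exp(-t/tau) + c`` to the non-response frames and dividing it
out; when the exponential fit fails its convergence/residual checks the correction
falls back to piecewise-linear interpolation between the means of the
non-response segments.  Peak heights (maximal cGMP response per stimulus)
are then read off smoothed, drift-corrected traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .protocol import StimulusEvent, nonresponse_frames
from .traceproc import RatioTrace, QCStatus

__all__ = ["DriftModel", "PeakMeasure", "correct_drift", "smooth", "measure_peaks"]

EXPONENTIAL = "EXPONENTIAL"
LINEAR_INTERP = "LINEAR_INTERP"


@dataclass
class DriftModel:
    """The baseline model divided out of a ratio trace.

    ``kind`` is ``EXPONENTIAL`` with params ``(a, tau, c)`` of
    ``a*exp(-t/tau)+c`` (t in frames), or ``LINEAR_INTERP`` with params
    ``(anchor_frames, anchor_values)``.
    """

    kind: str
    params: dict


@dataclass
class PeakMeasure:
    """Peak height of one stimulus response for one ROI.

    ``peak_height`` is the maximum of the smoothed, drift-corrected
    normalized ratio minus 1 over the event window plus tail, floored at 0.
    """

    roi: str
    event: StimulusEvent
    peak_height: float
    valid: bool


def _exp_model(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def _quiet_segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open runs of True in a boolean mask."""
    segs = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            segs.append((i, j))
            i = j
        else:
            i += 1
    return segs


def correct_drift(
    rt: RatioTrace,
    protocol: Sequence[StimulusEvent],
    tail: int = 20,
    residual_factor: float = 3.0,
) -> tuple[RatioTrace, DriftModel]:
    """Remove baseline drift from a normalized ratio trace.

    Fits ``a*exp(-t/tau)+c`` by least squares to frames outside all event
    windows (+ *tail*).  The fit is accepted iff it converges with tau > 0
    and its RMS residual on those frames is below
    ``residual_factor * baseline_noise_sd`` (with a small absolute floor so
    noiseless traces are not rejected for numerically-zero residuals).
    Otherwise the baseline is interpolated linearly between the means of the
    non-response segments.  The corrected trace is re-normalized so its
    baseline-window mean is exactly 1.
    """
    r = np.asarray(rt.r, dtype=float)
    n = len(r)
    quiet = nonresponse_frames(protocol, n, tail=tail)
    tq = np.flatnonzero(quiet).astype(float)
    if tq.size < 5:
        raise ValueError("fewer than 5 non-response frames; cannot fit drift")
    rq = r[quiet]

    model: DriftModel | None = None
    base: np.ndarray | None = None
    tol = max(residual_factor * rt.baseline_noise_sd, 1e-6)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # start from the observed head-tail decay
            a0 = float(rq[0] - rq[-1])
            p0 = (a0 if abs(a0) > 1e-12 else 1e-3, max(n / 2.0, 1.0), float(rq[-1]))
            popt, _ = curve_fit(
                _exp_model,
                tq,
                rq,
                p0=p0,
                bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
        a, tau, c = (float(v) for v in popt)
        resid = rq - _exp_model(tq, a, tau, c)
        rms = float(np.sqrt(np.mean(resid**2)))
        if tau > 0 and rms < tol:
            base = _exp_model(np.arange(n, dtype=float), a, tau, c)
            model = DriftModel(EXPONENTIAL, {"a": a, "tau": tau, "c": c})
    except (RuntimeError, ValueError):
        pass

    if model is None:
        anchors_t = []
        anchors_v = []
        for lo, hi in _quiet_segments(quiet):
            anchors_t.append((lo + hi - 1) / 2.0)
            anchors_v.append(float(np.mean(r[lo:hi])))
        base = np.interp(np.arange(n, dtype=float), anchors_t, anchors_v)
        model = DriftModel(
            LINEAR_INTERP, {"anchor_frames": anchors_t, "anchor_values": anchors_v}
        )

    if np.any(base <= 0):
        raise ValueError("fitted baseline non-positive; drift correction invalid")
    corrected = r / base
    lo, hi = rt.baseline_window
    corrected = corrected / np.mean(corrected[lo:hi])
    out = RatioTrace(
        roi=rt.roi,
        r=corrected,
        baseline_window=rt.baseline_window,
        baseline_noise_sd=float(np.std(corrected[lo:hi])),
        qc_status=rt.qc_status,
        valid_events=list(rt.valid_events),
        event_scores=list(rt.event_scores),
    )
    return out, model


def smooth(r: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge replication; length preserved."""
    r = np.asarray(r, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > len(r):
        raise ValueError("window longer than series")
    if window == 1:
        return r.copy()
    half = window // 2
    padded = np.pad(r, half, mode="edge")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def measure_peaks(
    rt: RatioTrace,
    protocol: Sequence[StimulusEvent],
    smoothing_window: int = 5,
    tail: int = 20,
) -> list[PeakMeasure]:
    """Per-stimulus peak heights on the smoothed, drift-corrected trace.

    Each event's search window is ``[start_frame, end_frame + tail)``,
    truncated at the next event's start if the tails would overlap.  Peak
    height is max(smoothed r) - 1, floored at 0; the antiparallel validity
    flag is carried over from trace QC.
    """
    r = smooth(rt.r, smoothing_window)
    n = len(r)
    ordered = sorted(range(len(protocol)), key=lambda i: protocol[i].start_frame)
    out: list[PeakMeasure] = [None] * len(protocol)  # type: ignore[list-item]
    for pos, idx in enumerate(ordered):
        ev = protocol[idx]
        hi = min(n, ev.end_frame + tail)
        if pos + 1 < len(ordered):
            nxt = protocol[ordered[pos + 1]].start_frame
            if hi > nxt:
                warnings.warn(
                    f"event tail at frame {hi} truncated at next event start {nxt}"
                )
                hi = nxt
        seg = r[ev.start_frame:hi]
        height = max(float(np.max(seg) - 1.0), 0.0) if seg.size else float("nan")
        valid = (
            bool(rt.valid_events[idx]) if idx < len(rt.valid_events) else True
        )
        out[idx] = PeakMeasure(roi=rt.roi, event=ev, peak_height=height, valid=valid)
    return out
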