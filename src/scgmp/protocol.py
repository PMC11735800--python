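"""Stimulation protocols for cGMP/FRET time-series experiments.

A protocol is an ordered list of :class:`StimulusEvent`, each a half-open
frame window ``[start_frame, end_frame)`` during which one drug (ANP, CNP or
the NO donor) is applied at a stated concentration.  The default protocol
mirrors a consecutive-stimulation experiment on cultured vascular smooth
muscle cells: ANP and CNP at two matched doses (50 and 250 nM) followed by
the NO donor at 80 nM, recorded at 0.2 Hz (one frame every 5 s).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

ANP = "ANP"
CNP = "CNP"
NO = "NO"
DRUGS = (ANP, CNP, NO)

#: Acquisition frame period in seconds (0.2 Hz).
DEFAULT_FRAME_PERIOD = 5.0


@dataclass(frozen=True)
class StimulusEvent:
    """One drug application window.

    Parameters
    ----------
    drug : str
        One of ``"ANP"``, ``"CNP"`` or ``"NO"``.
    concentration : float
        Applied concentration in nM.
    start_frame, end_frame : int
        Half-open application window ``[start_frame, end_frame)`` in frames.
    """

    drug: str
    concentration: float
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}; expected one of {DRUGS}")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if not self.start_frame < self.end_frame:
            raise ValueError("start_frame must be < end_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def validate_protocol(events: Sequence[StimulusEvent]) -> None:
    """Check that successive event windows do not overlap."""
    ordered = sorted(events, key=lambda e: e.start_frame)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start_frame < prev.end_frame:
            raise ValueError(
                f"overlapping stimulus windows: {prev} and {nxt}"
            )


def default_protocol() -> list[StimulusEvent]:
    """Consecutive ANP/CNP (50 and 250 nM) + NO (80 nM) protocol.

    A 30-frame pre-stimulus baseline precedes the first application; each
    application lasts 10 frames (50 s) with 40 inter-stimulus frames for the
    cGMP transient to decay.
    """
    return [
        StimulusEvent(ANP, 50.0, 30, 40),
        StimulusEvent(CNP, 50.0, 80, 90),
        StimulusEvent(ANP, 250.0, 130, 140),
        StimulusEvent(CNP, 250.0, 180, 190),
        StimulusEvent(NO, 80.0, 230, 240),
    ]


#: Number of frames covering the default protocol including the final decay.
DEFAULT_N_FRAMES = 290


def nonresponse_frames(
    events: Iterable[StimulusEvent], n_frames: int, tail: int = 20
) -> "np.ndarray":
    """Boolean mask of frames outside every event window extended by *tail*."""
    import numpy as np

    mask = np.ones(n_frames, dtype=bool)
    for ev in events:
        lo = max(0, ev.start_frame)
        hi = min(n_frames, ev.end_frame + tail)
        mask[lo:hi] = False
    return mask


def protocol_to_json(events: Sequence[StimulusEvent], path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(e) for e in events], fh, indent=1)


def protocol_from_json(path) -> list[StimulusEvent]:
    with open(path) as fh:
        raw = json.load(fh)
    events = [StimulusEvent(**d) for d in raw]
    validate_protocol(events)
    return events
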