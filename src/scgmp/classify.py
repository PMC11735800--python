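"""ANP/CNP preference classification from per-stimulus peak heights.

A cell that responds at least 1.5x more strongly to ANP than to CNP at a
matched concentration (50 or 250 nM) is ANP-preferring; the mirrored rule
gives CNP-preferring; cells responding similarly are ANP~CNP.  NO responses
are normalized to the cell's highest natriuretic-peptide peak so the
relative strength of the NO-sensitive pathway can be compared across
preference groups.  Ex vivo (qualitative) measurements are summarized as
responder fractions among ROIs responding to at least one stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .driftpeak import PeakMeasure
from .protocol import ANP, CNP, NO
from .traceproc import QCStatus

__all__ = [
    "ClassifierConfig",
    "CellClassification",
    "ResponderSummary",
    "classify_preference",
    "normalize_no_response",
    "score_exvivo_responses",
    "ANP_PREF",
    "ANP_CNP",
    "CNP_PREF",
    "NONRESPONDER",
    "EXCLUDED",
]

ANP_PREF = "ANP_PREF"
ANP_CNP = "ANP_CNP"
CNP_PREF = "CNP_PREF"
NONRESPONDER = "NONRESPONDER"
EXCLUDED = "EXCLUDED"

CLASS_LABELS = (ANP_PREF, ANP_CNP, CNP_PREF, NONRESPONDER)

#: Numerical floor for "no response" when the measured baseline noise is zero.
_EPS_PEAK = 1e-9


@dataclass(frozen=True)
class ClassifierConfig:
    """Parameters of the preference rule.

    ratio_threshold : peak-ratio threshold for a preference call (inclusive).
    matched_concentrations : doses (nM) at which ANP and CNP are compared.
    min_peak : floor below which a peak counts as "no response"; also used to
        floor denominators when forming peak ratios.
    """

    ratio_threshold: float = 1.5
    matched_concentrations: tuple[float, ...] = (50.0, 250.0)
    min_peak: float = 0.0

    def __post_init__(self) -> None:
        if not self.ratio_threshold > 1:
            raise ValueError("ratio_threshold must be > 1")


@dataclass
class CellClassification:
    roi: str
    label: str
    #: per-matched-concentration ANP/CNP peak ratio (NaN where unavailable)
    evidence: dict[float, float] = field(default_factory=dict)
    #: NO peak normalized to the highest ANP/CNP peak (NaN if undefined)
    no_norm: float = float("nan")
    reason: str = ""


@dataclass
class ResponderSummary:
    """Qualitative responder fractions among ROIs responding to >=1 stimulus."""

    fractions: dict[str, float]
    numerators: dict[str, int]
    denominator: int


def _peaks_by_drug(
    peaks: Iterable[PeakMeasure],
) -> dict[str, dict[float, PeakMeasure]]:
    by: dict[str, dict[float, PeakMeasure]] = {}
    for p in peaks:
        by.setdefault(p.event.drug, {})[p.event.concentration] = p
    return by


def classify_preference(
    peaks: Sequence[PeakMeasure],
    cfg: ClassifierConfig = ClassifierConfig(),
    qc_status: QCStatus = QCStatus.PASS,
) -> CellClassification:
    """Assign one cell its ANP/CNP preference label.

    The preference threshold may be met at either matched dose, but the
    ratio must not point the opposite way at the other dose (a conflict is
    labeled ANP~CNP).  Cells whose peaks are all below ``min_peak`` are
    non-responders.  QC-rejected cells are EXCLUDED, except low-signal
    rejections, which are by definition non-responders.
    """
    roi = peaks[0].roi if peaks else ""
    if qc_status is QCStatus.REJECT_LOW_SIGNAL:
        return CellClassification(roi=roi, label=NONRESPONDER, reason="low signal")
    if qc_status is not QCStatus.PASS:
        return CellClassification(
            roi=roi, label=EXCLUDED, reason=f"QC {qc_status.value}"
        )

    floor = max(cfg.min_peak, _EPS_PEAK)
    by = _peaks_by_drug(peaks)
    all_heights = [
        p.peak_height for p in peaks if np.isfinite(p.peak_height)
    ]
    if all_heights and max(all_heights) < floor:
        return CellClassification(roi=roi, label=NONRESPONDER, reason="all peaks below floor")

    evidence: dict[float, float] = {}
    for conc in cfg.matched_concentrations:
        pa = by.get(ANP, {}).get(conc)
        pc = by.get(CNP, {}).get(conc)
        if pa is None or pc is None or not (pa.valid and pc.valid):
            continue
        if not (np.isfinite(pa.peak_height) and np.isfinite(pc.peak_height)):
            continue
        evidence[conc] = max(pa.peak_height, floor) / max(pc.peak_height, floor)
    if not evidence:
        return CellClassification(
            roi=roi,
            label=EXCLUDED,
            reason="no valid ANP/CNP pair at any matched concentration",
        )

    ratios = np.array(list(evidence.values()))
    # the >= 1.5 threshold is inclusive; a 1e-9 relative tolerance keeps
    # exactly-at-threshold peak pairs (e.g. 0.30/0.20) on the preferring side
    # despite binary rounding of the quotient
    thr = cfg.ratio_threshold * (1.0 - 1e-9)
    anp_pref = bool(np.any(ratios >= thr) and np.all(ratios >= 1.0 - 1e-9))
    cnp_pref = bool(np.any(1.0 / ratios >= thr) and np.all(ratios <= 1.0 + 1e-9))
    if anp_pref and not cnp_pref:
        label = ANP_PREF
    elif cnp_pref and not anp_pref:
        label = CNP_PREF
    else:
        label = ANP_CNP
    return CellClassification(roi=roi, label=label, evidence=evidence)


def normalize_no_response(
    peaks: Sequence[PeakMeasure], min_peak: float = 0.0
) -> float:
    """NO peak height normalized to the cell's highest ANP/CNP peak.

    Returns NaN (undefined) when the best natriuretic-peptide peak is below
    ``min_peak`` or when the cell lacks a valid NO or ANP/CNP peak.
    """
    floor = max(min_peak, _EPS_PEAK)
    no_peaks = [
        p.peak_height
        for p in peaks
        if p.event.drug == NO and p.valid and np.isfinite(p.peak_height)
    ]
    np_peaks = [
        p.peak_height
        for p in peaks
        if p.event.drug in (ANP, CNP) and p.valid and np.isfinite(p.peak_height)
    ]
    if not no_peaks or not np_peaks:
        return float("nan")
    best = max(np_peaks)
    if best < floor:
        return float("nan")
    return max(no_peaks) / best


def score_exvivo_responses(
    flags: Mapping[str, Mapping[str, bool]],
    stimuli: Sequence[str] = (ANP, CNP, NO),
) -> ResponderSummary:
    """Responder fractions from per-ROI per-stimulus validity flags.

    ``flags[roi][stimulus]`` is True iff the ROI showed a confirmed
    (antiparallel) cGMP change to that stimulus.  Fractions are normalized
    to the number of ROIs responding to at least one of the stimuli; ROIs
    responding to none are excluded from the denominator.
    """
    responders = [
        roi for roi, f in flags.items() if any(f.get(s, False) for s in stimuli)
    ]
    denom = len(responders)
    if denom == 0:
        raise ValueError("no ROI responded to any stimulus; empty denominator")
    numerators = {
        s: sum(1 for roi in responders if flags[roi].get(s, False)) for s in stimuli
    }
    fractions = {s: numerators[s] / denom for s in stimuli}
    return ResponderSummary(
        fractions=fractions, numerators=numerators, denominator=denom
    )
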