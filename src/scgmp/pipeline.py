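"""End-to-end trace pipeline: raw traces -> per-cell preference labels.

Chains background correction, ratio normalization, antiparallel validation,
QC, drift correction, smoothed peak measurement and the 1.5x preference
classifier, and collects everything into tidy tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify as _classify
from . import driftpeak, traceproc
from .classify import CellClassification, ClassifierConfig
from .traceproc import QCStatus, TraceSet

__all__ = ["PipelineConfig", "PipelineResult", "run_trace_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    baseline_window: tuple[int, int] = (0, 25)
    background_mode: str = "scalar"
    tail: int = 20
    antiparallel_tail: int = 10
    rho_min: float = 0.5
    smoothing_window: int = 5
    classifier: ClassifierConfig = ClassifierConfig()


@dataclass
class PipelineResult:
    ratio_traces: dict[str, traceproc.RatioTrace]
    drift_models: dict[str, driftpeak.DriftModel]
    peaks: pd.DataFrame
    classifications: dict[str, CellClassification]

    @property
    def labels(self) -> dict[str, str]:
        return {roi: c.label for roi, c in self.classifications.items()}

    def summary(self) -> pd.DataFrame:
        rows = []
        for roi, c in self.classifications.items():
            rt = self.ratio_traces[roi]
            rows.append(
                {
                    "roi": roi,
                    "label": c.label,
                    "qc_status": rt.qc_status.value,
                    "baseline_noise_sd": rt.baseline_noise_sd,
                    "no_norm": c.no_norm,
                    **{f"ratio_{int(k)}nM": v for k, v in c.evidence.items()},
                }
            )
        return pd.DataFrame(rows)


def run_trace_pipeline(
    traces: TraceSet, cfg: PipelineConfig = PipelineConfig()
) -> PipelineResult:
    """Process a trace set through the full analysis chain."""
    rts = traceproc.process_traceset(
        traces,
        baseline_window=cfg.baseline_window,
        background_mode=cfg.background_mode,
        tail=cfg.tail,
        antiparallel_tail=cfg.antiparallel_tail,
        rho_min=cfg.rho_min,
    )
    drift_models: dict[str, driftpeak.DriftModel] = {}
    peak_rows = []
    classifications: dict[str, CellClassification] = {}
    for roi, rt in rts.items():
        if rt.qc_status in (QCStatus.PASS, QCStatus.REJECT_LOW_SIGNAL):
            corrected, model = driftpeak.correct_drift(
                rt, traces.protocol, tail=cfg.tail
            )
            drift_models[roi] = model
            peaks = driftpeak.measure_peaks(
                corrected,
                traces.protocol,
                smoothing_window=cfg.smoothing_window,
                tail=cfg.tail,
            )
        else:
            peaks = []
        # "no response" floor: twice the cell's own baseline noise, with the
        # global minimum-ratio-change floor for effectively noiseless traces
        min_peak = (
            2.0 * rt.baseline_noise_sd if np.isfinite(rt.baseline_noise_sd) else 0.0
        )
        ccfg = ClassifierConfig(
            ratio_threshold=cfg.classifier.ratio_threshold,
            matched_concentrations=cfg.classifier.matched_concentrations,
            min_peak=max(
                cfg.classifier.min_peak, min_peak, traceproc.MIN_RATIO_CHANGE
            ),
        )
        c = _classify.classify_preference(peaks, ccfg, qc_status=rt.qc_status)
        if not peaks:
            c.roi = roi
        c.no_norm = _classify.normalize_no_response(peaks, min_peak=ccfg.min_peak)
        classifications[roi] = c
        for p in peaks:
            peak_rows.append(
                {
                    "roi": roi,
                    "drug": p.event.drug,
                    "concentration": p.event.concentration,
                    "peak_height": p.peak_height,
                    "valid": p.valid,
                }
            )
    return PipelineResult(
        ratio_traces=rts,
        drift_models=drift_models,
        peaks=pd.DataFrame(peak_rows),
        classifications=classifications,
    )
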