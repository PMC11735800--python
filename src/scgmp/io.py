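"""File I/O: trace tables (CSV), protocols/truth/landmarks (JSON), images
(TIFF), masks (label-image TIFF) and count matrices (MatrixMarket + TSV)."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import StimulusEvent, protocol_from_json, protocol_to_json
from .traceproc import TraceSet

__all__ = [
    "write_traceset",
    "read_traceset",
    "write_truth",
    "read_truth",
    "write_landmarks",
    "read_landmarks",
    "write_image",
    "read_image",
    "write_count_matrix",
    "read_count_matrix",
    "protocol_to_json",
    "protocol_from_json",
]


def write_traceset(traces: TraceSet, csv_path, protocol_path=None) -> None:
    """One row per frame; columns ``frame`` then ``CFP_<roi>``/``YFP_<roi>``."""
    data = {"frame": np.arange(traces.n_frames)}
    for roi in list(traces.rois) + [traces.background_roi]:
        data[f"CFP_{roi}"] = traces.cfp[roi]
        data[f"YFP_{roi}"] = traces.yfp[roi]
    pd.DataFrame(data).to_csv(csv_path, index=False)
    if protocol_path is not None:
        protocol_to_json(traces.protocol, protocol_path)


def read_traceset(
    csv_path,
    protocol_path,
    background_roi: str = "background",
    frame_period: float = 5.0,
) -> TraceSet:
    df = pd.read_csv(csv_path)
    cfp, yfp = {}, {}
    for col in df.columns:
        if col.startswith("CFP_"):
            cfp[col[4:]] = df[col].to_numpy(dtype=float)
        elif col.startswith("YFP_"):
            yfp[col[4:]] = df[col].to_numpy(dtype=float)
    protocol = protocol_from_json(protocol_path)
    return TraceSet(
        frame_period=frame_period,
        cfp=cfp,
        yfp=yfp,
        background_roi=background_roi,
        protocol=protocol,
    )


def write_truth(truth: dict, path) -> None:
    """Ground-truth cell profiles as a JSON map roi -> profile fields."""
    payload = {}
    for roi, profile in truth.items():
        d = asdict(profile)
        d["amp"] = dict(d["amp"])
        d["marker_levels"] = dict(d["marker_levels"])
        for k, v in list(d.items()):
            if isinstance(v, float) and not np.isfinite(v):
                d[k] = None  # JSON has no inf
        payload[roi] = d
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(path) -> dict:
    from .synthio import CellProfile

    with open(path) as fh:
        raw = json.load(fh)
    out = {}
    for roi, d in raw.items():
        for k, v in list(d.items()):
            if v is None:
                d[k] = float("inf")
        out[roi] = CellProfile(**d)
    return out


def write_landmarks(ref: np.ndarray, if_: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"reference": np.asarray(ref).tolist(), "if": np.asarray(if_).tolist()},
            fh,
            indent=1,
        )


def read_landmarks(path) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        d = json.load(fh)
    return np.asarray(d["reference"], dtype=float), np.asarray(d["if"], dtype=float)


def write_image(image: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(image))


def read_image(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


def write_count_matrix(result, out_dir) -> None:
    """MatrixMarket counts + genes.tsv (id, mito) + cells.tsv (id)."""
    from scipy.io import mmwrite

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(out / "counts.mtx", result.counts.tocoo())
    pd.DataFrame({"gene": result.gene_ids, "mito": np.asarray(result.mito, int)}).to_csv(
        out / "genes.tsv", sep="\t", index=False
    )
    pd.DataFrame({"cell": result.cell_ids}).to_csv(
        out / "cells.tsv", sep="\t", index=False
    )


def read_count_matrix(in_dir):
    from scipy.io import mmread

    from .scqc import CountMatrix

    d = Path(in_dir)
    counts = mmread(d / "counts.mtx").tocsc().astype(np.int64)
    genes = pd.read_csv(d / "genes.tsv", sep="\t")
    cells = pd.read_csv(d / "cells.tsv", sep="\t")
    return CountMatrix(
        counts=counts,
        gene_ids=genes["gene"].astype(str).tolist(),
        cell_ids=cells["cell"].astype(str).tolist(),
        mito=genes["mito"].to_numpy(dtype=bool),
    )
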