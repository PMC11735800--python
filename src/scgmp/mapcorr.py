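"""Grid-landmark registration and per-cell immunofluorescence correlation.

Cells measured live (FRET session) are re-identified after fixation and
immunostaining via the etched coordinate grid of the coverslip: landmark
pairs visible in both sessions define an affine mapping from the reference
(FRET) frame to the immunofluorescence (IF) frame.  Per-cell masks from the
FRET session are transferred through that mapping, mean marker intensities
are background-corrected and normalized to the mean of the ANP-preferring
group, and a roundness metric summarizes cell shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AffineTransform",
    "estimate_grid_transform",
    "transfer_rois",
    "quantify_if",
    "normalize_to_reference_group",
    "roundness",
    "correlate_cells",
]


@dataclass(frozen=True)
class AffineTransform:
    """2-D affine map p -> A @ p + t, (x, y) pixel convention, origin top-left."""

    linear: np.ndarray  # (2, 2)
    translation: np.ndarray  # (2,)
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValueError("linear part is singular")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix."""
        m = np.eye(3)
        m[:2, :2] = self.linear
        m[:2, 2] = self.translation
        return m

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.linear.T + self.translation


def estimate_grid_transform(
    ref_points: np.ndarray, if_points: np.ndarray
) -> AffineTransform:
    """Least-squares affine mapping reference-frame landmarks to IF-frame ones.

    Requires >= 3 non-collinear pairs; solves the normal equations via
    ``lstsq`` on the design ``[x, y, 1]`` per output coordinate and reports
    the RMS residual over all pairs.
    """
    ref = np.asarray(ref_points, dtype=float)
    tgt = np.asarray(if_points, dtype=float)
    if ref.shape != tgt.shape or ref.ndim != 2 or ref.shape[1] != 2:
        raise ValueError("landmarks must be matching (n, 2) arrays")
    n = len(ref)
    if n < 3:
        raise ValueError("at least 3 landmark pairs required")
    if len(np.unique(ref, axis=0)) != n:
        raise ValueError("reference landmarks must be distinct")
    design = np.hstack([ref, np.ones((n, 1))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("landmarks are collinear; affine transform underdetermined")
    coef, *_ = np.linalg.lstsq(design, tgt, rcond=None)
    linear = coef[:2].T
    translation = coef[2]
    resid = design @ coef - tgt
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineTransform(linear=linear, translation=translation, residual_rms=rms)


def transfer_rois(
    masks: np.ndarray,
    t: AffineTransform,
    output_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Map a label image through *t* into the IF frame (nearest-neighbor labels).

    Returns the transformed label image and the labels that map fully
    outside the output frame (unmeasurable cells).
    """
    from skimage.transform import AffineTransform as SkAffine, warp

    masks = np.asarray(masks)
    shape = output_shape or masks.shape
    sk = SkAffine(matrix=t.matrix)
    warped = warp(
        masks.astype(float),
        inverse_map=sk.inverse,
        output_shape=shape,
        order=0,
        preserve_range=True,
        cval=0.0,
    ).astype(masks.dtype)
    before = set(np.unique(masks)) - {0}
    after = set(np.unique(warped)) - {0}
    lost = sorted(before - after)
    return warped, lost


def quantify_if(
    image: np.ndarray,
    masks: np.ndarray,
    background_region: tuple[slice, slice] | np.ndarray,
) -> dict[int, float]:
    """Background-corrected mean IF intensity per mask label.

    ``background_region`` is a cell-free area given as slices or a boolean
    mask; its mean intensity is subtracted from each cell's mean.
    """
    image = np.asarray(image, dtype=float)
    masks = np.asarray(masks)
    if isinstance(background_region, tuple):
        bg_mask = np.zeros(image.shape, dtype=bool)
        bg_mask[background_region] = True
    else:
        bg_mask = np.asarray(background_region, dtype=bool)
    if np.any(masks[bg_mask] != 0):
        raise ValueError("background region overlaps a cell mask")
    bg = float(np.mean(image[bg_mask]))
    out: dict[int, float] = {}
    for label in np.unique(masks):
        if label == 0:
            continue
        sel = masks == label
        if not sel.any():
            raise ValueError(f"empty mask {label}")
        out[int(label)] = float(np.mean(image[sel])) - bg
    return out


def normalize_to_reference_group(
    records: pd.DataFrame,
    reference_label: str = "ANP_PREF",
    value_col: str = "if_intensity_raw",
    label_col: str = "label",
) -> pd.DataFrame:
    """Add ``if_intensity_norm`` = raw intensity / reference-group mean.

    After normalization the reference group has mean exactly 1.
    """
    ref = records.loc[records[label_col] == reference_label, value_col]
    if ref.empty:
        raise ValueError(f"no records with reference label {reference_label!r}")
    mean = float(ref.mean())
    if mean == 0:
        raise ValueError("reference group has zero mean intensity")
    out = records.copy()
    out["if_intensity_norm"] = out[value_col] / mean
    return out


def roundness(mask: np.ndarray) -> float:
    """ImageJ-style roundness 4*area / (pi * major_axis^2) of a binary mask.

    The major axis comes from the mask's second-moment (inertia) ellipse.
    1.0 for a circle; for an ellipse with axis ratio e = major/minor the
    value is 1/e (area pi*a*b over pi*a^2).  Clipped to (0, 1].
    """
    from skimage.measure import regionprops

    mask = np.asarray(mask).astype(bool)
    area = int(mask.sum())
    if area < 5:
        raise ValueError("mask too small (<5 pixels)")
    props = regionprops(mask.astype(np.uint8))[0]
    major = props.axis_major_length
    if major <= 0:
        raise ValueError("degenerate mask: zero major axis")
    return float(np.clip(4.0 * area / (np.pi * major**2), np.finfo(float).tiny, 1.0))


def correlate_cells(
    images,
    classifications: Mapping[str, str],
    marker: str | None = None,
) -> pd.DataFrame:
    """Join classifications with registered IF intensity and shape per cell.

    *images* is a :class:`scgmp.synthio.GriddedImages`-like object (or any
    object exposing the same attributes, typically loaded from disk).  The
    transform is estimated from the landmark pairs, reference masks are
    transferred into the IF frame, intensities quantified and normalized to
    the ANP-preferring group mean, and roundness computed on the reference
    masks.  Returns a tidy records table.
    """
    t = estimate_grid_transform(images.landmarks_ref, images.landmarks_if)
    warped, lost = transfer_rois(images.masks, t, output_shape=images.immuno.shape)
    intensities = quantify_if(images.immuno, warped, images.background_region)
    rows = []
    for label_id, roi in images.roi_for_label.items():
        if label_id in lost or label_id not in intensities:
            continue
        cls = classifications.get(roi)
        if cls is None:
            continue
        rows.append(
            {
                "roi": roi,
                "label": cls,
                "marker": marker or images.marker,
                "if_intensity_raw": intensities[label_id],
                "roundness": roundness(images.masks == label_id),
            }
        )
    records = pd.DataFrame(rows)
    if not records.empty and (records["label"] == "ANP_PREF").any():
        records = normalize_to_reference_group(records)
    return records
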