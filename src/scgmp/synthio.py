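"""Ground-truth-labelled synthetic data emulating single-cell cGMP/FRET experiments.

Three generators, all deterministic for a fixed (config, seed):

* **Trace sets** — dual-channel (CFP/YFP) fluorescence time series per cell,
  driven by a saturable ratiometric sensor law (apparent EC50 = 500 nM cGMP),
  class-conditional response amplitudes (ANP-preferring, ANP~CNP,
  CNP-preferring, non-responder), first-order rise/decay kinetics, shared
  exponential photobleaching, additive Gaussian channel noise and a constant
  background offset, plus one cell-free background ROI.
* **Gridded images** — a reference image and an immunofluorescence image of
  elliptical cells on a landmark grid, the IF frame related to the reference
  frame by a configurable affine perturbation; per-cell label masks and
  paired landmark coordinates are emitted alongside.
* **Count matrices** — sparse gene x cell counts with mitochondrial-gene
  flags and optional cells/genes planted exactly at QC boundaries.

The channel construction ``CFP = CFP0*b(t)*sqrt(R/r0)``,
``YFP = YFP0*b(t)*sqrt(r0/R)`` guarantees antiparallel channel movement and
CFP/YFP proportional to the sensor ratio R, with the common bleach factor
b(t) cancelling in the ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .protocol import (
    ANP,
    CNP,
    DEFAULT_FRAME_PERIOD,
    DEFAULT_N_FRAMES,
    NO,
    StimulusEvent,
    default_protocol,
    validate_protocol,
)
from .traceproc import TraceSet

__all__ = [
    "SensorModel",
    "CellProfile",
    "SyntheticBundle",
    "TraceDatasetConfig",
    "ImageConfig",
    "BoundaryPlan",
    "CountMatrixResult",
    "sensor_ratio",
    "simulate_cgmp_course",
    "render_trace",
    "generate_trace_dataset",
    "generate_gridded_images",
    "generate_count_matrix",
    "DEFAULT_CLASS_PROFILES",
]

ANP_PREF = "ANP_PREF"
ANP_CNP = "ANP_CNP"
CNP_PREF = "CNP_PREF"
NONRESPONDER = "NONRESPONDER"
CLASS_LABELS = (ANP_PREF, ANP_CNP, CNP_PREF, NONRESPONDER)


@dataclass(frozen=True)
class SensorModel:
    """Saturable (Hill) law of the ratiometric cGMP sensor.

    ratio(c) = r0 * (1 + delta_rmax * c^hill / (c^hill + ec50^hill))

    so ratio(0) = r0, ratio(ec50) = r0*(1 + delta_rmax/2) and the saturation
    limit is r0*(1 + delta_rmax).  Default ec50 = 500 nM (apparent EC50 of
    the cGi500 indicator); hill = 1 and delta_rmax = 0.5 are free choices.
    """

    r0: float = 1.0
    delta_rmax: float = 0.5
    ec50: float = 500.0
    hill: float = 1.0

    def __post_init__(self) -> None:
        if not (self.r0 > 0 and self.delta_rmax > 0 and self.ec50 > 0 and self.hill > 0):
            raise ValueError("all sensor parameters must be positive")


def sensor_ratio(c, model: SensorModel = SensorModel()):
    """Sensor CFP/YFP ratio at cGMP concentration *c* (nM; scalar or array)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("cGMP concentration must be non-negative")
    ch = np.power(c, model.hill)
    out = model.r0 * (1.0 + model.delta_rmax * ch / (ch + model.ec50**model.hill))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CellProfile:
    """Ground-truth response phenotype of one synthetic cell."""

    true_class: str
    #: stimulus -> evoked cGMP amplitude (nM)
    amp: Mapping[str, float]
    rise_tau: float = 10.0  # s
    decay_tau: float = 25.0  # s; transients decay fully between stimuli
    bleach_tau: float = 4000.0  # s; np.inf disables bleaching
    #: extra YFP-only bleach time constant (np.inf disables); makes the
    #: channel ratio itself drift, exercising drift correction downstream
    differential_bleach_tau: float = float("inf")
    noise_sd: float = 0.0  # fraction of channel baseline
    elongation: float = 1.0  # major/minor axis ratio, >= 1
    marker_levels: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amp.values()):
            raise ValueError("amplitudes must be non-negative")
        if self.true_class == NONRESPONDER and any(a != 0 for a in self.amp.values()):
            raise ValueError("NONRESPONDER must have all amplitudes zero")
        if self.elongation < 1:
            raise ValueError("elongation must be >= 1")


# Class-conditional defaults.  Amplitudes (nM cGMP) are chosen so the
# noiseless sensor-peak ratio between the preferred and non-preferred
# peptide clearly exceeds the 1.5x classification threshold (2.0x), NO
# amplitudes fall with phenotypic modulation (NO-GC downregulation in
# modulated cells), elongation falls from contractile to modulated cells,
# and contractile markers (aSMA) anti-correlate with non-SMC markers
# (S100A4) across classes.
DEFAULT_CLASS_PROFILES: dict[str, CellProfile] = {
    ANP_PREF: CellProfile(
        ANP_PREF,
        amp={ANP: 1500.0, CNP: 300.0, NO: 1000.0},
        elongation=3.0,
        marker_levels={"aSMA": 200.0, "S100A4": 60.0},
    ),
    ANP_CNP: CellProfile(
        ANP_CNP,
        amp={ANP: 800.0, CNP: 800.0, NO: 600.0},
        elongation=2.0,
        marker_levels={"aSMA": 140.0, "S100A4": 100.0},
    ),
    CNP_PREF: CellProfile(
        CNP_PREF,
        amp={ANP: 300.0, CNP: 1500.0, NO: 200.0},
        elongation=1.3,
        marker_levels={"aSMA": 80.0, "S100A4": 180.0},
    ),
    NONRESPONDER: CellProfile(
        NONRESPONDER,
        amp={ANP: 0.0, CNP: 0.0, NO: 0.0},
        elongation=2.0,
        marker_levels={"aSMA": 120.0, "S100A4": 120.0},
    ),
}


def simulate_cgmp_course(
    protocol: Sequence[StimulusEvent],
    profile: CellProfile,
    n_frames: int,
    frame_period: float = DEFAULT_FRAME_PERIOD,
) -> np.ndarray:
    """Intracellular cGMP concentration (nM) per frame for one cell.

    Each event contributes a first-order rise toward ``amp[drug]`` during
    its window and an exponential decay after it; contributions of
    successive events superpose.  ``rise_tau``/``decay_tau`` of 0 give
    rectangular pulses.
    """
    validate_protocol(protocol)
    for ev in protocol:
        if ev.start_frame < 0 or ev.end_frame > n_frames:
            raise ValueError(f"event window {ev} outside [0, {n_frames})")
    t = np.arange(n_frames, dtype=float) * frame_period
    c = np.zeros(n_frames)
    for ev in protocol:
        amp = float(profile.amp.get(ev.drug, 0.0))
        if amp == 0.0:
            continue
        t_on = ev.start_frame * frame_period
        t_off = ev.end_frame * frame_period
        during = (t >= t_on) & (t < t_off)
        after = t >= t_off
        if profile.rise_tau > 0:
            rise = amp * (1.0 - np.exp(-(t[during] - t_on) / profile.rise_tau))
            level_off = amp * (1.0 - math.exp(-(t_off - t_on) / profile.rise_tau))
        else:
            rise = np.full(during.sum(), amp)
            level_off = amp
        c[during] += rise
        if profile.decay_tau > 0:
            c[after] += level_off * np.exp(-(t[after] - t_off) / profile.decay_tau)
        # decay_tau == 0: concentration drops to 0 immediately after t_off
    return c


def render_trace(
    course: np.ndarray,
    profile: CellProfile,
    model: SensorModel = SensorModel(),
    seed: int = 0,
    cfp0: float = 1000.0,
    yfp0: float = 1000.0,
    frame_period: float = DEFAULT_FRAME_PERIOD,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a cGMP course into noisy, bleached CFP and YFP channel traces.

    CFP(t) = CFP0 * b(t) * sqrt(R(c_t)/r0) * (1 + e1),
    YFP(t) = YFP0 * b(t) * d(t) * sqrt(r0/R(c_t)) * (1 + e2),

    with b(t) = exp(-t/bleach_tau) common to both channels, an optional
    YFP-only differential bleach d(t), and i.i.d. Gaussian noise of SD
    ``noise_sd`` per channel.  Background offsets are NOT included here;
    they are added by :func:`generate_trace_dataset` and recorded separately.
    """
    course = np.asarray(course, dtype=float)
    if not np.all(np.isfinite(course)) or np.any(course < 0):
        raise ValueError("course must be finite and non-negative")
    t = np.arange(len(course), dtype=float) * frame_period
    ratio = sensor_ratio(course, model)
    b = (
        np.exp(-t / profile.bleach_tau)
        if np.isfinite(profile.bleach_tau)
        else np.ones_like(t)
    )
    d = (
        np.exp(-t / profile.differential_bleach_tau)
        if np.isfinite(profile.differential_bleach_tau)
        else np.ones_like(t)
    )
    rng = np.random.default_rng(seed)
    e1 = rng.normal(0.0, profile.noise_sd, len(course)) if profile.noise_sd else 0.0
    e2 = rng.normal(0.0, profile.noise_sd, len(course)) if profile.noise_sd else 0.0
    cfp = cfp0 * b * np.sqrt(ratio / model.r0) * (1.0 + e1)
    yfp = yfp0 * b * d * np.sqrt(model.r0 / ratio) * (1.0 + e2)
    return cfp, yfp


@dataclass(frozen=True)
class TraceDatasetConfig:
    """Study conditions for a synthetic trace cohort.

    ``noise_sd`` = 0.013 puts the smallest class-default response peak
    (~0.19 ratio units) at ~10x the baseline ratio noise
    (sqrt(2)*0.013 ~ 0.018), i.e. SNR ~ 10.
    """

    n_cells: int = 300
    proportions: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.25 for c in CLASS_LABELS}
    )
    exact_split: bool = True
    protocol: tuple[StimulusEvent, ...] = tuple(default_protocol())
    n_frames: int = DEFAULT_N_FRAMES
    frame_period: float = DEFAULT_FRAME_PERIOD
    sensor: SensorModel = SensorModel()
    noise_sd: float = 0.013
    bleach_tau: float = 4000.0
    differential_bleach_tau: float = float("inf")
    cfp0: float = 1000.0
    yfp0: float = 1000.0
    background_offset_cfp: float = 100.0
    background_offset_yfp: float = 120.0
    background_noise_sd: float = 1.0  # absolute a.u. on the background ROI

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1 (got {total})")
        if any(v < 0 for v in self.proportions.values()):
            raise ValueError("proportions must be non-negative")
        unknown = set(self.proportions) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels {unknown}")


@dataclass
class SyntheticBundle:
    """A generated trace cohort with its ground truth (and optional images)."""

    traces: TraceSet
    truth: dict[str, CellProfile]
    seed: int
    images: "GriddedImages | None" = None

    def __post_init__(self) -> None:
        missing = set(self.traces.rois) - set(self.truth)
        if missing:
            raise ValueError(f"ROIs without truth entries: {missing}")


def _class_counts(cfg: TraceDatasetConfig, rng: np.random.Generator) -> dict[str, int]:
    labels = [c for c in CLASS_LABELS if cfg.proportions.get(c, 0.0) > 0]
    props = np.array([cfg.proportions[c] for c in labels])
    if cfg.exact_split:
        counts = np.floor(props * cfg.n_cells).astype(int)
        # distribute the remainder by largest fractional part
        frac = props * cfg.n_cells - counts
        for i in np.argsort(-frac)[: cfg.n_cells - counts.sum()]:
            counts[i] += 1
    else:
        counts = rng.multinomial(cfg.n_cells, props / props.sum())
    return dict(zip(labels, (int(k) for k in counts)))


def generate_trace_dataset(
    cfg: TraceDatasetConfig = TraceDatasetConfig(), seed: int = 0
) -> SyntheticBundle:
    """Generate a labelled cohort of dual-channel traces plus a background ROI."""
    rng = np.random.default_rng(seed)
    counts = _class_counts(cfg, rng)

    cfp: dict[str, np.ndarray] = {}
    yfp: dict[str, np.ndarray] = {}
    truth: dict[str, CellProfile] = {}
    i = 0
    for label in CLASS_LABELS:
        base = DEFAULT_CLASS_PROFILES[label]
        profile = replace(
            base,
            noise_sd=cfg.noise_sd,
            bleach_tau=cfg.bleach_tau,
            differential_bleach_tau=cfg.differential_bleach_tau,
        )
        for _ in range(counts.get(label, 0)):
            roi = f"cell_{i:04d}"
            course = simulate_cgmp_course(
                cfg.protocol, profile, cfg.n_frames, cfg.frame_period
            )
            # per-cell child seed keeps cells independent yet reproducible
            c, y = render_trace(
                course,
                profile,
                cfg.sensor,
                seed=rng.integers(0, 2**31 - 1),
                cfp0=cfg.cfp0,
                yfp0=cfg.yfp0,
                frame_period=cfg.frame_period,
            )
            cfp[roi] = c + cfg.background_offset_cfp
            yfp[roi] = y + cfg.background_offset_yfp
            truth[roi] = profile
            i += 1

    bg_c = cfg.background_offset_cfp + rng.normal(
        0.0, cfg.background_noise_sd, cfg.n_frames
    )
    bg_y = cfg.background_offset_yfp + rng.normal(
        0.0, cfg.background_noise_sd, cfg.n_frames
    )
    cfp["background"] = bg_c
    yfp["background"] = bg_y

    traces = TraceSet(
        frame_period=cfg.frame_period,
        cfp=cfp,
        yfp=yfp,
        background_roi="background",
        protocol=list(cfg.protocol),
    )
    return SyntheticBundle(traces=traces, truth=truth, seed=seed)


# ---------------------------------------------------------------------------
# Gridded images


@dataclass(frozen=True)
class ImageConfig:
    """Rendering parameters for the paired reference / IF images."""

    shape: tuple[int, int] = (512, 512)
    cell_area_px: float = 400.0
    grid_spacing: int = 64
    position_jitter: float = 8.0
    n_landmarks: int = 5
    marker: str = "aSMA"
    if_background: float = 20.0
    if_noise_sd: float = 0.0
    reference_intensity: float = 150.0
    # affine perturbation reference -> IF frame
    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_landmarks < 3:
            raise ValueError("at least 3 grid landmarks required")


@dataclass
class GriddedImages:
    """Reference image, IF image, per-cell label masks and paired landmarks."""

    reference: np.ndarray
    immuno: np.ndarray
    masks: np.ndarray  # label image in the reference frame; 0 = background
    roi_for_label: dict[int, str]
    landmarks_ref: np.ndarray  # (n, 2) (x, y) pixels
    landmarks_if: np.ndarray
    transform_matrix: np.ndarray  # 3x3 homogeneous, reference -> IF
    background_region: tuple[slice, slice]
    marker: str


def _affine_matrix(cfg: ImageConfig, center: tuple[float, float]) -> np.ndarray:
    """Rotation+scale about the image center, then translation; (x, y) convention."""
    th = math.radians(cfg.rotation_deg)
    s = cfg.scale
    cx, cy = center
    a = s * math.cos(th)
    b = s * math.sin(th)
    # rotate/scale about center, then translate
    tx = cx - (a * cx - b * cy) + cfg.translation[0]
    ty = cy - (b * cx + a * cy) + cfg.translation[1]
    return np.array([[a, -b, tx], [b, a, ty], [0.0, 0.0, 1.0]])


def _apply_affine(m: np.ndarray, pts: np.ndarray) -> np.ndarray:
    pts = np.asarray(pts, dtype=float)
    homo = np.hstack([pts, np.ones((len(pts), 1))])
    return (homo @ m.T)[:, :2]


def generate_gridded_images(
    bundle: SyntheticBundle,
    cfg: ImageConfig = ImageConfig(),
    seed: int = 0,
) -> GriddedImages:
    """Render paired reference/IF images of the bundle's cells on a grid.

    Cells are drawn as ellipses (axis ratio = the profile's elongation) at
    jittered grid positions in the reference frame; the IF image shows the
    same ellipses mapped by the configured affine perturbation, filled with
    the class-conditional marker intensity plus a constant background and
    optional noise.  A cell-free rectangle in the IF frame is reserved for
    background correction.  Requires more grid positions than cells.
    """
    from skimage.draw import ellipse as draw_ellipse

    rng = np.random.default_rng(seed)
    h, w = cfg.shape
    rois = bundle.traces.rois

    # candidate centers on the etched grid, away from the border and from
    # the background-correction rectangle in the top-left corner
    centers = [
        (float(x), float(y))
        for y in range(cfg.grid_spacing, h - cfg.grid_spacing // 2, cfg.grid_spacing)
        for x in range(cfg.grid_spacing, w - cfg.grid_spacing // 2, cfg.grid_spacing)
    ]
    if len(rois) > len(centers):
        raise ValueError(
            f"{len(rois)} cells do not fit on a {cfg.grid_spacing}px grid in {cfg.shape}"
        )
    order = rng.permutation(len(centers))[: len(rois)]

    m = _affine_matrix(cfg, center=((w - 1) / 2.0, (h - 1) / 2.0))

    reference = np.zeros(cfg.shape, dtype=float)
    immuno = np.full(cfg.shape, cfg.if_background, dtype=float)
    masks = np.zeros(cfg.shape, dtype=np.int32)
    roi_for_label: dict[int, str] = {}

    for label_id, (roi, ci) in enumerate(zip(rois, order), start=1):
        profile = bundle.truth[roi]
        cx, cy = centers[ci]
        cx += rng.uniform(-cfg.position_jitter, cfg.position_jitter)
        cy += rng.uniform(-cfg.position_jitter, cfg.position_jitter)
        e = profile.elongation
        minor = math.sqrt(cfg.cell_area_px / (math.pi * e))
        major = e * minor
        theta = rng.uniform(0, math.pi)
        rr, cc = draw_ellipse(cy, cx, minor, major, shape=cfg.shape, rotation=theta)
        masks[rr, cc] = label_id
        reference[rr, cc] = cfg.reference_intensity
        roi_for_label[label_id] = roi

        # same ellipse in the IF frame: mapped center, rotated orientation,
        # scaled axes
        ifc = _apply_affine(m, np.array([[cx, cy]]))[0]
        th_if = theta - math.radians(cfg.rotation_deg)  # y-down: rotation flips sign
        rr2, cc2 = draw_ellipse(
            ifc[1],
            ifc[0],
            minor * cfg.scale,
            major * cfg.scale,
            shape=cfg.shape,
            rotation=th_if,
        )
        level = float(profile.marker_levels.get(cfg.marker, 0.0))
        immuno[rr2, cc2] = cfg.if_background + level

    if cfg.if_noise_sd > 0:
        immuno = immuno + rng.normal(0.0, cfg.if_noise_sd, cfg.shape)

    # grid-cross landmarks: corner-ish grid intersections plus the center
    lm_candidates = np.array(
        [
            (cfg.grid_spacing, cfg.grid_spacing),
            (w - cfg.grid_spacing, cfg.grid_spacing),
            (cfg.grid_spacing, h - cfg.grid_spacing),
            (w - cfg.grid_spacing, h - cfg.grid_spacing),
            (w // 2, h // 2),
            (w // 2, cfg.grid_spacing),
            (cfg.grid_spacing, h // 2),
            (w - cfg.grid_spacing, h // 2),
            (w // 2, h - cfg.grid_spacing),
        ],
        dtype=float,
    )
    lm_ref = lm_candidates[: cfg.n_landmarks]
    lm_if = _apply_affine(m, lm_ref)

    return GriddedImages(
        reference=reference,
        immuno=immuno,
        masks=masks,
        roi_for_label=roi_for_label,
        landmarks_ref=lm_ref,
        landmarks_if=lm_if,
        transform_matrix=m,
        background_region=(slice(0, 24), slice(0, 24)),
        marker=cfg.marker,
    )


# ---------------------------------------------------------------------------
# Count matrices


@dataclass(frozen=True)
class PlantedCell:
    """A cell constructed with exact QC statistics."""

    detected_genes: int
    total_counts: int
    mito_pct: float = 0.0


@dataclass(frozen=True)
class PlantedGene:
    """A gene constructed to be detected in exactly `detected_in_cells` cells."""

    detected_in_cells: int


@dataclass(frozen=True)
class BoundaryPlan:
    cells: tuple[PlantedCell, ...] = ()
    genes: tuple[PlantedGene, ...] = ()


@dataclass
class CountMatrixResult:
    """Sparse counts plus ids, mito flags and planted-entity metadata."""

    counts: "scipy.sparse.csc_matrix"
    gene_ids: list[str]
    cell_ids: list[str]
    mito: np.ndarray  # boolean per gene
    planted_cells: dict[str, PlantedCell]
    planted_genes: dict[str, PlantedGene]


def _planted_column(
    plan: PlantedCell, n_genes: int, mito: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    d, total = plan.detected_genes, plan.total_counts
    m_counts = int(round(total * plan.mito_pct / 100.0))
    if d < 1 or total < d:
        raise ValueError("planted cell needs total_counts >= detected_genes >= 1")
    col = np.zeros(n_genes, dtype=np.int64)
    mito_idx = np.flatnonzero(mito)
    nonmito_idx = np.flatnonzero(~mito)
    n_mito_genes = 1 if m_counts > 0 else 0
    n_nonmito_genes = d - n_mito_genes
    if n_mito_genes > len(mito_idx) or n_nonmito_genes > len(nonmito_idx):
        raise ValueError("not enough genes to plant cell")
    if m_counts > 0:
        col[rng.choice(mito_idx, 1)[0]] = m_counts
    if n_nonmito_genes > 0:
        chosen = rng.choice(nonmito_idx, n_nonmito_genes, replace=False)
        col[chosen] = 1
        remainder = total - m_counts - n_nonmito_genes
        if remainder < 0:
            raise ValueError("mito_pct incompatible with detected_genes/total_counts")
        col[chosen[0]] += remainder
    elif total - m_counts != 0:
        raise ValueError("all-mito planted cell must put all counts on mito genes")
    return col


def generate_count_matrix(
    n_genes: int = 2000,
    n_cells: int = 200,
    plan: BoundaryPlan = BoundaryPlan(),
    seed: int = 0,
    n_mito_genes: int = 13,
    mean_detected: int = 600,
    mean_total: int = 10000,
) -> CountMatrixResult:
    """Generate a sparse gene x cell count matrix with QC-boundary plants.

    Background cells draw their counts from gene-specific log-normal rates
    scaled so a typical cell detects ~``mean_detected`` genes, keeps a mito
    fraction well under 20%, and totals well above 3000.  Planted cells
    are appended after the background cells with exact detected-gene,
    total-count and mito-percentage values; planted genes are appended after
    the background genes with counts only in non-planted cells.
    """
    from scipy import sparse

    rng = np.random.default_rng(seed)
    n_bg_cells = n_cells
    n_bg_genes = n_genes

    mito = np.zeros(n_bg_genes + len(plan.genes), dtype=bool)
    mito[:n_mito_genes] = True

    rates = rng.lognormal(mean=0.0, sigma=1.0, size=n_bg_genes)
    # scale so expected detected genes per cell ~ mean_detected
    # P(detect) = 1 - exp(-lam); tune a global factor by bisection
    target_detected = min(mean_detected, 0.7 * n_bg_genes)

    def detected(f):
        return float(np.sum(1.0 - np.exp(-f * rates)))

    lo_f, hi_f = 1e-6, 1e3
    for _ in range(60):
        mid = math.sqrt(lo_f * hi_f)
        if detected(mid) < target_detected:
            lo_f = mid
        else:
            hi_f = mid
    lam = hi_f * rates

    # deepen the library: boost already-saturated genes until the expected
    # total per cell reaches mean_total (leaves detection probs ~unchanged)
    shortfall = mean_total - float(lam.sum())
    if shortfall > 0:
        top = lam >= np.quantile(lam, 0.9)
        lam[top] *= 1.0 + shortfall / float(lam[top].sum())

    # pin the expected mitochondrial share at ~6% of the library (healthy
    # cells sit well below the 20% QC bound)
    if n_mito_genes > 0 and lam[:n_mito_genes].sum() > 0:
        mito_share = 0.06
        other = float(lam[n_mito_genes:].sum())
        lam[:n_mito_genes] *= (
            mito_share * other / ((1.0 - mito_share) * float(lam[:n_mito_genes].sum()))
        )

    cols: list[np.ndarray] = []
    for _ in range(n_bg_cells):
        size_factor = rng.lognormal(0.0, 0.25)
        cols.append(rng.poisson(lam * size_factor))
    bg = np.stack(cols, axis=1).astype(np.int64)  # genes x cells

    planted_cols = [
        _planted_column(pc, n_bg_genes, mito[:n_bg_genes], rng) for pc in plan.cells
    ]
    counts = (
        np.hstack([bg] + [c[:, None] for c in planted_cols]) if planted_cols else bg
    )

    # planted genes: rows detected in exactly k non-planted cells
    gene_rows = []
    for pg in plan.genes:
        if pg.detected_in_cells > n_bg_cells:
            raise ValueError("planted gene cannot exceed the background cell count")
        row = np.zeros(counts.shape[1], dtype=np.int64)
        idx = rng.choice(n_bg_cells, pg.detected_in_cells, replace=False)
        row[idx] = 1
        gene_rows.append(row)
    if gene_rows:
        counts = np.vstack([counts, np.stack(gene_rows)])

    gene_ids = [f"mt-G{i:04d}" if mito[i] else f"G{i:04d}" for i in range(n_bg_genes)]
    gene_ids += [f"planted_gene_{j}" for j in range(len(plan.genes))]
    cell_ids = [f"C{i:04d}" for i in range(n_bg_cells)]
    cell_ids += [f"planted_cell_{j}" for j in range(len(plan.cells))]

    return CountMatrixResult(
        counts=sparse.csc_matrix(counts),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        mito=mito,
        planted_cells={
            f"planted_cell_{j}": pc for j, pc in enumerate(plan.cells)
        },
        planted_genes={
            f"planted_gene_{j}": pg for j, pg in enumerate(plan.genes)
        },
    )
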