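"""Whole-mount spatial quantification.

Registers dural whole-mount images to a common sinus reference with a
control-point affine, binarizes signal channels with batch-consistent
thresholds, aggregates per-pixel mean heatmaps across samples, partitions
the tissue into a sinus-proximal area (SPA: sinus plus everything within a
fixed distance, default 300 um, of the sinus edge) and a sinus-distal area
(SDA: everything farther), and reports signal coverage per region.

Conventions: images are 2D arrays indexed (row, col), 0-based, pixel centers
at integer coordinates; pixel size is isotropic in um/px. Masks are boolean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

REGION_SPA = "SPA"
REGION_SDA = "SDA"


@dataclass
class WholeMountImage:
    """A registered (or raw) multi-channel whole-mount raster.

    ``channel_roles`` maps each channel name to ``"landmark"`` (vessel /
    sinus stain, e.g. aSMA) or ``"signal"`` (e.g. B220, Cxcl12 reporter).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    channel_roles: dict[str, str]
    sample_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels must share one shape, got {shapes}")
        roles = set(self.channel_roles.values())
        if not {"landmark", "signal"} <= roles:
            raise ValueError("need at least one landmark and one signal channel")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class RegistrationTransform:
    """2D affine ``A`` (2x3) mapping moving pixel coords to reference coords."""

    matrix: np.ndarray
    residual_rms: float
    output_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("affine matrix must be finite")
        if self.residual_rms < 0:
            raise ValueError("residual RMS must be >= 0")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]


@dataclass
class BinarizationConfig:
    """Absolute per-channel thresholds, fixed once per acquisition batch."""

    batch_id: str
    thresholds: Mapping[str, float]

    def threshold_for(self, channel: str) -> float:
        if channel not in self.thresholds:
            raise KeyError(
                f"no threshold defined for channel {channel!r} in batch "
                f"{self.batch_id!r}; thresholds are set per batch, never "
                "auto-derived per image"
            )
        t = float(self.thresholds[channel])
        if not np.isfinite(t):
            raise ValueError(f"threshold for {channel!r} must be finite")
        return t


@dataclass
class RegionPartition:
    """SPA / SDA partition of the canvas derived from the sinus mask."""

    sinus: np.ndarray
    spa: np.ndarray
    sda: np.ndarray
    exclusions: np.ndarray
    dilation_um: float
    pixel_size: float

    def __post_init__(self) -> None:
        assert not np.any(self.spa & self.sda), "SPA and SDA must be disjoint"
        assert not np.any(self.exclusions & (self.spa | self.sda))

    def region_mask(self, region: str) -> np.ndarray:
        if region == REGION_SPA:
            return self.spa
        if region == REGION_SDA:
            return self.sda
        raise KeyError(region)


@dataclass
class AggregateHeatmap:
    """Per-pixel mean of binarized masks across registered samples."""

    mean: np.ndarray
    n_valid: np.ndarray
    n_samples: int
    group: str = ""


def fit_registration(
    moving: np.ndarray,
    fixed: np.ndarray,
    output_shape: tuple[int, int] | None = None,
) -> RegistrationTransform:
    """Least-squares affine from moving/fixed control-point pairs.

    Minimizes sum ||A @ moving_i - fixed_i||^2 over 2x3 affines A. Requires
    at least three pairs whose moving points are not collinear.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.ndim != 2 or moving.shape[1] != 2 or moving.shape != fixed.shape:
        raise ValueError("moving and fixed must both be (n, 2) arrays")
    n = moving.shape[0]
    if n < 3:
        raise ValueError(f"affine fit needs >= 3 point pairs, got {n}")
    centered = moving - moving.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10 * max(1.0, np.abs(moving).max())) < 2:
        raise ValueError("moving points are collinear; affine fit is degenerate")
    design = np.hstack([moving, np.ones((n, 1))])
    coef, *_ = np.linalg.lstsq(design, fixed, rcond=None)
    matrix = coef.T  # (2, 3)
    resid = design @ coef - fixed
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    if output_shape is None:
        shape = tuple(int(np.ceil(fixed[:, i].max())) + 1 for i in range(2))
        output_shape = (shape[0], shape[1])
    return RegistrationTransform(matrix=matrix, residual_rms=rms, output_shape=output_shape)


def warp_channel(
    channel: np.ndarray,
    transform: RegistrationTransform,
    *,
    is_mask: bool | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a channel onto the reference canvas.

    Intensity channels use bilinear interpolation, boolean masks nearest
    neighbor (preserving binarity). Returns ``(warped, valid)`` where
    ``valid`` marks reference pixels that map inside the moving image;
    out-of-field pixels are filled with 0.
    """
    channel = np.asarray(channel)
    if is_mask is None:
        is_mask = channel.dtype == bool
    linear = transform.matrix[:, :2]
    det = np.linalg.det(linear)
    if not np.isfinite(det) or abs(det) < 1e-12:
        raise ValueError("registration transform is not invertible")
    inv = np.linalg.inv(linear)
    offset = -inv @ transform.matrix[:, 2]
    order = 0 if is_mask else 1
    warped = ndimage.affine_transform(
        channel.astype(float),
        inv,
        offset=offset,
        output_shape=transform.output_shape,
        order=order,
        mode="constant",
        cval=0.0,
    )
    valid = ndimage.affine_transform(
        np.ones_like(channel, dtype=float),
        inv,
        offset=offset,
        output_shape=transform.output_shape,
        order=0,
        mode="constant",
        cval=0.0,
    ) > 0.5
    if is_mask:
        return warped > 0.5, valid
    return warped, valid


def binarize_channel(
    channel: np.ndarray, channel_name: str, config: BinarizationConfig
) -> np.ndarray:
    """Strict ``intensity > threshold`` mask using the batch threshold."""
    t = config.threshold_for(channel_name)
    return np.asarray(channel) > t


def apply_exclusions(mask: np.ndarray, exclusions: Sequence[np.ndarray]) -> np.ndarray:
    """Remove manually-masked regions (pineal gland, bubbles) from a mask."""
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    for excl in exclusions:
        excl = np.asarray(excl, dtype=bool)
        if excl.shape != mask.shape:
            raise ValueError(
                f"exclusion shape {excl.shape} does not match mask {mask.shape}"
            )
        out &= ~excl
    return out


def aggregate_heatmap(
    masks: Sequence[np.ndarray],
    valid: Sequence[np.ndarray] | None = None,
    group: str = "",
) -> AggregateHeatmap:
    """Arithmetic per-pixel mean of 0/1 masks for one experimental group.

    When per-sample validity masks are given (from warping), each pixel
    averages only the samples valid there; pixels valid in no sample are NaN.
    """
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    shape = np.asarray(masks[0]).shape
    stack = np.empty((len(masks),) + shape, dtype=float)
    for i, m in enumerate(masks):
        m = np.asarray(m)
        if m.shape != shape:
            raise ValueError("masks must share one canvas")
        stack[i] = m.astype(float)
    if valid is None:
        vstack = np.ones_like(stack, dtype=bool)
    else:
        if len(valid) != len(masks):
            raise ValueError("one validity mask per sample required")
        vstack = np.stack([np.asarray(v, dtype=bool) for v in valid])
    n_valid = vstack.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_valid > 0, (stack * vstack).sum(axis=0) / np.maximum(n_valid, 1), np.nan)
    return AggregateHeatmap(mean=mean, n_valid=n_valid, n_samples=len(masks), group=group)


def segment_regions(
    sinus: np.ndarray,
    exclusions: np.ndarray | None = None,
    *,
    dilation_um: float = 300.0,
    pixel_size: float = 1.0,
) -> RegionPartition:
    """Partition the canvas into sinus-proximal and sinus-distal areas.

    SPA is every pixel whose Euclidean distance to the nearest sinus pixel is
    at most ``dilation_um`` (the sinus itself included); SDA is the rest of
    the canvas. Exclusion pixels belong to neither. The distance is the true
    Euclidean distance transform in pixels scaled by ``pixel_size`` — no
    integer rounding of the radius.
    """
    sinus = np.asarray(sinus, dtype=bool)
    if not sinus.any():
        raise ValueError("sinus mask is empty; SPA/SDA partition is undefined")
    if dilation_um < 0:
        raise ValueError("dilation_um must be >= 0")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if exclusions is None:
        exclusions = np.zeros_like(sinus)
    exclusions = np.asarray(exclusions, dtype=bool)
    if exclusions.shape != sinus.shape:
        raise ValueError("exclusion mask shape must match sinus mask")
    dist_px = ndimage.distance_transform_edt(~sinus)
    within = dist_px * pixel_size <= dilation_um
    spa = within & ~exclusions
    sda = ~within & ~exclusions
    return RegionPartition(
        sinus=sinus, spa=spa, sda=sda, exclusions=exclusions,
        dilation_um=dilation_um, pixel_size=pixel_size,
    )


def compute_coverage(
    signal: np.ndarray, partition: RegionPartition, sample_id: str = ""
) -> pd.DataFrame:
    """Coverage report for one binarized signal channel.

    For each region R in {SPA, SDA}: ``coverage_pct`` = 100*|signal ∩ R|/|R|
    (percent of the region occupied by signal) and ``signal_fraction_pct`` =
    100*|signal ∩ R| / |signal in SPA ∪ SDA| (percent of total signal in the
    region). Excluded pixels count toward neither numerator nor denominator.
    """
    signal = np.asarray(signal, dtype=bool)
    if signal.shape != partition.sinus.shape:
        raise ValueError("signal mask shape must match partition canvas")
    sig = signal & ~partition.exclusions
    total_signal = int((sig & (partition.spa | partition.sda)).sum())
    rows = []
    for region in (REGION_SPA, REGION_SDA):
        rmask = partition.region_mask(region)
        area = int(rmask.sum())
        s = int((sig & rmask).sum())
        if area == 0:
            warnings.warn(f"region {region} is empty; coverage undefined", stacklevel=2)
            cov = np.nan
        else:
            cov = 100.0 * s / area
        frac = 100.0 * s / total_signal if total_signal > 0 else np.nan
        rows.append(
            {
                "sample": sample_id,
                "region": region,
                "area_px": area,
                "area_um2": area * partition.pixel_size**2,
                "signal_px": s,
                "coverage_pct": cov,
                "signal_fraction_pct": frac,
            }
        )
    return pd.DataFrame(rows)


def roi_percent_coverage(
    mask: np.ndarray, roi: tuple[int, int, int, int]
) -> float:
    """Percent of an axis-aligned rectangular ROI covered by true pixels.

    ``roi`` is ``(row_start, col_start, n_rows, n_cols)`` in pixels. Used for
    the BaseScope-style quantification: a rectangle centered on the sinus
    confluence, percent area covered by thresholded signal.
    """
    mask = np.asarray(mask, dtype=bool)
    r0, c0, nr, nc = roi
    if nr <= 0 or nc <= 0:
        raise ValueError("ROI must have positive area")
    if r0 < 0 or c0 < 0 or r0 + nr > mask.shape[0] or c0 + nc > mask.shape[1]:
        raise ValueError(f"ROI {roi} exceeds canvas {mask.shape}")
    window = mask[r0 : r0 + nr, c0 : c0 + nc]
    return 100.0 * float(window.sum()) / (nr * nc)


def propose_batch_threshold(channels: Sequence[np.ndarray]) -> float:
    """Otsu threshold over the pooled intensities of a batch's channels.

    A helper for choosing one absolute threshold per channel per batch; it is
    never applied implicitly — the chosen value goes into a
    :class:`BinarizationConfig`.
    """
    pooled = np.concatenate([np.asarray(c, dtype=float).ravel() for c in channels])
    return float(threshold_otsu(pooled))
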