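"""Synthetic dural whole-mount images.

Emulates tile scans of flattened dura stained for a vessel landmark (the
dural venous sinuses: a sagittal trunk meeting two transverse branches at a
confluence) and a signal channel (B cells or a niche reporter) whose pixels
are enriched within a fixed distance (default 300 um) of the sinuses. The
sinus geometry is parameterized as centerline polylines plus a width, so the
ground-truth sinus mask, the proximal band, and the exact signal mask are
all known by construction.

Signal placement is collision-free: exactly ``n_clusters *
pixels_per_cluster`` distinct pixels are set. Each cluster (or, in
``"uniform"`` mode, each pixel) is assigned to the proximal band with
probability ``proximal_fraction``; the realized proximal fraction is
therefore binomial with n = n_clusters (clustered) or n = total pixels
(uniform).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import disk, line

from duraquant.spatial import WholeMountImage


def _default_polylines(shape: tuple[int, int]) -> list[np.ndarray]:
    """Sagittal trunk down the midline meeting two transverse branches."""
    rows, cols = shape
    confluence = (int(rows * 0.55), cols // 2)
    return [
        np.array([(int(rows * 0.05), cols // 2), confluence]),
        np.array([confluence, (int(rows * 0.9), int(cols * 0.08))]),
        np.array([confluence, (int(rows * 0.9), int(cols * 0.92))]),
    ]


@dataclass
class SinusGeometry:
    """Sinus centerlines (pixel (row, col) vertices) and vessel width in um."""

    polylines: list[np.ndarray]
    width_um: float = 150.0


@dataclass
class ArtifactSpec:
    """A bright blob mimicking pineal-gland autofluorescence."""

    center: tuple[int, int]
    radius_um: float
    intensity: float = 1.0


@dataclass
class ImageSimConfig:
    shape: tuple[int, int] = (256, 256)
    pixel_size: float = 10.0  # um/px
    sinus: SinusGeometry | None = None
    n_clusters: int = 30
    cluster_radius_um: float = 100.0
    pixels_per_cluster: int = 40
    proximal_fraction: float = 0.8
    dilation_um: float = 300.0
    placement: str = "clustered"  # or "uniform"
    noise_level: float = 0.2
    artifact: ArtifactSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.proximal_fraction <= 1.0:
            raise ValueError("proximal_fraction must be in [0, 1]")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.placement not in ("clustered", "uniform"):
            raise ValueError("placement must be 'clustered' or 'uniform'")
        if self.sinus is None:
            self.sinus = SinusGeometry(polylines=_default_polylines(self.shape))
        for poly in self.sinus.polylines:
            poly = np.asarray(poly)
            if np.any(poly < 0) or np.any(poly[:, 0] >= self.shape[0]) or np.any(
                poly[:, 1] >= self.shape[1]
            ):
                raise ValueError(
                    f"sinus polyline vertices {poly.tolist()} fall outside the "
                    f"canvas {self.shape}"
                )


def _rasterize_sinus(config: ImageSimConfig) -> np.ndarray:
    center = np.zeros(config.shape, dtype=bool)
    for poly in config.sinus.polylines:
        poly = np.asarray(poly, dtype=int)
        for (r0, c0), (r1, c1) in zip(poly[:-1], poly[1:]):
            rr, cc = line(r0, c0, r1, c1)
            center[rr, cc] = True
    half_w_px = (config.sinus.width_um / 2.0) / config.pixel_size
    return ndimage.distance_transform_edt(~center) <= half_w_px


def _sample_cluster(
    rng: np.random.Generator,
    pool_flat: np.ndarray,
    available: np.ndarray,
    center_flat: int,
    radius_px: float,
    n_pixels: int,
    shape: tuple[int, int],
) -> np.ndarray:
    """Pick ``n_pixels`` distinct available pool pixels near a center."""
    cr, cc = divmod(center_flat, shape[1])
    pr, pc = divmod(pool_flat, shape[1])
    r = radius_px
    while True:
        near = (pr - cr) ** 2 + (pc - cc) ** 2 <= r**2
        cand = pool_flat[near & available]
        if len(cand) >= n_pixels or r > max(shape) * 2:
            break
        r *= 1.5
    if len(cand) < n_pixels:  # pool nearly exhausted: top up from anywhere in it
        cand = pool_flat[available]
    chosen = rng.choice(cand, size=n_pixels, replace=False)
    return chosen


def simulate_whole_mount(
    config: ImageSimConfig,
) -> tuple[WholeMountImage, dict]:
    """Simulate one whole mount plus exact ground-truth masks.

    Returns ``(image, truth)`` with ``truth`` holding ``sinus_mask``,
    ``signal_mask``, ``artifact_mask``, the true proximal ``band_mask``
    (distance to sinus <= dilation_um), and the realized proximal pixel
    counts. Binarizing either channel at any threshold in
    (noise_level, 1.0] recovers the corresponding mask exactly as long as
    ``noise_level < 1``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_place, rng_noise = [np.random.default_rng(c) for c in ss.spawn(2)]
    shape = config.shape

    sinus = _rasterize_sinus(config)
    dist_px = ndimage.distance_transform_edt(~sinus)
    band = dist_px * config.pixel_size <= config.dilation_um

    artifact = np.zeros(shape, dtype=bool)
    if config.artifact is not None:
        rr, cc = disk(
            config.artifact.center,
            config.artifact.radius_um / config.pixel_size,
            shape=shape,
        )
        artifact[rr, cc] = True

    prox_pool = np.flatnonzero(band & ~artifact)
    dist_pool = np.flatnonzero(~band & ~artifact)
    if len(prox_pool) == 0 or len(dist_pool) == 0:
        raise ValueError("canvas leaves no room for proximal and distal signal")

    signal = np.zeros(shape, dtype=bool)
    n_total = config.n_clusters * config.pixels_per_cluster
    if config.placement == "uniform":
        n_prox = int(rng_place.binomial(n_total, config.proximal_fraction))
        chosen = np.concatenate(
            [
                rng_place.choice(prox_pool, size=min(n_prox, len(prox_pool)), replace=False),
                rng_place.choice(
                    dist_pool, size=min(n_total - n_prox, len(dist_pool)), replace=False
                ),
            ]
        )
        n_prox_realized = min(n_prox, len(prox_pool))
    else:
        radius_px = config.cluster_radius_um / config.pixel_size
        avail = {id(prox_pool): np.ones(len(prox_pool), dtype=bool),
                 id(dist_pool): np.ones(len(dist_pool), dtype=bool)}
        chosen_parts = []
        n_prox_realized = 0
        proximal_flags = rng_place.random(config.n_clusters) < config.proximal_fraction
        for is_prox in proximal_flags:
            pool = prox_pool if is_prox else dist_pool
            a = avail[id(pool)]
            center = int(rng_place.choice(pool[a]))
            picked = _sample_cluster(
                rng_place, pool, a, center, radius_px, config.pixels_per_cluster, shape
            )
            a[np.searchsorted(pool, picked)] = False
            chosen_parts.append(picked)
            if is_prox:
                n_prox_realized += len(picked)
        chosen = np.concatenate(chosen_parts)
    signal.flat[chosen] = True

    landmark_ch = sinus.astype(float) + rng_noise.uniform(0, config.noise_level, shape)
    signal_ch = (
        signal.astype(float)
        + (artifact.astype(float) * (config.artifact.intensity if config.artifact else 0.0))
        + rng_noise.uniform(0, config.noise_level, shape)
    )

    image = WholeMountImage(
        channels={"landmark": landmark_ch, "signal": signal_ch},
        pixel_size=config.pixel_size,
        channel_roles={"landmark": "landmark", "signal": "signal"},
        sample_id=f"sim-{config.seed}",
    )
    truth = {
        "sinus_mask": sinus,
        "signal_mask": signal,
        "artifact_mask": artifact,
        "band_mask": band,
        "n_signal_total": int(signal.sum()),
        "n_signal_proximal": int(n_prox_realized),
        "n_assignments": config.n_clusters if config.placement == "clustered" else n_total,
    }
    return image, truth
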