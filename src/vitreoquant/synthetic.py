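"""Synthetic Spectralis-like OCT volumes with known ground truth.

Every downstream stage (pre-processing, segmentation, VI scoring, the
reliability statistics) is testable against these volumes because the
generator records the truth it draws from: per-scan particle counts,
the ILM and RPE boundary rows, and the cross-volume inflammation
profile.

Image model, top (row 0, vitreous side) to bottom:

* a dark vitreous compartment — intensity ``diffuse_level`` (default 0)
  plus sparse hyperreflective particles, rendered as Gaussian blobs whose
  expected count is ``inflammation_level × gradient[scan] × area / 1000``
  (particles per 1000 px² of vitreous, Poisson-distributed);
* the retina from the ILM downward at ``retina_intensity``, with a
  smooth foveal dip in the ILM curve;
* a distinctly brightest RPE band (``rpe_intensity``, the global
  maximum) of ``rpe_thickness_px`` rows around ``rpe_row_frac``;
* a dimmer sub-RPE (choroid/sclera) region.

All intensities are scaled by ``opacity_factor`` (media opacity) and
multiplied by log-normal speckle of scale ``speckle_sigma``. Pixels stay
float64 in [0, ~1]; :func:`quantize_volume` converts to uint16 for
lossless PNG storage.

The per-scan quality score is a dB-like SNR proxy,
``10·log10(RPE-band mean / robust SD of the vitreous background)``
clipped to [0, 40], mimicking HEYEX quality scores so the quality gate
is exercisable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .io import BScan, OCTVolume

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_bscan",
    "generate_volume",
    "generate_cohort",
    "quadratic_gradient",
    "quantize_volume",
    "quantize_scan",
    "simulate_score_matrix",
]

#: fixed uint16 quantization scale; leaves headroom above 1.0 for speckle
QUANT_SCALE = 40000.0


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic volume generator.

    Defaults emulate the study geometry: 19 B-scans of 512 × 496 px
    covering 20° × 15°, 243 µm apart.
    """

    n_scans: int = 19
    width_px: int = 512
    height_px: int = 496
    inter_scan_um: float = 243.0
    #: expected particle density in the vitreous, particles per 1000 px²
    inflammation_level: float = 2.0
    #: per-scan multiplicative profile (length n_scans, all > 0); None = flat
    inflammation_gradient: np.ndarray | None = None
    particle_intensity_mean: float = 0.8
    particle_intensity_sd: float = 0.1
    #: Gaussian blob scale (sigma) of one particle, px
    particle_radius_px: float = 2.5
    #: optional diffuse vitreous background term
    diffuse_level: float = 0.0
    retina_intensity: float = 0.35
    rpe_intensity: float = 1.0
    sub_rpe_intensity: float = 0.12
    rpe_row_frac: float = 0.80
    rpe_thickness_px: int = 8
    ilm_row_frac: float = 0.55
    fovea_dip_px: float = 12.0
    rpe_tilt_px: float = 4.0
    #: global multiplicative attenuation (media opacity), in (0, 1]
    opacity_factor: float = 1.0
    #: multiplicative log-normal speckle scale (0 = noiseless)
    speckle_sigma: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_scans < 1 or self.width_px < 8 or self.height_px < 8:
            raise ValidationError("n_scans/width_px/height_px out of range")
        if not (0 < self.ilm_row_frac < self.rpe_row_frac < 1):
            raise ValidationError("need 0 < ilm_row_frac < rpe_row_frac < 1")
        if not (0 < self.opacity_factor <= 1):
            raise ValidationError("opacity_factor must be in (0, 1]")
        if self.inflammation_level < 0 or self.speckle_sigma < 0:
            raise ValidationError("inflammation_level and speckle_sigma must be >= 0")
        if self.particle_radius_px <= 0 or self.rpe_thickness_px < 1:
            raise ValidationError("particle_radius_px and rpe_thickness_px must be positive")
        g = self.gradient()
        if g.shape != (self.n_scans,) or np.any(g <= 0):
            raise ValidationError("inflammation_gradient must have length n_scans, all > 0")

    def gradient(self) -> np.ndarray:
        if self.inflammation_gradient is None:
            return np.ones(self.n_scans)
        return np.asarray(self.inflammation_gradient, dtype=float)


@dataclass
class GroundTruth:
    """What the generator actually drew for one volume."""

    per_scan_particle_count: list[int]
    #: rank (0 = lowest) of each scan's expected VI, from the gradient
    per_scan_expected_vi_rank: list[int]
    #: (n_scans, width) true first retinal row per column
    ilm_rows: np.ndarray
    #: (n_scans, width) true top row of the RPE band per column
    rpe_rows: np.ndarray
    gradient: np.ndarray
    inflammation_level: float
    extra: dict = field(default_factory=dict)

    def summary(self) -> dict:
        """Compact JSON-safe summary (full boundary arrays stay in memory)."""
        return {
            "inflammation_level": float(self.inflammation_level),
            "gradient": [float(g) for g in self.gradient],
            "per_scan_particle_count": [int(c) for c in self.per_scan_particle_count],
            "per_scan_expected_vi_rank": [int(r) for r in self.per_scan_expected_vi_rank],
            "mean_ilm_row_per_scan": [float(m) for m in self.ilm_rows.mean(axis=1)],
            "mean_rpe_row_per_scan": [float(m) for m in self.rpe_rows.mean(axis=1)],
            **{k: v for k, v in self.extra.items()},
        }


def _boundaries(config: SyntheticConfig):
    """True ILM and RPE-top rows per column (int arrays of length width)."""
    w, h = config.width_px, config.height_px
    cols = np.arange(w)
    center = (w - 1) / 2.0
    dip = config.fovea_dip_px * np.exp(-(((cols - center) / (0.15 * w)) ** 2))
    ilm = np.rint(config.ilm_row_frac * h + dip).astype(int)
    rpe_center = np.rint(
        config.rpe_row_frac * h + config.rpe_tilt_px * (cols - center) / w
    ).astype(int)
    rpe_top = rpe_center - config.rpe_thickness_px // 2
    ilm = np.clip(ilm, 1, h - 2)
    rpe_top = np.clip(rpe_top, ilm + 1, h - config.rpe_thickness_px)
    return ilm, rpe_top


def generate_bscan(config: SyntheticConfig, scan_index: int, rng: np.random.Generator):
    """Generate one B-scan and its ground-truth slice.

    Returns ``(BScan, gt)`` where ``gt`` is a dict with keys
    ``particle_count``, ``ilm_rows``, ``rpe_rows``. Pixels are float64;
    the opacity factor scales them exactly (multiplicative model).
    """
    config.validate()
    if not 0 <= scan_index < config.n_scans:
        raise ValidationError("scan_index out of range")
    w, h = config.width_px, config.height_px
    ilm, rpe_top = _boundaries(config)
    rpe_bot = rpe_top + config.rpe_thickness_px - 1

    rows = np.arange(h)[:, None]
    img = np.full((h, w), config.diffuse_level, dtype=float)
    img[(rows >= ilm[None, :]) & (rows < rpe_top[None, :])] = config.retina_intensity
    img[(rows >= rpe_top[None, :]) & (rows <= rpe_bot[None, :])] = config.rpe_intensity
    img[rows > rpe_bot[None, :]] = config.sub_rpe_intensity

    # Poisson particle count at the scan's local density
    density = config.inflammation_level * config.gradient()[scan_index]
    vitreous_area = int(ilm.sum())
    n_particles = int(rng.poisson(density * vitreous_area / 1000.0))
    sigma = config.particle_radius_px
    margin = int(math.ceil(3 * sigma))
    half = margin
    for _ in range(n_particles):
        c = int(rng.integers(0, w))
        top = ilm[c] - margin
        if top <= margin:  # vitreous too shallow here; drop along the ILM edge
            r = max(1, ilm[c] // 2)
        else:
            r = int(rng.integers(margin, top))
        amp = float(np.clip(rng.normal(config.particle_intensity_mean, config.particle_intensity_sd), 0.3, 0.95))
        r0, r1 = max(0, r - half), min(h, r + half + 1)
        c0, c1 = max(0, c - half), min(w, c + half + 1)
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        blob = amp * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2))
        np.maximum(img[r0:r1, c0:c1], blob, out=img[r0:r1, c0:c1])

    img *= config.opacity_factor
    if config.speckle_sigma > 0:
        s = config.speckle_sigma
        img *= rng.lognormal(mean=-(s**2) / 2.0, sigma=s, size=img.shape)

    quality = _quality_proxy(config, img, rpe_top, rpe_bot)
    scan = BScan(
        pixels=img,
        quality=quality,
        index_in_volume=scan_index,
        y_position_um=scan_index * config.inter_scan_um,
    )
    gt = {"particle_count": n_particles, "ilm_rows": ilm, "rpe_rows": rpe_top}
    return scan, gt


def _quality_proxy(config: SyntheticConfig, img, rpe_top, rpe_bot) -> float:
    """dB-like SNR proxy: rendered RPE-band mean over the true background
    noise SD of the generator's own model.

    The background noise floor is what the acquisition noise does to the
    diffuse vitreous background (log-normal speckle of scale
    ``speckle_sigma`` on ``diffuse_level × opacity_factor``); vitreous
    particles are signal, not noise, so inflammation does not masquerade
    as poor image quality. A zero noise floor clips to the 40 dB cap.
    """
    rows = np.arange(img.shape[0])[:, None]
    rpe_mean = float(img[(rows >= rpe_top[None, :]) & (rows <= rpe_bot[None, :])].mean())
    s = config.speckle_sigma
    bg_sd = config.diffuse_level * config.opacity_factor * math.sqrt(max(math.exp(s**2) - 1.0, 0.0))
    if bg_sd <= 0 or rpe_mean <= 0:
        return 40.0
    return float(np.clip(10.0 * np.log10(rpe_mean / bg_sd), 0.0, 40.0))


def generate_volume(config: SyntheticConfig, quantize: bool = False):
    """Generate a full volume; deterministic for a fixed ``config.seed``.

    With ``quantize=True`` pixels are converted to uint16 (lossless PNG
    storage); otherwise they stay float64, which keeps the multiplicative
    opacity model exact.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    scans, counts, ilms, rpes = [], [], [], []
    for i in range(config.n_scans):
        scan, gt = generate_bscan(config, i, rng)
        scans.append(scan)
        counts.append(gt["particle_count"])
        ilms.append(gt["ilm_rows"])
        rpes.append(gt["rpe_rows"])
    gradient = config.gradient()
    ranks = np.argsort(np.argsort(gradient, kind="stable"), kind="stable")
    volume = OCTVolume(
        scans=scans,
        inter_scan_um=config.inter_scan_um,
        eye_id=f"synthetic_seed{config.seed}",
        metadata={"synthetic": True, "inflammation_level": float(config.inflammation_level)},
    )
    truth = GroundTruth(
        per_scan_particle_count=counts,
        per_scan_expected_vi_rank=[int(r) for r in ranks],
        ilm_rows=np.stack(ilms),
        rpe_rows=np.stack(rpes),
        gradient=gradient,
        inflammation_level=config.inflammation_level,
    )
    if quantize:
        volume = quantize_volume(volume)
    return volume, truth


def quantize_scan(scan: BScan, scale: float = QUANT_SCALE) -> BScan:
    q = np.rint(np.clip(scan.pixels * scale, 0, 65535)).astype(np.uint16)
    return BScan(q, scan.quality, scan.index_in_volume, scan.y_position_um)


def quantize_volume(volume: OCTVolume, scale: float = QUANT_SCALE) -> OCTVolume:
    """uint16 copy of a float volume (fixed scale, clipped at 65535)."""
    return OCTVolume(
        scans=[quantize_scan(s, scale) for s in volume.scans],
        inter_scan_um=volume.inter_scan_um,
        eye_id=volume.eye_id,
        metadata=dict(volume.metadata),
    )


def quadratic_gradient(n_scans: int, curvature: float) -> np.ndarray:
    """Smooth cross-volume profile 1 + c·((i − center)/center)².

    Positive curvature raises the peripheral scans relative to the
    center, negative curvature the reverse. Central-scan-only selections
    are blind to this curvature, which is exactly what makes sparse but
    widely distributed selections competitive.
    """
    center = (n_scans - 1) / 2.0
    i = np.arange(n_scans)
    g = 1.0 + curvature * ((i - center) / center) ** 2
    if np.any(g <= 0):
        raise ValidationError("curvature makes the gradient non-positive")
    return g


_LEVEL_KINDS = {"lognormal", "uniform", "fixed"}


def _level_sampler(spec: dict):
    if not isinstance(spec, dict) or spec.get("kind") not in _LEVEL_KINDS:
        raise ValidationError(f"level_distribution must be a dict with kind in {_LEVEL_KINDS}")
    kind = spec["kind"]
    if kind == "lognormal":
        median = float(spec.get("median", 2.0))
        sigma = float(spec.get("sigma", 0.8))
        if median <= 0 or sigma < 0:
            raise ValidationError("lognormal needs median > 0 and sigma >= 0")
        return lambda rng: float(rng.lognormal(mean=math.log(median), sigma=sigma))
    if kind == "uniform":
        low, high = float(spec.get("low", 0.5)), float(spec.get("high", 6.0))
        if not 0 <= low < high:
            raise ValidationError("uniform needs 0 <= low < high")
        return lambda rng: float(rng.uniform(low, high))
    value = float(spec.get("value", 2.0))
    if value < 0:
        raise ValidationError("fixed level must be >= 0")
    return lambda rng: value


def generate_cohort(
    n_eyes: int,
    level_distribution: dict | None = None,
    base_config: SyntheticConfig | None = None,
    seed: int = 0,
    curvature_range: tuple[float, float] = (-0.4, 0.8),
    quantize: bool = False,
):
    """Generate a cohort of synthetic eyes with varying inflammation.

    Per eye, the inflammation level is drawn from ``level_distribution``
    (default: log-normal, median 2 particles/1000 px², sigma 0.8 — a
    right-skewed severity distribution) and the cross-volume profile is
    quadratic with curvature drawn uniformly from ``curvature_range``.
    Fully reproducible under ``seed`` via per-eye substreams.
    """
    if n_eyes < 1:
        raise ValidationError("n_eyes must be >= 1")
    sampler = _level_sampler(level_distribution or {"kind": "lognormal", "median": 2.0, "sigma": 0.8})
    base = base_config if base_config is not None else SyntheticConfig()
    cohort = []
    children = np.random.SeedSequence(seed).spawn(n_eyes)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        level = sampler(rng)
        curvature = float(rng.uniform(*curvature_range))
        eye_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = replace(
            base,
            inflammation_level=level,
            inflammation_gradient=quadratic_gradient(base.n_scans, curvature),
            seed=eye_seed,
        )
        volume, truth = generate_volume(cfg, quantize=quantize)
        volume.eye_id = f"eye_{i:03d}"
        volume.metadata.update(
            {"inflammation_level": level, "curvature": curvature, "cohort_seed": seed}
        )
        truth.extra["curvature"] = curvature
        cohort.append((volume, truth))
    return cohort


def simulate_score_matrix(
    n_eyes: int,
    n_scans: int,
    between_sd: float,
    within_sd: float,
    rng: np.random.Generator,
    grand_mean: float = 0.05,
) -> np.ndarray:
    """Additive two-way random-effects VI matrix (eyes × scans).

    ``x_ij = mu + b_i + e_ij`` with ``b_i ~ N(0, between_sd²)`` and
    ``e_ij ~ N(0, within_sd²)``; the theoretical single-measure ICC is
    ``between_sd² / (between_sd² + within_sd²)``. Used for ICC parameter
    recovery without the imaging stack.
    """
    b = rng.normal(0.0, between_sd, size=(n_eyes, 1))
    e = rng.normal(0.0, within_sd, size=(n_eyes, n_scans))
    return grand_mean + b + e
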