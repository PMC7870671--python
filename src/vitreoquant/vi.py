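"""Vitreous/RPE-relative intensity (VI) of a B-scan.

The score quantifies posterior vitreous inflammation as the supra-
threshold OCT signal in the vitreous compartment, normalised by the RPE
band signal so that global attenuation by media opacities cancels:

    VI = (Σ preprocessed vitreous intensity / n_vitreous_px) / RPE signal

Three stages:

1. :func:`preprocess_bscan` — grayscale morphological opening (removes
   isolated speckle spikes), soft thresholding at ``k`` robust SDs above
   the image's robust background level (the dark vitreous dominates a
   macular B-scan, so the image median is a background estimate), and a
   linear rescale of the surviving range to [0, 1]. Every statistic is
   relative to the image, so the preprocessed image — and hence VI — is
   exactly invariant under global multiplicative rescaling.
2. :func:`segment_retina` — per column: the RPE band around the brightest
   smoothed axial peak (ties broken toward the deeper row), the ILM as
   the shallowest sustained rise above a fraction of the column peak, and
   the vitreous mask as everything strictly above the ILM. Columns where
   detection fails are excluded from all sums; if more than half the
   columns fail the scan is rejected.
3. :func:`compute_vi` — the ratio itself, with the RPE denominator taken
   from the *raw* band intensity mapped through the same global
   adjustment as the numerator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .errors import (
    DegenerateImageWarning,
    GatedVolumeError,
    SegmentationError,
    UndefinedScoreError,
    ValidationError,
)
from .io import BScan, OCTVolume, quality_gate
from .selection import thin_every_other

__all__ = [
    "VIParams",
    "Preprocessed",
    "VitreousSegmentation",
    "VIScore",
    "preprocess_bscan",
    "segment_retina",
    "compute_vi",
    "compute_volume_vi",
]


@dataclass(frozen=True)
class VIParams:
    """Tunable parameters of the VI computation (all overridable)."""

    #: disc radius of the grayscale opening structuring element, px
    opening_radius: int = 1
    #: threshold = background median + k robust SDs ("relative" mode)
    threshold_k: float = 3.0
    #: top fraction of rows used to estimate the vitreous background
    background_row_frac: float = 0.4
    #: disc radius of the opening that strips particles before the
    #: background estimate; must exceed the expected particle radius
    background_opening_radius: int = 6
    #: "relative" (scale-invariant, default) or "absolute"
    threshold_mode: str = "relative"
    #: fixed threshold used only in "absolute" mode (raw intensity units)
    absolute_threshold: float = 0.0
    #: axial Gaussian smoothing sigma for boundary detection, rows
    smooth_sigma: float = 2.0
    #: ILM threshold as a fraction of the column's peak (RPE) intensity
    ilm_fraction: float = 0.2
    #: minimum preprocessed peak intensity for a column to be valid
    min_peak: float = 0.3
    #: rows just above the RPE that must look like retinal tissue
    retina_check_px: int = 20
    #: the vitreous above the ILM must stay below this fraction of the
    #: column peak on average — rejects structureless bright noise
    vitreous_max_frac: float = 0.25
    #: RPE band = detected peak row ± this halfwidth, px
    rpe_halfwidth: int = 4
    #: reject the scan when more than this fraction of columns is invalid
    max_invalid_frac: float = 0.5
    #: normalise the vitreous sum by vitreous area (recommended); the raw
    #: sum depends on ILM height and is kept only for sensitivity analysis
    area_normalised: bool = True
    #: "mean" (default) or "median" RPE band statistic
    rpe_statistic: str = "mean"


@dataclass
class Preprocessed:
    """Preprocessed image plus the global adjustment that produced it."""

    image: np.ndarray
    threshold: float
    scale_high: float
    degenerate: bool = False

    def adjust(self, value: float) -> float:
        """Map a raw intensity through the same linear adjustment."""
        if self.degenerate or self.scale_high <= self.threshold:
            return 0.0
        return (value - self.threshold) / (self.scale_high - self.threshold)


@dataclass
class VitreousSegmentation:
    """Per-column retinal boundaries and the posterior vitreous mask."""

    ilm_row_per_column: np.ndarray  # int, -1 where invalid
    rpe_top_per_column: np.ndarray
    rpe_bottom_per_column: np.ndarray
    vitreous_mask: np.ndarray  # bool (H, W)
    valid_columns: np.ndarray  # bool (W,)

    @property
    def rpe_band_per_column(self) -> np.ndarray:
        """(W, 2) array of (top_row, bottom_row) per column."""
        return np.stack([self.rpe_top_per_column, self.rpe_bottom_per_column], axis=1)


@dataclass(frozen=True)
class VIScore:
    """The VI of one B-scan and its ingredients."""

    vi: float
    vitreous_signal: float
    rpe_signal: float
    n_vitreous_px: int
    n_rpe_px: int


def _as_image(scan) -> np.ndarray:
    px = scan.pixels if isinstance(scan, BScan) else scan
    return np.asarray(px, dtype=float)


def preprocess_bscan(scan, params: VIParams = VIParams()) -> Preprocessed:
    """Opening → soft threshold → linear rescale of the surviving range.

    A constant (zero-variance) image yields an all-zeros output with a
    :class:`DegenerateImageWarning`, never an exception.
    """
    img = _as_image(scan)
    if img.max() == img.min():
        warnings.warn("constant image: preprocessing returns all zeros", DegenerateImageWarning)
        return Preprocessed(np.zeros_like(img), 0.0, 0.0, degenerate=True)
    if params.opening_radius > 0:
        opened = morphology.opening(img, morphology.disk(params.opening_radius))
    else:
        opened = img
    if params.threshold_mode == "relative":
        # robust vitreous-background level from the anterior rows only
        # (deeper rows contain retina/choroid and would bias the median),
        # with hyperreflective particles stripped by a coarse opening so
        # the estimate stays a *background* level at any particle density
        n_bg = max(1, int(round(params.background_row_frac * img.shape[0])))
        bg_region = opened[:n_bg]
        if params.background_opening_radius > 0:
            bg_region = morphology.opening(
                bg_region, morphology.disk(params.background_opening_radius)
            )
        bg = float(np.median(bg_region))
        robust_sd = 1.4826 * float(np.median(np.abs(bg_region - bg)))
        thr = bg + params.threshold_k * robust_sd
    elif params.threshold_mode == "absolute":
        thr = params.absolute_threshold
    else:
        raise ValidationError(f"unknown threshold_mode {params.threshold_mode!r}")
    hi = float(opened.max())
    if hi <= thr:
        warnings.warn("no intensity survives the threshold", DegenerateImageWarning)
        return Preprocessed(np.zeros_like(img), thr, hi, degenerate=True)
    adj = (opened - thr) / (hi - thr)
    np.clip(adj, 0.0, None, out=adj)
    return Preprocessed(adj, thr, hi)


def segment_retina(prep, params: VIParams = VIParams()) -> VitreousSegmentation:
    """Detect the RPE band and ILM per column of a preprocessed image.

    Raises :class:`SegmentationError` (with diagnostics) when more than
    ``params.max_invalid_frac`` of the columns fail — e.g. on pure-noise
    images without a retina.
    """
    img = prep.image if isinstance(prep, Preprocessed) else np.asarray(prep, dtype=float)
    h, w = img.shape
    smoothed = ndimage.gaussian_filter1d(img, sigma=params.smooth_sigma, axis=0)

    # brightest smoothed row per column; ties broken toward the deeper row
    rpe_row = (h - 1) - np.argmax(smoothed[::-1, :], axis=0)
    cols = np.arange(w)
    peak = smoothed[rpe_row, cols]
    valid = peak >= params.min_peak

    # ILM: walk up from the RPE peak through the contiguous retinal band.
    # The deepest row above the RPE whose smoothed profile drops below
    # ilm_fraction*peak marks the vitreoretinal gap; the ILM is the next
    # row down. Bright vitreous particles cannot fool this rule as long
    # as a sub-threshold gap separates them from the retina.
    thr_col = params.ilm_fraction * peak
    all_rows = np.arange(h)[:, None]
    below = (smoothed < thr_col[None, :]) & (all_rows < rpe_row[None, :])
    found = below.any(axis=0)
    deepest_below = (h - 1) - np.argmax(below[::-1, :], axis=0)
    ilm_row = np.where(found, deepest_below + 1, -1)

    rpe_top = np.clip(rpe_row - params.rpe_halfwidth, 0, h - 1)
    rpe_bottom = np.clip(rpe_row + params.rpe_halfwidth, 0, h - 1)
    valid &= found & (ilm_row < rpe_top) & (ilm_row > 0)

    # a real retina shows sustained tissue signal just above the RPE and
    # a *dark* vitreous above the ILM; structureless noise has neither
    csum2 = np.vstack([np.zeros((1, w)), np.cumsum(smoothed, axis=0)])
    if params.retina_check_px > 0:
        band_start = np.clip(rpe_top - params.retina_check_px, 0, h - 1)
        band_sum = csum2[rpe_top, cols] - csum2[band_start, cols]
        band_n = np.maximum(rpe_top - band_start, 1)
        valid &= (band_sum / band_n) >= 0.5 * params.ilm_fraction * peak
    if params.vitreous_max_frac < 1.0:
        vit_n = np.maximum(ilm_row, 1)
        vit_mean = csum2[np.clip(ilm_row, 0, h), cols] / vit_n
        valid &= vit_mean <= params.vitreous_max_frac * peak

    n_invalid = int(w - valid.sum())
    if n_invalid > params.max_invalid_frac * w:
        raise SegmentationError(
            f"{n_invalid}/{w} columns failed boundary detection",
            diagnostics={
                "n_columns": w,
                "n_invalid": n_invalid,
                "n_no_peak": int((peak < params.min_peak).sum()),
                "n_no_ilm": int((~found).sum()),
            },
        )
    ilm_row = np.where(valid, ilm_row, -1)
    all_rows = np.arange(h)[:, None]
    vitreous_mask = valid[None, :] & (ilm_row[None, :] > 0) & (all_rows < ilm_row[None, :])
    return VitreousSegmentation(
        ilm_row_per_column=ilm_row,
        rpe_top_per_column=rpe_top,
        rpe_bottom_per_column=rpe_bottom,
        vitreous_mask=vitreous_mask,
        valid_columns=valid,
    )


def compute_vi(scan, params: VIParams = VIParams()) -> VIScore:
    """VI of one B-scan.

    Numerator: mean preprocessed intensity over the vitreous mask (or the
    raw sum with ``area_normalised=False``). Denominator: mean (or
    median) raw RPE-band intensity over valid columns, mapped through the
    same global adjustment as the numerator. In "relative" threshold mode
    the ratio is exactly invariant to global multiplicative rescaling of
    the raw image — the media-opacity property.
    """
    raw = _as_image(scan)
    prep = preprocess_bscan(scan, params)
    seg = segment_retina(prep, params)

    vit_vals = prep.image[seg.vitreous_mask]
    n_vit = int(vit_vals.size)
    total = float(vit_vals.sum())
    vitreous_signal = (total / n_vit) if (params.area_normalised and n_vit > 0) else total

    h, w = raw.shape
    all_rows = np.arange(h)[:, None]
    rpe_mask = (
        seg.valid_columns[None, :]
        & (all_rows >= seg.rpe_top_per_column[None, :])
        & (all_rows <= seg.rpe_bottom_per_column[None, :])
    )
    rpe_vals = raw[rpe_mask]
    n_rpe = int(rpe_vals.size)
    if n_rpe == 0:
        raise UndefinedScoreError("no RPE pixels in valid columns")
    stat = float(np.median(rpe_vals)) if params.rpe_statistic == "median" else float(rpe_vals.mean())
    rpe_signal = prep.adjust(stat)
    if rpe_signal <= 0:
        raise UndefinedScoreError("non-positive adjusted RPE signal; VI undefined")
    return VIScore(
        vi=vitreous_signal / rpe_signal,
        vitreous_signal=vitreous_signal,
        rpe_signal=rpe_signal,
        n_vitreous_px=n_vit,
        n_rpe_px=n_rpe,
    )


def compute_volume_vi(
    volume: OCTVolume,
    params: VIParams = VIParams(),
    gate: bool = True,
    phase="auto",
) -> list[VIScore | None]:
    """Per-scan VI over the analysable (every-other) scans of a volume.

    Returns one entry per analysable scan position, order preserved;
    scans whose segmentation fails are recorded as ``None`` rather than
    silently dropped. Raises :class:`GatedVolumeError` when the volume
    fails the quality gate (disable with ``gate=False``).
    """
    if gate:
        result = quality_gate(volume)
        if not result.included:
            raise GatedVolumeError(
                f"volume {volume.eye_id}: {result.n_low_quality} scans below "
                f"quality {result.threshold} (max allowed {result.max_allowed})"
            )
    scores: list[VIScore | None] = []
    for idx in thin_every_other(volume.n_scans, phase=phase):
        try:
            scores.append(compute_vi(volume.scans[idx], params))
        except (SegmentationError, UndefinedScoreError):
            scores.append(None)
    return scores
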