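"""OCT volumes on disk: grayscale PNG stacks plus a JSON sidecar.

A volume is a directory of 8- or 16-bit grayscale PNGs (one per B-scan)
and a ``volume.json`` sidecar that fixes the scan order, per-scan quality
scores and lateral positions, the mean inter-scan spacing and free-form
eye metadata::

    {
      "eye_id": "eye_000",
      "inter_scan_um": 243.0,
      "scans": [
        {"file": "scan_000.png", "quality": 31.2, "y_position_um": 0.0},
        ...
      ],
      "metadata": {...}
    }

Scan order follows the sidecar list, never a filename sort. The round
trip ``read_volume(write_volume(v))`` is bit-exact on pixels.

Axial orientation convention: row 0 is the vitreous (anterior) side of
every B-scan; depth increases downward. The synthetic generator enforces
the same convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ConsistencyError, FormatError, ValidationError

SIDECAR_NAME = "volume.json"

__all__ = [
    "BScan",
    "OCTVolume",
    "QualityGateResult",
    "read_volume",
    "write_volume",
    "quality_gate",
    "SIDECAR_NAME",
]


@dataclass
class BScan:
    """One grayscale OCT cross-section.

    ``pixels`` has rows = axial depth (row 0 anterior / vitreous side)
    and columns = lateral position. ``quality`` is a HEYEX-like scalar
    quality score in arbitrary (dB-like) units, or ``None`` if unknown.
    """

    pixels: np.ndarray
    quality: float | None
    index_in_volume: int
    y_position_um: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValidationError("BScan pixels must be a non-empty 2D array")
        if not np.all(np.isfinite(self.pixels.astype(float))):
            raise ValidationError("BScan pixels must be finite")
        if np.any(self.pixels.astype(float) < 0):
            raise ValidationError("BScan pixels must be >= 0")
        if self.index_in_volume < 0:
            raise ValidationError("index_in_volume must be >= 0")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class OCTVolume:
    """Ordered stack of parallel B-scans with acquisition metadata."""

    scans: list[BScan]
    inter_scan_um: float
    eye_id: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.scans:
            raise ValidationError("OCTVolume needs at least one scan")
        if self.inter_scan_um <= 0:
            raise ValidationError("inter_scan_um must be > 0")
        idx = [s.index_in_volume for s in self.scans]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("scan indices must be strictly increasing")
        ys = [s.y_position_um for s in self.scans]
        if any(b - a <= 0 for a, b in zip(ys, ys[1:])):
            raise ValidationError("adjacent y_position_um differences must be positive")
        shapes = {s.shape for s in self.scans}
        if len(shapes) > 1:
            raise ConsistencyError(f"non-uniform B-scan dimensions: {sorted(shapes)}")

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    @property
    def shape(self):
        return self.scans[0].shape


@dataclass(frozen=True)
class QualityGateResult:
    """Outcome of the image-quality gate for one volume."""

    included: bool
    n_low_quality: int
    threshold: float
    max_allowed: int


def quality_gate(volume: OCTVolume, threshold: float = 20.0, max_allowed: int = 3) -> QualityGateResult:
    """Apply the study's inclusion rule to a volume.

    A volume is excluded when strictly more than ``max_allowed`` B-scans
    have a quality score strictly below ``threshold`` (default: score
    < 20 in > 3 B-scans). Exactly ``threshold`` does not count as low,
    and exactly ``max_allowed`` low scans still passes.
    """
    for s in volume.scans:
        if s.quality is None:
            raise ValidationError(f"scan {s.index_in_volume} has no quality score")
    n_low = sum(1 for s in volume.scans if s.quality < threshold)
    return QualityGateResult(
        included=n_low <= max_allowed,
        n_low_quality=n_low,
        threshold=threshold,
        max_allowed=max_allowed,
    )


def write_volume(volume: OCTVolume, path) -> None:
    """Write a volume as PNGs + sidecar under ``path`` (created if needed).

    Pixels must already be ``uint8`` or ``uint16`` (use
    :func:`vitreoquant.synthetic.quantize_volume` for float volumes);
    PNG storage is then lossless.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, scan in enumerate(volume.scans):
        if scan.pixels.dtype not in (np.uint8, np.uint16):
            raise ValidationError(
                f"cannot write dtype {scan.pixels.dtype} losslessly to PNG; quantize first"
            )
        fname = f"scan_{i:03d}.png"
        iio.imwrite(path / fname, scan.pixels)
        entries.append(
            {
                "file": fname,
                "index_in_volume": scan.index_in_volume,
                "quality": None if scan.quality is None else float(scan.quality),
                "y_position_um": float(scan.y_position_um),
            }
        )
    sidecar = {
        "eye_id": volume.eye_id,
        "inter_scan_um": float(volume.inter_scan_um),
        "scans": entries,
        "metadata": volume.metadata,
    }
    with open(path / SIDECAR_NAME, "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1, ensure_ascii=False, sort_keys=True)


def read_volume(path) -> OCTVolume:
    """Read a volume written by :func:`write_volume` (or hand-assembled)."""
    path = Path(path)
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.is_file():
        raise FormatError(f"missing sidecar {sidecar_path}")
    try:
        with open(sidecar_path, encoding="utf-8") as fh:
            sidecar = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"unparseable sidecar {sidecar_path}: {exc}") from exc
    for key in ("eye_id", "inter_scan_um", "scans"):
        if key not in sidecar:
            raise FormatError(f"sidecar missing required key {key!r}")

    scans = []
    for i, entry in enumerate(sidecar["scans"]):
        fpath = path / entry["file"]
        if not fpath.is_file():
            raise ConsistencyError(
                f"sidecar lists {entry['file']} but the file is absent "
                f"({len(sidecar['scans'])} listed)"
            )
        pixels = np.asarray(iio.imread(fpath))
        if pixels.ndim != 2:
            raise FormatError(f"{entry['file']} is not single-channel grayscale")
        scans.append(
            BScan(
                pixels=pixels,
                quality=entry.get("quality"),
                index_in_volume=int(entry.get("index_in_volume", i)),
                y_position_um=float(entry["y_position_um"]),
            )
        )
    shapes = {s.shape for s in scans}
    if len(shapes) > 1:
        raise ConsistencyError(f"non-uniform image dimensions on disk: {sorted(shapes)}")
    return OCTVolume(
        scans=scans,
        inter_scan_um=float(sidecar["inter_scan_um"]),
        eye_id=sidecar["eye_id"],
        metadata=sidecar.get("metadata", {}),
    )
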