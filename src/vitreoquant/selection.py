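"""Every-other thinning and the six B-scan sub-selection schemes.

A 19-scan macular volume is thinned to 9 analysable scans (every other
scan, chosen so the central scan is kept). Within those 9 positions
(0-based, center = 4) the study's selections are:

======  =====================  =========================
name    positions              description
======  =====================  =========================
``1c``  {4}                    1 central scan
``3c``  {3,4,5}                3 central scans
``5c``  {2..6}                 5 central scans
``7c``  {1..7}                 7 central scans
``9s``  {0..8}                 all 9 (reference standard)
``3w``  {0,4,8}                3 widely distributed scans
======  =====================  =========================

At the study spacing of 243 µm between acquired scans, adjacent
analysable scans are 486 µm apart and the 3w selection averages
1944 µm between selected scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedScoreError, ValidationError

__all__ = [
    "SCHEME_NAMES",
    "SelectionScheme",
    "SchemeScore",
    "select_scans",
    "thin_every_other",
    "mean_selection_distance",
    "scheme_mean_vi",
]

_SCHEME_INDICES: dict[str, tuple[int, ...]] = {
    "1c": (4,),
    "3c": (3, 4, 5),
    "5c": (2, 3, 4, 5, 6),
    "7c": (1, 2, 3, 4, 5, 6, 7),
    "9s": tuple(range(9)),
    "3w": (0, 4, 8),
}

SCHEME_NAMES = tuple(_SCHEME_INDICES)


@dataclass(frozen=True)
class SelectionScheme:
    """A named sub-selection of the 9 analysable scan positions."""

    name: str
    indices: tuple[int, ...]


@dataclass(frozen=True)
class SchemeScore:
    """Mean VI of one eye under one selection scheme."""

    eye_id: str | None
    scheme: str
    mean_vi: float
    n_used: int


def select_scans(scheme_name: str) -> SelectionScheme:
    """Return the fixed index set of a named scheme."""
    try:
        return SelectionScheme(scheme_name, _SCHEME_INDICES[scheme_name])
    except KeyError:
        raise ValidationError(
            f"unknown scheme {scheme_name!r}; valid: {', '.join(SCHEME_NAMES)}"
        ) from None


def thin_every_other(volume_or_n, phase="auto") -> list[int]:
    """Original-volume indices of the analysable (every-other) scans.

    ``phase="auto"`` (default) picks the parity that contains the central
    scan ``(n-1)//2``: for the study's 19 scans that is the odd indices
    {1, 3, …, 17} — 9 scans with the true central scan 9 at analysable
    position 4. An explicit phase of 0 or 1 overrides this. Even scan
    counts are ambiguous (no central scan) and rejected.
    """
    n = volume_or_n if isinstance(volume_or_n, (int, np.integer)) else volume_or_n.n_scans
    if n < 3:
        raise ValidationError("thinning needs at least 3 scans")
    if n % 2 == 0:
        raise ValidationError(f"even scan count ({n}) has no central scan; thinning ambiguous")
    center = (n - 1) // 2
    if phase == "auto":
        phase = center % 2
    if phase not in (0, 1):
        raise ValidationError("phase must be 'auto', 0 or 1")
    return list(range(phase, n, 2))


def mean_selection_distance(
    scheme: SelectionScheme, inter_scan_um: float, thinning_stride: int = 2
) -> float:
    """Mean distance (µm) between adjacent selected scans.

    Each unit gap between analysable positions spans ``thinning_stride``
    acquired scans: 9s at 243 µm → 486 µm, 3w → 1944 µm.
    """
    if len(scheme.indices) < 2:
        raise UndefinedScoreError(f"scheme {scheme.name!r} selects a single scan; distance undefined")
    gaps = np.diff(sorted(scheme.indices))
    return float(np.mean(gaps) * thinning_stride * inter_scan_um)


def scheme_mean_vi(per_scan_scores, scheme: SelectionScheme, eye_id: str | None = None) -> SchemeScore:
    """Arithmetic mean VI over the scheme's positions, skipping missing.

    ``per_scan_scores`` holds 9 entries (floats, VIScore objects, or
    None/NaN for scans whose scoring failed). The 9s mean is the study's
    reference standard.
    """
    if len(per_scan_scores) != 9:
        raise ValidationError(f"expected 9 per-scan scores, got {len(per_scan_scores)}")
    values = []
    for i in scheme.indices:
        s = per_scan_scores[i]
        v = s.vi if hasattr(s, "vi") else s
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        values.append(float(v))
    if not values:
        raise UndefinedScoreError(f"all scans of scheme {scheme.name!r} are missing")
    return SchemeScore(eye_id=eye_id, scheme=scheme.name, mean_vi=float(np.mean(values)), n_used=len(values))
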