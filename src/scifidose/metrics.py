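"""Beam-profile QA metrics: field center, FWHM, 20-80% penumbra, output factor.

Metric conventions follow routine small-field QA practice: levels are referred
to the profile maximum (small fields have no flat plateau to fit), crossings
are located by linear interpolation between bracketing samples, and the search
walks outward from the global maximum so spurious noise crossings far from the
field are ignored.  Radial (half) profiles — the natural output of the
rotationally symmetric reconstruction — report full widths as twice the
one-sided width, and their single edge stands for both (equal) edges.

All metrics are invariant under positive rescaling of the profile; FWHM and
penumbra are invariant under translation, while the field center shifts with
it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import HalfProfile, ProjectedProfile

__all__ = [
    "BeamMetrics",
    "field_center",
    "fwhm",
    "penumbra_20_80",
    "output_factor",
    "metrics_report",
]

logger = logging.getLogger(__name__)


@dataclass
class BeamMetrics:
    """QA summary for one field."""

    name: str
    center_mm: float
    fwhm_mm: float
    penumbra_20_80_mm: float
    on_axis_dose: float
    output_factor: float | None = None


def _as_xy(profile) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(profile, ProjectedProfile):
        return profile.x, profile.p
    if isinstance(profile, HalfProfile):
        return profile.x, profile.S
    x, y = profile
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def _is_half(x: np.ndarray, half: bool | None) -> bool:
    if half is not None:
        return half
    return bool(x[0] >= 0 and np.all(np.diff(x) > 0) and x[0] < 1e-9)


def field_center(profile, threshold: float = 0.05) -> float:
    """Intensity-weighted centroid of the projected profile (mm).

    Only samples at or above ``threshold`` of the maximum contribute, which
    makes the centroid robust to residual background far from the field.
    """
    x, p = _as_xy(profile)
    peak = p.max(initial=0.0)
    if peak <= 0:
        raise ValueError("cannot locate the center of an all-zero profile")
    mask = p >= threshold * peak
    return float(np.sum(x[mask] * p[mask]) / np.sum(p[mask]))


def _first_crossing_out(x, y, start: int, level: float, step: int) -> float:
    """First crossing of ``level`` walking from index ``start`` in ``step``."""
    i = start
    while 0 <= i + step < len(y):
        j = i + step
        if y[j] < level <= y[i]:
            t = (y[i] - level) / (y[i] - y[j])
            return float(x[i] + t * (x[j] - x[i]))
        i = j
    raise ValueError(f"profile does not cross {level:.4g} on this side")


def fwhm(profile, half: bool | None = None) -> float:
    """Full width at half maximum (mm), crossings by linear interpolation.

    For radial/half profiles (auto-detected as non-negative x starting at 0,
    or forced with ``half``) the result is twice the axis-to-crossing
    distance.
    """
    x, y = _as_xy(profile)
    peak = y.max(initial=0.0)
    if peak <= 0:
        raise ValueError("cannot measure FWHM of an all-zero profile")
    imax = int(np.argmax(y))
    level = 0.5 * peak
    right = _first_crossing_out(x, y, imax, level, +1)
    if _is_half(x, half):
        return 2.0 * (right - x[0])
    left = _first_crossing_out(x, y, imax, level, -1)
    return float(right - left)


def penumbra_20_80(profile, half: bool | None = None) -> float:
    """20%-80% penumbra width (mm), averaged over both field edges.

    On each edge the width is |x(80%) - x(20%)| with levels relative to the
    profile maximum.  A radial/half profile has a single edge representing
    both, so its width is returned directly.
    """
    x, y = _as_xy(profile)
    peak = y.max(initial=0.0)
    if peak <= 0:
        raise ValueError("cannot measure penumbra of an all-zero profile")
    imax = int(np.argmax(y))
    right = abs(
        _first_crossing_out(x, y, imax, 0.2 * peak, +1)
        - _first_crossing_out(x, y, imax, 0.8 * peak, +1)
    )
    if _is_half(x, half):
        return float(right)
    left = abs(
        _first_crossing_out(x, y, imax, 0.2 * peak, -1)
        - _first_crossing_out(x, y, imax, 0.8 * peak, -1)
    )
    return float(0.5 * (left + right))


def on_axis_dose(profile) -> float:
    """Dose at the beam axis (r = 0) of a radial profile."""
    x, y = _as_xy(profile)
    return float(np.interp(0.0, x, y))


def output_factor(profile, reference, metadata=None, reference_metadata=None) -> float:
    """Relative output factor: on-axis dose ratio to the reference field.

    Both profiles must come from the same signal-calibration chain; if
    metadata dictionaries are supplied they are compared and a mismatch is
    logged as a warning (the ratio is still returned).
    """
    if metadata is not None and reference_metadata is not None:
        if metadata != reference_metadata:
            logger.warning(
                "output_factor: calibration metadata differs between field and "
                "reference (%r vs %r)",
                metadata,
                reference_metadata,
            )
    ref = on_axis_dose(reference)
    if ref <= 0:
        raise ValueError("reference profile has zero on-axis dose")
    return on_axis_dose(profile) / ref


def metrics_report(
    profiles: dict[str, dict],
    reference_field: str | None = None,
) -> pd.DataFrame:
    """Assemble one BeamMetrics row per field into a table.

    ``profiles`` maps field name to a dict with key ``"radial"`` (radial dose
    profile as (r, d) or HalfProfile) and optionally ``"projected"`` (lateral
    ProjectedProfile used for the field center; the center is reported as NaN
    when absent).  Output factors are normalized to ``reference_field``; if it
    is missing the OF column is omitted with a warning.
    """
    if not profiles:
        raise ValueError("metrics_report requires at least one field")
    have_reference = reference_field is not None and reference_field in profiles
    if reference_field is not None and not have_reference:
        logger.warning(
            "reference field %r not found; output-factor column omitted",
            reference_field,
        )
    ref_d0 = (
        on_axis_dose(profiles[reference_field]["radial"]) if have_reference else None
    )
    rows = []
    for name, entry in profiles.items():
        radial = entry["radial"]
        projected = entry.get("projected")
        center = field_center(projected) if projected is not None else float("nan")
        row = {
            "field": name,
            "center_mm": center,
            "fwhm_mm": fwhm(radial, half=True),
            "penumbra_20_80_mm": penumbra_20_80(radial, half=True),
            "on_axis_dose": on_axis_dose(radial),
        }
        if have_reference:
            row["output_factor"] = row["on_axis_dose"] / ref_d0
        rows.append(row)
    return pd.DataFrame(rows)
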