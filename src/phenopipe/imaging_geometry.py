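"""Pixel-to-metric conversion of side- and top-view plant images.

Side-view lengths convert with a single pixel-size constant.  The top-view
pixel size depends on plant height (taller plants are closer to the top
camera), which is proxied by the y-coordinate of the plant's centre of
mass in the side view.  Projected areas scale with the square of the pixel
size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CameraCalibration

__all__ = [
    "side_distance_mm",
    "top_coeff",
    "projected_areas_mm2",
    "convert_image_table",
]


def side_distance_mm(d_px, cal: CameraCalibration | None = None):
    """Convert a side-view distance in pixels to mm.

    Parameters
    ----------
    d_px : float or array-like
        Distance in pixels, must be non-negative.
    cal : CameraCalibration, optional
        Camera constants; defaults to the platform calibration.
    """
    cal = cal or CameraCalibration()
    d_px = np.asarray(d_px, dtype=float)
    if np.any(d_px < 0):
        raise ValueError("side-view distance in pixels must be non-negative")
    out = d_px * cal.side_coeff
    return float(out) if out.ndim == 0 else out


def top_coeff(cm_pix, cal: CameraCalibration | None = None):
    """Top-view pixel size (mm px^-1) as a linear function of plant height.

    ``cm_pix`` is the y-coordinate (pixels, y increasing downward) of the
    plant centre of mass from the side views.
    """
    cal = cal or CameraCalibration()
    cm_pix = np.asarray(cm_pix, dtype=float)
    if np.any(cm_pix < 0):
        raise ValueError("cm_pix must be non-negative")
    out = cal.top_slope * cm_pix + cal.top_offset
    return float(out) if out.ndim == 0 else out


def projected_areas_mm2(side_area_px, top_area_px, cm_pix,
                        cal: CameraCalibration | None = None):
    """Convert projected areas in pixels to mm^2 for both views.

    Returns ``(side_area_mm2, top_area_mm2)``.  The side area scales with
    the square of the side pixel size; the top area with the square of the
    height-dependent top pixel size.
    """
    cal = cal or CameraCalibration()
    side_area_px = np.asarray(side_area_px, dtype=float)
    top_area_px = np.asarray(top_area_px, dtype=float)
    if np.any(side_area_px < 0) or np.any(top_area_px < 0):
        raise ValueError("pixel areas must be non-negative")
    side_mm2 = side_area_px * cal.side_coeff ** 2
    top_mm2 = top_area_px * np.asarray(top_coeff(cm_pix, cal)) ** 2
    if side_mm2.ndim == 0:
        return float(side_mm2), float(top_mm2)
    return side_mm2, top_mm2


def convert_image_table(df: pd.DataFrame,
                        cal: CameraCalibration | None = None) -> pd.DataFrame:
    """Append metric projected areas to an image-record table.

    Expects columns ``plant_id, day, side_area_px, top_area_px, cm_pix``
    (one row per plant per imaging day, side views already averaged) and
    returns a copy with ``side_area_mm2`` and ``top_area_mm2`` appended.
    """
    required = {"plant_id", "day", "side_area_px", "top_area_px", "cm_pix"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"image table missing columns: {sorted(missing)}")
    out = df.copy()
    side, top = projected_areas_mm2(
        df["side_area_px"].to_numpy(),
        df["top_area_px"].to_numpy(),
        df["cm_pix"].to_numpy(),
        cal,
    )
    out["side_area_mm2"] = side
    out["top_area_mm2"] = top
    return out
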