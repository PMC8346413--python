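"""Wind-chill temperature (WCT) and the four-category frostbite-time chart.

Cold-weather guidance traditionally expresses frostbite risk of exposed
cheek skin as a lookup chart over air temperature and wind speed with four
time categories: unlimited, 30 min, 10 min, and 5 min.  This module
implements the WCT regression

    WCT = 13.12 + 0.6215*T + (0.3965*T - 11.37) * V**0.16

with T in C and V in km/h, valid for T <= 10 C and V >= 4.8 km/h (below the
floor the index is defined as the air temperature itself), and a
nearest-cell category lookup in a bundled chart.

The bundled chart (``data/wct_chart_synthetic.csv``) is a *synthetic
reconstruction*: the published chart's cell shading is treated as external
guidance data, and the bundled grid was generated from the WCT regression
with category boundaries calibrated to two documented anchor cells
(-32 C / 2.2 m/s -> 30 min; -17.8 C / 6.7 m/s -> 30 min).  The file is
swappable for a transcription of any chart edition with the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Validity floor of the regression, km/h.
VALIDITY_FLOOR_KMH = 4.8
#: Validity ceiling on air temperature, C.
VALIDITY_MAX_T = 10.0

#: Chart categories from mildest to most severe.
CATEGORIES: tuple[str, ...] = ("unlimited", "30 min", "10 min", "5 min")


@dataclass(frozen=True)
class WCTResult:
    wct: float                   # C
    category: str | None
    in_validity_range: bool


def wct(t_air: float, v_wind: float) -> float:
    """Wind-chill temperature (C) for air temperature (C) and wind (m/s).

    Below the 4.8 km/h validity floor the air temperature is returned
    unchanged (the index is undefined in near-calm air).
    """
    v_kmh = v_wind * 3.6
    if v_kmh < VALIDITY_FLOOR_KMH:
        return float(t_air)
    return float(13.12 + 0.6215 * t_air + (0.3965 * t_air - 11.37) * v_kmh ** 0.16)


def default_chart_path() -> Path:
    return Path(str(resources.files("coweda.data") / "wct_chart_synthetic.csv"))


@lru_cache(maxsize=4)
def _load_chart(path_str: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    frame = pd.read_csv(path_str)
    temps = frame["t_air_c"].to_numpy(dtype=float)
    winds = np.array([float(c) for c in frame.columns[1:]])
    cells = frame.iloc[:, 1:].to_numpy(dtype=object)
    bad = {c for row in cells for c in row} - set(CATEGORIES)
    if bad:
        raise ValidationError(f"chart contains unknown categories {sorted(bad)}")
    return temps, winds, cells


def chart_grid(chart_path: str | Path | None = None):
    """(temperatures C, winds m/s, category matrix) of the bundled chart."""
    return _load_chart(str(chart_path or default_chart_path()))


def frostbite_category(t_air: float, v_wind: float,
                       chart_path: str | Path | None = None) -> str:
    """Nearest-grid-cell frostbite-time category from the bundled chart."""
    temps, winds, cells = chart_grid(chart_path)
    t_step = np.abs(np.diff(temps)).max() if temps.size > 1 else 0.0
    v_step = np.abs(np.diff(winds)).max() if winds.size > 1 else 0.0
    if not (temps.min() - t_step / 2 <= t_air <= temps.max() + t_step / 2):
        raise ValidationError(
            f"air temperature {t_air} C outside chart range "
            f"[{temps.min()}, {temps.max()}] C")
    if not (winds.min() - v_step / 2 <= v_wind <= winds.max() + v_step / 2):
        raise ValidationError(
            f"wind speed {v_wind} m/s outside chart range "
            f"[{winds.min()}, {winds.max()}] m/s")
    i = int(np.argmin(np.abs(temps - t_air)))
    j = int(np.argmin(np.abs(winds - v_wind)))
    return str(cells[i, j])


def compute(t_air: float, v_wind: float,
            chart_path: str | Path | None = None) -> WCTResult:
    """WCT plus chart category plus validity flag, in one object."""
    value = wct(t_air, v_wind)
    valid = t_air <= VALIDITY_MAX_T and v_wind * 3.6 >= VALIDITY_FLOOR_KMH
    try:
        category: str | None = frostbite_category(t_air, v_wind, chart_path)
    except ValidationError:
        category = None
    return WCTResult(wct=value, category=category, in_validity_range=valid)
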