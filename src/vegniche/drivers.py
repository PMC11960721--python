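"""Monthly per-soil-layer environmental drivers.

The community model consumes monthly series of soil-solution pH, nitrogen
concentration (mg/L) and moisture saturation per soil layer, together with
a single soil temperature and the fraction of above-canopy light reaching
the forest floor. Real series come from a biogeochemical simulator; the
synthetic generator here emulates that kind of output (seasonal cycle,
multi-decadal trend, stochastic scatter) so the community and calibration
machinery can be exercised end to end without one.

Series are stored long-format (one row per month x layer) and validated on
read; root-zone aggregation reduces the per-layer values to the slice of
soil a species' roots reach.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SoilProfile",
    "DriverSeries",
    "SyntheticDriverConfig",
    "DriverSchemaError",
    "read_drivers",
    "write_drivers",
    "aggregate_root_zone",
    "generate_synthetic_drivers",
]

log = logging.getLogger(__name__)

DRIVER_COLUMNS = [
    "year", "month", "layer", "pH", "N_mgL", "moisture_frac",
    "soil_temp_C", "floor_light_frac",
]

LAYER_DRIVERS = {"pH": "pH", "N": "N_mgL", "moisture": "moisture_frac"}


class DriverSchemaError(ValueError):
    """A driver file or frame violates the documented schema."""


@dataclass(frozen=True)
class SoilProfile:
    """Ordered, contiguous soil layers as (label, top m, bottom m)."""

    layers: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise DriverSchemaError("soil profile needs at least one layer")
        prev_bottom = 0.0
        for label, top, bottom in self.layers:
            if not math.isclose(top, prev_bottom, abs_tol=1e-9):
                raise DriverSchemaError(
                    f"layer {label!r} top {top} does not continue from {prev_bottom}"
                )
            if bottom <= top:
                raise DriverSchemaError(f"layer {label!r} has bottom <= top")
            prev_bottom = bottom

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(l for l, _, _ in self.layers)

    @property
    def bottom(self) -> float:
        return self.layers[-1][2]

    @classmethod
    def from_thicknesses(cls, labels: Sequence[str], thicknesses: Sequence[float]) -> "SoilProfile":
        tops = np.concatenate([[0.0], np.cumsum(thicknesses)[:-1]])
        return cls(tuple(
            (str(l), float(t), float(t + h))
            for l, t, h in zip(labels, tops, thicknesses)
        ))


@dataclass
class DriverSeries:
    """Monthly environmental state: per-layer chemistry/moisture plus a
    profile-wide soil temperature and forest-floor light fraction.

    Wraps a long-format :class:`pandas.DataFrame` with columns
    ``year, month, layer, pH, N_mgL, moisture_frac, soil_temp_C,
    floor_light_frac``; temperature and floor light repeat across the layer
    rows of each month.
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = _validate_frame(self.frame)
        # memoizes root-zone aggregation; keyed (year, month, depth, mode)
        self._agg_cache: dict = {}

    @property
    def layers(self) -> tuple[str, ...]:
        first = self.frame[self.frame["time_idx"] == self.frame["time_idx"].iloc[0]]
        return tuple(first["layer"])

    @property
    def months(self) -> list[tuple[int, int]]:
        sub = self.frame.drop_duplicates("time_idx")
        return list(zip(sub["year"].astype(int), sub["month"].astype(int)))

    @property
    def years(self) -> list[int]:
        return sorted({y for y, _ in self.months})

    def month_slice(self, year: int, month: int) -> pd.DataFrame:
        sub = self.frame[(self.frame["year"] == year) & (self.frame["month"] == month)]
        if sub.empty:
            raise KeyError(f"no driver rows for {year}-{month:02d}")
        return sub

    def scalars(self, year: int, month: int) -> tuple[float, float]:
        """(soil_temp_C, floor_light_frac) for one month."""
        sub = self.month_slice(year, month)
        return float(sub["soil_temp_C"].iloc[0]), float(sub["floor_light_frac"].iloc[0])


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        raise DriverSchemaError("no records")
    missing = [c for c in DRIVER_COLUMNS if c not in df.columns]
    if missing:
        raise DriverSchemaError(f"missing columns: {missing}")
    df = df.copy()
    for col, lo, hi in [
        ("moisture_frac", 0.0, 1.0),
        ("floor_light_frac", 0.0, 1.0),
    ]:
        bad = df.index[(df[col] < lo) | (df[col] > hi) | df[col].isna()]
        if len(bad):
            raise DriverSchemaError(
                f"column {col!r} out of [{lo}, {hi}] at row {int(bad[0])}"
            )
    bad = df.index[(df["N_mgL"] < 0) | df["N_mgL"].isna()]
    if len(bad):
        raise DriverSchemaError(f"column 'N_mgL' negative or missing at row {int(bad[0])}")
    # strict monthly grid with no gaps
    df["time_idx"] = df["year"].astype(int) * 12 + (df["month"].astype(int) - 1)
    idx = np.array(sorted(df["time_idx"].unique()))
    if not np.all(np.diff(idx) == 1):
        gap = int(idx[np.argmax(np.diff(idx) > 1)])
        raise DriverSchemaError(
            f"time must advance in whole months with no gaps (gap after "
            f"{gap // 12}-{gap % 12 + 1:02d})"
        )
    return df.sort_values(["time_idx", "layer"], kind="stable").reset_index(drop=True)


def read_drivers(path: str | Path) -> DriverSeries:
    """Read a driver CSV (schema in :data:`DRIVER_COLUMNS`, '#' comments)."""
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise DriverSchemaError("no records") from None
    return DriverSeries(df)


def write_drivers(series: DriverSeries, path: str | Path) -> None:
    """Write a driver CSV that round-trips through :func:`read_drivers`."""
    series.frame[DRIVER_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# root-zone aggregation
# ---------------------------------------------------------------------------


def aggregate_root_zone(
    profile: SoilProfile,
    series: DriverSeries,
    rooting_depth: float,
    month: tuple[int, int],
    *,
    mode: str = "weighted_mean",
) -> dict[str, float]:
    """Per-axis driver values over the root zone [0, rooting_depth].

    ``mode='weighted_mean'`` (default) takes the thickness-weighted mean of
    each layer driver over the layers the roots intersect, a partially
    intersected layer contributing its intersected thickness;
    ``mode='deepest'`` takes the values of the deepest intersected layer.
    A rooting depth below the profile bottom is clamped with a warning.
    """
    if rooting_depth <= 0:
        raise ValueError("rooting_depth must be > 0")
    if mode not in ("weighted_mean", "deepest"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if rooting_depth > profile.bottom + 1e-12:
        log.warning(
            "rooting depth %.3f m exceeds profile bottom %.3f m; clamping",
            rooting_depth, profile.bottom,
        )
        rooting_depth = profile.bottom

    cache_key = (month, round(rooting_depth, 9), mode, id(profile))
    cached = series._agg_cache.get(cache_key)
    if cached is not None:
        return dict(cached)

    sub = series.month_slice(*month).set_index("layer")
    weights: list[float] = []
    rows: list[pd.Series] = []
    for label, top, bottom in profile.layers:
        overlap = max(0.0, min(bottom, rooting_depth) - top)
        if overlap <= 0:
            continue
        if label not in sub.index:
            raise DriverSchemaError(f"layer {label!r} absent from drivers for {month}")
        weights.append(overlap)
        rows.append(sub.loc[label])
    if mode == "deepest":
        deepest = rows[-1]
        out = {axis: float(deepest[col]) for axis, col in LAYER_DRIVERS.items()}
    else:
        w = np.asarray(weights)
        w = w / w.sum()
        out = {
            axis: float(np.dot(w, [r[col] for r in rows]))
            for axis, col in LAYER_DRIVERS.items()
        }
    series._agg_cache[cache_key] = dict(out)
    return out


# ---------------------------------------------------------------------------
# synthetic driver generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DriverSignal:
    """One driver's generating signal: baseline + seasonal sine + linear
    trend per decade + noise. ``noise`` is a scale: the sigma of additive
    Gaussian noise, or the sigma of multiplicative lognormal noise for
    non-negative concentrations."""

    baseline: float
    amplitude: float = 0.0
    trend_per_decade: float = 0.0
    noise: float = 0.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise scale must be >= 0")


#: Defaults emulate monthly biogeochemical output for an acid northeastern
#: hardwood soil: pH ~4.3 with a slow recovery, dilute inorganic N with a
#: seasonal pulse and a declining-deposition trend, moist soils with summer
#: drawdown, a seasonal temperature swing, and a closed-canopy forest floor
#: receiving ~12% of above-canopy light with a spring (pre-leaf-out) peak.
DEFAULT_SIGNALS: dict[str, DriverSignal] = {
    "pH": DriverSignal(baseline=4.3, amplitude=0.05, trend_per_decade=0.05, noise=0.04),
    "N": DriverSignal(baseline=1.2, amplitude=0.4, trend_per_decade=-0.15, noise=0.15),
    "moisture": DriverSignal(baseline=0.55, amplitude=0.12, trend_per_decade=0.0,
                             noise=0.04, phase=math.pi),
    "soil_temp": DriverSignal(baseline=6.0, amplitude=9.0, trend_per_decade=0.2,
                              noise=0.8, phase=-2.0),
    "floor_light": DriverSignal(baseline=0.12, amplitude=0.04, trend_per_decade=0.0,
                                noise=0.015, phase=math.pi / 2),
}

#: Additive per-layer offsets with depth (index = layer number from the
#: surface, scaled into [0, 1]); pH rises and N falls down-profile,
#: moisture increases toward the water table.
_DEPTH_GRADIENTS = {"pH": 0.5, "N": -0.4, "moisture": 0.15}

PHYSICAL_RANGES = {
    "pH": (2.5, 9.0),
    "N": (0.0, math.inf),
    "moisture": (0.0, 1.0),
    "floor_light": (0.0, 1.0),
    "soil_temp": (-30.0, 40.0),
}


@dataclass(frozen=True)
class SyntheticDriverConfig:
    """Configuration for the synthetic driver generator."""

    start_year: int = 1990
    n_years: int = 10
    layers: tuple[tuple[str, float, float], ...] = (
        ("O", 0.0, 0.07), ("A", 0.07, 0.2), ("B", 0.2, 0.6),
    )
    signals: Mapping[str, DriverSignal] = field(
        default_factory=lambda: dict(DEFAULT_SIGNALS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("span must cover at least one year")
        missing = [k for k in DEFAULT_SIGNALS if k not in self.signals]
        if missing:
            raise ValueError(f"missing driver signals: {missing}")

    @property
    def profile(self) -> SoilProfile:
        return SoilProfile(self.layers)


def _clip(name: str, values: np.ndarray) -> np.ndarray:
    lo, hi = PHYSICAL_RANGES[name]
    return np.clip(values, lo, hi)


def generate_synthetic_drivers(config: SyntheticDriverConfig) -> DriverSeries:
    """Deterministic (per seed) synthetic monthly driver series.

    Each driver is ``baseline + amplitude*sin(2*pi*month/12 + phase)
    + trend*elapsed_decades + noise``, clipped to its physical range.
    Noise is lognormal-multiplicative for N (keeps concentrations
    non-negative and right-skewed, like observed solution chemistry) and
    additive Gaussian for everything else. Layer drivers get a fixed
    down-profile gradient on top of the shared signal.
    """
    rng = np.random.default_rng(config.seed)
    n_months = config.n_years * 12
    months = np.arange(n_months)
    cal_month = months % 12 + 1
    decades = months / 120.0
    layers = config.layers
    n_layers = len(layers)
    depth_pos = (
        np.linspace(0.0, 1.0, n_layers) if n_layers > 1 else np.zeros(1)
    )

    def base_signal(sig: DriverSignal) -> np.ndarray:
        return (
            sig.baseline
            + sig.amplitude * np.sin(2 * np.pi * cal_month / 12 + sig.phase)
            + sig.trend_per_decade * decades
        )

    def with_noise(name: str, sig: DriverSignal, signal: np.ndarray) -> np.ndarray:
        if sig.noise == 0:
            return signal
        if name == "N":
            return signal * rng.lognormal(mean=0.0, sigma=sig.noise, size=signal.shape)
        return signal + rng.normal(0.0, sig.noise, size=signal.shape)

    per_layer: dict[str, np.ndarray] = {}
    for name in ("pH", "N", "moisture"):
        sig = config.signals[name]
        shared = base_signal(sig)
        grad = _DEPTH_GRADIENTS[name] * depth_pos
        stacked = shared[None, :] + grad[:, None]
        if name == "N":
            stacked = np.maximum(stacked, 0.05 * sig.baseline)
        per_layer[name] = _clip(name, with_noise(name, sig, stacked))

    temp = _clip("soil_temp", with_noise(
        "soil_temp", config.signals["soil_temp"], base_signal(config.signals["soil_temp"])
    ))
    light = _clip("floor_light", with_noise(
        "floor_light", config.signals["floor_light"], base_signal(config.signals["floor_light"])
    ))

    records = []
    for m in months:
        year = config.start_year + m // 12
        for li, (label, _, _) in enumerate(layers):
            records.append({
                "year": year, "month": int(cal_month[m]), "layer": label,
                "pH": per_layer["pH"][li, m],
                "N_mgL": per_layer["N"][li, m],
                "moisture_frac": per_layer["moisture"][li, m],
                "soil_temp_C": temp[m],
                "floor_light_frac": light[m],
            })
    return DriverSeries(pd.DataFrame.from_records(records), meta={"seed": config.seed})
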