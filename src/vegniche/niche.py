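"""Species niche representation and environmental suitability.

Each understory plant species is described by a set of fundamental niches:
Gaussian response curves for soil-solution pH, soil-solution nitrogen
(mg/L), soil moisture (saturation fraction) and light (fraction of
above-canopy light reaching the plant), plus a hard minimum/maximum
temperature window. The response along one Gaussian axis is

    resp(driver, opt, var) = exp(-(driver - opt)**2 / var)

where ``opt`` is the driver value at which the response peaks and ``var``
is the tolerance, in squared driver units, controlling how quickly
suitability falls off away from the optimum. Site suitability is the
product of the four Gaussian responses gated by the temperature window.

Niche parameters may also be expressed as integer *class ranks* (the way
expert elicitation typically records them); a :class:`ClassKey` maps ranks
to physical units and back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "GAUSSIAN_AXES",
    "AXIS_PRIORITY",
    "NicheAxis",
    "TemperatureWindow",
    "PlantSpecies",
    "ClassKey",
    "ParameterTable",
    "InvalidParameterError",
    "ClassLookupError",
    "response_gaussian",
    "response_temperature",
    "site_suitability",
    "read_parameter_table",
    "write_parameter_table",
    "default_class_key",
    "read_class_key",
    "write_class_key",
]

#: The four environmental axes with Gaussian responses, in canonical order.
GAUSSIAN_AXES = ("pH", "N", "moisture", "light")

#: Deterministic tie-break order used when ranking axes during calibration
#: (most frequently revised axis first).
AXIS_PRIORITY = ("light", "N", "pH", "shading_height", "moisture")

#: Responses smaller than this are clamped to exactly zero; at this size the
#: species is numerically excluded anyway and clamping avoids underflow noise.
RESPONSE_FLOOR = 1e-300

#: Maximum shading height of the herbaceous layer (m).
MAX_SHADING_HEIGHT = 1.8


class InvalidParameterError(ValueError):
    """A niche parameter or driver value is outside its valid domain."""


class ClassLookupError(KeyError):
    """A class rank or axis name is not present in the class key."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NicheAxis:
    """One environmental axis of a species' fundamental niche.

    Parameters
    ----------
    axis_name
        One of ``pH``, ``N``, ``moisture``, ``light``.
    opt
        Optimum driver value (pH unitless, N in mg/L, moisture and light as
        fractions in [0, 1]).
    var
        Tolerance in squared driver units; must be positive.
    """

    axis_name: str
    opt: float
    var: float

    def __post_init__(self) -> None:
        if self.axis_name not in GAUSSIAN_AXES:
            raise InvalidParameterError(
                f"unknown axis {self.axis_name!r}; expected one of {GAUSSIAN_AXES}"
            )
        if not math.isfinite(self.opt) or not math.isfinite(self.var):
            raise InvalidParameterError(f"non-finite niche parameters on {self.axis_name}")
        if self.var <= 0:
            raise InvalidParameterError(f"var must be > 0 on axis {self.axis_name}, got {self.var}")
        if self.axis_name in ("moisture", "light") and not 0.0 <= self.opt <= 1.0:
            raise InvalidParameterError(
                f"{self.axis_name} optimum must lie in [0, 1], got {self.opt}"
            )
        if self.axis_name == "N" and self.opt < 0:
            raise InvalidParameterError(f"N optimum must be >= 0, got {self.opt}")


@dataclass(frozen=True)
class TemperatureWindow:
    """Closed temperature interval [tmin, tmax] (deg C) within which a
    species can persist; outside it the response is zero."""

    tmin: float
    tmax: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.tmin) and math.isfinite(self.tmax)):
            raise InvalidParameterError("temperature window bounds must be finite")
        if self.tmin >= self.tmax:
            raise InvalidParameterError(
                f"temperature window requires tmin < tmax, got [{self.tmin}, {self.tmax}]"
            )


@dataclass(frozen=True)
class PlantSpecies:
    """A species' full niche set plus rooting depth and shading height.

    ``class_ranks`` optionally records the integer class rank behind each
    physical parameter (axes plus ``shading_height`` / ``rooting_depth``);
    calibration operates on ranks when they are present.
    """

    name: str
    axes: Mapping[str, NicheAxis]
    temperature: TemperatureWindow
    rooting_depth: float
    shading_height: float
    class_ranks: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidParameterError("species name must be nonempty")
        missing = [a for a in GAUSSIAN_AXES if a not in self.axes]
        if missing:
            raise InvalidParameterError(f"species {self.name!r} missing axes {missing}")
        if self.rooting_depth <= 0:
            raise InvalidParameterError(f"rooting_depth must be > 0 for {self.name!r}")
        if not 0 < self.shading_height <= MAX_SHADING_HEIGHT:
            raise InvalidParameterError(
                f"shading_height must lie in (0, {MAX_SHADING_HEIGHT}] m for {self.name!r},"
                f" got {self.shading_height}"
            )


@dataclass(frozen=True)
class ParameterTable:
    """An ordered collection of species with unique names."""

    species: tuple[PlantSpecies, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        names = [sp.name for sp in self.species]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise InvalidParameterError(f"duplicate species names: {sorted(dupes)}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(sp.name for sp in self.species)

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self):
        return iter(self.species)

    def get(self, name: str) -> PlantSpecies:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(name)

    def with_species(self, updated: PlantSpecies) -> "ParameterTable":
        """Return a copy with one species replaced (matched by name)."""
        out = tuple(updated if sp.name == updated.name else sp for sp in self.species)
        if updated.name not in self.names:
            raise KeyError(updated.name)
        return replace(self, species=out)


class ClassKey:
    """Mapping between integer class ranks and physical niche parameters.

    For each Gaussian axis the key maps rank -> (opt, var); for
    ``shading_height`` and ``rooting_depth`` it maps rank -> a scalar in
    metres. Ranks are strictly ordered and mapped optima strictly monotone
    in rank, so the inverse lookup is well defined.
    """

    SCALAR_AXES = ("shading_height", "rooting_depth")

    def __init__(self, mapping: Mapping[str, Mapping[int, tuple | float]]) -> None:
        self._map: dict[str, dict[int, tuple[float, float] | float]] = {}
        for axis, entries in mapping.items():
            if axis not in GAUSSIAN_AXES + self.SCALAR_AXES:
                raise ClassLookupError(f"unknown axis {axis!r} in class key")
            ranks = sorted(int(r) for r in entries)
            vals: dict[int, tuple[float, float] | float] = {}
            for r in ranks:
                v = entries[r]
                if axis in self.SCALAR_AXES:
                    vals[r] = float(v)  # type: ignore[arg-type]
                else:
                    opt, var = v  # type: ignore[misc]
                    vals[r] = (float(opt), float(var))
            opts = [vals[r][0] if axis in GAUSSIAN_AXES else vals[r] for r in ranks]
            if any(b <= a for a, b in zip(opts, opts[1:])):
                raise InvalidParameterError(
                    f"class key optima must be strictly increasing in rank on {axis!r}"
                )
            self._map[axis] = vals

    @property
    def axes(self) -> tuple[str, ...]:
        return tuple(self._map)

    def ranks(self, axis_name: str) -> tuple[int, ...]:
        self._check_axis(axis_name)
        return tuple(sorted(self._map[axis_name]))

    def _check_axis(self, axis_name: str) -> None:
        if axis_name not in self._map:
            raise ClassLookupError(
                f"axis {axis_name!r} not in class key; valid axes: {sorted(self._map)}"
            )

    def class_to_units(self, rank: int, axis_name: str):
        """Physical-unit parameters for ``rank`` on ``axis_name``.

        Returns ``(opt, var)`` for Gaussian axes and a scalar (m) for
        shading height / rooting depth. The lookup is strict: ranks between
        defined entries are an error, never interpolated.
        """
        self._check_axis(axis_name)
        try:
            return self._map[axis_name][int(rank)]
        except KeyError:
            raise ClassLookupError(
                f"rank {rank} not defined for axis {axis_name!r};"
                f" valid ranks: {list(self.ranks(axis_name))}"
            ) from None

    def units_to_class(self, value, axis_name: str, atol: float = 1e-9) -> int:
        """Inverse of :meth:`class_to_units` on defined entries.

        ``value`` is an ``(opt, var)`` pair for Gaussian axes or a scalar
        for the scalar axes; only the optimum is matched for Gaussian axes.
        """
        self._check_axis(axis_name)
        target = value[0] if axis_name in GAUSSIAN_AXES else float(value)
        for r in self.ranks(axis_name):
            entry = self._map[axis_name][r]
            opt = entry[0] if axis_name in GAUSSIAN_AXES else entry
            if abs(opt - target) <= atol:
                return r
        raise ClassLookupError(
            f"value {target} does not match any defined class optimum on {axis_name!r}"
        )

    def nearest_rank(self, value: float, axis_name: str) -> int:
        """Rank whose optimum is closest to ``value`` (ties -> lower rank)."""
        self._check_axis(axis_name)
        best = None
        for r in self.ranks(axis_name):
            entry = self._map[axis_name][r]
            opt = entry[0] if axis_name in GAUSSIAN_AXES else entry
            d = abs(opt - value)
            if best is None or d < best[0] - 1e-15:
                best = (d, r)
        assert best is not None
        return best[1]

    def to_mapping(self) -> dict:
        return {
            axis: {
                r: (list(v) if isinstance(v, tuple) else v)
                for r, v in sorted(entries.items())
            }
            for axis, entries in self._map.items()
        }


# ---------------------------------------------------------------------------
# responses (the model core)
# ---------------------------------------------------------------------------


def response_gaussian(driver: float, axis: NicheAxis, *, var_is_sd: bool = False) -> float:
    """Gaussian niche response ``exp(-(driver - opt)**2 / var)``.

    Equals 1 exactly at the optimum and decays symmetrically with distance
    from it. ``var`` carries squared driver units; with ``var_is_sd=True``
    it is instead read as a standard-deviation-like width and squared
    internally.

    Raises
    ------
    InvalidParameterError
        If ``driver`` is not finite (invalid ``var`` is rejected when the
        axis is constructed).
    """
    if not math.isfinite(driver):
        raise InvalidParameterError(f"driver must be finite, got {driver}")
    var = axis.var * axis.var if var_is_sd else axis.var
    z = (driver - axis.opt) ** 2 / var
    # exp underflows to subnormals near 745; clamp to a hard zero
    if z > 690.0:
        return 0.0
    r = math.exp(-z)
    return 0.0 if r < RESPONSE_FLOOR else r


def response_temperature(t: float, window: TemperatureWindow) -> float:
    """Hard {0, 1} indicator of the closed interval [tmin, tmax]."""
    if not math.isfinite(t):
        raise InvalidParameterError(f"temperature must be finite, got {t}")
    return 1.0 if window.tmin <= t <= window.tmax else 0.0


def site_suitability(
    plant: PlantSpecies,
    env: Mapping[str, float],
    t: float,
    light: float,
    *,
    var_is_sd: bool = False,
) -> float:
    """Product of the four Gaussian responses, gated by temperature.

    ``env`` supplies the pH, N and moisture driver values; ``light`` is the
    fraction of above-canopy light available to this plant (after any
    shading by taller neighbours). The product is bounded above by each
    individual factor, and a temperature outside the window forces zero.
    """
    if not 0.0 <= light <= 1.0:
        raise InvalidParameterError(f"light fraction must lie in [0, 1], got {light}")
    if response_temperature(t, plant.temperature) == 0.0:
        return 0.0
    drivers = {**env, "light": light}
    out = 1.0
    for axis_name in GAUSSIAN_AXES:
        out *= response_gaussian(drivers[axis_name], plant.axes[axis_name], var_is_sd=var_is_sd)
        if out == 0.0:
            return 0.0
    return out


def response_factors(
    plant: PlantSpecies,
    env: Mapping[str, float],
    light: float,
    *,
    var_is_sd: bool = False,
) -> dict[str, float]:
    """Per-axis Gaussian responses (no temperature gate), keyed by axis."""
    drivers = {**env, "light": light}
    return {
        a: response_gaussian(drivers[a], plant.axes[a], var_is_sd=var_is_sd)
        for a in GAUSSIAN_AXES
    }


# ---------------------------------------------------------------------------
# default class key
# ---------------------------------------------------------------------------

#: Physical ranges spanned by the default, evenly spaced 9-class key.
_DEFAULT_RANGES = {
    "pH": (3.0, 7.0),
    "N": (0.0, 10.0),
    "moisture": (0.05, 0.95),
    "light": (0.02, 1.0),
}
_DEFAULT_N_CLASSES = 9

#: Default scalar class ladders (m). Shading heights stay within the 1.8 m
#: herbaceous layer; rooting depths span litter-rooted to deep-rooted forbs.
_DEFAULT_SHADING = (0.05, 0.15, 0.3, 0.6, 1.0, 1.4, 1.8)
_DEFAULT_ROOTING = (0.05, 0.1, 0.2, 0.4, 0.8)


def default_class_key() -> ClassKey:
    """The built-in rank -> physical-units key.

    Nine evenly spaced optima per Gaussian axis over plausible field ranges
    (pH 3-7, N 0-10 mg/L, moisture 0.05-0.95, light 0.02-1.0), with the
    per-class tolerance set to the squared class spacing so that the
    response at a neighbouring class centre is e**-1. Deliberately a
    replaceable stand-in: supply a site-specific key via YAML where one
    exists.
    """
    mapping: dict[str, dict[int, tuple | float]] = {}
    for axis, (lo, hi) in _DEFAULT_RANGES.items():
        step = (hi - lo) / (_DEFAULT_N_CLASSES - 1)
        mapping[axis] = {
            r: (lo + (r - 1) * step, step * step) for r in range(1, _DEFAULT_N_CLASSES + 1)
        }
    mapping["shading_height"] = {r: h for r, h in enumerate(_DEFAULT_SHADING, start=1)}
    mapping["rooting_depth"] = {r: d for r, d in enumerate(_DEFAULT_ROOTING, start=1)}
    return ClassKey(mapping)


def read_class_key(path: str | Path) -> ClassKey:
    """Load a class key from YAML (axis -> {rank: [opt, var]} entries)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise InvalidParameterError(f"class key file {path} must map axes to rank tables")
    return ClassKey(raw)


def write_class_key(key: ClassKey, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(key.to_mapping(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# parameter table I/O (TSV)
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "name",
    "pH_opt", "pH_var", "N_opt", "N_var",
    "moisture_opt", "moisture_var", "light_opt", "light_var",
    "tmin_C", "tmax_C", "rooting_depth_m", "shading_height_m",
]
_RANK_COLUMNS = ["pH_class", "N_class", "moisture_class", "light_class",
                 "shading_height_class", "rooting_depth_class"]


def species_from_ranks(
    name: str,
    ranks: Mapping[str, int],
    key: ClassKey,
    temperature: TemperatureWindow,
) -> PlantSpecies:
    """Build a species from integer class ranks using a class key."""
    axes = {}
    for a in GAUSSIAN_AXES:
        opt, var = key.class_to_units(ranks[a], a)
        axes[a] = NicheAxis(a, opt, var)
    shading = key.class_to_units(ranks["shading_height"], "shading_height")
    rooting = key.class_to_units(ranks["rooting_depth"], "rooting_depth")
    return PlantSpecies(
        name=name,
        axes=axes,
        temperature=temperature,
        rooting_depth=float(rooting),
        shading_height=float(shading),
        class_ranks=dict(ranks),
    )


def read_parameter_table(
    path: str | Path,
    key: ClassKey | None = None,
    provenance: str = "",
) -> ParameterTable:
    """Read a species parameter TSV.

    Rows hold either physical parameters (``pH_opt``/``pH_var`` ...) or
    class ranks (``pH_class`` ...; requires ``key``); '#' lines are
    comments. A row whose name duplicates an earlier one is collapsed onto
    the first occurrence (keeping the first row's values).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    if "name" not in df.columns:
        raise InvalidParameterError(f"{path}: parameter table needs a 'name' column")
    df = df.drop_duplicates(subset="name", keep="first")
    use_ranks = all(c in df.columns for c in _RANK_COLUMNS)
    species = []
    for _, row in df.iterrows():
        window = TemperatureWindow(float(row["tmin_C"]), float(row["tmax_C"]))
        if use_ranks:
            if key is None:
                raise InvalidParameterError(
                    f"{path}: table uses class ranks but no class key was supplied"
                )
            ranks = {
                "pH": int(row["pH_class"]), "N": int(row["N_class"]),
                "moisture": int(row["moisture_class"]), "light": int(row["light_class"]),
                "shading_height": int(row["shading_height_class"]),
                "rooting_depth": int(row["rooting_depth_class"]),
            }
            species.append(species_from_ranks(str(row["name"]), ranks, key, window))
        else:
            axes = {
                a: NicheAxis(a, float(row[f"{a}_opt"]), float(row[f"{a}_var"]))
                for a in GAUSSIAN_AXES
            }
            species.append(
                PlantSpecies(
                    name=str(row["name"]),
                    axes=axes,
                    temperature=window,
                    rooting_depth=float(row["rooting_depth_m"]),
                    shading_height=float(row["shading_height_m"]),
                )
            )
    return ParameterTable(tuple(species), provenance=provenance or str(path))


def write_parameter_table(table: ParameterTable, path: str | Path) -> None:
    """Write a species table as a physical-units TSV (round-trips with
    :func:`read_parameter_table`); class ranks, when present, are appended
    as extra columns."""
    import pandas as pd

    rows = []
    has_ranks = any(sp.class_ranks for sp in table)
    for sp in table:
        row: dict[str, object] = {"name": sp.name}
        for a in GAUSSIAN_AXES:
            row[f"{a}_opt"] = sp.axes[a].opt
            row[f"{a}_var"] = sp.axes[a].var
        row["tmin_C"] = sp.temperature.tmin
        row["tmax_C"] = sp.temperature.tmax
        row["rooting_depth_m"] = sp.rooting_depth
        row["shading_height_m"] = sp.shading_height
        if has_ranks:
            for axis in GAUSSIAN_AXES + ("shading_height", "rooting_depth"):
                row[f"{axis}_class"] = sp.class_ranks.get(axis, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
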