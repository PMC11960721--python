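"""Community assembly: from per-species suitabilities to relative cover.

Species compete for light, taller plants shading shorter ones, and each
species' environmental suitability (computed with its *shaded* light as the
light driver) is its competitive strength. Relative surface cover is
strength normalized over the community, so covers sum to one. Because the
light a species receives depends on the covers of taller species, which in
turn depend on every species' strength, the within-year solution is a
damped fixed point; years are then chained with an optional inertia factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .drivers import DriverSeries, SoilProfile, aggregate_root_zone
from .niche import (
    GAUSSIAN_AXES,
    ParameterTable,
    PlantSpecies,
    response_gaussian,
    response_temperature,
)

__all__ = [
    "CommunityState",
    "SimulationOptions",
    "light_at_height",
    "plant_strength",
    "assign_relative_cover",
    "step_community",
    "simulate_community",
    "covers_to_frame",
    "write_covers",
    "read_covers",
]

log = logging.getLogger(__name__)

#: Shading heights closer than this (m) count as equal: neither shades the other.
HEIGHT_TIE_TOL = 1e-9


@dataclass(frozen=True)
class CommunityState:
    """Normalized relative surface cover per species at one time point.

    ``viable`` is False when no species had positive strength (covers are
    all zero and deliberately *not* normalized); ``converged`` is False
    when the within-year fixed point hit its iteration cap.
    """

    covers: Mapping[str, float]
    time: int | tuple[int, int] | None = None
    viable: bool = True
    converged: bool = True

    def __post_init__(self) -> None:
        vals = np.array(list(self.covers.values()), dtype=float)
        if (vals < -1e-12).any():
            raise ValueError("covers must be non-negative")
        if self.viable and abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"covers must sum to 1, got {vals.sum()!r}")

    def as_array(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.covers[n] for n in names], dtype=float)

    @classmethod
    def uniform(cls, names: Sequence[str], time=None) -> "CommunityState":
        n = len(names)
        return cls({name: 1.0 / n for name in names}, time=time)


@dataclass(frozen=True)
class SimulationOptions:
    """Tunables of the community model.

    shading_efficiency
        Fraction of light removed under full cover of taller plants
        (``s`` in ``light * (1 - s * C_taller)``).
    dominance_exponent
        ``gamma`` in ``strength = suitability ** gamma``; values above 1
        sharpen dominance.
    inertia
        Year-to-year update rate ``lambda`` in (0, 1]; 1 replaces the
        community with the new equilibrium every year.
    growing_season
        Inclusive (first, last) calendar months whose suitabilities are
        averaged before strengths are computed.
    """

    shading_efficiency: float = 0.75
    dominance_exponent: float = 1.0
    inertia: float = 1.0
    growing_season: tuple[int, int] = (5, 9)
    root_mode: str = "weighted_mean"
    var_is_sd: bool = False
    fp_tol: float = 1e-6
    fp_max_iter: int = 100
    fp_damping: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.shading_efficiency <= 1.0:
            raise ValueError("shading efficiency must lie in [0, 1]")
        if not 0.0 < self.inertia <= 1.0:
            raise ValueError("inertia (lambda) must lie in (0, 1]")
        if self.dominance_exponent <= 0:
            raise ValueError("dominance exponent must be > 0")

    def season_months(self) -> tuple[int, ...]:
        first, last = self.growing_season
        if first <= last:
            return tuple(range(first, last + 1))
        return tuple(range(first, 13)) + tuple(range(1, last + 1))


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def light_at_height(
    plant: PlantSpecies,
    state: CommunityState,
    table: ParameterTable,
    floor_light: float,
    shading_efficiency: float = 0.75,
) -> float:
    """Light available to ``plant`` after occlusion by strictly taller plants.

    ``floor_light * (1 - s * C_taller)`` with ``C_taller`` the summed cover
    of species whose shading height strictly exceeds the plant's, clipped
    to ``[floor_light * (1 - s), floor_light]``. Species of equal shading
    height do not shade each other.
    """
    if not 0.0 <= floor_light <= 1.0:
        raise ValueError("floor_light must lie in [0, 1]")
    c_taller = sum(
        state.covers.get(sp.name, 0.0)
        for sp in table
        if sp.shading_height > plant.shading_height + HEIGHT_TIE_TOL
    )
    avail = floor_light * (1.0 - shading_efficiency * c_taller)
    return float(np.clip(avail, floor_light * (1.0 - shading_efficiency), floor_light))


def plant_strength(suitability: float, dominance_exponent: float = 1.0) -> float:
    """Competitive strength from suitability.

    The identity map by default — shading already enters through the light
    response, so suitability (computed with shaded light) *is* the
    strength. ``dominance_exponent`` other than 1 applies
    ``suitability ** gamma`` for sharper or flatter dominance.
    """
    if not 0.0 <= suitability:
        raise ValueError("suitability must be >= 0")
    if dominance_exponent == 1.0:
        return float(suitability)
    return float(suitability**dominance_exponent)


def assign_relative_cover(strengths: Mapping[str, float], time=None) -> CommunityState:
    """Proportional-to-strength cover: ``cover_i = s_i / sum_j s_j``.

    All-zero strengths yield a flagged non-viable state (all covers zero)
    rather than a division error.
    """
    names = list(strengths)
    vals = np.array([strengths[n] for n in names], dtype=float)
    if (vals < 0).any() or not np.isfinite(vals).all():
        raise ValueError("strengths must be finite and non-negative")
    total = vals.sum()
    if total == 0.0:
        log.warning("no species viable: all strengths are zero")
        return CommunityState(dict.fromkeys(names, 0.0), time=time, viable=False)
    return CommunityState(dict(zip(names, vals / total)), time=time)


# ---------------------------------------------------------------------------
# vectorized engine
# ---------------------------------------------------------------------------


class _YearEngine:
    """Precomputes the cover-independent pieces of one year's strengths.

    For each species and growing-season month the product of the pH, N and
    moisture responses gated by temperature is fixed; only the light
    response depends on the evolving covers (through shading).
    """

    def __init__(
        self,
        table: ParameterTable,
        drivers: DriverSeries,
        profile: SoilProfile,
        year: int,
        opts: SimulationOptions,
    ) -> None:
        self.names = list(table.names)
        species = list(table)
        months = [m for m in opts.season_months() if (year, m) in set(drivers.months)]
        if not months:
            raise ValueError(f"drivers contain no growing-season months for year {year}")
        n, m = len(species), len(months)
        self.opts = opts
        self.static = np.empty((n, m))
        self.floor_light = np.empty(m)
        self.light_opt = np.array([sp.axes["light"].opt for sp in species])
        light_var = np.array([sp.axes["light"].var for sp in species])
        self.light_var = light_var**2 if opts.var_is_sd else light_var
        self.heights = np.array([sp.shading_height for sp in species])
        # strict-majority mask: taller[i, j] == species j strictly taller than i
        self.taller = self.heights[None, :] > self.heights[:, None] + HEIGHT_TIE_TOL

        for mi, month in enumerate(months):
            t, fl = drivers.scalars(year, month)
            self.floor_light[mi] = fl
            for si, sp in enumerate(species):
                env = aggregate_root_zone(
                    profile, drivers, sp.rooting_depth, (year, month), mode=opts.root_mode
                )
                q = response_temperature(t, sp.temperature)
                for axis in ("pH", "N", "moisture"):
                    if q == 0.0:
                        break
                    q *= response_gaussian(env[axis], sp.axes[axis], var_is_sd=opts.var_is_sd)
                self.static[si, mi] = q

    def strengths(self, covers: np.ndarray) -> np.ndarray:
        """Per-species strength given the current cover vector."""
        s = self.opts.shading_efficiency
        c_taller = self.taller @ covers
        avail = self.floor_light[None, :] * (1.0 - s * c_taller[:, None])
        avail = np.clip(
            avail, self.floor_light[None, :] * (1.0 - s), self.floor_light[None, :]
        )
        resp_light = np.exp(
            -((avail - self.light_opt[:, None]) ** 2) / self.light_var[:, None]
        )
        suit = (self.static * resp_light).mean(axis=1)
        return suit**self.opts.dominance_exponent

    def solve(self, covers0: np.ndarray) -> tuple[np.ndarray, bool, bool]:
        """Damped fixed point of covers -> normalized strengths.

        Returns (covers, viable, converged).
        """
        c = covers0.copy()
        damp = self.opts.fp_damping
        for _ in range(self.opts.fp_max_iter):
            s = self.strengths(c)
            total = s.sum()
            if total == 0.0:
                return np.zeros_like(c), False, True
            target = s / total
            c_new = c + damp * (target - c)
            c_new /= c_new.sum()
            if np.abs(c_new - c).max() < self.opts.fp_tol:
                return c_new, True, True
            c = c_new
        log.warning("cover fixed point did not converge within %d iterations",
                    self.opts.fp_max_iter)
        return c, True, False


# ---------------------------------------------------------------------------
# stepping and simulation
# ---------------------------------------------------------------------------


def step_community(
    state: CommunityState,
    table: ParameterTable,
    profile: SoilProfile,
    drivers: DriverSeries,
    month: tuple[int, int],
    inertia: float = 1.0,
    opts: SimulationOptions | None = None,
) -> CommunityState:
    """One monthly relaxation step toward the current-month target covers.

    The target is :func:`assign_relative_cover` of this month's strengths
    with light computed against the *current* state; the new state is the
    renormalized convex combination ``(1 - lambda) * old + lambda *
    target``. ``inertia`` = 1 is instantaneous replacement.
    """
    opts = opts or SimulationOptions()
    if not 0.0 < inertia <= 1.0:
        raise ValueError("inertia (lambda) must lie in (0, 1]")
    year, cal_month = month
    season_opts = _with_month(opts, cal_month)
    engine = _YearEngine(table, drivers, profile, year, season_opts)
    old = state.as_array(engine.names)
    strengths = engine.strengths(old)
    target_state = assign_relative_cover(dict(zip(engine.names, strengths)), time=month)
    if not target_state.viable:
        return CommunityState(dict(state.covers), time=month, viable=state.viable)
    target = target_state.as_array(engine.names)
    mixed = (1.0 - inertia) * old + inertia * target
    mixed /= mixed.sum()
    return CommunityState(dict(zip(engine.names, mixed)), time=month)


def _with_month(opts: SimulationOptions, month: int) -> SimulationOptions:
    from dataclasses import replace

    return replace(opts, growing_season=(month, month))


def simulate_community(
    table: ParameterTable,
    drivers: DriverSeries,
    profile: SoilProfile,
    years: Sequence[int] | None = None,
    opts: SimulationOptions | None = None,
    initial: CommunityState | None = None,
) -> list[CommunityState]:
    """Annual cover trajectory.

    For each year, growing-season monthly suitabilities are averaged into
    strengths, the cover/shading interdependence is resolved by a damped
    fixed-point iteration, and the year's state blends the previous state
    with the equilibrium at rate ``inertia``. Non-convergence yields the
    last iterate flagged ``converged=False``.
    """
    opts = opts or SimulationOptions()
    years = list(years) if years is not None else drivers.years
    if not years:
        raise ValueError("no simulation years requested")
    names = list(table.names)
    state = initial or CommunityState.uniform(names)
    out: list[CommunityState] = []
    for year in years:
        engine = _YearEngine(table, drivers, profile, year, opts)
        c0 = state.as_array(names)
        if not state.viable or c0.sum() == 0:
            c0 = np.full(len(names), 1.0 / len(names))
        target, viable, converged = engine.solve(c0)
        if not viable:
            state = CommunityState(
                dict.fromkeys(names, 0.0), time=year, viable=False, converged=converged
            )
        else:
            lam = opts.inertia
            prev = state.as_array(names) if state.viable else target
            mixed = (1.0 - lam) * prev + lam * target
            mixed /= mixed.sum()
            state = CommunityState(
                dict(zip(names, mixed)), time=year, converged=converged
            )
        out.append(state)
    return out


# ---------------------------------------------------------------------------
# cover I/O
# ---------------------------------------------------------------------------


def covers_to_frame(states: Sequence[CommunityState]) -> pd.DataFrame:
    rows = [
        {"year": st.time, "species": name, "cover_frac": cov}
        for st in states
        for name, cov in st.covers.items()
    ]
    return pd.DataFrame(rows).sort_values(["year", "species"]).reset_index(drop=True)


def write_covers(states: Sequence[CommunityState], path: str | Path) -> None:
    covers_to_frame(states).to_csv(path, index=False)


def read_covers(path: str | Path) -> list[CommunityState]:
    df = pd.read_csv(path, comment="#")
    need = {"year", "species", "cover_frac"}
    if not need.issubset(df.columns):
        raise ValueError(f"cover CSV needs columns {sorted(need)}")
    states = []
    for year, sub in df.groupby("year", sort=True):
        covers = dict(zip(sub["species"], sub["cover_frac"].astype(float)))
        total = sum(covers.values())
        viable = total > 0
        if viable and abs(total - 1.0) > 1e-6:
            covers = {k: v / total for k, v in covers.items()}
        states.append(CommunityState(covers, time=int(year), viable=viable))
    return states
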