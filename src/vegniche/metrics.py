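"""Model-evaluation metrics for paired predicted/observed data.

Four metrics cover the standard questions asked of an ecosystem model:

* NAE — normalized average error, ``(mean(P) - mean(O)) / mean(O)``: bias
  of the predicted mean; sign gives direction.
* NRMSE — normalized root mean square error,
  ``sqrt(mean((P - O)**2)) / mean(O)``: total pairwise error, amplifying
  large individual misses.
* 1:1 slope — zero-intercept least-squares slope of predicted (y) on
  observed (x), with its standard error and the Pearson correlation; a
  slope below 1 indicates underestimation.
* CzI — Czekanowski similarity (quantitative Sörensen / reverse
  Bray-Curtis), ``1 - sum|P - O| / sum(P + O)`` over aligned cover
  vectors; 1 is a perfect community match.

Monthly model output is paired with dated observations by yearly medians
before the first three metrics are applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairedSeries",
    "CoverPair",
    "EvaluationReport",
    "UndefinedMetricError",
    "annual_median_pairs",
    "nae",
    "nrmse",
    "one_to_one",
    "czekanowski",
    "evaluate",
]

log = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """The metric is undefined for this input (e.g. observed mean of 0)."""


@dataclass(frozen=True)
class PairedSeries:
    """Aligned predicted/observed value pairs.

    ``predicted[i]`` corresponds to ``observed[i]``; ``times`` optionally
    labels each pair (e.g. with the calendar year).
    """

    predicted: tuple[float, ...]
    observed: tuple[float, ...]
    times: tuple | None = None

    def __post_init__(self) -> None:
        if len(self.predicted) != len(self.observed):
            raise ValueError("predicted and observed must have equal length")
        if len(self.predicted) < 1:
            raise ValueError("a paired series needs at least one pair")
        p = np.asarray(self.predicted, dtype=float)
        o = np.asarray(self.observed, dtype=float)
        if not (np.isfinite(p).all() and np.isfinite(o).all()):
            raise ValueError("paired series must contain no missing values")
        if self.times is not None and len(self.times) != len(self.predicted):
            raise ValueError("times must align with the pairs")

    def __len__(self) -> int:
        return len(self.predicted)

    @property
    def P(self) -> np.ndarray:
        return np.asarray(self.predicted, dtype=float)

    @property
    def O(self) -> np.ndarray:
        return np.asarray(self.observed, dtype=float)

    @classmethod
    def from_arrays(cls, predicted, observed, times=None) -> "PairedSeries":
        return cls(
            tuple(float(x) for x in predicted),
            tuple(float(x) for x in observed),
            tuple(times) if times is not None else None,
        )


@dataclass(frozen=True)
class CoverPair:
    """Aligned per-species modeled (P) and observed (O) cover vectors.

    The species sets are unioned: a species present in only one vector is
    kept with 0 in the other, which the CzI handles naturally.
    """

    modeled: Mapping[str, float]
    observed: Mapping[str, float]

    def __post_init__(self) -> None:
        for side, vec in (("modeled", self.modeled), ("observed", self.observed)):
            vals = np.array(list(vec.values()), dtype=float)
            if (vals < 0).any() or not np.isfinite(vals).all():
                raise ValueError(f"{side} covers must be finite and non-negative")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.modeled) | set(self.observed)))

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        sp = self.species
        p = np.array([self.modeled.get(s, 0.0) for s in sp])
        o = np.array([self.observed.get(s, 0.0) for s in sp])
        return p, o


@dataclass(frozen=True)
class EvaluationReport:
    """Bundle of metrics computed from one paired dataset."""

    nae: float | None = None
    nrmse: float | None = None
    slope: float | None = None
    slope_se: float | None = None
    correlation: float | None = None
    czi: float | None = None
    n: int = 0
    meta: Mapping[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if k != "meta" and v is not None}
        out.update({f"meta_{k}": v for k, v in self.meta.items()})
        return out


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------


def annual_median_pairs(
    modeled: pd.DataFrame,
    observations: pd.DataFrame,
    *,
    value_col: str = "value",
    agg: str = "median",
) -> PairedSeries:
    """Pair yearly medians of monthly model output with yearly medians of
    dated observations.

    Both frames need ``year`` and ``value_col`` columns. Observation years
    outside the modeled span are excluded (logged); ``agg='mean'`` switches
    to yearly means.
    """
    if agg not in ("median", "mean"):
        raise ValueError("agg must be 'median' or 'mean'")
    m_years = set(modeled["year"].astype(int))
    o_years = set(observations["year"].astype(int))
    dropped = sorted(o_years - m_years)
    if dropped:
        log.info("excluding observation years outside the modeled span: %s", dropped)
    common = sorted(o_years & m_years)
    if not common:
        raise UndefinedMetricError("no overlapping years between model and observations")
    reduce = np.median if agg == "median" else np.mean
    pred, obs = [], []
    for year in common:
        pred.append(float(reduce(modeled.loc[modeled["year"] == year, value_col])))
        obs.append(float(reduce(observations.loc[observations["year"] == year, value_col])))
    return PairedSeries.from_arrays(pred, obs, times=common)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def nae(series: PairedSeries) -> float:
    """Normalized average error ``(mean(P) - mean(O)) / mean(O)``."""
    o_bar = series.O.mean()
    if o_bar == 0.0:
        raise UndefinedMetricError("NAE undefined: observed mean is zero")
    return float((series.P.mean() - o_bar) / o_bar)


def nrmse(series: PairedSeries) -> float:
    """Normalized RMSE ``sqrt(mean((P - O)**2)) / mean(O)``."""
    o_bar = series.O.mean()
    if o_bar == 0.0:
        raise UndefinedMetricError("NRMSE undefined: observed mean is zero")
    return float(math.sqrt(np.mean((series.P - series.O) ** 2)) / o_bar)


def one_to_one(series: PairedSeries) -> tuple[float, float, float]:
    """Zero-intercept 1:1 regression of predicted on observed.

    Returns ``(slope, slope_SE, pearson_r)`` with
    ``slope = sum(P*O) / sum(O**2)`` and the through-origin standard error
    ``sqrt(sum(residual**2) / (n - 1) / sum(O**2))``. A slope below 1
    indicates model underestimation.
    """
    if len(series) < 2:
        raise UndefinedMetricError("1:1 slope needs at least two pairs")
    P, O = series.P, series.O
    sxx = float(np.dot(O, O))
    if sxx == 0.0:
        raise UndefinedMetricError("1:1 slope undefined: observed values are all zero")
    slope = float(np.dot(P, O) / sxx)
    resid = P - slope * O
    se = float(math.sqrt(np.dot(resid, resid) / (len(series) - 1) / sxx))
    if np.std(P) == 0.0 or np.std(O) == 0.0:
        corr = math.nan
    else:
        corr = float(np.corrcoef(P, O)[0, 1])
    return slope, se, corr


def czekanowski(pair: CoverPair) -> float:
    """Czekanowski similarity ``1 - sum|P - O| / sum(P + O)``.

    Symmetric in the two communities; 1 iff identical, 0 for disjoint
    supports.
    """
    p, o = pair.arrays()
    denom = float((p + o).sum())
    if denom == 0.0:
        raise UndefinedMetricError("CzI undefined: both cover vectors are all zero")
    return float(1.0 - np.abs(p - o).sum() / denom)


def evaluate(
    series: PairedSeries | None = None,
    cover_pair: CoverPair | None = None,
    meta: Mapping[str, str] | None = None,
) -> EvaluationReport:
    """Compute every applicable metric for the supplied data."""
    kw: dict = {"meta": dict(meta or {})}
    if series is not None:
        kw["n"] = len(series)
        kw["nae"] = nae(series)
        kw["nrmse"] = nrmse(series)
        if len(series) >= 2:
            slope, se, corr = one_to_one(series)
            kw.update(slope=slope, slope_se=se, correlation=corr)
    if cover_pair is not None:
        kw["czi"] = czekanowski(cover_pair)
        kw.setdefault("n", len(cover_pair.species))
    if series is None and cover_pair is None:
        raise ValueError("nothing to evaluate")
    return EvaluationReport(**kw)
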