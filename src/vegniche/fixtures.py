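"""Packaged reference data.

Ships the published three-site cover table (observed relevé vs blind and
calibrated model runs at HBEF, EB and WB — northeastern US sugar
maple/beech/yellow birch sites) as plain CSVs, plus a small synthetic
example species table for demos and smoke tests.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import pandas as pd

from .metrics import CoverPair
from .niche import (
    ParameterTable,
    TemperatureWindow,
    default_class_key,
    species_from_ranks,
)

__all__ = ["SITES", "load_site_covers", "load_cover_pairs", "example_parameter_table"]

SITES = ("HBEF", "EB", "WB")

_COLUMNS = ("observed", "blind", "calibrated")


def _data_path(name: str):
    return resources.files("vegniche.data").joinpath(name)


def load_site_covers(site: str) -> dict[str, dict[str, float]]:
    """Cover vectors for one site.

    Returns ``{"observed": {...}, "blind": {...}, "calibrated": {...}}``
    keyed by species; species absent from the site's published block are
    simply missing (treat as zero cover). The one species printed twice in
    the source table is collapsed to a single entry.
    """
    site = site.upper()
    if site not in SITES:
        raise KeyError(f"unknown site {site!r}; valid sites: {list(SITES)}")
    with resources.as_file(_data_path(f"site_covers_{site.lower()}.csv")) as path:
        df = pd.read_csv(path, comment="#")
    df = df.drop_duplicates(subset="species", keep="first")
    return {
        col: dict(zip(df["species"], df[col].astype(float))) for col in _COLUMNS
    }


def load_cover_pairs(site: str) -> dict[str, CoverPair]:
    """Observed-vs-blind and observed-vs-calibrated pairs for one site."""
    cov = load_site_covers(site)
    return {
        "blind": CoverPair(modeled=cov["blind"], observed=cov["observed"]),
        "calibrated": CoverPair(modeled=cov["calibrated"], observed=cov["observed"]),
    }


def all_species() -> set[str]:
    """Union of species named across the three packaged sites."""
    out: set[str] = set()
    for site in SITES:
        out |= set(load_site_covers(site)["observed"])
    return out


#: Synthetic example community: class ranks chosen around an acid,
#: shaded-understory driver regime. Purely illustrative.
_EXAMPLE_RANKS: Mapping[str, Mapping[str, int]] = {
    "Fern tall":        {"pH": 3, "N": 2, "moisture": 5, "light": 2, "shading_height": 5, "rooting_depth": 3},
    "Fern low":         {"pH": 3, "N": 2, "moisture": 5, "light": 1, "shading_height": 3, "rooting_depth": 2},
    "Shrub tall":       {"pH": 4, "N": 2, "moisture": 4, "light": 3, "shading_height": 7, "rooting_depth": 4},
    "Herb shade":       {"pH": 3, "N": 1, "moisture": 5, "light": 1, "shading_height": 2, "rooting_depth": 1},
    "Herb light":       {"pH": 4, "N": 3, "moisture": 4, "light": 4, "shading_height": 2, "rooting_depth": 2},
    "Seedling broad":   {"pH": 3, "N": 2, "moisture": 4, "light": 2, "shading_height": 6, "rooting_depth": 3},
}


def example_parameter_table() -> ParameterTable:
    """A six-species synthetic example table (built from the default class
    key; names are descriptive growth forms, not real taxa)."""
    key = default_class_key()
    window = TemperatureWindow(-5.0, 30.0)
    species = tuple(
        species_from_ranks(name, ranks, key, window)
        for name, ranks in _EXAMPLE_RANKS.items()
    )
    return ParameterTable(species, provenance="synthetic example")
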