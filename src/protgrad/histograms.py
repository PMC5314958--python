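"""Gradient histograms: per (region | globe) x variable summaries of protection.

A gradient histogram slices the grid cells into ordered classes of one
independent variable and carries three measures per class *j*:

* ``AREA``       — total terrestrial area in the class (km²), descriptive;
* ``AREA_PROT``  — absolute protected area in the class (km²), the quota-
  representativeness measure;
* ``FRAC_PROT``  — the fraction of the class's terrestrial area that is
  protected, ``AREA_PROT / AREA``, the fraction-representativeness measure.

Class construction: the class width is set from the global (all-region)
distribution of the variable; interior classes of that fixed width span the
2.5th–97.5th percentile range, and cells beyond either percentile are pooled
into a single tail class on each side, so long distribution tails do not
produce a string of near-empty classes. Regional histograms reuse the global
layout so classes are comparable across regions. Any histogram entering a
statistical analysis must expose at least eight nonempty classes; if not, the
class width is halved until it does.

Intervals are half-open ``[lower, upper)`` with the final class closed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateDataError
from .variables import CANONICAL_VARIABLES, group_of

logger = logging.getLogger(__name__)

GLOBAL = "GLOBAL"

#: Default percentile truncation of the distribution tails.
DEFAULT_TRUNCATION = (0.025, 0.975)
#: Default number of interior classes between the truncation percentiles.
DEFAULT_INTERIOR_CLASSES = 20
#: Minimum nonempty classes required before modeling.
MIN_CLASSES = 8
#: Width-halving floor for the class-splitting repair rule, relative to start.
WIDTH_FLOOR_FACTOR = 2.0 ** -10


@dataclass(frozen=True)
class VariableSpec:
    """One gradient variable: its motivation group and class-width settings."""

    name: str
    group: str
    class_width: float | None = None   # None -> derived from the global data
    log_display: bool = False          # display-only hint, never used in stats

    def __post_init__(self):
        if self.class_width is not None and self.class_width <= 0:
            raise ConfigError(f"class_width must be > 0 for {self.name!r}")
        if self.name in CANONICAL_VARIABLES and group_of(self.name) != self.group:
            raise ConfigError(
                f"variable {self.name!r} belongs to group {group_of(self.name)!r}, "
                f"not {self.group!r}"
            )


def canonical_specs() -> list[VariableSpec]:
    """VariableSpec list for the 15 canonical variables."""
    return [VariableSpec(name=v, group=g) for v, g in CANONICAL_VARIABLES.items()]


@dataclass(frozen=True)
class HistogramClass:
    index: int
    lower: float
    upper: float
    area: float         # km² terrestrial
    area_prot: float    # km² protected
    n_cells: int

    @property
    def frac_prot(self) -> float:
        return self.area_prot / self.area if self.area > 0 else math.nan

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


@dataclass(frozen=True)
class Histogram:
    variable: str
    region: str
    classes: tuple[HistogramClass, ...]
    truncation: tuple[float, float]
    class_width: float

    @property
    def nonempty(self) -> tuple[HistogramClass, ...]:
        return tuple(c for c in self.classes if c.area > 0)

    @property
    def total_area(self) -> float:
        return sum(c.area for c in self.classes)

    @property
    def total_area_prot(self) -> float:
        return sum(c.area_prot for c in self.classes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variable,
                "region": self.region,
                "j": [c.index for c in self.classes],
                "lower": [c.lower for c in self.classes],
                "upper": [c.upper for c in self.classes],
                "area_km2": [c.area for c in self.classes],
                "area_prot_km2": [c.area_prot for c in self.classes],
                "frac_prot": [c.frac_prot for c in self.classes],
                "n_cells": [c.n_cells for c in self.classes],
            }
        )


# ---------------------------------------------------------------------------
# class layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassLayout:
    """Ordered class boundaries for one variable, shared by all regions.

    ``bounds`` has one more entry than there are classes; class ``k`` spans
    ``[bounds[k], bounds[k+1])`` (final class closed). When truncation is
    active the first/last class may be a pooled tail wider than ``width``.
    """

    bounds: np.ndarray
    width: float
    lower_tail: bool
    upper_tail: bool

    @property
    def n_classes(self) -> int:
        return len(self.bounds) - 1

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Class index per value; values on an internal bound open the upper class."""
        v = np.asarray(values, dtype=float)
        return np.searchsorted(self.bounds[1:-1], v, side="right")


def class_layout(
    global_values: np.ndarray,
    width: float | None = None,
    truncation: tuple[float, float] = DEFAULT_TRUNCATION,
    n_interior: int = DEFAULT_INTERIOR_CLASSES,
) -> ClassLayout:
    """Build the shared class layout from the global distribution of a variable."""
    v = np.asarray(global_values, dtype=float)
    if v.size == 0:
        raise DegenerateDataError("no values to build classes from")
    if not np.isfinite(v).all():
        raise DegenerateDataError("non-finite values in gradient variable")
    vmin, vmax = float(v.min()), float(v.max())
    if vmin == vmax:
        raise DegenerateDataError("constant variable: cannot set a class width")
    p_lo, p_hi = truncation
    if not (0.0 <= p_lo < p_hi <= 1.0):
        raise ConfigError(f"invalid truncation percentiles {truncation!r}")
    lo = vmin if p_lo <= 0.0 else float(np.quantile(v, p_lo))
    hi = vmax if p_hi >= 1.0 else float(np.quantile(v, p_hi))
    if hi <= lo:
        # heavy ties can collapse the percentile range; fall back to full range
        lo, hi = vmin, vmax
    if width is None:
        width = (hi - lo) / n_interior
    if width <= 0:
        raise DegenerateDataError("class width must be > 0")

    if hi >= vmax:  # no upper pooling: extend fixed-width classes past the maximum
        m = int(math.floor((vmax - lo) / width)) + 1
    else:
        m = max(1, int(math.ceil((hi - lo) / width - 1e-9)))
    edges = lo + width * np.arange(m + 1)

    bounds = list(edges)
    lower_tail = vmin < lo
    upper_tail = vmax > edges[-1]
    if lower_tail:
        bounds = [vmin] + bounds
    if upper_tail:
        bounds = bounds + [vmax]
    return ClassLayout(
        bounds=np.asarray(bounds, dtype=float),
        width=float(width),
        lower_tail=lower_tail,
        upper_tail=upper_tail,
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

TERRESTRIAL_MIN_FRACTION = 0.05


def filter_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Drop cells whose terrestrial fraction is below 5%."""
    keep = cells["terrestrial_fraction"] >= TERRESTRIAL_MIN_FRACTION
    removed = int((~keep).sum())
    logger.info("filter_cells: removed %d of %d cells (<5%% terrestrial)", removed, len(cells))
    out = cells.loc[keep].reset_index(drop=True)
    if out.empty:
        raise DegenerateDataError("no cells left after the 5% terrestrial filter")
    return out


def default_class_width(
    cells: pd.DataFrame,
    variable: str,
    truncation: tuple[float, float] = DEFAULT_TRUNCATION,
    n_interior: int = DEFAULT_INTERIOR_CLASSES,
) -> float:
    """Class width from the global distribution: (P97.5 - P2.5) / n_interior.

    The same width is reused for every region so class boundaries stay
    comparable; a regional call must pass the global cell table here.
    """
    v = np.asarray(cells[variable], dtype=float)
    if np.unique(v).size < 2:
        raise DegenerateDataError(f"variable {variable!r} is constant")
    p_lo, p_hi = truncation
    lo = float(np.quantile(v, p_lo)) if p_lo > 0 else float(v.min())
    hi = float(np.quantile(v, p_hi)) if p_hi < 1 else float(v.max())
    if hi <= lo:
        lo, hi = float(v.min()), float(v.max())
    return (hi - lo) / n_interior


def _terrestrial_and_protected_area(cells: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    terr = np.asarray(cells["cell_area_km2"] * cells["terrestrial_fraction"], dtype=float)
    prot = terr * np.asarray(cells["protected_fraction"], dtype=float)
    return terr, prot


def build_histogram(
    cells: pd.DataFrame,
    variable_spec: VariableSpec,
    region: str = GLOBAL,
    width: float | None = None,
    truncation: tuple[float, float] = DEFAULT_TRUNCATION,
    n_interior: int = DEFAULT_INTERIOR_CLASSES,
) -> Histogram:
    """Aggregate AREA / AREA_PROT / FRAC_PROT per class of one variable.

    ``cells`` is the (already filtered) global table; the class layout is
    always derived from it, and ``region`` selects which cells are counted
    (``GLOBAL`` counts all). Empty classes are retained with AREA = 0.
    """
    name = variable_spec.name
    if name not in cells.columns:
        raise ConfigError(f"variable {name!r} not present in cell table")
    layout = class_layout(
        np.asarray(cells[name], dtype=float),
        width=width if width is not None else variable_spec.class_width,
        truncation=truncation,
        n_interior=n_interior,
    )
    if region == GLOBAL:
        sub = cells
    else:
        sub = cells[cells["region"] == region]
        if sub.empty:
            raise ConfigError(f"unknown or empty region {region!r}")

    idx = layout.assign(np.asarray(sub[name], dtype=float))
    terr, prot = _terrestrial_and_protected_area(sub)
    k = layout.n_classes
    area = np.bincount(idx, weights=terr, minlength=k)
    area_prot = np.bincount(idx, weights=prot, minlength=k)
    n_cells = np.bincount(idx, minlength=k)

    classes = tuple(
        HistogramClass(
            index=j,
            lower=float(layout.bounds[j]),
            upper=float(layout.bounds[j + 1]),
            area=float(area[j]),
            area_prot=float(area_prot[j]),
            n_cells=int(n_cells[j]),
        )
        for j in range(k)
    )
    return Histogram(
        variable=name,
        region=region,
        classes=classes,
        truncation=truncation,
        class_width=layout.width,
    )


def ensure_min_classes(
    histogram: Histogram,
    cells: pd.DataFrame,
    variable_spec: VariableSpec,
    min_classes: int = MIN_CLASSES,
    n_interior: int = DEFAULT_INTERIOR_CLASSES,
) -> Histogram:
    """Halve the class width until at least ``min_classes`` classes are nonempty."""
    name = variable_spec.name
    region = histogram.region
    sub = cells if region == GLOBAL else cells[cells["region"] == region]
    distinct = np.unique(np.asarray(sub[name], dtype=float)).size
    if distinct < min_classes:
        raise DegenerateDataError(
            f"variable {name!r} in region {region!r} has only {distinct} distinct "
            f"values; cannot reach {min_classes} nonempty classes"
        )
    h = histogram
    width = histogram.class_width
    floor = histogram.class_width * WIDTH_FLOOR_FACTOR
    while len(h.nonempty) < min_classes:
        width *= 0.5
        if width < floor:
            raise DegenerateDataError(
                f"could not reach {min_classes} nonempty classes for {name!r} in "
                f"region {region!r} before the width floor"
            )
        h = build_histogram(
            cells, variable_spec, region=region, width=width,
            truncation=histogram.truncation, n_interior=n_interior,
        )
    if h is not histogram:
        logger.info(
            "ensure_min_classes: %s/%s width halved %s -> %s (%d nonempty classes)",
            name, region, histogram.class_width, width, len(h.nonempty),
        )
    return h


def histograms_to_frame(histograms: list[Histogram]) -> pd.DataFrame:
    """Concatenate histograms into the standard long-format table."""
    if not histograms:
        return pd.DataFrame(
            columns=["variable", "region", "j", "lower", "upper",
                     "area_km2", "area_prot_km2", "frac_prot", "n_cells"]
        )
    return pd.concat([h.to_frame() for h in histograms], ignore_index=True)
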