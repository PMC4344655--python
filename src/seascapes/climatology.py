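"""Per-pixel climatological statistics from monthly (or daily) stacks.

Long-term means and the per-calendar-month climatology with its pixel-level
extremes — the source of the Avg/Max/Min SST variables. Cloud-gap handling:
a pixel must be valid in at least ``min_valid_frac`` (default 50%) of the
time steps entering a mean, otherwise it is marked invalid; gaps are
otherwise simply ignored. The products the means are modeled on do not
document a gap rule, so the threshold is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import MonthlyStack, RasterGrid

__all__ = ["Climatology12", "longterm_mean", "monthly_climatology", "climatology_extremes"]

DEFAULT_MIN_VALID_FRAC = 0.5


@dataclass
class Climatology12:
    """Twelve co-registered monthly grids (January..December)."""

    months: list[RasterGrid]

    def __post_init__(self) -> None:
        if len(self.months) != 12:
            raise ValueError("a climatology has exactly 12 monthly grids")
        geo = self.months[0].geo
        if any(g.geo != geo for g in self.months):
            raise ValueError("climatology grids are not co-registered")

    @property
    def geo(self):
        return self.months[0].geo


def _masked_mean(data: np.ndarray, min_valid_frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean over axis 0 ignoring NaN; invalid below the coverage threshold."""
    valid = np.isfinite(data)
    n_valid = valid.sum(axis=0)
    enough = n_valid >= np.ceil(min_valid_frac * data.shape[0])
    enough &= n_valid > 0
    with np.errstate(invalid="ignore"):
        mean = np.where(enough, np.nansum(np.where(valid, data, 0.0), axis=0)
                        / np.maximum(n_valid, 1), np.nan)
    return mean, enough


def longterm_mean(stack: MonthlyStack,
                  min_valid_frac: float = DEFAULT_MIN_VALID_FRAC) -> RasterGrid:
    """Per-pixel arithmetic mean over all time steps with valid data."""
    if len(stack) == 0:
        raise ValueError("empty stack")
    mean, mask = _masked_mean(stack.to_array(), min_valid_frac)
    g0 = stack.grids[0]
    return RasterGrid(geo=stack.geo, values=mean, mask=mask,
                      units=g0.units, name=f"{g0.name}_mean")


def monthly_climatology(stack: MonthlyStack,
                        min_valid_frac: float = DEFAULT_MIN_VALID_FRAC) -> Climatology12:
    """Per-calendar-month mean over all years (missing-ignored)."""
    data = stack.to_array()
    months = np.array([m for _, m in stack.times])
    present = set(months.tolist())
    absent = sorted(set(range(1, 13)) - present)
    if absent:
        raise ValueError(f"calendar months {absent} absent from the stack")
    g0 = stack.grids[0]
    out = []
    for m in range(1, 13):
        mean, mask = _masked_mean(data[months == m], min_valid_frac)
        out.append(RasterGrid(geo=stack.geo, values=mean, mask=mask,
                              units=g0.units, name=f"{g0.name}_clim{m:02d}"))
    return Climatology12(out)


def climatology_extremes(clim: Climatology12) -> tuple[RasterGrid, RasterGrid]:
    """Pixel-level (max, min) over the 12 monthly climatology grids.

    A pixel is invalid in the output if it is invalid in any month: an
    extreme taken over an incomplete seasonal cycle would be biased.
    """
    data = np.stack([g.masked_values() for g in clim.months])
    mask = np.all(np.stack([g.mask for g in clim.months]), axis=0)
    with np.errstate(invalid="ignore"):
        vmax = np.where(mask, np.nanmax(np.where(np.isfinite(data), data, -np.inf), axis=0), np.nan)
        vmin = np.where(mask, np.nanmin(np.where(np.isfinite(data), data, np.inf), axis=0), np.nan)
    g0 = clim.months[0]
    base = g0.name.rsplit("_clim", 1)[0]
    return (
        RasterGrid(geo=clim.geo, values=vmax, mask=mask, units=g0.units, name=f"{base}_max"),
        RasterGrid(geo=clim.geo, values=vmin, mask=mask, units=g0.units, name=f"{base}_min"),
    )
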