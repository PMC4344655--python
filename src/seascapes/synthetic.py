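"""Seeded synthetic ocean fields with planted biophysical regimes.

The generator emulates the statistical structure of the satellite/model
inputs used for seascape bioregionalization: a fine lat/lon grid over the
Sunda Banda study box (113-135 degE, 0-13 degS) with blob-like land, K
spatially contiguous regimes with distinct six-variable mean signatures
(average / climatological-maximum / climatological-minimum SST, chlorophyll
a, current speed, salinity), monthly SST-like stacks with a seasonal cycle,
a positively skewed chlorophyll field, and coarser current/salinity grids
that exercise the resampling step.

All draws go through a single integer seed; generation is bit-reproducible
for a fixed seed and package version.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import GridGeo, MonthlyStack, RasterGrid

__all__ = [
    "VARIABLES",
    "UNITS",
    "SBS_BBOX",
    "SynthConfig",
    "PlantedTruth",
    "sbs_geo",
    "synth_land_mask",
    "plant_regions",
    "make_class_means",
    "synth_variable_fields",
    "synth_monthly_stack",
    "coarse_geo",
]

#: Fixed variable order used across the whole package.
VARIABLES = ("avg_sst", "max_sst", "min_sst", "chla", "currents", "salinity")
UNITS = ("degC", "degC", "degC", "mg m-3", "m s-1", "PSU")

#: Study box: 113-135 degE, 13 degS-0.
SBS_BBOX = (113.0, 135.0, -13.0, 0.0)

# Plausible spans of regime means per variable, informed by published
# regional climatologies of the study box. Chlorophyll is handled on a log
# scale (strongly right-skewed in nature).
_MEAN_RANGES = {
    "avg_sst": (26.5, 29.2),
    "max_sst": (28.7, 30.6),
    "min_sst": (24.7, 28.5),
    "chla": (0.15, 1.6),      # geometric span; interpolated in log space
    "currents": (0.05, 0.35),
    "salinity": (32.5, 34.6),
}


def sbs_geo(n_rows: int = 60, n_cols: int = 60) -> GridGeo:
    """Grid over the study box at the requested shape (default 60x60)."""
    lon_min, lon_max, lat_min, lat_max = SBS_BBOX
    return GridGeo(lon_min, lon_max, lat_min, lat_max, n_rows, n_cols)


def coarse_geo(geo: GridGeo, factor: int = 3) -> GridGeo:
    """Same extent at 1/factor the resolution (currents/salinity analogue)."""
    return GridGeo(geo.lon_min, geo.lon_max, geo.lat_min, geo.lat_max,
                   max(1, geo.n_rows // factor), max(1, geo.n_cols // factor))


@dataclass(frozen=True)
class SynthConfig:
    """Generation knobs; defaults are the package's standard study conditions.

    ``noise_level`` is the per-variable noise SD expressed as a fraction of
    that variable's mean-signature span (so noise is commensurate across
    variables); ``min_separation`` is the minimum pairwise Euclidean distance
    between regime signatures in span-standardized coordinates.
    """

    K: int = 9
    noise_level: float = 0.04
    min_separation: float = 0.5
    smooth_len: float = 2.0
    seasonal_amplitude: float = 1.5  # degC
    years: int = 11
    land_fraction: float = 0.1
    coarse_factor: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K >= 2 required")
        if self.years < 1:
            raise ValueError("years >= 1 required")
        if self.noise_level < 0:
            raise ValueError("noise level must be non-negative")
        if not 0 <= self.land_fraction < 1:
            raise ValueError("land_fraction must lie in [0, 1)")


@dataclass
class PlantedTruth:
    """Ground-truth regionalization a recovery experiment is scored against."""

    geo: GridGeo
    labels: np.ndarray            # int matrix, 0 = land, 1..K = regime
    class_means: np.ndarray       # K x 6, physical units, VARIABLES order
    class_means_std: np.ndarray   # K x 6, span-standardized coordinates
    sea_mask: np.ndarray
    seed: int

    @property
    def K(self) -> int:
        return self.class_means.shape[0]


def _smooth_unit_noise(shape: tuple[int, int], smooth_len: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Spatially correlated Gaussian noise with unit marginal SD.

    White noise is convolved with a Gaussian kernel of scale ``smooth_len``
    cells and rescaled by the kernel's exact l2 norm (measured on an
    impulse), so the marginal SD is 1 regardless of smoothing.
    """
    z = rng.standard_normal(shape)
    if smooth_len <= 0:
        return z
    sm = ndimage.gaussian_filter(z, smooth_len, mode="wrap")
    imp = np.zeros((int(8 * smooth_len) * 2 + 9,) * 2)
    imp[imp.shape[0] // 2, imp.shape[1] // 2] = 1.0
    norm = float(np.sqrt(np.sum(ndimage.gaussian_filter(imp, smooth_len) ** 2)))
    return sm / norm


def synth_land_mask(geo: GridGeo, land_fraction: float, seed: int,
                    smooth_len: float = 3.0) -> np.ndarray:
    """Blob-like land mask (True = land) covering ~``land_fraction`` of cells.

    A smoothed noise field is thresholded at its (1 - land_fraction)
    empirical quantile, so the achieved fraction matches the request up to
    the one-cell quantile granularity.
    """
    if not 0 <= land_fraction < 1:
        raise ValueError("land_fraction must lie in [0, 1)")
    if land_fraction == 0:
        return np.zeros(geo.shape, dtype=bool)
    rng = np.random.default_rng(seed)
    f = _smooth_unit_noise(geo.shape, smooth_len, rng)
    thr = np.quantile(f, 1.0 - land_fraction)
    return f > thr


def plant_regions(geo: GridGeo, K: int, seed: int,
                  sea_mask: np.ndarray | None = None) -> np.ndarray:
    """Partition sea cells into K contiguous regimes by nearest-seed rule.

    K seed cells are drawn uniformly without replacement among sea cells;
    every sea cell takes the label (1..K) of the Euclidean-nearest seed in
    cell coordinates (ties go to the lowest seed index). Land cells get 0.
    """
    if sea_mask is None:
        sea_mask = np.ones(geo.shape, dtype=bool)
    sea_rc = np.argwhere(sea_mask)
    if K > len(sea_rc):
        raise ValueError(f"K={K} exceeds the {len(sea_rc)} available sea cells")
    rng = np.random.default_rng(seed)
    seeds = sea_rc[rng.choice(len(sea_rc), size=K, replace=False)]
    d2 = ((sea_rc[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    lab = d2.argmin(axis=1) + 1  # argmin ties -> lowest index
    out = np.zeros(geo.shape, dtype=np.int32)
    out[sea_rc[:, 0], sea_rc[:, 1]] = lab
    return out


def make_class_means(K: int, seed: int,
                     min_separation: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Draw K distinct six-variable regime signatures.

    Signatures are sampled uniformly in span-standardized [0,1]^6 space with
    a rejection step enforcing a minimum pairwise Euclidean distance, then
    mapped to physical units (chlorophyll through log space so its means are
    log-uniformly spread). Returns (physical K x 6, standardized K x 6).
    """
    rng = np.random.default_rng(seed)
    for _ in range(10_000):
        u = rng.uniform(size=(K, 6))
        d = np.sqrt(((u[:, None, :] - u[None, :, :]) ** 2).sum(axis=2))
        if np.min(d[np.triu_indices(K, 1)]) >= min_separation:
            break
    else:
        raise RuntimeError("could not place regime signatures with the "
                           "requested separation; lower min_separation or K")
    phys = np.empty_like(u)
    for j, v in enumerate(VARIABLES):
        lo, hi = _MEAN_RANGES[v]
        if v == "chla":
            phys[:, j] = np.exp(np.log(lo) + u[:, j] * (np.log(hi) - np.log(lo)))
        else:
            phys[:, j] = lo + u[:, j] * (hi - lo)
    # keep climatological max above min for every regime (spans overlap only
    # marginally, but the draw does not couple the two columns)
    i_max, i_min = VARIABLES.index("max_sst"), VARIABLES.index("min_sst")
    bad = phys[:, i_max] <= phys[:, i_min] + 0.3
    phys[bad, i_max] = phys[bad, i_min] + 0.3
    return phys, u


def synth_variable_fields(truth: PlantedTruth, config: SynthConfig,
                          geo: GridGeo | None = None,
                          variables: tuple[str, ...] = VARIABLES,
                          seed_offset: int = 1) -> dict[str, RasterGrid]:
    """Per-variable fields: regime mean plus smoothed noise.

    Each pixel carries the physical-unit mean of its regime plus spatially
    correlated Gaussian noise of SD ``noise_level * span``. Chlorophyll is
    generated multiplicatively (lognormal with the regime mean as arithmetic
    mean), and the climatological-max SST field is built as min + positive
    excess so max >= min holds at every pixel by construction.

    If ``geo`` differs from the truth grid (coarser currents/salinity
    analogues), regime membership is looked up at the nearest fine cell.
    """
    if config.noise_level < 0:
        raise ValueError("negative noise level")
    out_geo = geo or truth.geo
    labels = _labels_on(truth, out_geo)
    sea = labels > 0
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, seed_offset]))
    sd = {v: config.noise_level * _span(v) for v in VARIABLES}
    noise = {v: _smooth_unit_noise(out_geo.shape, config.smooth_len, rng)
             for v in VARIABLES}

    fields: dict[str, np.ndarray] = {}
    lab0 = np.maximum(labels, 1) - 1  # safe regime index; land masked later
    for v in ("avg_sst", "currents", "salinity"):
        j = VARIABLES.index(v)
        fields[v] = truth.class_means[lab0, j] + sd[v] * noise[v]
    fields["currents"] = np.maximum(fields["currents"], 0.0)

    j_chla = VARIABLES.index("chla")
    s = sd["chla"]  # SD in log space (span of log-means)
    fields["chla"] = truth.class_means[lab0, j_chla] * np.exp(
        s * noise["chla"] - s * s / 2.0)

    j_max, j_min = VARIABLES.index("max_sst"), VARIABLES.index("min_sst")
    fmin = truth.class_means[lab0, j_min] + sd["min_sst"] * noise["min_sst"]
    excess = (truth.class_means[lab0, j_max] - truth.class_means[lab0, j_min]
              + sd["max_sst"] * noise["max_sst"])
    fields["min_sst"] = fmin
    fields["max_sst"] = fmin + np.maximum(excess, 0.0)

    grids = {}
    for v in variables:
        vals = fields[v].astype(float)
        vals[~sea] = np.nan
        grids[v] = RasterGrid(geo=out_geo, values=vals, mask=sea.copy(),
                              units=UNITS[VARIABLES.index(v)], name=v)
    return grids


def _span(v: str) -> float:
    lo, hi = _MEAN_RANGES[v]
    return float(np.log(hi) - np.log(lo)) if v == "chla" else float(hi - lo)


def _labels_on(truth: PlantedTruth, geo: GridGeo) -> np.ndarray:
    """Regime labels sampled at the cell centers of ``geo``."""
    if geo == truth.geo:
        return truth.labels
    src = truth.geo
    rows = np.clip(((src.lat_max - geo.lat_centers()) / src.cell_height - 0.5)
                   .round().astype(int), 0, src.n_rows - 1)
    cols = np.clip(((geo.lon_centers() - src.lon_min) / src.cell_width - 0.5)
                   .round().astype(int), 0, src.n_cols - 1)
    return truth.labels[np.ix_(rows, cols)]


def synth_monthly_stack(geo: GridGeo, annual_mean: RasterGrid,
                        amplitude: float | np.ndarray,
                        years: int, noise_sd: float, seed: int,
                        start_year: int = 2003) -> MonthlyStack:
    """Monthly stack: annual mean + sinusoidal seasonal cycle + noise.

    Month m of every year equals ``annual_mean + amplitude*sin(2*pi*(m-1)/12)``
    plus white noise; the 12 sampled phases sum to zero, so the noiseless
    long-term mean equals the annual mean exactly. ``amplitude`` may be a
    scalar (degC) or a per-pixel array for a spatially varying cycle.
    """
    if years < 1:
        raise ValueError("years >= 1 required")
    rng = np.random.default_rng(seed)
    grids, times = [], []
    for y in range(years):
        for m in range(1, 13):
            season = amplitude * np.sin(2 * np.pi * (m - 1) / 12.0)
            vals = annual_mean.masked_values() + season
            if noise_sd > 0:
                vals = vals + noise_sd * rng.standard_normal(geo.shape)
            vals[~annual_mean.mask] = np.nan
            grids.append(RasterGrid(geo=geo, values=vals, mask=annual_mean.mask.copy(),
                                    units=annual_mean.units, name=annual_mean.name))
            times.append((start_year + y, m))
    return MonthlyStack(grids=grids, times=times)


def make_truth(geo: GridGeo, config: SynthConfig) -> PlantedTruth:
    """Land mask + planted regimes + signatures, all from ``config.seed``."""
    ss = np.random.SeedSequence([config.seed, 0])
    s_land, s_regions, s_means = (int(c.generate_state(1)[0] % (2**31))
                                  for c in ss.spawn(3))
    land = synth_land_mask(geo, config.land_fraction, s_land)
    sea = ~land
    labels = plant_regions(geo, config.K, s_regions, sea_mask=sea)
    phys, std = make_class_means(config.K, s_means, config.min_separation)
    return PlantedTruth(geo=geo, labels=labels, class_means=phys,
                        class_means_std=std, sea_mask=sea, seed=config.seed)


__all__.append("make_truth")
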