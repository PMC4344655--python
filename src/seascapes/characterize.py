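"""Per-class summaries of a selected partition and range arithmetic.

Produces the standard class-characterization table of a seascape
delineation: the percentage of the study seascape covered by each class and
the mean +/- SD of every raw-unit variable over each class's pixels, plus
the per-variable (min, max, max-min) spread of class means used when
discussing how strongly the classes differ. A published nine-class summary
of the Sunda Banda Seascape delineation ships with the package as a
reference fixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .features import FeatureTable, scatter_to_grid
from .grids import GridGeo, RasterGrid, write_grid, read_grid
from .synthetic import VARIABLES

__all__ = [
    "ClassSummary",
    "class_summary",
    "summary_ranges",
    "export_class_map",
    "load_reference_class_summary",
    "MAJOR_REFERENCE_CLASSES",
]

#: The four classes covering >93% of the seascape in the reference summary.
MAJOR_REFERENCE_CLASSES = (2, 4, 5, 6)


@dataclass
class ClassSummary:
    """Per-class area share and raw-variable statistics.

    ``table`` columns: ``class_id``, ``sbs_percent``, and ``<var>_mean`` /
    ``<var>_sd`` for each variable. SDs are population SDs (the classes are
    full pixel enumerations, not samples); area percentages are relative to
    the classified pixels inside the seascape-of-interest mask, so classes
    lying entirely outside it score 0.
    """

    table: pd.DataFrame
    columns: tuple[str, ...] = VARIABLES

    def __post_init__(self) -> None:
        need = {"class_id", "sbs_percent"} | {f"{v}_{s}" for v in self.columns
                                              for s in ("mean", "sd")}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"summary table missing columns: {sorted(missing)}")
        if (self.table["sbs_percent"] < 0).any():
            raise ValueError("negative area percentage")

    @property
    def class_ids(self) -> list[int]:
        return self.table["class_id"].astype(int).tolist()

    def means(self, class_subset=None) -> pd.DataFrame:
        t = self.table.set_index("class_id")
        if class_subset is not None:
            t = t.loc[list(class_subset)]
        return t[[f"{v}_mean" for v in self.columns]].rename(
            columns={f"{v}_mean": v for v in self.columns})

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ClassSummary":
        return cls(table=pd.read_csv(path))


def class_summary(raw_table: FeatureTable, labels: np.ndarray,
                  sbs_mask: np.ndarray) -> ClassSummary:
    """Summarize a labeling of ``raw_table`` (physical units).

    Means/SDs are taken over *all* pixels of each class, inside the study
    bounding box; area percentages only count pixels inside ``sbs_mask``
    (the seascape-of-interest polygon) and are normalized by the classified
    pixels inside it.
    """
    labels = np.asarray(labels)
    if len(labels) != len(raw_table):
        raise ValueError("labels not aligned with table rows")
    if sbs_mask.shape != raw_table.geo.shape:
        raise ValueError("seascape mask not co-registered")
    in_sbs = sbs_mask[raw_table.pixel_index[:, 0], raw_table.pixel_index[:, 1]]
    n_sbs = int(in_sbs.sum())
    if n_sbs == 0:
        raise ValueError("no classified pixels inside the seascape mask")
    rows = []
    for c in np.unique(labels):
        sel = labels == c
        rec = {"class_id": int(c),
               "n_pixels": int(sel.sum()),
               "sbs_percent": 100.0 * float((sel & in_sbs).sum()) / n_sbs}
        for j, v in enumerate(raw_table.columns):
            col = raw_table.values[sel, j]
            rec[f"{v}_mean"] = float(col.mean())
            rec[f"{v}_sd"] = float(col.std(ddof=0))
        rows.append(rec)
    return ClassSummary(table=pd.DataFrame(rows), columns=raw_table.columns)


def summary_ranges(summary: ClassSummary,
                   class_subset=None) -> pd.DataFrame:
    """Per-variable (min, max, range) of the *class means*.

    ``class_subset`` restricts the spread to a subset of classes (e.g. the
    four dominant classes of the reference summary); default is all classes.
    """
    means = summary.means(class_subset)
    if means.empty:
        raise ValueError("empty class subset")
    return pd.DataFrame({"min": means.min(axis=0),
                         "max": means.max(axis=0),
                         "range": means.max(axis=0) - means.min(axis=0)})


def export_class_map(labels: np.ndarray, pixel_index: np.ndarray,
                     geo: GridGeo, path, class_offset: int = 1) -> RasterGrid:
    """Write the classification as an integer raster (0 = unclassified).

    ``labels`` are 0-based neuron indices; on the map classes are numbered
    ``class_offset``.. so 0 stays free as the nodata sentinel.
    """
    labels = np.asarray(labels, int)
    if len(labels) != len(pixel_index):
        raise ValueError("labels and pixel_index lengths differ")
    vals = np.zeros(geo.shape, dtype=np.int32)
    vals[pixel_index[:, 0], pixel_index[:, 1]] = labels + class_offset
    mask = vals > 0
    grid = RasterGrid(geo=geo, values=vals, mask=mask, units="class", name="class_map")
    write_grid(grid, path)
    return grid


def load_reference_class_summary() -> ClassSummary:
    """Published nine-class summary of the Sunda Banda Seascape delineation.

    Class means and population-style SDs of the six variables plus each
    class's share of the seascape area, as printed (two decimals). Class 3
    lies entirely outside the seascape proper (0%).
    """
    with resources.files("seascapes.data").joinpath(
            "sbs_reference_classes.csv").open() as fh:
        return ClassSummary(table=pd.read_csv(fh))
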