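"""Reference tables from a four-plot ginkgo-plantation validation campaign.

Four 10 m x 10 m plots of a leaf-off ginkgo plantation (planting grid
about 1.6 m north-south by 2.8 m west-east) were each scanned once from
near the plot centre, and every stem was tape-measured.  Two tables are
packaged:

* detection counts per plot (reference stems, correct / false detections,
  omissions, plot area), and
* the surveyed stem map: tape-measured and scanner-estimated plan
  positions of the 64 detected trees, metres, scanner at the origin.

Both are inputs to the evaluation utilities and to the worked examples;
nothing in the pipeline depends on them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_detection_counts",
    "load_stem_map",
    "pooled_detection_rate",
    "stem_density",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("stemscan.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_detection_counts() -> pd.DataFrame:
    """Per-plot detection bookkeeping of the validation campaign."""
    return _read("plantation_detection_counts.csv")


def load_stem_map() -> pd.DataFrame:
    """Measured and estimated stem positions (64 trees over 4 plots)."""
    return _read("plantation_stem_map.csv")


def pooled_detection_rate(counts: pd.DataFrame | None = None) -> float:
    """Pooled detection rate (percent) over all plots."""
    counts = counts if counts is not None else load_detection_counts()
    return float(counts["correct"].sum() / counts["n_trees"].sum() * 100.0)


def stem_density(counts: pd.DataFrame | None = None, plot: int | None = None) -> float:
    """Stems per hectare, for one plot or pooled over all."""
    counts = counts if counts is not None else load_detection_counts()
    if plot is not None:
        counts = counts[counts["plot"] == plot]
        if counts.empty:
            raise ValueError(f"no plot {plot}")
    return float(counts["n_trees"].sum() / counts["area_m2"].sum() * 1e4)
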