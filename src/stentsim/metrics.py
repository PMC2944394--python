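"""Lesion metrics: neointimal area per slice, lesion volume, cell counts,
population doublings.

Neointimal area at an axial slice is the cross-sectional area of sites
containing matrix (ECM > 0) minus the same count at day 0, floored at 0
and scaled by dl^2 (mm^2); lesion volume is the Riemann sum of the slice
areas with slice thickness dl (mm^3). The daily population doubling is
log2(N / N0) with N the current and N0 the previous day's SMC count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import Lattice


@dataclass
class MetricsRecord:
    day: int
    area_by_slice: np.ndarray   # mm^2 per axial slice
    lesion_volume: float        # mm^3
    n_csmc: int
    n_ssmc: int
    n_ec: int
    doubling: float             # log2 of daily SMC count ratio; NaN at day 0


def slice_ecm_counts(lat: Lattice) -> np.ndarray:
    """Per-slice count of sites containing matrix (ECM > 0)."""
    return (lat.ecm > 0.0).sum(axis=(0, 1)).astype(np.int64)


def neointimal_area(lat: Lattice, slice_k: int, baseline: np.ndarray) -> float:
    """Neointimal area (mm^2) of axial slice ``slice_k``: matrix-containing
    site count minus the day-0 baseline, floored at 0, times dl^2."""
    nz = lat.dims[2]
    if not 0 <= slice_k < nz:
        raise IndexError(f"slice {slice_k} out of range [0, {nz})")
    count = int((lat.ecm[:, :, slice_k] > 0.0).sum())
    return max(0, count - int(baseline[slice_k])) * lat.dl ** 2


def neointimal_areas(lat: Lattice, baseline: np.ndarray) -> np.ndarray:
    counts = slice_ecm_counts(lat)
    return np.maximum(counts - np.asarray(baseline), 0) * lat.dl ** 2


def lesion_volume(area_by_slice: np.ndarray, dl: float) -> float:
    """Lesion volume (mm^3): sum of slice areas times slice thickness."""
    return float(dl * np.sum(area_by_slice))


def cumulative_population_doubling(n: int, n0: int) -> float:
    """log2(N / N0); NaN when the reference count N0 is zero."""
    if n0 == 0:
        return float("nan")
    return math.log2(n / n0)


# ---------------------------------------------------------------------------
# Series IO
# ---------------------------------------------------------------------------

def series_to_frame(records: list[MetricsRecord]) -> pd.DataFrame:
    nz = len(records[0].area_by_slice) if records else 0
    cols = {
        "day": [r.day for r in records],
        "lesion_volume": [r.lesion_volume for r in records],
        "n_csmc": [r.n_csmc for r in records],
        "n_ssmc": [r.n_ssmc for r in records],
        "n_ec": [r.n_ec for r in records],
        "doubling": [r.doubling for r in records],
    }
    areas = np.array([r.area_by_slice for r in records]).reshape(len(records), nz)
    for k in range(nz):
        cols[f"area_{k:04d}"] = areas[:, k]
    return pd.DataFrame(cols)


def write_metrics_csv(frame: pd.DataFrame, path) -> None:
    """One row per day; floats at 12 significant digits (round-trip safe
    for the magnitudes involved)."""
    frame.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def read_metrics_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
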