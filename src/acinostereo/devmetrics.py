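"""Derived developmental morphometry: per-animal tables and lung-level metrics.

Turns per-acinus records (volume, alveolar number, density) into the
summaries a developmental study reports: per-animal counting tables,
day-level weighted means, coefficients of variation, size-dispersion
metrics (smallest/largest-quintile ratio, volumes normalized to the day
maximum), and lung-level extrapolations (number of acini, total alveoli,
individual alveolar volume and sphere-equivalent diameter).

Day-level means are acinus-weighted: Σnᵢmᵢ/Σnᵢ over the animals of a day
equals the pooled per-acinus mean, which is what a per-acinus analysis
reports. All internal math runs at full precision; rounding is display-only
(integers for counts and densities, 2–3 decimals for mm³).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .volio import CountingTable

__all__ = [
    "AcinusRecord",
    "LungMetrics",
    "records_frame",
    "summarize_by_animal",
    "day_weighted_mean",
    "day_pooled_sd",
    "cv_of_day",
    "quintile_ratio",
    "normalize_volumes",
    "estimate_n_acini",
    "total_alveoli",
    "alveolar_volume_and_diameter",
    "sphere_equivalent_diameter_um",
    "linear_scale_factor",
    "day_boxplot",
]

RECORD_COLUMNS = ["animal_id", "day", "acinus_id", "volume_mm3", "n_alveoli", "density_per_mm3"]


@dataclasses.dataclass
class AcinusRecord:
    """One assessed acinus: shrinkage-corrected volume, alveolar number, density."""

    animal_id: str
    day: int
    acinus_id: str
    volume_mm3: float
    n_alveoli: float

    def __post_init__(self) -> None:
        if self.volume_mm3 <= 0:
            raise ValueError(f"{self.acinus_id}: volume must be positive")
        if self.n_alveoli < 0:
            raise ValueError(f"{self.acinus_id}: alveolar number must be >= 0")

    @property
    def density_per_mm3(self) -> float:
        return self.n_alveoli / self.volume_mm3


@dataclasses.dataclass
class LungMetrics:
    """Lung-level extrapolations for one day.

    ``n_acini_estimated`` divides the parenchymal volume (an external
    scalar from whole-lung stereology) by the mean acinar volume;
    ``total_alveoli_millions`` multiplies it by the mean alveolar number
    per acinus; alveolar volume and diameter follow from the per-alveolus
    share of acinar air space corrected for the ductal fraction.
    """

    parenchymal_volume_mm3: float
    n_acini_estimated: float
    total_alveoli_millions: float
    alveolar_volume_um3: float
    alveolar_diameter_um: float
    ductal_fraction: float


def records_frame(records: Sequence[AcinusRecord] | pd.DataFrame) -> pd.DataFrame:
    """Normalize a record collection to a DataFrame with the canonical columns."""
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
        if "density_per_mm3" not in frame.columns:
            frame["density_per_mm3"] = frame["n_alveoli"] / frame["volume_mm3"]
        return frame[RECORD_COLUMNS]
    rows = [
        {
            "animal_id": r.animal_id,
            "day": r.day,
            "acinus_id": r.acinus_id,
            "volume_mm3": r.volume_mm3,
            "n_alveoli": r.n_alveoli,
            "density_per_mm3": r.density_per_mm3,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def summarize_by_animal(
    records: Sequence[AcinusRecord] | pd.DataFrame, quantity: str = "volume_mm3"
) -> CountingTable:
    """Per-animal n/mean/sd/min/max table for one quantity.

    The SD is the sample standard deviation (n−1 denominator); an animal
    with a single acinus has no defined SD and is reported as 0, with its
    animal_id listed in the returned table's ``undefined_sd`` attribute.
    """
    frame = records_frame(records)
    if quantity not in {"counts", "volume_mm3", "density_per_mm3"}:
        raise KeyError(f"unknown quantity {quantity!r}")
    col = {"counts": "n_alveoli", "volume_mm3": "volume_mm3", "density_per_mm3": "density_per_mm3"}[quantity]
    rows = []
    undefined = []
    for (animal, day), sub in frame.groupby(["animal_id", "day"], sort=True):
        vals = sub[col].to_numpy(float)
        if len(vals) > 1:
            sd = float(np.std(vals, ddof=1))
        else:
            sd = 0.0
            undefined.append(animal)
        rows.append(
            {
                "animal_id": animal,
                "day": int(day),
                "assessed_acini": len(vals),
                "average": float(np.mean(vals)),
                "sd": sd,
                "minimum": float(vals.min()),
                "maximum": float(vals.max()),
            }
        )
    table = CountingTable(quantity=quantity, frame=pd.DataFrame(rows))
    table.undefined_sd = undefined
    return table


def day_weighted_mean(table: CountingTable, day: int) -> float:
    """Acinus-weighted day mean Σnᵢmᵢ/Σnᵢ (equals the pooled per-acinus mean)."""
    sub = table.rows_for_day(day)
    n = sub["assessed_acini"].to_numpy(float)
    m = sub["average"].to_numpy(float)
    return float((n * m).sum() / n.sum())


def _pooled_variance(n: np.ndarray, m: np.ndarray, s: np.ndarray) -> float:
    """Pooled per-acinus variance from per-animal (n, mean, sd) rows.

    [Σ(nᵢ−1)sᵢ² + Σnᵢ(mᵢ−m̄)²] / (Σnᵢ−1), the exact variance of the pooled
    sample reconstructed from group moments.
    """
    total = n.sum()
    if total < 2:
        raise ValueError("pooled variance needs at least 2 acini")
    grand = (n * m).sum() / total
    return float(((n - 1) * s**2).sum() + (n * (m - grand) ** 2).sum()) / (total - 1)


def day_pooled_sd(table: CountingTable, day: int) -> float:
    sub = table.rows_for_day(day)
    return math.sqrt(
        _pooled_variance(
            sub["assessed_acini"].to_numpy(float),
            sub["average"].to_numpy(float),
            sub["sd"].to_numpy(float),
        )
    )


def cv_of_day(source: CountingTable | Sequence[AcinusRecord] | pd.DataFrame, day: int,
              quantity: str = "volume_mm3") -> float:
    """Coefficient of variation (pooled SD / pooled mean) of a day's acini.

    From raw records this is the direct sample CV of the pooled values;
    from a per-animal table the pooled moments are reconstructed exactly
    from the group (n, mean, sd) rows.
    """
    if isinstance(source, CountingTable):
        return day_pooled_sd(source, day) / day_weighted_mean(source, day)
    frame = records_frame(source)
    col = {"counts": "n_alveoli", "volume_mm3": "volume_mm3", "density_per_mm3": "density_per_mm3"}[quantity]
    vals = frame.loc[frame["day"] == day, col].to_numpy(float)
    if len(vals) < 2:
        raise ValueError("CV needs at least 2 acini")
    return float(np.std(vals, ddof=1) / np.mean(vals))


def quintile_ratio(
    volumes: Sequence[float] | pd.DataFrame,
    day: int | None = None,
    fraction: float = 0.2,
) -> tuple[float, float, float, int]:
    """Ratio of mean volume of the largest to the smallest tail fraction.

    Volumes are sorted ascending; the tail size is ``round(fraction·N)``
    (nearest integer, at least 1). Returns ``(ratio, mean_low, mean_high,
    n_per_tail)``. A day's size dispersion is large when the ratio is
    large; equal-tail means give exactly 1.
    """
    if isinstance(volumes, pd.DataFrame):
        if day is None:
            raise ValueError("day required when passing a record frame")
        volumes = volumes.loc[volumes["day"] == day, "volume_mm3"].to_numpy(float)
    vals = np.sort(np.asarray(list(volumes), dtype=float))
    n_tail = int(round(fraction * len(vals)))
    if n_tail < 1:
        raise ValueError(
            f"tail of fraction {fraction} of {len(vals)} acini is empty; need >= {math.ceil(1 / fraction)}"
        )
    mean_low = float(vals[:n_tail].mean())
    mean_high = float(vals[-n_tail:].mean())
    return mean_high / mean_low, mean_low, mean_high, n_tail


def normalize_volumes(
    volumes: Sequence[float] | pd.DataFrame, day: int | None = None
) -> tuple[np.ndarray, float]:
    """Divide a day's volumes by the day maximum; returns (normalized, median).

    The maximum of the output is 1 by construction and order statistics are
    preserved. The median of the normalized volumes is the skewness
    readout: well below 0.5 early in development, 0.5 when the
    distribution is symmetric over its range.
    """
    if isinstance(volumes, pd.DataFrame):
        if day is None:
            raise ValueError("day required when passing a record frame")
        volumes = volumes.loc[volumes["day"] == day, "volume_mm3"].to_numpy(float)
    vals = np.asarray(list(volumes), dtype=float)
    if vals.size == 0:
        raise ValueError("no volumes to normalize")
    normalized = vals / vals.max()
    return normalized, float(np.median(normalized))


def estimate_n_acini(parenchymal_volume_mm3: float, mean_acinar_volume_mm3: float) -> float:
    """Number of acini per lung: parenchymal volume / mean acinar volume."""
    if parenchymal_volume_mm3 <= 0 or mean_acinar_volume_mm3 <= 0:
        raise ValueError("volumes must be positive")
    return parenchymal_volume_mm3 / mean_acinar_volume_mm3


def total_alveoli(n_acini: float, mean_alveoli_per_acinus: float) -> float:
    """Total alveoli per lung, in millions."""
    return n_acini * mean_alveoli_per_acinus / 1e6


def sphere_equivalent_diameter_um(volume_um3: float) -> float:
    """Diameter of a sphere of the given volume: d = (6V/π)^(1/3)."""
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    return (6.0 * volume_um3 / math.pi) ** (1.0 / 3.0)


def alveolar_volume_and_diameter(
    mean_acinar_volume_mm3: float,
    mean_alveoli: float,
    ductal_fraction: float,
) -> tuple[float, float]:
    """Individual alveolar volume (µm³) and sphere-equivalent diameter (µm).

    The per-alveolus share of acinar volume, corrected for the fraction of
    the acinus occupied by alveoli proper (``ductal_fraction`` multiplies
    the quotient; the remainder is alveolar duct):
    V = f · V_acinus / N_alveoli, then d = (6V/π)^(1/3) assuming spherical
    alveoli.
    """
    if mean_alveoli <= 0:
        raise ValueError("mean alveolar count must be positive")
    if not (0 < ductal_fraction <= 1):
        raise ValueError("ductal_fraction must lie in (0, 1]")
    v_um3 = ductal_fraction * mean_acinar_volume_mm3 * 1e9 / mean_alveoli
    return v_um3, sphere_equivalent_diameter_um(v_um3)


def compute_lung_metrics(
    parenchymal_volume_mm3: float,
    mean_acinar_volume_mm3: float,
    mean_alveoli: float,
    ductal_fraction: float,
) -> LungMetrics:
    """Assemble the lung-level metrics for one day."""
    n_acini = estimate_n_acini(parenchymal_volume_mm3, mean_acinar_volume_mm3)
    v_um3, d_um = alveolar_volume_and_diameter(
        mean_acinar_volume_mm3, mean_alveoli, ductal_fraction
    )
    return LungMetrics(
        parenchymal_volume_mm3=parenchymal_volume_mm3,
        n_acini_estimated=n_acini,
        total_alveoli_millions=total_alveoli(n_acini, mean_alveoli),
        alveolar_volume_um3=v_um3,
        alveolar_diameter_um=d_um,
        ductal_fraction=ductal_fraction,
    )


def linear_scale_factor(
    series_ref: Sequence[float], series_own: Sequence[float], mode: str = "ratio_of_sums"
) -> float:
    """Linear scale factor between two per-day series.

    ``ratio_of_sums`` = Σref/Σown (a single global factor);
    ``mean_of_ratios`` = mean(refᵢ/ownᵢ) (average per-day factor). Used to
    collate per-lung totals or alveolar volumes against an independent
    whole-lung histology series.
    """
    ref = np.asarray(list(series_ref), dtype=float)
    own = np.asarray(list(series_own), dtype=float)
    if ref.shape != own.shape:
        raise ValueError(f"series length mismatch: {ref.shape} vs {own.shape}")
    if np.any(ref <= 0) or np.any(own <= 0):
        raise ValueError("series values must be positive")
    if mode == "ratio_of_sums":
        return float(ref.sum() / own.sum())
    if mode == "mean_of_ratios":
        return float(np.mean(ref / own))
    raise ValueError(f"unknown mode {mode!r}")


def day_boxplot(records: pd.DataFrame, quantity: str = "volume_mm3", log: bool = False, ax=None):
    """Box plot of a per-acinus quantity by day (linear or log axis)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    frame = records_frame(records)
    col = {"counts": "n_alveoli", "volume_mm3": "volume_mm3", "density_per_mm3": "density_per_mm3"}[quantity]
    days = sorted(frame["day"].unique())
    data = [frame.loc[frame["day"] == d, col].to_numpy(float) for d in days]
    if ax is None:
        _, ax = plt.subplots()
    ax.boxplot(data, tick_labels=[str(d) for d in days])
    ax.set_xlabel("postnatal day")
    ax.set_ylabel(col)
    if log:
        ax.set_yscale("log")
    return ax
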