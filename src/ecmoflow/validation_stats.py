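"""Agreement statistics between predicted and measured circuit variables.

For each series (flow, P1, P2, P3) the report carries:

* R^2 of the observed-on-predicted regression (headline), plus an
  identity-line variant ``r2_identity`` = 1 - SS(meas - pred)/SS about the
  measured mean, for transparency;
* RMSD in the series' own units;
* bias = predicted - measured, summarised as median and IQR;
* signed relative error = (measured - predicted)/measured * 100, median;
* slope and intercept of the OLS line of measured (y) on predicted (x).

Quantiles use linear interpolation between order statistics (numpy's
default, matching R's type 7).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateRegressionError,
    InsufficientDataError,
    ZeroMeasurementError,
)


@dataclass(frozen=True)
class PairedSeries:
    """Predicted/measured value pairs for one variable.

    ``label`` is conventionally one of flow, P1, P2, P3; ``combo_ids``
    optionally identifies each pair (cannula sizes, rpm, height) for error
    reporting.
    """

    label: str
    predicted: tuple[float, ...]
    measured: tuple[float, ...]
    combo_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        pred = tuple(float(x) for x in self.predicted)
        meas = tuple(float(x) for x in self.measured)
        object.__setattr__(self, "predicted", pred)
        object.__setattr__(self, "measured", meas)
        if len(pred) != len(meas):
            raise InsufficientDataError(
                f"{self.label}: predicted and measured lengths differ "
                f"({len(pred)} vs {len(meas)})"
            )
        if any(not np.isfinite(v) for v in pred + meas):
            raise InsufficientDataError(f"{self.label}: missing/non-finite values")
        if self.combo_ids is not None:
            ids = tuple(str(c) for c in self.combo_ids)
            if len(ids) != len(pred):
                raise InsufficientDataError(
                    f"{self.label}: combo_ids length mismatch"
                )
            object.__setattr__(self, "combo_ids", ids)

    def __len__(self) -> int:
        return len(self.predicted)


@dataclass(frozen=True)
class ValidationReport:
    """Agreement summary for one predicted-vs-measured series."""

    label: str
    n: int
    r2: float
    r2_identity: float
    rmsd: float
    bias_median: float
    bias_q1: float
    bias_q3: float
    rel_err_median: float
    slope: float
    intercept: float

    def as_dict(self) -> dict:
        return {
            "label": self.label, "n": self.n, "r2": self.r2,
            "r2_identity": self.r2_identity, "rmsd": self.rmsd,
            "bias_median": self.bias_median, "bias_q1": self.bias_q1,
            "bias_q3": self.bias_q3, "rel_err_median": self.rel_err_median,
            "slope": self.slope, "intercept": self.intercept,
        }


def regress_observed_on_predicted(series: PairedSeries) -> tuple[float, float]:
    """OLS line of measured (y) on predicted (x): returns (slope, intercept)."""
    if len(series) < 2:
        raise InsufficientDataError(
            f"{series.label}: need at least 2 pairs for regression, "
            f"got {len(series)}"
        )
    x = np.asarray(series.predicted)
    y = np.asarray(series.measured)
    if np.ptp(x) == 0:
        raise DegenerateRegressionError(
            f"{series.label}: all predicted values identical; regression "
            f"line undefined"
        )
    xc = x - x.mean()
    slope = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept


def compute_validation_stats(series: PairedSeries) -> ValidationReport:
    """Full agreement report for one series.

    Raises :class:`ZeroMeasurementError` (naming the combo) if any measured
    value is zero, since the relative error is then undefined, and
    :class:`InsufficientDataError` for fewer than two pairs.
    """
    n = len(series)
    if n < 2:
        raise InsufficientDataError(
            f"{series.label}: need at least 2 pairs, got {n}"
        )
    pred = np.asarray(series.predicted)
    meas = np.asarray(series.measured)
    for i, m in enumerate(meas):
        if m == 0:
            combo = series.combo_ids[i] if series.combo_ids else f"pair {i}"
            raise ZeroMeasurementError(combo)

    bias = pred - meas
    rel_err = (meas - pred) / meas * 100.0
    rmsd = float(np.sqrt(np.mean(bias**2)))
    q1, med, q3 = np.percentile(bias, [25, 50, 75])

    slope, intercept = regress_observed_on_predicted(series)
    ss_tot = float(np.sum((meas - meas.mean()) ** 2))
    ss_res = float(np.sum(bias**2))
    # regression R^2 == squared Pearson correlation for simple OLS; exact
    # agreement short-circuits to 1 so perfect pipelines report exactly 1
    if ss_res == 0.0:
        r2 = 1.0
    elif np.ptp(meas) == 0:
        r2 = 0.0
    else:
        r2 = min(float(np.corrcoef(pred, meas)[0, 1] ** 2), 1.0)
    r2_identity = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)

    return ValidationReport(
        label=series.label, n=n, r2=r2, r2_identity=r2_identity, rmsd=rmsd,
        bias_median=float(med), bias_q1=float(q1), bias_q3=float(q3),
        rel_err_median=float(np.percentile(rel_err, 50)),
        slope=slope, intercept=intercept,
    )
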