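"""Tumor purity estimation from a qPCR standard curve.

The fraction of cancer cells in a bulk tumor sample is measured with a
real-time PCR assay targeting the un-recombined LSL cassette, which is
present only in non-tumor cells.  A dilution series of tumor-cell DNA
mixed into normal DNA at known proportions yields cycle-threshold (Ct)
readouts; a linear model ``Ct = A * purity + B`` is fitted to the
standards and inverted to estimate the purity of each tumor sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StandardCurve", "fit_standard_curve", "estimate_purity"]


@dataclass(frozen=True)
class StandardCurve:
    """Fitted linear map from tumor purity to qPCR cycle threshold.

    Attributes
    ----------
    slope : float
        Change in Ct per unit purity (``A``); non-zero for a usable assay.
    intercept : float
        Ct at purity 0 (``B``).
    r_squared : float
        Coefficient of determination of the least-squares fit, a residual
        fit-quality score in [0, 1].
    """

    slope: float
    intercept: float
    r_squared: float

    def predict(self, purity: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(purity, dtype=float) + self.intercept


def fit_standard_curve(purities, ct_values) -> StandardCurve:
    """Fit the standard curve by ordinary least squares on replicate points.

    Parameters
    ----------
    purities : array-like of float
        Known tumor-cell fraction of each standard point, in [0, 1].
        Replicates are passed as repeated entries; all replicate points
        enter the regression individually.
    ct_values : array-like of float
        Measured Ct of each point, matching ``purities``.

    Returns
    -------
    StandardCurve

    Raises
    ------
    ValueError
        If fewer than two distinct purity levels are provided (singular
        design) or any Ct is non-finite.
    """
    x = np.asarray(purities, dtype=float).ravel()
    y = np.asarray(ct_values, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("purities and ct_values must have the same length")
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("standard curve needs >= 2 distinct purity levels")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite purity or Ct value in standards")

    slope, intercept = np.polyfit(x, y, deg=1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return StandardCurve(slope=float(slope), intercept=float(intercept), r_squared=r2)


def estimate_purity(ct_values, curve: StandardCurve) -> float:
    """Invert the standard curve on replicate Cts and average.

    Each replicate Ct is mapped to ``(Ct - B) / A``; the mean of the
    per-replicate estimates is reported, clamped to [0, 1] (assay noise can
    push individual inversions slightly past the extreme standards).
    """
    y = np.asarray(ct_values, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("need at least one Ct replicate")
    if not np.isfinite(y).all():
        raise ValueError("non-finite Ct value")
    if curve.slope == 0:
        raise ValueError("standard curve slope is zero; cannot invert")
    est = float(np.mean((y - curve.intercept) / curve.slope))
    return min(1.0, max(0.0, est))
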