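"""Shared two-parameter ordinary least squares used by the linearized fits."""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .errors import InsufficientDataError


class OLSResult(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


def ols(x, y) -> OLSResult:
    """Least-squares line y = slope*x + intercept with coefficient of determination.

    r_squared is defined as 1 - SS_res/SS_tot; for a degenerate response with
    zero total variance it is 1.0 when the residuals are (numerically) zero
    and 0.0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise InsufficientDataError("at least two points are required for a line fit")
    design = np.column_stack([x, np.ones_like(x)])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 0.0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res <= 1e-20 * max(1.0, float(y @ y)) else 0.0
    return OLSResult(slope, intercept, min(max(r2, 0.0), 1.0))
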