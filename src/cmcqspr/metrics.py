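"""Goodness-of-fit and cross-validation statistics for QSPR regression.

All statistics operate on a vector of observed responses ``y_exp`` (here
log10(CMC)) and a vector of model predictions ``y_cal``:

* ``r_squared``   -- 1 - SS_res / SS_tot, SS_tot about the mean of ``y_exp``
* ``rmsd``        -- root-mean-square deviation
* ``mae``         -- mean absolute error
* ``rsd``         -- residual standard deviation sqrt(SS_res / (n - d - 1)),
  the objective minimised during descriptor subset selection
* ``cv_metrics``  -- Q2 / RMSECV computed from out-of-fold predictions

The mean used in SS_tot is always the mean of the ``y_exp`` vector that is
passed in; the caller decides whether that is a training mean or a pooled
mean, and nothing is cached.  Q2 may be negative (y-randomisation relies on
that); no clamping is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


@dataclass(frozen=True)
class MetricsReport:
    """Fit statistics for one prediction vector against observations."""

    n: int
    d: int
    r2: float
    rmsd: float
    mae: float
    rsd: float

    def to_tsv(self, label: str = "") -> str:
        """Flat key/value TSV (``R2_train``-style names when *label* given)."""
        suffix = f"_{label}" if label else ""
        rows = [(f"{k}{suffix}" if k not in ("n", "d") else f"{k}{suffix}", v)
                for k, v in asdict(self).items()]
        return "\n".join(f"{k}\t{v}" for k, v in rows)


@dataclass(frozen=True)
class CrossValMetrics:
    """Cross-validated analogues of R2 and RMSD."""

    q2: float
    rmsecv: float


def _as_pair(y_exp, y_cal, min_len: int = 1):
    a = np.asarray(y_exp, dtype=float).ravel()
    b = np.asarray(y_cal, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < min_len:
        raise ValueError(f"need at least {min_len} observations, got {a.size}")
    return a, b


def r_squared(y_exp, y_cal) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot.

    SS_tot is taken about the mean of *y_exp*.  Raises if *y_exp* is
    constant (zero denominator).
    """
    a, b = _as_pair(y_exp, y_cal, min_len=2)
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("y_exp is constant; R^2 denominator is zero")
    ss_res = float(np.sum((a - b) ** 2))
    return 1.0 - ss_res / ss_tot


def rmsd(y_exp, y_cal) -> float:
    """Root-mean-square deviation sqrt(mean((y_exp - y_cal)^2))."""
    a, b = _as_pair(y_exp, y_cal)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def mae(y_exp, y_cal) -> float:
    """Mean absolute error."""
    a, b = _as_pair(y_exp, y_cal)
    return float(np.mean(np.abs(a - b)))


def rsd(y_exp, y_cal, d: int) -> float:
    """Residual standard deviation sqrt(SS_res / (n - d - 1)).

    *d* is the number of model variables (the intercept is accounted for by
    the extra -1).  Requires n - d - 1 >= 1.
    """
    a, b = _as_pair(y_exp, y_cal)
    dof = a.size - d - 1
    if dof < 1:
        raise ValueError(f"degrees of freedom n-d-1 = {dof} < 1 (n={a.size}, d={d})")
    return float(np.sqrt(np.sum((a - b) ** 2) / dof))


def cv_metrics(y_exp, y_cv) -> CrossValMetrics:
    """Q2 and RMSECV from a vector of out-of-fold predictions.

    Q2 has the same algebraic form as ``r_squared`` and RMSECV the same
    form as ``rmsd``; both are simply applied to cross-validation
    predictions instead of in-sample ones.
    """
    return CrossValMetrics(q2=r_squared(y_exp, y_cv), rmsecv=rmsd(y_exp, y_cv))


def absolute_error(y_exp: float, y_cal: float) -> float:
    """AE = |y_exp - y_cal| for a single observation."""
    if not (np.isfinite(y_exp) and np.isfinite(y_cal)):
        raise ValueError("absolute_error requires finite inputs")
    return abs(float(y_exp) - float(y_cal))


def metrics_report(y_exp, y_cal, d: int) -> MetricsReport:
    """Bundle R2, RMSD, MAE and RSD for one prediction vector."""
    a, _ = _as_pair(y_exp, y_cal, min_len=2)
    return MetricsReport(
        n=int(a.size),
        d=int(d),
        r2=r_squared(y_exp, y_cal),
        rmsd=rmsd(y_exp, y_cal),
        mae=mae(y_exp, y_cal),
        rsd=rsd(y_exp, y_cal, d),
    )
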