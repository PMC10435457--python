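"""Ordinary-least-squares multivariate linear QSPR models.

The fitted object mirrors the shape of a published CMC correlation: an
intercept plus one coefficient per variable, each with its classical OLS
standard error (residual variance SS_res / (n - d - 1)).  An intercept is
always included and nothing is standardised: coefficients act on raw
variable values, so they can be compared directly with printed correlations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

# Relative condition-number ceiling on the augmented design.  Above this the
# fit refuses rather than silently regularising: subset selection depends on
# singular candidate designs failing honestly.
_COND_LIMIT = 1e10


class SingularDesignError(np.linalg.LinAlgError):
    pass


@dataclass(frozen=True)
class LinearQsprModel:
    variable_names: tuple[str, ...]
    coefficients: np.ndarray
    coefficient_ses: np.ndarray
    intercept: float
    intercept_se: float
    n: int
    d: int

    def __post_init__(self):
        object.__setattr__(self, "coefficients", np.asarray(self.coefficients, float))
        object.__setattr__(self, "coefficient_ses", np.asarray(self.coefficient_ses, float))
        if not (len(self.variable_names) == self.coefficients.size
                == self.coefficient_ses.size == self.d):
            raise ValueError("inconsistent model dimensions")

    def to_json(self) -> str:
        return json.dumps(
            {
                "variable_names": list(self.variable_names),
                "coefficients": self.coefficients.tolist(),
                "coefficient_ses": self.coefficient_ses.tolist(),
                "intercept": self.intercept,
                "intercept_se": self.intercept_se,
                "n": self.n,
                "d": self.d,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearQsprModel":
        obj = json.loads(text)
        return cls(
            variable_names=tuple(obj["variable_names"]),
            coefficients=np.asarray(obj["coefficients"], float),
            coefficient_ses=np.asarray(obj["coefficient_ses"], float),
            intercept=float(obj["intercept"]),
            intercept_se=float(obj["intercept_se"]),
            n=int(obj["n"]),
            d=int(obj["d"]),
        )


def fit_ols(X, y, variable_names=None) -> LinearQsprModel:
    """Fit y = b0 + X b by least squares with classical standard errors.

    Requires n >= d + 2 and a well-conditioned augmented design (relative
    condition number below 1e10); otherwise raises rather than regularise.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, d = X.shape
    if y.size != n:
        raise ValueError("X and y row counts differ")
    if n < d + 2:
        raise ValueError(f"need n >= d + 2 (n={n}, d={d})")
    if variable_names is None:
        variable_names = tuple(f"x{j+1}" for j in range(d))
    A = np.column_stack([np.ones(n), X])
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] == 0 or sv[0] / sv[-1] > _COND_LIMIT:
        raise SingularDesignError(
            f"augmented design is singular or ill-conditioned "
            f"(cond ~ {sv[0] / max(sv[-1], np.finfo(float).tiny):.2e})"
        )
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    s2 = float(resid @ resid) / (n - d - 1)
    cov = s2 * np.linalg.inv(A.T @ A)
    ses = np.sqrt(np.diag(cov))
    return LinearQsprModel(
        variable_names=tuple(variable_names),
        coefficients=beta[1:],
        coefficient_ses=ses[1:],
        intercept=float(beta[0]),
        intercept_se=float(ses[0]),
        n=n,
        d=d,
    )


def predict_linear(model: LinearQsprModel, X) -> np.ndarray:
    """intercept + X @ coefficients, checking the column count."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.d:
        raise ValueError(f"expected {model.d} columns, got {X.shape[1]}")
    return model.intercept + X @ model.coefficients
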