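"""QSPR validation battery for linear CMC models.

Implements the standard chemometric checks applied to a multivariate linear
model: leave-one-out cross-validation (Q2/RMSECV), repeated leave-N-out
cross-validation, split-resampling (repeated random train/test divisions,
each scored by training R2 and LOO Q2), y-randomization against chance
correlation, external validation on a held-out set, and the overfitting
verdict based on the R2 - Q2 gap.

LOO predictions are obtained through the exact PRESS identity for OLS:
deleting observation i and predicting it is algebraically identical to
e_i / (1 - h_ii) where e_i is the in-sample residual and h_ii the leverage.
This makes the 1000-repeat y-randomization and 5000-split resampling loops
cheap while remaining exactly equal to the refit-each-sample definition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .metrics import CrossValMetrics, cv_metrics, r_squared, rmsd
from .mlr import SingularDesignError, fit_ols, predict_linear

logger = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    q2_loo: float
    rmsecv_loo: float
    lno_runs: list[tuple[int, float, float]]
    q2_lno_mean: float
    rmsecv_lno_mean: float
    r2_boot: float
    q2_boot: float
    yrand_points: list[tuple[float, float]]
    r2_ext: float
    q2_ext: float
    r2_train: float
    overfit_flag: bool
    chance_flag: bool
    seeds: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, default=list)

    def to_tsv(self) -> str:
        rows = [
            ("R2_train", self.r2_train),
            ("Q2_LOO", self.q2_loo),
            ("RMSECV_LOO", self.rmsecv_loo),
            ("Q2_LNO_mean", self.q2_lno_mean),
            ("RMSECV_LNO_mean", self.rmsecv_lno_mean),
            ("R2_boot", self.r2_boot),
            ("Q2_boot", self.q2_boot),
            ("R2_ext", self.r2_ext),
            ("Q2_ext", self.q2_ext),
            ("overfit_flag", self.overfit_flag),
            ("chance_flag", self.chance_flag),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows)


def _loo_predictions(X, y) -> np.ndarray:
    """Exact leave-one-out predictions via the hat-matrix identity."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, d = X.shape
    if n < d + 3:
        raise ValueError(f"LOO needs n >= d + 3 (n={n}, d={d})")
    A = np.column_stack([np.ones(n), X])
    try:
        G = np.linalg.inv(A.T @ A)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(str(exc)) from exc
    beta = G @ (A.T @ y)
    resid = y - A @ beta
    h = np.einsum("ij,jk,ik->i", A, G, A)
    if np.any(h >= 1.0 - 1e-12):
        i = int(np.argmax(h))
        raise SingularDesignError(f"leave-one-out refit singular at sample {i}")
    return y - resid / (1.0 - h)


def loo_cv(X, y) -> CrossValMetrics:
    """Leave-one-out cross-validation: Q2 and RMSECV from deleted residuals.

    Deterministic — repeating the computation cannot change the result.
    """
    return cv_metrics(y, _loo_predictions(X, y))


def _lno_groups(n: int, leave_fraction: float, rng) -> list[np.ndarray]:
    k = int(np.ceil(1.0 / leave_fraction))
    perm = rng.permutation(n)
    base, extra = divmod(n, k)
    groups, pos = [], 0
    for g in range(k):
        size = base + (1 if g < extra else 0)
        groups.append(perm[pos:pos + size])
        pos += size
    return groups


def lno_cv(X, y, leave_fraction: float = 0.25, repeats: int = 3, seed: int = 0):
    """Repeated leave-N-out cross-validation.

    Each repeat partitions the samples into ceil(1/leave_fraction) disjoint
    random groups; each group is held out once and predicted by a model fit
    on the rest.  Defaults follow the leave-25%-out scheme repeated three
    times.  Returns (list of per-repeat CrossValMetrics, mean metrics).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if leave_fraction >= 0.5:
        raise ValueError("leave_fraction must be < 0.5 (train must exceed the held-out group)")
    if leave_fraction <= 0:
        raise ValueError("leave_fraction must be positive")
    rng = np.random.default_rng(seed)
    n = y.size
    runs = []
    for _ in range(repeats):
        pred = np.empty(n)
        for group in _lno_groups(n, leave_fraction, rng):
            mask = np.ones(n, dtype=bool)
            mask[group] = False
            model = fit_ols(X[mask], y[mask])
            pred[group] = predict_linear(model, X[group])
        runs.append(cv_metrics(y, pred))
    mean = CrossValMetrics(
        q2=float(np.mean([r.q2 for r in runs])),
        rmsecv=float(np.mean([r.rmsecv for r in runs])),
    )
    return runs, mean


def split_resampling(X, y, n_boot: int = 5000, test_fraction: float = 0.1, seed: int = 0):
    """Repeated random train/test splitting ("bootstrapping" in the QSPR sense).

    The dataset is divided into train and test n_boot times; for each split
    a fresh model is fit on the training part and scored by its training R2
    and LOO Q2.  The averages over splits are reported.  Note this is
    literal repeated splitting, not resampling with replacement.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    n = y.size
    n_test = max(1, int(np.floor(test_fraction * n)))
    rng = np.random.default_rng(seed)
    r2s, q2s, failures = [], [], 0
    for _ in range(n_boot):
        test = rng.choice(n, size=n_test, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        try:
            model = fit_ols(X[mask], y[mask])
            r2s.append(r_squared(y[mask], predict_linear(model, X[mask])))
            q2s.append(loo_cv(X[mask], y[mask]).q2)
        except (SingularDesignError, ValueError):
            failures += 1
    if failures > 0.1 * n_boot:
        raise SingularDesignError(f"{failures}/{n_boot} resampling fits failed")
    return float(np.mean(r2s)), float(np.mean(q2s))


def y_randomization(X, y, repeats: int = 1000, seed: int = 0,
                    threshold: float = 0.2, model_r2: float | None = None,
                    model_q2: float | None = None):
    """Chance-correlation test: permute the response, refit, score.

    The design matrix stays fixed while y is shuffled without replacement;
    each shuffled fit is scored by its R2 and LOO Q2.  Absence of chance
    correlation requires every shuffled R2 and Q2 to stay below the 0.2
    threshold while the real model's statistics sit far above the cloud.
    Returns (list of (r2_yi, q2_yi), chance_flag) where chance_flag=True
    signals a chance-correlation risk.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    rng = np.random.default_rng(seed)
    points = []
    for _ in range(repeats):
        y_perm = rng.permutation(y)
        try:
            model = fit_ols(X, y_perm)
            r2_i = r_squared(y_perm, predict_linear(model, X))
            q2_i = loo_cv(X, y_perm).q2
        except (SingularDesignError, ValueError):
            logger.debug("skipping singular y-randomization fit")
            continue
        points.append((r2_i, q2_i))
    cloud_ok = all(r < threshold and q < threshold for r, q in points)
    dominates = True
    if model_r2 is not None and points:
        dominates = model_r2 > max(r for r, _ in points)
    if model_q2 is not None and points:
        dominates = dominates and model_q2 > max(q for _, q in points)
    chance_flag = not (cloud_ok and dominates)
    return points, chance_flag


def external_validation(train: tuple, test: tuple):
    """Fit on the training set, score R2 and Q2-form statistics on the test set.

    Both statistics use the external set's own mean in the total
    sum-of-squares denominator.
    """
    X_tr, y_tr = train
    X_te, y_te = test
    y_te = np.asarray(y_te, float).ravel()
    if y_te.size < 2:
        raise ValueError("external set needs at least 2 samples")
    model = fit_ols(X_tr, y_tr)
    pred = predict_linear(model, X_te)
    r2_ext = r_squared(y_te, pred)
    q2_ext = cv_metrics(y_te, pred).q2
    return r2_ext, q2_ext


def overfit_verdict(r2: float, q2: float, threshold: float = 0.3) -> bool:
    """True when the R2 - Q2 gap exceeds *threshold* (overfitting signal)."""
    if not (np.isfinite(r2) and np.isfinite(q2)):
        raise ValueError("r2 and q2 must be finite")
    return (r2 - q2) > threshold


def yrand_to_csv(points) -> str:
    lines = ["r2_yi,q2_yi"]
    lines += [f"{r!r},{q!r}" for r, q in points]
    return "\n".join(lines) + "\n"


def validate_linear_model(X_train, y_train, X_test, y_test, *,
                          lno_fraction: float = 0.25, lno_repeats: int = 3,
                          n_boot: int = 5000, boot_fraction: float = 0.1,
                          yrand_repeats: int = 1000,
                          overfit_threshold: float = 0.3,
                          seed: int = 0) -> ValidationReport:
    """Run the full battery and assemble a :class:`ValidationReport`."""
    model = fit_ols(X_train, y_train)
    r2_train = r_squared(y_train, predict_linear(model, X_train))
    loo = loo_cv(X_train, y_train)
    lno_runs, lno_mean = lno_cv(X_train, y_train, lno_fraction, lno_repeats, seed=seed + 1)
    r2_boot, q2_boot = split_resampling(X_train, y_train, n_boot, boot_fraction, seed=seed + 2)
    points, chance = y_randomization(X_train, y_train, yrand_repeats, seed=seed + 3,
                                     model_r2=r2_train, model_q2=loo.q2)
    r2_ext, q2_ext = external_validation((X_train, y_train), (X_test, y_test))
    return ValidationReport(
        q2_loo=loo.q2,
        rmsecv_loo=loo.rmsecv,
        lno_runs=[(i + 1, r.q2, r.rmsecv) for i, r in enumerate(lno_runs)],
        q2_lno_mean=lno_mean.q2,
        rmsecv_lno_mean=lno_mean.rmsecv,
        r2_boot=r2_boot,
        q2_boot=q2_boot,
        yrand_points=points,
        r2_ext=r2_ext,
        q2_ext=q2_ext,
        r2_train=r2_train,
        overfit_flag=overfit_verdict(r2_train, loo.q2, overfit_threshold),
        chance_flag=chance,
        seeds={"lno": seed + 1, "boot": seed + 2, "yrand": seed + 3},
    )
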