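"""Best-subset descriptor selection by the replacement method family.

The replacement method (RM) walks a d-variable linear model towards a local
optimum of the residual standard deviation (RSD): fit the current subset,
visit the position whose coefficient is least reliable (largest relative
standard error SE/|coef|), try every pool column not in the subset at that
position, accept the swap that most lowers RSD if it improves, otherwise
lock the position; repeat until every position is locked.

The enhanced replacement method (ERM) interleaves a "modified RM" pass in
which the first visited position is forced to its best replacement even if
RSD worsens — one deliberate uphill move to escape shallow local minima —
before ordinary RM polishing resumes.  The full ERM sequence from each
random restart is RM, modified RM, RM, and the best subset seen anywhere
(including initial subsets) is returned.

An exhaustive enumerator over all d-combinations is provided as the ground
truth for small pools, and a subset-size scan re-runs ERM for d = d_min..
d_max to locate the plateau where extra descriptors stop paying for
themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .metrics import r_squared, rsd
from .mlr import SingularDesignError, fit_ols, predict_linear

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    d: int
    seed: int = 0
    n_restarts: int = 10
    max_passes: int = 50  # position-visits allowed per RM pass

    def __post_init__(self):
        if self.d < 1:
            raise ValueError("subset size d must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class SelectionResult:
    subset: tuple[str, ...]
    indices: tuple[int, ...]
    rsd: float
    r2: float
    trace: list[tuple[str, tuple[int, ...], float]] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "subset": list(self.subset),
            "indices": list(self.indices),
            "rsd": self.rsd,
            "r2": self.r2,
            "trace": [[lbl, list(idx), v] for lbl, idx, v in self.trace],
        }


def _check_pool(pool, y, d):
    pool = np.asarray(pool, float)
    y = np.asarray(y, float).ravel()
    if pool.ndim != 2 or pool.shape[0] != y.size:
        raise ValueError("pool must be n x p with matching y")
    p = pool.shape[1]
    if d > p:
        raise ValueError(f"subset size d={d} exceeds pool size {p}")
    if y.size - d - 1 < 1:
        raise ValueError(f"degrees of freedom n-d-1 < 1 (n={y.size}, d={d})")
    return pool, y


def _subset_stats(pool, y, idx):
    """RSD and R2 of the OLS model on the given pool columns, or None if singular."""
    try:
        model = fit_ols(pool[:, idx], y)
    except (SingularDesignError, np.linalg.LinAlgError):
        return None
    pred = predict_linear(model, pool[:, idx])
    return rsd(y, pred, len(idx)), r_squared(y, pred), model


def exhaustive_best_subset(pool, y, d, pool_names=None, max_combinations=200_000) -> SelectionResult:
    """Enumerate all d-combinations and return the minimum-RSD subset.

    Deterministic oracle for validating the heuristic search; refuses when
    C(p, d) exceeds *max_combinations*.  Ties break to the lexicographically
    smallest index tuple (combinations are enumerated in that order and only
    strict improvements are accepted).
    """
    pool, y = _check_pool(pool, y, d)
    p = pool.shape[1]
    total = comb(p, d)
    if total > max_combinations:
        raise ValueError(f"{total} combinations exceed cap {max_combinations}")
    names = list(pool_names) if pool_names is not None else [f"x{j}" for j in range(p)]
    best = None
    for idx in combinations(range(p), d):
        stats = _subset_stats(pool, y, list(idx))
        if stats is None:
            continue
        if best is None or stats[0] < best[1]:
            best = (idx, stats[0], stats[1])
    if best is None:
        raise SingularDesignError("every candidate subset was singular")
    idx, rsd_val, r2_val = best
    return SelectionResult(
        subset=tuple(names[j] for j in idx),
        indices=tuple(idx),
        rsd=rsd_val,
        r2=r2_val,
        trace=[("exhaustive", tuple(idx), rsd_val)],
    )


def _replacement_pass(pool, y, idx, *, forced_first: bool, max_passes: int,
                      trace: list, label: str):
    """One RM (or modified-RM) pass.  Returns the final index tuple.

    Positions are visited in descending relative standard error of their
    coefficients; a visited position either takes the best strictly
    improving replacement or locks.  With *forced_first* the first visited
    position takes its best replacement unconditionally and is then locked,
    so the escape move cannot be undone within the pass.
    """
    idx = list(idx)
    d = len(idx)
    locked: set[int] = set()
    first = forced_first
    visits = 0
    while len(locked) < d and visits < max_passes:
        visits += 1
        stats = _subset_stats(pool, y, idx)
        if stats is None:
            break
        current_rsd, _, model = stats
        rel_se = np.abs(model.coefficient_ses) / np.maximum(np.abs(model.coefficients), 1e-300)
        order = np.argsort(-rel_se, kind="stable")
        pos = next((int(k) for k in order if k not in locked), None)
        if pos is None:
            break
        in_subset = set(idx)
        best_cand, best_rsd = None, np.inf
        for j in range(pool.shape[1]):
            if j in in_subset:
                continue
            trial = list(idx)
            trial[pos] = j
            st = _subset_stats(pool, y, trial)
            if st is None:
                logger.debug("skipping singular candidate %d at position %d", j, pos)
                continue
            if st[0] < best_rsd:
                best_rsd, best_cand = st[0], j
        if first:
            first = False
            if best_cand is not None:
                idx[pos] = best_cand
                trace.append((label, tuple(idx), best_rsd))
            locked.add(pos)
            continue
        if best_cand is not None and best_rsd < current_rsd:
            idx[pos] = best_cand
            trace.append((label, tuple(idx), best_rsd))
        else:
            locked.add(pos)
    return tuple(idx)


def rm_pass(subset_indices, pool, y, pool_names=None, max_passes: int = 50) -> SelectionResult:
    """Run a single RM pass from the given subset and report the local optimum."""
    d = len(subset_indices)
    pool, y = _check_pool(pool, y, d)
    names = list(pool_names) if pool_names is not None else [f"x{j}" for j in range(pool.shape[1])]
    trace: list = []
    start = _subset_stats(pool, y, list(subset_indices))
    if start is not None:
        trace.append(("start", tuple(subset_indices), start[0]))
    final = _replacement_pass(pool, y, subset_indices, forced_first=False,
                              max_passes=max_passes, trace=trace, label="rm")
    stats = _subset_stats(pool, y, list(final))
    if stats is None:
        raise SingularDesignError("final subset is singular")
    return SelectionResult(
        subset=tuple(names[j] for j in final),
        indices=final,
        rsd=stats[0],
        r2=stats[1],
        trace=trace,
    )


def erm_search(pool, y, config: SelectionConfig, pool_names=None) -> SelectionResult:
    """ERM best-subset search: RM -> modified RM -> RM from random restarts.

    Returns the minimum-RSD subset observed anywhere during the search;
    reproducible under ``config.seed``.
    """
    pool, y = _check_pool(pool, y, config.d)
    p = pool.shape[1]
    names = list(pool_names) if pool_names is not None else [f"x{j}" for j in range(p)]
    rng = np.random.default_rng(config.seed)
    best_idx, best_rsd, best_r2 = None, np.inf, np.nan
    trace: list = []

    def consider(idx, label):
        nonlocal best_idx, best_rsd, best_r2
        st = _subset_stats(pool, y, list(idx))
        if st is None:
            return
        trace.append((label, tuple(idx), st[0]))
        if st[0] < best_rsd:
            best_idx, best_rsd, best_r2 = tuple(idx), st[0], st[1]

    for restart in range(config.n_restarts):
        idx = tuple(int(j) for j in rng.choice(p, size=config.d, replace=False))
        consider(idx, f"init[{restart}]")
        local: list = []
        idx = _replacement_pass(pool, y, idx, forced_first=False,
                                max_passes=config.max_passes, trace=local, label="rm")
        consider(idx, f"rm1[{restart}]")
        idx = _replacement_pass(pool, y, idx, forced_first=True,
                                max_passes=config.max_passes, trace=local, label="mrm")
        consider(idx, f"mrm[{restart}]")
        idx = _replacement_pass(pool, y, idx, forced_first=False,
                                max_passes=config.max_passes, trace=local, label="rm")
        consider(idx, f"rm2[{restart}]")
        # every intermediate subset also competes for "best seen"
        for lbl, sub, _ in local:
            consider(sub, lbl + f"[{restart}]")
    if best_idx is None:
        raise SingularDesignError("no non-singular subset found")
    return SelectionResult(
        subset=tuple(names[j] for j in best_idx),
        indices=best_idx,
        rsd=best_rsd,
        r2=best_r2,
        trace=trace,
    )


def subset_size_scan(pool, y, d_min: int, d_max: int, config: SelectionConfig,
                     pool_names=None, plateau_threshold: float = 0.02):
    """Run ERM for each subset size and pick the plateau point.

    The chosen size is the smallest d whose relative RSD improvement to
    d+1 falls below *plateau_threshold* (default 2%): past that point extra
    descriptors no longer buy predictive power.  d_max is chosen when the
    curve never flattens.
    """
    if d_min < 2:
        raise ValueError("scan starts at d_min >= 2")
    if d_max < d_min:
        raise ValueError("d_max must be >= d_min")
    results = []
    for d in range(d_min, d_max + 1):
        cfg = SelectionConfig(d=d, seed=config.seed + d, n_restarts=config.n_restarts,
                              max_passes=config.max_passes)
        results.append((d, erm_search(pool, y, cfg, pool_names=pool_names)))
    # an RSD at rounding-error level means the subset already fits exactly;
    # further columns only chase noise in the last bits
    zero_floor = max(1e-12, 1e-10 * float(np.std(np.asarray(y, float))))
    chosen = d_max
    for (d, res), (_, nxt) in zip(results, results[1:]):
        if res.rsd <= zero_floor:
            chosen = d
            break
        if (res.rsd - nxt.rsd) / res.rsd < plateau_threshold:
            chosen = d
            break
    if results and results[-1][1].rsd <= zero_floor and chosen == d_max:
        # exact fit first reached at d_max
        chosen = results[-1][0]
    return results, chosen


def scan_to_csv(results) -> str:
    lines = ["d,rsd,r2"]
    lines += [f"{d},{r.rsd!r},{r.r2!r}" for d, r in results]
    return "\n".join(lines) + "\n"
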