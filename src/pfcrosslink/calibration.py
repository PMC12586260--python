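"""Fixed-parameter calibration (linking approach 3, "IRT re-estimation").

The linked instrument's item parameters are re-estimated on the study
sample by marginal maximum likelihood while the anchor instrument's
parameters stay fixed at their original published values.  Fixing the
anchors (and the N(0,1) latent density) transfers the original metric to
the re-estimated items, so EAP scores computed from them are directly on
the anchor T metric.

Estimation is an EM algorithm on a quadrature grid:

* E-step: per-person posterior weights over the grid, using every observed
  item — fixed anchors plus the current free-item parameters — under the
  standard-normal prior.
* M-step: per free item, maximize the expected complete-data log-likelihood
  over (a, b_1..b_{K-1}).  The objective depends on the data only through
  the expected grid x category counts, so each inner maximization is cheap.
  Monotone thresholds are enforced by optimizing (log a, b_1, log-gaps).

The marginal log-likelihood is nondecreasing across cycles (EM ascent);
convergence is declared when the largest absolute parameter change falls
below ``tol``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .grm import (
    ItemParameters,
    QuadratureGrid,
    ResponseMatrix,
    category_probabilities,
    log_likelihood_matrix,
    make_grid,
)

__all__ = [
    "CalibrationResult",
    "initialize_free_items",
    "collapse_sparse_categories",
    "calibrate_fixed",
    "FixedParameterCalibrator",
]


@dataclass
class CalibrationResult:
    free_item_params: list[ItemParameters]
    anchor_params: list[ItemParameters]
    loglik_trace: np.ndarray
    converged: bool
    n_cycles: int
    max_param_change_final: float
    category_maps: dict[str, dict[int, int]] = field(default_factory=dict)


def initialize_free_items(responses: ResponseMatrix, item_ids: list[str], a_init: float = 1.5) -> list[ItemParameters]:
    """Starting values: a = 1.5, thresholds at normal quantiles of the
    observed cumulative category proportions (clipped to [-3.5, 3.5])."""
    init = []
    for iid in item_ids:
        j = responses.item_ids.index(iid)
        obs = responses.values[~responses.missing[:, j], j]
        if obs.size == 0:
            raise ValueError(f"item {iid!r}: no observed responses")
        K = int(obs.max()) if responses.n_categories is None else int(responses.n_categories[j])
        counts = np.bincount(obs, minlength=K + 1)[1:]
        if np.count_nonzero(counts) < 2:
            raise ValueError(f"item {iid!r}: all responses in one category; thresholds undefined")
        cum = np.cumsum(counts)[:-1] / obs.size
        b = np.clip(stats.norm.ppf(cum), -3.5, 3.5)
        # strict ordering even after clipping or empty interior categories
        for k in range(1, b.size):
            if b[k] <= b[k - 1]:
                b[k] = b[k - 1] + 1e-3
        init.append(ItemParameters(item_id=iid, discrimination=a_init, thresholds=tuple(b)))
    return init


def collapse_sparse_categories(
    values: np.ndarray, missing: np.ndarray, n_categories: int, min_count: int = 5
) -> tuple[np.ndarray, dict[int, int], int]:
    """Merge categories observed fewer than ``min_count`` times into their
    neighbor toward the modal category; keeps thresholds identifiable at
    modest n.  Returns (recoded values, old->new map, new K)."""
    obs = values[~missing]
    counts = np.bincount(obs, minlength=n_categories + 1)[1:]
    cats = list(range(1, n_categories + 1))
    mode = cats[int(np.argmax(counts))]
    groups = [[c] for c in cats]  # contiguous groups, merged in place
    counts = list(counts)
    changed = True
    while changed and len(groups) > 2:
        changed = False
        for gi, g in enumerate(groups):
            if counts[gi] < min_count:
                # merge toward the group containing the mode
                target = gi + 1 if g[-1] < mode else gi - 1
                target = min(max(target, 0), len(groups) - 1)
                if target == gi:
                    target = gi - 1 if gi > 0 else gi + 1
                lo, hi = sorted((gi, target))
                groups[lo] = groups[lo] + groups[hi]
                counts[lo] += counts[hi]
                del groups[hi], counts[hi]
                changed = True
                break
    mapping = {}
    for new_k, g in enumerate(groups, start=1):
        for c in g:
            mapping[c] = new_k
    if any(mapping[c] != c for c in cats):
        warnings.warn(f"collapsed sparse categories: {mapping}", stacklevel=2)
    lut = np.array([0] + [mapping[c] for c in cats])
    new_values = np.where(missing, values, lut[np.clip(values, 0, n_categories)])
    return new_values, mapping, len(groups)


def _pack(item: ItemParameters) -> np.ndarray:
    b = np.asarray(item.thresholds)
    return np.concatenate([[np.log(item.discrimination), b[0]], np.log(np.diff(b))]) if b.size > 1 else np.array(
        [np.log(item.discrimination), b[0]]
    )


def _unpack(x: np.ndarray, item_id: str) -> ItemParameters:
    a = float(np.exp(x[0]))
    b = [float(x[1])]
    for g in x[2:]:
        b.append(b[-1] + float(np.exp(g)))
    return ItemParameters(item_id=item_id, discrimination=a, thresholds=tuple(b))


def _m_step_item(item: ItemParameters, r: np.ndarray, nodes: np.ndarray) -> ItemParameters:
    """Maximize expected complete-data log-likelihood for one item.

    ``r`` is the (G, K) table of expected counts per grid node x category.
    """

    def neg(x):
        cand = _unpack(x, item.item_id)
        logp = np.log(category_probabilities(cand, nodes))
        return -float(np.sum(r * logp))

    x0 = _pack(item)
    n_par = x0.size
    bounds = [(np.log(0.05), np.log(12.0)), (-8.0, 8.0)] + [(-6.0, 3.0)] * (n_par - 2)
    res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
    # EM ascent requires the M-step never to decrease the objective
    if res.fun <= neg(x0):
        return _unpack(res.x, item.item_id)
    return item


def calibrate_fixed(
    responses: ResponseMatrix,
    anchor_params: list[ItemParameters],
    init: list[ItemParameters] | None = None,
    grid: QuadratureGrid | None = None,
    tol: float = 1e-4,
    max_cycles: int = 500,
    min_category_count: int = 5,
) -> CalibrationResult:
    """EM re-estimation of the linked instrument with anchors held fixed.

    Every person must have at least one observed item; persons violating
    this (wholly missing questionnaires) are expected to have been screened
    out beforehand.
    """
    grid = grid if grid is not None else make_grid()
    if (responses.missing.all(axis=1)).any():
        raise ValueError("persons with no observed items present; screen them out first")

    anchor_ids = {p.item_id for p in anchor_params}
    free_cols = [j for j, iid in enumerate(responses.item_ids) if iid not in anchor_ids]
    free_ids = [responses.item_ids[j] for j in free_cols]
    if not free_ids:
        raise ValueError("no free items to calibrate")

    # sparse-category collapse on the free items only
    values = responses.values.copy()
    category_maps: dict[str, dict[int, int]] = {}
    item_K: dict[str, int] = {}
    for j, iid in zip(free_cols, free_ids):
        obs = values[~responses.missing[:, j], j]
        K = int(obs.max())
        col, mapping, newK = collapse_sparse_categories(
            values[:, j], responses.missing[:, j], K, min_count=min_category_count
        )
        values[:, j] = col
        item_K[iid] = newK
        if any(mapping[c] != c for c in mapping):
            category_maps[iid] = mapping
    work = ResponseMatrix(
        person_ids=responses.person_ids,
        item_ids=list(responses.item_ids),
        values=values,
        missing=responses.missing,
        instrument=responses.instrument,
    )

    free = list(init) if init is not None else initialize_free_items(work, free_ids)
    if [p.item_id for p in free] != free_ids:
        raise ValueError("init items do not match the free items in the data")
    for p in free:
        if p.n_categories != item_K[p.item_id]:
            raise ValueError(f"init for {p.item_id!r} has K={p.n_categories}, data has K={item_K[p.item_id]}")

    logw = np.log(grid.weights)
    trace = []
    converged = False
    max_change = np.inf
    cycle = 0
    for cycle in range(1, max_cycles + 1):
        bank = anchor_params + free
        ll = log_likelihood_matrix(work, bank, grid)  # (n, G)
        joint = ll + logw[None, :]
        marg = logsumexp(joint, axis=1)
        trace.append(float(marg.sum()))
        post = np.exp(joint - marg[:, None])  # (n, G)

        new_free = []
        max_change = 0.0
        for j, item in zip(free_cols, free):
            obsmask = ~work.missing[:, j]
            v = work.values[obsmask, j]
            K = item.n_categories
            # expected counts r[g, k] = sum_p post[p, g] * 1[x_pj = k+1]
            r = np.zeros((len(grid), K))
            for k in range(K):
                sel = v == k + 1
                if sel.any():
                    r[:, k] = post[obsmask][sel].sum(axis=0)
            updated = _m_step_item(item, r, grid.nodes)
            delta = max(
                abs(updated.discrimination - item.discrimination),
                float(np.max(np.abs(np.array(updated.thresholds) - np.array(item.thresholds)))),
            )
            max_change = max(max_change, delta)
            new_free.append(updated)
        free = new_free
        if max_change < tol:
            converged = True
            break

    # final marginal log-likelihood under the converged parameters
    ll = log_likelihood_matrix(work, anchor_params + free, grid)
    trace.append(float(logsumexp(ll + logw[None, :], axis=1).sum()))

    return CalibrationResult(
        free_item_params=free,
        anchor_params=list(anchor_params),
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_cycles=cycle,
        max_param_change_final=float(max_change),
        category_maps=category_maps,
    )


class FixedParameterCalibrator(BaseEstimator):
    """Sklearn-style wrapper around :func:`calibrate_fixed`.

    Attributes (after ``fit``)
    --------------------------
    free_params_ : list of ItemParameters
    anchor_params_ : list of ItemParameters (unchanged copy of the input)
    loglik_trace_ : ndarray, marginal log-likelihood per EM cycle
    converged_ : bool
    n_cycles_ : int
    """

    def __init__(self, anchor_params=None, grid=None, tol=1e-4, max_cycles=500, min_category_count=5):
        self.anchor_params = anchor_params
        self.grid = grid
        self.tol = tol
        self.max_cycles = max_cycles
        self.min_category_count = min_category_count

    def fit(self, X: ResponseMatrix, y=None, init: list[ItemParameters] | None = None):
        if not self.anchor_params:
            raise ValueError("anchor_params required")
        result = calibrate_fixed(
            X,
            anchor_params=list(self.anchor_params),
            init=init,
            grid=self.grid,
            tol=self.tol,
            max_cycles=self.max_cycles,
            min_category_count=self.min_category_count,
        )
        self.result_ = result
        self.free_params_ = result.free_item_params
        self.anchor_params_ = result.anchor_params
        self.loglik_trace_ = result.loglik_trace
        self.converged_ = result.converged
        self.n_cycles_ = result.n_cycles
        return self
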