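"""EAP response-pattern scoring against fixed item parameters.

This implements both the observed benchmark (scoring the 20-item anchor
short form) and the first linking approach, item-level linking: score the
10-item instrument directly with its parameters from the original joint
calibration, so its EAP estimates land on the anchor metric without any
re-estimation.

Scores are expected-a-posteriori (EAP) trait estimates under a standard
normal prior, computed on a quadrature grid, and reported on the T metric
``T = 50 + 10 * theta`` (reference-population mean 50, SD 10).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, TransformerMixin

from .grm import (
    ItemParameters,
    QuadratureGrid,
    ResponseMatrix,
    log_likelihood_matrix,
    make_grid,
)

__all__ = [
    "theta_to_t",
    "eap_score",
    "EAPScorer",
    "item_level_link",
    "observed_benchmark",
]


def theta_to_t(theta):
    """Linear T-metric transform: T = 50 + 10*theta."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    out = 50.0 + 10.0 * theta
    return float(out) if out.ndim == 0 else out


def _posterior_moments(ll: np.ndarray, grid: QuadratureGrid) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and SD per person from a log-likelihood matrix [n, G]."""
    logpost = ll + np.log(grid.weights)[None, :]
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost)
    mean = post @ grid.nodes
    var = post @ (grid.nodes**2) - mean**2
    return mean, np.sqrt(np.maximum(var, 0.0))


def eap_score(
    values: np.ndarray,
    missing: np.ndarray,
    bank: list[ItemParameters],
    grid: QuadratureGrid | None = None,
) -> tuple[float, float]:
    """EAP estimate (posterior mean, posterior SD) for one response pattern.

    With every response missing the posterior equals the prior, so the
    returned values are the discretized prior mean and SD.
    """
    if len(bank) == 0:
        raise ValueError("empty item bank")
    grid = grid if grid is not None else make_grid()
    rm = ResponseMatrix(
        person_ids=np.array(["_"]),
        item_ids=[it.item_id for it in bank],
        values=np.asarray(values, dtype=int)[None, :],
        missing=np.asarray(missing, dtype=bool)[None, :],
        instrument=np.array(["x"] * len(bank)),
    )
    ll = log_likelihood_matrix(rm, bank, grid)
    mean, sd = _posterior_moments(ll, grid)
    return float(mean[0]), float(sd[0])


class EAPScorer(BaseEstimator, TransformerMixin):
    """Score response patterns by EAP against a fixed item bank.

    Parameters
    ----------
    bank : list of ItemParameters
        Item parameters, treated as known constants (never re-fit here).
    grid : QuadratureGrid, optional
        Discretized scoring prior; defaults to 49 nodes on [-6, 6] with
        standard-normal weights — the prior under which T = 50 + 10*theta
        is meaningful.
    drop_unscorable : bool
        Exclude persons with zero observed items (they carry no data) rather
        than returning the prior for them.

    Attributes
    ----------
    bank_ : list of ItemParameters
        Validated bank in scoring order.
    grid_ : QuadratureGrid
        The grid actually used.
    n_dropped_ : int
        Persons excluded for having no observed item (after ``transform``).
    """

    def __init__(self, bank=None, grid=None, drop_unscorable=True):
        self.bank = bank
        self.grid = grid
        self.drop_unscorable = drop_unscorable

    def fit(self, X=None, y=None):
        if not self.bank:
            raise ValueError("empty item bank")
        for item in self.bank:
            if not isinstance(item, ItemParameters):
                raise TypeError("bank entries must be ItemParameters")
        self.bank_ = list(self.bank)
        self.grid_ = self.grid if self.grid is not None else make_grid()
        return self

    def transform(self, X: ResponseMatrix) -> pd.DataFrame:
        """Score every person; returns one row per scored person.

        Columns: person_id, theta, theta_se, t_score, t_se, n_items_observed.
        """
        if not hasattr(self, "bank_"):
            self.fit()
        n_obs = (~X.missing).sum(axis=1)
        scorable = n_obs > 0
        self.n_dropped_ = int((~scorable).sum()) if self.drop_unscorable else 0
        rm = X.subset_persons(scorable) if self.drop_unscorable else X
        ll = log_likelihood_matrix(rm, self.bank_, self.grid_)
        theta, se = _posterior_moments(ll, self.grid_)
        return pd.DataFrame(
            {
                "person_id": rm.person_ids,
                "theta": theta,
                "theta_se": se,
                "t_score": theta_to_t(theta),
                "t_se": 10.0 * se,
                "n_items_observed": (~rm.missing).sum(axis=1),
            }
        )


def _score_instrument(
    responses: ResponseMatrix,
    params: list[ItemParameters],
    instrument: str,
    method: str,
    grid: QuadratureGrid | None,
) -> pd.DataFrame:
    sub = responses.subset_items(instrument)
    scores = EAPScorer(bank=[p for p in params if p.item_id in set(sub.item_ids)], grid=grid).fit().transform(sub)
    scores.insert(1, "instrument", instrument)
    scores.insert(2, "method", method)
    return scores


def item_level_link(
    responses: ResponseMatrix,
    linked_params: list[ItemParameters],
    grid: QuadratureGrid | None = None,
) -> pd.DataFrame:
    """Linking approach 1: EAP-score the linked instrument with its fixed
    original-metric parameters."""
    return _score_instrument(responses, linked_params, "linked", "item_level", grid)


def observed_benchmark(
    responses: ResponseMatrix,
    anchor_params: list[ItemParameters],
    grid: QuadratureGrid | None = None,
) -> pd.DataFrame:
    """Benchmark T-scores from the anchor instrument's own responses."""
    return _score_instrument(responses, anchor_params, "anchor", "benchmark", grid)
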