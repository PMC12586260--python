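"""Core graded response model (GRM) computations.

The GRM is the standard IRT model for ordered polytomous items, and the
model under which the PROMIS physical-function metric was calibrated.  For
an item with discrimination ``a`` and ordered thresholds ``b_1 < ... <
b_{K-1}``, the cumulative probability of responding in category ``k`` or
above is logistic in the latent trait theta::

    P(X >= k | theta) = 1 / (1 + exp(-a * (theta - b_{k-1})))

and category probabilities are adjacent differences of these curves.  The
pure logistic metric is used throughout (no 1.7 scaling constant), matching
the convention of the PROMIS calibrations.

Everything downstream — pattern scoring, summed-score crosswalks,
fixed-parameter calibration — is built from the three primitives here:
category probabilities, pattern log-likelihoods, and a quadrature grid
discretizing the latent prior.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ItemParameters",
    "QuadratureGrid",
    "ResponseMatrix",
    "category_probabilities",
    "pattern_log_likelihood",
    "log_likelihood_matrix",
    "make_grid",
    "read_item_bank_csv",
    "write_item_bank_csv",
    "read_responses_csv",
    "write_responses_csv",
]

# smallest probability kept when taking logs; far below any quadrature weight
_PROB_FLOOR = 1e-300


@dataclass(frozen=True)
class ItemParameters:
    """Graded-response parameters of one item on the latent metric.

    Parameters
    ----------
    item_id : str
        Identifier, unique within a bank.
    discrimination : float
        Slope ``a`` in the logistic metric; must be positive.
    thresholds : tuple of float
        Ordered category boundaries ``b_1 < ... < b_{K-1}``; the item has
        ``K = len(thresholds) + 1`` response categories coded ``1..K``.
    """

    item_id: str
    discrimination: float
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        a = float(self.discrimination)
        b = np.asarray(self.thresholds, dtype=float)
        if not np.isfinite(a) or a <= 0:
            raise ValueError(f"item {self.item_id!r}: discrimination must be positive, got {a}")
        if b.size < 1 or not np.all(np.isfinite(b)):
            raise ValueError(f"item {self.item_id!r}: thresholds must be finite and non-empty")
        if np.any(np.diff(b) <= 0):
            raise ValueError(f"item {self.item_id!r}: thresholds must be strictly increasing, got {tuple(b)}")
        object.__setattr__(self, "discrimination", a)
        object.__setattr__(self, "thresholds", tuple(float(x) for x in b))

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1


@dataclass(frozen=True)
class QuadratureGrid:
    """Equally spaced latent-trait nodes with a discretized prior density."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.size < 2 or np.any(np.diff(nodes) <= 0):
            raise ValueError("grid nodes must be a strictly increasing 1-d array")
        if weights.shape != nodes.shape or np.any(weights < 0):
            raise ValueError("grid weights must be nonnegative and match nodes")
        if abs(weights.sum() - 1.0) > 1e-12:
            raise ValueError("grid weights must sum to 1 within 1e-12")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    def __len__(self) -> int:
        return self.nodes.size


def make_grid(
    n_nodes: int = 49,
    bounds: tuple[float, float] = (-6.0, 6.0),
    prior_mean: float = 0.0,
    prior_sd: float = 1.0,
) -> QuadratureGrid:
    """Equally spaced quadrature grid with normal-prior weights.

    The default 49 nodes on [-6, 6] resolve EAP estimates to about 1e-3 on
    the theta scale, well below the 0.1-T reporting precision.
    """
    lo, hi = float(bounds[0]), float(bounds[1])
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    if not lo < hi:
        raise ValueError(f"degenerate bounds {bounds}")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    nodes = np.linspace(lo, hi, int(n_nodes))
    weights = stats.norm.pdf(nodes, loc=prior_mean, scale=prior_sd)
    weights = weights / weights.sum()
    return QuadratureGrid(nodes=nodes, weights=weights)


def category_probabilities(item: ItemParameters, thetas: np.ndarray) -> np.ndarray:
    """Category probability matrix ``[G, K]`` for one item over theta values.

    Row ``g`` holds ``P(X = 1..K | theta_g)``; rows sum to 1 by construction.
    """
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    if not np.all(np.isfinite(thetas)):
        raise ValueError("thetas must be finite")
    a = item.discrimination
    b = np.asarray(item.thresholds)
    # cumulative curves P(X >= k+1 | theta), shape (G, K-1)
    cum = 1.0 / (1.0 + np.exp(-a * (thetas[:, None] - b[None, :])))
    ones = np.ones((thetas.size, 1))
    zeros = np.zeros((thetas.size, 1))
    star = np.hstack([ones, cum, zeros])
    probs = star[:, :-1] - star[:, 1:]
    return np.clip(probs, _PROB_FLOOR, 1.0)


@dataclass
class ResponseMatrix:
    """Persons x items integer response categories with missingness.

    ``values[p, i]`` holds the category (coded ``1..K_i``) of person ``p`` on
    item ``i``; entries where ``missing`` is True are ignored everywhere.
    ``instrument[i]`` labels each item as belonging to the anchor instrument
    (the 20-item benchmark short form) or the linked one (the 10-item scale).
    """

    person_ids: np.ndarray
    item_ids: list[str]
    values: np.ndarray
    missing: np.ndarray
    instrument: np.ndarray
    n_categories: np.ndarray = field(default=None)  # per item, optional

    def __post_init__(self) -> None:
        self.person_ids = np.asarray(self.person_ids)
        self.values = np.asarray(self.values, dtype=int)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.instrument = np.asarray(self.instrument)
        n, p = self.values.shape
        if self.person_ids.shape != (n,) or self.missing.shape != (n, p):
            raise ValueError("person_ids / missing shapes inconsistent with values")
        if len(self.item_ids) != p or self.instrument.shape != (p,):
            raise ValueError("item_ids / instrument length inconsistent with values")
        if self.instrument.size == 0:
            raise ValueError("at least one instrument label required")
        if self.n_categories is not None:
            self.n_categories = np.asarray(self.n_categories, dtype=int)
            obs = np.where(self.missing, 1, self.values)
            if np.any(obs < 1) or np.any(obs > self.n_categories[None, :]):
                raise ValueError("observed response outside [1, K_i] for some item")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def item_index(self, instrument: str | None = None) -> np.ndarray:
        if instrument is None:
            return np.arange(self.n_items)
        return np.flatnonzero(self.instrument == instrument)

    def subset_items(self, instrument: str) -> "ResponseMatrix":
        idx = self.item_index(instrument)
        if idx.size == 0:
            raise ValueError(f"no items labelled {instrument!r}")
        return ResponseMatrix(
            person_ids=self.person_ids,
            item_ids=[self.item_ids[i] for i in idx],
            values=self.values[:, idx],
            missing=self.missing[:, idx],
            instrument=self.instrument[idx],
            n_categories=None if self.n_categories is None else self.n_categories[idx],
        )

    def subset_persons(self, keep: np.ndarray) -> "ResponseMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ResponseMatrix(
            person_ids=self.person_ids[keep],
            item_ids=list(self.item_ids),
            values=self.values[keep],
            missing=self.missing[keep],
            instrument=self.instrument,
            n_categories=self.n_categories,
        )


def _validate_pattern(values: np.ndarray, missing: np.ndarray, bank: list[ItemParameters]) -> None:
    if values.shape != (len(bank),) or missing.shape != (len(bank),):
        raise ValueError("pattern length does not match bank")
    for v, m, item in zip(values, missing, bank):
        if not m and not (1 <= v <= item.n_categories):
            raise ValueError(f"item {item.item_id!r}: category {v} outside [1, {item.n_categories}]")


def pattern_log_likelihood(
    values: np.ndarray,
    missing: np.ndarray,
    bank: list[ItemParameters],
    theta: float,
) -> float:
    """Log-likelihood of one response pattern at a single theta.

    Missing items contribute nothing (ignorable-missingness contract); an
    all-missing pattern therefore has log-likelihood 0.
    """
    values = np.asarray(values, dtype=int)
    missing = np.asarray(missing, dtype=bool)
    _validate_pattern(values, missing, bank)
    total = 0.0
    for v, m, item in zip(values, missing, bank):
        if m:
            continue
        p = category_probabilities(item, np.array([theta]))[0, v - 1]
        total += float(np.log(p))
    return total


def log_likelihood_matrix(responses: ResponseMatrix, bank: list[ItemParameters], grid: QuadratureGrid) -> np.ndarray:
    """Log-likelihood of every person's pattern at every grid node, ``[n, G]``.

    Vectorized over persons; the per-item loop is over at most a few dozen
    items so it dominates nothing.
    """
    if len(bank) == 0:
        raise ValueError("empty item bank")
    by_id = {it.item_id: it for it in bank}
    missing_ids = [iid for iid in responses.item_ids if iid not in by_id]
    if missing_ids:
        raise ValueError(f"bank lacks parameters for items: {missing_ids}")
    n, G = responses.n_persons, len(grid)
    ll = np.zeros((n, G))
    for j, iid in enumerate(responses.item_ids):
        item = by_id[iid]
        obs = ~responses.missing[:, j]
        if not obs.any():
            continue
        v = responses.values[obs, j]
        if v.min() < 1 or v.max() > item.n_categories:
            raise ValueError(f"item {iid!r}: observed category outside [1, {item.n_categories}]")
        logp = np.log(category_probabilities(item, grid.nodes))  # (G, K)
        ll[obs, :] += logp[:, v - 1].T
    return ll


# ---------------------------------------------------------------------------
# file formats
#
# Item-parameter CSV: item_id, instrument, n_categories, a, b1..b4 (unused b
# columns empty).  Response CSV: first column person_id, one column per item,
# missing cells empty.

_B_COLS = ["b1", "b2", "b3", "b4"]


def write_item_bank_csv(path, bank: list[ItemParameters], instrument: dict[str, str] | str = "anchor") -> None:
    rows = []
    for item in bank:
        label = instrument if isinstance(instrument, str) else instrument[item.item_id]
        row = {
            "item_id": item.item_id,
            "instrument": label,
            "n_categories": item.n_categories,
            "a": repr(float(item.discrimination)),
        }
        for k, col in enumerate(_B_COLS):
            row[col] = repr(float(item.thresholds[k])) if k < len(item.thresholds) else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_item_bank_csv(path) -> tuple[list[ItemParameters], dict[str, str]]:
    """Read an item-parameter CSV; returns (bank, item_id -> instrument map)."""
    df = pd.read_csv(path, dtype={"item_id": str, "instrument": str})
    bank, labels = [], {}
    for _, row in df.iterrows():
        K = int(row["n_categories"])
        b = [float(row[c]) for c in _B_COLS[: K - 1]]
        bank.append(ItemParameters(item_id=str(row["item_id"]), discrimination=float(row["a"]), thresholds=tuple(b)))
        labels[str(row["item_id"])] = str(row["instrument"])
    return bank, labels


def write_responses_csv(path, responses: ResponseMatrix) -> None:
    df = pd.DataFrame(
        np.where(responses.missing, np.nan, responses.values),
        columns=responses.item_ids,
    )
    df.insert(0, "person_id", responses.person_ids)
    df.to_csv(path, index=False, float_format="%.0f")


def read_responses_csv(path, instrument_labels: dict[str, str], default_label: str | None = None) -> ResponseMatrix:
    df = pd.read_csv(path, dtype={"person_id": str})
    item_ids = [c for c in df.columns if c != "person_id"]
    unknown = [c for c in item_ids if c not in instrument_labels]
    if unknown and default_label is None:
        raise ValueError(f"response columns without an instrument label: {unknown}")
    if unknown:
        instrument_labels = {**instrument_labels, **{c: default_label for c in unknown}}
    raw = df[item_ids].to_numpy(dtype=float)
    missing = ~np.isfinite(raw)
    values = np.where(missing, 1, raw).astype(int)
    return ResponseMatrix(
        person_ids=df["person_id"].to_numpy(),
        item_ids=item_ids,
        values=values,
        missing=missing,
        instrument=np.array([instrument_labels[c] for c in item_ids]),
    )
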