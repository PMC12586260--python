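"""Raw-summed-score to T-score crosswalk tables (linking approach 2).

A crosswalk table maps each achievable raw summed score of an instrument to
a latent-trait estimate and T-score, so scores can be converted by lookup
with no modelling software.  The table is built from item parameters by the
Lord–Wingersky recursion, which produces the conditional distribution of
the summed score given theta, followed by summed-score EAP against the
scoring prior:

    theta(s) = sum_g theta_g w_g L(s|theta_g) / sum_g w_g L(s|theta_g)

With items scored by their category indices 1..K_i, the raw score of a
10-item, 3-category instrument ranges over 10..30 — 21 table rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .grm import ItemParameters, QuadratureGrid, category_probabilities, make_grid
from .scoring import theta_to_t

__all__ = [
    "summed_score_likelihoods",
    "CrosswalkTable",
    "build_crosswalk",
    "apply_crosswalk",
    "CrosswalkLinker",
]


def summed_score_likelihoods(
    bank: list[ItemParameters], grid: QuadratureGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Lord–Wingersky recursion: L(s | theta_g) for every achievable sum s.

    Returns ``(scores, L)`` with ``L`` of shape ``[n_scores, G]``; each
    column sums to 1 (total probability over summed scores).
    """
    if len(bank) == 0:
        raise ValueError("empty item bank")
    G = len(grid)
    # category k of item i contributes k to the sum (1-based coding)
    probs = [category_probabilities(item, grid.nodes) for item in bank]  # each (G, K_i)
    s_min = len(bank)
    L = probs[0].T.copy()  # rows indexed by s - 1 for the first item
    for P in probs[1:]:
        K = P.shape[1]
        n_old = L.shape[0]
        new = np.zeros((n_old + K - 1, G))
        for k in range(K):
            new[k : k + n_old] += L * P.T[k][None, :]
        L = new
    scores = np.arange(s_min, s_min + L.shape[0])
    return scores, L


@dataclass
class CrosswalkTable:
    """Lookup from raw summed score to (theta, SE, T, T-SE).

    ``table`` has one row per achievable raw score, contiguous from the
    minimum to the maximum; ``meta`` records the bank and grid it was built
    from.
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = self.table["raw_score"].to_numpy()
        if not np.array_equal(s, np.arange(s[0], s[-1] + 1)):
            raise ValueError("raw scores must be contiguous integers")

    @property
    def s_min(self) -> int:
        return int(self.table["raw_score"].iloc[0])

    @property
    def s_max(self) -> int:
        return int(self.table["raw_score"].iloc[-1])

    def to_csv(self, path) -> None:
        """Write table with ``#`` metadata header lines; full-precision repr
        so a read/write round trip is bit-exact."""
        lines = [f"# {k}={v}" for k, v in sorted(self.meta.items())]
        lines.append("raw_score,theta,theta_se,t_score,t_se")
        for _, row in self.table.iterrows():
            lines.append(
                f"{int(row.raw_score)},{float(row.theta)!r},{float(row.theta_se)!r},"
                f"{float(row.t_score)!r},{float(row.t_se)!r}"
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path) -> "CrosswalkTable":
        meta = {}
        with open(path) as fh:
            lines = fh.read().splitlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k.strip()] = v.strip()
                body_start = i + 1
            else:
                break
        header = lines[body_start].split(",")
        rows = [dict(zip(header, ln.split(","))) for ln in lines[body_start + 1 :] if ln]
        df = pd.DataFrame(rows)
        df["raw_score"] = df["raw_score"].astype(int)
        for c in header[1:]:
            df[c] = df[c].astype(float)
        return cls(table=df, meta=meta)


def build_crosswalk(
    bank: list[ItemParameters],
    grid: QuadratureGrid | None = None,
    meta: dict | None = None,
) -> CrosswalkTable:
    """Build the summed-score EAP crosswalk table for an item bank."""
    grid = grid if grid is not None else make_grid()
    scores, L = summed_score_likelihoods(bank, grid)
    post = L * grid.weights[None, :]
    norm = post.sum(axis=1)
    theta = (post @ grid.nodes) / norm
    var = (post @ grid.nodes**2) / norm - theta**2
    se = np.sqrt(np.maximum(var, 0.0))
    df = pd.DataFrame(
        {
            "raw_score": scores,
            "theta": theta,
            "theta_se": se,
            "t_score": theta_to_t(theta),
            "t_se": 10.0 * se,
        }
    )
    info = {"n_items": len(bank), "grid": f"{len(grid)}@[{grid.nodes[0]},{grid.nodes[-1]}]"}
    if meta:
        info.update(meta)
    return CrosswalkTable(table=df, meta=info)


def apply_crosswalk(raw_scores: np.ndarray, table: CrosswalkTable) -> pd.DataFrame:
    """Exact table lookup of raw summed scores (no interpolation).

    The tabulated range is mathematically exhaustive for the bank the table
    was built from, so an out-of-range score signals corrupt input and
    raises, naming the offending position.
    """
    raw = np.asarray(raw_scores)
    if not np.issubdtype(raw.dtype, np.integer):
        if np.any(raw != np.round(raw)):
            raise ValueError("raw scores must be integers")
        raw = raw.astype(int)
    bad = (raw < table.s_min) | (raw > table.s_max)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"raw score {raw[i]} at position {i} outside table range [{table.s_min}, {table.s_max}]"
        )
    rows = table.table.iloc[raw - table.s_min].reset_index(drop=True)
    return rows.copy()


class CrosswalkLinker(BaseEstimator, TransformerMixin):
    """Crosswalk linking as a transformer: fit builds the table from item
    parameters, transform maps complete response patterns via their raw sum.

    Attributes
    ----------
    table_ : CrosswalkTable
        The fitted lookup table.
    n_skipped_ : int
        Persons skipped at transform time for incomplete patterns (a raw
        sum requires every item; complete-case rule).
    """

    def __init__(self, bank=None, grid=None):
        self.bank = bank
        self.grid = grid

    def fit(self, X=None, y=None):
        if not self.bank:
            raise ValueError("empty item bank")
        self.table_ = build_crosswalk(self.bank, self.grid)
        return self

    def transform(self, X) -> pd.DataFrame:
        """X: a ResponseMatrix restricted to the table's instrument.

        Returns person_id plus the looked-up score columns.
        """
        complete = ~X.missing.any(axis=1)
        self.n_skipped_ = int((~complete).sum())
        sums = X.values[complete].sum(axis=1)
        out = apply_crosswalk(sums, self.table_)
        out.insert(0, "person_id", X.person_ids[complete])
        out.insert(1, "method", "crosswalk")
        return out
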