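"""Pre-linking assumption screening.

Unidimensional IRT linking assumes the pooled item set measures one
construct and that items behave the same across groups.  Two families of
checks are implemented:

* dimensionality — a one-factor unweighted-least-squares (ULS) fit on the
  polychoric correlation matrix with the usual indices (CFI, TLI, RMSEA,
  SRMR), plus an exploratory bifactor decomposition (Schmid-Leiman
  orthogonalization of an oblique solution) summarized by explained common
  variance (ECV) and hierarchical omega;
* differential item functioning (DIF) — nested proportional-odds models
  per item (trait; + group; + trait x group) compared by the change in
  Nagelkerke pseudo-R2, with change > 0.03 flagging potentially relevant
  DIF.

Benchmark flags follow the conventional criteria: CFI > 0.95, TLI > 0.95,
RMSEA < 0.06, SRMR < 0.08, ECV > 0.60, omega_H > 0.80.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .grm import ResponseMatrix

__all__ = [
    "DimensionalityReport",
    "DIFReport",
    "polychoric_matrix",
    "one_factor_fit",
    "bifactor_ecv_omega",
    "dif_screen",
    "DEFAULT_BENCHMARKS",
]

DEFAULT_BENCHMARKS = {
    "cfi": (">", 0.95),
    "tli": (">", 0.95),
    "rmsea": ("<", 0.06),
    "srmr": ("<", 0.08),
    "ecv": (">", 0.60),
    "omega_h": (">", 0.80),
}


# ---------------------------------------------------------------------------
# bivariate normal CDF via quadrature on the correlation path:
# Phi2(h, k, rho) = Phi(h) Phi(k) + integral_0^rho phi2(h, k, r) dr
# (vectorized over h, k; accurate to ~1e-7 with 48 Gauss-Legendre points)

_GL_X, _GL_W = np.polynomial.legendre.leggauss(48)


def _bvn_cdf(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    base = stats.norm.cdf(h) * stats.norm.cdf(k)
    if rho == 0.0:
        return base
    r = 0.5 * rho * (_GL_X + 1.0)  # nodes on (0, rho)
    w = 0.5 * rho * _GL_W
    hh, kk = h[..., None], k[..., None]
    om = 1.0 - r**2
    with np.errstate(invalid="ignore"):
        dens = np.exp(-(hh**2 - 2.0 * r * hh * kk + kk**2) / (2.0 * om)) / (2.0 * np.pi * np.sqrt(om))
    # infinite limits contribute nothing beyond the product term
    dens = np.where(np.isfinite(hh) & np.isfinite(kk), dens, 0.0)
    return base + (dens * w).sum(axis=-1)


def _cell_probs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of a discretized bivariate normal.

    tau_x, tau_y: thresholds with -inf/+inf sentinels included.
    """
    H, K = np.meshgrid(tau_x, tau_y, indexing="ij")
    F = _bvn_cdf(H, K, rho)
    return F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]


def _concordance(table: np.ndarray) -> tuple[float, float]:
    """Concordant and discordant pair counts of a contingency table."""
    nr, nc = table.shape
    conc = disc = 0.0
    for i in range(nr):
        for j in range(nc):
            if table[i, j] == 0:
                continue
            conc += table[i, j] * table[i + 1 :, j + 1 :].sum()
            disc += table[i, j] * table[i + 1 :, :j].sum()
    return conc, disc


def _pair_polychoric(table: np.ndarray) -> float:
    """Two-step ML polychoric for one contingency table (categories x categories)."""
    # perfect monotone association: the bounded optimizer cannot reach +/-1
    conc, disc = _concordance(table)
    if conc > 0 and disc == 0 and table.shape[0] == table.shape[1] and np.all(table == np.diag(np.diag(table))):
        return 1.0
    if disc > 0 and conc == 0 and np.all(table == np.fliplr(np.diag(np.diag(np.fliplr(table))))):
        return -1.0
    nx = table.sum(axis=1)
    ny = table.sum(axis=0)
    n = table.sum()
    tau_x = np.concatenate([[-np.inf], stats.norm.ppf(np.cumsum(nx)[:-1] / n), [np.inf]])
    tau_y = np.concatenate([[-np.inf], stats.norm.ppf(np.cumsum(ny)[:-1] / n), [np.inf]])

    def negll(rho):
        p = np.clip(_cell_probs(tau_x, tau_y, rho), 1e-12, 1.0)
        return -float(np.sum(table * np.log(p)))

    res = optimize.minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded",
                                   options={"xatol": 1e-6})
    return float(res.x)


def polychoric_matrix(responses: ResponseMatrix | np.ndarray) -> np.ndarray:
    """Pairwise two-step ML polychoric correlation matrix.

    Falls back to a Spearman correlation (with a warning) for a pair whose
    contingency structure leaves the latent correlation inestimable.
    """
    if isinstance(responses, ResponseMatrix):
        values, missing = responses.values, responses.missing
    else:
        values = np.asarray(responses, dtype=int)
        missing = np.zeros_like(values, dtype=bool)
    n, p = values.shape
    if p < 2:
        raise ValueError("need at least 2 items")
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            ok = ~missing[:, i] & ~missing[:, j]
            x, y = values[ok, i], values[ok, j]
            cx = np.unique(x)
            cy = np.unique(y)
            if cx.size < 2 or cy.size < 2:
                warnings.warn(f"pair ({i},{j}): a margin is constant; falling back to Spearman", stacklevel=2)
                rho = stats.spearmanr(x, y).statistic if cx.size > 1 or cy.size > 1 else 0.0
                rho = 0.0 if not np.isfinite(rho) else float(rho)
            else:
                table = np.zeros((cx.size, cy.size))
                for a, cxa in enumerate(cx):
                    for b, cyb in enumerate(cy):
                        table[a, b] = np.sum((x == cxa) & (y == cyb))
                try:
                    rho = _pair_polychoric(table)
                except Exception:
                    warnings.warn(f"pair ({i},{j}): polychoric inestimable; Spearman fallback", stacklevel=2)
                    rho = float(stats.spearmanr(x, y).statistic)
            R[i, j] = R[j, i] = rho
    return R


def _repair_psd(R: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= 1e-6:
        return R
    vals = np.clip(vals, 1e-6, None)
    R2 = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(R2))
    return R2 / np.outer(d, d)


def _principal_axis(R: np.ndarray, n_factors: int, max_iter: int = 500, tol: float = 1e-8) -> np.ndarray:
    """Iterated principal-axis (ULS) factor extraction; returns loadings [p, m]."""
    p = R.shape[0]
    h2 = 1.0 - 1.0 / np.maximum(np.diag(np.linalg.inv(R)), 1.0)  # SMC start
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        vals, vecs = np.linalg.eigh(Rr)
        idx = np.argsort(vals)[::-1][:n_factors]
        lam = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0.0, None))
        new_h2 = np.clip((lam**2).sum(axis=1), 0.0, 0.995)  # Heywood guard
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            break
        h2 = new_h2
    Rr = R.copy()
    np.fill_diagonal(Rr, h2)
    vals, vecs = np.linalg.eigh(Rr)
    idx = np.argsort(vals)[::-1][:n_factors]
    lam = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0.0, None))
    # sign convention: dominant direction positive
    for f in range(lam.shape[1]):
        if lam[:, f].sum() < 0:
            lam[:, f] = -lam[:, f]
    return lam


@dataclass
class DimensionalityReport:
    polychoric: np.ndarray
    loadings: np.ndarray
    fit: dict
    bifactor: dict
    benchmark_flags: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        out = []
        values = {**self.fit, **self.bifactor}
        for key, (op, crit) in DEFAULT_BENCHMARKS.items():
            if key in values:
                out.append(
                    {
                        "statistic": key,
                        "criterion": f"{op} {crit}",
                        "result": values[key],
                        "pass": bool(self.benchmark_flags.get(key)),
                    }
                )
        return {"indices": out}


def one_factor_fit(poly: np.ndarray, n: int) -> dict:
    """One-factor ULS fit indices on a polychoric matrix.

    The discrepancy is the sum of squared off-diagonal residual
    correlations; T = (n-1) F gives a chi-square-type statistic from which
    CFI, TLI and RMSEA are formed against the independence baseline.
    """
    R = _repair_psd(np.asarray(poly, dtype=float))
    p = R.shape[0]
    lam = _principal_axis(R, 1)[:, 0]
    resid = R - np.outer(lam, lam)
    iu = np.triu_indices(p, 1)
    F_m = float(np.sum(resid[iu] ** 2))
    F_0 = float(np.sum(R[iu] ** 2))
    df_m = p * (p - 1) // 2 - p
    df_0 = p * (p - 1) // 2
    T_m, T_0 = (n - 1) * F_m, (n - 1) * F_0
    eps = 1e-12
    cfi = 1.0 - max(T_m - df_m, 0.0) / max(T_0 - df_0, T_m - df_m, eps)
    tli_den = max(T_0 / df_0 - 1.0, eps)
    tli = min((T_0 / df_0 - T_m / max(df_m, 1)) / tli_den, 1.0)
    rmsea = float(np.sqrt(max(T_m - df_m, 0.0) / (max(df_m, 1) * (n - 1))))
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    return {"cfi": float(cfi), "tli": float(tli), "rmsea": rmsea, "srmr": srmr, "loadings": lam}


def _varimax(L: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    p, m = L.shape
    Rot = np.eye(m)
    var = 0.0
    for _ in range(max_iter):
        Lr = L @ Rot
        u, s, vt = np.linalg.svd(L.T @ (Lr**3 - Lr * (Lr**2).sum(axis=0) / p))
        Rot = u @ vt
        new_var = s.sum()
        if new_var < var * (1 + tol):
            break
        var = new_var
    return L @ Rot


def _promax(L: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Promax rotation: varimax, then oblique fit to the powered target.

    Returns (pattern matrix, factor correlation matrix)."""
    V = _varimax(L)
    target = np.sign(V) * np.abs(V) ** power
    Q, *_ = np.linalg.lstsq(V, target, rcond=None)
    d = np.sqrt(np.diag(np.linalg.inv(Q.T @ Q)))
    Q = Q * d[None, :]
    pattern = V @ Q
    Qinv = np.linalg.inv(Q)
    Phi = Qinv @ Qinv.T
    d2 = np.sqrt(np.diag(Phi))
    Phi = Phi / np.outer(d2, d2)
    return pattern, Phi


def bifactor_ecv_omega(poly: np.ndarray, n: int, n_group_factors: int = 4) -> tuple[float, float, np.ndarray]:
    """Exploratory bifactor indices via Schmid-Leiman orthogonalization.

    An oblique ``n_group_factors`` solution (principal axis + promax) is
    decomposed into a general factor (from a one-factor model of the factor
    correlations) plus orthogonal group factors.  ECV is the share of common
    variance on the general factor; omega_h the reliability attributable to
    it.  The default of 4 group factors mirrors the physical-function
    subdomains (mobility, dexterity, central regions, complex activities).
    """
    R = _repair_psd(np.asarray(poly, dtype=float))
    p = R.shape[0]
    if n_group_factors < 1:
        raise ValueError("n_group_factors must be >= 1")
    if n_group_factors >= p / 3:
        raise ValueError("too many group factors for the item count")
    L = _principal_axis(R, n_group_factors)
    if n_group_factors == 1:
        general = L[:, 0]
        group = np.zeros((p, 1))
    else:
        pattern, Phi = _promax(L)
        # second-order one-factor model of the factor correlations
        gamma = _principal_axis(_repair_psd(Phi), 1)[:, 0]
        gamma = np.clip(gamma, -0.999, 0.999)
        general = pattern @ gamma
        group = pattern * np.sqrt(1.0 - gamma**2)[None, :]
    lam2_g = float(np.sum(general**2))
    lam2_grp = float(np.sum(group**2))
    ecv = lam2_g / max(lam2_g + lam2_grp, 1e-12)
    h2 = np.clip(general**2 + (group**2).sum(axis=1), 0.0, 1.0)
    uniq = float(np.sum(1.0 - h2))
    total_var = general.sum() ** 2 + float(np.sum(group.sum(axis=0) ** 2)) + uniq
    omega_h = float(general.sum() ** 2 / max(total_var, 1e-12))
    loadings = np.column_stack([general, group])
    return float(np.clip(ecv, 0.0, 1.0)), float(np.clip(omega_h, 0.0, 1.0)), loadings


def dimensionality_report(responses: ResponseMatrix, n_group_factors: int = 4,
                          benchmarks: dict = DEFAULT_BENCHMARKS) -> DimensionalityReport:
    """Convenience wrapper: polychorics, one-factor fit, bifactor indices,
    and pass flags against the configured benchmarks."""
    R = polychoric_matrix(responses)
    n = responses.n_persons
    fit = one_factor_fit(R, n)
    loadings = fit.pop("loadings")
    ecv, omega_h, bl = bifactor_ecv_omega(R, n, n_group_factors)
    bifactor = {"ecv": ecv, "omega_h": omega_h}
    values = {**fit, **bifactor}
    flags = {}
    for key, (op, crit) in benchmarks.items():
        if key in values:
            flags[key] = values[key] > crit if op == ">" else values[key] < crit
    return DimensionalityReport(polychoric=R, loadings=loadings, fit=fit, bifactor=bifactor, benchmark_flags=flags)


# ---------------------------------------------------------------------------
# DIF screening


@dataclass
class DIFReport:
    table: pd.DataFrame  # per item: loglik m1/m2/m3, r2 m1/m2/m3, delta_r2, flagged
    threshold: float

    @property
    def flagged_items(self) -> list[str]:
        return list(self.table.loc[self.table["flagged"], "item_id"])


def _nagelkerke(ll_model: float, ll_null: float, n: int) -> float:
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll_null - ll_model))
    max_cs = 1.0 - np.exp((2.0 / n) * ll_null)
    return float(cox_snell / max_cs)


def _fit_ordinal(y: np.ndarray, X: np.ndarray) -> float:
    """Log-likelihood of a proportional-odds logit fit; coefficient blow-ups
    (separation) are clipped by the optimizer bounds on iterations."""
    model = OrderedModel(y, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=200, disp=False)
        if not np.all(np.isfinite(res.params)) or np.any(np.abs(res.params[: X.shape[1]]) > 20):
            res = model.fit(method="lbfgs", maxiter=200, disp=False)
    return float(res.llf)


def dif_screen(
    responses: ResponseMatrix,
    group: np.ndarray,
    trait: np.ndarray,
    threshold: float = 0.03,
    min_group_size: int = 20,
) -> DIFReport:
    """Per-item DIF screen by nested proportional-odds models.

    M1: item ~ trait; M2: + group; M3: + trait x group.  The reported
    change is Nagelkerke R2(M3) - R2(M1) against an intercept-only
    baseline, so uniform and non-uniform DIF are tested jointly; values
    above ``threshold`` are flagged.
    """
    group = np.asarray(group)
    trait = np.asarray(trait, dtype=float)
    if not np.all(np.isfinite(trait)):
        raise ValueError("trait must be finite")
    levels, counts = np.unique(group, return_counts=True)
    if levels.size < 2:
        raise ValueError("group must have at least 2 levels")
    if counts.min() < min_group_size:
        raise ValueError(f"every group level needs >= {min_group_size} persons")
    # dummy coding, first level as reference
    dummies = np.column_stack([(group == lv).astype(float) for lv in levels[1:]])

    rows = []
    for j, iid in enumerate(responses.item_ids):
        obs = ~responses.missing[:, j]
        y = responses.values[obs, j].astype(float)
        cats, cnt = np.unique(y, return_counts=True)
        # collapse categories empty within any group level for a stable fit
        if cats.size < 2:
            continue
        t = trait[obs]
        d = dummies[obs]
        n = y.size
        _, ncat = np.unique(y, return_inverse=True)
        counts_k = np.bincount(ncat)
        ll0 = float(np.sum(counts_k * np.log(counts_k / n)))
        X1 = t[:, None]
        X2 = np.column_stack([t[:, None], d])
        X3 = np.column_stack([t[:, None], d, t[:, None] * d])
        try:
            ll1 = _fit_ordinal(y, X1)
            ll2 = max(_fit_ordinal(y, X2), ll1)
            ll3 = max(_fit_ordinal(y, X3), ll2)
        except Exception as exc:  # separation or optimizer failure
            warnings.warn(f"item {iid!r}: DIF fit failed ({exc}); skipped", stacklevel=2)
            continue
        r2 = [_nagelkerke(ll, ll0, n) for ll in (ll1, ll2, ll3)]
        delta = max(r2[2] - r2[0], 0.0)
        rows.append(
            {
                "item_id": iid, "n": n,
                "loglik_m1": ll1, "loglik_m2": ll2, "loglik_m3": ll3,
                "r2_m1": r2[0], "r2_m2": r2[1], "r2_m3": r2[2],
                "delta_r2": delta, "flagged": delta > threshold,
            }
        )
    return DIFReport(table=pd.DataFrame(rows), threshold=threshold)
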