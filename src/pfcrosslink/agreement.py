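"""Agreement between observed (benchmark) and linked T-scores.

Conventions, fixed package-wide:

* mean difference MD = mean(observed - linked); its sample SD uses n-1;
* MAE = mean |observed - linked|, RMSE = sqrt(mean (observed - linked)^2),
  so RMSE^2 = MD^2 + SD^2 (n-1)/n holds identically;
* paired SMD = MD / sqrt((SD_obs^2 + SD_linked^2) / 2) — the pooled SD of
  the two score sets, with |SMD| < 0.2 read as a negligible group-level
  difference;
* bootstrap CIs are percentile intervals over person-level resamples;
* Bland-Altman limits of agreement are MD +/- 1.96 SD of the differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AgreementReport",
    "smd_from_summary",
    "score_agreement",
    "bootstrap_ci",
    "bland_altman",
    "round_half_away",
]


def round_half_away(x, ndigits: int = 2):
    """Round half away from zero (report-table convention), elementwise."""
    x = np.asarray(x, dtype=float)
    factor = 10.0**ndigits
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


def smd_from_summary(mean_diff: float, sd_a: float, sd_b: float) -> float:
    """Paired standardized mean difference with pooled-SD denominator."""
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("SDs must be positive")
    return float(mean_diff / math.sqrt((sd_a**2 + sd_b**2) / 2.0))


@dataclass
class AgreementStats:
    n: int
    pearson_r: float | None
    mean_diff: float
    sd_diff: float
    mae: float
    rmse: float
    smd: float | None
    loa: tuple[float, float]
    ci_mae: tuple[float, float] | None = None
    ci_rmse: tuple[float, float] | None = None
    ci_smd: tuple[float, float] | None = None
    r_undefined: bool = False


@dataclass
class AgreementReport:
    overall: AgreementStats
    by_subsample: dict[str, AgreementStats] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, s in [("analytic", self.overall)] + list(self.by_subsample.items()):
            rows.append(
                {
                    "sample": name,
                    "n": s.n,
                    "r": s.pearson_r,
                    "MD": s.mean_diff,
                    "SD": s.sd_diff,
                    "MAE": s.mae,
                    "MAE_lo": None if s.ci_mae is None else s.ci_mae[0],
                    "MAE_hi": None if s.ci_mae is None else s.ci_mae[1],
                    "RMSE": s.rmse,
                    "RMSE_lo": None if s.ci_rmse is None else s.ci_rmse[0],
                    "RMSE_hi": None if s.ci_rmse is None else s.ci_rmse[1],
                    "SMD": s.smd,
                    "SMD_lo": None if s.ci_smd is None else s.ci_smd[0],
                    "SMD_hi": None if s.ci_smd is None else s.ci_smd[1],
                }
            )
        return pd.DataFrame(rows)


def _stats(observed: np.ndarray, linked: np.ndarray) -> AgreementStats:
    n = observed.size
    diff = observed - linked
    md = float(diff.mean())
    sd = float(diff.std(ddof=1)) if n > 1 else 0.0
    mae = float(np.abs(diff).mean())
    rmse = float(np.sqrt((diff**2).mean()))
    sd_o, sd_l = observed.std(ddof=1), linked.std(ddof=1)
    undefined = sd_o <= 0 or sd_l <= 0
    r = None if undefined else float(np.corrcoef(observed, linked)[0, 1])
    smd = None if undefined else smd_from_summary(md, sd_o, sd_l)
    return AgreementStats(
        n=n, pearson_r=r, mean_diff=md, sd_diff=sd, mae=mae, rmse=rmse, smd=smd,
        loa=(md - 1.96 * sd, md + 1.96 * sd), r_undefined=undefined,
    )


def _mae(obs, lnk):
    return float(np.abs(obs - lnk).mean())


def _rmse(obs, lnk):
    return float(np.sqrt(((obs - lnk) ** 2).mean()))


def _smd(obs, lnk):
    sd_o, sd_l = obs.std(ddof=1), lnk.std(ddof=1)
    if sd_o <= 0 or sd_l <= 0:
        return float((obs - lnk).mean() == 0) * 0.0
    return smd_from_summary(float((obs - lnk).mean()), sd_o, sd_l)


_STATISTICS = {"MAE": _mae, "RMSE": _rmse, "SMD": _smd}


def bootstrap_ci(
    observed: np.ndarray,
    linked: np.ndarray,
    statistic: str,
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile 95% bootstrap CI for MAE, RMSE or SMD over person-level
    resamples with replacement; deterministic given the seed."""
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {sorted(_STATISTICS)}")
    if B < 200:
        raise ValueError("B must be >= 200")
    observed = np.asarray(observed, dtype=float)
    linked = np.asarray(linked, dtype=float)
    n = observed.size
    if n < 3 or linked.size != n:
        raise ValueError("paired vectors of length >= 3 required")
    fn = _STATISTICS[statistic]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    vals = np.array([fn(observed[i], linked[i]) for i in idx])
    return float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))


def score_agreement(
    observed_T: np.ndarray,
    linked_T: np.ndarray,
    subsample_labels: np.ndarray | None = None,
    bootstrap: dict | None = None,
) -> AgreementReport:
    """Full agreement report, overall and per subsample.

    ``bootstrap`` (optional): dict with keys ``B`` and ``seed``; when given,
    percentile CIs are attached for MAE, RMSE and SMD.
    """
    observed_T = np.asarray(observed_T, dtype=float)
    linked_T = np.asarray(linked_T, dtype=float)
    if observed_T.size != linked_T.size or observed_T.size < 3:
        raise ValueError("paired vectors of length >= 3 required")

    def build(obs, lnk, seed_offset):
        s = _stats(obs, lnk)
        if bootstrap is not None and obs.size >= 3:
            B, seed = int(bootstrap.get("B", 1000)), int(bootstrap["seed"]) + seed_offset
            s.ci_mae = bootstrap_ci(obs, lnk, "MAE", B=B, seed=seed)
            s.ci_rmse = bootstrap_ci(obs, lnk, "RMSE", B=B, seed=seed)
            s.ci_smd = bootstrap_ci(obs, lnk, "SMD", B=B, seed=seed)
        return s

    report = AgreementReport(overall=build(observed_T, linked_T, 0))
    if subsample_labels is not None:
        labels = np.asarray(subsample_labels)
        for k, name in enumerate(pd.unique(labels)):
            m = labels == name
            report.by_subsample[str(name)] = build(observed_T[m], linked_T[m], k + 1)
    return report


def bland_altman(
    observed_T: np.ndarray,
    linked_T: np.ndarray,
    subsample_labels: np.ndarray | None = None,
    person_ids: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bland-Altman data: per-person (average, difference) records and a
    per-subsample summary with limits of agreement and the least-squares
    trend of difference on average.

    Subsamples with fewer than 3 persons get no trend (flagged NaN slope).
    """
    observed_T = np.asarray(observed_T, dtype=float)
    linked_T = np.asarray(linked_T, dtype=float)
    n = observed_T.size
    labels = np.asarray(subsample_labels) if subsample_labels is not None else np.array(["all"] * n)
    pids = np.asarray(person_ids) if person_ids is not None else np.arange(n)
    avg = (observed_T + linked_T) / 2.0
    diff = observed_T - linked_T
    points = pd.DataFrame({"person_id": pids, "subsample": labels, "average": avg, "difference": diff})

    rows = []
    for name in pd.unique(labels):
        m = labels == name
        d, a = diff[m], avg[m]
        md = float(d.mean())
        sd = float(d.std(ddof=1)) if m.sum() > 1 else 0.0
        if m.sum() >= 3 and a.std() > 0:
            slope, intercept = np.polyfit(a, d, 1)
        else:
            slope, intercept = np.nan, np.nan
        rows.append(
            {
                "subsample": name, "n": int(m.sum()), "MD": md, "SD": sd,
                "loa_lower": md - 1.96 * sd, "loa_upper": md + 1.96 * sd,
                "trend_slope": slope, "trend_intercept": intercept,
            }
        )
    return points, pd.DataFrame(rows)
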