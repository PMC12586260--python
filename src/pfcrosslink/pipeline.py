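"""Config-driven orchestration of the full validation flow.

The study design this reproduces: screen the raw sample (drop wholly
missing questionnaires and probable reversed-coding responders), check the
linking assumptions, score the anchor benchmark, produce three sets of
linked T-scores for the 10-item instrument (item-level EAP linking, raw
summed-score crosswalk, fixed-parameter re-estimation followed by EAP
scoring), and quantify agreement of each linked set with the benchmark,
overall and per clinical subsample.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement as agr
from .calibration import FixedParameterCalibrator
from .checks import dif_screen, dimensionality_report
from .crosswalk import CrosswalkLinker
from .grm import ItemParameters, make_grid, read_item_bank_csv, read_responses_csv
from .scoring import EAPScorer, item_level_link, observed_benchmark
from .simulate import SyntheticConfig, contaminate, make_item_banks, screen_exclusions, simulate_sample

__all__ = ["RunConfig", "ValidationReport", "run_validation", "run_synthetic_study", "derive_summary_checks"]

log = logging.getLogger("pfcrosslink")

METHODS = ("item_level", "crosswalk", "reestimation")


@dataclass
class RunConfig:
    """Validated run configuration (YAML-loadable)."""

    responses: str | None = None
    anchor_params: str | None = None
    linked_params: str | None = None  # path, or None to re-estimate only
    out_dir: str = "pfcrosslink_out"
    grid_nodes: int = 49
    grid_bounds: tuple[float, float] = (-6.0, 6.0)
    bootstrap_B: int = 1000
    seed: int = 1
    dif_threshold: float = 0.03
    smd_benchmark: float = 0.2
    run_checks: bool = True
    n_group_factors: int = 4
    rounding: int = 2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("responses", "anchor_params", "linked_params"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config {key}: {p} does not exist")
        if isinstance(cfg.grid_bounds, list):
            cfg.grid_bounds = tuple(cfg.grid_bounds)
        return cfg


@dataclass
class ValidationReport:
    n_initial: int
    n_analytic: int
    exclusions: dict
    subsample_shares: dict
    benchmark_scores: pd.DataFrame
    linked_scores: dict[str, pd.DataFrame]
    agreement: dict[str, agr.AgreementReport]
    bland_altman_points: pd.DataFrame
    bland_altman_summary: pd.DataFrame
    dimensionality: dict | None = None
    dif: pd.DataFrame | None = None
    calibration: dict | None = None

    def table3(self) -> pd.DataFrame:
        """Correlations and MD(SD) per method and sample."""
        rows = []
        for method, rep in self.agreement.items():
            frame = rep.to_frame()
            for _, r in frame.iterrows():
                rows.append({"method": method, "sample": r["sample"], "n": r["n"],
                             "r": r["r"], "MD": r["MD"], "SD": r["SD"]})
        return pd.DataFrame(rows)

    def table4(self) -> pd.DataFrame:
        """T-score means (SD) of the benchmark and each linked set per sample."""
        rows = []
        bench = self.benchmark_scores
        labels = bench["subsample"].to_numpy()
        samples = [("analytic", np.ones(len(bench), bool))] + [
            (s, labels == s) for s in pd.unique(labels)
        ]
        for name, mask in samples:
            rows.append({"sample": name, "score_set": "benchmark",
                         "mean": bench.loc[mask, "t_score"].mean(),
                         "sd": bench.loc[mask, "t_score"].std(ddof=1)})
            for method, scores in self.linked_scores.items():
                t = scores["t_score"].to_numpy()
                rows.append({"sample": name, "score_set": method,
                             "mean": t[mask].mean(), "sd": t[mask].std(ddof=1)})
        return pd.DataFrame(rows)

    def table5(self) -> pd.DataFrame:
        """MAE / RMSE / SMD with bootstrap CIs per method and sample."""
        rows = []
        for method, rep in self.agreement.items():
            frame = rep.to_frame()
            frame.insert(0, "method", method)
            rows.append(frame)
        return pd.concat(rows, ignore_index=True)


def _min_seed(rng_or_seed) -> int:
    return int(np.random.default_rng(rng_or_seed).integers(0, 2**31 - 1))


def link_all_methods(
    responses,
    anchor_params: list[ItemParameters],
    linked_params: list[ItemParameters],
    grid=None,
    calib_kwargs: dict | None = None,
):
    """Benchmark scores plus the three linked score sets, aligned by person.

    Returns (benchmark DataFrame, {method: DataFrame}, calibration info).
    """
    grid = grid if grid is not None else make_grid()
    bench = observed_benchmark(responses, anchor_params, grid)

    linked = {}
    linked["item_level"] = item_level_link(responses, linked_params, grid)

    xw = CrosswalkLinker(bank=linked_params, grid=grid).fit()
    linked["crosswalk"] = xw.transform(responses.subset_items("linked"))

    calib = FixedParameterCalibrator(anchor_params=anchor_params, grid=grid, **(calib_kwargs or {}))
    calib.fit(responses)
    reest = EAPScorer(bank=calib.free_params_, grid=grid).fit().transform(responses.subset_items("linked"))
    reest.insert(1, "method", "reestimation")
    linked["reestimation"] = reest

    calib_info = {
        "converged": bool(calib.converged_),
        "n_cycles": int(calib.n_cycles_),
        "loglik_first": float(calib.loglik_trace_[0]),
        "loglik_final": float(calib.loglik_trace_[-1]),
        "free_params": calib.free_params_,
    }
    return bench, linked, calib_info


def run_synthetic_study(
    seed: int,
    config: SyntheticConfig | None = None,
    contaminated: bool = False,
    bootstrap_B: int | None = None,
    run_checks: bool = False,
    calib_kwargs: dict | None = None,
) -> ValidationReport:
    """End-to-end study on generated data under the default conditions.

    With ``contaminated`` the generator plants the exclusion-screen targets
    (reversed coders, wholly missing questionnaires) before screening;
    otherwise the clean analytic-scale sample is analyzed directly.
    The linked instrument's true generating parameters play the role of the
    published original-calibration parameters (correct specification).
    """
    base = config or SyntheticConfig(seed=seed)
    if contaminated and config is None:
        # draw at the initial recruitment sizes; screening trims the sample
        base = SyntheticConfig(seed=seed, n_per_subsample=base.n_initial_per_subsample)
    rng = np.random.default_rng(seed)
    anchor_params, linked_params = make_item_banks(base, rng)
    data = simulate_sample((anchor_params, linked_params), base, seed=_min_seed(rng))
    n_initial = data.responses.n_persons

    exclusions = {"missing_instrument": 0, "reversed_coding": 0}
    if contaminated:
        data = contaminate(data, base.reversed_fraction, base.missing_fraction, rng)
        data, excl_log = screen_exclusions(data, anchor_params, linked_params)
        counts = excl_log.loc[excl_log["excluded"], "reason"].value_counts().to_dict()
        exclusions.update({k: int(v) for k, v in counts.items()})
    analytic = data

    grid = make_grid()
    bench, linked, calib_info = link_all_methods(
        analytic.responses, anchor_params, linked_params, grid, calib_kwargs=calib_kwargs
    )
    bench = bench.merge(analytic.truth_frame()[["person_id", "subsample"]], on="person_id")

    boot = None if bootstrap_B is None else {"B": bootstrap_B, "seed": _min_seed(rng)}
    reports, ba_points, ba_summaries = {}, [], []
    for method in METHODS:
        merged = bench.merge(linked[method], on="person_id", suffixes=("_obs", "_lnk"))
        obs = merged["t_score_obs"].to_numpy()
        lnk = merged["t_score_lnk"].to_numpy()
        labels = merged["subsample"].to_numpy()
        reports[method] = agr.score_agreement(obs, lnk, labels, bootstrap=boot)
        pts, summ = agr.bland_altman(obs, lnk, labels, merged["person_id"].to_numpy())
        pts.insert(2, "method", method)
        summ.insert(0, "method", method)
        ba_points.append(pts)
        ba_summaries.append(summ)

    n_analytic = analytic.responses.n_persons
    label_counts = pd.Series(analytic.subsample).value_counts()
    shares = {k: 100.0 * v / n_analytic for k, v in label_counts.items()}

    dim = dif = None
    if run_checks:
        dim_report = dimensionality_report(analytic.responses, n_group_factors=4)
        dim = dim_report.to_json_dict()
        pooled_bank = anchor_params + linked_params
        trait = EAPScorer(bank=pooled_bank, grid=grid).fit().transform(analytic.responses)["theta"].to_numpy()
        dif = dif_screen(analytic.responses, analytic.subsample, trait).table

    return ValidationReport(
        n_initial=n_initial,
        n_analytic=n_analytic,
        exclusions=exclusions,
        subsample_shares=shares,
        benchmark_scores=bench,
        linked_scores=linked,
        agreement=reports,
        bland_altman_points=pd.concat(ba_points, ignore_index=True),
        bland_altman_summary=pd.concat(ba_summaries, ignore_index=True),
        dimensionality=dim,
        dif=dif,
        calibration=calib_info,
    )


def derive_summary_checks(report: ValidationReport, tol: float = 1e-9) -> dict[str, bool]:
    """Internal-consistency flags on a finished report.

    Verifies the RMSE/MD/SD identity, SMD recomputation from the score-set
    summary statistics, crosswalk T monotonicity in the raw score, and the
    subsample-share bookkeeping.
    """
    flags = {}
    ok = True
    for method, rep in report.agreement.items():
        for s in [rep.overall] + list(rep.by_subsample.values()):
            lhs = s.rmse**2
            rhs = s.mean_diff**2 + s.sd_diff**2 * (s.n - 1) / s.n
            ok &= abs(lhs - rhs) <= tol * max(1.0, lhs)
    flags["rmse_identity"] = bool(ok)

    ok = True
    bench_t = report.benchmark_scores["t_score"]
    labels = report.benchmark_scores["subsample"].to_numpy()
    for method, rep in report.agreement.items():
        lnk_t = report.linked_scores[method]["t_score"].to_numpy()
        md = float((bench_t.to_numpy() - lnk_t).mean())
        smd = agr.smd_from_summary(md, bench_t.std(ddof=1), np.std(lnk_t, ddof=1))
        ok &= rep.overall.smd is not None and abs(smd - rep.overall.smd) <= 1e-9
    flags["smd_recomputation"] = bool(ok)

    xw_t = report.linked_scores["crosswalk"].sort_values("raw_score")["t_score"].to_numpy()
    flags["crosswalk_monotone"] = bool(np.all(np.diff(xw_t) >= 0))

    shares = sum(report.subsample_shares.values())
    counts_ok = abs(shares - 100.0) < 1e-6
    flags["bookkeeping"] = bool(counts_ok and report.n_analytic <= report.n_initial)
    flags["all_pass"] = all(flags.values())
    return flags


def _write_outputs(report: ValidationReport, out_dir: Path, rounding: int) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)

    def rounded(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        for c in df.columns:
            if pd.api.types.is_float_dtype(df[c]):
                df[c] = agr.round_half_away(df[c].to_numpy(), rounding)
        return df

    rounded(report.table3()).to_csv(out_dir / "table3.csv", index=False)
    rounded(report.table4()).to_csv(out_dir / "table4.csv", index=False)
    rounded(report.table5()).to_csv(out_dir / "table5.csv", index=False)
    report.bland_altman_points.to_csv(out_dir / "bland_altman.csv", index=False)
    report.bland_altman_summary.to_csv(out_dir / "bland_altman_summary.csv", index=False)
    if report.dimensionality is not None:
        with open(out_dir / "table2.json", "w") as fh:
            json.dump(report.dimensionality, fh, indent=2)
    if report.dif is not None:
        report.dif.to_csv(out_dir / "dif.csv", index=False)
    summary = {
        "n_initial": report.n_initial,
        "n_analytic": report.n_analytic,
        "exclusions": report.exclusions,
        "subsample_shares": {k: round(v, 2) for k, v in report.subsample_shares.items()},
        "calibration": None
        if report.calibration is None
        else {k: v for k, v in report.calibration.items() if k != "free_params"},
        "consistency": derive_summary_checks(report),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


def run_validation(config: RunConfig) -> ValidationReport:
    """File-driven validation run: read inputs, execute every stage, write
    the table CSVs / JSON reports into ``config.out_dir``."""
    if config.responses is None or config.anchor_params is None:
        raise ValueError("config must name responses and anchor_params files")
    anchor_params, _ = read_item_bank_csv(config.anchor_params)
    if config.linked_params is None:
        raise ValueError("linked_params file required (item-level linking and crosswalk need fixed parameters)")
    linked_params, _ = read_item_bank_csv(config.linked_params)
    labels = {p.item_id: "anchor" for p in anchor_params}
    labels.update({p.item_id: "linked" for p in linked_params})
    responses = read_responses_csv(config.responses, labels)
    log.info("stage=load n=%d items=%d", responses.n_persons, responses.n_items)

    # screen: drop persons with a wholly missing instrument
    anchor_cols = responses.item_index("anchor")
    linked_cols = responses.item_index("linked")
    whole_missing = responses.missing[:, anchor_cols].all(axis=1) | responses.missing[:, linked_cols].all(axis=1)
    analytic = responses.subset_persons(~whole_missing)
    log.info("stage=screen excluded=%d analytic=%d", int(whole_missing.sum()), analytic.n_persons)

    grid = make_grid(config.grid_nodes, config.grid_bounds)
    bench, linked, calib_info = link_all_methods(analytic, anchor_params, linked_params, grid)
    labels_arr = np.array(["analytic"] * len(bench))
    bench = bench.assign(subsample=labels_arr)

    boot = {"B": config.bootstrap_B, "seed": config.seed}
    reports, ba_points, ba_summaries = {}, [], []
    for method in METHODS:
        merged = bench.merge(linked[method], on="person_id", suffixes=("_obs", "_lnk"))
        obs = merged["t_score_obs"].to_numpy()
        lnk = merged["t_score_lnk"].to_numpy()
        reports[method] = agr.score_agreement(obs, lnk, bootstrap=boot)
        pts, summ = agr.bland_altman(obs, lnk, None, merged["person_id"].to_numpy())
        pts.insert(2, "method", method)
        summ.insert(0, "method", method)
        ba_points.append(pts)
        ba_summaries.append(summ)
        log.info("stage=agreement method=%s n=%d", method, len(merged))

    dim = dif = None
    if config.run_checks:
        dim = dimensionality_report(analytic, n_group_factors=config.n_group_factors).to_json_dict()

    report = ValidationReport(
        n_initial=responses.n_persons,
        n_analytic=analytic.n_persons,
        exclusions={"missing_instrument": int(whole_missing.sum()), "reversed_coding": 0},
        subsample_shares={"analytic": 100.0},
        benchmark_scores=bench,
        linked_scores=linked,
        agreement=reports,
        bland_altman_points=pd.concat(ba_points, ignore_index=True),
        bland_altman_summary=pd.concat(ba_summaries, ignore_index=True),
        dimensionality=dim,
        dif=dif,
        calibration=calib_info,
    )
    _write_outputs(report, Path(config.out_dir), config.rounding)
    return report
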