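"""Simulation metrics and the replicate study harness.

Two truths are tracked per replicate: the *oracle* ARE (the best region
in the population) and the *data-adaptive* ARE (the true effect of the
region the procedure actually discovered, evaluated against the
generating law).  Region recovery is scored as a classification of
observations into/out of the oracle region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cv import CVRegionTMLE
from .regions import Region, membership
from .synthetic import AnySpec, GroundTruth, generate, true_are

__all__ = [
    "ClassificationMetrics",
    "EstimatorMetrics",
    "SimulationReport",
    "classification_metrics",
    "estimator_metrics",
    "run_replicates",
    "run_simulation_study",
]


@dataclass(frozen=True)
class ClassificationMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_defined: bool = True
    specificity_defined: bool = True


def classification_metrics(true_member: np.ndarray, est_member: np.ndarray) -> ClassificationMetrics:
    """Confusion-matrix ratios of estimated vs. true region membership."""
    t = np.asarray(true_member).astype(bool)
    e = np.asarray(est_member).astype(bool)
    if len(t) != len(e):
        raise ValueError(f"length mismatch: {len(t)} vs {len(e)}")
    tp = int(np.sum(t & e))
    fn = int(np.sum(t & ~e))
    tn = int(np.sum(~t & ~e))
    fp = int(np.sum(~t & e))
    sens_def, spec_def = (tp + fn) > 0, (tn + fp) > 0
    return ClassificationMetrics(
        sensitivity=tp / (tp + fn) if sens_def else np.nan,
        specificity=tn / (tn + fp) if spec_def else np.nan,
        accuracy=(tp + tn) / len(t),
        sensitivity_defined=sens_def,
        specificity_defined=spec_def,
    )


@dataclass(frozen=True)
class EstimatorMetrics:
    abs_bias: float
    percent_bias: float
    mse: float
    coverage: float
    percent_bias_defined: bool = True
    n_replicates: int = 0


def estimator_metrics(
    estimates: np.ndarray, ci_pairs: np.ndarray, psi0: float
) -> EstimatorMetrics:
    """Bias, percent bias, MSE (bias^2 + replicate variance) and coverage.

    Sample variance uses the n-1 denominator; percent bias is flagged
    undefined when psi0 = 0.
    """
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("at least two replicates are required for the MSE variance term")
    ci = np.asarray(ci_pairs, dtype=float).reshape(-1, 2)
    mean = float(est.mean())
    bias = mean - psi0
    defined = psi0 != 0
    return EstimatorMetrics(
        abs_bias=abs(bias),
        percent_bias=100.0 * bias / psi0 if defined else np.nan,
        mse=bias**2 + float(np.var(est, ddof=1)),
        coverage=float(np.mean((ci[:, 0] <= psi0) & (psi0 <= ci[:, 1]))),
        percent_bias_defined=defined,
        n_replicates=est.size,
    )


@dataclass
class SimulationReport:
    """Aggregated replicate results per sample size."""

    table: pd.DataFrame
    records: pd.DataFrame
    seeds: dict


def _majority_region(est: CVRegionTMLE) -> Region | None:
    if est.pooled_.status != "ok" or not est.pooled_.groups:
        return None
    return est.pooled_.groups[0].mean_region


def run_replicates(
    spec: AnySpec,
    n: int,
    reps: int,
    seed: int,
    estimator_params: dict,
    adaptive_truth: bool = False,
    truth_n_mc: int = 20000,
) -> pd.DataFrame:
    """Run the full discovery+estimation pipeline on ``reps`` fresh datasets.

    Returns one record per replicate: discovery status, pooled estimate
    and CI, the root-split pass flag, the discovered (majority-group)
    region and — when ``adaptive_truth`` — the oracle ARE of that region.
    Replicate-level failures are recorded, not fatal.
    """
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(reps + 1)
    truth_seed = int(child[-1].generate_state(1)[0] % (2**31 - 1))
    rows = []
    for r in range(reps):
        rs = int(child[r].generate_state(1)[0] % (2**31 - 1))
        row = {"rep": r, "n": n, "seed": rs, "status": "error", "root_split_passed": False}
        try:
            data = generate(spec, n, rs)
            est = CVRegionTMLE(exposures=data.exposure_names, random_state=rs, **estimator_params)
            est.fit_dataset(data)
            row["root_split_passed"] = any(f.root_any_valid for f in est.fold_results_)
            row["status"] = est.pooled_.status
            if est.pooled_.status == "ok":
                row.update(
                    are=est.pooled_.are,
                    se=est.pooled_.se,
                    ci_low=est.pooled_.ci_low,
                    ci_high=est.pooled_.ci_high,
                    p_value=est.pooled_.p_value,
                )
                region = _majority_region(est)
                row["region"] = str(region) if region is not None else None
                if region is not None:
                    row["region_records"] = region.to_records()
                    if adaptive_truth:
                        truth = true_are(spec, region, truth_n_mc, truth_seed)
                        row["psi0_adaptive"] = truth.are
        except Exception as exc:  # noqa: BLE001 - replicate failures are data
            row["error"] = repr(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def run_simulation_study(
    spec: AnySpec,
    n_grid: list[int],
    reps: int,
    estimator_params: dict,
    seed: int,
    oracle: GroundTruth | None = None,
    adaptive_truth: bool = False,
    classification_n: int = 5000,
    truth_n_mc: int = 20000,
) -> SimulationReport:
    """Replicate study across sample sizes with aggregated metrics.

    For each n: discovery rate, bias/MSE/coverage versus the oracle ARE
    (when ``oracle`` is given) and versus the per-replicate data-adaptive
    truth (when ``adaptive_truth``), and classification of a fresh
    evaluation sample against the oracle region.  Fully seeded: the same
    seed reproduces the report exactly.
    """
    ss = np.random.SeedSequence(seed)
    seeds = {n: int(s.generate_state(1)[0] % (2**31 - 1)) for n, s in zip(n_grid, ss.spawn(len(n_grid) + 1))}
    class_seed = int(ss.spawn(len(n_grid) + 2)[-1].generate_state(1)[0] % (2**31 - 1))

    eval_data = None
    if oracle is not None:
        eval_data = generate(spec, classification_n, class_seed)
        true_member = membership(oracle.region, eval_data.A)

    all_records, summary = [], []
    for n in n_grid:
        rec = run_replicates(
            spec, n, reps, seeds[n], estimator_params, adaptive_truth, truth_n_mc
        )
        all_records.append(rec)
        ok = rec[rec["status"] == "ok"]
        row = {
            "n": n,
            "replicates": len(rec),
            "n_estimated": len(ok),
            "n_errors": int((rec["status"] == "error").sum()),
            "discovery_rate": len(ok) / len(rec),
            "root_split_rate": float(rec["root_split_passed"].mean()),
        }
        if len(ok) >= 2:
            ci = ok[["ci_low", "ci_high"]].to_numpy()
            if oracle is not None:
                m = estimator_metrics(ok["are"].to_numpy(), ci, oracle.are)
                row.update(
                    abs_bias_oracle=m.abs_bias,
                    pct_bias_oracle=m.percent_bias,
                    mse_oracle=m.mse,
                    coverage_oracle=m.coverage,
                )
            if adaptive_truth and "psi0_adaptive" in ok:
                ok_ad = ok.dropna(subset=["psi0_adaptive"])
                if len(ok_ad) >= 2:
                    errs = ok_ad["are"].to_numpy() - ok_ad["psi0_adaptive"].to_numpy()
                    ci_ad = ok_ad[["ci_low", "ci_high"]].to_numpy()
                    cover = np.mean(
                        (ci_ad[:, 0] <= ok_ad["psi0_adaptive"].to_numpy())
                        & (ok_ad["psi0_adaptive"].to_numpy() <= ci_ad[:, 1])
                    )
                    row.update(
                        abs_bias_adaptive=abs(float(errs.mean())),
                        mse_adaptive=float(errs.mean()) ** 2 + float(np.var(errs, ddof=1)),
                        coverage_adaptive=float(cover),
                    )
            if oracle is not None and "region_records" in ok:
                accs, senss, specs = [], [], []
                for recs in ok["region_records"].dropna():
                    est_member = membership(Region.from_records(recs), eval_data.A)
                    cm = classification_metrics(true_member, est_member)
                    accs.append(cm.accuracy)
                    senss.append(cm.sensitivity)
                    specs.append(cm.specificity)
                if accs:
                    row.update(
                        accuracy=float(np.mean(accs)),
                        sensitivity=float(np.nanmean(senss)),
                        specificity=float(np.nanmean(specs)),
                    )
        summary.append(row)
    return SimulationReport(
        table=pd.DataFrame(summary),
        records=pd.concat(all_records, ignore_index=True),
        seeds=seeds,
    )
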