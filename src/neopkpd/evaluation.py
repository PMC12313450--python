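"""External evaluation of a population PK model against an observation dataset.

Implements the standard simulation-based external-validation battery for
nonlinear mixed-effects models:

* population predictions (eta = 0) and MAP empirical-Bayes individual
  predictions;
* numeric predictive-performance metrics: percentage prediction errors
  (PPE), absolute PPE, normalized RMSE, and P10-P30 (share of population
  predictions within 10-30% of the observations);
* prediction-corrected visual predictive check (pcVPC): observations and
  model replicates are rescaled by bin-median population prediction and the
  observed percentiles are compared with simulation confidence bands;
* normalized prediction distribution errors (NPDE): each observation vector
  is decorrelated with the empirical mean and Cholesky factor of its own
  simulation covariance, ranked within its decorrelated replicates, and
  inverse-normal transformed; ~N(0,1) under a correct model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataset import ObservationDataset, SubjectRecords
from .model import ModelSpec, individual_parameters
from .simulate import simulate_profile


def _predict_subject(
    sub: SubjectRecords,
    spec: ModelSpec,
    typical_values: Optional[dict[str, float]],
    eta: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Model-predicted concentrations at the subject's observation times."""
    times = sub.observation_times
    if times.size == 0:
        return np.empty(0)
    params = individual_parameters(sub.virtual_subject, spec, typical_values, eta=eta)
    return simulate_profile(params, sub.schedule, times).total


def population_predict(
    dataset: ObservationDataset,
    spec: ModelSpec,
    typical_values: Optional[dict[str, float]] = None,
) -> np.ndarray:
    """Population predictions (eta = 0) for every observation row, in dataset order."""
    preds = []
    for sid, _ in dataset.iter_subjects():
        preds.append(_predict_subject(dataset.subject(sid), spec, typical_values))
    return np.concatenate(preds) if preds else np.empty(0)


def map_etas(
    sub: SubjectRecords,
    spec: ModelSpec,
    typical_values: Optional[dict[str, float]] = None,
    n_restarts: int = 4,
    seed: int = 0,
) -> dict[str, float]:
    """MAP (empirical-Bayes) random-effect estimate for one subject.

    Minimizes -2 x [residual log-likelihood + log prior], i.e.

        sum_j [ log sigma_j^2 + (DV_j - f_j(eta))^2 / sigma_j^2 ] + sum_i eta_i^2 / omega_i

    with sigma_j^2 = (prop_sd * f_j)^2 + add_sd^2. Multi-start (eta = 0 plus
    ``n_restarts`` seeded random starts) with a gradient-free fallback keeps
    the 1-4-observation subjects robust; deterministic given the data.
    """
    names = [p for p in spec.random_effect_names if spec.omega[p] > 0]
    if not names:
        return {}
    dv = sub.dv
    if dv.size == 0:
        return {name: 0.0 for name in names}  # prior mode
    omega = np.array([spec.omega[p] for p in names])
    err = spec.residual_error
    if err.proportional_sd == 0 and err.additive_sd == 0:
        raise ValueError("MAP estimation needs a non-degenerate residual error model")

    full_names = spec.random_effect_names

    def expand(eta_free: np.ndarray) -> np.ndarray:
        full = np.zeros(len(full_names))
        for val, name in zip(eta_free, names):
            full[full_names.index(name)] = val
        return full

    def objective(eta_free: np.ndarray) -> float:
        pred = _predict_subject(sub, spec, typical_values, eta=expand(eta_free))
        var = err.sd(pred) ** 2
        if np.any(var <= 0) or np.any(~np.isfinite(pred)):
            return 1e12
        return float(
            np.sum(np.log(var) + (dv - pred) ** 2 / var) + np.sum(eta_free**2 / omega)
        )

    rng = np.random.default_rng(seed)
    starts = [np.zeros(len(names))] + [
        rng.normal(0.0, np.sqrt(omega)) for _ in range(n_restarts)
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="L-BFGS-B", tol=1e-8)
        if not res.success:
            res = optimize.minimize(objective, x0, method="Nelder-Mead", tol=1e-8)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(f"MAP estimation failed for subject {sub.records.iloc[0]['ID']}")
    return dict(zip(names, best.x))


def individual_predict(
    dataset: ObservationDataset,
    spec: ModelSpec,
    typical_values: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Goodness-of-fit table: OBS, PRED, IPRED and residuals per observation."""
    rows = []
    for sid, _ in dataset.iter_subjects():
        sub = dataset.subject(sid)
        if sub.observation_times.size == 0:
            continue
        eta = map_etas(sub, spec, typical_values)
        full = np.array([eta.get(p, 0.0) for p in spec.random_effect_names])
        pred = _predict_subject(sub, spec, typical_values)
        ipred = _predict_subject(sub, spec, typical_values, eta=full)
        for t, y, pp, ip in zip(sub.observation_times, sub.dv, pred, ipred):
            rows.append({"ID": sid, "TIME": t, "OBS": y, "PRED": pp, "IPRED": ip})
    gof = pd.DataFrame(rows)
    gof["RES"] = gof["OBS"] - gof["PRED"]
    gof["IRES"] = gof["OBS"] - gof["IPRED"]
    return gof


@dataclass
class PredictionErrorReport:
    """Numeric predictive-performance summary of PRED vs observations."""

    per_observation: pd.DataFrame  # PPE/APPE per observation
    ppe_median: float
    ppe_iqr: tuple[float, float]
    appe_median: float
    appe_iqr: tuple[float, float]
    nrmse: float  # %, RMSE normalized by mean(DV)
    p10: float
    p20: float
    p30: float


def prediction_error_metrics(pred: np.ndarray, dv: np.ndarray) -> PredictionErrorReport:
    """PPE_i = 100 (PRED_i - DV_i) / DV_i; P_k = % of |PPE| <= k."""
    pred = np.asarray(pred, dtype=float)
    dv = np.asarray(dv, dtype=float)
    if pred.shape != dv.shape:
        raise ValueError("PRED and DV must have equal length")
    if np.any(dv <= 0):
        raise ValueError("DV must be strictly positive")
    ppe = 100.0 * (pred - dv) / dv
    appe = np.abs(ppe)
    rmse = float(np.sqrt(np.mean((pred - dv) ** 2)))
    report = PredictionErrorReport(
        per_observation=pd.DataFrame({"PRED": pred, "DV": dv, "PPE": ppe, "APPE": appe}),
        ppe_median=float(np.median(ppe)),
        ppe_iqr=tuple(np.percentile(ppe, [25, 75])),
        appe_median=float(np.median(appe)),
        appe_iqr=tuple(np.percentile(appe, [25, 75])),
        nrmse=float(100.0 * rmse / dv.mean()),
        p10=float(100.0 * (appe <= 10).mean()),
        p20=float(100.0 * (appe <= 20).mean()),
        p30=float(100.0 * (appe <= 30).mean()),
    )
    return report


def _observed_subjects(dataset: ObservationDataset) -> list[SubjectRecords]:
    """Subjects with at least one observation, in dataset order."""
    subs = [dataset.subject(sid) for sid, _ in dataset.iter_subjects()]
    return [s for s in subs if s.observation_times.size > 0]


def simulate_replicate_dv(
    dataset: ObservationDataset,
    spec: ModelSpec,
    typical_values: Optional[dict[str, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """One replicate of the study: new BSV draws + residual error, same design."""
    out = [
        _simulate_subject_replicates(sub, spec, typical_values, 1, rng)[0]
        for sub in _observed_subjects(dataset)
    ]
    return np.concatenate(out) if out else np.empty(0)


def _simulate_subject_replicates(
    sub: SubjectRecords,
    spec: ModelSpec,
    typical_values: Optional[dict[str, float]],
    n_sim: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_sim, n_obs) matrix of simulated DVs under BSV + residual error.

    BSV enters as per-parameter factors exp(eta) on the subject's covariate-
    adjusted base parameters, so the whole replicate block is one vectorized
    closed-form evaluation on the subject's own schedule and sample times.
    """
    from .model import sample_etas
    from .simulate import batch_profile

    times = sub.observation_times
    schedule = sub.schedule
    base = individual_parameters(sub.virtual_subject, spec, typical_values)
    etas = sample_etas(spec, n_sim, rng)
    fac = {name: np.exp(etas[:, i]) for i, name in enumerate(spec.random_effect_names)}
    ones = np.ones(n_sim)
    ipred = batch_profile(
        base.cl * fac.get("CL", ones),
        base.v * fac.get("V", ones),
        schedule,
        times,
        q=None if base.q is None else base.q * fac.get("Q", ones),
        v2=None if base.v2 is None else base.v2 * fac.get("V2", ones),
    )
    err = spec.residual_error
    eps_p = rng.standard_normal(ipred.shape)
    eps_a = rng.standard_normal(ipred.shape)
    return ipred * (1.0 + err.proportional_sd * eps_p) + err.additive_sd * eps_a


@dataclass
class PcVpcResult:
    """Prediction-corrected VPC: observed pc-percentiles + simulation bands per bin."""

    table: pd.DataFrame
    n_sim: int
    bin_variable: str = "time_after_dose"

    @property
    def coverage(self) -> float:
        """Fraction of (bin, percentile) cells with the observed statistic
        inside its 95% simulation band."""
        ok = 0
        total = 0
        for q in ("p2.5", "p50", "p97.5"):
            obs = self.table[f"obs_{q}"]
            inside = (obs >= self.table[f"sim_{q}_lo"]) & (obs <= self.table[f"sim_{q}_hi"])
            ok += int(inside.sum())
            total += len(inside)
        return ok / total


def _time_after_dose(sub: SubjectRecords) -> np.ndarray:
    dose_times = np.array([e.start_time for e in sub.schedule.events])
    return np.array(
        [t - dose_times[dose_times <= t + 1e-9].max() for t in sub.observation_times]
    )


def pcvpc(
    dataset: ObservationDataset,
    spec: ModelSpec,
    typical_values: Optional[dict[str, float]] = None,
    n_sim: int = 1000,
    n_bins: int = 4,
    seed: int = 0,
) -> PcVpcResult:
    """Prediction-corrected VPC on quantile bins of time-after-most-recent-dose.

    pcY_ij = Y_ij x median(PRED in bin) / PRED_ij, applied identically to the
    observed data and to each of ``n_sim`` model replicates (BSV + residual
    error); per bin the 2.5/50/97.5 observed pc-percentiles are compared with
    their 95% simulation bands.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    pred = population_predict(dataset, spec, typical_values)
    if np.any(pred <= 0):
        raise ValueError("population prediction <= 0; cannot prediction-correct")
    subs = _observed_subjects(dataset)
    dv = np.concatenate([s.dv for s in subs])
    tad = np.concatenate([_time_after_dose(s) for s in subs])

    bins = pd.qcut(tad, q=n_bins, duplicates="drop")
    med_pred = pd.Series(pred).groupby(bins, observed=True).transform("median").to_numpy()
    correction = med_pred / pred
    pc_obs = dv * correction

    rng = np.random.default_rng(seed)
    qs = (2.5, 50.0, 97.5)
    codes = bins.codes
    n_used = codes.max() + 1
    # all replicates at once, one vectorized block per subject
    dv_sim = np.concatenate(
        [_simulate_subject_replicates(s, spec, typical_values, n_sim, rng) for s in subs],
        axis=1,
    )
    pc_sim = dv_sim * correction
    sim_stats = np.empty((n_sim, n_used, len(qs)))
    for b in range(n_used):
        sim_stats[:, b, :] = np.percentile(pc_sim[:, codes == b], qs, axis=1).T

    rows = []
    for b, interval in enumerate(bins.categories):
        mask = codes == b
        obs_q = np.percentile(pc_obs[mask], qs)
        row = {
            "bin": str(interval),
            "tad_mid": float(np.median(tad[mask])),
            "n": int(mask.sum()),
        }
        for j, q in enumerate(qs):
            lo, hi = np.percentile(sim_stats[:, b, j], [2.5, 97.5])
            row[f"obs_p{q:g}"] = float(obs_q[j])
            row[f"sim_p{q:g}_lo"] = float(lo)
            row[f"sim_p{q:g}_hi"] = float(hi)
        rows.append(row)
    return PcVpcResult(table=pd.DataFrame(rows), n_sim=n_sim)


@dataclass
class NpdeResult:
    """NPDE diagnostics: per-observation values and global calibration tests."""

    per_observation: pd.DataFrame  # ID, TIME, npde
    mean: float
    variance: float
    t_statistic: float
    t_pvalue: float  # H0: mean 0
    variance_pvalue: float  # H0: variance 1 (chi-square)
    normality_pvalue: float  # Shapiro-Wilk

    @property
    def npde(self) -> np.ndarray:
        return self.per_observation["npde"].to_numpy()


def npde(
    dataset: ObservationDataset,
    spec: ModelSpec,
    typical_values: Optional[dict[str, float]] = None,
    n_sim: int = 1000,
    seed: int = 0,
) -> NpdeResult:
    """Normalized prediction distribution errors.

    Per subject, ``n_sim`` replicate observation vectors are simulated under
    the full model (BSV + residual error). Observed and simulated vectors are
    decorrelated with the empirical simulation mean and the Cholesky factor
    of the empirical simulation covariance; the prediction discrepancy
    pde_ij is the fraction of decorrelated replicates below the decorrelated
    observation, clamped to [1/(2 n_sim), 1 - 1/(2 n_sim)], and
    npde = Phi^{-1}(pde).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    rows = []
    for sub in _observed_subjects(dataset):
        sid = sub.records.iloc[0]["ID"]
        sims = _simulate_subject_replicates(sub, spec, typical_values, n_sim, rng)
        mean = sims.mean(axis=0)
        cov = np.atleast_2d(np.cov(sims, rowvar=False))
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                f"singular simulation covariance for subject {sid}; increase n_sim"
            ) from exc
        y_dec = np.linalg.solve(chol, sub.dv - mean)
        sim_dec = np.linalg.solve(chol, (sims - mean).T).T
        pde = (sim_dec < y_dec).mean(axis=0)
        pde = np.clip(pde, 1.0 / (2 * n_sim), 1.0 - 1.0 / (2 * n_sim))
        values = stats.norm.ppf(pde)
        for t, v in zip(sub.observation_times, values):
            rows.append({"ID": sid, "TIME": t, "npde": v})

    per_obs = pd.DataFrame(rows)
    x = per_obs["npde"].to_numpy()
    n = x.size
    t_stat, t_p = stats.ttest_1samp(x, 0.0)
    # two-sided chi-square test of Var = 1
    chi2 = (n - 1) * x.var(ddof=1)
    p_lo = stats.chi2.cdf(chi2, n - 1)
    var_p = float(2 * min(p_lo, 1 - p_lo))
    _, norm_p = stats.shapiro(x) if 3 <= n <= 5000 else (np.nan, np.nan)
    return NpdeResult(
        per_observation=per_obs,
        mean=float(x.mean()),
        variance=float(x.var(ddof=1)),
        t_statistic=float(t_stat),
        t_pvalue=float(t_p),
        variance_pvalue=var_p,
        normality_pvalue=float(norm_p),
    )
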