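"""Synthetic serosurveys under known seroincidence, for testing and design.

The simulator draws from exactly the generative model the likelihood
evaluates (one shared observation-model definition), so parameter-recovery
and distributional (KS) tests close the loop without any external data:

* age ~ Uniform(age_range) years (pluggable sampler);
* with probability exp(-λ·age_days) the subject is never infected, else the
  time since the latest seroconversion τ ~ Exp(λ) truncated to (0, age_days),
  sampled by inverse CDF;
* per antigen-isotype: one kinetics draw uniformly from the ensemble,
  y_model = antibody_level(τ), observed Y = (y_model + B)·E with
  B ~ Uniform(0, ν) and mean-one lognormal E with CV ε;
* optional clamping to [y_low, y_high] (the estimator treats clamped values
  as censored).

By default each antigen-isotype of a subject gets its own independent τ,
matching the independence assumption of the likelihood exactly
(self-consistent oracle tests).  ``shared_tau=True`` instead uses one
infection clock per subject across biomarkers — closer to reality — letting
tests quantify the cost of the independence approximation.

Default study conditions (two enteric-fever-like HlyE biomarkers, ages 2–15,
ELISA-like noise) are in :data:`default_ensemble` / :data:`default_noise`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (DAYS_PER_YEAR, NoiseParams, PopData, SerorateError,
                         SeroresponseDraw, SRParamEnsemble)
from .estimation import EstimationOptions, est_seroincidence
from .kinetics import _level_arrays
from .likelihood import LikelihoodOptions

__all__ = ["SimulationConfig", "simulate_pop_data", "simulate_survey",
           "simulate_sr_ensemble", "recovery_experiment",
           "default_center_draws", "default_noise", "default_ensemble"]


def default_center_draws() -> dict[str, SeroresponseDraw]:
    """Central kinetics for the default biomarkers (concentrations in assay
    units, times in days)."""
    return {
        "HlyE_IgG": SeroresponseDraw("HlyE_IgG", y0=1.0, y1=100.0, t1=10.0,
                                     alpha=0.01, r=2.0),
        "HlyE_IgA": SeroresponseDraw("HlyE_IgA", y0=1.0, y1=60.0, t1=8.0,
                                     alpha=0.015, r=1.8),
    }


def default_noise() -> dict[str, NoiseParams]:
    return {
        "HlyE_IgG": NoiseParams("HlyE_IgG", nu=1.0, eps=0.2,
                                y_low=0.1, y_high=5000.0),
        "HlyE_IgA": NoiseParams("HlyE_IgA", nu=1.5, eps=0.2,
                                y_low=0.3, y_high=5000.0),
    }


#: per-parameter lognormal coefficients of variation for the default ensemble
DEFAULT_ENSEMBLE_CV = {"y0": 0.15, "y1": 0.15, "t1": 0.1, "alpha": 0.15,
                       "r": 0.1}


def simulate_sr_ensemble(center: SeroresponseDraw, cv_per_param, K: int,
                         seed: int) -> SRParamEnsemble:
    """Synthetic stand-in for the posterior-predictive kinetics ensemble.

    Each parameter is dispersed lognormally around the center (median =
    center value); the shape ``r`` is shifted so r ≥ 1 is preserved
    (``r = 1 + lognormal around r-1``; a center exactly at r = 1 stays
    degenerate at 1).  The invariant y1 > y0 is enforced by rejection.

    ``cv_per_param`` may be a scalar CV or a dict over
    {"y0","y1","t1","alpha","r"}.
    """
    if K < 1:
        raise SerorateError("K must be ≥ 1")
    if np.isscalar(cv_per_param):
        cv = {p: float(cv_per_param) for p in ("y0", "y1", "t1", "alpha", "r")}
    else:
        cv = {p: float(cv_per_param.get(p, 0.0))
              for p in ("y0", "y1", "t1", "alpha", "r")}
    if any(v < 0 for v in cv.values()):
        raise SerorateError("cv values must be ≥ 0")
    rng = np.random.default_rng(seed)

    def disperse(value, c, n):
        if c == 0:
            return np.full(n, value)
        s = np.sqrt(np.log1p(c * c))
        return value * np.exp(s * rng.standard_normal(n))

    rows, n_tried = [], 0
    while len(rows) < K:
        batch = max(K - len(rows), 16)
        n_tried += batch
        y0 = disperse(center.y0, cv["y0"], batch)
        y1 = disperse(center.y1, cv["y1"], batch)
        t1 = disperse(center.t1, cv["t1"], batch)
        alpha = disperse(center.alpha, cv["alpha"], batch)
        if center.r > 1.0:
            r = 1.0 + disperse(center.r - 1.0, cv["r"], batch)
        else:
            r = np.full(batch, 1.0)
        keep = y1 > y0
        for vals in zip(y0[keep], y1[keep], t1[keep], alpha[keep], r[keep]):
            rows.append(vals)
        if n_tried >= 100 * K and len(rows) < 0.01 * n_tried:
            raise SerorateError(
                "ensemble rejection rate > 99%: center/cv incoherent")
    df = pd.DataFrame(rows[:K], columns=["y0", "y1", "t1", "alpha", "r"])
    df.insert(0, "antigen_iso", center.antigen_iso)
    return SRParamEnsemble(df)


def default_ensemble(K: int = 20, seed: int = 0,
                     antigen_isos=None) -> SRParamEnsemble:
    """Default study-condition ensemble: K draws per default biomarker."""
    centers = default_center_draws()
    antigen_isos = list(antigen_isos or centers)
    parts = [simulate_sr_ensemble(centers[ai], DEFAULT_ENSEMBLE_CV, K,
                                  seed + 1000 * i).df
             for i, ai in enumerate(antigen_isos)]
    return SRParamEnsemble(pd.concat(parts, ignore_index=True))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cross-sectional survey."""

    lambda_true: float                      # events per person-year
    n_subjects: int
    ensemble: SRParamEnsemble
    noise: dict[str, NoiseParams]
    antigen_isos: list[str] = field(default_factory=list)
    age_range: tuple[float, float] = (2.0, 15.0)
    seed: int = 0
    apply_censoring: bool = True
    shared_tau: bool = False
    age_sampler: object = None              # callable (rng, n) -> ages (years)

    def __post_init__(self):
        if self.n_subjects < 1:
            raise SerorateError("n_subjects must be ≥ 1")
        lo, hi = self.age_range
        if not (0 < lo < hi):
            raise SerorateError("need 0 < age_min < age_max")
        if not (self.lambda_true > 0):
            raise SerorateError("lambda_true must be > 0")
        if not self.antigen_isos:
            self.antigen_isos = list(self.ensemble.antigen_isos)
        for ai in self.antigen_isos:
            if ai not in self.noise:
                raise SerorateError(f"no noise parameters for {ai!r}")


def _sample_tau(rng, lam_day, age_days):
    """Latent time since infection; NaN marks never-infected.

    P(never) = exp(-λ·age); otherwise inverse-CDF sampling of Exp(λ)
    truncated to (0, age) — exact, no rejection.
    """
    n = age_days.shape[0]
    p_never = np.exp(-lam_day * age_days)
    never = rng.uniform(size=n) < p_never
    u = rng.uniform(size=n)
    with np.errstate(divide="ignore"):
        tau = -np.log1p(-u * (1.0 - p_never)) / lam_day
    tau[never] = np.nan
    return tau


def simulate_survey(config: SimulationConfig):
    """Simulate a survey; returns (PopData, truth DataFrame).

    The truth table (one row per observation) records the latent τ in days
    (NaN when never infected), the kinetics draw index, the noiseless level
    and the censoring that was applied — for validation only, never used by
    the estimator.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    lam_day = config.lambda_true / DAYS_PER_YEAR
    if config.age_sampler is not None:
        ages = np.asarray(config.age_sampler(rng, n), dtype=float)
    else:
        ages = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    age_days = ages * DAYS_PER_YEAR
    ids = np.array([f"S{i:06d}" for i in range(n)])

    tau_shared = _sample_tau(rng, lam_day, age_days) if config.shared_tau else None

    pop_rows, truth_rows = [], []
    for ai in config.antigen_isos:
        g = config.ensemble.group(ai)
        nz = config.noise[ai]
        K = len(g)
        tau = tau_shared if config.shared_tau \
            else _sample_tau(rng, lam_day, age_days)
        k = rng.integers(0, K, size=n)
        y0 = g["y0"].to_numpy()[k]
        y1 = g["y1"].to_numpy()[k]
        t1 = g["t1"].to_numpy()[k]
        alpha = g["alpha"].to_numpy()[k]
        r = g["r"].to_numpy()[k]
        mu = np.log(y1 / y0) / t1
        infected = ~np.isnan(tau)
        y_model = np.zeros(n)
        y_model[infected] = _level_arrays(tau[infected], y0[infected],
                                          y1[infected], t1[infected],
                                          alpha[infected], r[infected],
                                          mu[infected])
        b = rng.uniform(0.0, nz.nu, size=n)
        if nz.eps > 0:
            s = np.sqrt(np.log1p(nz.eps ** 2))
            e = np.exp(s * rng.standard_normal(n) - 0.5 * s * s)
        else:
            e = np.ones(n)
        value = (y_model + b) * e
        censored = np.full(n, "", dtype=object)
        if config.apply_censoring:
            low = value <= nz.y_low
            high = value >= nz.y_high
            value = np.clip(value, nz.y_low, nz.y_high)
            censored[low] = "low"
            censored[high] = "high"
        pop_rows.append(pd.DataFrame({
            "id": ids, "age": ages, "antigen_iso": ai, "value": value}))
        truth_rows.append(pd.DataFrame({
            "id": ids, "antigen_iso": ai, "tau_days": tau,
            "infected": infected, "draw_index": k,
            "y_model": y_model, "censored": censored}))
    pop = PopData(pd.concat(pop_rows, ignore_index=True))
    truth = pd.concat(truth_rows, ignore_index=True)
    return pop, truth


def simulate_pop_data(config: SimulationConfig) -> PopData:
    """Simulated cross-sectional population data (see :func:`simulate_survey`)."""
    return simulate_survey(config)[0]


def recovery_experiment(lambda_grid, n: int, reps: int,
                        base_config: SimulationConfig,
                        est_opts: EstimationOptions | None = None,
                        lik_options: LikelihoodOptions | None = None
                        ) -> pd.DataFrame:
    """Simulate-and-estimate over a λ grid; the workhorse validation harness.

    For each λ on the grid, ``reps`` surveys of ``n`` subjects are simulated
    (seeds = base seed + replicate index) under ``base_config``'s ensemble,
    noise and ages, then estimated with the same ensemble.  Returns one row
    per λ with the mean/SD of λ̂, relative bias of the mean, and empirical
    95%-CI coverage.  Estimation failures are counted, never propagated.
    """
    import dataclasses as _dc

    if reps < 1:
        raise SerorateError("reps must be ≥ 1")
    est_opts = est_opts or EstimationOptions()
    rows = []
    for lam in lambda_grid:
        hats, covered, n_failed = [], 0, 0
        for rep in range(reps):
            cfg = _dc.replace(base_config, lambda_true=float(lam),
                              n_subjects=int(n),
                              seed=int(base_config.seed + rep))
            pop = simulate_pop_data(cfg)
            try:
                est = est_seroincidence(pop, cfg.ensemble, cfg.noise,
                                        cfg.antigen_isos, est_opts,
                                        lik_options)
            except SerorateError:
                n_failed += 1
                continue
            hats.append(est.lambda_hat)
            covered += int(est.ci_low <= lam <= est.ci_high)
        hats = np.asarray(hats)
        n_ok = len(hats)
        rows.append({
            "lambda_true": float(lam),
            "n_subjects": int(n),
            "reps": int(reps),
            "n_estimated": n_ok,
            "n_failed": n_failed,
            "mean_lambda_hat": float(hats.mean()) if n_ok else np.nan,
            "sd_lambda_hat": float(hats.std(ddof=1)) if n_ok > 1 else np.nan,
            "relative_bias": float(hats.mean() / lam - 1.0) if n_ok else np.nan,
            "ci_coverage": covered / n_ok if n_ok else np.nan,
        })
    return pd.DataFrame(rows)
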