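"""Cross-sectional likelihood of antibody measurements given seroincidence.

Generative model for one measurement Y on a subject of age ``a`` (days):

* Exposure is a Poisson process with rate λ (per day internally).  With
  probability ``exp(-λ a)`` the subject was never infected; otherwise the
  time since the most recent seroconversion τ has density
  ``λ exp(-λ τ)`` on ``(0, a)`` (truncated at birth).
* Given τ, the underlying antibody level is ``y_model = y(τ; θ_k)`` from the
  two-phase kinetics, with θ_k drawn uniformly from the K posterior draws of
  the antigen-isotype's seroresponse ensemble (equal-weight mixture);
  ``y_model = 0`` for the never-infected.
* The observed value is ``Y = (y_model + B) · E`` with biologic noise
  ``B ~ Uniform(0, ν)`` and multiplicative measurement noise
  ``E ~ LogNormal(-σ²/2, σ)``, ``σ² = ln(1 + ε²)`` so that ``E`` has mean 1
  (``E ≡ 1`` when ε = 0).
* Values at or outside the quantification limits contribute censored tail
  probabilities ``P(Y ≤ y_low)`` / ``P(Y ≥ y_high)`` instead of densities.

The Uniform×LogNormal noise convolution has a closed form in the normal CDF
(used for both pdf and cdf kernels; see docs/methods.md for the derivation),
so the only numerical integral is over τ.  That integral is evaluated after
the change of variables τ → ln y_model on each monotone branch of the
trajectory, with Gauss–Legendre panels refined geometrically towards the
high-antibody end, and restricted to the region where the noise kernel is
non-negligible (beyond ``tail_sigmas`` lognormal SDs the kernel is dropped).

Every per-observation likelihood reduces to the form

    p_i(λ) = Σ_c ω_c e^{-λ τ_c}  +  λ Σ_j g_j e^{-λ τ_j},

with λ-independent weights, so a fit precomputes (ω, g, τ) once and each
likelihood/gradient/curvature evaluation is a weighted sum of exponentials.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .data_model import (DAYS_PER_YEAR, NoiseParams, PopData, SerorateError,
                         SeroresponseDraw, SRParamEnsemble)
from .kinetics import _decay_time_arrays, _level_arrays

__all__ = [
    "LikelihoodOptions", "ObservationModel", "CrossSectionalLikelihood",
    "obs_density", "obs_cdf", "closed_form_density_no_noise", "neg_log_lik",
    "QuadratureError", "DensityZeroError",
]

_TINY = 1e-300

#: geometric panel offsets (in ln-concentration units, measured down from the
#: top of each integration range); the final huge offset guarantees coverage.
#: Spacing roughly doubles with depth: the exponential-survival weight decays
#: towards small antibody levels, so resolution is spent near the top.
DEFAULT_PANEL_OFFSETS = (0.0, 0.6, 1.3, 2.2, 3.5, 5.5, 9.0, 15.0, 26.0, 45.0,
                         80.0, 150.0, 1e6)


class QuadratureError(SerorateError):
    """Raised when refinement does not reach the requested tolerance."""

    def __init__(self, msg, diagnostics=None):
        super().__init__(msg)
        self.diagnostics = diagnostics


class DensityZeroError(SerorateError):
    """An observation's density is zero: the model cannot produce the value."""

    def __init__(self, antigen_iso, ids):
        super().__init__(
            f"zero likelihood for {antigen_iso} record(s) {list(ids[:10])}; "
            "the observation model cannot generate these values")
        self.antigen_iso = antigen_iso
        self.ids = list(ids)


@dataclass(frozen=True)
class LikelihoodOptions:
    """Numerical and structural options for one estimation run.

    mode
        "full" uses both noise sources; "no-measurement-noise" sets ε = 0;
        "noise-free" additionally shrinks ν to a numerical floor (1e-9),
        giving the pure change-of-variables limit.
    include_rise
        Whether the rise phase of the trajectory enters the τ-integral
        (True by default; False gives the decay-only submodel matched by the
        closed-form oracle).
    gl_nodes / panel_offsets
        Gauss–Legendre nodes per panel and the geometric panel layout.
    rel_tol / check_quadrature
        When checking, the integral is recomputed on a refined grid (double
        nodes, halved panel spacing) and a relative difference above
        ``rel_tol`` raises :class:`QuadratureError`.
    tail_sigmas
        Half-width of the noise-kernel window in lognormal SDs.
    """

    mode: str = "full"
    include_rise: bool = True
    gl_nodes: int = 6
    panel_offsets: tuple = DEFAULT_PANEL_OFFSETS
    tail_sigmas: float = 8.0
    rel_tol: float = 1e-6
    check_quadrature: bool = False

    def refined(self) -> "LikelihoodOptions":
        off = np.asarray(self.panel_offsets)
        mids = 0.5 * (off[:-1] + off[1:])
        new = tuple(sorted(set(np.concatenate([off, mids]))))
        return dataclasses.replace(self, gl_nodes=2 * self.gl_nodes,
                                   panel_offsets=new)


class ObservationModel:
    """Seroresponse ensemble + noise parameters for one antigen-isotype."""

    def __init__(self, antigen_iso: str, draws_df, noise: NoiseParams,
                 options: LikelihoodOptions | None = None):
        self.antigen_iso = antigen_iso
        self.noise = noise
        self.options = options or LikelihoodOptions()
        if self.options.mode not in ("full", "no-measurement-noise", "noise-free"):
            raise SerorateError(f"unknown mode {self.options.mode!r}")
        self.y0s = np.asarray(draws_df["y0"], dtype=float)
        self.y1s = np.asarray(draws_df["y1"], dtype=float)
        self.t1s = np.asarray(draws_df["t1"], dtype=float)
        self.alphas = np.asarray(draws_df["alpha"], dtype=float)
        self.rs = np.asarray(draws_df["r"], dtype=float)
        self.mus = np.log(self.y1s / self.y0s) / self.t1s
        self.K = len(self.y0s)
        if self.K < 1:
            raise SerorateError(f"no kinetics draws for {antigen_iso}")
        # effective noise under the composition mode
        if self.options.mode == "full":
            self.sigma = float(np.sqrt(np.log1p(noise.eps ** 2)))
            self.nu = float(noise.nu)
        elif self.options.mode == "no-measurement-noise":
            self.sigma, self.nu = 0.0, float(noise.nu)
        else:  # noise-free: numerical floor keeps the density well-defined
            self.sigma, self.nu = 0.0, 1e-9

    @classmethod
    def from_inputs(cls, ensemble: SRParamEnsemble, noise, antigen_iso: str,
                    options: LikelihoodOptions | None = None,
                    subsample: int | None = None, subsample_seed: int = 0):
        """Build from an ensemble and a noise dict/NoiseParams; optionally
        subsample K' ≤ K draws (seeded) for speed."""
        g = ensemble.group(antigen_iso)
        if subsample is not None and subsample < len(g):
            rng = np.random.default_rng(subsample_seed)
            g = g.iloc[np.sort(rng.choice(len(g), subsample, replace=False))]
        nz = noise[antigen_iso] if isinstance(noise, dict) else noise
        return cls(antigen_iso, g, nz, options)

    def with_options(self, options: LikelihoodOptions) -> "ObservationModel":
        df = {"y0": self.y0s, "y1": self.y1s, "t1": self.t1s,
              "alpha": self.alphas, "r": self.rs}
        return ObservationModel(self.antigen_iso, df, self.noise, options)


# ---------------------------------------------------------------------------
# noise kernels: Y = (m + B)·E, B ~ U(0, ν), E ~ LogNormal(-σ²/2, σ)
#
# pdf:  p(y|m) = (e^{σ²}/ν) [Φ(q(m)) - Φ(q(m+ν))],  q(u) = (ln(y/u) + 3σ²/2)/σ
# cdf:  P(Y≤c|m) = [A(m+ν) - A(m)]/ν,
#       A(u) = u Φ(h(u)) - c e^{σ²} Φ(h(u)+σ),  h(u) = (ln(c/u) + σ²/2)/σ,
#       A(0) = -c e^{σ²}.
# Both reduce to the Uniform(m, m+ν) pdf/cdf when σ = 0.


def _pdf_kernel(y, m, nu, sigma):
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    if sigma == 0.0:
        return np.where((m < y) & (y <= m + nu), 1.0 / nu, 0.0)
    s2 = sigma * sigma
    with np.errstate(divide="ignore", invalid="ignore"):
        q1 = np.where(m > 0,
                      (np.log(y / np.maximum(m, _TINY)) + 1.5 * s2) / sigma,
                      np.inf)
        q2 = (np.log(y / (m + nu)) + 1.5 * s2) / sigma
    out = (np.exp(s2) / nu) * (ndtr(q1) - ndtr(q2))
    return np.where(y > 0, out, 0.0)


def _cdf_antideriv(c, u, sigma):
    s2 = sigma * sigma
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(u > 0,
                     (np.log(np.maximum(c, _TINY) / np.maximum(u, _TINY))
                      + 0.5 * s2) / sigma,
                     np.inf)
    return np.where(u > 0,
                    u * ndtr(h) - c * np.exp(s2) * ndtr(h + sigma),
                    -c * np.exp(s2))


def _cdf_kernel(c, m, nu, sigma):
    c = np.asarray(c, dtype=float)
    m = np.asarray(m, dtype=float)
    if sigma == 0.0:
        with np.errstate(invalid="ignore"):
            return np.where(c > 0, np.clip((c - m) / nu, 0.0, 1.0), 0.0)
    out = (_cdf_antideriv(c, m + nu, sigma) - _cdf_antideriv(c, m, sigma)) / nu
    return np.where(c > 0, np.clip(out, 0.0, 1.0), 0.0)


def _sf_kernel(c, m, nu, sigma):
    return np.clip(1.0 - _cdf_kernel(c, m, nu, sigma), 0.0, 1.0)


def _never_pdf(y, nu, sigma):
    """Density of Y = B·E at y (the never-infected component)."""
    return _pdf_kernel(y, np.zeros_like(np.asarray(y, dtype=float)), nu, sigma)


def _never_cdf(c, nu, sigma):
    return _cdf_kernel(c, np.zeros_like(np.asarray(c, dtype=float)), nu, sigma)


# ---------------------------------------------------------------------------
# precomputed per-observation terms


@dataclass
class _GroupTerms:
    """Flat λ-independent representation of one antigen-isotype group."""

    n: int
    node_idx: np.ndarray    # observation index of each quadrature node
    node_tau: np.ndarray    # τ (days) at the node
    node_g: np.ndarray      # weight: contributes λ g e^{-λτ}
    const_idx: np.ndarray   # observation index of each closed-form term
    const_tau: np.ndarray
    const_w: np.ndarray     # contributes w e^{-λτ}


class _TermAccumulator:
    def __init__(self):
        self.ni, self.nt, self.ng = [], [], []
        self.ci, self.ct, self.cw = [], [], []

    def nodes(self, idx, tau, g):
        if len(idx):
            self.ni.append(np.asarray(idx, dtype=np.int64))
            self.nt.append(np.asarray(tau, dtype=float))
            self.ng.append(np.asarray(g, dtype=float))

    def consts(self, idx, tau, w):
        idx = np.asarray(idx, dtype=np.int64)
        tau = np.broadcast_to(np.asarray(tau, dtype=float), idx.shape)
        w = np.broadcast_to(np.asarray(w, dtype=float), idx.shape)
        keep = w != 0
        if keep.any():
            self.ci.append(idx[keep])
            self.ct.append(tau[keep])
            self.cw.append(w[keep])

    def build(self, n) -> _GroupTerms:
        cat = lambda parts, dt: (np.concatenate(parts) if parts
                                 else np.empty(0, dtype=dt))
        return _GroupTerms(
            n,
            cat(self.ni, np.int64), cat(self.nt, float), cat(self.ng, float),
            cat(self.ci, np.int64), cat(self.ct, float), cat(self.cw, float))


def _gl_rule(n):
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


def _branch_quad(acc, idx, c, lo, hi, valid, tau_of_m, dtau_dm, kern, scale,
                 offsets, xq, wq):
    """Accumulate quadrature nodes for ∫ kern(c, m) e^{...} dτ over one
    monotone trajectory branch, integrating in ln m over [lo, hi].

    ``scale`` multiplies the weights (mixture weight 1/K, orientation sign).
    The λ-dependent factor e^{-λτ} is applied at evaluation time.
    """
    lo = np.maximum(lo, _TINY)
    ok = valid & (hi > lo)
    if not ok.any():
        return
    lnlo = np.log(np.where(ok, lo, 1.0))
    lnhi = np.log(np.where(ok, np.where(hi > lo, hi, 2.0), 2.0))
    edges = np.maximum(lnhi[:, None] - offsets[None, :], lnlo[:, None])
    b, a = edges[:, :-1], edges[:, 1:]
    half = 0.5 * (b - a)
    lnm = (0.5 * (b + a))[:, :, None] + half[:, :, None] * xq
    m = np.exp(lnm)
    g = (half[:, :, None] * wq) * m * dtau_dm(m) * kern(c[:, None, None], m) * scale
    tau = tau_of_m(m)
    mask = ok[:, None, None] & (half[:, :, None] > 0) & (g != 0) & np.isfinite(g)
    if mask.any():
        flat_idx = np.broadcast_to(idx[:, None, None], g.shape)[mask]
        acc.nodes(flat_idx, tau[mask], g[mask])


def _build_group(y, age_days, model: ObservationModel,
                 options: LikelihoodOptions | None = None,
                 force_cdf: bool = False) -> _GroupTerms:
    """Precompute λ-independent likelihood terms for one group.

    Per observation the term set encodes either the density at ``y`` (interior
    values), the censored-low mass P(Y ≤ y_low), or the censored-high mass
    P(Y ≥ y_high).  With ``force_cdf`` every observation instead encodes
    P(Y ≤ y) (used for model-CDF evaluation).
    """
    opts = options or model.options
    y = np.asarray(y, dtype=float)
    age_days = np.broadcast_to(np.asarray(age_days, dtype=float), y.shape)
    nu, sigma = model.nu, model.sigma
    s = opts.tail_sigmas * sigma
    offsets = np.asarray(opts.panel_offsets, dtype=float)
    xq, wq = _gl_rule(opts.gl_nodes)
    acc = _TermAccumulator()
    n = y.shape[0]
    all_idx = np.arange(n, dtype=np.int64)

    if force_cdf:
        kinds = {"lo": (all_idx, y)}
    else:
        is_lo = y <= model.noise.y_low
        is_hi = y >= model.noise.y_high
        kinds = {
            "den": (all_idx[~is_lo & ~is_hi], None),
            "lo": (all_idx[is_lo], np.full(int(is_lo.sum()), model.noise.y_low)),
            "hi": (all_idx[is_hi], np.full(int(is_hi.sum()), model.noise.y_high)),
        }

    for kind, (idx, c_over) in kinds.items():
        if len(idx) == 0:
            continue
        c = y[idx] if c_over is None else np.asarray(c_over, dtype=float)
        a = age_days[idx]
        # noise-kernel window in underlying-level space
        wlo = c * np.exp(-s) - nu
        whi = c * np.exp(s)
        if kind == "den":
            acc.consts(idx, a, _never_pdf(c, nu, sigma))
            kern = lambda cc, mm: _pdf_kernel(cc, mm, nu, sigma)
        elif kind == "lo":
            acc.consts(idx, a, _never_cdf(c, nu, sigma))
            kern = lambda cc, mm: _cdf_kernel(cc, mm, nu, sigma)
        else:
            acc.consts(idx, a, np.clip(1.0 - _never_cdf(c, nu, sigma), 0, 1))
            kern = lambda cc, mm: _sf_kernel(cc, mm, nu, sigma)

        for k in range(model.K):
            y0, y1 = model.y0s[k], model.y1s[k]
            t1, alpha, r = model.t1s[k], model.alphas[k], model.rs[k]
            mu = model.mus[k]
            scale = 1.0 / model.K

            # ---- decay branch: m from level(age) (τ=age) up to y1 (τ=t1)
            has_decay = a > t1
            mA = _level_arrays(a, y0, y1, t1, alpha, r, mu)
            dec_tau = lambda m: _decay_time_arrays(m, y1, t1, alpha, r)
            dec_dtau = lambda m: 1.0 / (alpha * m ** r)
            if kind == "den":
                _branch_quad(acc, idx, c, np.maximum(mA, wlo),
                             np.minimum(np.full_like(c, y1), whi),
                             has_decay, dec_tau, dec_dtau, kern, scale,
                             offsets, xq, wq)
            elif kind == "lo":
                # plateau: m < wlo has P(Y≤c|m) = 1
                pl = has_decay & (wlo > mA)
                if pl.any():
                    m_cut = np.clip(wlo[pl], mA[pl], y1)
                    tau1 = _decay_time_arrays(m_cut, y1, t1, alpha, r)
                    acc.consts(idx[pl], tau1, scale)
                    acc.consts(idx[pl], a[pl], -scale)
                _branch_quad(acc, idx, c, np.maximum(mA, wlo),
                             np.minimum(np.full_like(c, y1), whi),
                             has_decay, dec_tau, dec_dtau, kern, scale,
                             offsets, xq, wq)
            else:
                # plateau: m > whi has P(Y≥c|m) = 1, i.e. τ ∈ [t1, τ(whi))
                pl = has_decay & (whi < y1)
                if pl.any():
                    m_cut = np.clip(whi[pl], mA[pl], y1)
                    tau1 = _decay_time_arrays(m_cut, y1, t1, alpha, r)
                    acc.consts(idx[pl], np.full(int(pl.sum()), t1), scale)
                    acc.consts(idx[pl], tau1, -scale)
                _branch_quad(acc, idx, c, np.maximum(mA, wlo),
                             np.minimum(np.full_like(c, y1), whi),
                             has_decay, dec_tau, dec_dtau, kern, scale,
                             offsets, xq, wq)

            # ---- rise branch: m from y0 (τ=0) up to level(min(t1, age))
            if not opts.include_rise:
                continue
            mBr = y0 * np.exp(mu * np.minimum(t1, a))
            rise_tau = lambda m: np.log(m / y0) / mu
            rise_dtau = lambda m: 1.0 / (mu * m)
            always = np.ones_like(a, dtype=bool)
            if kind == "lo":
                pl = wlo > y0
                if pl.any():
                    m_cut = np.minimum(wlo[pl], mBr[pl])
                    acc.consts(idx[pl], np.zeros(int(pl.sum())), scale)
                    acc.consts(idx[pl], np.log(m_cut / y0) / mu, -scale)
            elif kind == "hi":
                pl = whi < mBr
                if pl.any():
                    m_cut = np.maximum(whi[pl], y0)
                    acc.consts(idx[pl], np.log(m_cut / y0) / mu, scale)
                    acc.consts(idx[pl], np.minimum(t1, a[pl]), -scale)
            _branch_quad(acc, idx, c, np.maximum(np.full_like(c, y0), wlo),
                         np.minimum(mBr, whi), always, rise_tau, rise_dtau,
                         kern, scale, offsets, xq, wq)

    return acc.build(n)


def _bincount(idx, weights, n) -> np.ndarray:
    return np.bincount(idx, weights=weights, minlength=n).astype(float)


def _eval_terms(terms: _GroupTerms, lam_day: float) -> np.ndarray:
    ec = terms.const_w * np.exp(-lam_day * terms.const_tau)
    en = terms.node_g * np.exp(-lam_day * terms.node_tau)
    p = _bincount(terms.const_idx, ec, terms.n)
    p += lam_day * _bincount(terms.node_idx, en, terms.n)
    return p


def _eval_terms_derivs(terms: _GroupTerms, lam_day: float, order: int = 2):
    """Return (p, dp/dλ, d²p/dλ²) with λ in events/day."""
    ec = terms.const_w * np.exp(-lam_day * terms.const_tau)
    en = terms.node_g * np.exp(-lam_day * terms.node_tau)
    n = terms.n
    bc = lambda i, w: _bincount(i, w, n)
    C0 = bc(terms.const_idx, ec)
    S1 = bc(terms.node_idx, en)
    p = C0 + lam_day * S1
    C1 = bc(terms.const_idx, ec * terms.const_tau)
    T1 = bc(terms.node_idx, en * terms.node_tau)
    dp = -C1 + S1 - lam_day * T1
    if order < 2:
        return p, dp, None
    C2 = bc(terms.const_idx, ec * terms.const_tau ** 2)
    T2 = bc(terms.node_idx, en * terms.node_tau ** 2)
    d2p = C2 - 2.0 * T1 + lam_day * T2
    return p, dp, d2p


# ---------------------------------------------------------------------------
# public operations


def _as_points(y, age):
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    age_arr = np.broadcast_to(np.asarray(age, dtype=float), y_arr.shape)
    scalar = np.isscalar(y) or np.asarray(y).ndim == 0
    return y_arr, age_arr * DAYS_PER_YEAR, scalar


def obs_density(y, age, lam, model: ObservationModel):
    """Density (or censored probability mass) of an observed value.

    Parameters: ``y`` concentration (scalar or array), ``age`` in years,
    ``lam`` in events per person-year.  Values at/outside the quantification
    limits return the corresponding tail mass.  With
    ``model.options.check_quadrature`` the τ-integral is verified on a
    refined grid at ``rel_tol``.
    """
    if not lam > 0:
        raise SerorateError("lambda must be > 0")
    y_arr, age_days, scalar = _as_points(y, age)
    lam_day = lam / DAYS_PER_YEAR
    terms = _build_group(y_arr, age_days, model)
    p = _eval_terms(terms, lam_day)
    if model.options.check_quadrature:
        fine = _build_group(y_arr, age_days, model,
                            options=model.options.refined())
        p2 = _eval_terms(fine, lam_day)
        denom = np.maximum(np.abs(p2), _TINY)
        rel = np.abs(p - p2) / denom
        bad = rel > model.options.rel_tol
        if np.any(bad & (p2 > 1e-280)):
            raise QuadratureError(
                f"τ-quadrature did not converge to rel_tol="
                f"{model.options.rel_tol:g} for {int(bad.sum())} point(s)",
                diagnostics={"y": y_arr[bad], "coarse": p[bad],
                             "refined": p2[bad], "rel": rel[bad]})
        p = p2
    p = np.maximum(p, 0.0)
    return float(p[0]) if scalar else p


def obs_cdf(y, age, lam, model: ObservationModel):
    """Model CDF P(Y ≤ y | λ, age) of the (uncensored) observed value."""
    if not lam > 0:
        raise SerorateError("lambda must be > 0")
    y_arr, age_days, scalar = _as_points(y, age)
    terms = _build_group(y_arr, age_days, model, force_cdf=True)
    p = np.clip(_eval_terms(terms, lam / DAYS_PER_YEAR), 0.0, 1.0)
    return float(p[0]) if scalar else p


def closed_form_density_no_noise(y, age, lam, draw: SeroresponseDraw):
    """Analytic decay-only density in the no-noise limit (ε=0, ν→0).

    By the change of variables through dy/dτ = -alpha·y^r on the decay
    branch, ``p(y|λ) = λ e^{-λ τ(y)} / (alpha · y^r)`` for y between the
    level at age and y1; 0 outside that range (documented, not an error).
    The never-infected point mass exp(-λ·a_days) sits at the floor.
    """
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    scalar = np.isscalar(y) or np.asarray(y).ndim == 0
    lam_day = lam / DAYS_PER_YEAR
    a_days = age * DAYS_PER_YEAR
    floor = _level_arrays(np.array(a_days), draw.y0, draw.y1, draw.t1,
                          draw.alpha, draw.r,
                          np.log(draw.y1 / draw.y0) / draw.t1)
    out = np.zeros_like(y_arr)
    ok = (y_arr > floor) & (y_arr <= draw.y1)
    if ok.any():
        tau = _decay_time_arrays(y_arr[ok], draw.y1, draw.t1, draw.alpha, draw.r)
        out[ok] = lam_day * np.exp(-lam_day * tau) / (draw.alpha * y_arr[ok] ** draw.r)
    return float(out[0]) if scalar else out


class CrossSectionalLikelihood:
    """Precomputed multi-biomarker negative log-likelihood of a survey.

    Biomarkers are treated as independent, so the NLL is the sum of the
    per-antigen-isotype record NLLs; group sums are accumulated separately
    and added in the order the models are given, which makes additivity
    across biomarkers exact in floating point.
    """

    def __init__(self, pop: PopData, models: dict[str, ObservationModel]):
        self.groups = []
        self.n_observations = 0
        for ai, model in models.items():
            sub = pop.df[pop.df["antigen_iso"] == ai]
            if sub.empty:
                continue
            yv = sub["value"].to_numpy(dtype=float)
            ad = sub["age"].to_numpy(dtype=float) * DAYS_PER_YEAR
            terms = _build_group(yv, ad, model)
            self.groups.append((ai, terms, sub["id"].to_numpy()))
            self.n_observations += len(yv)
        if self.n_observations == 0:
            raise SerorateError("no observations for the requested biomarkers")

    def _probs(self, lam_day):
        for ai, terms, ids in self.groups:
            p = _eval_terms(terms, lam_day)
            self._check(p, ai, ids)
            yield p

    @staticmethod
    def _check(p, ai, ids):
        bad = ~(p > 0)
        if bad.any():
            raise DensityZeroError(ai, ids[bad])

    def nll(self, lam: float) -> float:
        """Negative log-likelihood at λ (events per person-year)."""
        if not lam > 0:
            raise SerorateError("lambda must be > 0")
        lam_day = lam / DAYS_PER_YEAR
        total = 0.0
        for p in self._probs(lam_day):
            total += -float(np.sum(np.log(p)))
        return total

    def nll_derivs(self, x: float, order: int = 2):
        """NLL and its derivatives w.r.t. x = ln λ (λ per person-year)."""
        lam = float(np.exp(x))
        lam_day = lam / DAYS_PER_YEAR
        val = grad = hess = 0.0
        for ai, terms, ids in self.groups:
            p, dp, d2p = _eval_terms_derivs(terms, lam_day, order)
            self._check(p, ai, ids)
            # d/dx = λ_day d/dλ_day
            dpdx = lam_day * dp
            val += -float(np.sum(np.log(p)))
            grad += -float(np.sum(dpdx / p))
            if order >= 2:
                d2pdx2 = lam_day * dp + lam_day ** 2 * d2p
                hess += -float(np.sum(d2pdx2 / p - (dpdx / p) ** 2))
        return (val, grad, hess) if order >= 2 else (val, grad)


def neg_log_lik(lam: float, pop: PopData,
                models: dict[str, ObservationModel]) -> float:
    """Multi-biomarker negative log-likelihood (convenience one-shot form).

    For repeated evaluation build a :class:`CrossSectionalLikelihood` once.
    """
    return CrossSectionalLikelihood(pop, models).nll(lam)
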