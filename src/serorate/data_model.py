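"""Typed containers, validation and CSV I/O for seroincidence inputs and outputs.

Three inputs drive a seroincidence analysis:

1. *Seroresponse parameters* — posterior draws of the within-host antibody
   trajectory parameters (``y0``, ``y1``, ``t1``, ``alpha``, ``r``) per
   antigen-isotype, previously estimated from longitudinal data on confirmed
   cases.  Held as an :class:`SRParamEnsemble`.
2. *Noise parameters* — per antigen-isotype biologic noise level ``nu``,
   measurement coefficient of variation ``eps`` and the assay quantification
   limits ``y_low`` / ``y_high``.  Held as :class:`NoiseParams`.
3. *Cross-sectional population data* — one quantitative antibody measurement
   per (participant, antigen-isotype), with age in years and optional strata
   covariates.  Held as :class:`PopData`.

Internally kinetics use **days** (``t1``, ``alpha``, the latent time since
infection) and survey age uses **years**; readers convert explicitly.  CSV is
the interchange format.  R users can export a data frame with
``write.csv(df, "file.csv", row.names = FALSE)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

#: canonical column names for each input schema
POP_COLUMNS = ("id", "age", "antigen_iso", "value")
SR_COLUMNS = ("antigen_iso", "y0", "y1", "t1", "alpha", "r")
NOISE_COLUMNS = ("antigen_iso", "nu", "eps", "y_low", "y_high")


class SerorateError(Exception):
    """Base class for all package errors."""


class DataValidationError(SerorateError):
    """Raised when an input violates its schema or invariants."""


def _normalize(name: str) -> str:
    """Normalize a CSV header: case-insensitive, dots == underscores.

    Accepts dialect synonyms such as ``y.low`` / ``y_low`` and ``y.0`` / ``y0``.
    """
    key = name.strip().lower().replace(".", "_").replace(" ", "_")
    # collapse separated digit suffixes: y_0 -> y0, y_1 -> y1, t_1 -> t1
    for a, b in (("y_0", "y0"), ("y_1", "y1"), ("t_1", "t1")):
        if key == a:
            key = b
    return key


def _resolve_columns(df: pd.DataFrame, required: tuple[str, ...],
                     column_map: dict[str, str] | None = None) -> dict[str, str]:
    """Map canonical column names to actual dataframe columns.

    ``column_map`` entries (canonical -> actual) take precedence over
    auto-detection by normalized header name.
    """
    column_map = column_map or {}
    norm_to_actual: dict[str, str] = {}
    for col in df.columns:
        norm_to_actual.setdefault(_normalize(col), col)
    out: dict[str, str] = {}
    for canon in required:
        if canon in column_map:
            actual = column_map[canon]
            if actual not in df.columns:
                raise DataValidationError(
                    f"mapped column {actual!r} for {canon!r} not found")
            out[canon] = actual
        elif _normalize(canon) in norm_to_actual:
            out[canon] = norm_to_actual[_normalize(canon)]
        else:
            raise DataValidationError(f"required column {canon!r} not found")
    return out


def _numeric(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.index[out.isna()]
    if len(bad):
        raise DataValidationError(
            f"non-numeric {what} at row index {list(bad[:10])}")
    return out.astype(float)


# ---------------------------------------------------------------------------
# seroresponse parameters


@dataclass(frozen=True)
class SeroresponseDraw:
    """One posterior draw of the two-phase antibody trajectory parameters.

    Units: ``y0``/``y1`` in antibody concentration units, ``t1`` in days,
    ``alpha`` in concentration^(1-r)/day, ``r`` dimensionless (>= 1).
    """

    antigen_iso: str
    y0: float
    y1: float
    t1: float
    alpha: float
    r: float

    def __post_init__(self) -> None:
        if not (self.y0 > 0):
            raise DataValidationError(f"{self.antigen_iso}: y0 must be > 0")
        if not (self.y1 > self.y0):
            raise DataValidationError(f"{self.antigen_iso}: y1 must be > y0")
        if not (self.t1 > 0):
            raise DataValidationError(f"{self.antigen_iso}: t1 must be > 0")
        if not (self.alpha > 0):
            raise DataValidationError(f"{self.antigen_iso}: alpha must be > 0")
        if not (self.r >= 1):
            raise DataValidationError(f"{self.antigen_iso}: r must be ≥ 1")


class SRParamEnsemble:
    """A collection of seroresponse draws grouped by antigen-isotype.

    The ensemble represents predictive uncertainty in the antibody kinetics:
    the cross-sectional likelihood is an equal-weight mixture over the draws
    of each antigen-isotype.  Internal time unit is always days.
    Optional extra columns are kept as stratum labels (curves that differ by
    subpopulation).
    """

    def __init__(self, df: pd.DataFrame, strata: tuple[str, ...] = ()):
        self.df = df.reset_index(drop=True)
        self.strata = tuple(strata)
        self._validate()

    def _validate(self) -> None:
        df = self.df
        for col in SR_COLUMNS[1:]:
            if not np.issubdtype(df[col].dtype, np.number):
                raise DataValidationError(f"column {col!r} must be numeric")
        checks = [
            (~(df["y0"] > 0), "y0 must be > 0"),
            (~(df["y1"] > df["y0"]), "y1 must be > y0"),
            (~(df["t1"] > 0), "t1 must be > 0"),
            (~(df["alpha"] > 0), "alpha must be > 0"),
            (~(df["r"] >= 1), "r must be ≥ 1"),
        ]
        for bad, msg in checks:
            if bad.any():
                idx = list(df.index[bad][:10])
                raise DataValidationError(f"{msg} (draw index {idx})")
        if df.empty:
            raise DataValidationError("seroresponse ensemble is empty")

    @property
    def antigen_isos(self) -> list[str]:
        return list(dict.fromkeys(self.df["antigen_iso"]))

    def group(self, antigen_iso: str) -> pd.DataFrame:
        g = self.df[self.df["antigen_iso"] == antigen_iso]
        if g.empty:
            raise DataValidationError(
                f"no seroresponse draws for {antigen_iso!r}")
        return g.reset_index(drop=True)

    def n_draws(self, antigen_iso: str) -> int:
        return int((self.df["antigen_iso"] == antigen_iso).sum())

    def restrict(self, mask_or_query: pd.Series) -> "SRParamEnsemble":
        return SRParamEnsemble(self.df[mask_or_query], self.strata)

    def draws(self, antigen_iso: str) -> list[SeroresponseDraw]:
        g = self.group(antigen_iso)
        return [SeroresponseDraw(antigen_iso, *row)
                for row in g[["y0", "y1", "t1", "alpha", "r"]].itertuples(index=False)]


def read_sr_params(source, time_unit: str = "day") -> SRParamEnsemble:
    """Read seroresponse parameter draws from CSV.

    Parameters
    ----------
    source : path or file-like
        CSV with columns ``antigen_iso, y0, y1, t1, alpha, r`` (dialect
        synonyms such as ``y.0`` accepted); extra columns are retained as
        stratum labels.
    time_unit : {"day", "year"}
        Unit of ``t1`` and ``alpha`` in the file.  ``"year"`` converts to the
        internal day scale (``t1 *= 365.25``, ``alpha /= 365.25``).
    """
    if time_unit not in ("day", "year"):
        raise DataValidationError(f"unknown time_unit {time_unit!r}")
    raw = pd.read_csv(source)
    cols = _resolve_columns(raw, SR_COLUMNS)
    df = pd.DataFrame({"antigen_iso": raw[cols["antigen_iso"]].astype(str)})
    for c in SR_COLUMNS[1:]:
        df[c] = _numeric(raw, cols[c], c)
    if time_unit == "year":
        df["t1"] = df["t1"] * DAYS_PER_YEAR
        df["alpha"] = df["alpha"] / DAYS_PER_YEAR
    extras = [c for c in raw.columns if c not in cols.values()]
    for c in extras:
        df[c] = raw[c]
    return SRParamEnsemble(df, strata=tuple(extras))


def write_sr_params(ensemble: SRParamEnsemble, path) -> None:
    ensemble.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# noise parameters


@dataclass(frozen=True)
class NoiseParams:
    """Assay/biology noise and quantification limits for one antigen-isotype.

    ``nu`` is the biologic noise level (concentration units): the upper level
    of antibody signal seen in never-exposed individuals through non-specific
    binding.  ``eps`` is the measurement coefficient of variation of the
    assay.  Observations at or outside ``[y_low, y_high]`` are censored.
    """

    antigen_iso: str
    nu: float
    eps: float
    y_low: float
    y_high: float

    def __post_init__(self) -> None:
        if not (self.nu > 0):
            raise DataValidationError(f"{self.antigen_iso}: nu must be > 0")
        if not (self.eps >= 0):
            raise DataValidationError(f"{self.antigen_iso}: eps must be ≥ 0")
        if not (0 <= self.y_low < self.y_high):
            raise DataValidationError(
                f"{self.antigen_iso}: need 0 ≤ y_low < y_high")


def read_noise_params(source) -> dict[str, NoiseParams]:
    """Read per-antigen-isotype noise parameters from CSV.

    Expects columns ``antigen_iso, nu, eps, y.low, y.high`` (dot or
    underscore forms).  Returns a dict keyed by antigen-isotype.
    """
    raw = pd.read_csv(source)
    cols = _resolve_columns(raw, NOISE_COLUMNS)
    out: dict[str, NoiseParams] = {}
    for i in range(len(raw)):
        ai = str(raw[cols["antigen_iso"]].iloc[i])
        if ai in out:
            raise DataValidationError(f"duplicate noise row for {ai!r}")
        out[ai] = NoiseParams(
            ai,
            float(_numeric(raw, cols["nu"], "nu").iloc[i]),
            float(_numeric(raw, cols["eps"], "eps").iloc[i]),
            float(_numeric(raw, cols["y_low"], "y_low").iloc[i]),
            float(_numeric(raw, cols["y_high"], "y_high").iloc[i]),
        )
    if not out:
        raise DataValidationError("noise parameter file is empty")
    return out


def write_noise_params(noise: dict[str, NoiseParams], path) -> None:
    pd.DataFrame(
        [{"antigen_iso": n.antigen_iso, "nu": n.nu, "eps": n.eps,
          "y.low": n.y_low, "y.high": n.y_high} for n in noise.values()]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cross-sectional population data


class PopData:
    """Long-format cross-sectional antibody measurements.

    One row per (participant, antigen-isotype): ``id`` (string), ``age``
    (years, > 0), ``antigen_iso``, ``value`` (concentration, ≥ 0), plus any
    number of strata covariate columns.
    """

    def __init__(self, df: pd.DataFrame, strata: tuple[str, ...] = ()):
        self.df = df.reset_index(drop=True)
        self.strata = tuple(strata)
        self._validate()

    def _validate(self) -> None:
        df = self.df
        if (~(df["age"] > 0)).any():
            idx = list(df.index[~(df["age"] > 0)][:10])
            raise DataValidationError(f"age must be > 0 (row index {idx})")
        if (~(df["value"] >= 0)).any():
            idx = list(df.index[~(df["value"] >= 0)][:10])
            raise DataValidationError(f"value must be ≥ 0 (row index {idx})")
        dup = df.duplicated(subset=["id", "antigen_iso"])
        if dup.any():
            ids = sorted(set(df.loc[dup, "id"].astype(str)))[:10]
            raise DataValidationError(
                f"duplicated (id, antigen_iso) rows for ids {ids}")

    @property
    def antigen_isos(self) -> list[str]:
        return list(dict.fromkeys(self.df["antigen_iso"]))

    @property
    def n_subjects(self) -> int:
        return int(self.df["id"].nunique())

    def subset(self, antigen_isos) -> "PopData":
        """Rows for the requested antigen-isotypes, original order kept."""
        mask = self.df["antigen_iso"].isin(list(antigen_isos))
        return PopData(self.df[mask], self.strata)

    def split_by(self, strata: tuple[str, ...]):
        """Yield (stratum dict, PopData) per observed strata combination."""
        for name in strata:
            if name not in self.df.columns:
                raise DataValidationError(f"unknown covariate {name!r}")
        groups = self.df.groupby(list(strata), sort=True, dropna=False)
        for key, g in groups:
            if not isinstance(key, tuple):
                key = (key,)
            yield dict(zip(strata, key)), PopData(g, self.strata)


def read_pop_data(source, column_map: dict[str, str] | None = None) -> PopData:
    """Read cross-sectional population data from CSV.

    Default column names (``id, age, antigen_iso, value``) are auto-detected
    case-insensitively; ``column_map`` overrides detection (canonical ->
    actual name).  Extra columns are retained as strata covariates.
    """
    raw = pd.read_csv(source)
    cols = _resolve_columns(raw, POP_COLUMNS, column_map)
    df = pd.DataFrame({
        "id": raw[cols["id"]].astype(str),
        "age": _numeric(raw, cols["age"], "age"),
        "antigen_iso": raw[cols["antigen_iso"]].astype(str),
        "value": _numeric(raw, cols["value"], "value"),
    })
    extras = [c for c in raw.columns if c not in cols.values()]
    for c in extras:
        df[c] = raw[c]
    return PopData(df, strata=tuple(extras))


def write_pop_data(pop: PopData, path) -> None:
    cols = list(POP_COLUMNS) + [c for c in pop.strata]
    pop.df[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# estimates


@dataclass
class SeroincidenceEstimate:
    """A fitted seroincidence rate λ with uncertainty and provenance.

    Rates are in events per person-year; the CI is a Wald interval on the
    natural-log scale: ``exp(log_lambda_hat ∓ 1.96 · se_log_lambda)``.
    """

    log_lambda_hat: float
    se_log_lambda: float
    lambda_hat: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_observations: int
    antigen_isos: list[str]
    stratum: dict = field(default_factory=dict)
    converged: bool = True
    nll_at_optimum: float = float("nan")

    @classmethod
    def from_log_scale(cls, log_lambda_hat: float, se_log_lambda: float,
                       **kw) -> "SeroincidenceEstimate":
        lam = float(np.exp(log_lambda_hat))
        half = 1.96 * se_log_lambda
        return cls(log_lambda_hat=float(log_lambda_hat),
                   se_log_lambda=float(se_log_lambda),
                   lambda_hat=lam,
                   ci_low=float(np.exp(log_lambda_hat - half)),
                   ci_high=float(np.exp(log_lambda_hat + half)),
                   **kw)


def write_estimates(estimates, path, strata: tuple[str, ...] = ()) -> None:
    """Write one or more estimates to CSV (6 significant digits)."""
    if isinstance(estimates, SeroincidenceEstimate):
        estimates = [estimates]
    rows = []
    for e in estimates:
        row = {name: e.stratum.get(name, "") for name in strata}
        row.update({
            "antigen_isos": ";".join(e.antigen_isos),
            "lambda_hat": e.lambda_hat,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "se_log_lambda": e.se_log_lambda,
            "n_subjects": e.n_subjects,
            "converged": e.converged,
        })
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# cross-input validation


@dataclass
class ValidationReport:
    """Presence of each requested antigen-isotype in the three inputs, plus
    counts of population values outside the quantification limits (these are
    not errors — they are censored downstream)."""

    antigen_isos: list[str]
    in_pop: dict[str, bool]
    in_ensemble: dict[str, bool]
    in_noise: dict[str, bool]
    censor_warnings: dict[str, int]
    messages: list[str]

    @property
    def ok(self) -> bool:
        return all(self.in_pop.values()) and all(self.in_ensemble.values()) \
            and all(self.in_noise.values())

    def __str__(self) -> str:
        lines = []
        for ai in self.antigen_isos:
            lines.append(
                f"{ai}: pop={'yes' if self.in_pop[ai] else 'MISSING'} "
                f"ensemble={'yes' if self.in_ensemble[ai] else 'MISSING'} "
                f"noise={'yes' if self.in_noise[ai] else 'MISSING'} "
                f"outside_limits={self.censor_warnings.get(ai, 0)}")
        lines += self.messages
        return "\n".join(lines)


def validate_inputs(pop: PopData, ensemble: SRParamEnsemble,
                    noise: dict[str, NoiseParams], antigen_isos,
                    raise_on_error: bool = True) -> ValidationReport:
    """Check that every requested antigen-isotype is present in all three
    inputs; warn (not fail) on values outside the quantification limits."""
    antigen_isos = list(antigen_isos)
    pop_set = set(pop.antigen_isos)
    ens_set = set(ensemble.antigen_isos)
    report = ValidationReport(
        antigen_isos=antigen_isos,
        in_pop={ai: ai in pop_set for ai in antigen_isos},
        in_ensemble={ai: ai in ens_set for ai in antigen_isos},
        in_noise={ai: ai in noise for ai in antigen_isos},
        censor_warnings={},
        messages=[],
    )
    for ai in antigen_isos:
        if ai in noise and ai in pop_set:
            np_ = noise[ai]
            vals = pop.df.loc[pop.df["antigen_iso"] == ai, "value"]
            n_out = int(((vals <= np_.y_low) | (vals >= np_.y_high)).sum())
            report.censor_warnings[ai] = n_out
            if n_out:
                report.messages.append(
                    f"{ai}: {n_out} value(s) at/outside [y_low, y_high] "
                    "will be treated as censored")
    if raise_on_error:
        for label, presence in (("population data", report.in_pop),
                                ("seroresponse parameters", report.in_ensemble),
                                ("noise parameters", report.in_noise)):
            missing = [ai for ai, ok in presence.items() if not ok]
            if missing:
                raise DataValidationError(
                    f"{', '.join(missing)} missing from {label}")
    return report
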