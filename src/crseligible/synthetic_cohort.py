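"""Synthetic CRSwNP cohort generator calibrated to published marginals.

The registry behind the published cohort is not public, so every pipeline
stage is exercised on synthetic cohorts whose *marginal* distributions,
category frequencies and per-field missingness emulate the published
patient-characteristics table (n = 206) and the denominators of the
indication tables.  Only marginals are published; the joint distribution is
not identifiable, so no attempt is made to reproduce composite counts.

Families
--------
* ``truncnorm`` — mean/SD fields reported as mean ± SD (age, BMI), truncated
  to a plausible range.
* ``lognormal`` — strictly positive right-skewed labs (blood eosinophils,
  total IgE) and disease duration, calibrated to the published
  median/quartiles.
* ``scaled_beta`` — bounded scores (SNOT-22 on [0,110], Lund-Mackay on
  [0,24], the three VAS scales on [0,100]), calibrated to median/quartiles.
* ``categorical`` / ``banded_int`` — reported category or band frequencies
  (sex, smoking; surgery/corticosteroid counts, nasal polyp score bands,
  uniform within band).
* ``bernoulli`` — comorbidity and treatment flags.

Median/IQR calibration is *median-anchored*: the family's median matches
the published median exactly (the location parameter in closed form for the
log-normal, a root-finding constraint for the scaled beta) and the spread
parameter is least-squares fitted to the two quartiles.  The published
quartiles are asymmetric around the median on every scale, so a symmetric
three-quantile fit would trade median error for quartile error; anchoring
keeps the statistic the acceptance checks target — the sample median —
unbiased, at the price of a few percent residual on the quartiles.

Dependence is a single shared standard-normal severity factor with
per-field loadings (Gaussian copula); the default loading is 0 everywhere,
i.e. independent fields, which the published margins are consistent with.
Missingness is missing-completely-at-random with per-field rates derived
from the printed denominators (e.g. nasal polyp score observed in 158 of
206 patients).
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import yaml
from scipy import optimize, stats

from .cohort_model import FIELDS, CohortTable, PatientRecord

__all__ = [
    "CalibrationError", "ConfigError", "Marginal", "TruncNormal", "LogNormal",
    "ScaledBeta", "Categorical", "BandedInt", "Bernoulli",
    "calibrate_quantiles", "GeneratorConfig", "default_config",
    "generate_cohort", "apply_missingness", "simulate_cohort",
]

_Z75 = float(stats.norm.ppf(0.75))
_FIT_XTOL = 1e-6


class CalibrationError(ValueError):
    """Quantile targets infeasible for the requested family."""


class ConfigError(ValueError):
    """Invalid generator configuration."""


def _round_values(x: np.ndarray, decimals: Optional[int]):
    if decimals is None:
        return [float(v) for v in x]
    if decimals == 0:
        return [int(v) for v in np.rint(x)]
    return [float(v) for v in np.round(x, decimals)]


@dataclass(frozen=True)
class TruncNormal:
    """Normal(mean, sd) truncated to [low, high]."""

    mean: float
    sd: float
    low: float
    high: float
    decimals: Optional[int] = 1

    def ppf(self, u: np.ndarray):
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        x = stats.truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)
        x = np.clip(x, self.low, self.high)
        return _round_values(x, self.decimals)


@dataclass(frozen=True)
class LogNormal:
    """exp(Normal(mu, sigma)); median = exp(mu).

    ``high`` optionally clips the far right tail (e.g. disease duration
    cannot exceed a lifetime); it should sit well above q3 so the clipped
    mass is negligible and the calibrated quartiles are unaffected.
    """

    mu: float
    sigma: float
    decimals: Optional[int] = 1
    high: Optional[float] = None

    def quantiles(self) -> Tuple[float, float, float]:
        """(median, q1, q3) implied by the parameters."""
        m = float(np.exp(self.mu))
        return (m, float(np.exp(self.mu - _Z75 * self.sigma)),
                float(np.exp(self.mu + _Z75 * self.sigma)))

    def ppf(self, u: np.ndarray):
        x = np.exp(self.mu + self.sigma * stats.norm.ppf(u))
        if self.high is not None:
            x = np.minimum(x, self.high)
        return _round_values(x, self.decimals)


@dataclass(frozen=True)
class ScaledBeta:
    """low + (high - low) * Beta(a, b)."""

    a: float
    b: float
    low: float
    high: float
    decimals: Optional[int] = 1

    def quantiles(self) -> Tuple[float, float, float]:
        q = self.low + (self.high - self.low) * stats.beta.ppf(
            [0.5, 0.25, 0.75], self.a, self.b)
        return tuple(float(v) for v in q)

    def ppf(self, u: np.ndarray):
        x = self.low + (self.high - self.low) * stats.beta.ppf(u, self.a, self.b)
        x = np.clip(x, self.low, self.high)
        return _round_values(x, self.decimals)


@dataclass(frozen=True)
class Categorical:
    """Labelled categories with given probabilities (normalized on input)."""

    labels: Tuple[str, ...]
    probs: Tuple[float, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.probs) or not self.labels:
            raise ConfigError("labels and probs must be non-empty, same length")
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0):
            raise ConfigError("negative category probability")
        total = float(p.sum())
        if abs(total - 1.0) > 0.01:
            raise ConfigError(f"category probabilities sum to {total}, not 1")
        object.__setattr__(self, "probs", tuple(float(v) for v in p / total))

    def ppf(self, u: np.ndarray):
        cum = np.cumsum(self.probs)
        idx = np.minimum(np.searchsorted(cum, u, side="right"),
                         len(self.labels) - 1)
        return [self.labels[i] for i in idx]


@dataclass(frozen=True)
class BandedInt:
    """Integer bands with given frequencies, uniform within each band.

    The within-band position reuses the residual of the copula uniform
    inside its band's probability interval, so higher latent severity maps
    to higher values within as well as across bands.
    """

    bands: Tuple[Tuple[int, int], ...]
    probs: Tuple[float, ...]

    def __post_init__(self):
        if len(self.bands) != len(self.probs) or not self.bands:
            raise ConfigError("bands and probs must be non-empty, same length")
        for lo, hi in self.bands:
            if lo > hi:
                raise ConfigError(f"band ({lo}, {hi}) reversed")
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0):
            raise ConfigError("negative band probability")
        total = float(p.sum())
        if abs(total - 1.0) > 0.01:
            raise ConfigError(f"band probabilities sum to {total}, not 1")
        object.__setattr__(self, "probs", tuple(float(v) for v in p / total))
        object.__setattr__(self, "bands",
                           tuple((int(lo), int(hi)) for lo, hi in self.bands))

    def ppf(self, u: np.ndarray):
        cum = np.cumsum(self.probs)
        lower = np.concatenate([[0.0], cum[:-1]])
        idx = np.minimum(np.searchsorted(cum, u, side="right"),
                         len(self.bands) - 1)
        out = []
        for ui, i in zip(u, idx):
            lo, hi = self.bands[i]
            width = hi - lo + 1
            span = cum[i] - lower[i]
            resid = (ui - lower[i]) / span if span > 0 else 0.0
            out.append(lo + min(int(resid * width), width - 1))
        return out


@dataclass(frozen=True)
class Bernoulli:
    """Boolean with success probability p (upper copula tail = True)."""

    p: float

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ConfigError(f"bernoulli p={self.p} outside [0, 1]")

    def ppf(self, u: np.ndarray):
        return [bool(v) for v in (u >= 1.0 - self.p)]


Marginal = Union[TruncNormal, LogNormal, ScaledBeta, Categorical, BandedInt,
                 Bernoulli]


# ---------------------------------------------------------------------------
# calibration


def calibrate_quantiles(median: float, q1: float, q3: float, family: str,
                        *, low: Optional[float] = None,
                        high: Optional[float] = None,
                        decimals: Optional[int] = 1) -> Marginal:
    """Fit a two-parameter family to published (median, q1, q3).

    Median-anchored: the returned distribution's median equals *median*
    exactly; the spread parameter minimizes the squared error of the two
    theoretical quartiles against (q1, q3).  Supported families:
    ``"lognormal"`` (closed form) and ``"scaled_beta"`` (bounded numerical
    search, tolerance 1e-6; requires *low* < *high* bracketing the targets).

    Raises :class:`CalibrationError` for disordered or infeasible targets.
    """
    if not (q1 <= median <= q3):
        raise CalibrationError(
            f"targets must satisfy q1 <= median <= q3, got "
            f"({q1}, {median}, {q3})")
    if family == "lognormal":
        if q1 <= 0:
            raise CalibrationError("lognormal targets must be positive")
        mu = float(np.log(median))
        # least squares on the two log-quartiles, median held fixed
        sigma = float((np.log(q3) - np.log(q1)) / (2.0 * _Z75))
        if sigma <= 0:
            raise CalibrationError("degenerate spread (q1 == q3)")
        if high is not None and high < q3:
            raise CalibrationError(f"clip bound {high} below q3 target {q3}")
        return LogNormal(mu=mu, sigma=sigma, decimals=decimals, high=high)
    if family == "scaled_beta":
        if low is None or high is None or not low < high:
            raise CalibrationError("scaled_beta requires bounds low < high")
        if not (low <= q1 and q3 <= high):
            raise CalibrationError(
                f"targets ({q1}, {median}, {q3}) outside range "
                f"[{low}, {high}]")
        if q1 == q3:
            raise CalibrationError("degenerate spread (q1 == q3)")
        span = high - low
        m, t1, t3 = [(t - low) / span for t in (median, q1, q3)]
        if not (0.0 < m < 1.0):
            raise CalibrationError("median must lie strictly inside the range")

        def b_for(a: float) -> float:
            f = lambda b: stats.beta.ppf(0.5, a, b) - m
            return optimize.brentq(f, 1e-8, 1e8, xtol=1e-12)

        def quartile_sse(log_a: float) -> float:
            a = float(np.exp(log_a))
            b = b_for(a)
            qq = stats.beta.ppf([0.25, 0.75], a, b)
            return float((qq[0] - t1) ** 2 + (qq[1] - t3) ** 2)

        res = optimize.minimize_scalar(
            quartile_sse, bounds=(np.log(1e-3), np.log(1e3)),
            method="bounded", options={"xatol": _FIT_XTOL})
        a = float(np.exp(res.x))
        return ScaledBeta(a=a, b=float(b_for(a)), low=float(low),
                          high=float(high), decimals=decimals)
    raise CalibrationError(f"unknown or uncalibratable family {family!r}")


# ---------------------------------------------------------------------------
# configuration


#: Fields apply_missingness may blank (everything except the identifier).
MASKABLE_FIELDS = tuple(c for c in FIELDS if c != "patient_id")


@dataclass
class GeneratorConfig:
    """Cohort size, seed, marginals, dependence loadings, missingness."""

    n: int
    seed: int
    marginals: Dict[str, Marginal]
    loadings: Dict[str, float] = dc_field(default_factory=dict)
    missingness: Dict[str, float] = dc_field(default_factory=dict)

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigError(f"n={self.n} must be >= 0")
        for name in self.marginals:
            if name not in FIELDS or name == "patient_id":
                raise ConfigError(f"marginal for unknown field {name!r}")
        for name, lam in self.loadings.items():
            if name not in self.marginals:
                raise ConfigError(f"loading for unconfigured field {name!r}")
            if not -1.0 <= lam <= 1.0:
                raise ConfigError(f"loading {name}={lam} outside [-1, 1]")
        for name, rate in self.missingness.items():
            if name not in MASKABLE_FIELDS:
                raise ConfigError(f"missingness rate for unknown field {name!r}")
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"missingness {name}={rate} outside [0, 1]")


def _marginal_from_dict(name: str, doc: Mapping) -> Marginal:
    family = doc.get("family")
    decimals = doc.get("decimals", 1)
    if family == "truncnorm":
        return TruncNormal(doc["mean"], doc["sd"], doc["low"], doc["high"],
                           decimals=decimals)
    if family == "lognormal":
        if "mu" in doc:
            return LogNormal(doc["mu"], doc["sigma"], decimals=decimals,
                             high=doc.get("high"))
        return calibrate_quantiles(doc["median"], doc["q1"], doc["q3"],
                                   "lognormal", decimals=decimals,
                                   high=doc.get("high"))
    if family == "scaled_beta":
        if "a" in doc:
            return ScaledBeta(doc["a"], doc["b"], doc["low"], doc["high"],
                              decimals=decimals)
        return calibrate_quantiles(doc["median"], doc["q1"], doc["q3"],
                                   "scaled_beta", low=doc["low"],
                                   high=doc["high"], decimals=decimals)
    if family == "categorical":
        return Categorical(tuple(doc["labels"]), tuple(doc["probs"]))
    if family == "banded_int":
        return BandedInt(tuple(tuple(b) for b in doc["bands"]),
                         tuple(doc["probs"]))
    if family == "bernoulli":
        return Bernoulli(doc["p"])
    raise ConfigError(f"field {name!r}: unknown family {family!r}")


def config_from_dict(doc: Mapping, *, n: Optional[int] = None,
                     seed: Optional[int] = None) -> GeneratorConfig:
    """Build a validated config from a parsed YAML/JSON mapping; *n* and
    *seed* override the document's values."""
    try:
        marginals = {name: _marginal_from_dict(name, spec)
                     for name, spec in doc["marginals"].items()}
    except KeyError as exc:
        raise ConfigError(f"missing configuration key: {exc}") from exc
    config = GeneratorConfig(
        n=int(doc.get("n", 0)) if n is None else int(n),
        seed=int(doc.get("seed", 0)) if seed is None else int(seed),
        marginals=marginals,
        loadings={k: float(v) for k, v in (doc.get("loadings") or {}).items()},
        missingness={k: float(v)
                     for k, v in (doc.get("missingness") or {}).items()},
    )
    config.validate()
    return config


def config_from_yaml(path: Union[str, Path], *, n: Optional[int] = None,
                     seed: Optional[int] = None) -> GeneratorConfig:
    """Load a generator configuration from a YAML (or JSON) file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return config_from_dict(doc, n=n, seed=seed)


def default_config(*, n: Optional[int] = None,
                   seed: Optional[int] = None) -> GeneratorConfig:
    """The packaged configuration calibrated to the published cohort."""
    ref = importlib.resources.files("crseligible").joinpath(
        "data/default_generator.yaml")
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return config_from_dict(doc, n=n, seed=seed)


# ---------------------------------------------------------------------------
# generation


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw a fully observed cohort of ``config.n`` records.

    Sampling is Gaussian-copula style: one shared standard-normal severity
    factor per patient, one idiosyncratic normal per field, combined with
    the field's loading, mapped through the standard-normal CDF to a
    uniform, then through the marginal's quantile function.  Deterministic
    given the seed.  Missingness is NOT applied here; see
    :func:`apply_missingness` / :func:`simulate_cohort`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    factor = rng.standard_normal(n)
    columns: Dict[str, list] = {}
    for name, marginal in config.marginals.items():
        lam = config.loadings.get(name, 0.0)
        eps = rng.standard_normal(n)
        z = lam * factor + np.sqrt(1.0 - lam * lam) * eps
        u = stats.norm.cdf(z)
        # keep u strictly inside (0, 1) for the ppf
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
        columns[name] = marginal.ppf(u)
    records = [
        PatientRecord(patient_id=f"SYN{i + 1:05d}",
                      **{name: columns[name][i] for name in columns})
        for i in range(n)
    ]
    cohort = CohortTable(records=records,
                         provenance=f"synthetic(seed={config.seed}, n={n})")
    cohort.validate()
    return cohort


def apply_missingness(cohort: CohortTable, rates: Mapping[str, float],
                      seed) -> CohortTable:
    """Blank each field independently with its rate (MCAR); returns a copy.

    ``patient_id`` is never blanked.  Deterministic given the seed (an int
    or anything ``numpy.random.default_rng`` accepts): masks are drawn
    field by field in the iteration order of *rates*.
    """
    for name, rate in rates.items():
        if name not in MASKABLE_FIELDS:
            raise ValueError(f"cannot mask unknown field {name!r}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate {name}={rate} outside [0, 1]")
    rng = np.random.default_rng(seed)
    records = [copy.copy(rec) for rec in cohort.records]
    for name, rate in rates.items():
        mask = rng.random(len(records)) < rate
        for rec, hit in zip(records, mask):
            if hit:
                setattr(rec, name, None)
    return CohortTable(records=records, provenance=cohort.provenance)


def simulate_cohort(config: GeneratorConfig) -> CohortTable:
    """generate_cohort followed by apply_missingness, one deterministic run.

    The masking stream is seeded from ``[config.seed, 1]`` so it is
    independent of the value stream for any seed.
    """
    cohort = generate_cohort(config)
    if not config.missingness:
        return cohort
    return apply_missingness(cohort, config.missingness,
                             np.random.SeedSequence([config.seed, 1]))
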