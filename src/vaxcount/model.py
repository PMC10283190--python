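"""Three-level Bayesian count regression: design assembly, likelihood, posterior.

For child i in community j(i) in state s(i):

    y_i ~ Family(mu_i, k, pi_i)
    log(mu_i)   = x_i' beta + u_comm[j(i)] + u_state[s(i)]
    logit(pi_i) = z_i' gamma (+ r_comm[j(i)] + r_state[s(i)] if enabled)

with exchangeable Gaussian random effects u ~ N(0, sigma^2) per level and
weakly informative priors whose centers are derived from the data (the
intercept prior is centred at the log weighted mean outcome, the
zero-part intercept at the logit of the observed zero excess).

Categorical covariates are reference-coded: the first listed level of
each covariate is the reference, matching the convention of the survey
analysis this emulates (e.g. survey year 2003 is the reference year).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import HierarchicalCountData
from .families import Family, log_pmf_array

_HALFNORM_CONST = 0.5 * np.log(2.0 / np.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Which family to fit and which covariates enter each linear predictor.

    ``count_formula`` lists covariate names entering the log-mean;
    ``zero_formula`` those entering the logit of pi (empty = intercept
    only; only meaningful for zip/zinb). ``zero_random_effects`` switches
    on community/state random effects in the zero part (off by default:
    the zero part is a scalar-intercept mixture unless asked otherwise).
    ``random_effects=False`` drops the count-part random effects entirely
    (a flat fixed-effects model, useful for exact small checks).
    """

    family: Family
    count_formula: tuple[str, ...] = ()
    zero_formula: tuple[str, ...] = ()
    zero_random_effects: bool = False
    random_effects: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        object.__setattr__(self, "count_formula", tuple(self.count_formula))
        object.__setattr__(self, "zero_formula", tuple(self.zero_formula))
        if not self.family.has_zero_inflation and (self.zero_formula or self.zero_random_effects):
            raise ValueError(f"zero part not allowed for family {self.family.value!r}")
        if self.zero_random_effects and not self.random_effects:
            raise ValueError("zero-part random effects require count-part random effects")

    def to_dict(self) -> dict:
        return {
            "family": self.family.value,
            "count_formula": list(self.count_formula),
            "zero_formula": list(self.zero_formula),
            "zero_random_effects": self.zero_random_effects,
            "random_effects": self.random_effects,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            family=Family(d["family"]),
            count_formula=tuple(d.get("count_formula", ())),
            zero_formula=tuple(d.get("zero_formula", ())),
            zero_random_effects=bool(d.get("zero_random_effects", False)),
            random_effects=bool(d.get("random_effects", True)),
        )


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative priors; centers may be derived from the data.

    beta_j ~ N(0, beta_scale) except the intercept ~ N(intercept_center,
    intercept_scale); sigma_* ~ half-Normal(sd_scale); log k ~
    N(log_k_center, log_k_scale); zero-part gamma as for beta with its
    own intercept center.
    """

    beta_scale: float = 1.0
    intercept_center: float = 0.0
    intercept_scale: float = 1.5
    sd_scale: float = 1.0
    log_k_center: float = 0.0
    log_k_scale: float = 1.5
    gamma_scale: float = 1.0
    pi_intercept_center: float = 0.0
    pi_intercept_scale: float = 1.5

    def __post_init__(self) -> None:
        for name in ("beta_scale", "intercept_scale", "sd_scale", "log_k_scale",
                     "gamma_scale", "pi_intercept_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_data(cls, data: HierarchicalCountData, **overrides) -> "PriorConfig":
        """Center the intercept priors on crude weighted data summaries."""
        w = data.weights
        ybar = float(np.sum(w * data.y) / np.sum(w))
        zero_frac = float(np.sum(w * (data.y == 0)) / np.sum(w))
        excess = max(zero_frac - np.exp(-ybar), 0.02)
        base = cls(
            intercept_center=float(np.log(max(ybar, 0.1))),
            pi_intercept_center=float(np.log(excess / (1 - excess))),
        )
        return replace(base, **overrides) if overrides else base

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "PriorConfig":
        return cls(**d)


@dataclass
class DesignMatrices:
    """Reference-coded design matrices and group index maps for one model."""

    X: np.ndarray
    x_names: list[str]
    Z: np.ndarray | None
    z_names: list[str]
    comm_idx: np.ndarray
    state_idx: np.ndarray
    n_comm: int
    n_state: int
    comm_labels: np.ndarray
    state_labels: np.ndarray


def _encode(df: pd.DataFrame, covariates: tuple[str, ...], what: str) -> tuple[np.ndarray, list[str]]:
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    for cov in covariates:
        if cov not in df.columns:
            raise ValueError(f"{what} refers to unknown covariate {cov!r}")
        s = df[cov]
        if isinstance(s.dtype, pd.CategoricalDtype):
            levels = list(s.cat.categories)
        else:
            levels = sorted(pd.unique(s).tolist())
        present = set(s.unique().tolist())
        for lvl in levels[1:]:
            if lvl not in present:
                warnings.warn(f"covariate {cov!r}: level {lvl!r} absent from data; column dropped")
                continue
            cols.append((s == lvl).to_numpy(dtype=float))
            names.append(f"{cov}={lvl}")
    return np.column_stack(cols), names


def build_design(data: HierarchicalCountData, spec: ModelSpec) -> DesignMatrices:
    """Expand covariates to indicator columns and index rows by group.

    Column order is deterministic: intercept first, then each covariate's
    non-reference levels in the covariate's listed order.  Reference level
    = first category (categorical dtype) or first in sorted order.
    """
    if data.n == 0:
        raise ValueError("dataset is empty")
    df = data.df
    X, x_names = _encode(df, spec.count_formula, "count_formula")
    Z, z_names = (None, [])
    if spec.family.has_zero_inflation:
        Z, z_names = _encode(df, spec.zero_formula, "zero_formula")
    comm_labels, comm_idx = np.unique(df["community_id"].to_numpy(), return_inverse=True)
    state_labels, state_idx = np.unique(df["state_id"].to_numpy(), return_inverse=True)
    return DesignMatrices(
        X=X, x_names=x_names, Z=Z, z_names=z_names,
        comm_idx=comm_idx, state_idx=state_idx,
        n_comm=len(comm_labels), n_state=len(state_labels),
        comm_labels=comm_labels, state_labels=state_labels,
    )


@dataclass
class ParameterVector:
    """One point in the posterior, on natural scales."""

    beta: np.ndarray
    u_community: np.ndarray | None = None
    u_state: np.ndarray | None = None
    sigma_community: float | None = None
    sigma_state: float | None = None
    k: float | None = None
    gamma: np.ndarray | None = None
    r_community: np.ndarray | None = None
    r_state: np.ndarray | None = None
    sigma_r_community: float | None = None
    sigma_r_state: float | None = None


class HierarchicalCountModel:
    """Likelihood and posterior for one family over one dataset."""

    def __init__(
        self,
        data: HierarchicalCountData,
        spec: ModelSpec,
        priors: PriorConfig | None = None,
    ):
        self.data = data
        self.spec = spec
        self.priors = priors if priors is not None else PriorConfig.from_data(data)
        self.design = build_design(data, spec)
        self.y = data.y

    # -- linear predictors -------------------------------------------------
    def eta(self, pv: ParameterVector) -> np.ndarray:
        d = self.design
        eta = d.X @ pv.beta
        if self.spec.random_effects:
            eta = eta + pv.u_community[d.comm_idx] + pv.u_state[d.state_idx]
        if not np.all(np.isfinite(eta)):
            bad = int(np.flatnonzero(~np.isfinite(eta))[0])
            raise FloatingPointError(f"non-finite linear predictor at row {bad}")
        return eta

    def pi(self, pv: ParameterVector) -> np.ndarray | None:
        if not self.spec.family.has_zero_inflation:
            return None
        d = self.design
        zeta = d.Z @ pv.gamma
        if self.spec.zero_random_effects:
            zeta = zeta + pv.r_community[d.comm_idx] + pv.r_state[d.state_idx]
        # keep pi strictly inside (0, 1) so the zero-mixture log mass is finite
        return expit(np.clip(zeta, -30.0, 30.0))

    # -- log densities -----------------------------------------------------
    def log_likelihood_pointwise(self, pv: ParameterVector) -> np.ndarray:
        """Per-observation log p(y_i | theta), conditional on the random effects."""
        mu = np.exp(self.eta(pv))
        return log_pmf_array(self.y, self.spec.family, mu, k=pv.k, pi=self.pi(pv))

    def log_prior(self, pv: ParameterVector) -> float:
        """Joint log-prior density on the natural scale (k enters through a
        log-normal density, i.e. the Normal prior on log k including its
        Jacobian)."""
        pr = self.priors
        lp = _normal_logpdf(pv.beta[0], pr.intercept_center, pr.intercept_scale)
        lp += _normal_logpdf(pv.beta[1:], 0.0, pr.beta_scale).sum()
        if self.spec.random_effects:
            lp += _halfnormal_logpdf(pv.sigma_community, pr.sd_scale)
            lp += _halfnormal_logpdf(pv.sigma_state, pr.sd_scale)
            lp += _normal_logpdf(pv.u_community, 0.0, pv.sigma_community).sum()
            lp += _normal_logpdf(pv.u_state, 0.0, pv.sigma_state).sum()
        if self.spec.family.has_dispersion:
            lp += _normal_logpdf(np.log(pv.k), pr.log_k_center, pr.log_k_scale) - np.log(pv.k)
        if self.spec.family.has_zero_inflation:
            lp += _normal_logpdf(pv.gamma[0], pr.pi_intercept_center, pr.pi_intercept_scale)
            lp += _normal_logpdf(pv.gamma[1:], 0.0, pr.gamma_scale).sum()
            if self.spec.zero_random_effects:
                lp += _halfnormal_logpdf(pv.sigma_r_community, pr.sd_scale)
                lp += _halfnormal_logpdf(pv.sigma_r_state, pr.sd_scale)
                lp += _normal_logpdf(pv.r_community, 0.0, pv.sigma_r_community).sum()
                lp += _normal_logpdf(pv.r_state, 0.0, pv.sigma_r_state).sum()
        return float(lp)

    def log_posterior(self, pv: ParameterVector) -> float:
        """log p(theta | y) up to a constant: pointwise likelihood sum plus
        the log-prior above."""
        return float(self.log_likelihood_pointwise(pv).sum()) + self.log_prior(pv)

    # -- initial values ----------------------------------------------------
    def initial_values(self, rng: np.random.Generator | None = None) -> ParameterVector:
        """Deterministic starting point: quasi-Poisson least squares for beta
        (regress log(y + 0.5) on X), small sigmas, k = 1; optional jitter."""
        d = self.design
        beta, *_ = np.linalg.lstsq(d.X, np.log(self.y + 0.5), rcond=None)
        pv = ParameterVector(beta=beta)
        if self.spec.random_effects:
            pv.u_community = np.zeros(d.n_comm)
            pv.u_state = np.zeros(d.n_state)
            pv.sigma_community = 0.1
            pv.sigma_state = 0.1
        if self.spec.family.has_dispersion:
            pv.k = 1.0
        if self.spec.family.has_zero_inflation:
            pv.gamma = np.zeros(len(d.z_names))
            pv.gamma[0] = self.priors.pi_intercept_center
            if self.spec.zero_random_effects:
                pv.r_community = np.zeros(d.n_comm)
                pv.r_state = np.zeros(d.n_state)
                pv.sigma_r_community = 0.1
                pv.sigma_r_state = 0.1
        if rng is not None:
            pv.beta = pv.beta + 0.05 * rng.standard_normal(pv.beta.shape)
            if pv.gamma is not None:
                pv.gamma = pv.gamma + 0.05 * rng.standard_normal(pv.gamma.shape)
        return pv


def _normal_logpdf(x, loc, scale):
    z = (np.asarray(x, dtype=float) - loc) / scale
    return -0.5 * z**2 - np.log(scale) - 0.5 * np.log(2 * np.pi)


def _halfnormal_logpdf(x, scale):
    x = float(x)
    if x < 0:
        return -np.inf
    return _HALFNORM_CONST - np.log(scale) - 0.5 * (x / scale) ** 2
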