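"""Hierarchical synthetic-data generator.

Emulates the statistical structure of pooled multi-year household-survey
immunisation data: children (level 1) nested in communities (level 2)
nested in states (level 3), a 0-9 count outcome (number of vaccine doses
received), categorical covariates attached to each level, exchangeable
Gaussian random effects at community and state, and a configurable count
family with optional overdispersion and structural zeros.

The generative model, per child i in community j in state k:

    eta_ijk = x_ijk' beta + u_comm[j] + u_state[k]
    mu_ijk  = exp(eta_ijk)
    y*_ijk  ~ Family(mu_ijk, k, pi)
    y_ijk   = min(y*_ijk, max_count)        # right-truncation, logged

u_comm ~ N(0, sigma_community^2), u_state ~ N(0, sigma_state^2).  The
count families are unbounded; the observed outcome is a bounded count,
so draws are right-truncated and the truncated fraction recorded in the
dataset's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import HierarchicalCountData
from .families import Family, sample_with_rng


@dataclass(frozen=True)
class Covariate:
    """One categorical covariate: its levels (first = reference), the
    marginal probabilities of the levels (uniform if None), and the
    hierarchy level it is constant within."""

    name: str
    levels: tuple[str, ...]
    probs: tuple[float, ...] | None = None
    attach: str = "child"  # child | community | state

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"covariate {self.name!r} needs >= 2 levels")
        if self.probs is not None and len(self.probs) != len(self.levels):
            raise ValueError(f"covariate {self.name!r}: probs/levels length mismatch")
        if self.attach not in ("child", "community", "state"):
            raise ValueError(f"covariate {self.name!r}: unknown attach {self.attach!r}")


@dataclass(frozen=True)
class HierarchyDesign:
    """Sizes and covariate design of the three-level hierarchy."""

    n_states: int
    communities_per_state: int | tuple[int, ...]
    children_per_community: int | tuple[float, float]  # exact, or (mean, NB dispersion)
    years: tuple[int, ...] = (2003, 2008, 2013, 2018)
    year_probs: tuple[float, ...] | None = None
    covariates: tuple[Covariate, ...] = ()
    max_count: int = 9
    year_weights: Mapping[int, float] | None = None  # per-year SSW factor; 1.0 if None

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        cps = self.communities_per_state
        if isinstance(cps, tuple):
            if len(cps) != self.n_states or any(c < 1 for c in cps):
                raise ValueError("per-state community counts must have length n_states, all >= 1")
        elif cps < 1:
            raise ValueError("communities_per_state must be >= 1")

    @property
    def n_communities(self) -> int:
        cps = self.communities_per_state
        return sum(cps) if isinstance(cps, tuple) else self.n_states * cps

    def expected_children(self) -> float:
        cpc = self.children_per_community
        mean = cpc if isinstance(cpc, (int, float)) and not isinstance(cpc, tuple) else cpc[0]
        return self.n_communities * mean


@dataclass(frozen=True)
class TrueParameters:
    """Generating parameters on the log-mean (and logit-zero) scales.

    ``beta`` maps design-column names ("intercept", "year=2008",
    "education=primary", ...) to coefficients; unspecified columns get 0.
    ``pi_model`` is either a constant structural-zero probability or a
    mapping of the same form on the logit scale.
    """

    family: Family
    beta: Mapping[str, float]
    sigma_community: float
    sigma_state: float
    k: float | None = None
    pi_model: float | Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        if self.sigma_community < 0 or self.sigma_state < 0:
            raise ValueError("random-effect standard deviations must be >= 0")
        if "intercept" not in self.beta:
            raise ValueError("beta must include an 'intercept' entry")
        if self.family.has_dispersion and (self.k is None or self.k <= 0):
            raise ValueError(f"family {self.family.value!r} requires dispersion k > 0")
        if self.family.has_zero_inflation:
            if self.pi_model is None:
                raise ValueError(f"family {self.family.value!r} requires pi_model")
            if isinstance(self.pi_model, (int, float)) and not 0 <= self.pi_model < 1:
                raise ValueError("constant pi must lie in [0, 1)")


def design_columns(design: HierarchyDesign) -> list[str]:
    """Deterministic column order: intercept, year dummies (first year is
    the reference), then each covariate's non-reference levels in listed
    order."""
    cols = ["intercept"]
    cols += [f"year={y}" for y in design.years[1:]]
    for cov in design.covariates:
        cols += [f"{cov.name}={lvl}" for lvl in cov.levels[1:]]
    return cols


def _coef_vector(mapping: Mapping[str, float], cols: list[str], what: str) -> np.ndarray:
    unknown = set(mapping) - set(cols)
    if unknown:
        raise ValueError(f"{what} refers to unknown design columns: {sorted(unknown)}")
    return np.array([mapping.get(c, 0.0) for c in cols])


def simulate_dataset(
    design: HierarchyDesign, truth: TrueParameters, seed: int
) -> HierarchicalCountData:
    """Draw one complete dataset; byte-identical given (design, truth, seed)."""
    rng = np.random.default_rng(seed)

    # hierarchy: communities nested in states, children nested in communities
    cps = design.communities_per_state
    comm_counts = np.asarray(cps if isinstance(cps, tuple) else [cps] * design.n_states)
    comm_state = np.repeat(np.arange(design.n_states), comm_counts)
    n_comm = len(comm_state)
    cpc = design.children_per_community
    if isinstance(cpc, tuple):
        mean, disp = cpc
        sizes = np.maximum(1, sample_with_rng(rng, Family.NB, np.full(n_comm, mean), k=disp))
    else:
        sizes = np.full(n_comm, int(cpc))
    child_comm = np.repeat(np.arange(n_comm), sizes)
    child_state = comm_state[child_comm]
    n = len(child_comm)

    # covariates, drawn at the level they attach to then broadcast down
    cols = design_columns(design)
    year = rng.choice(design.years, size=n, p=design.year_probs)
    cat_values: dict[str, np.ndarray] = {}
    for cov in design.covariates:
        m = {"child": n, "community": n_comm, "state": design.n_states}[cov.attach]
        codes = rng.choice(len(cov.levels), size=m, p=cov.probs)
        if cov.attach == "community":
            codes = codes[child_comm]
        elif cov.attach == "state":
            codes = codes[child_state]
        cat_values[cov.name] = codes

    X = np.zeros((n, len(cols)))
    X[:, 0] = 1.0
    col_pos = {c: j for j, c in enumerate(cols)}
    for y_lvl in design.years[1:]:
        X[:, col_pos[f"year={y_lvl}"]] = year == y_lvl
    for cov in design.covariates:
        for lvl_idx, lvl in enumerate(cov.levels[1:], start=1):
            X[:, col_pos[f"{cov.name}={lvl}"]] = cat_values[cov.name] == lvl_idx

    # random effects and linear predictor
    u_state = rng.normal(0.0, truth.sigma_state, size=design.n_states)
    u_comm = rng.normal(0.0, truth.sigma_community, size=n_comm)
    beta = _coef_vector(truth.beta, cols, "beta")
    eta = X @ beta + u_comm[child_comm] + u_state[child_state]
    mu = np.exp(eta)

    pi = None
    if truth.family.has_zero_inflation:
        if isinstance(truth.pi_model, Mapping):
            gamma = _coef_vector(truth.pi_model, cols, "pi_model")
            pi = expit(X @ gamma)
        else:
            pi = np.full(n, float(truth.pi_model))

    y_raw = sample_with_rng(rng, truth.family, mu, k=truth.k, pi=pi)
    truncated = y_raw > design.max_count
    y = np.minimum(y_raw, design.max_count)

    if design.year_weights is not None:
        weight = np.array([design.year_weights[int(v)] for v in year], dtype=float)
    else:
        weight = np.ones(n)

    frame = {"y": y}
    covariate_levels: dict[str, list[str]] = {}
    for cov in design.covariates:
        labels = np.asarray(cov.levels)[cat_values[cov.name]]
        frame[cov.name] = pd.Categorical(labels, categories=list(cov.levels))
        covariate_levels[cov.name] = list(cov.levels)
    frame["community_id"] = child_comm
    frame["state_id"] = child_state
    frame["year"] = year
    frame["weight"] = weight
    df = pd.DataFrame(frame)

    meta = {
        "seed": int(seed),
        "max_count": design.max_count,
        "truncated_fraction": float(truncated.mean()),
        "n_truncated": int(truncated.sum()),
        "covariate_levels": covariate_levels,
        "design": design,
        "truth": truth,
        # generating random effects, for generator self-checks
        "u_community": u_comm.tolist(),
        "u_state": u_state.tolist(),
        "community_state": comm_state.tolist(),
    }
    return HierarchicalCountData(df=df, meta=meta)


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

# Covariate blocks shared by the larger presets.  Levels echo the analysis
# variables of multi-year DHS immunisation studies; the first level is the
# reference.  Marginal probabilities are conventions (uniform unless set).
CHILD_COVARIATES = (
    Covariate("age_group", ("15-24", "25-34", "35-49"), (0.30, 0.45, 0.25)),
    Covariate("education", ("none", "primary", "secondary+"), (0.40, 0.25, 0.35)),
    Covariate("religion", ("christian", "islam", "other"), (0.45, 0.50, 0.05)),
    Covariate("occupation", ("unemployed", "employed", "self_employed", "other"),
              (0.30, 0.25, 0.35, 0.10)),
    Covariate("wanted_child", ("then", "later", "no_more"), (0.75, 0.15, 0.10)),
    Covariate("place_of_delivery", ("home", "facility"), (0.55, 0.45)),
    Covariate("media_exposure", ("no", "yes"), (0.35, 0.65)),
    Covariate("birth_order", ("first", "second", "third", "fourth+"),
              (0.22, 0.20, 0.17, 0.41)),
    Covariate("wealth", ("bottom", "middle", "top"), (0.33, 0.34, 0.33)),
    Covariate("anc_visits", ("none", "1-3", "4-7", "8+"), (0.25, 0.20, 0.35, 0.20)),
    Covariate("sex", ("male", "female")),
    Covariate("pnc", ("no", "yes"), (0.60, 0.40)),
    Covariate("decision_maker", ("self", "husband", "joint", "other"),
              (0.30, 0.35, 0.30, 0.05)),
)
COMMUNITY_COVARIATES = (
    Covariate("residence", ("urban", "rural"), (0.40, 0.60), attach="community"),
    Covariate("community_poverty", ("low", "average", "high"), attach="community"),
    Covariate("community_illiteracy", ("low", "average", "high"), attach="community"),
    Covariate("community_unemployment", ("low", "average", "high"), attach="community"),
)
STATE_COVARIATES = (
    Covariate("rural_proportion", ("low", "average", "high"), attach="state"),
    Covariate("health_facilities", ("<15", "15-25", ">25"), attach="state"),
)

# Year effects of the dhs-like preset follow the observed upward trend in
# mean uptake across survey rounds (log-scale contrasts of the by-year
# means relative to the first round).
_DHS_YEAR_EFFECTS = {"year=2008": 0.1236, "year=2013": 0.3281, "year=2018": 0.4126}

# Calibration of (intercept, pi) at k=3 moment-matched so the capped-at-9
# marginal outcome has mean 4.36, variance 12.82 and median 4, with a
# structural zero spike (~0.28) far above the Poisson-implied zero mass
# (see _calibration.py; the fold at the cap creates the spike of fully
# vaccinated children).
_DHS_INTERCEPT = 1.7542686
_DHS_K = 3.0
_DHS_PI = 0.2596304


def scaled_presets(name: str) -> tuple[HierarchyDesign, TrueParameters]:
    """Named (design, truth) pairs at different scales.

    ``full``     ~ the pooled-survey scale (37 states, ~1,338 communities,
                   ~12,760 children) with the complete covariate design;
    ``dhs-like`` ~ 10^4 children, moment-matched ZINB truth (overall mean
                   ~4.36, variance ~12.8, zero spike);
    ``desk``     = 10 states x 5 communities x 40 children = 2,000 rows,
                   a small covariate set, ZINB truth (pi=0.25, k=1.5);
    ``tiny``     = 3 x 2 x 10 = 60 rows, Poisson truth, for unit tests.
    """
    if name == "tiny":
        design = HierarchyDesign(
            n_states=3, communities_per_state=2, children_per_community=10,
            covariates=(Covariate("sex", ("male", "female")),),
        )
        truth = TrueParameters(
            family=Family.POISSON,
            beta={"intercept": float(np.log(4.36)), "year=2013": 0.1, "sex=female": 0.02},
            sigma_community=0.1, sigma_state=0.1,
        )
        return design, truth
    if name == "desk":
        design = HierarchyDesign(
            n_states=10, communities_per_state=5, children_per_community=40,
            covariates=(
                Covariate("age_group", ("15-24", "25-34", "35-49"), (0.30, 0.45, 0.25)),
                Covariate("education", ("none", "primary", "secondary+"), (0.40, 0.25, 0.35)),
                Covariate("residence", ("urban", "rural"), (0.40, 0.60), attach="community"),
            ),
            # the generating families are unbounded; a high cap keeps the
            # recovery benchmark inside the fitted model family
            max_count=30,
        )
        truth = TrueParameters(
            family=Family.ZINB,
            beta={
                "intercept": 1.30,
                "year=2008": 0.10, "year=2013": 0.18, "year=2018": 0.22,
                "age_group=25-34": 0.08, "age_group=35-49": 0.10,
                "education=primary": 0.15, "education=secondary+": 0.25,
                "residence=rural": -0.10,
            },
            sigma_community=0.20, sigma_state=0.15, k=1.5, pi_model=0.25,
        )
        return design, truth
    if name in ("full", "dhs-like"):
        covariates = CHILD_COVARIATES + COMMUNITY_COVARIATES + STATE_COVARIATES
        if name == "full":
            # 1,338 communities over 37 states; community sizes NB(mean 9.54)
            cps = tuple(37 if s < 6 else 36 for s in range(37))  # 6*37 + 31*36 = 1338
            design = HierarchyDesign(
                n_states=37, communities_per_state=cps,
                children_per_community=(9.54, 8.0), covariates=covariates,
            )
        else:
            design = HierarchyDesign(
                n_states=37, communities_per_state=10,
                children_per_community=27, covariates=covariates,
            )
        beta = {"intercept": _DHS_INTERCEPT, **_DHS_YEAR_EFFECTS}
        truth = TrueParameters(
            family=Family.ZINB, beta=beta,
            sigma_community=0.07, sigma_state=0.13,  # latent SDs of the best-fit model
            k=_DHS_K, pi_model=_DHS_PI,
        )
        return design, truth
    raise KeyError(f"unknown preset {name!r}; expected full, dhs-like, desk or tiny")
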