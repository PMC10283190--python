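"""Survey weights, weighted descriptive summaries, dispersion diagnostics,
and variance partitioning coefficients.

Weights follow the pooled multi-survey convention: the analysis weight of
a child is the provided sampling weight (rescaled by its documentation
divisor) times a survey-specific weight (SSW), the ratio of sampled to
population women of reproductive age in that survey round.  Weights are
used only for descriptive summaries; the model likelihoods are
unweighted (a weighted multilevel pseudo-likelihood is a different
estimator and is deliberately out of scope).

Weighted statistics use the frequency-weight convention: duplicating a
row and doubling its weight are equivalent, and unit weights reproduce
the unweighted formulas exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .mcmc import PosteriorDraws
from .model import HierarchicalCountModel


@dataclass(frozen=True)
class SurveyWeightSpec:
    """Per-survey-year weighting inputs."""

    dhs_weight_scale: float  # divisor applied to provided raw weights
    n_sampled_women: int
    n_population_women: int

    def __post_init__(self) -> None:
        if self.dhs_weight_scale <= 0:
            raise ValueError("dhs_weight_scale must be > 0")
        if self.n_sampled_women <= 0 or self.n_population_women <= 0:
            raise ValueError("women counts must be > 0")
        if self.n_sampled_women > self.n_population_women:
            raise ValueError("sampled women cannot exceed the population")

    @property
    def ssw(self) -> float:
        return self.n_sampled_women / self.n_population_women


def survey_weights(
    raw_weights: np.ndarray,
    year_labels: np.ndarray,
    spec: Mapping[int, SurveyWeightSpec],
) -> np.ndarray:
    """w_i = (raw_i / scale) * SSW(year_i); strictly positive."""
    raw = np.asarray(raw_weights, dtype=float)
    years = np.asarray(year_labels)
    missing = sorted({int(y) for y in np.unique(years)} - {int(y) for y in spec})
    if missing:
        raise ValueError(f"no weight spec for survey year(s) {missing}")
    out = np.empty_like(raw)
    for year, entry in spec.items():
        mask = years == year
        out[mask] = raw[mask] / entry.dhs_weight_scale * entry.ssw
    if np.any(out <= 0):
        raise ValueError("survey weights must be strictly positive")
    return out


def _weighted_stats(y: np.ndarray, w: np.ndarray) -> dict[str, float]:
    wsum = w.sum()
    mean = float(np.sum(w * y) / wsum)
    # frequency-weight variance with the ddof=1 analogue (sum w - 1)
    var = float(np.sum(w * (y - mean) ** 2) / (wsum - 1.0)) if wsum > 1 else np.nan
    order = np.argsort(y, kind="mergesort")
    cum = np.cumsum(w[order])
    median = float(y[order][np.searchsorted(cum, 0.5 * wsum)])
    zero_frac = float(np.sum(w * (y == 0)) / wsum)
    return {"mean": mean, "median": median, "variance": var, "zero_fraction": zero_frac}


def weighted_summary(
    y: np.ndarray,
    weights: np.ndarray,
    by_year: np.ndarray | None = None,
) -> pd.DataFrame:
    """Weighted mean/median/variance/zero-fraction, per year and overall."""
    y = np.asarray(y)
    w = np.asarray(weights, dtype=float)
    if len(y) != len(w):
        raise ValueError("y and weights must have equal length")
    if not np.any(w > 0):
        raise ValueError("all weights are zero")
    rows = []
    if by_year is not None:
        years = np.asarray(by_year)
        if len(years) != len(y):
            raise ValueError("by_year must match y in length")
        for year in np.unique(years):
            m = years == year
            rows.append({"group": str(year), **_weighted_stats(y[m], w[m])})
    rows.append({"group": "overall", **_weighted_stats(y, w)})
    return pd.DataFrame(rows).set_index("group")


def zero_histogram(y: np.ndarray, weights: np.ndarray, max_count: int = 9) -> pd.DataFrame:
    """Weighted percentage distribution of the outcome (histogram data)."""
    y = np.asarray(y)
    w = np.asarray(weights, dtype=float)
    counts = np.arange(max_count + 1)
    pct = np.array([np.sum(w[y == c]) for c in counts]) / w.sum() * 100.0
    return pd.DataFrame({"count": counts, "percent": pct})


@dataclass
class DispersionReport:
    mean: float
    variance: float
    ratio: float  # variance / mean
    zero_fraction: float
    poisson_zero: float  # e^{-mean}
    overdispersed: bool
    excess_zeros: bool

    def describe(self) -> str:
        msgs = [f"mean {self.mean:.2f}, variance {self.variance:.2f} "
                f"(ratio {self.ratio:.2f})"]
        if self.overdispersed:
            msgs.append("variance exceeds the mean: Poisson equidispersion is violated")
        if self.excess_zeros:
            msgs.append(f"zero fraction {self.zero_fraction:.3f} exceeds the "
                        f"Poisson-implied {self.poisson_zero:.3f}")
        return "; ".join(msgs)


def dispersion_check(y: np.ndarray, weights: np.ndarray | None = None) -> DispersionReport:
    """Overdispersion and excess-zero flags (descriptive, not inferential).

    Overdispersion is flagged when variance/mean exceeds 1 by more than
    twice the sampling SD of the ratio under Poisson data (~ sqrt(2/n)),
    so an equidispersed sample is not flagged on noise alone.
    """
    y = np.asarray(y)
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    s = _weighted_stats(y, w)
    ratio = s["variance"] / s["mean"] if s["mean"] > 0 else 0.0
    poisson_zero = float(np.exp(-s["mean"]))
    n_eff = float(w.sum() ** 2 / np.sum(w**2))
    allowance = 2.0 * np.sqrt(2.0 / n_eff)
    return DispersionReport(
        mean=s["mean"], variance=s["variance"], ratio=ratio,
        zero_fraction=s["zero_fraction"], poisson_zero=poisson_zero,
        overdispersed=bool(ratio > 1 + allowance),
        excess_zeros=bool(s["zero_fraction"] > poisson_zero),
    )


def vpc(
    draws: PosteriorDraws,
    model: HierarchicalCountModel | None = None,
    include_level1: bool = True,
) -> pd.DataFrame:
    """Variance partitioning coefficients on the latent (log-mean) scale.

    Per draw: VPC_level = sigma_level^2 / (sigma_comm^2 + sigma_state^2
    + V1), where the level-1 term V1 is a family-specific convention:
    1/exp(eta-bar) for Poisson-type counts (the log-normal-Poisson
    approximation at the average linear predictor), plus 1/k for the NB
    families; the logistic variance pi^2/3 is added when zero-part random
    effects are modelled.  ``include_level1=False`` drops V1 (pure
    latent-share definition).  Returns posterior median and 95% interval
    per level.
    """
    sc = np.asarray(draws.block("sigma_community"), dtype=float).ravel()
    ss = np.asarray(draws.block("sigma_state"), dtype=float).ravel()
    v_comm, v_state = sc**2, ss**2
    v1 = np.zeros_like(v_comm)
    if include_level1:
        if model is None:
            raise ValueError("include_level1 requires the fitted model (for eta-bar)")
        flat = draws.flat()
        eta_bar = np.array([
            float(np.mean(model.eta(draws.parameter_vector(row)))) for row in flat
        ])
        v1 = 1.0 / np.exp(eta_bar)
        if draws.spec.family.has_dispersion:
            v1 = v1 + 1.0 / np.asarray(draws.block("k"), dtype=float).ravel()
        if draws.spec.zero_random_effects:
            v1 = v1 + np.pi**2 / 3.0
    total = v_comm + v_state + v1
    rows = {}
    shares = {"community": v_comm / total, "state": v_state / total}
    if include_level1:
        shares["level1"] = v1 / total
    for name, share in shares.items():
        rows[name] = {
            "vpc": float(np.median(share)),
            "q2.5": float(np.quantile(share, 0.025)),
            "q97.5": float(np.quantile(share, 0.975)),
        }
    return pd.DataFrame(rows).T
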