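"""Posterior sampling by adaptive Metropolis-within-Gibbs.

The sampler updates parameters in blocks — fixed effects jointly,
zero-part coefficients jointly, each random-effect vector by vectorised
single-site proposals, and the scalars (log sigmas, log k) individually.
Proposal scales adapt during warmup only (Robbins–Monro toward standard
target acceptance rates: 0.234 for joint blocks, 0.44 for scalars and
single-site updates), so the post-warmup chain is a valid fixed-kernel
Markov chain.  Random-effect and dispersion scales are sampled on the
log scale with the Jacobian included in the conditional target.

Defaults mirror the original analysis configuration: 15,000 iterations
per chain including warmup, 4 chains, thinning 50.  Warmup defaults to
half the iterations (the split is a convention; the source analysis does
not state it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import HierarchicalCountData
from .families import log_pmf_array
from .model import (
    HierarchicalCountModel,
    ModelSpec,
    ParameterVector,
    PriorConfig,
    _halfnormal_logpdf,
    _normal_logpdf,
)


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run configuration; ``iterations`` includes warmup."""

    iterations: int = 15000
    warmup: int = 7500
    chains: int = 4
    thin: int = 50
    seed: int = 0
    backend: str = "builtin_metropolis"

    def __post_init__(self) -> None:
        if not 0 < self.warmup < self.iterations:
            raise ValueError("need 0 < warmup < iterations")
        if self.thin < 1 or self.chains < 1:
            raise ValueError("thin and chains must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.warmup) // self.thin

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "SamplerConfig":
        return cls(**d)


@dataclass
class PosteriorDraws:
    """Retained posterior draws, indexed (chain, draw, parameter).

    ``names`` label the flat parameter axis; ``blocks`` maps block names
    (beta, gamma, u_community, ...) to slices of that axis.  All values
    are stored on natural scales.
    """

    draws: np.ndarray
    names: list[str]
    blocks: dict[str, slice]
    config: SamplerConfig
    spec: ModelSpec
    accept_rates: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def block(self, name: str) -> np.ndarray:
        """(chain, draw, dim) array for one block; scalars squeeze to (chain, draw)."""
        out = self.draws[:, :, self.blocks[name]]
        return out[:, :, 0] if out.shape[2] == 1 else out

    def flat(self) -> np.ndarray:
        """(chain*draw, parameter) with chains concatenated."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def parameter_vector(self, flat_row: np.ndarray) -> ParameterVector:
        b = self.blocks
        get = lambda name: flat_row[b[name]] if name in b else None
        scalar = lambda name: float(flat_row[b[name]][0]) if name in b else None
        return ParameterVector(
            beta=get("beta"),
            u_community=get("u_community"),
            u_state=get("u_state"),
            sigma_community=scalar("sigma_community"),
            sigma_state=scalar("sigma_state"),
            k=scalar("k"),
            gamma=get("gamma"),
            r_community=get("r_community"),
            r_state=get("r_state"),
            sigma_r_community=scalar("sigma_r_community"),
            sigma_r_state=scalar("sigma_r_state"),
        )

    def posterior_mean(self) -> ParameterVector:
        """Posterior mean of every parameter on its natural scale."""
        return self.parameter_vector(self.flat().mean(axis=0))

    def to_arviz(self):
        import arviz as az

        data = {name: self.draws[:, :, sl] for name, sl in self.blocks.items()}
        for name in list(data):
            if data[name].shape[2] == 1:
                data[name] = data[name][:, :, 0]
        return az.from_dict(posterior=data)

    def to_csv(self, path) -> None:
        c, d, p = self.draws.shape
        df = pd.DataFrame(self.draws.reshape(c * d, p), columns=self.names)
        df.insert(0, "draw", np.tile(np.arange(d), c))
        df.insert(0, "chain", np.repeat(np.arange(c), d))
        df.to_csv(path, index=False)


def run_mcmc(
    data: HierarchicalCountData,
    spec: ModelSpec,
    priors: PriorConfig | None = None,
    config: SamplerConfig = SamplerConfig(),
) -> PosteriorDraws:
    """Sample the posterior of one family's multilevel fit.

    Any correct sampler targeting the model's posterior would do; the
    built-in backend is the adaptive Metropolis-within-Gibbs scheme
    described in the module docstring, seeded and fully reproducible.
    """
    if config.backend != "builtin_metropolis":
        raise ValueError(
            f"backend {config.backend!r} is not available in this build; "
            "use 'builtin_metropolis'"
        )
    model = HierarchicalCountModel(data, spec, priors)
    chain_seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chains = []
    rates: dict[str, float] = {}
    for c, ss in enumerate(chain_seeds):
        sampler = _GibbsChain(model, config, np.random.default_rng(ss))
        stored, rates = sampler.run()
        chains.append(stored)
    draws = np.stack(chains, axis=0)
    names, blocks = _layout(model)
    return PosteriorDraws(
        draws=draws, names=names, blocks=blocks, config=config,
        spec=spec, accept_rates=rates,
    )


def _layout(model: HierarchicalCountModel) -> tuple[list[str], dict[str, slice]]:
    d = model.design
    spec = model.spec
    names: list[str] = []
    blocks: dict[str, slice] = {}

    def add(block: str, labels: list[str]) -> None:
        start = len(names)
        names.extend(labels)
        blocks[block] = slice(start, len(names))

    add("beta", [f"beta[{n}]" for n in d.x_names])
    if spec.family.has_zero_inflation:
        add("gamma", [f"gamma[{n}]" for n in d.z_names])
    if spec.random_effects:
        add("u_community", [f"u_community[{v}]" for v in d.comm_labels])
        add("u_state", [f"u_state[{v}]" for v in d.state_labels])
    if spec.zero_random_effects:
        add("r_community", [f"r_community[{v}]" for v in d.comm_labels])
        add("r_state", [f"r_state[{v}]" for v in d.state_labels])
    if spec.random_effects:
        add("sigma_community", ["sigma_community"])
        add("sigma_state", ["sigma_state"])
    if spec.zero_random_effects:
        add("sigma_r_community", ["sigma_r_community"])
        add("sigma_r_state", ["sigma_r_state"])
    if spec.family.has_dispersion:
        add("k", ["k"])
    return names, blocks


class _GibbsChain:
    """One chain of the adaptive Metropolis-within-Gibbs sampler."""

    def __init__(self, model: HierarchicalCountModel, config: SamplerConfig, rng):
        self.m = model
        self.cfg = config
        self.rng = rng
        self.spec = model.spec
        self.d = model.design
        self.y = model.y
        self.zi = self.spec.family.has_zero_inflation
        self.disp = self.spec.family.has_dispersion
        self.zre = self.spec.zero_random_effects
        self.re = self.spec.random_effects

        pv = None
        for _ in range(20):
            cand = model.initial_values(rng=self.rng)
            if np.isfinite(model.log_posterior(cand)):
                pv = cand
                break
        if pv is None:
            raise RuntimeError("could not find a finite starting point after 20 attempts")
        self.pv = pv
        if self.re:
            self.log_sigma_c = np.log(pv.sigma_community)
            self.log_sigma_s = np.log(pv.sigma_state)
        self.log_k = np.log(pv.k) if self.disp else None
        if self.zre:
            self.log_sigma_rc = np.log(pv.sigma_r_community)
            self.log_sigma_rs = np.log(pv.sigma_r_state)

        self.eta = self.d.X @ pv.beta
        if self.re:
            self.eta = self.eta + pv.u_community[self.d.comm_idx] + pv.u_state[self.d.state_idx]
        self.zeta = None
        if self.zi:
            self.zeta = self.d.Z @ pv.gamma
            if self.zre:
                self.zeta = self.zeta + pv.r_community[self.d.comm_idx] + pv.r_state[self.d.state_idx]
        self.ll = self._loglik(self.eta, self.zeta, self.pv.k)

        p = len(pv.beta)
        self.beta_scale = 0.0
        self.beta_chol = np.eye(p) * (0.1 / np.sqrt(p))
        self._beta_hist: list[np.ndarray] = []
        if self.zi:
            q = len(pv.gamma)
            self.gamma_scale = 0.0
            self.gamma_chol = np.eye(q) * (0.2 / np.sqrt(q))
            self._gamma_hist: list[np.ndarray] = []
        self.s_uc = np.full(self.d.n_comm, np.log(0.2))
        self.s_us = np.full(self.d.n_state, np.log(0.2))
        if self.zre:
            self.s_rc = np.full(self.d.n_comm, np.log(0.3))
            self.s_rs = np.full(self.d.n_state, np.log(0.3))
        self.s_scalars = {"log_sigma_c": np.log(0.3), "log_sigma_s": np.log(0.3),
                          "log_k": np.log(0.2), "log_sigma_rc": np.log(0.3),
                          "log_sigma_rs": np.log(0.3)}
        self.acc = {b: [0, 0] for b in
                    ("beta", "gamma", "u_community", "u_state", "r_community", "r_state",
                     "sigma_community", "sigma_state", "k",
                     "sigma_r_community", "sigma_r_state")}

    # -- likelihood on cached linear predictors ---------------------------
    def _loglik(self, eta, zeta, k):
        from scipy.special import expit

        mu = np.exp(np.clip(eta, -30, 30))
        # clip keeps pi strictly inside (0, 1) so log1p(-pi) stays finite
        pi = expit(np.clip(zeta, -30, 30)) if self.zi else None
        return log_pmf_array(self.y, self.spec.family, mu, k=k, pi=pi)

    def run(self) -> tuple[np.ndarray, dict[str, float]]:
        cfg = self.cfg
        n_keep = cfg.retained_per_chain
        names, blocks = _layout(self.m)
        stored = np.empty((n_keep, len(names)))
        kept = 0
        for t in range(cfg.iterations):
            self.warming = t < cfg.warmup
            self.gamma_t = (t + 1) ** -0.6
            self._update_beta(t)
            if self.zi:
                self._update_gamma(t)
            if self.re:
                self._update_u("u_community", self.pv.u_community, self.d.comm_idx,
                               self.d.n_comm, self.s_uc, np.exp(self.log_sigma_c))
                self._update_u("u_state", self.pv.u_state, self.d.state_idx,
                               self.d.n_state, self.s_us, np.exp(self.log_sigma_s))
            if self.zre:
                self._update_r("r_community", self.pv.r_community, self.d.comm_idx,
                               self.d.n_comm, self.s_rc, np.exp(self.log_sigma_rc))
                self._update_r("r_state", self.pv.r_state, self.d.state_idx,
                               self.d.n_state, self.s_rs, np.exp(self.log_sigma_rs))
            if self.re:
                self.log_sigma_c = self._update_log_sigma(
                    "sigma_community", "log_sigma_c", self.log_sigma_c, self.pv.u_community)
                self.log_sigma_s = self._update_log_sigma(
                    "sigma_state", "log_sigma_s", self.log_sigma_s, self.pv.u_state)
            if self.zre:
                self.log_sigma_rc = self._update_log_sigma(
                    "sigma_r_community", "log_sigma_rc", self.log_sigma_rc, self.pv.r_community)
                self.log_sigma_rs = self._update_log_sigma(
                    "sigma_r_state", "log_sigma_rs", self.log_sigma_rs, self.pv.r_state)
            if self.disp:
                self._update_log_k(t)
            if not self.warming and (t - cfg.warmup + 1) % cfg.thin == 0 and kept < n_keep:
                stored[kept] = self._flatten()
                kept += 1
        rates = {b: (a / n if n else np.nan) for b, (a, n) in self.acc.items()}
        low = [b for b, r in rates.items() if np.isfinite(r) and r < 0.01]
        if low:
            warnings.warn(f"near-zero post-adaptation acceptance in blocks {low}; "
                          "chain may be stuck")
        return stored, rates

    def _flatten(self) -> np.ndarray:
        pv = self.pv
        parts = [pv.beta]
        if self.zi:
            parts.append(pv.gamma)
        if self.re:
            parts += [pv.u_community, pv.u_state]
        if self.zre:
            parts += [pv.r_community, pv.r_state]
        if self.re:
            parts += [[np.exp(self.log_sigma_c)], [np.exp(self.log_sigma_s)]]
        if self.zre:
            parts += [[np.exp(self.log_sigma_rc)], [np.exp(self.log_sigma_rs)]]
        if self.disp:
            parts.append([np.exp(self.log_k)])
        return np.concatenate([np.asarray(p, dtype=float) for p in parts])

    def _tally(self, block: str, accepted: float, total: float) -> None:
        if not self.warming:
            self.acc[block][0] += accepted
            self.acc[block][1] += total

    # -- block updates -----------------------------------------------------
    def _update_beta(self, t: int) -> None:
        pv, pr = self.pv, self.m.priors
        step = np.exp(self.beta_scale) * (self.beta_chol @ self.rng.standard_normal(len(pv.beta)))
        beta_new = pv.beta + step
        eta_new = self.eta + self.d.X @ step
        ll_new = self._loglik(eta_new, self.zeta, pv.k)
        lp_old = (_normal_logpdf(pv.beta[0], pr.intercept_center, pr.intercept_scale)
                  + _normal_logpdf(pv.beta[1:], 0.0, pr.beta_scale).sum())
        lp_new = (_normal_logpdf(beta_new[0], pr.intercept_center, pr.intercept_scale)
                  + _normal_logpdf(beta_new[1:], 0.0, pr.beta_scale).sum())
        logr = ll_new.sum() - self.ll.sum() + lp_new - lp_old
        ok = np.log(self.rng.random()) < logr
        if ok:
            pv.beta, self.eta, self.ll = beta_new, eta_new, ll_new
        self._tally("beta", ok, 1)
        if self.warming:
            self.beta_scale += self.gamma_t * (float(ok) - 0.234)
            self._beta_hist.append(pv.beta.copy())
            if t >= 200 and t % 100 == 0:
                cov = np.cov(np.asarray(self._beta_hist[-1500:]).T)
                cov = np.atleast_2d(cov) + 1e-8 * np.eye(len(pv.beta))
                self.beta_chol = np.linalg.cholesky(2.38**2 / len(pv.beta) * cov)

    def _update_gamma(self, t: int) -> None:
        pv, pr = self.pv, self.m.priors
        step = np.exp(self.gamma_scale) * (self.gamma_chol @ self.rng.standard_normal(len(pv.gamma)))
        gamma_new = pv.gamma + step
        zeta_new = self.zeta + self.d.Z @ step
        ll_new = self._loglik(self.eta, zeta_new, pv.k)
        lp_old = (_normal_logpdf(pv.gamma[0], pr.pi_intercept_center, pr.pi_intercept_scale)
                  + _normal_logpdf(pv.gamma[1:], 0.0, pr.gamma_scale).sum())
        lp_new = (_normal_logpdf(gamma_new[0], pr.pi_intercept_center, pr.pi_intercept_scale)
                  + _normal_logpdf(gamma_new[1:], 0.0, pr.gamma_scale).sum())
        logr = ll_new.sum() - self.ll.sum() + lp_new - lp_old
        ok = np.log(self.rng.random()) < logr
        if ok:
            pv.gamma, self.zeta, self.ll = gamma_new, zeta_new, ll_new
        self._tally("gamma", ok, 1)
        if self.warming:
            self.gamma_scale += self.gamma_t * (float(ok) - 0.234)
            self._gamma_hist.append(pv.gamma.copy())
            if t >= 200 and t % 100 == 0:
                cov = np.cov(np.asarray(self._gamma_hist[-1500:]).T)
                cov = np.atleast_2d(cov) + 1e-8 * np.eye(len(pv.gamma))
                self.gamma_chol = np.linalg.cholesky(2.38**2 / len(pv.gamma) * cov)

    def _update_u(self, block: str, u: np.ndarray, idx: np.ndarray, n_groups: int,
                  log_scales: np.ndarray, sigma: float) -> None:
        """Vectorised single-site Metropolis for one random-effect vector in
        the count part: each group's update depends only on its own rows."""
        du = np.exp(log_scales) * self.rng.standard_normal(n_groups)
        eta_new = self.eta + du[idx]
        ll_new = self._loglik(eta_new, self.zeta, self.pv.k)
        dll = np.bincount(idx, weights=ll_new - self.ll, minlength=n_groups)
        u_new = u + du
        dprior = (u**2 - u_new**2) / (2 * sigma**2)
        accept = np.log(self.rng.random(n_groups)) < dll + dprior
        u[accept] = u_new[accept]
        row_acc = accept[idx]
        self.eta = np.where(row_acc, eta_new, self.eta)
        self.ll = np.where(row_acc, ll_new, self.ll)
        self._tally(block, int(accept.sum()), n_groups)
        if self.warming:
            log_scales += self.gamma_t * (accept.astype(float) - 0.44)

    def _update_r(self, block: str, r: np.ndarray, idx: np.ndarray, n_groups: int,
                  log_scales: np.ndarray, sigma: float) -> None:
        """Same scheme for zero-part random effects (acting on zeta)."""
        dr = np.exp(log_scales) * self.rng.standard_normal(n_groups)
        zeta_new = self.zeta + dr[idx]
        ll_new = self._loglik(self.eta, zeta_new, self.pv.k)
        dll = np.bincount(idx, weights=ll_new - self.ll, minlength=n_groups)
        r_new = r + dr
        dprior = (r**2 - r_new**2) / (2 * sigma**2)
        accept = np.log(self.rng.random(n_groups)) < dll + dprior
        r[accept] = r_new[accept]
        row_acc = accept[idx]
        self.zeta = np.where(row_acc, zeta_new, self.zeta)
        self.ll = np.where(row_acc, ll_new, self.ll)
        self._tally(block, int(accept.sum()), n_groups)
        if self.warming:
            log_scales += self.gamma_t * (accept.astype(float) - 0.44)

    def _update_log_sigma(self, block: str, key: str, log_sigma: float,
                          u: np.ndarray) -> float:
        """RW on log sigma; conditional involves only the prior terms.

        Target in x = log(sigma) space:  sum_j N(u_j | 0, e^x)
        + halfNormal(e^x | sd_scale) + x  (the Jacobian of sigma = e^x).
        """
        pr = self.m.priors

        def logp(x: float) -> float:
            s = np.exp(x)
            return (float(_normal_logpdf(u, 0.0, s).sum())
                    + _halfnormal_logpdf(s, pr.sd_scale) + x)

        x_new = log_sigma + np.exp(self.s_scalars[key]) * self.rng.standard_normal()
        ok = np.log(self.rng.random()) < logp(x_new) - logp(log_sigma)
        self._tally(block, ok, 1)
        if self.warming:
            self.s_scalars[key] += self.gamma_t * (float(ok) - 0.44)
        return x_new if ok else log_sigma

    def _update_log_k(self, t: int) -> None:
        """RW on log k; Normal prior lives on the log scale directly."""
        pr = self.m.priors
        x_old = self.log_k
        x_new = x_old + np.exp(self.s_scalars["log_k"]) * self.rng.standard_normal()
        ll_new = self._loglik(self.eta, self.zeta, np.exp(x_new))
        logr = (ll_new.sum() - self.ll.sum()
                + _normal_logpdf(x_new, pr.log_k_center, pr.log_k_scale)
                - _normal_logpdf(x_old, pr.log_k_center, pr.log_k_scale))
        ok = np.log(self.rng.random()) < logr
        if ok:
            self.log_k = x_new
            self.pv.k = float(np.exp(x_new))
            self.ll = ll_new
        self._tally("k", ok, 1)
        if self.warming:
            self.s_scalars["log_k"] += self.gamma_t * (float(ok) - 0.44)


# --------------------------------------------------------------------------
# convergence diagnostics
# --------------------------------------------------------------------------

@dataclass
class ConvergenceReport:
    """Split R-hat and bulk ESS per scalar parameter, with flags."""

    table: pd.DataFrame
    flagged: list[str]
    messages: list[str]

    @property
    def ok(self) -> bool:
        return not self.flagged


def diagnostics(draws: PosteriorDraws, rhat_limit: float = 1.01,
                ess_limit: float = 400.0) -> ConvergenceReport:
    """Rank-normalised split R-hat and bulk ESS (via arviz) per parameter.

    Parameters with R-hat above ``rhat_limit`` or ESS below ``ess_limit``
    are flagged; constant (degenerate) parameters are flagged as such
    rather than raising.  With a single chain R-hat is not defined and is
    reported absent with a warning message.
    """
    import arviz as az

    messages: list[str] = []
    single = draws.n_chains < 2
    if single:
        messages.append("single chain: split R-hat not reported")
    idata = draws.to_arviz()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = az.ess(idata, method="bulk")
        rhat = az.rhat(idata) if not single else None

    rows = []
    flat = draws.flat()
    for name, sl in draws.blocks.items():
        ess_vals = np.atleast_1d(np.asarray(ess[name]))
        rhat_vals = (np.atleast_1d(np.asarray(rhat[name])) if rhat is not None
                     else np.full(ess_vals.shape, np.nan))
        labels = draws.names[sl]
        for j, label in enumerate(labels):
            col = flat[:, sl.start + j]
            degenerate = bool(np.ptp(col) == 0)
            rows.append({
                "parameter": label,
                "rhat": float(rhat_vals[j]) if rhat_vals.size > 1 else float(rhat_vals[0]),
                "ess_bulk": float(ess_vals[j]) if ess_vals.size > 1 else float(ess_vals[0]),
                "degenerate": degenerate,
            })
    table = pd.DataFrame(rows)
    flagged = []
    for _, row in table.iterrows():
        if row["degenerate"]:
            flagged.append(f"{row['parameter']}: degenerate (constant draws)")
        elif np.isfinite(row["rhat"]) and row["rhat"] > rhat_limit:
            flagged.append(f"{row['parameter']}: R-hat {row['rhat']:.3f} > {rhat_limit}")
        elif np.isfinite(row["ess_bulk"]) and row["ess_bulk"] < ess_limit:
            flagged.append(f"{row['parameter']}: ESS {row['ess_bulk']:.0f} < {ess_limit:.0f}")
    return ConvergenceReport(table=table, flagged=flagged, messages=messages)
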