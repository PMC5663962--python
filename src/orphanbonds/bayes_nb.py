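"""Hierarchical Bayesian negative-binomial regression for dyadic counts.

Model
-----
For dyad (focal j, partner i) with affiliative count y_ij, covariates x_ij and
co-occurrence exposure gamma_ij (minutes):

    ln(lambda_ij) = alpha_j + beta' x_ij + ln(gamma_ij)
    y_ij | .      ~ NegBinom(p_ij, r),   p_ij = r / (r + lambda_ij)

so lambda_ij is the expected count and Var = lambda (1 + lambda / r). Priors
(normal distributions parameterized by mean and *precision*, the convention of
the BUGS-family samplers this model class comes from):

    beta_k  ~ N(0, prec 0.1)        (variance 10)
    alpha_j ~ N(mu_alpha, prec tau_alpha)
    mu_alpha ~ N(0, prec 0.1)
    tau_alpha ~ Uniform(0.001, 100)
    r ~ Uniform(0, 100)

Inference is by adaptive Metropolis-within-Gibbs: componentwise Gaussian
random walks on beta, the alpha_j block, mu_alpha, and on logit-type
transforms of the bounded tau_alpha and r, with proposal scales tuned toward
0.44 acceptance during burn-in only (adaptation is frozen afterwards so the
post-burn-in chain has the exact target as its stationary law). Runs are
deterministic given the configuration seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import _mcmc_kernels as K
from .focal_data_io import DyadObservation
from .population_model import covariate_order, standardize_design

TAU_SUPPORT = (0.001, 100.0)
R_SUPPORT = (0.0, 100.0)
BETA_PRECISION = 0.1  # prior precision of beta_k and mu_alpha
RHAT_THRESHOLD = 1.1
TARGET_ACCEPTANCE = 0.44


@dataclass(frozen=True)
class ModelSpec:
    """Which of the four models is being fit, and its covariate order."""

    stratum: str
    activity: str
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.covariates:
            object.__setattr__(self, "covariates", covariate_order(self.stratum))
        elif self.covariates != covariate_order(self.stratum):
            raise ValueError(
                f"covariates must match the {self.stratum} stratum's declared set"
            )

    @property
    def name(self) -> str:
        return f"{self.stratum}_{self.activity}"


@dataclass(frozen=True)
class McmcConfig:
    n_chains: int = 3
    n_iter: int = 100_000
    burn_in_fraction: float = 0.10
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.burn_in_fraction < 1.0):
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if self.n_chains < 2:
            raise ValueError("at least two chains are needed for diagnostics")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_burn(self) -> int:
        return int(self.n_iter * self.burn_in_fraction)


@dataclass
class ModelState:
    """One point in parameter space."""

    beta: np.ndarray
    alpha: np.ndarray
    mu_alpha: float
    tau_alpha: float
    r: float

    def in_support(self) -> bool:
        return (TAU_SUPPORT[0] < self.tau_alpha < TAU_SUPPORT[1]
                and R_SUPPORT[0] < self.r < R_SUPPORT[1])


@dataclass
class NbData:
    """Dyad table prepared for fitting: arrays plus focal bookkeeping."""

    y: np.ndarray            # float64 counts
    gamma: np.ndarray
    log_gamma: np.ndarray
    X: np.ndarray            # standardized design, (n, K)
    focal_ids: list[str]
    focal_index: np.ndarray  # int64, row -> focal position

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_focals(self) -> int:
        return len(self.focal_ids)


def prepare_data(dyads: Sequence[DyadObservation], spec: ModelSpec) -> NbData:
    """Stack a dyad table into arrays, z-scoring the continuous covariates."""
    for d in dyads:
        if d.stratum != spec.stratum or d.activity != spec.activity:
            raise ValueError(
                f"dyad ({d.focal_id},{d.partner_id}) is {d.stratum}/{d.activity}, "
                f"spec wants {spec.stratum}/{spec.activity}"
            )
    if dyads:
        raw = np.stack([d.covariates for d in dyads])
        X = standardize_design(raw, spec.covariates)
        y = np.array([d.y for d in dyads], dtype=float)
        gamma = np.array([d.gamma_minutes for d in dyads], dtype=float)
        focal_ids = sorted({d.focal_id for d in dyads})
        pos = {f: i for i, f in enumerate(focal_ids)}
        fidx = np.array([pos[d.focal_id] for d in dyads], dtype=np.int64)
        log_gamma = np.log(gamma)
    else:
        k = len(spec.covariates)
        X = np.zeros((0, k))
        y = gamma = log_gamma = np.zeros(0)
        focal_ids = []
        fidx = np.zeros(0, dtype=np.int64)
    return NbData(y, gamma, log_gamma, X, focal_ids, fidx)


def linear_predictor(state: ModelState, data: NbData) -> np.ndarray:
    """Expected counts lambda_ij = gamma * exp(alpha_j + beta'x)."""
    eta = data.X @ state.beta
    if data.n_focals:
        eta = eta + state.alpha[data.focal_index]
    lam = data.gamma * np.exp(eta)
    if not np.all(np.isfinite(lam)) or np.any(lam <= 0):
        raise FloatingPointError("non-finite or non-positive expected count")
    return lam


def nb_log_pmf(y, lam, r):
    """Log PMF of the negative binomial with mean ``lam`` and dispersion ``r``.

    Success probability p = r/(r + lam); r may be any positive real, so the
    PMF is evaluated through log-gamma functions. Variance is
    lam * (1 + lam/r).
    """
    y = np.asarray(y, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be non-negative integers")
    if np.any(lam <= 0) or not r > 0:
        raise ValueError("lam and r must be positive")
    return (gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * (np.log(r) - np.log(r + lam))
            + y * (np.log(lam) - np.log(r + lam)))


def _normal_logpdf_prec(x, mean, precision):
    return 0.5 * (np.log(precision) - np.log(2 * np.pi)) - 0.5 * precision * (x - mean) ** 2


def log_posterior(state: ModelState, data: NbData) -> float:
    """Exact (normalized) log posterior density; -inf outside prior support."""
    if not state.in_support():
        return -np.inf
    lp = 0.0
    lp += float(np.sum(_normal_logpdf_prec(state.beta, 0.0, BETA_PRECISION)))
    lp += float(_normal_logpdf_prec(state.mu_alpha, 0.0, BETA_PRECISION))
    lp += float(np.sum(_normal_logpdf_prec(state.alpha, state.mu_alpha, state.tau_alpha)))
    lp += -math.log(TAU_SUPPORT[1] - TAU_SUPPORT[0])
    lp += -math.log(R_SUPPORT[1] - R_SUPPORT[0])
    if data.n_obs:
        lam = linear_predictor(state, data)
        lp += float(np.sum(nb_log_pmf(data.y, lam, state.r)))
    return lp


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

def _to_unconstrained(u: float, lo: float, hi: float) -> float:
    return math.log((u - lo) / (hi - u))


def _from_unconstrained(t: float, lo: float, hi: float) -> float:
    e = math.exp(-abs(t))
    if t >= 0:
        return (lo * e + hi) / (1.0 + e)
    return (lo + hi * e) / (1.0 + e)


def _log_jacobian(u: float, lo: float, hi: float) -> float:
    return math.log(u - lo) + math.log(hi - u) - math.log(hi - lo)


def _init_state(rng: np.random.Generator, n_cov: int, n_focals: int) -> ModelState:
    """Overdispersed initial values drawn from the priors."""
    sd = math.sqrt(1.0 / BETA_PRECISION)
    beta = rng.normal(0.0, sd, size=n_cov)
    mu = float(rng.normal(0.0, sd))
    tau = float(rng.uniform(*TAU_SUPPORT))
    r = float(rng.uniform(R_SUPPORT[0] + 1e-3, R_SUPPORT[1]))
    alpha = rng.normal(mu, 1.0 / math.sqrt(tau), size=n_focals)
    return ModelState(beta, alpha, mu, tau, r)


def _run_chain(
    data: NbData,
    config: McmcConfig,
    rng: np.random.Generator,
    init: Optional[ModelState] = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """One chain; returns draws (n_kept, P) with layout [beta, mu, tau, r, alpha]."""
    y, lo, X, fidx = data.y, data.log_gamma, data.X, data.focal_index
    n_cov, n_focals = data.X.shape[1], data.n_focals
    XT = np.ascontiguousarray(X.T)  # contiguous covariate columns for the kernels
    state = init if init is not None else _init_state(rng, n_cov, n_focals)
    beta = state.beta.astype(float).copy()
    alpha = state.alpha.astype(float).copy()
    mu, tau, r = float(state.mu_alpha), float(state.tau_alpha), float(state.r)
    t_tau = _to_unconstrained(tau, *TAU_SUPPORT)
    t_r = _to_unconstrained(r, *R_SUPPORT)

    eta = (X @ beta + (alpha[fidx] if n_focals else 0.0)) if data.n_obs else np.zeros(0)
    cur_pll = K.pll(eta, lo, y, r)

    s_beta = np.full(n_cov, 0.1)
    s_alpha = np.full(n_focals, 0.1)
    s_mu, s_tau, s_r = 0.1, 0.5, 0.5

    n_burn, thin = config.n_burn, config.thin
    n_kept = (config.n_iter - n_burn + thin - 1) // thin
    P = n_cov + 3 + n_focals
    draws = np.empty((n_kept, P))

    batch = 50
    acc_beta = np.zeros(n_cov)
    acc_alpha = np.zeros(n_focals)
    acc_mu = acc_tau = acc_r = 0.0
    post_acc = {"beta": np.zeros(n_cov), "alpha": np.zeros(n_focals),
                "mu_alpha": 0.0, "tau_alpha": 0.0, "r": 0.0}

    old_f = np.zeros(n_focals)
    new_f = np.zeros(n_focals)
    kept = 0
    for it in range(config.n_iter):
        # --- beta, componentwise random walk ------------------------------
        for k in range(n_cov):
            d = s_beta[k] * rng.standard_normal()
            new_pll = K.pll_shift_col(eta, XT[k], d, lo, y, r)
            dlp = (new_pll - cur_pll
                   - 0.5 * BETA_PRECISION * ((beta[k] + d) ** 2 - beta[k] ** 2))
            if math.log(rng.uniform()) < dlp:
                beta[k] += d
                eta = eta + d * XT[k]
                cur_pll = new_pll
                acc_beta[k] += 1

        # --- alpha block: simultaneous independent componentwise moves ----
        if n_focals:
            dal = s_alpha * rng.standard_normal(n_focals)
            K.pll_by_focal(eta, lo, y, r, fidx, old_f)
            K.pll_by_focal_shift(eta, dal, fidx, lo, y, r, new_f)
            dprior = -0.5 * tau * ((alpha + dal - mu) ** 2 - (alpha - mu) ** 2)
            accept = np.log(rng.uniform(size=n_focals)) < (new_f - old_f + dprior)
            if accept.any():
                alpha[accept] += dal[accept]
                dal_eff = np.where(accept, dal, 0.0)
                eta = eta + dal_eff[fidx]
                cur_pll += float(np.sum((new_f - old_f)[accept]))
            acc_alpha += accept

        # --- mu_alpha ------------------------------------------------------
        d = s_mu * rng.standard_normal()
        ssq_old = float(np.sum((alpha - mu) ** 2))
        ssq_new = float(np.sum((alpha - mu - d) ** 2))
        dlp = (-0.5 * tau * (ssq_new - ssq_old)
               - 0.5 * BETA_PRECISION * ((mu + d) ** 2 - mu ** 2))
        if math.log(rng.uniform()) < dlp:
            mu += d
            acc_mu += 1

        # --- tau_alpha on its logit transform ------------------------------
        d = s_tau * rng.standard_normal()
        tau_new = _from_unconstrained(t_tau + d, *TAU_SUPPORT)
        ssq = float(np.sum((alpha - mu) ** 2))
        dlp = (0.5 * n_focals * (math.log(tau_new) - math.log(tau))
               - 0.5 * (tau_new - tau) * ssq
               + _log_jacobian(tau_new, *TAU_SUPPORT) - _log_jacobian(tau, *TAU_SUPPORT))
        if math.log(rng.uniform()) < dlp:
            tau = tau_new
            t_tau += d
            acc_tau += 1

        # --- r on its logit transform --------------------------------------
        d = s_r * rng.standard_normal()
        r_new = _from_unconstrained(t_r + d, *R_SUPPORT)
        if r_new > 0.0:
            dlp = (K.ll_r(eta, lo, y, r_new) - K.ll_r(eta, lo, y, r)
                   + _log_jacobian(r_new, *R_SUPPORT) - _log_jacobian(r, *R_SUPPORT))
            if math.log(rng.uniform()) < dlp:
                r = r_new
                t_r += d
                cur_pll = K.pll(eta, lo, y, r)
                acc_r += 1

        # --- adaptation (burn-in only) -------------------------------------
        if it < n_burn and (it + 1) % batch == 0:
            step = min(0.5, ((it + 1) // batch) ** -0.5)

            def _tune(scale, rate):
                return scale * math.exp(step if rate > TARGET_ACCEPTANCE else -step)

            s_beta *= np.exp(np.where(acc_beta / batch > TARGET_ACCEPTANCE, step, -step))
            if n_focals:
                s_alpha *= np.exp(np.where(acc_alpha / batch > TARGET_ACCEPTANCE, step, -step))
            s_mu = _tune(s_mu, acc_mu / batch)
            s_tau = _tune(s_tau, acc_tau / batch)
            s_r = _tune(s_r, acc_r / batch)
            acc_beta[:] = 0
            acc_alpha[:] = 0
            acc_mu = acc_tau = acc_r = 0.0
        if it == n_burn - 1:  # reset counters so post-burn-in rates are clean
            acc_beta[:] = 0
            acc_alpha[:] = 0
            acc_mu = acc_tau = acc_r = 0.0

        # --- record --------------------------------------------------------
        if it >= n_burn and (it - n_burn) % thin == 0:
            draws[kept, :n_cov] = beta
            draws[kept, n_cov] = mu
            draws[kept, n_cov + 1] = tau
            draws[kept, n_cov + 2] = r
            if n_focals:
                draws[kept, n_cov + 3:] = alpha
            kept += 1

    n_post = max(config.n_iter - n_burn, 1)
    post_acc["beta"] = acc_beta / n_post
    post_acc["alpha"] = acc_alpha / n_post
    post_acc["mu_alpha"] = acc_mu / n_post
    post_acc["tau_alpha"] = acc_tau / n_post
    post_acc["r"] = acc_r / n_post
    return draws[:kept], post_acc


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor of one parameter.

    ``chains`` is (n_chains, n_draws). R-hat = sqrt(((n-1)/n W + B/n) / W)
    with W the mean within-chain variance and B the between-chain variance.
    Returns NaN when the within-chain variance is zero for non-identical
    chains (undefined), and exactly 1.0 for identical degenerate chains.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = chains.shape
    if n < 10:
        raise ValueError("chains too short for a meaningful diagnostic")
    w = float(np.mean(np.var(chains, axis=1, ddof=1)))
    b = n * float(np.var(np.mean(chains, axis=1), ddof=1))
    if w == 0.0:
        return 1.0 if b == 0.0 else float("nan")
    v = (n - 1) / n * w + b / n
    return math.sqrt(v / w)


@dataclass
class NbFit:
    """Post-burn-in samples from all chains, with diagnostics and summaries."""

    spec: ModelSpec
    config: McmcConfig
    param_names: list[str]
    draws: np.ndarray  # (n_chains, n_kept, P)
    acceptance: list[dict] = field(repr=False, default_factory=list)

    def pooled(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])

    def rhat(self) -> pd.Series:
        vals = [gelman_rubin(self.draws[:, :, p]) for p in range(self.draws.shape[2])]
        return pd.Series(vals, index=self.param_names, name="rhat")

    @property
    def max_rhat(self) -> float:
        return float(np.nanmax(self.rhat().values))

    @property
    def converged(self) -> bool:
        r = self.rhat().values
        return bool(np.all(np.isfinite(r)) and np.all(r < RHAT_THRESHOLD))

    def summary(self) -> pd.DataFrame:
        pooled = self.pooled()
        med = np.median(pooled, axis=0)
        lo = np.percentile(pooled, 2.5, axis=0)
        hi = np.percentile(pooled, 97.5, axis=0)
        return pd.DataFrame(
            {"median": med, "ci_2.5": lo, "ci_97.5": hi, "rhat": self.rhat().values},
            index=pd.Index(self.param_names, name="parameter"),
        )

    def chains_to_frame(self) -> pd.DataFrame:
        """Tidy (chain, iteration, parameter, value) view of all draws."""
        n_chains, n_kept, P = self.draws.shape
        recs = []
        for c in range(n_chains):
            df = pd.DataFrame(self.draws[c], columns=self.param_names)
            df.insert(0, "iteration", np.arange(n_kept))
            df.insert(0, "chain", c)
            recs.append(df.melt(id_vars=["chain", "iteration"],
                                var_name="parameter", value_name="value"))
        return pd.concat(recs, ignore_index=True)


def fit(
    dyads: Sequence[DyadObservation] | NbData,
    spec: ModelSpec,
    config: McmcConfig,
    inits: Optional[Sequence[ModelState]] = None,
) -> NbFit:
    """Run the adaptive Metropolis-within-Gibbs sampler.

    Chains start from independent draws from the priors (bounded parameters
    from their uniforms) unless explicit ``inits`` are given. Deterministic
    given ``config.seed``.
    """
    data = dyads if isinstance(dyads, NbData) else prepare_data(dyads, spec)
    n_cov = data.X.shape[1]
    for k, name in enumerate(spec.covariates):
        col = data.X[:, k]
        if data.n_obs and np.any(col != 0) and np.sum(data.y[col != 0]) == 0:
            warnings.warn(
                f"covariate {name!r}: all counts are zero where it is non-zero; "
                "its coefficient is weakly identified", RuntimeWarning,
            )

    K.warm_up()
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    all_draws = []
    acceptance = []
    for c in range(config.n_chains):
        rng = np.random.Generator(np.random.PCG64(seeds[c]))
        init = inits[c] if inits is not None else None
        draws, acc = _run_chain(data, config, rng, init)
        all_draws.append(draws)
        acceptance.append(acc)

    for c, acc in enumerate(acceptance):
        rates = np.concatenate([np.atleast_1d(acc["beta"]),
                                np.atleast_1d(acc["alpha"]),
                                [acc["mu_alpha"], acc["tau_alpha"], acc["r"]]])
        bad = (rates < 0.05) | (rates > 0.95)
        if data.n_obs and bad.any():
            warnings.warn(
                f"chain {c}: {int(bad.sum())} proposal(s) with acceptance rate "
                "outside [0.05, 0.95] after adaptation", RuntimeWarning,
            )

    names = ([f"beta[{n}]" for n in spec.covariates]
             + ["mu_alpha", "tau_alpha", "r"]
             + [f"alpha[{f}]" for f in data.focal_ids])
    return NbFit(spec, config, names, np.stack(all_draws), acceptance)


def summarize(fit_result: NbFit) -> pd.DataFrame:
    """Median and equal-tailed 95% credible interval per parameter."""
    return fit_result.summary()
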