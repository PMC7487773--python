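"""Double-hierarchical Gaussian model of strike placement, fitted by MCMC.

The fine-scale analysis separates *accuracy* (where, on average, strikes
land) from *precision* (how tightly they cluster).  For POI j of
individual (fight) i, with y the cube-root-scaled distance to a shell
landmark:

    y_ij = beta0 + beta' x_i + a_i + e_ij,      e_ij ~ N(0, sigma_ij^2)
    log sigma_ij = delta0 + gamma' x_i + b_i
    a_i ~ N(0, sigma_a^2),   b_i ~ N(0, sigma_b^2)

with identical fixed-effect sets x_i = (RWD, outcome, vigour) in both
submodels and individual random effects in both.  The mean submodel
measures accuracy; the log-SD submodel measures precision.

Fitting is Metropolis-within-Gibbs: the mean-model fixed effects and
the a_i have Gaussian full conditionals given the observation SDs and
are Gibbs-updated exactly; SD-model parameters, b_i and the two
random-effect SDs use adaptive random-walk Metropolis (target
acceptance 0.44, adaptation frozen after burn-in).  Because every
covariate is constant within an individual, sigma_ij varies only across
individuals and the whole posterior depends on the data through the
per-individual sufficient statistics (n_i, sum y_ij, sum y_ij^2) — one
MCMC sweep costs O(n_individuals), not O(n_POIs).

Priors: Normal(0, tau_fix^2) on fixed effects of the standardized
design (default tau_fix = 10), half-Cauchy(2.5) on sigma_a and sigma_b.
Covariates are standardized for sampling and every reported draw is
back-transformed to the raw covariate scale.
"""

from __future__ import annotations

import dataclasses
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .io_model import FightRecord, ScaledPOI
from .preprocess import scale_poi

__all__ = [
    "DHGLMSpec",
    "DHGLMData",
    "DHGLMPosterior",
    "ConvergenceWarning",
    "build_design",
    "log_posterior",
    "sample_posterior",
    "pseudo_p",
    "convergence_diagnostics",
    "run_dhglm_suite",
]

COVARIATE_NAMES = ("rwd", "outcome", "vigour")
_LOG_2PI = float(np.log(2.0 * np.pi))


class ConvergenceWarning(UserWarning):
    """Emitted when R-hat or effective sample size fails its threshold."""


@dataclass
class DHGLMSpec:
    """What to fit and how to sample.

    ``fixed_sigma`` switches the model into its conjugate limit (known,
    common residual SD; no SD submodel); ``include_random_effects=False``
    additionally drops a_i.  Both exist for oracle testing against the
    closed-form Gaussian linear-model posterior.
    """

    response: str = "scaled_dist_B"  # "scaled_dist_A" | "scaled_dist_B"
    poi_filter: str = "whole"  # "whole" | "zone1"
    n_chains: int = 3
    n_iter: int = 20000
    burn_in: int = 5000
    thin: int = 5
    seed: int = 0
    tau_fix: float = 10.0  # prior SD of fixed effects (standardized scale)
    hc_scale: float = 2.5  # half-Cauchy scale for sigma_a, sigma_b
    include_random_effects: bool = True
    include_sd_model: bool = True
    fixed_sigma: float | None = None
    rhat_threshold: float = 1.05
    ess_threshold: float = 400.0

    def validate(self) -> None:
        if self.response not in ("scaled_dist_A", "scaled_dist_B"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.poi_filter not in ("whole", "zone1"):
            raise ValueError(f"unknown poi_filter {self.poi_filter!r}")
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.n_chains < 2:
            raise ValueError("need n_chains >= 2 for split R-hat")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.fixed_sigma is not None and self.include_sd_model:
            raise ValueError("fixed_sigma requires include_sd_model=False")
        if not self.include_sd_model and self.fixed_sigma is None:
            raise ValueError("include_sd_model=False requires fixed_sigma")


@dataclass
class DHGLMData:
    """Model-ready arrays produced by :func:`build_design`.

    ``Z`` holds the standardized per-individual covariates (one row per
    individual, columns in COVARIATE_NAMES order); ``idx`` maps each POI
    to its individual's row.
    """

    y: np.ndarray
    idx: np.ndarray
    Z: np.ndarray
    cov_means: np.ndarray
    cov_sds: np.ndarray
    fight_ids: tuple[str, ...]
    response: str
    poi_filter: str
    n_single_poi: int  # individuals with < 2 POIs (SD info prior-dominated)

    @property
    def n_obs(self) -> int:
        return int(self.y.size)

    @property
    def n_ind(self) -> int:
        return int(self.Z.shape[0])

    def suffstats(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(n_i, sum_i y, sum_i y^2) per individual."""
        n_i = np.bincount(self.idx, minlength=self.n_ind).astype(float)
        sum_y = np.bincount(self.idx, weights=self.y, minlength=self.n_ind)
        sum_y2 = np.bincount(self.idx, weights=self.y**2, minlength=self.n_ind)
        return n_i, sum_y, sum_y2


def build_design(
    fights: Sequence[FightRecord],
    scaled_pois: Sequence[ScaledPOI],
    spec: DHGLMSpec,
) -> DHGLMData:
    """Assemble response vector, standardized covariates and index map.

    Individuals with fewer than 2 POIs are retained (they still inform
    the mean model; their SD contribution is prior-dominated) but
    counted in ``n_single_poi`` for the diagnostics report.
    """
    spec.validate()
    by_fight: dict[str, FightRecord] = {f.fight_id: f for f in fights}
    pois = list(scaled_pois)
    if spec.poi_filter == "zone1":
        pois = [p for p in pois if p.zone == "1"]
    for p in pois:
        if p.fight_id not in by_fight:
            raise ValueError(f"POI {p.poi_id} references unknown fight {p.fight_id}")
    if not pois:
        raise ValueError(
            f"no POIs left after applying filter {spec.poi_filter!r}"
        )
    used_ids = sorted({p.fight_id for p in pois})
    if len(used_ids) < 2:
        raise ValueError(
            "only one individual has POIs: random-effect SDs are unidentifiable"
        )
    pos = {fid: k for k, fid in enumerate(used_ids)}
    y = np.array([getattr(p, spec.response) for p in pois], dtype=float)
    idx = np.array([pos[p.fight_id] for p in pois], dtype=int)

    raw = np.empty((len(used_ids), 3))
    for fid, k in pos.items():
        f = by_fight[fid]
        raw[k] = (f.rwd, float(f.outcome_code), f.mean_raps_per_bout)
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)
    for j, name in enumerate(COVARIATE_NAMES):
        if sds[j] == 0:
            raise ValueError(
                f"covariate {name!r} is constant across individuals; "
                "its effect is unidentifiable"
            )
    Z = (raw - means) / sds

    counts = np.bincount(idx, minlength=len(used_ids))
    return DHGLMData(
        y=y,
        idx=idx,
        Z=Z,
        cov_means=means,
        cov_sds=sds,
        fight_ids=tuple(used_ids),
        response=spec.response,
        poi_filter=spec.poi_filter,
        n_single_poi=int(np.sum(counts < 2)),
    )


# ---------------------------------------------------------------------------
# Log posterior (reference, per-observation form)
# ---------------------------------------------------------------------------


def _half_cauchy_logpdf(sigma: float, scale: float) -> float:
    if sigma <= 0:
        return -np.inf
    return float(np.log(2.0 / (np.pi * scale)) - np.log1p((sigma / scale) ** 2))


def _normal_logpdf(x: np.ndarray, sd: float | np.ndarray) -> np.ndarray:
    return -0.5 * _LOG_2PI - np.log(sd) - 0.5 * (x / sd) ** 2


def log_posterior(
    params: Mapping[str, Any], data: DHGLMData, spec: DHGLMSpec
) -> float:
    """Joint log-density of data and parameters (standardized scale).

    Reference implementation summing the Normal log-density observation
    by observation; the sampler's sufficient-statistic shortcut is
    required (and tested) to agree with it.  ``params`` uses keys
    ``beta`` (length 4: intercept + covariates), ``a``, ``sigma_a``,
    ``gamma``, ``b``, ``sigma_b``; the latter groups may be omitted when
    the spec disables them.
    """
    beta = np.asarray(params["beta"], dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("non-finite beta")
    X = np.column_stack([np.ones(data.n_ind), data.Z])
    mu_ind = X @ beta
    if spec.include_random_effects:
        a = np.asarray(params["a"], dtype=float)
        sigma_a = float(params["sigma_a"])
        if sigma_a <= 0:
            raise ValueError("sigma_a must be > 0")
        mu_ind = mu_ind + a
    if spec.include_sd_model:
        gamma = np.asarray(params["gamma"], dtype=float)
        b = np.asarray(params["b"], dtype=float)
        sigma_b = float(params["sigma_b"])
        if sigma_b <= 0:
            raise ValueError("sigma_b must be > 0")
        eta_ind = X @ gamma + b
        sd_ind = np.exp(eta_ind)
    else:
        sd_ind = np.full(data.n_ind, float(spec.fixed_sigma))
    if not np.all(np.isfinite(mu_ind)) or not np.all(np.isfinite(sd_ind)):
        raise ValueError("non-finite parameter state")

    lp = 0.0
    if data.n_obs:
        resid = data.y - mu_ind[data.idx]
        lp += float(np.sum(_normal_logpdf(resid, sd_ind[data.idx])))
    lp += float(np.sum(_normal_logpdf(beta, spec.tau_fix)))
    if spec.include_random_effects:
        lp += float(np.sum(_normal_logpdf(a, sigma_a)))
        lp += _half_cauchy_logpdf(sigma_a, spec.hc_scale)
    if spec.include_sd_model:
        lp += float(np.sum(_normal_logpdf(gamma, spec.tau_fix)))
        lp += float(np.sum(_normal_logpdf(b, sigma_b)))
        lp += _half_cauchy_logpdf(sigma_b, spec.hc_scale)
    return lp


# ---------------------------------------------------------------------------
# Gibbs conditionals (exact, used by the sampler and unit-testable)
# ---------------------------------------------------------------------------


def _beta_conditional(
    X: np.ndarray,
    n_i: np.ndarray,
    sum_y: np.ndarray,
    w: np.ndarray,
    a: np.ndarray,
    tau_fix: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of beta | everything else.

    w is the per-individual observation precision exp(-2 eta_i).
    """
    p = X.shape[1]
    prec = (X * (w * n_i)[:, None]).T @ X + np.eye(p) / tau_fix**2
    rhs = X.T @ (w * (sum_y - n_i * a))
    cov = np.linalg.inv(prec)
    return cov @ rhs, cov


def _a_conditional(
    X: np.ndarray,
    n_i: np.ndarray,
    sum_y: np.ndarray,
    w: np.ndarray,
    beta: np.ndarray,
    sigma_a: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual mean and variance of a_i | everything else."""
    prec = n_i * w + 1.0 / sigma_a**2
    mean = w * (sum_y - n_i * (X @ beta)) / prec
    return mean, 1.0 / prec


def _sd_model_loglik(
    eta: np.ndarray, n_i: np.ndarray, s_i: np.ndarray
) -> np.ndarray:
    """Per-individual log-likelihood as a function of log-SD eta_i.

    s_i is the per-individual residual sum of squares around the current
    mean-model fit; the -n_i/2 log(2 pi) constant is dropped.
    """
    return -n_i * eta - 0.5 * s_i * np.exp(-2.0 * eta)


# ---------------------------------------------------------------------------
# Posterior container and summaries
# ---------------------------------------------------------------------------


def pseudo_p(draws: Sequence[float]) -> float:
    """Bayesian tail-probability summary of one parameter's draws.

    Twice the smaller of the posterior masses at or below zero and above
    zero, floored at 2/N (no tail can be declared emptier than one draw
    would resolve).  Symmetric draws give p = 1.
    """
    d = np.asarray(draws, dtype=float)
    n = d.size
    if n < 100:
        raise ValueError("need at least 100 draws for a pseudo-P value")
    n_le = int(np.sum(d <= 0))
    p = 2.0 * min(n_le, n - n_le) / n
    return float(max(p, 2.0 / n))


def convergence_diagnostics(chains: np.ndarray) -> tuple[float, float]:
    """Split-chain R-hat and effective sample size for one parameter.

    ``chains`` has shape (n_chains, n_draws).  R-hat is the potential
    scale reduction factor on half-split chains; ESS uses the combined
    autocorrelation series truncated by Geyer's initial monotone
    positive-pair rule.  Constant chains give (inf, 0) — flagged, not
    raised, so a degenerate parameter cannot abort a whole run.
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = chains.shape
    if m < 2 or n < 4:
        raise ValueError("need >= 2 chains and >= 4 draws each")
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    sm, sn = split.shape
    means = split.mean(axis=1)
    variances = split.var(axis=1, ddof=1)
    W = float(variances.mean())
    B = sn * float(np.var(means, ddof=1))
    if W <= 0:
        return float("inf"), 0.0
    var_plus = (sn - 1) / sn * W + B / sn
    rhat = float(np.sqrt(var_plus / W))

    # combined autocorrelation via per-chain FFT autocovariance
    acov = np.empty((sm, sn))
    for c in range(sm):
        x = split[c] - means[c]
        size = 2 ** int(np.ceil(np.log2(2 * sn)))
        f = np.fft.rfft(x, size)
        ac = np.fft.irfft(f * np.conjugate(f), size)[:sn].real
        acov[c] = ac / sn
    mean_acov = acov.mean(axis=0)
    rho = 1.0 - (W - mean_acov) / var_plus
    # Geyer: sum consecutive pairs while positive, enforce monotone decrease
    tau_sum = 0.0
    prev_pair = np.inf
    t = 1
    while t + 1 < sn:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        tau_sum += pair
        prev_pair = pair
        t += 2
    ess = sm * sn / (1.0 + 2.0 * tau_sum)
    return rhat, float(min(ess, sm * sn))


@dataclass
class DHGLMPosterior:
    """Posterior draws and Table-style summaries for one DHGLM run.

    ``draws`` maps parameter name to pooled post-burn-in draws on the
    raw covariate scale; ``per_chain`` keeps the chain structure for
    diagnostics.  Summary rows carry estimate mean/SD, the central 95%
    credible interval, the pseudo-P value, split R-hat and ESS.
    """

    response: str
    poi_filter: str
    n_obs: int
    n_ind: int
    n_single_poi: int
    draws: dict[str, np.ndarray]
    per_chain: dict[str, np.ndarray]
    summaries: dict[str, dict[str, float]]
    converged: bool
    convergence_flags: tuple[str, ...] = field(default_factory=tuple)

    def summary(self, name: str) -> dict[str, float]:
        return self.summaries[name]

    def to_json_dict(self) -> dict:
        out: dict = {
            "meta": {
                "response": self.response,
                "poi_filter": self.poi_filter,
                "n_obs": self.n_obs,
                "n_ind": self.n_ind,
                "n_single_poi": self.n_single_poi,
                "converged": self.converged,
                "convergence_flags": list(self.convergence_flags),
            }
        }
        for name, s in self.summaries.items():
            out[name] = {
                "estimate_mean": s["estimate_mean"],
                "estimate_sd": s["estimate_sd"],
                "ci_low": s["ci_low"],
                "ci_high": s["ci_high"],
                "p": s["p"],
                "rhat": s["rhat"],
                "ess": s["ess"],
            }
        return out


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------


def _chain_start(
    rng: np.random.Generator, data: DHGLMData, spec: DHGLMSpec
) -> dict[str, Any]:
    """Over-dispersed but plausible initial state for one chain."""
    if data.n_obs:
        ybar = float(data.y.mean())
        ysd = float(data.y.std()) or 1.0
    else:
        ybar, ysd = 0.0, 1.0
    p = 4
    beta = np.zeros(p)
    beta[0] = ybar
    beta += rng.normal(0.0, 0.5 * ysd, p)
    state: dict[str, Any] = {"beta": beta}
    if spec.include_random_effects:
        state["a"] = rng.normal(0.0, 0.1 * ysd, data.n_ind)
        state["sigma_a"] = float(np.exp(rng.normal(np.log(0.5 * ysd), 0.5)))
    if spec.include_sd_model:
        gamma = np.zeros(p)
        gamma[0] = np.log(ysd)
        gamma += rng.normal(0.0, 0.3, p)
        state["gamma"] = gamma
        state["b"] = rng.normal(0.0, 0.1, data.n_ind)
        state["sigma_b"] = float(np.exp(rng.normal(np.log(0.3), 0.5)))
    return state


def _adapt(log_step, acc, t: int, target: float = 0.44):
    """Robbins-Monro step-size adaptation toward a target acceptance."""
    rate = min(0.25, t ** -0.6)
    return log_step + rate * (acc - target)


def _run_chain(
    data: DHGLMData, spec: DHGLMSpec, seed: np.random.SeedSequence
) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    n_ind = data.n_ind
    X = np.column_stack([np.ones(n_ind), data.Z])
    n_i, sum_y, sum_y2 = data.suffstats()
    state = _chain_start(rng, data, spec)
    p = 4

    # adaptive RW step sizes (log scale)
    ls_gamma = np.full(p, np.log(0.2))
    ls_b = np.full(n_ind, np.log(0.3))
    ls_sa = np.log(0.3)
    ls_sb = np.log(0.3)

    kept_names = ["beta"]
    if spec.include_sd_model:
        kept_names += ["gamma", "sigma_b"]
    if spec.include_random_effects:
        kept_names += ["sigma_a"]
    n_kept = (spec.n_iter - spec.burn_in) // spec.thin
    store: dict[str, np.ndarray] = {
        "beta": np.empty((n_kept, p)),
    }
    if spec.include_sd_model:
        store["gamma"] = np.empty((n_kept, p))
        store["sigma_b"] = np.empty(n_kept)
    if spec.include_random_effects:
        store["sigma_a"] = np.empty(n_kept)

    beta = state["beta"]
    a = state.get("a", np.zeros(n_ind))
    sigma_a = state.get("sigma_a", 1.0)
    if spec.include_sd_model:
        gamma = state["gamma"]
        b = state["b"]
        sigma_b = state["sigma_b"]
        eta = X @ gamma + b
    else:
        gamma = None
        b = np.zeros(n_ind)
        sigma_b = 1.0
        eta = np.full(n_ind, np.log(float(spec.fixed_sigma)))

    kept = 0
    for t in range(1, spec.n_iter + 1):
        adapting = t <= spec.burn_in
        w = np.exp(-2.0 * eta)

        # --- mean model: exact Gibbs ---
        mean_b_, cov_b = _beta_conditional(X, n_i, sum_y, w, a, spec.tau_fix)
        beta = mean_b_ + np.linalg.cholesky(cov_b) @ rng.standard_normal(p)

        if spec.include_random_effects:
            mean_a, var_a = _a_conditional(X, n_i, sum_y, w, beta, sigma_a)
            a = mean_a + np.sqrt(var_a) * rng.standard_normal(n_ind)

            # sigma_a: RW Metropolis on log sigma_a
            log_sa = np.log(sigma_a)
            prop = log_sa + np.exp(ls_sa) * rng.standard_normal()
            sa_new = np.exp(prop)
            cur = (
                float(np.sum(_normal_logpdf(a, sigma_a)))
                + _half_cauchy_logpdf(sigma_a, spec.hc_scale)
                + log_sa
            )
            new = (
                float(np.sum(_normal_logpdf(a, sa_new)))
                + _half_cauchy_logpdf(sa_new, spec.hc_scale)
                + prop
            )
            acc = min(1.0, float(np.exp(min(new - cur, 0.0))))
            if rng.random() < acc:
                sigma_a = sa_new
            if adapting:
                ls_sa = _adapt(ls_sa, acc, t)

        if spec.include_sd_model:
            # residual sum of squares per individual at current (beta, a)
            m_i = X @ beta + a
            s_i = sum_y2 - 2.0 * m_i * sum_y + n_i * m_i**2

            # gamma_j: scalar adaptive RW (eta maintained incrementally)
            for j in range(p):
                step = np.exp(ls_gamma[j])
                delta = step * rng.standard_normal()
                eta_new = eta + delta * X[:, j]
                cur = float(np.sum(_sd_model_loglik(eta, n_i, s_i))) + float(
                    _normal_logpdf(np.array([gamma[j]]), spec.tau_fix)[0]
                )
                new = float(np.sum(_sd_model_loglik(eta_new, n_i, s_i))) + float(
                    _normal_logpdf(np.array([gamma[j] + delta]), spec.tau_fix)[0]
                )
                acc = min(1.0, float(np.exp(min(new - cur, 0.0))))
                if rng.random() < acc:
                    gamma = gamma.copy()
                    gamma[j] += delta
                    eta = eta_new
                if adapting:
                    ls_gamma[j] = _adapt(ls_gamma[j], acc, t)

            # b_i: independent scalar RW updates, vectorized
            delta_b = np.exp(ls_b) * rng.standard_normal(n_ind)
            eta_new = eta + delta_b
            ll_cur = _sd_model_loglik(eta, n_i, s_i) - 0.5 * (b / sigma_b) ** 2
            ll_new = _sd_model_loglik(eta_new, n_i, s_i) - 0.5 * (
                (b + delta_b) / sigma_b
            ) ** 2
            acc_vec = np.exp(np.minimum(ll_new - ll_cur, 0.0))
            take = rng.random(n_ind) < acc_vec
            b = np.where(take, b + delta_b, b)
            eta = np.where(take, eta_new, eta)
            if adapting:
                ls_b = _adapt(ls_b, acc_vec, t)

            # sigma_b: RW Metropolis on log sigma_b
            log_sb = np.log(sigma_b)
            prop = log_sb + np.exp(ls_sb) * rng.standard_normal()
            sb_new = np.exp(prop)
            cur = (
                float(np.sum(_normal_logpdf(b, sigma_b)))
                + _half_cauchy_logpdf(sigma_b, spec.hc_scale)
                + log_sb
            )
            new = (
                float(np.sum(_normal_logpdf(b, sb_new)))
                + _half_cauchy_logpdf(sb_new, spec.hc_scale)
                + prop
            )
            acc = min(1.0, float(np.exp(min(new - cur, 0.0))))
            if rng.random() < acc:
                sigma_b = sb_new
            if adapting:
                ls_sb = _adapt(ls_sb, acc, t)

        if not adapting and (t - spec.burn_in) % spec.thin == 0 and kept < n_kept:
            store["beta"][kept] = beta
            if spec.include_sd_model:
                store["gamma"][kept] = gamma
                store["sigma_b"][kept] = sigma_b
            if spec.include_random_effects:
                store["sigma_a"][kept] = sigma_a
            kept += 1

    for k in store:
        store[k] = store[k][:kept]
    return store


def _raw_scale_draws(
    store: dict[str, np.ndarray], data: DHGLMData, spec: DHGLMSpec
) -> dict[str, np.ndarray]:
    """Back-transform standardized-scale draws to raw covariate scale."""
    out: dict[str, np.ndarray] = {}
    m, s = data.cov_means, data.cov_sds

    def expand(block: np.ndarray, prefix: str) -> None:
        coefs = block[:, 1:] / s[None, :]
        intercept = block[:, 0] - coefs @ m
        out[f"{prefix}.intercept"] = intercept
        for j, name in enumerate(COVARIATE_NAMES):
            out[f"{prefix}.{name}"] = coefs[:, j]

    expand(store["beta"], "mean")
    if spec.include_sd_model:
        expand(store["gamma"], "sd")
        out["sigma_b"] = store["sigma_b"]
    if spec.include_random_effects:
        out["sigma_a"] = store["sigma_a"]
    return out


def sample_posterior(data: DHGLMData, spec: DHGLMSpec) -> DHGLMPosterior:
    """Run the full Metropolis-within-Gibbs sampler.

    Independent chains with over-dispersed starts are pooled after
    burn-in and thinning.  A parameter with split R-hat above the
    threshold or ESS below it flags the result non-converged (returned,
    with a warning) rather than raising.
    """
    spec.validate()
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_chains)
    chain_draws = [
        _raw_scale_draws(_run_chain(data, spec, s), data, spec) for s in seeds
    ]

    names = list(chain_draws[0].keys())
    per_chain = {
        name: np.stack([cd[name] for cd in chain_draws]) for name in names
    }
    pooled = {name: per_chain[name].reshape(-1) for name in names}

    summaries: dict[str, dict[str, float]] = {}
    flags: list[str] = []
    for name in names:
        d = pooled[name]
        rhat, ess = convergence_diagnostics(per_chain[name])
        lo, hi = np.quantile(d, [0.025, 0.975])
        is_scale = name.startswith("sigma")
        summaries[name] = {
            "estimate_mean": float(d.mean()),
            "estimate_sd": float(d.std(ddof=1)),
            "ci_low": float(lo),
            "ci_high": float(hi),
            "p": float("nan") if is_scale else pseudo_p(d),
            "rhat": rhat,
            "ess": ess,
        }
        if not np.isfinite(rhat) or rhat > spec.rhat_threshold:
            flags.append(f"{name}: R-hat {rhat:.3f} > {spec.rhat_threshold}")
        if ess < spec.ess_threshold:
            flags.append(f"{name}: ESS {ess:.0f} < {spec.ess_threshold:.0f}")

    converged = not flags
    if not converged:
        _warnings.warn(
            "DHGLM run flagged non-converged: " + "; ".join(flags),
            ConvergenceWarning,
        )
    return DHGLMPosterior(
        response=data.response,
        poi_filter=data.poi_filter,
        n_obs=data.n_obs,
        n_ind=data.n_ind,
        n_single_poi=data.n_single_poi,
        draws=pooled,
        per_chain=per_chain,
        summaries=summaries,
        converged=converged,
        convergence_flags=tuple(flags),
    )


SUITE_RUNS = (
    ("dist_A_whole", "scaled_dist_A", "whole"),
    ("dist_B_whole", "scaled_dist_B", "whole"),
    ("dist_A_zone1", "scaled_dist_A", "zone1"),
    ("dist_B_zone1", "scaled_dist_B", "zone1"),
)


def run_dhglm_suite(
    fights: Sequence[FightRecord],
    pois: Sequence,
    spec: DHGLMSpec | None = None,
) -> dict[str, DHGLMPosterior]:
    """Fit all four DHGLMs: {distance to A, B} x {whole shell, zone 1 only}.

    ``pois`` may be raw POIRecords (they are cube-root-scaled here using
    each fight's defender shell weight) or ready ScaledPOIs.  Each run
    gets a distinct seed derived from the base spec's seed.
    """
    base = spec or DHGLMSpec()
    shell = {f.fight_id: f.defender_shell_weight for f in fights}
    scaled = [
        p if isinstance(p, ScaledPOI) else scale_poi(p, shell[p.fight_id])
        for p in pois
    ]
    results: dict[str, DHGLMPosterior] = {}
    sub_seeds = np.random.SeedSequence(base.seed).spawn(len(SUITE_RUNS))
    for (key, response, poi_filter), sseed in zip(SUITE_RUNS, sub_seeds):
        run_spec = dataclasses.replace(
            base,
            response=response,
            poi_filter=poi_filter,
            seed=int(sseed.generate_state(1)[0] % (2**31 - 1)),
        )
        data = build_design(fights, scaled, run_spec)
        results[key] = sample_posterior(data, run_spec)
    return results
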