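"""Coarse-scale analysis of strike placement and contest outcome.

Two statistical primitives are implemented here from first principles and
checked against independent oracles in the test suite:

* a binomial-family GLM (logit link) fitted by iteratively reweighted
  least squares, with term-wise likelihood-ratio chi-square tests, and
* Kendall's rank correlation in its tie-corrected tau-b form, with a
  normal-approximation p-value (exact permutation p for very small n).

``run_coarse_analysis`` glues them together: a GLM of eviction on the
zone-1 and zone-2 strike proportions (plus their interaction) with
relative weight difference (RWD) as covariate, and the four correlations
between spatial (zone proportions) and temporal (total raps, mean raps
per bout) performance measures — each reported with and without
outlier-flagged fights.
"""

from __future__ import annotations

import itertools
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _stats
from scipy import special as _special

from .io_model import FightRecord, ZoneSummary

__all__ = [
    "GLMFit",
    "TauResult",
    "CoarseFit",
    "CoarseResult",
    "SeparationWarning",
    "kendall_tau_b",
    "fit_binomial_glm",
    "lrt_term",
    "run_coarse_analysis",
]


class SeparationWarning(UserWarning):
    """Emitted when a logistic fit shows signs of complete separation."""


# ---------------------------------------------------------------------------
# Kendall tau-b
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TauResult:
    """Tie-corrected Kendall rank correlation with pair bookkeeping.

    ``tied_x``/``tied_y`` count pairs tied in exactly one variable;
    ``tied_both`` pairs tied in both.  The five counts partition the
    n(n-1)/2 pairs.
    """

    tau: float
    p: float
    n: int
    concordant: int
    discordant: int
    tied_x: int
    tied_y: int
    tied_both: int

    @property
    def n_pairs(self) -> int:
        return self.n * (self.n - 1) // 2


def _tie_group_sizes(v: np.ndarray) -> np.ndarray:
    _, counts = np.unique(v, return_counts=True)
    return counts[counts > 1]


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> TauResult:
    """Kendall's tau-b with tie correction and two-sided p-value.

    tau_b = (C - D) / sqrt((N0 - Tx) (N0 - Ty)) with N0 = n(n-1)/2 and
    Tx, Ty the pair counts tied in x resp. y.  For n > 8 the p-value
    uses the normal approximation with the tie-corrected variance of
    C - D; for n <= 8 an exact permutation distribution over all n!
    orderings of y is enumerated.

    Raises ``ValueError`` when either variable is constant (the
    statistic is undefined: a zero tie-corrected denominator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2:
        raise ValueError("tau undefined: x has no distinct values (all ties)")
    if np.unique(y).size < 2:
        raise ValueError("tau undefined: y has no distinct values (all ties)")

    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    sx, sy = sx[iu], sy[iu]
    prod = sx * sy
    concordant = int(np.sum(prod > 0))
    discordant = int(np.sum(prod < 0))
    tied_both = int(np.sum((sx == 0) & (sy == 0)))
    tied_x = int(np.sum((sx == 0) & (sy != 0)))
    tied_y = int(np.sum((sx != 0) & (sy == 0)))

    n0 = n * (n - 1) // 2
    tx_all = tied_x + tied_both
    ty_all = tied_y + tied_both
    denom = np.sqrt(float(n0 - tx_all) * float(n0 - ty_all))
    s = concordant - discordant
    tau = s / denom

    if n <= 8:
        p = _exact_perm_p(x, y, s)
    else:
        p = _normal_approx_p(x, y, s, n)

    return TauResult(
        tau=float(tau),
        p=float(p),
        n=n,
        concordant=concordant,
        discordant=discordant,
        tied_x=tied_x,
        tied_y=tied_y,
        tied_both=tied_both,
    )


def _normal_approx_p(x: np.ndarray, y: np.ndarray, s: int, n: int) -> float:
    # tie-corrected variance of C - D (standard tau-b large-sample form)
    tx = _tie_group_sizes(x).astype(float)
    ty = _tie_group_sizes(y).astype(float)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = np.sum(tx * (tx - 1) * (2 * tx + 5))
    vu = np.sum(ty * (ty - 1) * (2 * ty + 5))
    v1 = np.sum(tx * (tx - 1)) * np.sum(ty * (ty - 1)) / (2.0 * n * (n - 1))
    v2 = (
        np.sum(tx * (tx - 1) * (tx - 2))
        * np.sum(ty * (ty - 1) * (ty - 2))
        / (9.0 * n * (n - 1) * (n - 2))
    )
    var = (v0 - vt - vu) / 18.0 + v1 + v2
    if var <= 0:
        return 1.0
    z = s / np.sqrt(var)
    return float(2.0 * _stats.norm.sf(abs(z)))


def _exact_perm_p(x: np.ndarray, y: np.ndarray, s_obs: int) -> float:
    # Tx, Ty are permutation-invariant, so |C - D| orders tau identically.
    n = x.size
    iu = np.triu_indices(n, k=1)
    sx = np.sign(x[:, None] - x[None, :])[iu]
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        yp = y[list(perm)]
        sy = np.sign(yp[:, None] - yp[None, :])[iu]
        s = int(np.sum(sx * sy))
        if abs(s) >= abs(s_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# Binomial GLM via IRLS
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GLMFit:
    """A fitted binomial (logit-link) GLM."""

    names: tuple[str, ...]
    coefficients: np.ndarray
    deviance: float
    log_likelihood: float
    converged: bool
    n_iter: int
    n: int
    separation_flag: bool

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])


def _design_matrix(
    design, names: Sequence[str] | None, add_intercept: bool
) -> tuple[np.ndarray, tuple[str, ...]]:
    if hasattr(design, "columns"):  # DataFrame
        cols = tuple(str(c) for c in design.columns)
        X = np.asarray(design, dtype=float)
    else:
        X = np.atleast_2d(np.asarray(design, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1 and names and len(names) == 1:
            X = X.T
        cols = tuple(names) if names else tuple(f"x{i}" for i in range(X.shape[1]))
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        cols = ("intercept",) + cols
    return X, cols


def _check_rank(X: np.ndarray, names: tuple[str, ...]) -> None:
    # pinpoint aliased columns via the QR diagonal
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.size else 0.0
    bad = [names[j] for j in range(len(names)) if diag[j] < 1e-10 * max(scale, 1.0)]
    if bad:
        raise ValueError(f"design is rank-deficient; aliased column(s): {', '.join(bad)}")


def fit_binomial_glm(
    design,
    outcome: Sequence[int],
    *,
    names: Sequence[str] | None = None,
    add_intercept: bool = True,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    dev_tol: float = 1e-10,
) -> GLMFit:
    """Maximum-likelihood logistic regression by IRLS.

    Converged when the score (gradient) max-norm falls below
    ``score_tol`` or the relative deviance change below ``dev_tol``.
    Step-halving guards the rare non-increasing update.  Coefficients
    with |beta| > 30 trigger a complete-separation warning and flag.
    """
    y = np.asarray(outcome, dtype=float)
    X, cols = _design_matrix(design, names, add_intercept)
    n, p = X.shape
    if n != y.size:
        raise ValueError("design and outcome lengths differ")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("outcome must be binary 0/1")
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    _check_rank(X, cols)

    beta = np.zeros(p)
    ll = _bernoulli_ll(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = _special.expit(eta)
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        w = np.clip(w, 1e-10, None)
        # solve (X'WX) delta = score
        xw = X * w[:, None]
        try:
            delta = np.linalg.solve(X.T @ xw, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(X.T @ xw, score, rcond=None)[0]
        step = 1.0
        for _ in range(30):  # step-halving: never decrease the likelihood
            cand = beta + step * delta
            ll_new = _bernoulli_ll(X, y, cand)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta = beta + step * delta
        if ll != 0 and abs(ll_new - ll) < dev_tol * abs(ll):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    ll = _bernoulli_ll(X, y, beta)
    separation = bool(np.any(np.abs(beta) > 30))
    if separation:
        _warnings.warn(
            "possible complete separation: |coefficient| > 30", SeparationWarning
        )
    return GLMFit(
        names=cols,
        coefficients=beta,
        deviance=float(-2.0 * ll),
        log_likelihood=float(ll),
        converged=converged,
        n_iter=it,
        n=n,
        separation_flag=separation,
    )


def _bernoulli_ll(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log L = sum y*eta - log(1 + e^eta), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def lrt_term(full: GLMFit, reduced: GLMFit) -> tuple[float, int, float]:
    """Likelihood-ratio (deviance) chi-square test of nested GLMs.

    Returns (chi2, df, p) with chi2 = deviance(reduced) - deviance(full)
    and df the difference in parameter counts.
    """
    if not set(reduced.names) <= set(full.names):
        extra = set(reduced.names) - set(full.names)
        raise ValueError(f"models are not nested: reduced has extra term(s) {extra}")
    df = len(full.names) - len(reduced.names)
    if df <= 0:
        # identical models: chi2 = 0, p = 1 by convention
        df = 0
    chi2 = reduced.deviance - full.deviance
    if chi2 < -1e-8:
        raise ValueError(
            f"negative LRT chi-square ({chi2:.3g}): reduced fit beats full fit"
        )
    chi2 = max(chi2, 0.0)
    p = 1.0 if df == 0 else float(_stats.chi2.sf(chi2, df))
    return float(chi2), df, p


# ---------------------------------------------------------------------------
# Full coarse-scale analysis
# ---------------------------------------------------------------------------

_TAU_PAIRS = (
    ("prop_zone1", "total_raps"),
    ("prop_zone1", "mean_raps_per_bout"),
    ("prop_zone2", "total_raps"),
    ("prop_zone2", "mean_raps_per_bout"),
)


@dataclass
class CoarseFit:
    """One pass of the coarse analysis (with or without flagged fights)."""

    glm: GLMFit
    lrt: dict[str, tuple[float, int, float]]
    taus: dict[str, TauResult | None]
    n: int
    excluded_fight_ids: tuple[str, ...]

    def to_json_dict(self) -> dict:
        out: dict = {"n": self.n, "excluded_fight_ids": list(self.excluded_fight_ids)}
        out["glm"] = {
            name: {
                "estimate_mean": float(b),
                "estimate_sd": None,
                "ci_low": None,
                "ci_high": None,
                "p": None,
            }
            for name, b in zip(self.glm.names, self.glm.coefficients)
        }
        for term, (chi2, df, p) in self.lrt.items():
            out["glm"][term]["p"] = p
            out["glm"][term]["lrt_chi2"] = chi2
            out["glm"][term]["lrt_df"] = df
        out["tau"] = {
            key: (
                None
                if res is None
                else {"estimate_mean": res.tau, "p": res.p, "n": res.n}
            )
            for key, res in self.taus.items()
        }
        return out


@dataclass
class CoarseResult:
    """Coarse analysis reported both with and without outlier-flagged fights."""

    with_outliers: CoarseFit
    without_outliers: CoarseFit
    n_flagged: int
    flagged_fight_ids: tuple[str, ...] = field(default_factory=tuple)

    def to_json_dict(self) -> dict:
        return {
            "with_outliers": self.with_outliers.to_json_dict(),
            "without_outliers": self.without_outliers.to_json_dict(),
            "n_flagged": self.n_flagged,
            "flagged_fight_ids": list(self.flagged_fight_ids),
        }


def _coarse_fit(
    fights: Sequence[FightRecord],
    summaries: Mapping[str, ZoneSummary],
    keep: np.ndarray,
    excluded: tuple[str, ...],
) -> CoarseFit:
    kept = [f for f, k in zip(fights, keep) if k]
    pz1 = np.array([summaries[f.fight_id].prop_zone1 for f in kept])
    pz2 = np.array([summaries[f.fight_id].prop_zone2 for f in kept])
    rwd = np.array([f.rwd for f in kept])
    y = np.array([f.outcome_code for f in kept])
    total_raps = np.array([float(f.total_raps) for f in kept])
    raps_per_bout = np.array([f.mean_raps_per_bout for f in kept])

    X = np.column_stack([pz1, pz2, pz1 * pz2, rwd])
    term_names = ("prop_zone1", "prop_zone2", "prop_zone1:prop_zone2", "rwd")
    full = fit_binomial_glm(X, y, names=term_names)
    lrt: dict[str, tuple[float, int, float]] = {}
    for j, term in enumerate(term_names):
        Xr = np.delete(X, j, axis=1)
        red = fit_binomial_glm(
            Xr, y, names=tuple(t for t in term_names if t != term)
        )
        lrt[term] = lrt_term(full, red)

    temporal = {"total_raps": total_raps, "mean_raps_per_bout": raps_per_bout}
    spatial = {"prop_zone1": pz1, "prop_zone2": pz2}
    taus: dict[str, TauResult | None] = {}
    for sname, tname in _TAU_PAIRS:
        key = f"{sname}~{tname}"
        try:
            taus[key] = kendall_tau_b(spatial[sname], temporal[tname])
        except ValueError:
            taus[key] = None  # undefined (all-ties); surfaced as missing
    return CoarseFit(glm=full, lrt=lrt, taus=taus, n=len(kept), excluded_fight_ids=excluded)


def run_coarse_analysis(
    fights: Sequence[FightRecord],
    zone_summaries: Sequence[ZoneSummary],
    outlier_flags: Sequence[bool] | None = None,
) -> CoarseResult:
    """GLM of eviction on zone proportions plus the four tau correlations.

    Only fights with at least one POI (i.e. with a zone summary) enter.
    ``outlier_flags`` aligns with the POI-bearing fights in input order;
    the analysis is run twice, keeping and dropping flagged fights.
    """
    summaries = {s.fight_id: s for s in zone_summaries}
    usable = [f for f in fights if f.fight_id in summaries]
    if outlier_flags is None:
        flags = np.zeros(len(usable), dtype=bool)
    else:
        flags = np.asarray(outlier_flags, dtype=bool)
        if flags.size != len(usable):
            raise ValueError(
                f"outlier_flags length {flags.size} != {len(usable)} POI-bearing fights"
            )
    all_keep = np.ones(len(usable), dtype=bool)
    flagged_ids = tuple(f.fight_id for f, fl in zip(usable, flags) if fl)
    fit_with = _coarse_fit(usable, summaries, all_keep, ())
    if flags.any():
        fit_without = _coarse_fit(usable, summaries, ~flags, flagged_ids)
    else:
        fit_without = fit_with
    return CoarseResult(
        with_outliers=fit_with,
        without_outliers=fit_without,
        n_flagged=int(flags.sum()),
        flagged_fight_ids=flagged_ids,
    )
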