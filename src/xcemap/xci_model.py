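"""Hierarchical Bayesian beta model of allele-specific X-inactivation.

The measured quantity is the fraction of X-linked expression attributable
to one parental X. All modeling happens on a single canonical scale: the
fraction attributable to a designated *focal* strain's active X (the strain
whose Xce allele is in question). For a measurement y_ij in gene-tissue
combination j of mouse i belonging to F1 cross c(i) (reciprocal crosses are
distinct), the generative model is

    p_i   ~ Beta(mean = mu_c(i),  precision = theta_c(i))
    y_ij  ~ Beta(mean = m_ij,     precision = tau_j * lambda_c(i))
    logit(m_ij) = logit(p_i) + beta_j

where the Beta(mean m, precision t) parameterization has shapes
(m*t, (1-m)*t), so the variance is m(1-m)/(t+1). mu_c is the cross-level
mean inactivation proportion; theta_c the between-mouse precision; p_i the
latent per-mouse proportion; beta_j / tau_j the bias and precision of the
gene-tissue assay; lambda_c a cross-specific multiplier on measurement
precision.

Inference is by adaptive random-walk Metropolis-within-Gibbs on transformed
(logit/log) parameters, with weakly informative hierarchical priors; see
``PriorConfig``. Posterior tail probabilities of mu_c against the 0.5 line
drive the Xce allele calls: when essentially all posterior mass for a cross
sits on one side of 0.5 the two parental strains carry functionally
different alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import betaln, expit, logit

from .io_tables import RunConfig, XCIMeasurement, XCE_SERIES_ORDER

__all__ = [
    "PriorConfig",
    "CrossPosterior",
    "AlleleCall",
    "XCIPosterior",
    "canonical_fraction",
    "beta_shapes",
    "fit_mcmc",
    "posterior_summary",
    "tail_probability",
    "call_allele",
]


def canonical_fraction(
    measurement: XCIMeasurement, focal: str, count_policy: str = "jeffreys"
) -> float:
    """Expression fraction attributed to the focal strain's X.

    If the focal strain is the dam this is the maternal fraction; if the
    sire, its complement.
    """
    frac = measurement.fraction(count_policy)
    if focal == measurement.dam:
        return frac
    if focal == measurement.sire:
        return 1.0 - frac
    raise ValueError(
        f"focal strain {focal!r} is not a parent of cross "
        f"{measurement.dam} x {measurement.sire}"
    )


def beta_shapes(mean: float, precision: float) -> tuple[float, float]:
    """Shape pair (alpha, beta) of a Beta with given mean and precision.

    alpha = mean * precision, beta = (1 - mean) * precision; the variance is
    mean(1-mean)/(precision+1).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean {mean} must be strictly inside (0, 1)")
    if precision <= 0.0:
        raise ValueError(f"precision {precision} must be positive")
    return mean * precision, (1.0 - mean) * precision


@dataclass
class PriorConfig:
    """Weakly informative hierarchical priors (transformed scales).

    logit(mu_c) ~ N(0, mu_logit_sd^2)
    log(theta_c) ~ N(m_theta, s_theta^2); m_theta ~ N(log 30, 1),
        s_theta ~ half-N(theta_log_sd_scale)
    beta_j ~ N(0, s_beta^2); s_beta ~ half-N(beta_sd_scale)
    log(tau_j) ~ N(m_tau, s_tau^2); m_tau ~ N(log 30, 1),
        s_tau ~ half-N(tau_log_sd_scale)
    log(lambda_c) ~ N(0, lambda_log_sd^2)
    """

    mu_logit_sd: float = 1.5
    theta_log_mean_loc: float = math.log(30.0)
    theta_log_mean_sd: float = 1.0
    theta_log_sd_scale: float = 1.0
    beta_sd_scale: float = 0.5
    tau_log_mean_loc: float = math.log(30.0)
    tau_log_mean_sd: float = 1.0
    tau_log_sd_scale: float = 1.0
    lambda_log_sd: float = 0.5


@dataclass
class CrossPosterior:
    """Posterior summary for one cross's mean inactivation proportion."""

    cross: tuple[str, str]
    mean: float
    median: float
    ci95: tuple[float, float]
    rhat: float
    ess: float
    n_mice: int
    n_measurements: int
    tail_prob: float
    weakly_identified: bool = False


@dataclass
class AlleleCall:
    """Outcome of testing a focal strain against known-allele partners."""

    focal: str
    tail_probs: dict[str, float]      # partner allele -> max tail prob over crosses
    directions: dict[str, str]        # partner allele -> "stronger" | "weaker" (focal vs partner)
    excluded: list[str]
    included: list[str]
    call: str                         # allele name, "new_between_x_y", "new_below_x", "new_above_x", "ambiguous"
    note: str = ""


# ---------------------------------------------------------------------------
# sampler internals


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _beta_logpdf_mp(y_log: np.ndarray, y_log1m: np.ndarray,
                    m: np.ndarray, prec: np.ndarray) -> np.ndarray:
    """Beta log-density in mean/precision form given precomputed log y terms."""
    a = m * prec
    b = (1.0 - m) * prec
    return (a - 1.0) * y_log + (b - 1.0) * y_log1m - betaln(a, b)


@dataclass
class _Design:
    y: np.ndarray
    y_log: np.ndarray
    y_log1m: np.ndarray
    mouse_of_obs: np.ndarray
    gt_of_obs: np.ndarray
    cross_of_obs: np.ndarray
    cross_of_mouse: np.ndarray
    n_obs: int
    n_mice: int
    n_gt: int
    n_cross: int


class _State:
    """Mutable chain state on transformed scales."""

    __slots__ = ("eta", "t", "l", "q", "b", "u", "m_th", "s_th", "s_b", "m_ta", "s_ta")

    def __init__(self, d: _Design, priors: PriorConfig, y_mouse_mean: np.ndarray,
                 y_cross_mean: np.ndarray):
        eps = 1e-3
        self.q = logit(np.clip(y_mouse_mean, eps, 1 - eps))
        self.eta = logit(np.clip(y_cross_mean, eps, 1 - eps))
        self.t = np.full(d.n_cross, priors.theta_log_mean_loc)
        self.l = np.zeros(d.n_cross)
        self.b = np.zeros(d.n_gt)
        self.u = np.full(d.n_gt, priors.tau_log_mean_loc)
        self.m_th = priors.theta_log_mean_loc
        self.s_th = 0.5
        self.s_b = 0.25
        self.m_ta = priors.tau_log_mean_loc
        self.s_ta = 0.5


def _obs_loglik(d: _Design, q: np.ndarray, b: np.ndarray,
                u: np.ndarray, l: np.ndarray) -> np.ndarray:
    m = expit(q[d.mouse_of_obs] + b[d.gt_of_obs])
    prec = np.exp(u[d.gt_of_obs] + l[d.cross_of_obs])
    with np.errstate(all="ignore"):
        ll = _beta_logpdf_mp(d.y_log, d.y_log1m, m, prec)
    return np.nan_to_num(ll, nan=-np.inf, posinf=-np.inf, neginf=-np.inf)


def _p_prior_loglik(d: _Design, q: np.ndarray, eta: np.ndarray,
                    t: np.ndarray) -> np.ndarray:
    """log density of q_i = logit(p_i) under the Beta cross prior (with Jacobian)."""
    mu = expit(eta[d.cross_of_mouse])
    th = np.exp(t[d.cross_of_mouse])
    a = mu * th
    b = (1.0 - mu) * th
    log_p = -_softplus(-q)
    log_1mp = -_softplus(q)
    with np.errstate(all="ignore"):
        lp = a * log_p + b * log_1mp - betaln(a, b)  # (a-1)logp+(b-1)log1mp + Jacobian(logp+log1mp)
    return np.nan_to_num(lp, nan=-np.inf, posinf=-np.inf, neginf=-np.inf)


def _mh_accept(rng: np.random.Generator, delta: np.ndarray) -> np.ndarray:
    return np.log(rng.random(delta.shape)) < delta


_ADAPT_TARGET = 0.44
_BOUND = 25.0  # reject proposals beyond this on any transformed scale


def _adapt(ls: np.ndarray, accepted: np.ndarray, it: int, adapting: bool) -> None:
    if not adapting:
        return
    gamma = min(0.25, 2.0 / math.sqrt(it + 1.0))
    ls += gamma * (accepted.astype(float) - _ADAPT_TARGET)
    np.clip(ls, -8.0, 4.0, out=ls)


def _run_chain(d: _Design, cfg: RunConfig, priors: PriorConfig,
               rng: np.random.Generator) -> dict[str, np.ndarray]:
    y_mouse_mean = np.bincount(d.mouse_of_obs, weights=d.y, minlength=d.n_mice) / \
        np.bincount(d.mouse_of_obs, minlength=d.n_mice)
    y_cross_mean = np.bincount(d.cross_of_mouse, weights=y_mouse_mean,
                               minlength=d.n_cross) / \
        np.bincount(d.cross_of_mouse, minlength=d.n_cross)
    st = _State(d, priors, y_mouse_mean, y_cross_mean)

    ls_q = np.full(d.n_mice, math.log(0.5))
    ls_b = np.full(d.n_gt, math.log(0.3))
    ls_u = np.full(d.n_gt, math.log(0.4))
    ls_eta = np.full(d.n_cross, math.log(0.3))
    ls_t = np.full(d.n_cross, math.log(0.4))
    ls_l = np.full(d.n_cross, math.log(0.4))
    ls_sc = {"s_th": math.log(0.4), "s_b": math.log(0.4), "s_ta": math.log(0.4)}

    n_keep = cfg.iterations - cfg.burn_in
    out = {
        "mu": np.empty((n_keep, d.n_cross)),
        "theta": np.empty((n_keep, d.n_cross)),
        "lambda": np.empty((n_keep, d.n_cross)),
        "p": np.empty((n_keep, d.n_mice)),
        "beta": np.empty((n_keep, d.n_gt)),
        "tau": np.empty((n_keep, d.n_gt)),
    }

    obs_ll = _obs_loglik(d, st.q, st.b, st.u, st.l)
    p_lp = _p_prior_loglik(d, st.q, st.eta, st.t)

    for it in range(cfg.iterations):
        adapting = it < cfg.burn_in

        # -- latent per-mouse proportions q_i (elementwise, conditionally independent)
        prop_q = st.q + np.exp(ls_q) * rng.standard_normal(d.n_mice)
        np.clip(prop_q, -_BOUND, _BOUND, out=prop_q)
        new_obs = _obs_loglik(d, prop_q, st.b, st.u, st.l)
        new_plp = _p_prior_loglik(d, prop_q, st.eta, st.t)
        delta = (
            np.bincount(d.mouse_of_obs, weights=new_obs - obs_ll, minlength=d.n_mice)
            + new_plp - p_lp
        )
        acc = _mh_accept(rng, delta)
        st.q = np.where(acc, prop_q, st.q)
        obs_ll = np.where(acc[d.mouse_of_obs], new_obs, obs_ll)
        p_lp = np.where(acc, new_plp, p_lp)
        _adapt(ls_q, acc, it, adapting)

        # -- gene-tissue biases beta_j
        prop_b = st.b + np.exp(ls_b) * rng.standard_normal(d.n_gt)
        np.clip(prop_b, -_BOUND, _BOUND, out=prop_b)
        new_obs = _obs_loglik(d, st.q, prop_b, st.u, st.l)
        delta = (
            np.bincount(d.gt_of_obs, weights=new_obs - obs_ll, minlength=d.n_gt)
            + (st.b**2 - prop_b**2) / (2.0 * st.s_b**2)
        )
        acc = _mh_accept(rng, delta)
        st.b = np.where(acc, prop_b, st.b)
        obs_ll = np.where(acc[d.gt_of_obs], new_obs, obs_ll)
        _adapt(ls_b, acc, it, adapting)

        # -- gene-tissue log precisions u_j
        prop_u = st.u + np.exp(ls_u) * rng.standard_normal(d.n_gt)
        np.clip(prop_u, -_BOUND, _BOUND, out=prop_u)
        new_obs = _obs_loglik(d, st.q, st.b, prop_u, st.l)
        delta = (
            np.bincount(d.gt_of_obs, weights=new_obs - obs_ll, minlength=d.n_gt)
            + ((st.u - st.m_ta) ** 2 - (prop_u - st.m_ta) ** 2) / (2.0 * st.s_ta**2)
        )
        acc = _mh_accept(rng, delta)
        st.u = np.where(acc, prop_u, st.u)
        obs_ll = np.where(acc[d.gt_of_obs], new_obs, obs_ll)
        _adapt(ls_u, acc, it, adapting)

        # -- cross means eta_c = logit(mu_c)
        prop_eta = st.eta + np.exp(ls_eta) * rng.standard_normal(d.n_cross)
        np.clip(prop_eta, -_BOUND, _BOUND, out=prop_eta)
        new_plp = _p_prior_loglik(d, st.q, prop_eta, st.t)
        delta = (
            np.bincount(d.cross_of_mouse, weights=new_plp - p_lp, minlength=d.n_cross)
            + (st.eta**2 - prop_eta**2) / (2.0 * priors.mu_logit_sd**2)
        )
        acc = _mh_accept(rng, delta)
        st.eta = np.where(acc, prop_eta, st.eta)
        p_lp = np.where(acc[d.cross_of_mouse], new_plp, p_lp)
        _adapt(ls_eta, acc, it, adapting)

        # -- cross precisions t_c = log(theta_c)
        prop_t = st.t + np.exp(ls_t) * rng.standard_normal(d.n_cross)
        np.clip(prop_t, -_BOUND, 12.0, out=prop_t)
        new_plp = _p_prior_loglik(d, st.q, st.eta, prop_t)
        delta = (
            np.bincount(d.cross_of_mouse, weights=new_plp - p_lp, minlength=d.n_cross)
            + ((st.t - st.m_th) ** 2 - (prop_t - st.m_th) ** 2) / (2.0 * st.s_th**2)
        )
        acc = _mh_accept(rng, delta)
        st.t = np.where(acc, prop_t, st.t)
        p_lp = np.where(acc[d.cross_of_mouse], new_plp, p_lp)
        _adapt(ls_t, acc, it, adapting)

        # -- cross measurement-precision multipliers l_c = log(lambda_c)
        prop_l = st.l + np.exp(ls_l) * rng.standard_normal(d.n_cross)
        np.clip(prop_l, -_BOUND, 12.0, out=prop_l)
        new_obs = _obs_loglik(d, st.q, st.b, st.u, prop_l)
        delta = (
            np.bincount(d.cross_of_obs, weights=new_obs - obs_ll, minlength=d.n_cross)
            + (st.l**2 - prop_l**2) / (2.0 * priors.lambda_log_sd**2)
        )
        acc = _mh_accept(rng, delta)
        st.l = np.where(acc, prop_l, st.l)
        obs_ll = np.where(acc[d.cross_of_obs], new_obs, obs_ll)
        _adapt(ls_l, acc, it, adapting)

        # -- hyperparameters
        # m_theta | t: conjugate normal
        prec0 = 1.0 / priors.theta_log_mean_sd**2
        precl = d.n_cross / st.s_th**2
        post_var = 1.0 / (prec0 + precl)
        post_mean = post_var * (priors.theta_log_mean_loc * prec0 + st.t.sum() / st.s_th**2)
        st.m_th = post_mean + math.sqrt(post_var) * rng.standard_normal()
        # m_tau | u
        precl = d.n_gt / st.s_ta**2
        post_var = 1.0 / (prec0 + precl)
        post_mean = post_var * (priors.tau_log_mean_loc * prec0 + st.u.sum() / st.s_ta**2)
        st.m_ta = post_mean + math.sqrt(post_var) * rng.standard_normal()

        def scale_update(name: str, cur: float, data_ss: float, n: int, hn_scale: float) -> float:
            x = math.log(cur)
            xp = x + math.exp(ls_sc[name]) * rng.standard_normal()
            xp = max(min(xp, 6.0), -8.0)
            sp = math.exp(xp)

            def logpost(s: float, lx: float) -> float:
                return (-s**2 / (2.0 * hn_scale**2) + lx   # half-normal prior + Jacobian
                        - n * lx - data_ss / (2.0 * s**2))

            dlt = logpost(sp, xp) - logpost(cur, x)
            ok = math.log(rng.random()) < dlt
            _adapt_scalar(ls_sc, name, ok, it, adapting)
            return sp if ok else cur

        st.s_th = scale_update("s_th", st.s_th, float(((st.t - st.m_th) ** 2).sum()),
                               d.n_cross, priors.theta_log_sd_scale)
        st.s_ta = scale_update("s_ta", st.s_ta, float(((st.u - st.m_ta) ** 2).sum()),
                               d.n_gt, priors.tau_log_sd_scale)
        st.s_b = scale_update("s_b", st.s_b, float((st.b**2).sum()),
                              d.n_gt, priors.beta_sd_scale)

        if it >= cfg.burn_in:
            k = it - cfg.burn_in
            out["mu"][k] = expit(st.eta)
            out["theta"][k] = np.exp(st.t)
            out["lambda"][k] = np.exp(st.l)
            out["p"][k] = expit(st.q)
            out["beta"][k] = st.b
            out["tau"][k] = np.exp(st.u)
    return out


def _adapt_scalar(ls: dict, name: str, accepted: bool, it: int, adapting: bool) -> None:
    if not adapting:
        return
    gamma = min(0.25, 2.0 / math.sqrt(it + 1.0))
    ls[name] = float(np.clip(ls[name] + gamma * (float(accepted) - _ADAPT_TARGET), -8.0, 4.0))


# ---------------------------------------------------------------------------
# public fitting interface


class XCIPosterior:
    """MCMC output: per-chain draws plus index labels.

    Arrays are shaped (n_chains, n_draws, dim). ``crosses`` orders the mu /
    theta / lambda axes, ``mouse_ids`` the p axis and ``gt_labels`` the
    beta / tau axes.
    """

    def __init__(self, chains: dict[str, np.ndarray], crosses: list[tuple[str, str]],
                 mouse_ids: list[str], gt_labels: list[tuple[str, str]],
                 focal_of_cross: dict[tuple[str, str], str],
                 n_mice_of_cross: dict[tuple[str, str], int],
                 n_meas_of_cross: dict[tuple[str, str], int],
                 weakly_identified: set[tuple[str, str]]):
        self.chains = chains
        self.crosses = crosses
        self.mouse_ids = mouse_ids
        self.gt_labels = gt_labels
        self.focal_of_cross = focal_of_cross
        self.n_mice_of_cross = n_mice_of_cross
        self.n_meas_of_cross = n_meas_of_cross
        self.weakly_identified = weakly_identified

    def _cross_index(self, cross: tuple[str, str]) -> int:
        try:
            return self.crosses.index(tuple(cross))
        except ValueError:
            raise KeyError(f"cross {cross} absent from posterior") from None

    def mu_samples(self, cross: tuple[str, str], pooled: bool = True) -> np.ndarray:
        c = self._cross_index(cross)
        draws = self.chains["mu"][:, :, c]
        return draws.reshape(-1) if pooled else draws

    def p_samples(self, mouse_id: str) -> np.ndarray:
        i = self.mouse_ids.index(mouse_id)
        return self.chains["p"][:, :, i].reshape(-1)

    def beta_samples(self, gt: tuple[str, str]) -> np.ndarray:
        j = self.gt_labels.index(tuple(gt))
        return self.chains["beta"][:, :, j].reshape(-1)

    def rhat(self, cross: tuple[str, str]) -> float:
        import arviz as az

        draws = self.mu_samples(cross, pooled=False)
        if draws.shape[0] < 2:
            return float("nan")
        return float(az.rhat(az.convert_to_dataset(draws[:, :, None]))["x"].values[0])

    def ess(self, cross: tuple[str, str]) -> float:
        import arviz as az

        draws = self.mu_samples(cross, pooled=False)
        return float(az.ess(az.convert_to_dataset(draws[:, :, None]))["x"].values[0])

    def rhat_max(self) -> float:
        vals = [self.rhat(c) for c in self.crosses]
        vals = [v for v in vals if not math.isnan(v)]
        return max(vals) if vals else float("nan")

    def convergence_warning(self, threshold: float = 1.05) -> bool:
        r = self.rhat_max()
        return (not math.isnan(r)) and r > threshold

    def summary_frame(self, alpha_share: float = 0.05):
        import pandas as pd

        rows = []
        for cross in self.crosses:
            s = posterior_summary(self, cross)
            rows.append(
                {
                    "cross": f"{cross[0]}x{cross[1]}",
                    "focal": self.focal_of_cross[cross],
                    "n_mice": s.n_mice,
                    "n_measurements": s.n_measurements,
                    "post_mean": s.mean,
                    "post_median": s.median,
                    "ci95_lo": s.ci95[0],
                    "ci95_hi": s.ci95[1],
                    "tail_prob": s.tail_prob,
                    "rhat": s.rhat,
                    "weakly_identified": s.weakly_identified,
                }
            )
        return pd.DataFrame(rows)


def fit_mcmc(
    measurements: Sequence[XCIMeasurement],
    focal_of_cross: Mapping[tuple[str, str], str] | None = None,
    config: RunConfig | None = None,
    priors: PriorConfig | None = None,
) -> XCIPosterior:
    """Fit the hierarchical beta model by MCMC.

    ``focal_of_cross`` maps each (dam, sire) cross to the strain whose
    active-X fraction defines the canonical scale for that cross; by default
    the dam (so the canonical fraction is the maternal fraction). Fractions
    are clamped to [eps, 1-eps] before likelihood evaluation. The run is
    reproducible bit-for-bit given (seed, chains, iterations).
    """
    if not measurements:
        raise ValueError("no measurements supplied")
    cfg = config or RunConfig()
    priors = priors or PriorConfig()

    crosses = sorted({m.cross for m in measurements})
    focal = {c: c[0] for c in crosses}
    if focal_of_cross:
        for c, f in focal_of_cross.items():
            c = tuple(c)
            if c in focal:
                if f not in c:
                    raise ValueError(f"focal {f!r} is not a parent of cross {c}")
                focal[c] = f
    mouse_ids = sorted({m.mouse_id for m in measurements})
    gt_labels = sorted({(m.gene, m.tissue) for m in measurements})
    cross_idx = {c: k for k, c in enumerate(crosses)}
    mouse_idx = {m: k for k, m in enumerate(mouse_ids)}
    gt_idx = {g: k for k, g in enumerate(gt_labels)}

    cross_of_mouse = np.empty(len(mouse_ids), dtype=np.intp)
    seen: dict[str, tuple[str, str]] = {}
    for m in measurements:
        prev = seen.get(m.mouse_id)
        if prev is not None and prev != m.cross:
            raise ValueError(f"mouse {m.mouse_id!r} appears in two crosses")
        seen[m.mouse_id] = m.cross
        cross_of_mouse[mouse_idx[m.mouse_id]] = cross_idx[m.cross]

    y = np.array(
        [canonical_fraction(m, focal[m.cross], cfg.count_policy) for m in measurements]
    )
    y = np.clip(y, cfg.epsilon, 1.0 - cfg.epsilon)
    mouse_of_obs = np.array([mouse_idx[m.mouse_id] for m in measurements], dtype=np.intp)
    gt_of_obs = np.array([gt_idx[(m.gene, m.tissue)] for m in measurements], dtype=np.intp)
    cross_of_obs = cross_of_mouse[mouse_of_obs]

    d = _Design(
        y=y,
        y_log=np.log(y),
        y_log1m=np.log1p(-y),
        mouse_of_obs=mouse_of_obs,
        gt_of_obs=gt_of_obs,
        cross_of_obs=cross_of_obs,
        cross_of_mouse=cross_of_mouse,
        n_obs=len(y),
        n_mice=len(mouse_ids),
        n_gt=len(gt_labels),
        n_cross=len(crosses),
    )

    chain_out: dict[str, list[np.ndarray]] = {
        k: [] for k in ("mu", "theta", "lambda", "p", "beta", "tau")
    }
    for chain in range(cfg.chains):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([cfg.seed, chain])))
        res = _run_chain(d, cfg, priors, rng)
        for k in chain_out:
            chain_out[k].append(res[k])
    chains = {k: np.stack(v) for k, v in chain_out.items()}

    n_mice_of_cross = {
        c: int((cross_of_mouse == cross_idx[c]).sum()) for c in crosses
    }
    n_meas_of_cross = {
        c: int((cross_of_obs == cross_idx[c]).sum()) for c in crosses
    }
    weak = {
        c for c in crosses
        if n_mice_of_cross[c] == 1 and n_meas_of_cross[c] == 1
    }
    return XCIPosterior(
        chains, crosses, mouse_ids, gt_labels, focal,
        n_mice_of_cross, n_meas_of_cross, weak,
    )


def posterior_summary(posterior: XCIPosterior, cross: tuple[str, str]) -> CrossPosterior:
    """Mean, median and equal-tailed 95% interval of mu_c from pooled draws."""
    cross = tuple(cross)
    samples = posterior.mu_samples(cross)
    lo, hi = np.quantile(samples, [0.025, 0.975])
    return CrossPosterior(
        cross=cross,
        mean=float(samples.mean()),
        median=float(np.median(samples)),
        ci95=(float(lo), float(hi)),
        rhat=posterior.rhat(cross),
        ess=posterior.ess(cross),
        n_mice=posterior.n_mice_of_cross[cross],
        n_measurements=posterior.n_meas_of_cross[cross],
        tail_prob=tail_probability(posterior, cross),
        weakly_identified=cross in posterior.weakly_identified,
    )


def tail_probability(
    posterior: XCIPosterior, cross: tuple[str, str], boundary: float = 0.5
) -> float:
    """Posterior mass on the lighter side of the boundary.

    min(P(mu_c < b), P(mu_c > b)), with draws exactly at the boundary split
    evenly between the sides.
    """
    samples = posterior.mu_samples(tuple(cross))
    below = float(np.mean(samples < boundary) + 0.5 * np.mean(samples == boundary))
    return min(below, 1.0 - below)


def call_allele(
    posterior: XCIPosterior,
    focal: str,
    partner_alleles: Mapping[tuple[str, str], str],
    series: Sequence[str] = XCE_SERIES_ORDER,
    alpha_share: float = 0.05,
) -> AlleleCall:
    """Call the focal strain's Xce allele from crosses to known partners.

    ``partner_alleles`` maps each tested cross (dam, sire) to the partner's
    known allele. A partner allele is excluded when every cross against it
    has tail probability below ``alpha_share`` (clear skew away from 0.5),
    with the direction recorded: focal stronger when the posterior mean of
    the focal-active fraction exceeds 0.5. A single surviving allele is the
    call; exclusion of all partners with a series-consistent direction
    pattern declares a new allele at the implied position; anything else is
    ambiguous.
    """
    if len(set(partner_alleles.values())) < 2:
        raise ValueError("need crosses against >= 2 distinct known partner alleles")
    per_allele: dict[str, list[tuple[float, str]]] = {}
    for cross, allele in partner_alleles.items():
        cross = tuple(cross)
        if posterior.focal_of_cross.get(cross) != focal:
            raise ValueError(
                f"posterior for cross {cross} is not on the focal scale of {focal!r}"
            )
        tp = tail_probability(posterior, cross)
        mean = float(posterior.mu_samples(cross).mean())
        per_allele.setdefault(allele, []).append(
            (tp, "stronger" if mean > 0.5 else "weaker")
        )

    tail_probs: dict[str, float] = {}
    directions: dict[str, str] = {}
    excluded: list[str] = []
    included: list[str] = []
    contradictory = False
    for allele, results in per_allele.items():
        tail_probs[allele] = max(tp for tp, _ in results)
        dirs = {dr for _, dr in results}
        directions[allele] = dirs.pop() if len(dirs) == 1 else "conflict"
        if tail_probs[allele] < alpha_share:
            if directions[allele] == "conflict":
                contradictory = True
            excluded.append(allele)
        else:
            included.append(allele)
    order = {a: k for k, a in enumerate(series)}
    excluded.sort(key=lambda a: order.get(a, len(series)))
    included.sort(key=lambda a: order.get(a, len(series)))

    note = ""
    if contradictory:
        call = "ambiguous"
        note = "replicate crosses against one allele disagree in direction"
    elif len(included) == 1:
        call = included[0]
        # sanity: excluded directions must respect the series around the call
        if not _directions_consistent(excluded, directions, series, pivot=included[0]):
            call = "ambiguous"
            note = "exclusion directions contradict the allelic series"
    elif len(included) == 0:
        call, note = _position_new_allele(excluded, directions, series)
    else:
        call = "ambiguous"
        note = f"multiple alleles not excluded: {included}"
    return AlleleCall(
        focal=focal,
        tail_probs=tail_probs,
        directions=directions,
        excluded=excluded,
        included=included,
        call=call,
        note=note,
    )


def _directions_consistent(
    excluded: Sequence[str], directions: Mapping[str, str],
    series: Sequence[str], pivot: str,
) -> bool:
    order = {a: k for k, a in enumerate(series)}
    if pivot not in order:
        return True
    for a in excluded:
        if a not in order:
            continue
        if directions[a] == "stronger" and order[a] > order[pivot]:
            return False  # focal beat an allele above its own position
        if directions[a] == "weaker" and order[a] < order[pivot]:
            return False
    return True


def _position_new_allele(
    excluded: Sequence[str], directions: Mapping[str, str], series: Sequence[str]
) -> tuple[str, str]:
    order = {a: k for k, a in enumerate(series)}
    weaker_partners = [a for a in excluded if directions[a] == "stronger" and a in order]
    stronger_partners = [a for a in excluded if directions[a] == "weaker" and a in order]
    lo = max(weaker_partners, key=order.get, default=None)   # strongest allele the focal beats
    hi = min(stronger_partners, key=order.get, default=None)  # weakest allele beating the focal
    if lo is not None and hi is not None:
        if order[lo] < order[hi]:
            return f"new_between_{lo}_{hi}", ""
        return "ambiguous", "direction pattern violates series transitivity"
    if lo is not None:
        return f"new_above_{lo}", ""
    if hi is not None:
        return f"new_below_{hi}", ""
    return "ambiguous", "no series-ordered partner informs the position"
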