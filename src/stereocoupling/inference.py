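"""Bayesian fitting of the logistic psychometric model.

The model for one subject's baseline data is

    P(convex | d) = 1 / (1 + exp(-(4.39/omega) * (d - theta)))

with a Bernoulli likelihood over trials.  Because the likelihood depends on the
data only through per-level convex counts, it is evaluated from a compact
(level, n, k) summary, which makes the sampler cheap.

Sampling is random-walk Metropolis on (theta, log omega) with per-chain step
size adaptation during burn-in (target acceptance 20-50%).  Convergence is
monitored with split-R-hat; the per-subject posterior is the pooled post
burn-in draws of all chains.

Two omega priors are available (both on the same support [omega_lo, omega_hi]):

* ``uniform-steepness`` (default): the steepness s = 1/omega is uniform, which
  places substantial prior mass on steep curves.  Flat data then concentrate
  the steepness posterior near zero relative to the prior, producing the
  strong null evidence (Savage-Dickey BF10 << 1) that flat observers should
  earn.
* ``log-uniform``: log omega uniform.

theta has a zero-centred normal prior (scale in arcmin).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .observers import PF_SLOPE_CONSTANT

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PsychometricPosterior",
    "log_likelihood",
    "sample_posterior",
    "fit_cohort",
    "fit_hierarchical",
    "hdi",
    "split_rhat",
]


@dataclass(frozen=True)
class PriorSpec:
    """Priors for (theta, omega); see module docstring for the omega options."""

    theta_scale_arcmin: float = 20.0
    omega_lo: float = 0.5
    omega_hi: float = 500.0
    omega_prior: str = "uniform-steepness"

    def __post_init__(self) -> None:
        if self.theta_scale_arcmin <= 0:
            raise ValueError("theta prior scale must be positive")
        if not 0 < self.omega_lo < self.omega_hi:
            raise ValueError("omega bounds must satisfy 0 < lo < hi")
        if self.omega_prior not in ("uniform-steepness", "log-uniform"):
            raise ValueError(f"unknown omega prior {self.omega_prior!r}")

    # --- densities -----------------------------------------------------
    def log_prior(self, theta: np.ndarray, log_omega: np.ndarray) -> np.ndarray:
        """Joint log prior density, parametrized by (theta, log omega)."""
        theta = np.asarray(theta, dtype=float)
        log_omega = np.asarray(log_omega, dtype=float)
        lp = -0.5 * (theta / self.theta_scale_arcmin) ** 2 - math.log(
            self.theta_scale_arcmin * math.sqrt(2.0 * math.pi)
        )
        lo, hi = math.log(self.omega_lo), math.log(self.omega_hi)
        inside = (log_omega >= lo) & (log_omega <= hi)
        if self.omega_prior == "log-uniform":
            lp_w = np.where(inside, -math.log(hi - lo), -np.inf)
        else:
            # s = 1/omega uniform: density in log-omega space is
            # s / (s_hi - s_lo) with s = exp(-log omega)
            s_lo, s_hi = 1.0 / self.omega_hi, 1.0 / self.omega_lo
            lp_w = np.where(inside, -log_omega - math.log(s_hi - s_lo), -np.inf)
        return lp + lp_w

    def steepness_prior_density(self, s: float) -> float:
        """Analytic prior density of the steepness s = 1/omega at a point."""
        s_lo, s_hi = 1.0 / self.omega_hi, 1.0 / self.omega_lo
        if not s_lo <= s <= s_hi:
            raise ValueError("steepness lies outside the prior support")
        if self.omega_prior == "log-uniform":
            return 1.0 / (s * math.log(self.omega_hi / self.omega_lo))
        return 1.0 / (s_hi - s_lo)

    def sample(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Draw (theta, omega) from the prior."""
        theta = rng.normal(0.0, self.theta_scale_arcmin, size=n)
        if self.omega_prior == "log-uniform":
            omega = np.exp(rng.uniform(math.log(self.omega_lo), math.log(self.omega_hi), size=n))
        else:
            s = rng.uniform(1.0 / self.omega_hi, 1.0 / self.omega_lo, size=n)
            omega = 1.0 / s
        return theta, omega


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 4
    n_samples: int = 5000
    n_burnin: int = 1000
    seed: int = 0
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_samples, self.n_burnin) <= 0:
            raise ValueError("chain, sample and burn-in counts must be positive")


@dataclass
class PsychometricPosterior:
    """Pooled posterior draws for one subject (or cohort-level container)."""

    subject_id: str
    theta: np.ndarray
    omega: np.ndarray
    rhat: dict[str, float]
    hdi_95: dict[str, tuple[float, float]]
    n_eff: dict[str, float]
    converged: bool
    prior_only: bool = False
    group_level: dict[str, np.ndarray] | None = None

    def summary(self) -> dict:
        out = {
            "theta_mean": float(np.mean(self.theta)),
            "theta_median": float(np.median(self.theta)),
            "omega_mean": float(np.mean(self.omega)),
            "omega_median": float(np.median(self.omega)),
            "hdi_95": {k: [float(v[0]), float(v[1])] for k, v in self.hdi_95.items()},
            "rhat": {k: float(v) for k, v in self.rhat.items()},
            "n_eff": {k: float(v) for k, v in self.n_eff.items()},
            "converged": bool(self.converged),
            "prior_only": bool(self.prior_only),
        }
        return out


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _level_counts(responses: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse baseline trials to (signed level, n trials, k convex)."""
    if len(responses) and (responses["experiment"] != "baseline").any():
        raise ValueError("psychometric likelihood accepts baseline trials only")
    grouped = responses.groupby("disparity_arcmin")["response"]
    d = np.array(sorted(responses["disparity_arcmin"].unique()), dtype=float)
    n = np.array([grouped.get_group(v).size for v in d], dtype=float)
    k = np.array([(grouped.get_group(v) == "convex").sum() for v in d], dtype=float)
    return d, n, k


def _loglik_counts(
    theta: np.ndarray, log_omega: np.ndarray, d: np.ndarray, n: np.ndarray, k: np.ndarray
) -> np.ndarray:
    """Bernoulli log likelihood from level counts; broadcasts over parameters."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    log_omega = np.atleast_1d(np.asarray(log_omega, dtype=float))
    z = (PF_SLOPE_CONSTANT * np.exp(-log_omega))[..., None] * (d - theta[..., None])
    log_p = -np.logaddexp(0.0, -z)
    log_q = -np.logaddexp(0.0, z)
    return (k * log_p + (n - k) * log_q).sum(axis=-1)


def log_likelihood(theta: float, omega: float, responses: pd.DataFrame) -> float:
    """Log likelihood of baseline responses under the logistic model."""
    if omega <= 0:
        raise ValueError("omega must be positive")
    d, n, k = _level_counts(responses)
    return float(_loglik_counts(np.array([theta]), np.array([math.log(omega)]), d, n, k)[0])


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat of a (n_chains, n_draws) array of draws."""
    chains = np.asarray(chains, dtype=float)
    half = chains.shape[1] // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = split.shape
    means = split.mean(axis=1)
    w = split.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else math.inf
    var_hat = (n - 1) / n * w + b / n
    return float(math.sqrt(var_hat / w))


def hdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(mass * n) sorted samples."""
    samples = np.sort(np.asarray(samples, dtype=float))
    n = samples.size
    if n < 2:
        raise ValueError("at least two samples are required for an HDI")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly between 0 and 1")
    m = math.ceil(mass * n)
    widths = samples[m - 1 :] - samples[: n - m + 1]
    i = int(np.argmin(widths))
    return float(samples[i]), float(samples[i + m - 1])


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def _run_metropolis(
    logpost,
    x0: np.ndarray,
    n_samples: int,
    n_burnin: int,
    rng: np.random.Generator,
    step0: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Vectorized adaptive random-walk Metropolis over chains.

    ``x0`` has shape (C, P); ``logpost`` maps (C, P) -> (C,).  During burn-in
    the proposal adapts per chain: a scalar scale targets ~30% acceptance
    (updated every 50 iterations), and from iteration 300 the proposal
    covariance is re-estimated from the chain history every 100 iterations
    (Haario-style adaptive Metropolis), which handles the correlated
    theta-omega ridge that flat observers produce.  Adaptation freezes at the
    end of burn-in.  Returns draws of shape (C, n_samples, P) and the
    post-burn-in acceptance rate.
    """
    x = np.array(x0, dtype=float)
    n_chain, n_par = x.shape
    scale = np.ones(n_chain) * 2.38 / math.sqrt(n_par)
    chol = np.tile(np.diag(np.asarray(step0, dtype=float)), (n_chain, 1, 1))
    lp = logpost(x)
    draws = np.empty((n_chain, n_samples, n_par))
    history = np.empty((n_chain, n_burnin, n_par))
    acc_window = np.zeros(n_chain)
    accepted_post = 0
    for it in range(n_burnin + n_samples):
        z = rng.standard_normal((n_chain, n_par))
        prop = x + scale[:, None] * np.einsum("cij,cj->ci", chol, z)
        lp_prop = logpost(prop)
        accept = np.log(rng.random(n_chain)) < (lp_prop - lp)
        x[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        if it < n_burnin:
            history[:, it, :] = x
            acc_window += accept
            if (it + 1) % 50 == 0:
                rate = acc_window / 50.0
                scale *= np.exp(1.5 * (rate - 0.3))
                acc_window[:] = 0.0
            if it >= 300 and (it + 1) % 100 == 0:
                for c in range(n_chain):
                    cov = np.cov(history[c, it // 2 : it + 1, :].T)
                    cov += 1e-6 * np.eye(n_par)
                    try:
                        chol[c] = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        pass
        else:
            draws[:, it - n_burnin, :] = x
            accepted_post += int(accept.sum())
    acc_rate = accepted_post / (n_chain * n_samples)
    return draws, acc_rate


def _ess(chains: np.ndarray) -> float:
    import arviz as az

    return float(az.ess(np.asarray(chains)))


def sample_posterior(
    responses: pd.DataFrame,
    priors: PriorSpec | None = None,
    cfg: MCMCConfig | None = None,
    subject_id: str | None = None,
) -> PsychometricPosterior:
    """Posterior over (theta, omega) for one subject's baseline responses.

    With no responses the sampler degenerates to the prior: direct prior draws
    are returned, flagged ``prior_only``.  Deterministic given ``cfg.seed``.
    """
    priors = priors or PriorSpec()
    cfg = cfg or MCMCConfig()
    sid = subject_id or (
        str(responses["subject_id"].iloc[0]) if len(responses) else "unknown"
    )
    rng = np.random.default_rng(cfg.seed)

    if len(responses) == 0:
        n = cfg.n_chains * cfg.n_samples
        theta, omega = priors.sample(rng, n)
        return _finalize(sid, theta[None, :], np.log(omega)[None, :], cfg, prior_only=True)

    d, n_l, k_l = _level_counts(responses)

    def logpost(x: np.ndarray) -> np.ndarray:
        theta, log_omega = x[:, 0], x[:, 1]
        lp = priors.log_prior(theta, log_omega)
        ok = np.isfinite(lp)
        out = np.full(x.shape[0], -np.inf)
        if ok.any():
            out[ok] = lp[ok] + _loglik_counts(theta[ok], log_omega[ok], d, n_l, k_l)
        return out

    # overdispersed starts: theta jittered around 0, log omega spread over the
    # prior range interior
    lo, hi = math.log(priors.omega_lo), math.log(priors.omega_hi)
    q = np.linspace(0.15, 0.85, cfg.n_chains)
    x0 = np.column_stack(
        [rng.normal(0.0, 2.0, cfg.n_chains), lo + q * (hi - lo)]
    )
    step0 = np.array([1.0, 0.3])
    draws, _ = _run_metropolis(logpost, x0, cfg.n_samples, cfg.n_burnin, rng, step0)
    return _finalize(sid, draws[:, :, 0], draws[:, :, 1], cfg)


def _finalize(
    sid: str,
    theta_chains: np.ndarray,
    log_omega_chains: np.ndarray,
    cfg: MCMCConfig,
    prior_only: bool = False,
) -> PsychometricPosterior:
    theta = theta_chains.reshape(-1)
    omega = np.exp(log_omega_chains.reshape(-1))
    multi = theta_chains.shape[0] > 1 and not prior_only
    rhat = {
        "theta": split_rhat(theta_chains) if multi else 1.0,
        "omega": split_rhat(log_omega_chains) if multi else 1.0,
    }
    n_eff = {
        "theta": _ess(theta_chains) if multi else float(theta.size),
        "omega": _ess(log_omega_chains) if multi else float(omega.size),
    }
    converged = prior_only or all(r <= cfg.rhat_threshold for r in rhat.values())
    return PsychometricPosterior(
        subject_id=sid,
        theta=theta,
        omega=omega,
        rhat=rhat,
        hdi_95={"theta": hdi(theta), "omega": hdi(omega)},
        n_eff=n_eff,
        converged=converged,
        prior_only=prior_only,
    )


def fit_cohort(
    responses: pd.DataFrame,
    priors: PriorSpec | None = None,
    cfg: MCMCConfig | None = None,
) -> dict[str, PsychometricPosterior]:
    """Independent per-subject fits of all baseline data in a response table."""
    priors = priors or PriorSpec()
    cfg = cfg or MCMCConfig()
    base = responses[responses["experiment"] == "baseline"]
    out: dict[str, PsychometricPosterior] = {}
    root = np.random.SeedSequence(cfg.seed)
    subjects = list(dict.fromkeys(base["subject_id"]))
    for sid, seq in zip(subjects, root.spawn(max(len(subjects), 1))):
        sub_cfg = MCMCConfig(
            n_chains=cfg.n_chains,
            n_samples=cfg.n_samples,
            n_burnin=cfg.n_burnin,
            seed=int(seq.generate_state(1)[0]) & 0x7FFFFFFF,
            rhat_threshold=cfg.rhat_threshold,
        )
        out[sid] = sample_posterior(
            base[base["subject_id"] == sid], priors, sub_cfg, subject_id=sid
        )
    return out


# ---------------------------------------------------------------------------
# hierarchical model
# ---------------------------------------------------------------------------

def fit_hierarchical(
    responses: pd.DataFrame,
    priors: PriorSpec | None = None,
    cfg: MCMCConfig | None = None,
) -> dict:
    """Hierarchical fit: theta_i ~ N(mu_t, sig_t), log omega_i ~ N(mu_w, sig_w).

    Gibbs-within-Metropolis: subject parameters get vectorized random-walk
    updates conditional on the hyperparameters; the hyperparameters get
    conjugate normal / inverse-gamma updates conditional on the subject
    parameters.  Hyperpriors: mu_t ~ N(0, theta prior scale),
    mu_w ~ N(midpoint of the log-omega range, 3), variances ~ InvGamma(1, 1).

    Returns per-subject posteriors (under hierarchical shrinkage) plus
    group-level draws.  With a single subject falls back to the per-subject
    fit with a warning.
    """
    priors = priors or PriorSpec()
    cfg = cfg or MCMCConfig()
    base = responses[responses["experiment"] == "baseline"]
    subjects = list(dict.fromkeys(base["subject_id"]))
    if len(subjects) < 2:
        warnings.warn("hierarchical fit requires >= 2 subjects; using per-subject fit")
        return {"subjects": fit_cohort(responses, priors, cfg), "group_level": None}

    counts = [_level_counts(base[base["subject_id"] == s]) for s in subjects]
    # common level axis padded with zero-count levels per subject
    all_levels = np.array(sorted({float(v) for d, _, _ in counts for v in d}))
    S, L = len(subjects), all_levels.size
    n_mat = np.zeros((S, L))
    k_mat = np.zeros((S, L))
    for i, (d, n, k) in enumerate(counts):
        idx = np.searchsorted(all_levels, d)
        n_mat[i, idx] = n
        k_mat[i, idx] = k

    lo, hi = math.log(priors.omega_lo), math.log(priors.omega_hi)
    mu_w0, tau_w0 = (lo + hi) / 2.0, 3.0
    mu_t0, tau_t0 = 0.0, priors.theta_scale_arcmin
    a0 = b0 = 1.0

    rng = np.random.default_rng(cfg.seed)
    n_keep = cfg.n_samples
    total = cfg.n_burnin + n_keep

    def subject_loglik(theta: np.ndarray, log_w: np.ndarray) -> np.ndarray:
        z = (PF_SLOPE_CONSTANT * np.exp(-log_w))[:, None] * (all_levels - theta[:, None])
        return (k_mat * (-np.logaddexp(0, -z)) + (n_mat - k_mat) * (-np.logaddexp(0, z))).sum(1)

    chains_out = []
    group_out = {k: [] for k in ("mu_theta", "sigma_theta", "mu_log_omega", "sigma_log_omega")}
    for chain, seq in enumerate(np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)):
        rng = np.random.default_rng(seq)
        theta = rng.normal(0.0, 2.0, S)
        log_w = rng.uniform(lo + 0.2 * (hi - lo), hi - 0.2 * (hi - lo), S)
        mu_t, sig_t, mu_w, sig_w = 0.0, 10.0, (lo + hi) / 2.0, 1.0
        step = np.tile(np.array([1.0, 0.3]), (S, 1))
        acc = np.zeros((S, 2))
        ll = subject_loglik(theta, log_w)
        keep = {
            "theta": np.empty((n_keep, S)),
            "log_w": np.empty((n_keep, S)),
            "mu_theta": np.empty(n_keep),
            "sigma_theta": np.empty(n_keep),
            "mu_log_omega": np.empty(n_keep),
            "sigma_log_omega": np.empty(n_keep),
        }
        for it in range(total):
            # --- subject-level MH updates (vectorized across subjects) ---
            for j, (vec, mu, sig) in enumerate(
                ((theta, mu_t, sig_t), (log_w, mu_w, sig_w))
            ):
                prop = vec + step[:, j] * rng.standard_normal(S)
                th_p, lw_p = (prop, log_w) if j == 0 else (theta, prop)
                ll_p = subject_loglik(th_p, lw_p)
                d_prior = -0.5 * ((prop - mu) / sig) ** 2 + 0.5 * ((vec - mu) / sig) ** 2
                accept = np.log(rng.random(S)) < ll_p - ll + d_prior
                vec[accept] = prop[accept]
                ll[accept] = ll_p[accept]
                acc[:, j] += accept
            if it < cfg.n_burnin and (it + 1) % 50 == 0:
                step *= np.exp(1.5 * (acc / 50.0 - 0.35))
                acc[:] = 0.0
            # --- conjugate hyperparameter updates ---
            for vec, mu0, tau0, which in (
                (theta, mu_t0, tau_t0, "t"),
                (log_w, mu_w0, tau_w0, "w"),
            ):
                sig = sig_t if which == "t" else sig_w
                prec = S / sig**2 + 1.0 / tau0**2
                mean = (vec.sum() / sig**2 + mu0 / tau0**2) / prec
                mu = rng.normal(mean, 1.0 / math.sqrt(prec))
                a_n = a0 + S / 2.0
                b_n = b0 + 0.5 * ((vec - mu) ** 2).sum()
                var = b_n / rng.gamma(a_n)
                if which == "t":
                    mu_t, sig_t = mu, math.sqrt(var)
                else:
                    mu_w, sig_w = mu, math.sqrt(var)
            if it >= cfg.n_burnin:
                i = it - cfg.n_burnin
                keep["theta"][i] = theta
                keep["log_w"][i] = log_w
                keep["mu_theta"][i] = mu_t
                keep["sigma_theta"][i] = sig_t
                keep["mu_log_omega"][i] = mu_w
                keep["sigma_log_omega"][i] = sig_w
        chains_out.append(keep)
        for k in group_out:
            group_out[k].append(keep[k])

    group_level = {k: np.concatenate(v) for k, v in group_out.items()}
    group_chains = {k: np.stack(v) for k, v in group_out.items()}
    subjects_out = {}
    for i, sid in enumerate(subjects):
        th_chains = np.stack([c["theta"][:, i] for c in chains_out])
        lw_chains = np.stack([c["log_w"][:, i] for c in chains_out])
        post = _finalize(sid, th_chains, lw_chains, cfg)
        post.group_level = group_level
        subjects_out[sid] = post
    group_rhat = {k: split_rhat(v) for k, v in group_chains.items()}
    return {"subjects": subjects_out, "group_level": group_level, "group_rhat": group_rhat}
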