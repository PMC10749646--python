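"""Bayesian General Condorcet Model (GCM) for binary relevance data.

The GCM is the cultural-consensus model for dichotomous "is this attribute
relevant for your satisfaction?" data.  Each respondent *i* carries a
competency ``theta_i`` (probability of knowing the culturally true answer)
and a guessing bias ``g_i`` (probability of answering 1 when not knowing);
each item *k* carries a difficulty ``delta_k`` and a latent truth bit
``z_k``.  Competency and difficulty combine into an effective accuracy

    D_ik = theta_i (1 - delta_k) / (theta_i (1 - delta_k) + delta_k (1 - theta_i)),

a Rasch-type composition: on the logit scale, logit D = logit theta - logit
delta.  The response model is

    P(y_ik = 1) = D_ik + (1 - D_ik) g_i   if z_k = 1,
    P(y_ik = 1) = (1 - D_ik) g_i          if z_k = 0.

Because the likelihood is invariant under a common shift of all competency
and difficulty logits, the model is estimated hierarchically with the
difficulty logits confined to the sum-to-zero subspace (mean difficulty
pinned at 0.5):

    logit theta_i ~ N(mu_theta, s2_theta),  logit g_i ~ N(mu_g, s2_g),
    logit delta_k ~ N(0, 1.25^2) with sum_k logit delta_k = 0,
    z_k ~ Bernoulli(1/2),

with weak conjugate hyperpriors on the competency and guessing hierarchies.
The difficulty prior scale is fixed, not estimated: it encodes the design
range of difficulties (roughly 0.1-0.9), and estimating it lets the chain
trade difficulty spread against the weakly identified cohort
competency/guessing levels.  Sampling combines Gibbs for the truth bits
and hyperparameters, adaptive random-walk Metropolis (logit scale, target
acceptance ~0.44) for individual parameters, pairwise difficulty exchange
moves inside the sum-to-zero subspace, population-level shift and ridge
moves that traverse the slow competency-level/guessing-level direction,
and joint truth-flip/difficulty moves for items whose truth is ambiguous.

The module also provides the eigenvalue (scree) analysis of the
respondent-respondent correlation matrix used to decide whether responses
arise from a single consensus culture, posterior-predictive checks built on
the same eigenvalue statistic, and the resilience rerun that repeats the
whole analysis after dropping chosen items.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.special import expit, logit

if TYPE_CHECKING:  # pragma: no cover
    from .classify import ClassificationResult
    from .survey import SurveyDataset

__all__ = [
    "GCMParameters",
    "GCMPosterior",
    "MCMCSettings",
    "ScreeResult",
    "ResilienceResult",
    "gcm_response_probability",
    "simulate_gcm",
    "fit_gcm",
    "posterior_predictive_check",
    "scree_analysis",
    "resilience_rerun",
]

_EPS = 1e-12

#: logit-guessing shift per unit logit-competency shift in the ridge moves
_RIDGE_SLOPES = (4.0, 3.0, 2.0, 1.0)


@dataclass
class GCMParameters:
    """Generating parameters of a GCM: one culture's truth and its informants.

    Parameters
    ----------
    theta
        Per-respondent competency in [0, 1], shape (n,).
    g
        Per-respondent guessing bias in [0, 1], shape (n,).
    delta
        Per-item difficulty in [0, 1], shape (m,).
    z
        Per-item latent truth bits in {0, 1}, shape (m,).
    """

    theta: np.ndarray
    g: np.ndarray
    delta: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.z = np.asarray(self.z, dtype=int)
        if self.theta.shape != self.g.shape or self.theta.ndim != 1:
            raise ValueError("theta and g must be 1-d arrays of equal length")
        if self.delta.shape != self.z.shape or self.delta.ndim != 1:
            raise ValueError("delta and z must be 1-d arrays of equal length")
        for name in ("theta", "g", "delta"):
            v = getattr(self, name)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not np.isin(self.z, (0, 1)).all():
            raise ValueError("z must be binary")

    @property
    def n_respondents(self) -> int:
        return self.theta.size

    @property
    def n_items(self) -> int:
        return self.delta.size


def _effective_accuracy(theta, delta):
    """Rasch-type accuracy D; the degenerate 0/0 case is defined as 0.5."""
    theta = np.asarray(theta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    num = theta * (1.0 - delta)
    den = num + delta * (1.0 - theta)
    out = np.full(np.broadcast(num, den).shape, 0.5)
    np.divide(num, den, out=out, where=den > 0)
    return out


def gcm_response_probability(theta, g, delta, z):
    """P(answer = 1) under the GCM; inputs broadcast elementwise.

    With effective accuracy ``D = theta(1-delta) / (theta(1-delta) +
    delta(1-theta))``: returns ``D + (1-D) g`` where ``z = 1`` and
    ``(1-D) g`` where ``z = 0``.
    """
    for name, v in (("theta", theta), ("g", g), ("delta", delta)):
        if np.any((np.asarray(v, float) < 0) | (np.asarray(v, float) > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")
    z = np.asarray(z)
    if not np.isin(z, (0, 1)).all():
        raise ValueError("z must be binary")
    D = _effective_accuracy(theta, delta)
    g = np.asarray(g, dtype=float)
    return np.where(z == 1, D + (1.0 - D) * g, (1.0 - D) * g)


def simulate_gcm(params: GCMParameters, seed: int | np.random.Generator) -> np.ndarray:
    """Draw one binary response matrix (n x m) from the GCM.

    Each cell is an independent Bernoulli draw from
    :func:`gcm_response_probability`; a fixed seed reproduces the matrix.
    """
    rng = np.random.default_rng(seed)
    p = gcm_response_probability(
        params.theta[:, None], params.g[:, None], params.delta[None, :], params.z[None, :]
    )
    return (rng.random(p.shape) < p).astype(np.int8)


@dataclass
class MCMCSettings:
    """Sampler configuration; ``samples`` are post-burn-in draws per chain."""

    chains: int = 3
    samples: int = 10_000
    burnin: int = 2_000
    seed: int = 0
    thin: int = 10

    def __post_init__(self) -> None:
        if self.chains < 1 or self.samples < 1 or self.burnin < 0:
            raise ValueError("chains and samples must be >= 1, burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class GCMPosterior:
    """Posterior summaries of a GCM fit.

    ``item_truth`` is the posterior probability that each item's culturally
    true answer is 1; ``binary_truth`` thresholds it at 0.5.  ``theta_mean``
    / ``theta_sd`` (and the ``g`` analogues) summarise the spread of
    per-respondent posterior means across the cohort.  ``rhat`` holds the
    split-R-hat convergence statistic for every continuous parameter.
    """

    item_truth: np.ndarray
    binary_truth: np.ndarray
    delta_mean: np.ndarray
    theta_individual: np.ndarray
    g_individual: np.ndarray
    theta_mean: float
    theta_sd: float
    g_mean: float
    g_sd: float
    rhat: dict[str, np.ndarray]
    settings: MCMCSettings
    item_ids: list[str] | None = None
    respondent_ids: list[str] | None = None
    chain_item_truth: np.ndarray | None = None
    draws: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def max_rhat(self) -> float:
        """Largest split-R-hat over all parameters (NaN for single-chain fits)."""
        allv = np.concatenate([np.ravel(v) for v in self.rhat.values()])
        if np.isnan(allv).all():
            return float("nan")
        return float(np.nanmax(allv))


def _loglik(Y1, obs, lt, lg, ld, z):
    """Observed-data log-likelihood contributions, shape (n, m).

    ``Y1`` is the boolean matrix (answer == 1) with missing cells False,
    ``obs`` the observedness mask; missing cells contribute 0.
    """
    D = expit(lt[:, None] - ld[None, :])
    g = expit(lg)[:, None]
    p = np.where(z[None, :] == 1, D + (1.0 - D) * g, (1.0 - D) * g)
    p = np.clip(p, _EPS, 1.0 - _EPS)
    ll = np.where(Y1, np.log(p), np.log1p(-p))
    return np.where(obs, ll, 0.0)


def _run_chain(Y1, obs, settings: MCMCSettings, rng: np.random.Generator):
    n, m = Y1.shape
    n_iter = settings.burnin + settings.samples

    lt = rng.normal(0.0, 0.5, n)
    lg = rng.normal(0.0, 0.5, n)
    ld = rng.normal(0.0, 0.5, m)
    ld -= ld.mean()  # difficulty logits live in the sum-to-zero subspace
    z = (rng.random(m) < 0.5).astype(int)
    mu_t = 0.0
    mu_g = 0.0
    s2_t = s2_g = 1.0

    step_t = np.full(n, 0.5)
    step_g = np.full(n, 0.5)
    step_d = np.full(m, 0.3)
    step_shift_t = 0.2
    step_shift_g = 0.2
    step_ridge = np.full(len(_RIDGE_SLOPES), 0.05)
    step_zd = 1.0
    acc_t = np.zeros(n)
    acc_g = np.zeros(n)
    acc_d = np.zeros(m)
    acc_st = 0.0
    acc_sg = 0.0
    acc_ridge = np.zeros(len(_RIDGE_SLOPES))
    acc_zd = 0.0

    sum_theta = np.zeros(n)
    sum_g = np.zeros(n)
    sum_delta = np.zeros(m)
    sum_z = np.zeros(m)
    kept = 0
    n_thinned = settings.samples // settings.thin
    trace = {
        "theta": np.empty((n_thinned, n)),
        "g": np.empty((n_thinned, n)),
        "delta": np.empty((n_thinned, m)),
        "z": np.empty((n_thinned, m), dtype=np.int8),
        "mu_theta": np.empty(n_thinned),
        "mu_g": np.empty(n_thinned),
        "sigma_theta": np.empty(n_thinned),
        "sigma_g": np.empty(n_thinned),
    }
    t_idx = 0

    for it in range(n_iter):
        # --- individual competency logits (rows, parallel Metropolis)
        ll = _loglik(Y1, obs, lt, lg, ld, z).sum(axis=1)
        prop = lt + rng.normal(0.0, step_t)
        llp = _loglik(Y1, obs, prop, lg, ld, z).sum(axis=1)
        logr = llp - ll - ((prop - mu_t) ** 2 - (lt - mu_t) ** 2) / (2.0 * s2_t)
        acc = np.log(rng.random(n)) < logr
        lt = np.where(acc, prop, lt)
        acc_t += acc

        # --- individual guessing-bias logits
        ll = _loglik(Y1, obs, lt, lg, ld, z).sum(axis=1)
        prop = lg + rng.normal(0.0, step_g)
        llp = _loglik(Y1, obs, lt, prop, ld, z).sum(axis=1)
        logr = llp - ll - ((prop - mu_g) ** 2 - (lg - mu_g) ** 2) / (2.0 * s2_g)
        acc = np.log(rng.random(n)) < logr
        lg = np.where(acc, prop, lg)
        acc_g += acc

        # --- item difficulty logits: pairwise exchange moves inside the
        # sum-to-zero subspace.  Pinning the difficulty-logit mean exactly
        # removes the Rasch ridge (a common shift of competency and
        # difficulty logits leaves the likelihood unchanged), which a soft
        # prior centering lets the chain drift along.
        if m >= 2:
            perm = rng.permutation(m)
            n_pairs = m // 2
            ii = perm[0:2 * n_pairs:2]
            jj = perm[1:2 * n_pairs:2]
            c = rng.normal(0.0, step_d[ii])
            prop = ld.copy()
            prop[ii] += c
            prop[jj] -= c
            ll = _loglik(Y1, obs, lt, lg, ld, z).sum(axis=0)
            llp = _loglik(Y1, obs, lt, lg, prop, z).sum(axis=0)
            # difficulty prior: fixed N(0, 1.25^2) on the logit scale, i.e.
            # difficulties a priori span roughly [0.1, 0.9].  The scale is
            # deliberately not estimated: an adaptive scale rewards
            # collapsing the difficulty spread, which drags the weakly
            # identified competency/guessing levels along the Rasch ridge,
            # while a much wider scale frees the same drift in reverse.
            logr = (
                llp[ii] + llp[jj] - ll[ii] - ll[jj]
                - (prop[ii] ** 2 - ld[ii] ** 2 + prop[jj] ** 2 - ld[jj] ** 2)
                / (2.0 * 1.5625)
            )
            acc = np.log(rng.random(n_pairs)) < logr
            ld[ii[acc]] = prop[ii[acc]]
            ld[jj[acc]] = prop[jj[acc]]
            acc_d[ii] += acc
            acc_d[jj] += acc

        # --- population shift moves: translate a whole logit population
        # together with its mean (prior-invariant), crossing the soft ridge
        # between overall competency level and overall guessing level.
        for which in ("t", "g"):
            step = step_shift_t if which == "t" else step_shift_g
            c = rng.normal(0.0, step)
            if which == "t":
                cand_lt, cand_mu_t = lt + c, mu_t + c
                cand_lg, cand_mu_g = lg, mu_g
            else:
                cand_lt, cand_mu_t = lt, mu_t
                cand_lg, cand_mu_g = lg + c, mu_g + c
            ll = _loglik(Y1, obs, lt, lg, ld, z).sum()
            llp = _loglik(Y1, obs, cand_lt, cand_lg, ld, z).sum()
            mu_old = mu_t if which == "t" else mu_g
            logr = llp - ll - ((mu_old + c) ** 2 - mu_old**2) / (2.0 * 100.0)
            if np.log(rng.random()) < logr:
                lt, mu_t, lg, mu_g = cand_lt, cand_mu_t, cand_lg, cand_mu_g
                if which == "t":
                    acc_st += 1
                else:
                    acc_sg += 1

        # --- ridge moves: the weakly identified direction couples the
        # population competency level against the guessing level with a
        # truth-aligned reshuffle of difficulties; a plain random walk
        # crosses it very slowly.  Each move applies a fixed linear
        # direction scaled by a symmetric scalar step, so plain Metropolis
        # acceptance applies; two slopes cover the varying local geometry.
        m1 = int(z.sum())
        if 0 < m1 < m:
            dir_ld = np.where(z == 1, -1.0 / m1, 1.0 / (m - m1))
            dir_ld = dir_ld - dir_ld.mean()
            for r_idx, slope in enumerate(_RIDGE_SLOPES):
                c = rng.normal(0.0, step_ridge[r_idx])
                cand_lt = lt + c
                cand_lg = lg - slope * c
                cand_ld = ld + c * dir_ld * m
                ll = _loglik(Y1, obs, lt, lg, ld, z).sum()
                llp = _loglik(Y1, obs, cand_lt, cand_lg, cand_ld, z).sum()
                logr = (
                    llp - ll
                    - ((mu_t + c) ** 2 - mu_t**2) / 200.0
                    - ((mu_g - slope * c) ** 2 - mu_g**2) / 200.0
                    - ((cand_ld**2).sum() - (ld**2).sum()) / (2.0 * 1.5625)
                )
                if np.log(rng.random()) < logr:
                    lt, lg, ld = cand_lt, cand_lg, cand_ld
                    mu_t += c
                    mu_g -= slope * c
                    acc_ridge[r_idx] += 1

        # --- joint truth-flip/difficulty moves: an item whose truth is
        # ambiguous has two modes, (z=1, harder) vs (z=0, easier); flipping
        # z alone is rarely accepted because delta must move with it.
        # Items are paired disjointly; within each pair the first item's
        # truth is flipped while the difficulty logits exchange mass, so
        # their sum stays zero and the pairs can be tested in parallel.
        if m >= 2:
            perm = rng.permutation(m)
            n_pairs = m // 2
            kk = perm[0:2 * n_pairs:2]
            jj2 = perm[1:2 * n_pairs:2]
            c = rng.normal(0.0, step_zd, n_pairs)
            cand_z = z.copy()
            cand_z[kk] = 1 - cand_z[kk]
            cand_ld = ld.copy()
            cand_ld[kk] += c
            cand_ld[jj2] -= c
            ll = _loglik(Y1, obs, lt, lg, ld, z).sum(axis=0)
            llp = _loglik(Y1, obs, lt, lg, cand_ld, cand_z).sum(axis=0)
            logr = (
                llp[kk] + llp[jj2] - ll[kk] - ll[jj2]
                - (cand_ld[kk] ** 2 - ld[kk] ** 2 + cand_ld[jj2] ** 2 - ld[jj2] ** 2)
                / (2.0 * 1.5625)
            )
            acc = np.log(rng.random(n_pairs)) < logr
            z[kk[acc]] = cand_z[kk[acc]]
            ld[kk[acc]] = cand_ld[kk[acc]]
            ld[jj2[acc]] = cand_ld[jj2[acc]]
            acc_zd += acc.mean() if n_pairs else 0.0

        # --- latent truth bits (exact Gibbs)
        l1 = _loglik(Y1, obs, lt, lg, ld, np.ones(m, dtype=int)).sum(axis=0)
        l0 = _loglik(Y1, obs, lt, lg, ld, np.zeros(m, dtype=int)).sum(axis=0)
        z = (rng.random(m) < expit(l1 - l0)).astype(int)

        # --- hyperparameters (conjugate Gibbs; mu ~ N(0, 10^2), s2 ~ IG(2, 1))
        for vals, which in ((lt, "t"), (lg, "g")):
            s2 = s2_t if which == "t" else s2_g
            prec = vals.size / s2 + 1.0 / 100.0
            mu = rng.normal(vals.sum() / s2 / prec, 1.0 / np.sqrt(prec))
            ss = float(((vals - mu) ** 2).sum())
            s2_new = 1.0 / rng.gamma(2.0 + vals.size / 2.0, 1.0 / (1.0 + ss / 2.0))
            if which == "t":
                mu_t, s2_t = mu, s2_new
            else:
                mu_g, s2_g = mu, s2_new

        # --- step-size adaptation toward ~0.44 acceptance (burn-in only)
        if it < settings.burnin and (it + 1) % 50 == 0:
            for stp, accv in ((step_t, acc_t), (step_g, acc_g), (step_d, acc_d)):
                stp *= np.exp(np.where(accv / 50.0 > 0.44, 0.1, -0.1))
                np.clip(stp, 1e-3, 3.0, out=stp)
                accv[:] = 0.0
            step_shift_t *= float(np.exp(0.1 if acc_st / 100.0 > 0.3 else -0.1))
            step_shift_g *= float(np.exp(0.1 if acc_sg / 100.0 > 0.3 else -0.1))
            step_shift_t = float(np.clip(step_shift_t, 1e-3, 2.0))
            step_shift_g = float(np.clip(step_shift_g, 1e-3, 2.0))
            step_ridge *= np.exp(np.where(acc_ridge / 50.0 > 0.3, 0.1, -0.1))
            np.clip(step_ridge, 1e-4, 1.0, out=step_ridge)
            acc_st = acc_sg = acc_zd = 0.0
            acc_ridge[:] = 0.0

        if it >= settings.burnin:
            sum_theta += expit(lt)
            sum_g += expit(lg)
            sum_delta += expit(ld)
            sum_z += z
            kept += 1
            k = it - settings.burnin
            if k % settings.thin == 0 and t_idx < n_thinned:
                trace["theta"][t_idx] = expit(lt)
                trace["g"][t_idx] = expit(lg)
                trace["delta"][t_idx] = expit(ld)
                trace["z"][t_idx] = z
                trace["mu_theta"][t_idx] = mu_t
                trace["mu_g"][t_idx] = mu_g
                trace["sigma_theta"][t_idx] = np.sqrt(s2_t)
                trace["sigma_g"][t_idx] = np.sqrt(s2_g)
                t_idx += 1

    means = {
        "theta": sum_theta / kept,
        "g": sum_g / kept,
        "delta": sum_delta / kept,
        "z": sum_z / kept,
    }
    return means, trace


def _as_matrix(data) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    if isinstance(data, pd.DataFrame):
        return (
            data.to_numpy(dtype=float),
            [str(c) for c in data.columns],
            [str(i) for i in data.index],
        )
    return np.asarray(data, dtype=float), None, None


def fit_gcm(
    data,
    chains: int = 3,
    samples: int = 10_000,
    burnin: int = 2_000,
    seed: int = 0,
    thin: int = 10,
) -> GCMPosterior:
    """Fit the hierarchical GCM by MCMC.

    Parameters
    ----------
    data
        Binary respondent x item matrix (ndarray or DataFrame).  NaN marks
        a missing cell and is excluded from the likelihood; all other
        entries must be 0 or 1.
    chains, samples, burnin, seed, thin
        Sampler settings; ``samples`` counts post-burn-in draws per chain.
        Per-chain streams are spawned deterministically from ``seed``.

    Returns
    -------
    GCMPosterior
        Posterior means, cohort summaries, per-parameter split-R-hat and
        thinned draws (used by the posterior-predictive check).
    """
    import arviz as az

    settings = MCMCSettings(chains=chains, samples=samples, burnin=burnin, seed=seed, thin=thin)
    Y, item_ids, respondent_ids = _as_matrix(data)
    if Y.ndim != 2 or Y.shape[0] < 2 or Y.shape[1] < 2:
        raise ValueError("data must be a 2-d matrix with >= 2 respondents and >= 2 items")
    obs = ~np.isnan(Y)
    vals = Y[obs]
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("data must be binary (0/1, NaN for missing)")
    with np.errstate(invalid="ignore"):
        row_const = np.all(Y == Y[:, [0]], axis=1) | (obs.sum(axis=1) <= 1)
        col_sd = np.nanstd(Y, axis=0)
    if np.any(col_sd == 0):
        warnings.warn("input has all-constant item column(s); fit proceeds", stacklevel=2)
    if row_const.any():
        warnings.warn("input has all-constant respondent row(s); fit proceeds", stacklevel=2)
    Y1 = (Y == 1.0) & obs

    seq = np.random.SeedSequence(settings.seed)
    chain_means = []
    chain_traces = []
    for child in seq.spawn(settings.chains):
        means, trace = _run_chain(Y1, obs, settings, np.random.default_rng(child))
        chain_means.append(means)
        chain_traces.append(trace)

    stack = lambda key: np.stack([t[key] for t in chain_traces])  # noqa: E731
    posterior_dict = {
        k: stack(k)
        for k in (
            "theta", "g", "delta",
            "mu_theta", "mu_g", "sigma_theta", "sigma_g",
        )
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat_ds = az.rhat(az.from_dict(posterior=posterior_dict))
    rhat = {k: np.atleast_1d(np.asarray(rhat_ds[k])) for k in posterior_dict}

    theta_ind = np.mean([m["theta"] for m in chain_means], axis=0)
    g_ind = np.mean([m["g"] for m in chain_means], axis=0)
    delta_mean = np.mean([m["delta"] for m in chain_means], axis=0)
    chain_truth = np.stack([m["z"] for m in chain_means])
    item_truth = chain_truth.mean(axis=0)

    return GCMPosterior(
        item_truth=item_truth,
        binary_truth=(item_truth > 0.5).astype(int),
        delta_mean=delta_mean,
        theta_individual=theta_ind,
        g_individual=g_ind,
        theta_mean=float(theta_ind.mean()),
        theta_sd=float(theta_ind.std(ddof=1)) if theta_ind.size > 1 else 0.0,
        g_mean=float(g_ind.mean()),
        g_sd=float(g_ind.std(ddof=1)) if g_ind.size > 1 else 0.0,
        rhat=rhat,
        settings=settings,
        item_ids=item_ids,
        respondent_ids=respondent_ids,
        chain_item_truth=chain_truth,
        draws={k: stack(k) for k in ("theta", "g", "delta", "z")},
    )


# ---------------------------------------------------------------------------
# Eigenvalue / scree consensus-group detection
# ---------------------------------------------------------------------------


@dataclass
class ScreeResult:
    """Eigenvalue spectrum of the respondent correlation matrix.

    ``n_cultures`` is 1 when a single dominant, same-sign first factor is
    found, else 2 (meaning ">= 2"; the analysis detects multiplicity, it
    does not count cultures beyond two).
    """

    eigenvalues: np.ndarray
    n_omitted: int
    ratio_first_second: float
    n_cultures: int
    negative_loading_fraction: float


def _respondent_correlation(Y: np.ndarray) -> tuple[np.ndarray, int]:
    """Correlation between respondents across items, omitting zero-variance rows."""
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(Y, axis=1)
    keep = sd > 0
    n_omitted = int((~keep).sum())
    Yk = Y[keep]
    if Yk.shape[0] < 3:
        raise ValueError("need at least 3 respondents with response variance")
    if np.isnan(Yk).any():
        C = pd.DataFrame(Yk.T).corr().to_numpy()
        C = np.nan_to_num(C, nan=0.0)
        np.fill_diagonal(C, 1.0)
    else:
        C = np.corrcoef(Yk)
    return C, n_omitted


def scree_analysis(
    data,
    ratio_threshold: float = 1.75,
    negative_loading_tolerance: float = 0.25,
) -> ScreeResult:
    """Detect whether binary responses reflect one consensus culture.

    Respondents with no response variance are omitted (their correlation
    with anyone is undefined), the respondent-respondent Pearson correlation
    matrix is eigendecomposed, and a single culture is declared when the
    first eigenvalue dominates the second (``ratio_first_second >=
    ratio_threshold``) *and* the first eigenvector's loadings are
    essentially of one sign (negative fraction <=
    ``negative_loading_tolerance``).  A large bipolar first factor — equally
    strong but with mixed-sign loadings — indicates opposed consensus
    groups, which a pure eigenvalue ratio cannot distinguish from a single
    culture.

    Default thresholds are calibrated for wide-format designs with many
    more respondents than items, where the correlation matrix is rank
    deficient and late eigenvalues are noise inflated; see the methods note.
    """
    Y, _, _ = _as_matrix(data)
    C, n_omitted = _respondent_correlation(Y)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    eigenvalues = np.clip(w[order], 0.0, None)
    v1 = V[:, order[0]]
    if v1.sum() < 0:
        v1 = -v1
    neg_frac = float((v1 < 0).mean())
    ratio = float(eigenvalues[0] / eigenvalues[1]) if eigenvalues[1] > 0 else np.inf
    one_culture = ratio >= ratio_threshold and neg_frac <= negative_loading_tolerance
    return ScreeResult(
        eigenvalues=eigenvalues,
        n_omitted=n_omitted,
        ratio_first_second=ratio,
        n_cultures=1 if one_culture else 2,
        negative_loading_fraction=neg_frac,
    )


def _eigen_ratio(Y: np.ndarray) -> float:
    C, _ = _respondent_correlation(Y)
    w = np.linalg.eigvalsh(C)
    return float(w[-1] / w[-2]) if w[-2] > 0 else np.inf


def posterior_predictive_check(
    posterior: GCMPosterior,
    data,
    n_replicates: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Posterior-predictive check on the first-to-second eigenvalue ratio.

    Draws parameter vectors from the stored posterior samples, simulates
    replicate response matrices, computes each replicate's eigenvalue ratio
    of the respondent correlation matrix, and locates the observed ratio
    within the replicate distribution.  A percentile in an extreme tail
    signals that the one-culture GCM does not reproduce the observed
    agreement structure.

    Returns a dict with ``observed``, ``percentile`` (of the observed ratio
    among replicates) and the replicate distribution quantiles.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not posterior.draws:
        raise ValueError("posterior carries no stored draws; refit with thin >= 1")
    Y, _, _ = _as_matrix(data)
    if Y.shape[0] < 3:
        raise ValueError("need at least 3 respondents")
    rng = np.random.default_rng(seed)
    theta = posterior.draws["theta"].reshape(-1, posterior.draws["theta"].shape[-1])
    g = posterior.draws["g"].reshape(-1, posterior.draws["g"].shape[-1])
    delta = posterior.draws["delta"].reshape(-1, posterior.draws["delta"].shape[-1])
    zdr = posterior.draws["z"].reshape(-1, posterior.draws["z"].shape[-1])
    observed = _eigen_ratio(Y)
    reps = np.empty(n_replicates)
    for r in range(n_replicates):
        j = rng.integers(theta.shape[0])
        params = GCMParameters(theta=theta[j], g=g[j], delta=delta[j], z=zdr[j])
        reps[r] = _eigen_ratio(simulate_gcm(params, rng))
    return {
        "observed": observed,
        "percentile": float(100.0 * (reps < observed).mean()),
        "replicate_q025": float(np.quantile(reps, 0.025)),
        "replicate_median": float(np.quantile(reps, 0.5)),
        "replicate_q975": float(np.quantile(reps, 0.975)),
    }


# ---------------------------------------------------------------------------
# Resilience rerun
# ---------------------------------------------------------------------------


@dataclass
class ResilienceResult:
    """Outcome of rerunning the consensus analysis on an item subset."""

    scree: ScreeResult
    posterior: GCMPosterior
    classifications: dict[str, "ClassificationResult"]
    changed: dict[str, tuple[str, str]]  #: attr -> (base CCA class, rerun CCA class)


def _consensus_classify(dataset: "SurveyDataset", settings: MCMCSettings):
    from .classify import DichotomizationScheme, binary_matrix, classify_attribute
    from .survey import tally_all

    tallies = tally_all(dataset)
    gcm_data = binary_matrix(dataset, DichotomizationScheme.RELEVANCE)
    scree_data = binary_matrix(dataset, DichotomizationScheme.RELEVANCE_WITH_REVERSE)
    scree = scree_analysis(scree_data)
    posterior = fit_gcm(
        gcm_data,
        chains=settings.chains,
        samples=settings.samples,
        burnin=settings.burnin,
        seed=settings.seed,
        thin=settings.thin,
    )
    truth = dict(zip(posterior.item_ids, posterior.item_truth))
    classifications = {
        attr: classify_attribute(attr, tally, item_truth=truth[attr])
        for attr, tally in tallies.items()
    }
    return scree, posterior, classifications


def resilience_rerun(
    dataset: "SurveyDataset",
    drop_item_ids: list[str],
    settings: MCMCSettings | None = None,
    base_classifications: dict[str, "ClassificationResult"] | None = None,
) -> ResilienceResult:
    """Rerun scree + GCM + consensus classification after dropping items.

    Mirrors the robustness question "do the remaining classifications
    survive removal of high-difficulty, obscure-truth items?".  The full
    pipeline is repeated on the item subset with the same settings;
    ``changed`` lists attributes whose consensus-based classification
    differs from the base run (computed here unless supplied).
    """
    settings = settings or MCMCSettings()
    if base_classifications is None:
        _, _, base_classifications = _consensus_classify(dataset, settings)
    subset = dataset.drop_attributes(drop_item_ids)
    scree, posterior, classifications = _consensus_classify(subset, settings)
    changed = {}
    for attr, res in classifications.items():
        base = base_classifications.get(attr)
        if base is not None and base.cca != res.cca:
            changed[attr] = (str(base.cca), str(res.cca))
    return ResilienceResult(
        scree=scree,
        posterior=posterior,
        classifications=classifications,
        changed=changed,
    )
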