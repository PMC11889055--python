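"""Metropolis-within-Gibbs sampler for the hierarchical multi-group GPCM.

Model
-----
Person ``i`` in group ``j`` answers item ``k`` with GPCM probabilities driven
by a group-specific discrimination ``alpha_kj`` and thresholds ``beta_ckj``.
Latent traits are normal within group, ``theta_i ~ N(mu_j, 1/tau_j)``, with a
diffuse normal prior on each group mean (precision 0.1, i.e. variance 10) and
a Gamma(shape 1, rate 0.1) prior on each group precision.  Group-specific
item-parameter vectors ``xi~_kj = (alpha, beta_1, beta_2)`` sit around
general item parameters ``xi_k`` with a deliberately low precision ``Q``
(0.1 * I by default) — the quasi-fixed-effects device that lets a small
number of groups have essentially free item parameters while still linking
cohorts through the common hierarchy.  The ``xi_k`` are multivariate normal
around a grand mean ``xi_0`` with covariance ``Sigma_xi``, which carries an
inverse-Wishart prior (identity scale, degrees of freedom equal to the
number of item parameters); ``xi_0`` is normal around (1, 0, ..., 0).

Identification
--------------
The latent scale's location and unit are pinned per group by transforming
each draw so the mean threshold over administered items is 0 and the product
of the discriminations is 1.  The transform (``alpha/g``, ``g*beta - m``,
``g*theta - m``, ``g*mu - m``, ``tau/g^2``) leaves every category
probability — hence the likelihood — unchanged, so it can be applied after
each sweep and all stored draws are already identified.

Sampling scheme
---------------
Gibbs for ``mu_j``, ``tau_j``, ``xi_k``, ``xi_0`` and ``Sigma_xi`` (all
conditionally conjugate); random-walk Metropolis for the person traits
(one proposal per person, vectorized) and for each administered
(group, item) parameter block jointly on (log alpha, beta_1, beta_2), so
discriminations stay positive by construction.  Proposal scales adapt during
burn-in toward a 20-50% acceptance rate, then freeze.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import gpcm
from .gpcm import ParamSet, loglik_cells
from .response_data import ResponseDataset, ValidationError


@dataclasses.dataclass
class PriorConfig:
    """Hyperparameters of the hierarchical model (defaults as described in
    the module docstring)."""

    mu_prec: float = 0.1  # precision of the N(0, .) prior on group means
    tau_shape: float = 1.0
    tau_rate: float = 0.1  # Gamma rate on group precisions (see gamma_as_rate)
    gamma_as_rate: bool = True  # False: interpret tau_rate as a scale instead
    q_prec: float = 0.1  # Q = q * I precision of group deviations around xi_k
    r_prec: float = 1.0  # precision of the xi_0 prior around mu_k
    iw_scale: float = 1.0  # inverse-Wishart scale matrix = iw_scale * I
    iw_df: float | None = None  # default: number of item parameters (C + 1)

    def tau_rate_value(self) -> float:
        return self.tau_rate if self.gamma_as_rate else 1.0 / self.tau_rate


@dataclasses.dataclass
class McmcConfig:
    n_burn: int = 1000
    n_keep: int = 10000
    thin: int = 1
    seed: int = 0
    n_chains: int = 1
    theta_scale: float = 0.8
    item_scale: float = 0.2
    adapt_window: int = 25
    identify: bool = True  # apply the per-sweep identification transform

    def __post_init__(self) -> None:
        if self.n_burn < 0 or self.n_keep < 1 or self.thin < 1 or self.n_chains < 1:
            raise ValueError("invalid MCMC configuration")


@dataclasses.dataclass
class LatentState:
    """Person traits and group-level trait distribution parameters."""

    theta: np.ndarray  # (N,)
    mu_theta: np.ndarray  # (J,)
    tau: np.ndarray  # (J,) precisions, > 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.tau) <= 0):
            raise ValueError("group precisions must be > 0")


@dataclasses.dataclass
class HyperState:
    """Item-hierarchy state: general item parameters and their hyperpriors."""

    xi: np.ndarray  # (K, P) general item parameters (alpha mean, beta means)
    xi0: np.ndarray  # (P,) grand mean
    sigma_xi: np.ndarray  # (P, P) covariance of xi_k around xi0
    q_prec: float
    r_prec: float
    d: float
    mu_k: np.ndarray  # (P,) prior means: 1 for alpha, 0 for thresholds


@dataclasses.dataclass
class ModelState:
    """Full parameter state for one draw (used by apply_identification)."""

    params: ParamSet
    latent: LatentState
    group_idx: np.ndarray


def apply_identification(state: ModelState) -> ModelState:
    """Rescale each group to mean-threshold 0 and discrimination-product 1.

    Per group ``j`` over administered items: ``g_j`` is the geometric mean of
    the discriminations and ``m_j`` the mean of the scaled thresholds; the
    transform is ``alpha' = alpha/g``, ``beta' = g*beta - m``,
    ``theta' = g*theta - m`` (persons in j), ``mu' = g*mu - m``,
    ``tau' = tau/g**2``.  The log-likelihood is unchanged.
    """
    p = state.params
    if np.any(p.alpha[p.admin_mask] <= 0):
        raise ValueError("all discriminations must be positive")
    alpha = p.alpha.copy()
    beta = p.beta.copy()
    theta = state.latent.theta.copy()
    mu = state.latent.mu_theta.copy()
    tau = state.latent.tau.copy()
    for j in range(p.n_groups):
        mask = p.admin_mask[j]
        if not mask.any():
            continue
        g = float(np.exp(np.mean(np.log(alpha[j, mask]))))
        scaled = beta[j, mask] * g
        m = float(scaled.mean())
        alpha[j, mask] = alpha[j, mask] / g
        beta[j, mask] = scaled - m
        rows = state.group_idx == j
        theta[rows] = g * theta[rows] - m
        mu[j] = g * mu[j] - m
        tau[j] = tau[j] / g**2
    return ModelState(
        params=ParamSet(alpha, beta, p.admin_mask, p.group_labels, p.item_labels),
        latent=LatentState(theta=theta, mu_theta=mu, tau=tau),
        group_idx=state.group_idx,
    )


class Posterior:
    """Retained, identified posterior draws plus bookkeeping.

    ``draws`` maps parameter names to arrays with a leading (chain, draw)
    pair of axes: ``mu`` (J,), ``tau`` (J,), ``alpha`` (J, K), ``beta``
    (J, K, C), ``xi`` (K, P), ``xi0`` (P,), ``sigma_xi`` (P, P) and
    ``theta`` (N,).
    """

    def __init__(
        self,
        draws: dict,
        admin_mask: np.ndarray,
        group_idx: np.ndarray,
        group_labels: list[str],
        item_labels: list[str],
        C: int,
        mcmc: McmcConfig,
        priors: PriorConfig,
        accept_rates: dict,
        constraint_residuals: dict,
    ) -> None:
        self.draws = draws
        self.admin_mask = admin_mask
        self.group_idx = group_idx
        self.group_labels = group_labels
        self.item_labels = item_labels
        self.C = C
        self.mcmc = mcmc
        self.priors = priors
        self.accept_rates = accept_rates
        self.constraint_residuals = constraint_residuals

    @property
    def n_chains(self) -> int:
        return self.draws["mu"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["mu"].shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains concatenated: shape (n_chains * n_draws, ...)."""
        arr = self.draws[name]
        return arr.reshape((-1,) + arr.shape[2:])

    def mean_paramset(self) -> ParamSet:
        """Posterior-mean group-specific item parameters."""
        alpha = self.stacked("alpha").mean(axis=0)
        beta = self.stacked("beta").mean(axis=0)
        return ParamSet(alpha, beta, self.admin_mask, self.group_labels, self.item_labels)

    @property
    def theta_mean(self) -> np.ndarray:
        return self.stacked("theta").mean(axis=0)

    @property
    def theta_sd(self) -> np.ndarray:
        return self.stacked("theta").std(axis=0, ddof=1)

    def group_mean_summary(self) -> pd.DataFrame:
        """Posterior mean, SD (reported as standard error) and central 95%
        interval of each group's latent-trait mean."""
        mu = self.stacked("mu")
        lo, hi = np.percentile(mu, [2.5, 97.5], axis=0)
        return pd.DataFrame(
            {
                "group": self.group_labels,
                "q2.5": lo,
                "q97.5": hi,
                "mean": mu.mean(axis=0),
                "se": mu.std(axis=0, ddof=1),
            }
        )

    def summary(self) -> pd.DataFrame:
        """Posterior summary (mean, SD, central 95%) for group-level and item
        parameters."""
        rows = []
        for name in ("mu", "tau"):
            arr = self.stacked(name)
            for j, g in enumerate(self.group_labels):
                v = arr[:, j]
                rows.append(_summary_row(f"{name}[{g}]", v))
        alpha = self.stacked("alpha")
        beta = self.stacked("beta")
        for j, g in enumerate(self.group_labels):
            for k, it in enumerate(self.item_labels):
                if not self.admin_mask[j, k]:
                    continue
                rows.append(_summary_row(f"alpha[{g},{it}]", alpha[:, j, k]))
                for c in range(self.C):
                    rows.append(_summary_row(f"beta{c + 1}[{g},{it}]", beta[:, j, k, c]))
        return pd.DataFrame(rows)

    def save(self, prefix) -> None:
        """Write draws to ``<prefix>.npz`` and a JSON manifest to
        ``<prefix>.json``."""
        prefix = Path(prefix)
        np.savez_compressed(
            prefix.with_suffix(".npz"),
            group_idx=self.group_idx,
            admin_mask=self.admin_mask,
            **self.draws,
        )
        manifest = {
            "model": "hierarchical multi-group GPCM",
            "group_labels": self.group_labels,
            "item_labels": self.item_labels,
            "C": self.C,
            "mcmc": dataclasses.asdict(self.mcmc),
            "priors": dataclasses.asdict(self.priors),
            "accept_rates": {k: float(v) for k, v in self.accept_rates.items()},
            "constraint_residuals": {
                k: float(v) for k, v in self.constraint_residuals.items()
            },
        }
        prefix.with_suffix(".json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, prefix) -> "Posterior":
        prefix = Path(prefix)
        manifest = json.loads(prefix.with_suffix(".json").read_text())
        data = np.load(prefix.with_suffix(".npz"))
        draw_names = ("mu", "tau", "alpha", "beta", "xi", "xi0", "sigma_xi", "theta")
        return cls(
            draws={k: data[k] for k in draw_names},
            admin_mask=data["admin_mask"],
            group_idx=data["group_idx"],
            group_labels=manifest["group_labels"],
            item_labels=manifest["item_labels"],
            C=manifest["C"],
            mcmc=McmcConfig(**manifest["mcmc"]),
            priors=PriorConfig(**manifest["priors"]),
            accept_rates=manifest["accept_rates"],
            constraint_residuals=manifest["constraint_residuals"],
        )


def _summary_row(name: str, v: np.ndarray) -> dict:
    lo, hi = np.percentile(v, [2.5, 97.5])
    return {
        "parameter": name,
        "mean": v.mean(),
        "sd": v.std(ddof=1) if v.size > 1 else 0.0,
        "q2.5": lo,
        "q97.5": hi,
    }


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit(
    ds: ResponseDataset,
    mcmc: McmcConfig | None = None,
    priors: PriorConfig | None = None,
) -> Posterior:
    """Run the sampler and return identified posterior draws.

    Requires at least two groups and at least two administered items per
    group (the identification constraints need them).  Reproducible for a
    fixed seed.
    """
    mcmc = mcmc or McmcConfig()
    priors = priors or PriorConfig()
    if ds.n_groups < 2:
        raise ValidationError("invariance analysis needs at least 2 groups")
    if np.any(ds.admin_mask.sum(axis=1) < 2):
        raise ValidationError("every group needs at least 2 administered items")

    children = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    chains = [_run_chain(ds, mcmc, priors, np.random.default_rng(ss)) for ss in children]

    draws = {
        name: np.stack([c["draws"][name] for c in chains])
        for name in chains[0]["draws"]
    }
    accept = {
        k: float(np.mean([c["accept"][k] for c in chains])) for k in chains[0]["accept"]
    }
    residuals = {
        k: float(np.max([c["residuals"][k] for c in chains]))
        for k in chains[0]["residuals"]
    }
    return Posterior(
        draws=draws,
        admin_mask=ds.admin_mask.copy(),
        group_idx=ds.group_idx.copy(),
        group_labels=list(ds.group_labels),
        item_labels=list(ds.item_labels),
        C=ds.C,
        mcmc=mcmc,
        priors=priors,
        accept_rates=accept,
        constraint_residuals=residuals,
    )


def _init_state(ds: ResponseDataset, rng: np.random.Generator):
    """Deterministic, data-driven start: traits from per-group standardized
    sum scores, discriminations 1, thresholds from adjacent-category logits."""
    N, K, J, C = ds.n_persons, ds.n_items, ds.n_groups, ds.C
    obs = ~np.isnan(ds.responses)
    y0 = np.nan_to_num(ds.responses, nan=0.0)
    theta = np.zeros(N)
    if N:
        sums = y0.sum(axis=1)
        for j in range(J):
            rows = ds.group_idx == j
            if rows.sum() == 0:
                continue
            s = sums[rows]
            sd = s.std()
            theta[rows] = (s - s.mean()) / (sd if sd > 0 else 1.0)
    alpha = np.ones((J, K))
    beta = np.zeros((J, K, C))
    for j in range(J):
        rows = ds.group_idx == j
        for k in range(K):
            if not ds.admin_mask[j, k]:
                alpha[j, k] = np.nan
                beta[j, k] = np.nan
                continue
            col = ds.responses[rows, k]
            col = col[~np.isnan(col)]
            counts = np.array([(col == c).sum() for c in range(C + 1)], dtype=float) + 0.5
            beta[j, k] = np.log(counts[:-1] / counts[1:])
    return theta, alpha, beta


def _run_chain(ds: ResponseDataset, mcmc: McmcConfig, priors: PriorConfig, rng) -> dict:
    N, K, J, C = ds.n_persons, ds.n_items, ds.n_groups, ds.C
    P = C + 1
    obs = ~np.isnan(ds.responses)
    y = np.nan_to_num(ds.responses, nan=0.0).astype(int)
    g = ds.group_idx
    admin = ds.admin_mask
    group_rows = [np.where(g == j)[0] for j in range(J)]
    n_per_group = np.array([r.size for r in group_rows])

    theta, alpha, beta = _init_state(ds, rng)
    mu = np.zeros(J)
    tau = np.ones(J)
    xi0 = np.concatenate([[1.0], np.zeros(C)])
    xi = np.where(
        admin.any(axis=0)[:, None],
        np.stack(
            [
                np.concatenate(
                    [
                        [np.nanmean(alpha[:, k]) if admin[:, k].any() else 1.0],
                        (np.nanmean(beta[:, k], axis=0) if admin[:, k].any() else np.zeros(C)),
                    ]
                )
                for k in range(K)
            ]
        ),
        xi0[None, :],
    )
    sigma = np.eye(P)
    mu_k = np.concatenate([[1.0], np.zeros(C)])
    q = priors.q_prec
    r = priors.r_prec
    iw_df = priors.iw_df if priors.iw_df is not None else float(P)
    iw_scale = priors.iw_scale * np.eye(P)
    tau_rate = priors.tau_rate_value()

    theta_scale = np.full(N, mcmc.theta_scale)
    item_scale = np.full((J, K), mcmc.item_scale)
    theta_acc = np.zeros(N)
    item_acc = np.zeros((J, K))
    theta_acc_total = 0.0
    item_acc_total = 0.0
    n_scans = 0

    def cells_for(th, a, b):
        return loglik_cells(y, obs, a[g], b[g], th)

    def group_item_sums(cells):
        out = np.zeros((J, K))
        for j in range(J):
            if group_rows[j].size:
                out[j] = cells[group_rows[j]].sum(axis=0)
        return out

    def identify():
        nonlocal theta, alpha, beta, mu, tau
        for j in range(J):
            mask = admin[j]
            gj = float(np.exp(np.mean(np.log(alpha[j, mask]))))
            scaled = beta[j, mask] * gj
            mj = float(scaled.mean())
            alpha[j, mask] = alpha[j, mask] / gj
            beta[j, mask] = scaled - mj
            rows = group_rows[j]
            theta[rows] = gj * theta[rows] - mj
            mu[j] = gj * mu[j] - mj
            tau[j] = tau[j] / gj**2

    if mcmc.identify:
        identify()

    n_save = mcmc.n_keep // mcmc.thin
    saved = {
        "mu": np.empty((n_save, J)),
        "tau": np.empty((n_save, J)),
        "alpha": np.empty((n_save, J, K)),
        "beta": np.empty((n_save, J, K, C)),
        "xi": np.empty((n_save, K, P)),
        "xi0": np.empty((n_save, P)),
        "sigma_xi": np.empty((n_save, P, P)),
        "theta": np.empty((n_save, N)),
    }
    max_thresh_resid = 0.0
    max_alpha_resid = 0.0
    save_i = 0

    total_iters = mcmc.n_burn + mcmc.n_keep
    # per-cell log-likelihood cache; Gibbs steps and the identification
    # transform leave it invariant, only accepted Metropolis moves update it
    cur_cells = cells_for(theta, alpha, beta)
    for it in range(total_iters):
        in_burn = it < mcmc.n_burn
        if it == mcmc.n_burn:  # drop partial burn-in window counts
            theta_acc[:] = 0.0
            item_acc[:] = 0.0

        # --- person traits: vectorized random-walk Metropolis ---------------
        if N:
            cur_pll = cur_cells.sum(axis=1)
            prop = theta + rng.normal(size=N) * theta_scale
            prop_cells = cells_for(prop, alpha, beta)
            prop_pll = prop_cells.sum(axis=1)
            pri_cur = -0.5 * tau[g] * (theta - mu[g]) ** 2
            pri_prop = -0.5 * tau[g] * (prop - mu[g]) ** 2
            if not (np.all(np.isfinite(cur_pll)) and np.all(np.isfinite(prop_pll))):
                raise RuntimeError(
                    f"non-finite log-posterior at iteration {it}; "
                    f"theta range [{theta.min():.3g}, {theta.max():.3g}]"
                )
            acc = np.log(rng.uniform(size=N)) < (prop_pll + pri_prop - cur_pll - pri_cur)
            theta = np.where(acc, prop, theta)
            cur_cells = np.where(acc[:, None], prop_cells, cur_cells)
            theta_acc += acc

        # --- item parameter blocks: joint RW on (log alpha, beta) -----------
        step = rng.normal(size=(J, K, P)) * item_scale[..., None]
        with np.errstate(invalid="ignore"):
            log_a = np.log(alpha)
            log_a_p = log_a + step[..., 0]
            alpha_p = np.exp(log_a_p)
            beta_p = beta + step[..., 1:]
            prop_cells = cells_for(theta, alpha_p, beta_p)
            L_cur = group_item_sums(cur_cells)
            L_prop = group_item_sums(prop_cells)
            pri_cur = -0.5 * q * (
                (alpha - xi[None, :, 0]) ** 2 + ((beta - xi[None, :, 1:]) ** 2).sum(-1)
            )
            pri_prop = -0.5 * q * (
                (alpha_p - xi[None, :, 0]) ** 2
                + ((beta_p - xi[None, :, 1:]) ** 2).sum(-1)
            )
            logr = (L_prop + pri_prop + log_a_p) - (L_cur + pri_cur + log_a)
            acc = (np.log(rng.uniform(size=(J, K))) < logr) & admin
        alpha = np.where(acc, alpha_p, alpha)
        beta = np.where(acc[..., None], beta_p, beta)
        cur_cells = np.where(acc[g], prop_cells, cur_cells)
        item_acc += acc

        # --- group means and precisions: Gibbs -------------------------------
        sums = np.array([theta[rows].sum() for rows in group_rows])
        post_prec = priors.mu_prec + n_per_group * tau
        post_mean = tau * sums / post_prec
        mu = post_mean + rng.normal(size=J) / np.sqrt(post_prec)
        ss = np.array(
            [((theta[rows] - mu[j]) ** 2).sum() for j, rows in enumerate(group_rows)]
        )
        tau = rng.gamma(
            shape=priors.tau_shape + n_per_group / 2.0,
            scale=1.0 / (tau_rate + 0.5 * ss),
        )

        # --- item hierarchy: Gibbs for xi_k, xi_0, Sigma_xi ------------------
        sigma_inv = _robust_inv(sigma)
        for k in range(K):
            js = np.where(admin[:, k])[0]
            nk = js.size
            obs_sum = np.zeros(P)
            for j in js:
                obs_sum += np.concatenate([[alpha[j, k]], beta[j, k]])
            prec = sigma_inv + nk * q * np.eye(P)
            rhs = sigma_inv @ xi0 + q * obs_sum
            xi[k] = _sample_mvn_from_precision(prec, rhs, rng)
        prec0 = r * np.eye(P) + K * sigma_inv
        rhs0 = r * mu_k + sigma_inv @ xi.sum(axis=0)
        xi0 = _sample_mvn_from_precision(prec0, rhs0, rng)
        dev = xi - xi0
        scale_post = iw_scale + dev.T @ dev
        scale_post = 0.5 * (scale_post + scale_post.T)
        try:
            sigma = stats.invwishart.rvs(df=iw_df + K, scale=scale_post, random_state=rng)
        except np.linalg.LinAlgError:  # pragma: no cover - defensive repair
            scale_post += 1e-8 * np.eye(P)
            sigma = stats.invwishart.rvs(df=iw_df + K, scale=scale_post, random_state=rng)
        sigma = 0.5 * (sigma + sigma.T)

        # --- identification + adaptation -------------------------------------
        if mcmc.identify:
            identify()
        n_scans += 1
        if in_burn and n_scans % mcmc.adapt_window == 0:
            w = mcmc.adapt_window
            rate_t = theta_acc / w
            theta_scale = np.clip(
                theta_scale * np.exp(1.2 * (rate_t - 0.35)), 1e-3, 20.0
            )
            rate_i = item_acc / w
            item_scale = np.clip(item_scale * np.exp(1.2 * (rate_i - 0.35)), 1e-4, 5.0)
            theta_acc[:] = 0.0
            item_acc[:] = 0.0
        if not in_burn:
            theta_acc_total += float(theta_acc.mean()) if N else 0.0
            item_acc_total += float(item_acc[admin].mean())
            theta_acc[:] = 0.0
            item_acc[:] = 0.0
            kept = it - mcmc.n_burn
            if kept % mcmc.thin == 0 and save_i < n_save:
                saved["mu"][save_i] = mu
                saved["tau"][save_i] = tau
                saved["alpha"][save_i] = alpha
                saved["beta"][save_i] = beta
                saved["xi"][save_i] = xi
                saved["xi0"][save_i] = xi0
                saved["sigma_xi"][save_i] = sigma
                saved["theta"][save_i] = theta
                for j in range(J):
                    mask = admin[j]
                    max_thresh_resid = max(max_thresh_resid, abs(float(beta[j, mask].mean())))
                    max_alpha_resid = max(
                        max_alpha_resid, abs(float(np.prod(alpha[j, mask])) - 1.0)
                    )
                save_i += 1

    return {
        "draws": saved,
        "accept": {
            "theta": theta_acc_total / max(mcmc.n_keep, 1),
            "items": item_acc_total / max(mcmc.n_keep, 1),
        },
        "residuals": {
            "max_mean_threshold": max_thresh_resid,
            "max_alpha_product_dev": max_alpha_resid,
        },
    }


def _robust_inv(m: np.ndarray) -> np.ndarray:
    """Inverse of a symmetric PD matrix, with jitter repair if needed."""
    try:
        return np.linalg.inv(m)
    except np.linalg.LinAlgError:
        return np.linalg.inv(m + 1e-8 * np.eye(m.shape[0]))


def _sample_mvn_from_precision(prec: np.ndarray, rhs: np.ndarray, rng) -> np.ndarray:
    """Draw from N(prec^-1 rhs, prec^-1) via Cholesky of the precision."""
    try:
        L = np.linalg.cholesky(prec)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(prec + 1e-8 * np.eye(prec.shape[0]))
    mean = np.linalg.solve(prec, rhs)
    z = rng.standard_normal(prec.shape[0])
    return mean + np.linalg.solve(L.T, z)


# ---------------------------------------------------------------------------
# diagnostics and scoring
# ---------------------------------------------------------------------------


def convergence_diagnostics(source, rhat_threshold: float = 1.05) -> pd.DataFrame:
    """Split-R-hat and effective sample size per parameter (via arviz).

    ``source`` is a :class:`Posterior` or a dict mapping names to arrays with
    a leading (chain, draw) pair of axes.  A single chain is split in half.
    Parameters with R-hat above ``rhat_threshold`` (or non-finite) are
    flagged.  Requires at least 50 draws.
    """
    import arviz as az

    if isinstance(source, Posterior):
        arrays = {"mu": source.draws["mu"], "tau": source.draws["tau"]}
        alpha = source.draws["alpha"]
        beta = source.draws["beta"]
        for j, gl in enumerate(source.group_labels):
            for k, il in enumerate(source.item_labels):
                if not source.admin_mask[j, k]:
                    continue
                arrays[f"alpha[{gl},{il}]"] = alpha[:, :, j, k]
                for c in range(source.C):
                    arrays[f"beta{c + 1}[{gl},{il}]"] = beta[:, :, j, k, c]
    else:
        arrays = dict(source)

    rows = []
    for name, arr in arrays.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        n_draws = arr.shape[1]
        if n_draws < 50:
            raise ValueError(f"need at least 50 draws for diagnostics, got {n_draws}")
        if arr.shape[0] == 1:  # split a single chain into two half-chains
            half = n_draws // 2
            arr = np.stack([arr[0, :half], arr[0, half : 2 * half]])
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        for idx in range(flat.shape[2]):
            sub = flat[:, :, idx]
            data = az.convert_to_dataset(sub)
            with np.errstate(invalid="ignore", divide="ignore"):
                rhat = float(az.rhat(data)["x"].values)
                ess = float(az.ess(data)["x"].values)
            label = name if flat.shape[2] == 1 else f"{name}[{idx}]"
            rows.append(
                {
                    "parameter": label,
                    "rhat": rhat,
                    "ess": ess,
                    "flagged": bool(not np.isfinite(rhat) or rhat > rhat_threshold),
                }
            )
    return pd.DataFrame(rows)


def score_persons(posterior: Posterior) -> pd.DataFrame:
    """Harmonized person scores: posterior mean and SD of each trait.

    One row per person; scores live on the common identified latent scale,
    so they are comparable across cohorts regardless of which instrument
    subset each cohort received.
    """
    return pd.DataFrame(
        {
            "person": np.arange(posterior.group_idx.size),
            "group": [posterior.group_labels[j] for j in posterior.group_idx],
            "theta_mean": posterior.theta_mean,
            "theta_sd": posterior.theta_sd,
        }
    )
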