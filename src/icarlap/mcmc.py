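"""Self-contained Metropolis-within-Gibbs sampler for validation.

A deliberately simple Bayesian counterpart to the Laplace MLE path: flat
priors on the intercept and coefficients, a weakly-informative normal prior
on ``log tau``, single-site random-walk updates of the spatial field
(vectorized over graph colour classes) and hard per-sweep sum-to-zero
recentring with the removed mean absorbed into the intercept.  Used only to
cross-check the MLEs — it is not a WinBUGS replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelData, ModelInputError

__all__ = ["mcmc_crosscheck", "McmcSummary"]


@dataclass
class McmcSummary:
    table: pd.DataFrame          # rows: parameter; cols: mean, sd, rhat
    converged: bool
    n_chains: int
    n_iterations: int
    n_kept: int

    def mean(self, name: str) -> float:
        return float(self.table.loc[name, "mean"])

    def sd(self, name: str) -> float:
        return float(self.table.loc[name, "sd"])


def _greedy_coloring(n: int, neighbors: list[np.ndarray]) -> list[np.ndarray]:
    color = np.full(n, -1)
    for i in range(n):
        used = {color[j] for j in neighbors[i] if color[j] >= 0}
        c = 0
        while c in used:
            c += 1
        color[i] = c
    return [np.nonzero(color == c)[0] for c in range(color.max() + 1)]


def _split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction (chains x draws)."""
    half = draws.shape[1] // 2
    chains = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    m, n = chains.shape
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return np.inf if b > 0 else 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def mcmc_crosscheck(
    data: ModelData,
    chains: int = 2,
    iterations: int = 4000,
    seed: int = 0,
    burn_fraction: float = 0.5,
    log_tau_prior_sd: float = 3.0,
) -> McmcSummary:
    """Posterior means/SDs and split R-hat for (beta0, beta, log tau, tau2).

    Requires a connected graph (the intercept absorbs the recentred field
    mean, which is only well-defined with one component) and at least 2000
    iterations.  Summary is flagged unconverged when any R-hat > 1.1.
    """
    if iterations < 2000:
        raise ModelInputError("mcmc_crosscheck needs iterations >= 2000")
    graph = data.graph
    if graph.n_components != 1:
        raise ModelInputError("mcmc_crosscheck requires a connected graph")
    n = graph.n_regions
    p = data.n_covariates
    y, E, X = data.y, data.E, data.X
    log_E = np.log(E)
    W = graph.W.tocsr()
    deg = graph.degrees
    neighbors = [W.indices[W.indptr[i] : W.indptr[i + 1]] for i in range(n)]
    blocks = _greedy_coloring(n, neighbors)
    rank = graph.rank_Q

    burn = int(burn_fraction * iterations)
    kept = iterations - burn
    names = ["beta0"] + [f"beta{j + 1}" for j in range(p)] + ["log_tau", "tau2"]
    all_draws = np.empty((chains, kept, len(names)))

    for chain in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, chain]))
        beta0 = float(np.log(y.sum() / E.sum())) if y.sum() > 0 else 0.0
        beta = np.zeros(p)
        log_tau = float(rng.normal(0.0, 0.3))
        s = np.zeros(n)
        step_s = np.full(n, 0.5)
        step_b0 = 0.1
        step_b = np.full(p, 0.1)
        step_lt = 0.3
        acc_s = np.zeros(n)
        acc_b0 = acc_lt = 0.0
        acc_b = np.zeros(p)

        def log_risk():
            return beta0 + (X @ beta if p else 0.0) + s

        for it in range(iterations):
            tau2 = np.exp(2.0 * log_tau)
            # --- spatial field, colour-blocked single-site Metropolis ---
            lr = log_risk()
            mu = E * np.exp(lr)
            for idx in blocks:
                eps = rng.normal(0.0, step_s[idx])
                s_new = s[idx] + eps
                wsum = np.asarray(W[idx] @ s).ravel()
                # local joint log-density difference for each site in the block
                d_quad = (
                    deg[idx] * (s_new**2 - s[idx] ** 2)
                    - 2.0 * wsum * (s_new - s[idx])
                ) / (2.0 * tau2)
                lr_new = lr[idx] + eps
                d_pois = y[idx] * eps - E[idx] * (np.exp(lr_new) - np.exp(lr[idx]))
                accept = np.log(rng.uniform(size=idx.size)) < (d_pois - d_quad)
                s[idx] = np.where(accept, s_new, s[idx])
                lr[idx] = np.where(accept, lr_new, lr[idx])
                acc_s[idx] += accept
            # hard recentring; intercept absorbs the shift
            shift = s.mean()
            s -= shift
            beta0 += shift

            # --- intercept ---
            lr = log_risk()
            loglik = float(y @ lr - (E * np.exp(lr)).sum())
            prop = float(rng.normal(beta0, step_b0))
            lr_prop = lr + (prop - beta0)
            loglik_prop = float(y @ lr_prop - (E * np.exp(lr_prop)).sum())
            if np.log(rng.uniform()) < loglik_prop - loglik:
                beta0, lr, loglik = prop, lr_prop, loglik_prop
                acc_b0 += 1

            # --- coefficients ---
            for j in range(p):
                prop = float(rng.normal(beta[j], step_b[j]))
                lr_prop = lr + (prop - beta[j]) * X[:, j]
                loglik_prop = float(y @ lr_prop - (E * np.exp(lr_prop)).sum())
                if np.log(rng.uniform()) < loglik_prop - loglik:
                    beta[j], lr, loglik = prop, lr_prop, loglik_prop
                    acc_b[j] += 1

            # --- log tau (field density + weak prior) ---
            quad = graph.quadratic(s)
            def lt_dens(lt):
                return (
                    -quad / (2.0 * np.exp(2.0 * lt))
                    - rank * lt
                    - 0.5 * (lt / log_tau_prior_sd) ** 2
                )
            prop = float(rng.normal(log_tau, step_lt))
            if np.log(rng.uniform()) < lt_dens(prop) - lt_dens(log_tau):
                log_tau = prop
                acc_lt += 1

            # --- adapt proposal scales during burn-in ---
            if it < burn and (it + 1) % 50 == 0:
                tgt = 0.44
                step_s *= np.exp((acc_s / 50.0 - tgt))
                step_s = np.clip(step_s, 1e-3, 10.0)
                step_b0 *= np.exp(acc_b0 / 50.0 - tgt)
                step_lt *= np.exp(acc_lt / 50.0 - tgt)
                if p:
                    step_b *= np.exp(acc_b / 50.0 - tgt)
                    step_b = np.clip(step_b, 1e-4, 10.0)
                acc_s[:] = 0.0
                acc_b0 = acc_lt = 0.0
                acc_b[:] = 0.0

            if it >= burn:
                row = [beta0, *beta, log_tau, np.exp(2.0 * log_tau)]
                all_draws[chain, it - burn, :] = row

    table = pd.DataFrame(
        {
            "mean": all_draws.reshape(-1, len(names)).mean(axis=0),
            "sd": all_draws.reshape(-1, len(names)).std(axis=0, ddof=1),
            "rhat": [_split_rhat(all_draws[:, :, j]) for j in range(len(names))],
        },
        index=names,
    )
    converged = bool((table["rhat"] <= 1.1).all())
    return McmcSummary(
        table=table,
        converged=converged,
        n_chains=chains,
        n_iterations=iterations,
        n_kept=kept,
    )
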