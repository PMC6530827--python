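"""Co-expression network reconstruction.

Five estimators of gene–gene association, all consuming a genes × samples
log-signal matrix and emitting a thresholded :class:`~gcnbench.network.Network`:

* ``pearson`` / ``spearman`` — marginal correlation, hard threshold on |r|;
* ``genenet`` — Schäfer–Strimmer shrinkage partial correlations with a
  two-component mixture model giving a posterior edge probability;
* ``space`` — sparse partial correlation estimation by joint L1-penalized
  regression (coordinate descent with soft thresholding);
* ``wgcna`` — soft-threshold adjacency |r|^beta with the topological
  overlap matrix for downstream robustness analysis.

Thresholds are monotone: raising any of them can only remove edges.
Genes left without a surviving edge are excluded from the network.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, gammaln
from scipy.stats import linregress, rankdata

from .errors import ConfigurationError, ConvergenceError
from .network import Network

__all__ = [
    "correlation_network",
    "correlation_matrix",
    "genenet_network",
    "genenet_posteriors",
    "space_network",
    "space_pcor",
    "wgcna_network",
    "wgcna_adjacency",
    "select_soft_power",
    "network_from_scores",
]


def _drop_zero_variance(matrix: pd.DataFrame) -> pd.DataFrame:
    sd = matrix.std(axis=1, ddof=1)
    bad = matrix.index[(sd == 0) | sd.isna()]
    if len(bad):
        warnings.warn(
            f"skipping {len(bad)} zero-variance gene(s): {list(map(str, bad[:5]))}"
        )
        matrix = matrix.drop(index=bad)
    return matrix


def _check_threshold(name: str, value: float) -> None:
    if not 0.0 < value <= 1.0:
        raise ConfigurationError(f"{name} must lie in (0, 1], got {value}")


def network_from_scores(
    genes: list[str],
    scores: np.ndarray,
    threshold: float,
    weights: np.ndarray | None = None,
    unsigned: bool = True,
) -> Network:
    """Threshold a symmetric score matrix into a network.

    Edge (i, j) iff ``|score| >= threshold`` (unsigned) or
    ``score >= threshold`` (signed); edge weight comes from ``weights``
    (default: the score itself).
    """
    if weights is None:
        weights = scores
    mask = np.abs(scores) >= threshold if unsigned else scores >= threshold
    net = Network()
    iu, ju = np.triu_indices(len(genes), k=1)
    for i, j in zip(iu[mask[iu, ju]], ju[mask[iu, ju]]):
        net.add_edge(genes[i], genes[j], float(weights[i, j]))
    return net


def correlation_matrix(matrix: pd.DataFrame, method: str = "pearson") -> tuple[list[str], np.ndarray]:
    """Pairwise gene correlation; rank-transformed first for spearman."""
    if method not in ("pearson", "spearman"):
        raise ConfigurationError(f"correlation method must be pearson or spearman, got {method!r}")
    matrix = _drop_zero_variance(matrix)
    if matrix.shape[0] < 2 or matrix.shape[1] < 3:
        raise ConfigurationError("need at least 2 genes and 3 samples")
    x = matrix.to_numpy(dtype=float)
    if method == "spearman":
        x = rankdata(x, axis=1)
    r = np.clip(np.corrcoef(x), -1.0, 1.0)
    # snap float roundoff so exact linear dependence yields |r| = 1 exactly
    snap = np.abs(r) > 1.0 - 1e-12
    r[snap] = np.sign(r[snap])
    np.fill_diagonal(r, 0.0)
    return [str(g) for g in matrix.index], r


def correlation_network(
    matrix: pd.DataFrame,
    method: str = "pearson",
    r_threshold: float = 0.8,
    unsigned: bool = True,
) -> Network:
    """Hard-thresholded correlation network (weight = r)."""
    _check_threshold("r_threshold", r_threshold)
    genes, r = correlation_matrix(matrix, method)
    return network_from_scores(genes, r, r_threshold, unsigned=unsigned)


# --------------------------------------------------------------------------
# GeneNet-style shrinkage partial correlations + mixture posterior


def _shrinkage_pcor(matrix: pd.DataFrame, shrinkage: float | None) -> tuple[list[str], np.ndarray, float]:
    matrix = _drop_zero_variance(matrix)
    p, n = matrix.shape
    if n < 4:
        raise ConfigurationError("need at least 4 samples for partial correlations")
    x = matrix.to_numpy(dtype=float)
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    r = (z @ z.T) / (n - 1)

    if shrinkage is None:
        # analytic shrinkage intensity (Schäfer & Strimmer): ratio of the
        # summed sampling variances of r_ij to the summed squared r_ij
        w = z[:, None, :] * z[None, :, :]  # p x p x n products
        w_bar = w.mean(axis=2)
        var_r = n / (n - 1) ** 3 * ((w - w_bar[:, :, None]) ** 2).sum(axis=2)
        iu = np.triu_indices(p, k=1)
        denom = (r[iu] ** 2).sum()
        lam = float(np.clip(var_r[iu].sum() / denom, 0.0, 1.0)) if denom > 0 else 1.0
    else:
        lam = float(np.clip(shrinkage, 0.0, 1.0))

    r_star = lam * np.eye(p) + (1.0 - lam) * r
    np.fill_diagonal(r_star, 1.0)
    try:
        omega = np.linalg.inv(r_star)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "shrunk correlation matrix is singular; raise the shrinkage floor"
        ) from exc
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    pcor = (pcor + pcor.T) / 2.0
    np.fill_diagonal(pcor, 0.0)
    return [str(g) for g in matrix.index], pcor, lam


def _log_f0(r: np.ndarray, kappa: float) -> np.ndarray:
    """Log density of the null partial correlation distribution,
    f0(r; kappa) ∝ (1 - r^2)^((kappa-3)/2) on [-1, 1]."""
    log_c = gammaln(kappa / 2.0) - 0.5 * math.log(math.pi) - gammaln((kappa - 1.0) / 2.0)
    return log_c + 0.5 * (kappa - 3.0) * np.log1p(-np.clip(r, -1, 1) ** 2 + 1e-300)


def _fit_null_mixture(r: np.ndarray, n_samples: int, n_genes: int) -> tuple[float, float]:
    """ML fit of eta0 * f0(r; kappa) + (1 - eta0) * Uniform[-1, 1].

    kappa is bounded below by the theoretical null degrees of freedom of
    unshrunk partial correlations, ~ n - p; shrinkage only concentrates
    the null further (larger kappa), so the bound is safe and keeps the
    fit identified when few pairs are observed.
    """
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    kappa_lb = max(4.0, float(n_samples - n_genes))

    def nll(params: np.ndarray) -> float:
        eta0 = expit(params[0])
        kappa = kappa_lb + math.exp(params[1])
        f = eta0 * np.exp(_log_f0(r, kappa)) + (1.0 - eta0) * 0.5
        return -float(np.log(f + 1e-300).sum())

    starts = [
        np.array([2.0, math.log(max(n_samples, 5.0))]),
        np.array([0.0, math.log(max(n_samples, 5.0))]),
        np.array([2.0, math.log(5.0)]),
    ]
    best = None
    for s in starts:
        res = optimize.minimize(nll, s, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    eta0 = float(expit(best.x[0]))
    kappa = float(kappa_lb + min(math.exp(best.x[1]), 1e8))
    return eta0, kappa


def genenet_posteriors(
    matrix: pd.DataFrame, shrinkage: float | None = None
) -> tuple[list[str], np.ndarray, np.ndarray, dict]:
    """Shrinkage partial correlations and per-pair posterior edge probabilities.

    Returns (genes, pcor matrix, posterior matrix, fit info). The posterior
    of a pair is the mixture weight of the non-null (uniform) component at
    its observed partial correlation.
    """
    genes, pcor, lam = _shrinkage_pcor(matrix, shrinkage)
    p = len(genes)
    n = matrix.shape[1]
    iu = np.triu_indices(p, k=1)
    r = pcor[iu]
    eta0, kappa = _fit_null_mixture(r, n, p)
    f0 = np.exp(_log_f0(r, kappa))
    f = eta0 * f0 + (1.0 - eta0) * 0.5
    post_flat = (1.0 - eta0) * 0.5 / np.maximum(f, 1e-300)
    post = np.zeros((p, p))
    post[iu] = post_flat
    post = post + post.T
    info = {"lambda_star": lam, "eta0": eta0, "kappa": kappa}
    return genes, pcor, post, info


def genenet_network(
    matrix: pd.DataFrame,
    omega: float = 0.9,
    shrinkage: float | None = None,
    omega_on_pcor: bool = False,
) -> Network:
    """GeneNet-style network: edge iff posterior edge probability >= omega.

    ``omega_on_pcor`` switches to thresholding |pcor| directly, bypassing
    the mixture model. Edge weight is the partial correlation.
    """
    _check_threshold("omega", omega)
    if omega_on_pcor:
        genes, pcor, _ = _shrinkage_pcor(matrix, shrinkage)
        return network_from_scores(genes, pcor, omega, unsigned=True)
    genes, pcor, post, _ = genenet_posteriors(matrix, shrinkage)
    return network_from_scores(genes, post, omega, weights=pcor, unsigned=True)


# --------------------------------------------------------------------------
# SPACE: sparse partial correlation estimation


def space_pcor(
    matrix: pd.DataFrame,
    lambda_scale: float = 1.0,
    n_outer: int = 3,
    max_sweeps: int = 250,
    tol: float = 5e-4,
) -> tuple[list[str], np.ndarray]:
    """Joint sparse regression estimate of the partial correlation matrix.

    Minimizes  (1/2) sum_i ||X_i - sum_{j!=i} rho_ij sqrt(s_jj/s_ii) X_j||^2
    + lambda * sum_{i<j} |rho_ij|  by coordinate descent over gene pairs,
    pooling the two regressions each rho_ij appears in; residual
    precisions s_ii are refreshed between outer iterations. The penalty is
    lambda = lambda_scale * sqrt(n log p) on column-standardized data.
    """
    if lambda_scale <= 0:
        raise ConfigurationError("lambda_scale must be positive")
    matrix = _drop_zero_variance(matrix)
    p, n = matrix.shape
    if n < 4:
        raise ConfigurationError("need at least 4 samples")
    genes = [str(g) for g in matrix.index]
    x = matrix.to_numpy(dtype=float).T  # n x p, columns = genes
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    lam = lambda_scale * math.sqrt(n * math.log(p))
    ssq = (x**2).sum(axis=0)

    rho = np.zeros((p, p))
    d = np.ones(p)  # diagonal precision estimates s_ii
    resid = x.copy()
    all_pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    last_change = np.inf

    def sweep(pairs: list[tuple[int, int]]) -> float:
        max_delta = 0.0
        for i, j in pairs:
            old = rho[i, j]
            sji = math.sqrt(d[j] / d[i])
            sij = 1.0 / sji
            den = d[j] / d[i] * ssq[j] + d[i] / d[j] * ssq[i]
            num = sji * (x[:, j] @ resid[:, i]) + sij * (x[:, i] @ resid[:, j]) + old * den
            new = math.copysign(max(abs(num) - lam, 0.0), num) / den
            if new != old:
                resid[:, i] += (old - new) * sji * x[:, j]
                resid[:, j] += (old - new) * sij * x[:, i]
                rho[i, j] = rho[j, i] = new
                max_delta = max(max_delta, abs(new - old))
        return max_delta

    def objective() -> float:
        return 0.5 * float((resid**2).sum()) + lam * float(
            np.abs(rho[np.triu_indices(p, 1)]).sum()
        )

    for outer in range(n_outer):
        prev_obj = np.inf
        converged = False
        sweeps_left = max_sweeps
        while sweeps_left > 0:
            # full pass over all pairs, then cheap passes over the active set
            last_change = sweep(all_pairs)
            sweeps_left -= 1
            obj = objective()
            assert obj <= prev_obj + 1e-8, "coordinate-descent objective increased"
            prev_obj = obj
            if last_change < tol:
                converged = True
                break
            active = [(i, j) for i, j in all_pairs if rho[i, j] != 0.0]
            while sweeps_left > 0 and active:
                last_change = sweep(active)
                sweeps_left -= 1
                obj = objective()
                assert obj <= prev_obj + 1e-8, "coordinate-descent objective increased"
                prev_obj = obj
                if last_change < tol:
                    break
        if not converged and last_change >= tol:
            raise ConvergenceError(
                f"SPACE did not converge within {max_sweeps} sweeps "
                f"(last max |delta rho| = {last_change:.3e})",
                last_change=last_change,
            )
        if outer < n_outer - 1:
            d = n / np.maximum((resid**2).sum(axis=0), 1e-12)
            # rebuild residuals under the new precisions
            b = rho * np.sqrt(d[None, :] / d[:, None])  # b[i, j]: coef of X_j in regression i
            np.fill_diagonal(b, 0.0)
            resid = x - x @ b.T
    return genes, rho


def space_network(
    matrix: pd.DataFrame,
    rho_threshold: float = 0.68,
    lambda_scale: float = 1.0,
    **kwargs,
) -> Network:
    """SPACE network: edge iff |rho_hat| >= rho_threshold (weight = rho_hat)."""
    _check_threshold("rho_threshold", rho_threshold)
    genes, rho = space_pcor(matrix, lambda_scale=lambda_scale, **kwargs)
    return network_from_scores(genes, rho, rho_threshold, unsigned=True)


# --------------------------------------------------------------------------
# WGCNA: soft-threshold adjacency and topological overlap


def wgcna_adjacency(matrix: pd.DataFrame, beta: int = 5) -> tuple[list[str], np.ndarray]:
    if not (isinstance(beta, (int, np.integer)) and beta >= 1):
        raise ConfigurationError(f"beta must be an integer >= 1, got {beta!r}")
    genes, r = correlation_matrix(matrix, "pearson")
    a = np.abs(r) ** beta
    np.fill_diagonal(a, 0.0)
    return genes, a


def wgcna_network(
    matrix: pd.DataFrame, beta: int = 5, tau: float = 0.33
) -> tuple[Network, pd.DataFrame]:
    """Soft-threshold network plus its topological overlap matrix.

    Adjacency a_ij = |r_ij|^beta; TOM_ij = (sum_u a_iu a_uj + a_ij) /
    (min(k_i, k_j) + 1 - a_ij). Edges are thresholded on the adjacency
    (a_ij >= tau); the TOM is returned for robustness analysis.
    """
    _check_threshold("tau", tau)
    genes, a = wgcna_adjacency(matrix, beta)
    k = a.sum(axis=1)
    shared = a @ a
    k_min = np.minimum.outer(k, k)
    tom = (shared + a) / (k_min + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    net = network_from_scores(genes, a, tau, unsigned=True)
    return net, pd.DataFrame(tom, index=genes, columns=genes)


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float | None:
    """R^2 of log-frequency vs log-degree for binned weighted degrees."""
    k = k[k > 0]
    if k.size < 3 or np.allclose(k, k[0]):
        return None
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    if keep.sum() < 3:
        return None
    fit = linregress(np.log(centers[keep]), np.log(counts[keep] / counts.sum()))
    return float(fit.rvalue**2)


def select_soft_power(
    matrix: pd.DataFrame,
    betas: list[int] = tuple(range(1, 13)),
    r2_target: float = 0.8,
) -> int:
    """Lowest soft power whose weighted-degree distribution fits the
    scale-free model at R^2 >= r2_target; falls back to the argmax-R^2
    power with a warning when no power qualifies."""
    betas = list(betas)
    if not betas or sorted(betas) != betas:
        raise ConfigurationError("betas must be a non-empty ascending list")
    r2s: dict[int, float] = {}
    for beta in betas:
        _, a = wgcna_adjacency(matrix, beta)
        r2 = _scale_free_r2(a.sum(axis=1))
        if r2 is None:
            continue  # degenerate degree distribution at this power
        if r2 >= r2_target:
            return beta
        r2s[beta] = r2
    if not r2s:
        raise ConfigurationError("scale-free fit undefined for every candidate power")
    best = max(r2s, key=lambda b: r2s[b])
    warnings.warn(
        f"no soft power reached scale-free R^2 >= {r2_target}; "
        f"returning argmax beta={best} (R^2 = {r2s[best]:.3f})"
    )
    return best
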