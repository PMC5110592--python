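"""Latent profile analysis (Gaussian mixtures) on composite indicators.

LPA is the continuous-indicator analogue of LCA: each class has a vector
of indicator means, and the indicator variances are diagonal and, by
default, shared across classes (``equal_diagonal``), matching the common
default of commercial mixture software; a free per-class diagonal is
available.  Fitting is EM with multiple starts, a variance floor, and the
same expected-total label ordering as the LCA so class numbers line up.

The module also provides the LCA/LPA agreement cross-tabulation: classes
from the two solutions are matched (greedy maximal overlap by default, or
optimal assignment), and agreement is the fraction of respondents on the
matched diagonal.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from ._rng import substream

__all__ = ["ProfileFit", "fit_lpa", "lpa_loglik", "crosstab_agreement", "AgreementResult"]

VAR_FLOOR = 1e-4


@dataclasses.dataclass
class ProfileFit:
    """A fitted K-class Gaussian profile mixture (diagonal covariance)."""

    n_classes: int
    weights: np.ndarray
    means: np.ndarray  # K x D
    variances: np.ndarray  # K x D (rows identical under equal_diagonal)
    mean_se: np.ndarray  # K x D, posterior-weighted information approximation
    covariance: str
    loglik: float
    n_params: int
    posterior: np.ndarray
    assignment: np.ndarray
    converged: bool
    degenerate: bool
    loglik_trace: np.ndarray


@dataclasses.dataclass
class AgreementResult:
    table: pd.DataFrame  # contingency, rows = assignment_a, cols = assignment_b
    mapping: dict[int, int]  # b-class -> a-class
    overall: float
    per_class: pd.DataFrame
    method: str


def _log_gauss(x: np.ndarray, mu: np.ndarray, var: np.ndarray) -> np.ndarray:
    """(n, K) log densities for diagonal Gaussians."""
    diff = x[:, None, :] - mu[None, :, :]  # n x K x D
    return -0.5 * (np.log(2 * np.pi * var)[None] + diff**2 / var[None]).sum(axis=2)


def _em_gauss(x, pi0, mu0, var0, covariance, tol, max_iter):
    n, d = x.shape
    pi, mu, var = pi0.copy(), mu0.copy(), np.maximum(var0, VAR_FLOOR)
    trace, converged = [], False
    post = None
    for _ in range(max_iter):
        log_joint = _log_gauss(x, mu, var) + np.log(pi)
        ll_rows = logsumexp(log_joint, axis=1)
        trace.append(float(ll_rows.sum()))
        post = np.exp(log_joint - ll_rows[:, None])
        nk = np.clip(post.sum(axis=0), 1e-10, None)
        pi = nk / n
        mu = (post.T @ x) / nk[:, None]
        sq = np.einsum("nk,nkd->kd", post, (x[:, None, :] - mu[None]) ** 2)
        if covariance == "equal_diagonal":
            shared = sq.sum(axis=0) / n
            var = np.tile(np.maximum(shared, VAR_FLOOR), (len(pi), 1))
        else:
            var = np.maximum(sq / nk[:, None], VAR_FLOOR)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            break
    # report the likelihood and posterior of the *returned* parameters
    log_joint = _log_gauss(x, mu, var) + np.log(pi)
    ll_rows = logsumexp(log_joint, axis=1)
    trace.append(float(ll_rows.sum()))
    post = np.exp(log_joint - ll_rows[:, None])
    return pi, mu, var, trace[-1], post, converged, trace


def fit_lpa(
    indicators: pd.DataFrame,
    n_classes: int,
    covariance: str = "equal_diagonal",
    n_starts: int = 50,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
    kmeans_start: bool = True,
) -> ProfileFit:
    """Fit a Gaussian profile mixture by EM; best of ``n_starts`` starts."""
    if covariance not in ("equal_diagonal", "free_diagonal"):
        raise ValueError(f"unknown covariance structure {covariance!r}")
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    x = indicators.to_numpy(dtype=float)
    n, d = x.shape
    if n_classes == 1:
        mu = x.mean(axis=0, keepdims=True)
        var = np.maximum(x.var(axis=0, ddof=0, keepdims=True), VAR_FLOOR)
        ll = float(_log_gauss(x, mu, var).sum())
        return ProfileFit(
            n_classes=1,
            weights=np.array([1.0]),
            means=mu,
            variances=var,
            mean_se=np.sqrt(var / n),
            covariance=covariance,
            loglik=ll,
            n_params=2 * d,
            posterior=np.ones((n, 1)),
            assignment=np.zeros(n, dtype=int),
            converged=True,
            degenerate=False,
            loglik_trace=np.array([ll]),
        )
    rng = substream(seed, 41)
    sample_var = np.maximum(x.var(axis=0, ddof=0), VAR_FLOOR)
    best = None
    any_converged = False
    for s in range(max(1, n_starts)):
        if s == 0 and kmeans_start:
            km = KMeans(n_clusters=n_classes, n_init=2, random_state=int(seed) % (2**31))
            lab = km.fit_predict(x)
            mu0 = np.vstack([
                x[lab == c].mean(axis=0) if np.any(lab == c) else x[rng.integers(n)]
                for c in range(n_classes)
            ])
            pi0 = np.clip(np.bincount(lab, minlength=n_classes) / n, 0.01, None)
            pi0 /= pi0.sum()
        else:
            pi0 = rng.dirichlet(np.ones(n_classes))
            mu0 = x[rng.choice(n, n_classes, replace=False)]
        var0 = np.tile(sample_var, (n_classes, 1))
        result = _em_gauss(x, pi0, mu0, var0, covariance, tol, max_iter)
        any_converged = any_converged or result[5]
        if best is None or result[3] > best[3]:
            best = result
    if not any_converged:
        raise RuntimeError("no EM start converged")
    pi, mu, var, ll, post, converged, trace = best
    order = np.argsort(mu.sum(axis=1))
    pi, mu, var, post = pi[order], mu[order], var[order], post[:, order]
    degenerate = bool(np.any(var <= VAR_FLOOR * (1 + 1e-9)))
    if degenerate:
        warnings.warn("variance collapsed to the floor: degenerate solution", RuntimeWarning)
    n_var = d if covariance == "equal_diagonal" else n_classes * d
    nk = np.clip(post.sum(axis=0), 1e-10, None)
    return ProfileFit(
        n_classes=n_classes,
        weights=pi,
        means=mu,
        variances=var,
        mean_se=np.sqrt(var / nk[:, None]),
        covariance=covariance,
        loglik=ll,
        n_params=(n_classes - 1) + n_classes * d + n_var,
        posterior=post,
        assignment=post.argmax(axis=1),
        converged=converged,
        degenerate=degenerate,
        loglik_trace=np.asarray(trace),
    )


def lpa_loglik(indicators: pd.DataFrame, weights, means, variances) -> float:
    """Log-likelihood of fixed LPA parameters."""
    x = indicators.to_numpy(dtype=float)
    log_joint = _log_gauss(x, np.asarray(means, float), np.asarray(variances, float)) + np.log(
        np.asarray(weights, float)
    )
    return float(logsumexp(log_joint, axis=1).sum())


def crosstab_agreement(assignment_a, assignment_b, method: str = "greedy") -> AgreementResult:
    """Matched-class contingency table and percent agreement.

    Classes of ``assignment_b`` are matched to classes of ``assignment_a``
    either greedily (repeatedly take the largest remaining cell) or by
    optimal assignment (Hungarian algorithm maximizing the diagonal).
    Per-class agreement is the matched cell divided by the a-class size.
    """
    a = np.asarray(assignment_a)
    b = np.asarray(assignment_b)
    if len(a) != len(b):
        raise ValueError("assignments must cover the same respondents")
    table = pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))
    counts = table.to_numpy()
    if method == "optimal":
        rows, cols = linear_sum_assignment(-counts)
        pairs = list(zip(rows, cols))
    elif method == "greedy":
        remaining = counts.astype(float).copy()
        pairs = []
        for _ in range(min(counts.shape)):
            r, c = np.unravel_index(np.argmax(remaining), remaining.shape)
            if remaining[r, c] < 0:
                break
            pairs.append((r, c))
            remaining[r, :] = -1
            remaining[:, c] = -1
    else:
        raise ValueError(f"unknown matching method {method!r}")
    matched = sum(counts[r, c] for r, c in pairs)
    mapping = {int(table.columns[c]): int(table.index[r]) for r, c in pairs}
    per_class = pd.DataFrame(
        [
            {
                "class_a": int(table.index[r]),
                "class_b": int(table.columns[c]),
                "n_matched": int(counts[r, c]),
                "agreement": counts[r, c] / counts[r, :].sum() if counts[r, :].sum() else 0.0,
            }
            for r, c in pairs
        ]
    )
    return AgreementResult(
        table=table,
        mapping=mapping,
        overall=float(matched / len(a)),
        per_class=per_class,
        method=method,
    )
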