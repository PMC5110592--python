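"""Latent class analysis of binary items.

A K-class LCA models each respondent's 50 binary item responses as locally
independent Bernoulli draws given class membership: the parameters are the
class weights pi (K) and the item endorsement probabilities rho (K x J).
Fitting is maximum likelihood by EM from multiple random starts (plus an
optional k-means-informed start, which greatly stabilizes class recovery
for well-separated profiles); classes are relabeled in increasing order of
expected total score so solutions are comparable across runs.

Model selection uses AIC, BIC (the index given the greatest weight for
class enumeration in this literature), the sample-size-adjusted BIC,
relative entropy, and the parametric bootstrapped likelihood-ratio test
(BLRT).  The Lo-Mendell-Rubin and Vuong-LMR tests are not implemented;
:func:`lmr_test` exists only to say so.

Local independence is checked through bivariate residuals: observed vs
model-expected 2x2 cell counts for every item pair.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from ._rng import substream

__all__ = [
    "MixtureFit",
    "FitIndices",
    "fit_lca",
    "lca_loglik",
    "fit_indices",
    "blrt",
    "lmr_test",
    "bivariate_residuals",
    "class_summaries",
    "class_covariate_regression",
    "simulate_lca",
]

RHO_EPS = 1e-4  # endorsement probabilities are clamped to [eps, 1 - eps]


@dataclasses.dataclass
class MixtureFit:
    """A fitted K-class Bernoulli mixture."""

    n_classes: int
    weights: np.ndarray  # pi, length K
    item_probs: np.ndarray  # rho, K x J
    loglik: float
    n_params: int
    posterior: np.ndarray  # n x K
    assignment: np.ndarray  # modal class per case
    converged: bool
    n_starts: int
    loglik_trace: np.ndarray  # best start's EM trace (non-decreasing)

    def to_json(self) -> str:
        """Parameter dump (weights, item probabilities, log-likelihood)."""
        import json

        return json.dumps(
            {
                "n_classes": self.n_classes,
                "weights": self.weights.tolist(),
                "item_probs": self.item_probs.tolist(),
                "loglik": self.loglik,
                "n_params": self.n_params,
                "converged": self.converged,
            },
            indent=2,
        )


@dataclasses.dataclass
class FitIndices:
    aic: float
    bic: float
    ssabic: float
    entropy: float
    blrt_p: float | None = None


def _em_bernoulli(
    x: np.ndarray,
    pi0: np.ndarray,
    rho0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, bool, list[float]]:
    n, _ = x.shape
    pi, rho = pi0.copy(), np.clip(rho0, RHO_EPS, 1 - RHO_EPS)
    trace: list[float] = []
    converged = False
    log_post = None
    for _ in range(max_iter):
        logb = x @ np.log(rho).T + (1 - x) @ np.log(1 - rho).T  # n x K
        log_joint = logb + np.log(pi)
        ll_rows = logsumexp(log_joint, axis=1)
        ll = float(ll_rows.sum())
        trace.append(ll)
        log_post = log_joint - ll_rows[:, None]
        post = np.exp(log_post)
        nk = post.sum(axis=0)
        pi = np.clip(nk / n, 1e-10, None)
        pi /= pi.sum()
        rho = np.clip((post.T @ x) / np.clip(nk[:, None], 1e-10, None), RHO_EPS, 1 - RHO_EPS)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            break
    # report the likelihood and posterior of the *returned* parameters
    logb = x @ np.log(rho).T + (1 - x) @ np.log(1 - rho).T
    log_joint = logb + np.log(pi)
    ll_rows = logsumexp(log_joint, axis=1)
    trace.append(float(ll_rows.sum()))
    post = np.exp(log_joint - ll_rows[:, None])
    return pi, rho, trace[-1], post, converged, trace


def fit_lca(
    items: pd.DataFrame,
    n_classes: int,
    n_starts: int = 50,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
    kmeans_start: bool = True,
) -> MixtureFit:
    """Fit a K-class binary LCA by EM; best of ``n_starts`` starts.

    Random starts draw class weights from a flat Dirichlet and item
    probabilities uniformly; with ``kmeans_start`` the first start instead
    seeds the item probabilities with k-means cluster means.  Classes are
    relabeled in increasing order of expected total score.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    x = items.to_numpy(dtype=float)
    n, j = x.shape
    n_patterns = len(np.unique(x, axis=0))
    if n_classes > n_patterns:
        warnings.warn(
            f"{n_classes} classes exceed the {n_patterns} distinct response patterns",
            RuntimeWarning,
        )
    if n_classes == 1:
        rho = np.clip(x.mean(axis=0, keepdims=True), RHO_EPS, 1 - RHO_EPS)
        ll = float(np.sum(x @ np.log(rho).T + (1 - x) @ np.log(1 - rho).T))
        return MixtureFit(
            n_classes=1,
            weights=np.array([1.0]),
            item_probs=rho,
            loglik=ll,
            n_params=j,
            posterior=np.ones((n, 1)),
            assignment=np.zeros(n, dtype=int),
            converged=True,
            n_starts=1,
            loglik_trace=np.array([ll]),
        )
    rng = substream(seed, 31)
    best = None
    any_converged = False
    for s in range(max(1, n_starts)):
        if s == 0 and kmeans_start:
            km = KMeans(n_clusters=n_classes, n_init=2, random_state=int(seed) % (2**31))
            lab = km.fit_predict(x)
            rho0 = np.vstack([
                x[lab == c].mean(axis=0) if np.any(lab == c) else rng.random(j)
                for c in range(n_classes)
            ])
            pi0 = np.bincount(lab, minlength=n_classes) / n
            pi0 = np.clip(pi0, 0.01, None)
            pi0 /= pi0.sum()
        else:
            pi0 = rng.dirichlet(np.ones(n_classes))
            rho0 = rng.random((n_classes, j))
        result = _em_bernoulli(x, pi0, rho0, tol, max_iter)
        any_converged = any_converged or result[4]
        if best is None or result[2] > best[2]:
            best = result
    if not any_converged:
        raise RuntimeError(
            f"no EM start converged within {max_iter} iterations; best trace tail "
            f"{best[5][-3:]}"
        )
    pi, rho, ll, post, converged, trace = best
    order = np.argsort(rho.sum(axis=1))  # label-switching convention
    pi, rho, post = pi[order], rho[order], post[:, order]
    return MixtureFit(
        n_classes=n_classes,
        weights=pi,
        item_probs=rho,
        loglik=ll,
        n_params=(n_classes - 1) + n_classes * j,
        posterior=post,
        assignment=post.argmax(axis=1),
        converged=converged,
        n_starts=max(1, n_starts),
        loglik_trace=np.asarray(trace),
    )


def lca_loglik(items: pd.DataFrame, weights: np.ndarray, item_probs: np.ndarray) -> float:
    """Log-likelihood of fixed LCA parameters (vectorized)."""
    x = items.to_numpy(dtype=float)
    rho = np.clip(item_probs, RHO_EPS, 1 - RHO_EPS)
    logb = x @ np.log(rho).T + (1 - x) @ np.log(1 - rho).T
    return float(logsumexp(logb + np.log(weights), axis=1).sum())


def fit_indices(fit, n: int, blrt_p: float | None = None) -> FitIndices:
    """AIC / BIC / SSABIC and relative entropy for a mixture fit.

    SSABIC replaces ln n with ln((n + 2) / 24).  Relative entropy is
    ``1 - sum(-p log p) / (n log K)`` (1 when K = 1 or posteriors are
    degenerate, 0 for uniform posteriors).
    """
    ll, p, k = fit.loglik, fit.n_params, fit.n_classes
    post = np.clip(fit.posterior, 1e-300, 1.0)
    if k == 1:
        entropy = 1.0
    else:
        entropy = 1.0 - float(-(post * np.log(post)).sum()) / (n * np.log(k))
    return FitIndices(
        aic=-2 * ll + 2 * p,
        bic=-2 * ll + p * np.log(n),
        ssabic=-2 * ll + p * np.log((n + 2) / 24.0),
        entropy=entropy,
        blrt_p=blrt_p,
    )


def simulate_lca(weights: np.ndarray, item_probs: np.ndarray, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Parametric draw from an LCA model (used by the BLRT bootstrap)."""
    edges = np.cumsum(weights)[:-1]
    labels = np.searchsorted(edges, rng.random(n), side="right")
    u = rng.random((n, item_probs.shape[1]))
    x = (u < item_probs[labels]).astype(np.int8)
    return pd.DataFrame(x, columns=[f"item_{i + 1}" for i in range(item_probs.shape[1])])


def blrt(
    items: pd.DataFrame,
    n_classes: int,
    reps: int = 100,
    seed: int = 0,
    n_starts: int = 10,
    tol: float = 1e-4,
    max_iter: int = 1000,
    fit_null: MixtureFit | None = None,
    fit_alt: MixtureFit | None = None,
) -> dict:
    """Parametric bootstrapped LRT of K-1 vs K classes.

    The observed statistic is ``2 (LL_K - LL_{K-1})``; its null reference
    distribution comes from refitting both models to ``reps`` datasets
    simulated from the fitted (K-1)-class model.  The p-value uses the
    add-one rule, so its minimum is ``1 / (reps + 1)``.
    """
    if n_classes < 2:
        raise ValueError("BLRT compares K >= 2 against K - 1")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n = len(items)
    null = fit_null or fit_lca(items, n_classes - 1, n_starts=n_starts, tol=tol,
                               max_iter=max_iter, seed=seed)
    alt = fit_alt or fit_lca(items, n_classes, n_starts=n_starts, tol=tol,
                             max_iter=max_iter, seed=seed)
    observed = max(0.0, 2.0 * (alt.loglik - null.loglik))
    boot: list[float] = []
    dropped = 0
    for b in range(reps):
        rng = substream(seed + 1 + b, 53)
        sim = simulate_lca(null.weights, null.item_probs, n, rng)
        try:
            f0 = fit_lca(sim, n_classes - 1, n_starts=n_starts, tol=tol,
                         max_iter=max_iter, seed=seed + b)
            f1 = fit_lca(sim, n_classes, n_starts=n_starts, tol=tol,
                         max_iter=max_iter, seed=seed + b)
        except RuntimeError:
            dropped += 1
            continue
        boot.append(max(0.0, 2.0 * (f1.loglik - f0.loglik)))
    if dropped > 0.2 * reps:
        raise RuntimeError(f"{dropped}/{reps} bootstrap refits failed")
    if dropped:
        warnings.warn(f"{dropped} bootstrap replicates dropped", RuntimeWarning)
    boot_arr = np.asarray(boot)
    p = (1.0 + float(np.sum(boot_arr >= observed))) / (len(boot_arr) + 1.0)
    return {
        "statistic": observed,
        "p_value": p,
        "bootstrap": boot_arr,
        "n_dropped": dropped,
        "ll_null": null.loglik,
        "ll_alt": alt.loglik,
    }


def lmr_test(*args, **kwargs):
    """Lo-Mendell-Rubin / Vuong-LMR tests are not implemented.

    Their reference-distribution derivation is out of scope; use
    :func:`blrt` for class enumeration.
    """
    raise NotImplementedError("LMR/VLMR tests are not implemented; use blrt()")


def bivariate_residuals(fit: MixtureFit, items: pd.DataFrame, threshold: float = 1.96) -> pd.DataFrame:
    """Standardized observed-vs-expected residuals for every item pair.

    Under local independence given class, the expected joint endorsement
    rate for items j, j' is ``sum_k pi_k rho_kj rho_kj'``; each 2x2 cell's
    standardized residual is ``(O - E) / sqrt(E)``.  Pairs with any cell
    beyond ``threshold`` are flagged.
    """
    x = items.to_numpy(dtype=float)
    n, j = x.shape
    pi, rho = fit.weights, fit.item_probs
    p1 = pi @ rho  # marginal endorsement
    p11 = np.einsum("k,kj,km->jm", pi, rho, rho)
    o11 = x.T @ x
    o10 = x.T @ (1 - x)
    o01 = (1 - x).T @ x
    o00 = (1 - x).T @ (1 - x)
    rows = []
    for a in range(j):
        for b in range(a + 1, j):
            e11 = n * p11[a, b]
            e10 = n * (p1[a] - p11[a, b])
            e01 = n * (p1[b] - p11[a, b])
            e00 = n - e11 - e10 - e01
            obs = np.array([o11[a, b], o10[a, b], o01[a, b], o00[a, b]])
            exp = np.clip(np.array([e11, e10, e01, e00]), 1e-10, None)
            res = (obs - exp) / np.sqrt(exp)
            rows.append(
                {
                    "item_a": items.columns[a],
                    "item_b": items.columns[b],
                    "max_abs_residual": float(np.max(np.abs(res))),
                    "res_11": res[0],
                    "res_10": res[1],
                    "res_01": res[2],
                    "res_00": res[3],
                    "e_11": exp[0],
                    "e_10": exp[1],
                    "e_01": exp[2],
                    "e_00": exp[3],
                    "flagged": bool(np.max(np.abs(res)) > threshold),
                }
            )
    return pd.DataFrame(rows)


def class_summaries(fit: MixtureFit, totals) -> pd.DataFrame:
    """Per-class modal share and mean/SD of the total score."""
    t = np.asarray(totals, dtype=float)
    rows = []
    for k in range(fit.n_classes):
        mask = fit.assignment == k
        share = float(mask.mean())
        rows.append(
            {
                "class": k + 1,
                "share": share,
                "mean_total": float(t[mask].mean()) if mask.any() else float("nan"),
                "sd_total": float(t[mask].std(ddof=1)) if mask.sum() > 1 else float("nan"),
                "empty": not mask.any(),
            }
        )
    return pd.DataFrame(rows)


def class_covariate_regression(
    assignment: np.ndarray,
    covariate: np.ndarray,
    reference_class: int = 0,
) -> dict:
    """Multinomial logit of modal class on a binary covariate.

    Returns per-class log-odds (relative to ``reference_class``), standard
    errors, Wald p-values, McFadden's pseudo-R2 and the likelihood-ratio
    G2 against the intercept-only model.
    """
    import statsmodels.api as sm

    y = np.asarray(assignment)
    xcov = np.asarray(covariate, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if not set(np.unique(xcov)) <= {0.0, 1.0}:
        raise ValueError("covariate must be binary (0/1)")
    # recode so the reference class is category 0 (statsmodels' baseline)
    mapping = {reference_class: 0}
    nxt = 1
    for c in classes:
        if c != reference_class:
            mapping[c] = nxt
            nxt += 1
    y_rec = np.array([mapping[c] for c in y])
    exog = sm.add_constant(xcov)
    try:
        model = sm.MNLogit(y_rec, exog)
        res = model.fit(disp=False, maxiter=200)
    except Exception as exc:  # pragma: no cover - separation is data-dependent
        raise RuntimeError(f"multinomial logit failed (separation?): {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("multinomial logit did not converge; check for separation")
    inverse = {v: k for k, v in mapping.items()}
    rows = [
        {
            "class": reference_class + 1,
            "log_odds": 0.0,
            "se": 0.0,
            "wald_p": float("nan"),
        }
    ]
    for col in range(res.params.shape[1]):
        rows.append(
            {
                "class": inverse[col + 1] + 1,
                "log_odds": float(res.params[1, col]),
                "se": float(res.bse[1, col]),
                "wald_p": float(res.pvalues[1, col]),
            }
        )
    table = pd.DataFrame(rows).sort_values("class").reset_index(drop=True)
    return {
        "table": table,
        "mcfadden_r2": float(res.prsquared),
        "g2": float(res.llr),
        "g2_p": float(res.llr_pvalue),
        "loglik": float(res.llf),
    }
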