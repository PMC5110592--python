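"""Taxometric curve procedures: MAMBAC, MAXCOV, MAXEIG and L-Mode.

All four procedures order cases along an *input* indicator and compute a
statistic of the remaining (*output*) indicators along that ordering:

* **MAMBAC** -- mean of the output above minus below each of a series of
  sliding cuts; a peaked curve suggests a latent taxon, a concave-up
  ("dish") shape a dimension.
* **MAXCOV** -- covariance of two outputs within overlapping windows; the
  covariance is maximal where the window mixes taxon and complement most
  evenly (the *hitmax* region).
* **MAXEIG** -- the largest eigenvalue of the zero-diagonal covariance
  matrix of all outputs within the same windows (a multivariate MAXCOV).
* **L-Mode** -- the kernel density of single-factor weighted-least-squares
  factor scores; bimodality suggests a taxon.

Cut and window positions are computed on case *ranks*, so the curves are
invariant to monotone transforms of the input.  Integer-valued composites
tie heavily; ties are broken by seeded random jitter and curves averaged
over ``tie_reps`` re-orderings.

Base rates: MAMBAC uses the endpoint estimator on the smoothed curve;
MAXCOV/MAXEIG use the classical hitmax general-covariance-mixture solution
(window taxon fraction ``p_t`` solves ``p(1-p) = y_t / (4 * y_hitmax)``,
after subtracting the curve minimum as a nuisance-covariance floor); L-Mode
reports the density mass above the antimode between the two modes.
"""

from __future__ import annotations

import dataclasses
import warnings
from itertools import combinations, permutations

import numpy as np
import pandas as pd
import scipy.stats

from ._rng import substream

__all__ = [
    "TaxometricCurve",
    "BaseRateEstimate",
    "LModeResult",
    "mambac_panel",
    "maxcov_panel",
    "maxeig_panel",
    "lmode_analysis",
    "estimate_base_rates",
    "window_width",
    "panel_to_frame",
]

LMODE_GRID = np.linspace(-4.0, 4.0, 161)


@dataclasses.dataclass
class TaxometricCurve:
    procedure: str  # MAMBAC | MAXCOV | MAXEIG | LMODE
    input_id: str
    output_ids: tuple[str, ...]
    x: np.ndarray  # strictly increasing cut/window positions (rank scale) or factor-score grid
    y: np.ndarray
    n_per_window: int | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")


@dataclasses.dataclass
class BaseRateEstimate:
    procedure: str
    per_curve: list[float]
    averaged_curve: float
    mean: float
    sd: float


@dataclasses.dataclass
class LModeResult:
    curve: TaxometricCurve
    scores: np.ndarray
    left_mode: float
    right_mode: float
    antimode: float | None
    bimodal: bool
    loadings: np.ndarray
    base_rate: float = float("nan")  # upper-component weight of a 2-Gaussian fit


def window_width(n: int, n_windows: int = 25, overlap: float = 0.9) -> int:
    """Width of overlapping windows covering ``n`` ranked cases.

    With ``n_windows`` windows advancing by ``(1 - overlap)`` of a width
    each, the total span is ``w * (1 + (n_windows - 1) * (1 - overlap))``.
    """
    return int(round(n / (1.0 + (n_windows - 1) * (1.0 - overlap))))


def _tie_orders(values: np.ndarray, tie_reps: int, seed: int, key: int) -> list[np.ndarray]:
    """Sorting permutations of ``values`` with seeded random tie-breaks."""
    rng = substream(seed, key)
    n = len(values)
    if values.max() == values.min():
        raise ValueError("constant input indicator: ordering undefined")
    reps = max(1, tie_reps)
    return [np.lexsort((rng.random(n), values)) for _ in range(reps)]


def mambac_panel(
    indicators: pd.DataFrame,
    n_cuts: int = 50,
    margin: int = 25,
    tie_reps: int = 10,
    seed: int = 0,
) -> list[TaxometricCurve]:
    """MAMBAC curves for every ordered (input, output) indicator pair.

    Cuts sit at ``n_cuts`` evenly spaced case ranks, the first ``margin``
    cases from each extreme; at each cut the statistic is mean(output above)
    minus mean(output below).  K indicators give K*(K-1) curves.
    """
    x = indicators.to_numpy(dtype=float)
    n, k = x.shape
    if k < 2:
        raise ValueError("MAMBAC needs at least 2 indicators")
    if n <= 2 * margin + n_cuts:
        raise ValueError("sample too small for the requested cuts and margins")
    cut_ranks = np.unique(np.round(np.linspace(margin, n - margin, n_cuts)).astype(int))
    curves = []
    for i, o in permutations(range(k), 2):
        acc = np.zeros(len(cut_ranks))
        orders = _tie_orders(x[:, i], tie_reps, seed, key=100 + i)
        for order in orders:
            out_sorted = x[order, o]
            csum = np.concatenate(([0.0], np.cumsum(out_sorted)))
            below = csum[cut_ranks] / cut_ranks
            above = (csum[-1] - csum[cut_ranks]) / (n - cut_ranks)
            acc += above - below
        curves.append(
            TaxometricCurve(
                procedure="MAMBAC",
                input_id=indicators.columns[i],
                output_ids=(indicators.columns[o],),
                x=cut_ranks.astype(float),
                y=acc / len(orders),
            )
        )
    return curves


def _window_slices(n: int, n_windows: int, overlap: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Window start ranks, centers and the common width."""
    w = window_width(n, n_windows, overlap)
    if w < 10:
        raise ValueError(f"window width {w} < 10 cases")
    step = (1.0 - overlap) * w
    starts = np.minimum(np.round(np.arange(n_windows) * step).astype(int), n - w)
    centers = starts + w / 2.0
    if np.any(np.diff(centers) <= 0):  # tiny n: collapse duplicates upstream
        centers = centers + np.arange(n_windows) * 1e-9
    return starts, centers.astype(float), w


def _window_cross_moments(outs: np.ndarray, starts: np.ndarray, w: int) -> np.ndarray:
    """Pairwise output covariances within each window.

    ``outs`` is (n, m) already ordered by the input.  Returns an array of
    shape (n_windows, m, m) of sample covariances (ddof=1) with the usual
    diagonal.  Uses cumulative sums, so cost is O(n m^2) per ordering.
    """
    n, m = outs.shape
    cum = np.concatenate([np.zeros((1, m)), np.cumsum(outs, axis=0)])
    prod = outs[:, :, None] * outs[:, None, :]
    cum_p = np.concatenate([np.zeros((1, m, m)), np.cumsum(prod, axis=0)])
    s_sum = cum[starts + w] - cum[starts]  # (T, m)
    s_prod = cum_p[starts + w] - cum_p[starts]  # (T, m, m)
    mean = s_sum / w
    return (s_prod - w * mean[:, :, None] * mean[:, None, :]) / (w - 1)


def maxcov_panel(
    indicators: pd.DataFrame,
    n_windows: int = 25,
    overlap: float = 0.9,
    tie_reps: int = 10,
    seed: int = 0,
) -> list[TaxometricCurve]:
    """MAXCOV curves for every input/output/output triplet.

    Cases are ranked on the input and sliced into ``n_windows`` overlapping
    windows; the statistic is the covariance of the two outputs within each
    window.  K indicators give K * C(K-1, 2) curves.
    """
    x = indicators.to_numpy(dtype=float)
    n, k = x.shape
    if k < 3:
        raise ValueError("MAXCOV needs at least 3 indicators")
    starts, centers, w = _window_slices(n, n_windows, overlap)
    curves = []
    for i in range(k):
        orders = _tie_orders(x[:, i], tie_reps, seed, key=200 + i)
        others = [j for j in range(k) if j != i]
        acc = np.zeros((n_windows, len(others), len(others)))
        for order in orders:
            acc += _window_cross_moments(x[order][:, others], starts, w)
        cov = acc / len(orders)
        for (a1, o1), (a2, o2) in combinations(enumerate(others), 2):
            curves.append(
                TaxometricCurve(
                    procedure="MAXCOV",
                    input_id=indicators.columns[i],
                    output_ids=(indicators.columns[o1], indicators.columns[o2]),
                    x=centers,
                    y=cov[:, a1, a2],
                    n_per_window=w,
                )
            )
    return curves


def maxeig_panel(
    indicators: pd.DataFrame,
    n_windows: int = 25,
    overlap: float = 0.9,
    tie_reps: int = 10,
    seed: int = 0,
) -> list[TaxometricCurve]:
    """MAXEIG curves, one per input indicator.

    Within each window the covariance matrix of all outputs has its
    diagonal replaced by zeros and the largest eigenvalue is recorded.
    """
    x = indicators.to_numpy(dtype=float)
    n, k = x.shape
    if k < 3:
        raise ValueError("MAXEIG needs at least 3 indicators")
    starts, centers, w = _window_slices(n, n_windows, overlap)
    curves = []
    eye = None
    for i in range(k):
        orders = _tie_orders(x[:, i], tie_reps, seed, key=200 + i)
        others = [j for j in range(k) if j != i]
        acc = np.zeros(n_windows)
        if eye is None or eye.shape[0] != len(others):
            eye = np.eye(len(others), dtype=bool)
        for order in orders:
            cov = _window_cross_moments(x[order][:, others], starts, w)
            cov[:, eye] = 0.0
            acc += np.linalg.eigvalsh(cov)[:, -1]
        curves.append(
            TaxometricCurve(
                procedure="MAXEIG",
                input_id=indicators.columns[i],
                output_ids=tuple(indicators.columns[j] for j in others),
                x=centers,
                y=acc / len(orders),
                n_per_window=w,
            )
        )
    return curves


def _one_factor_paf(corr: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Single-factor principal-axis loadings of a correlation matrix."""
    inv = np.linalg.inv(corr)
    comm = 1.0 - 1.0 / np.diag(inv)
    for _ in range(max_iter):
        reduced = corr.copy()
        np.fill_diagonal(reduced, comm)
        vals, vecs = np.linalg.eigh(reduced)
        lam = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
        new_comm = np.minimum(lam**2, 1.0)
        if np.max(np.abs(new_comm - comm)) < tol:
            break
        comm = new_comm
    if np.sum(lam) < 0:
        lam = -lam
    return lam


def lmode_analysis(
    indicators: pd.DataFrame,
    grid: np.ndarray = LMODE_GRID,
    bw_method: str | float = "silverman",
    estimate_base_rate: bool = True,
) -> LModeResult:
    """L-Mode: density of single-factor WLS factor scores on a fixed grid.

    Factor scores are Bartlett (uniqueness-weighted least squares) scores
    from a one-factor principal-axis solution, standardized to mean 0 and
    unit variance.  The left mode is the density maximum below 0 and the
    right mode the maximum above 0; the antimode is the density minimum
    between them.  The solution is flagged non-bimodal when either mode
    fails to exceed 1.05x the antimode density.
    """
    x = indicators.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("L-Mode needs at least 2 indicators")
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    corr = np.corrcoef(x, rowvar=False)
    lam = _one_factor_paf(corr)
    if np.all(np.abs(lam) < 1e-3):
        raise ValueError("degenerate one-factor solution: all loadings ~ 0")
    psi = np.clip(1.0 - lam**2, 1e-6, None)
    weights = (lam / psi) / float(lam @ (lam / psi))  # Bartlett WLS weights
    scores = z @ weights
    scores = (scores - scores.mean()) / scores.std(ddof=1)
    dens = scipy.stats.gaussian_kde(scores, bw_method=bw_method)(grid)
    neg, pos = grid < 0, grid >= 0
    left_i = int(np.argmax(np.where(neg, dens, -np.inf)))
    right_i = int(np.argmax(np.where(pos, dens, -np.inf)))
    left_mode, right_mode = float(grid[left_i]), float(grid[right_i])
    if right_i > left_i:
        between = slice(left_i, right_i + 1)
        anti_i = left_i + int(np.argmin(dens[between]))
        antimode = float(grid[anti_i])
        d_anti = dens[anti_i]
        bimodal = bool(dens[left_i] > 1.05 * d_anti and dens[right_i] > 1.05 * d_anti)
    else:  # degenerate: single grid-point mode region
        antimode, bimodal = None, False
    curve = TaxometricCurve(
        procedure="LMODE",
        input_id="factor",
        output_ids=tuple(indicators.columns),
        x=grid,
        y=dens,
    )
    return LModeResult(
        curve=curve,
        scores=scores,
        left_mode=left_mode,
        right_mode=right_mode,
        antimode=antimode,
        bimodal=bimodal,
        loadings=lam,
        base_rate=_two_class_score_base_rate(scores) if estimate_base_rate else float("nan"),
    )


def _two_class_score_base_rate(scores: np.ndarray) -> float:
    """Base rate from the latent modes of the factor-score distribution.

    A two-component equal-variance Gaussian mixture is fitted to the scores
    by EM; its component means are the latent modes, and the weight of the
    upper component is the taxon base rate.  Unlike counting scores above
    the antimode, this stays well-defined when the mixture is too weakly
    separated for the density itself to show a second peak.
    """
    from .lpa import fit_lpa  # local import: lpa does not depend on taxometrics

    frame = pd.DataFrame({"score": scores})
    try:
        fit = fit_lpa(frame, 2, n_starts=5, max_iter=3000, tol=1e-5, seed=0)
    except RuntimeError:  # weakly separated: mixture fit poorly identified
        return float("nan")
    return float(fit.weights[int(np.argmax(fit.means[:, 0]))])


# ---------------------------------------------------------------------------
# base-rate estimation

def _smooth(y: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average with edge shrinkage."""
    if window <= 1:
        return y
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def _mambac_base_rate(y: np.ndarray) -> float:
    """Endpoint estimator on the smoothed curve.

    With complement mean 0 and taxon mean Delta on the output, the cut at
    the bottom extreme gives mean-above ~ p*Delta and mean-below ~ 0, and
    the cut at the top extreme gives Delta - p*Delta, so
    p = y_left / (y_left + y_right).
    """
    ys = _smooth(y)
    left, right = ys[0], ys[-1]
    if left + right <= 0:
        return float("nan")
    return float(np.clip(left / (left + right), 0.0, 1.0))


def _hitmax_base_rate(y: np.ndarray, x: np.ndarray, width: int | None) -> float:
    """Taxon base rate from a MAXCOV/MAXEIG curve via the hitmax cut.

    The covariance statistic is proportional to p_t (1 - p_t) under the
    general two-class covariance mixture, so the maximizing window is the
    *hitmax* -- the point along the input where the window is half taxon.
    At that cut the taxon members below balance the complement members
    above, so the taxon fraction is the fraction of cases ranked above the
    hitmax window's center.
    """
    ys = _smooth(y)
    if ys.max() <= ys.min():
        return float("nan")
    cut = x[int(np.argmax(ys))]
    n = x[-1] + (width / 2.0 if width else 0.0)  # last window ends at rank n
    return float(np.clip((n - cut) / n, 0.0, 1.0))


def _lmode_base_rate(curve: TaxometricCurve) -> float:
    """Density mass above the antimode of a (possibly replicate) L-Mode curve."""
    x, dens = curve.x, curve.y
    neg, pos = x < 0, x >= 0
    left_i = int(np.argmax(np.where(neg, dens, -np.inf)))
    right_i = int(np.argmax(np.where(pos, dens, -np.inf)))
    if right_i <= left_i:
        return 0.0
    anti_i = left_i + int(np.argmin(dens[left_i: right_i + 1]))
    if dens[left_i] <= 1.05 * dens[anti_i] or dens[right_i] <= 1.05 * dens[anti_i]:
        return 0.0  # non-taxonic: no credible second mode
    total = np.trapezoid(dens, x)
    upper = np.trapezoid(dens[anti_i:], x[anti_i:])
    return float(np.clip(upper / total, 0.0, 1.0))


def estimate_base_rates(curves: list[TaxometricCurve], procedure: str | None = None) -> BaseRateEstimate:
    """Per-curve, averaged-curve and summary base-rate estimates."""
    if not curves:
        raise ValueError("no curves supplied")
    procs = {c.procedure for c in curves}
    if len(procs) > 1:
        raise ValueError(f"curves from multiple procedures: {procs}")
    proc = procedure or curves[0].procedure
    if proc == "MAMBAC":
        estimator = lambda c: _mambac_base_rate(c.y)
    elif proc in ("MAXCOV", "MAXEIG"):
        estimator = lambda c: _hitmax_base_rate(c.y, c.x, c.n_per_window)
    elif proc == "LMODE":
        estimator = _lmode_base_rate
    else:
        raise ValueError(f"unknown procedure {proc!r}")
    per_curve = []
    for c in curves:
        est = estimator(c)
        if np.isnan(est):
            warnings.warn(f"base rate undefined for a {proc} curve; excluded", RuntimeWarning)
        else:
            per_curve.append(est)
    mean_curve = TaxometricCurve(
        procedure=proc,
        input_id="averaged",
        output_ids=(),
        x=curves[0].x,
        y=np.mean([c.y for c in curves], axis=0),
        n_per_window=curves[0].n_per_window,
    )
    averaged = estimator(mean_curve)
    arr = np.asarray(per_curve)
    return BaseRateEstimate(
        procedure=proc,
        per_curve=per_curve,
        averaged_curve=float(averaged),
        mean=float(arr.mean()) if arr.size else float("nan"),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
    )


def panel_to_frame(curves: list[TaxometricCurve]) -> pd.DataFrame:
    """Long-format export of a curve panel (procedure, input, outputs, x, y)."""
    rows = []
    for c in curves:
        for xi, yi in zip(c.x, c.y):
            rows.append(
                {
                    "procedure": c.procedure,
                    "input": c.input_id,
                    "outputs": "+".join(c.output_ids),
                    "x": xi,
                    "y": yi,
                }
            )
    return pd.DataFrame(rows)
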