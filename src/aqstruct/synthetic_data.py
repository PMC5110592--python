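"""Synthetic AQ-style data with known latent structure.

The original questionnaire responses behind the analyses this package
implements are not publicly deposited, so every downstream stage is
exercised on simulated data whose latent structure is known exactly.  Three
generating processes are provided:

* **taxonic** -- a two-class mixture: a high-severity *taxon* (default
  prevalence 0.15) and a *complement*, each with its own Bernoulli item
  profile (items) or multivariate-normal indicator distribution
  (indicators).
* **dimensional** -- a single population with a standard-normal latent
  trait; items follow a one-factor probit model, indicators a common-factor
  Gaussian population moment-matched to the taxonic variant.
* **hybrid** -- a six-class mixture of Bernoulli item profiles whose class
  weights and expected total scores emulate the class structure reported
  for large non-clinical AQ samples (highest class mean ~ 37.9, lowest
  ~ 11.5).  The per-class item probabilities ship as an editable YAML
  resource; they are a calibrated emulation, not a reproduction of any
  published item-level table.

All generators are deterministic given a :class:`PopulationSpec` (including
its seed), and extending ``n`` leaves earlier rows unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from importlib import resources as _ilres
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._rng import substream

__all__ = [
    "PopulationSpec",
    "generate_taxonic_items",
    "generate_dimensional_items",
    "generate_six_class_items",
    "generate_continuous_indicators",
    "load_six_class_profiles",
    "six_class_spec",
    "write_matrix",
    "read_matrix",
    "spec_to_yaml",
    "spec_from_yaml",
]

#: Default integer score range of each composite indicator, chosen to match
#: the feasible ranges of composites built from dichotomized AQ items
#: (indicator 2 contains one negatively keyed item, hence the -1 floor).
DEFAULT_INDICATOR_RANGES: tuple[tuple[int, int], ...] = ((0, 18), (-1, 8), (0, 7), (0, 6))

_STRUCTURES = ("taxonic", "dimensional", "hybrid")


@dataclass
class PopulationSpec:
    """Parameters of a synthetic population.

    Parameters
    ----------
    structure:
        ``"taxonic"`` (two classes), ``"dimensional"`` (single population,
        one latent factor) or ``"hybrid"`` (multi-class Bernoulli mixture).
    n:
        Number of respondents.
    n_items:
        Number of questionnaire items (50 for the AQ).
    class_weights:
        Mixing proportions; must sum to 1.  For ``taxonic`` the convention
        is ``(complement, taxon)``.
    class_item_probs:
        Per-class Bernoulli endorsement probabilities, shape
        ``(n_classes, n_items)``; used by taxonic/hybrid item generators.
    loadings, thresholds:
        Per-item factor loadings (|lambda| <= 1) and probit thresholds for
        the dimensional item generator.
    indicator_map:
        Optional mapping of composite-indicator name -> item numbers.
    target_d:
        Between-class separation on each continuous indicator, in pooled
        within-class standard deviation units.
    within_class_r:
        Common within-class correlation among continuous indicators
        (nuisance covariance).
    indicator_ranges:
        Integer (lo, hi) score range per continuous indicator.
    seed:
        RNG seed; identical specs produce bit-identical data.
    """

    structure: str
    n: int
    n_items: int = 50
    class_weights: Sequence[float] | None = None
    class_item_probs: np.ndarray | None = None
    loadings: np.ndarray | None = None
    thresholds: np.ndarray | None = None
    indicator_map: Mapping[str, Sequence[int]] | None = None
    target_d: float = 2.0
    within_class_r: float = 0.2
    indicator_ranges: tuple[tuple[int, int], ...] = DEFAULT_INDICATOR_RANGES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structure not in _STRUCTURES:
            raise ValueError(f"structure must be one of {_STRUCTURES}, got {self.structure!r}")
        if int(self.n) < 1:
            raise ValueError("n must be >= 1")
        self.n = int(self.n)
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=float)
            if np.any(w < 0) or np.any(w > 1):
                raise ValueError("class weights must lie in [0, 1]")
            if abs(w.sum() - 1.0) > 1e-12:
                raise ValueError(f"class weights must sum to 1 (got {w.sum()!r})")
            self.class_weights = w
        if self.class_item_probs is not None:
            p = np.atleast_2d(np.asarray(self.class_item_probs, dtype=float))
            if np.any(p < 0) or np.any(p > 1):
                raise ValueError("item probabilities must lie in [0, 1]")
            if p.shape[1] != self.n_items:
                raise ValueError(
                    f"class_item_probs has {p.shape[1]} items, spec says n_items={self.n_items}"
                )
            self.class_item_probs = p
        if self.indicator_map is not None:
            seen: set[int] = set()
            for name, items in self.indicator_map.items():
                for it in items:
                    if abs(int(it)) in seen:
                        raise ValueError(f"item {it} mapped to more than one indicator")
                    seen.add(abs(int(it)))


def _item_frame(matrix: np.ndarray) -> pd.DataFrame:
    cols = [f"item_{j + 1}" for j in range(matrix.shape[1])]
    return pd.DataFrame(matrix.astype(np.int8), columns=cols)


def _draw_labels(rng: np.random.Generator, n: int, weights: np.ndarray) -> np.ndarray:
    """Multinomial class labels from a single uniform stream (row-stable)."""
    edges = np.cumsum(weights)[:-1]
    return np.searchsorted(edges, rng.random(n), side="right").astype(np.int64)


def generate_taxonic_items(spec: PopulationSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Two-class Bernoulli item mixture; returns (items, true labels).

    Label 1 is the taxon (second class weight), label 0 the complement.
    """
    if spec.structure != "taxonic":
        raise ValueError("spec.structure must be 'taxonic'")
    if spec.class_weights is None or len(spec.class_weights) != 2:
        raise ValueError("taxonic spec requires exactly 2 class weights")
    if spec.class_item_probs is None or spec.class_item_probs.shape[0] != 2:
        raise ValueError("taxonic spec requires class_item_probs with 2 rows")
    labels = _draw_labels(substream(spec.seed, 0), spec.n, np.asarray(spec.class_weights))
    u = substream(spec.seed, 1).random((spec.n, spec.n_items))
    items = (u < spec.class_item_probs[labels]).astype(np.int8)
    return _item_frame(items), labels


def generate_dimensional_items(spec: PopulationSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Single-factor probit item model; returns (items, true factor scores).

    Respondent latent score ``z ~ N(0, 1)``; item ``j`` is endorsed iff
    ``loading_j * z + sqrt(1 - loading_j^2) * e > threshold_j`` with
    ``e ~ N(0, 1)``, so the marginal endorsement rate is
    ``1 - Phi(threshold_j)``.
    """
    if spec.structure != "dimensional":
        raise ValueError("spec.structure must be 'dimensional'")
    if spec.loadings is None or spec.thresholds is None:
        raise ValueError("dimensional spec requires loadings and thresholds")
    lam = np.asarray(spec.loadings, dtype=float)
    tau = np.asarray(spec.thresholds, dtype=float)
    if lam.shape != (spec.n_items,) or tau.shape != (spec.n_items,):
        raise ValueError("loadings/thresholds must have length n_items")
    if np.any(np.abs(lam) > 1):
        raise ValueError("|loading| must not exceed 1")
    z = substream(spec.seed, 0).standard_normal(spec.n)
    noise = substream(spec.seed, 1).standard_normal((spec.n, spec.n_items))
    liability = lam * z[:, None] + np.sqrt(1.0 - lam**2) * noise
    items = (liability > tau).astype(np.int8)
    return _item_frame(items), z


def load_six_class_profiles() -> dict:
    """Load the packaged six-class profile resource.

    Returns a dict with keys ``weights`` (length 6), ``item_probs``
    (6 x 50 array), ``male_prob`` (per-class P(male), used only to simulate
    a gender covariate) and ``expected_totals`` (analytic per-class mean
    total scores, i.e. row sums of ``item_probs``).
    """
    text = _ilres.files("aqstruct.resources").joinpath("six_class_profiles.yaml").read_text()
    raw = yaml.safe_load(text)
    probs = np.array([raw["item_probs"][f"class_{c + 1}"] for c in range(6)], dtype=float)
    return {
        "weights": np.asarray(raw["weights"], dtype=float),
        "item_probs": probs,
        "male_prob": np.asarray(raw["male_prob"], dtype=float),
        "expected_totals": probs.sum(axis=1),
    }


def six_class_spec(n: int, seed: int = 0) -> PopulationSpec:
    """Convenience constructor: hybrid spec with the packaged profiles."""
    prof = load_six_class_profiles()
    return PopulationSpec(
        structure="hybrid",
        n=n,
        class_weights=prof["weights"],
        class_item_probs=prof["item_probs"],
        seed=seed,
    )


def generate_six_class_items(
    spec: PopulationSpec, with_gender: bool = False
) -> tuple[pd.DataFrame, np.ndarray] | tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Multi-class Bernoulli item mixture; returns (items, labels[, gender]).

    With ``with_gender=True`` a binary covariate (male = 1) is drawn from the
    packaged per-class male probabilities, emulating the gender imbalance of
    the severity classes; gender affects nothing but itself.
    """
    if spec.structure != "hybrid":
        raise ValueError("spec.structure must be 'hybrid'")
    if spec.class_weights is None or spec.class_item_probs is None:
        raise ValueError("hybrid spec requires class_weights and class_item_probs")
    if len(spec.class_weights) != spec.class_item_probs.shape[0]:
        raise ValueError("class_weights and class_item_probs disagree on class count")
    labels = _draw_labels(substream(spec.seed, 0), spec.n, np.asarray(spec.class_weights))
    u = substream(spec.seed, 1).random((spec.n, spec.n_items))
    items = (u < spec.class_item_probs[labels]).astype(np.int8)
    frame = _item_frame(items)
    if not with_gender:
        return frame, labels
    male_prob = load_six_class_profiles()["male_prob"]
    if len(male_prob) < len(spec.class_weights):
        raise ValueError("packaged male_prob does not cover all classes")
    gender = (substream(spec.seed, 2).random(spec.n) < male_prob[labels]).astype(np.int8)
    return frame, labels, gender


def _indicator_scale(ranges: Sequence[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-indicator (center, integer-unit SD, latent SD) for discretization.

    The latent SD is shrunk so that adding the ~1/12 variance of
    round-to-integer noise restores the nominal integer-unit SD, keeping the
    realized standardized separation close to ``target_d`` after rounding.
    """
    lo = np.array([r[0] for r in ranges], dtype=float)
    hi = np.array([r[1] for r in ranges], dtype=float)
    width = hi - lo
    sd = width / 8.0
    if np.any(sd**2 <= 1.0 / 12.0):
        raise ValueError("indicator range too narrow for integer discretization")
    latent_sd = np.sqrt(sd**2 - 1.0 / 12.0)
    center = lo + 0.3 * width
    return center, sd, latent_sd


def generate_continuous_indicators(spec: PopulationSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Integer-valued composite-indicator data; returns (indicators, labels).

    ``taxonic``: two multivariate-normal classes with equal within-class
    covariance (equicorrelation ``within_class_r``), mean separation
    ``target_d`` pooled-SD units on every indicator, prevalence from
    ``class_weights``.  ``dimensional``: a single Gaussian population with
    the same full-sample mean and covariance as the taxonic mixture (the
    mixture covariance is within-class covariance plus the rank-one
    between-class term, i.e. a common-factor structure), so the two variants
    are moment-matched.  Scores are rounded to integers and clamped to each
    indicator's feasible range.  Dimensional labels are all zero.
    """
    if spec.structure not in ("taxonic", "dimensional"):
        raise ValueError("structure must be 'taxonic' or 'dimensional'")
    ranges = spec.indicator_ranges
    k = len(ranges)
    r = float(spec.within_class_r)
    if not (-1.0 / (k - 1) < r < 1.0):
        raise ValueError(f"within_class_r={r} gives a non-positive-definite correlation matrix")
    center, sd, latent_sd = _indicator_scale(ranges)
    corr = np.full((k, k), r) + (1.0 - r) * np.eye(k)
    cov_within = np.outer(latent_sd, latent_sd) * corr
    delta = float(spec.target_d) * sd  # between-class separation, integer units

    if spec.structure == "taxonic":
        weights = (
            np.asarray(spec.class_weights, dtype=float)
            if spec.class_weights is not None
            else np.array([0.85, 0.15])
        )
        if len(weights) != 2:
            raise ValueError("taxonic indicator spec requires exactly 2 class weights")
        labels = _draw_labels(substream(spec.seed, 0), spec.n, weights)
        z = substream(spec.seed, 1).standard_normal((spec.n, k))
        latent = z @ np.linalg.cholesky(cov_within).T + center + labels[:, None] * delta
    else:
        p = (
            float(np.asarray(spec.class_weights, dtype=float)[1])
            if spec.class_weights is not None
            else 0.15
        )
        mean_full = center + p * delta
        cov_full = cov_within + p * (1.0 - p) * np.outer(delta, delta)
        labels = np.zeros(spec.n, dtype=np.int64)
        z = substream(spec.seed, 1).standard_normal((spec.n, k))
        latent = z @ np.linalg.cholesky(cov_full).T + mean_full

    lo = np.array([rg[0] for rg in ranges])
    hi = np.array([rg[1] for rg in ranges])
    scores = np.clip(np.rint(latent), lo, hi).astype(np.int64)
    cols = [f"ind_{j + 1}" for j in range(k)]
    return pd.DataFrame(scores, columns=cols), labels


# ---------------------------------------------------------------------------
# serialization

def write_matrix(
    frame: pd.DataFrame,
    path,
    labels: np.ndarray | None = None,
    gender: np.ndarray | None = None,
) -> None:
    """Write an item/indicator matrix as CSV, with optional label columns."""
    out = frame.copy()
    if labels is not None:
        out["label"] = labels
    if gender is not None:
        out["gender"] = gender
    out.to_csv(path, index=False)


def read_matrix(path) -> tuple[pd.DataFrame, np.ndarray | None, np.ndarray | None]:
    """Read a CSV written by :func:`write_matrix`; returns (data, labels, gender)."""
    frame = pd.read_csv(path)
    labels = frame.pop("label").to_numpy() if "label" in frame.columns else None
    gender = frame.pop("gender").to_numpy() if "gender" in frame.columns else None
    return frame, labels, gender


def spec_to_yaml(spec: PopulationSpec, path) -> None:
    d = asdict(spec)
    for key in ("class_weights", "class_item_probs", "loadings", "thresholds"):
        if d[key] is not None:
            d[key] = np.asarray(d[key]).tolist()
    d["indicator_ranges"] = [list(r) for r in d["indicator_ranges"]]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def spec_from_yaml(path) -> PopulationSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if d.get("class_item_probs") is not None:
        d["class_item_probs"] = np.asarray(d["class_item_probs"], dtype=float)
    if d.get("indicator_ranges") is not None:
        d["indicator_ranges"] = tuple(tuple(r) for r in d["indicator_ranges"])
    return PopulationSpec(**d)
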