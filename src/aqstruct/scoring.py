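"""Scoring of raw AQ responses.

Raw responses are on a 4-point agreement scale (1 = definitely agree ..
4 = definitely disagree).  Each item is dichotomized: it scores 1 when the
response falls on its *keyed* side (agree-keyed items on 1/2,
disagree-keyed on 3/4), and the total score counts endorsed items (0-50).
Conventional cutoffs are 26 (clinical screening context) and 32
(non-clinical samples); the putative taxon used to seed taxometric
indicator validation is "total >= cutoff".

The instrument's standard keying ships as an editable YAML resource; the
datasets analysed by this package never pin it down, so it is treated as
data rather than code.
"""

from __future__ import annotations

import dataclasses
from importlib import resources as _ilres

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from ._rng import substream

__all__ = [
    "ScoringKey",
    "Descriptives",
    "load_scoring_key",
    "dichotomize_and_score",
    "impute_missing",
    "describe_distribution",
    "assign_putative_taxon",
]


@dataclasses.dataclass(frozen=True)
class ScoringKey:
    """Per-item keyed direction plus conventional total-score cutoffs."""

    directions: dict[str, str]  # item name -> "agree" | "disagree"
    cutoffs: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.directions) != 50:
            raise ValueError(f"scoring key must have exactly 50 items, got {len(self.directions)}")
        bad = {d for d in self.directions.values()} - {"agree", "disagree"}
        if bad:
            raise ValueError(f"unknown keyed directions: {sorted(bad)}")


@dataclasses.dataclass(frozen=True)
class Descriptives:
    """Moments and shape of a total-score distribution.

    Skewness is the moment estimator g1 = m3 / m2^1.5 and kurtosis is excess
    (b2 - 3); both are undefined (NaN, ``degenerate=True``) for constant
    input.  ``normality_p`` is the Shapiro-Wilk p-value.
    """

    n: int
    mean: float
    sd: float
    median: float
    minimum: float
    maximum: float
    skew: float
    excess_kurtosis: float
    normality_p: float
    degenerate: bool = False

    @property
    def range(self) -> float:
        return self.maximum - self.minimum


def load_scoring_key(path=None) -> ScoringKey:
    """Load the packaged standard AQ key, or a user-supplied YAML."""
    if path is None:
        text = _ilres.files("aqstruct.resources").joinpath("aq_scoring_key.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return ScoringKey(directions=dict(raw["directions"]), cutoffs=dict(raw["cutoffs"]))


def dichotomize_and_score(
    raw: pd.DataFrame, key: ScoringKey
) -> tuple[pd.DataFrame, pd.Series]:
    """Dichotomize 4-level responses and count endorsed items per case.

    Missing cells stay missing (impute before relying on totals); the
    returned total counts endorsements over non-missing items.  Responses
    outside {1, 2, 3, 4} raise with the offending cells listed.
    """
    missing_cols = [c for c in key.directions if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"input lacks keyed items: {missing_cols[:5]}...")
    values = raw[list(key.directions)].to_numpy(dtype=float)
    observed = ~np.isnan(values)
    valid = np.isin(values, (1.0, 2.0, 3.0, 4.0)) | ~observed
    if not valid.all():
        rows, cols = np.nonzero(~valid)
        cells = [
            (int(raw.index[r]), list(key.directions)[c], values[r, c])
            for r, c in zip(rows[:10], cols[:10])
        ]
        raise ValueError(f"responses outside 1-4 at (row, item, value): {cells}")
    agree_keyed = np.array([key.directions[c] == "agree" for c in key.directions])
    binary = np.where(agree_keyed, values <= 2, values >= 3).astype(float)
    binary[~observed] = np.nan
    frame = pd.DataFrame(binary, columns=list(key.directions), index=raw.index)
    totals = pd.Series(np.nansum(binary, axis=1), index=raw.index, name="total")
    return frame, totals


def impute_missing(
    items: pd.DataFrame,
    method: str = "mode",
    seed: int | None = 0,
    item_ceiling: float = 0.025,
    case_ceiling: int = 13,
) -> tuple[pd.DataFrame, dict]:
    """Impute missing binary cells; drop cases with excessive missingness.

    Cases missing more than ``case_ceiling`` items are dropped (reported in
    the returned dict), mirroring the practice of excluding only cases with
    substantial missing data.  Items missing in more than ``item_ceiling``
    of retained cases violate the method's precondition and raise.  Observed
    cells are never altered.

    Methods: ``"mode"`` (deterministic per-item majority value, ties -> 0)
    or ``"bernoulli"`` (seeded draw from the observed item mean).
    """
    if method not in ("mode", "bernoulli"):
        raise ValueError(f"unknown imputation method {method!r}")
    values = items.to_numpy(dtype=float)
    miss = np.isnan(values)
    case_missing = miss.sum(axis=1)
    keep = case_missing <= case_ceiling
    report = {
        "method": method,
        "n_dropped_cases": int((~keep).sum()),
        "dropped_index": list(items.index[~keep]),
        "n_imputed_cells": int(miss[keep].sum()),
    }
    values, miss = values[keep], miss[keep]
    if values.shape[0] == 0:
        raise ValueError("all cases dropped by the missingness ceiling")
    item_miss_rate = miss.mean(axis=0)
    if np.any(item_miss_rate > item_ceiling):
        bad = [items.columns[j] for j in np.nonzero(item_miss_rate > item_ceiling)[0]]
        raise ValueError(f"items exceed the per-item missingness ceiling: {bad}")
    if np.any(item_miss_rate == 1.0):
        raise ValueError("an item is entirely missing")
    item_mean = np.nanmean(values, axis=0)
    if method == "mode":
        fill = (item_mean > 0.5).astype(float)  # tie at exactly 0.5 -> 0
        filled = np.where(miss, fill[None, :], values)
    else:
        rng = substream(0 if seed is None else seed, 7)
        draws = (rng.random(values.shape) < item_mean[None, :]).astype(float)
        filled = np.where(miss, draws, values)
    out = pd.DataFrame(filled, columns=items.columns, index=items.index[keep])
    return out, report


def describe_distribution(totals) -> Descriptives:
    """Distributional summary of total scores (n >= 8 required)."""
    x = np.asarray(totals, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 observations")
    sd = float(np.std(x, ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        skew = kurt = p = float("nan")
    else:
        skew = float(scipy.stats.skew(x, bias=True))
        kurt = float(scipy.stats.kurtosis(x, fisher=True, bias=True))
        p = float(scipy.stats.shapiro(x).pvalue)
    return Descriptives(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=sd,
        median=float(np.median(x)),
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        skew=skew,
        excess_kurtosis=kurt,
        normality_p=p,
        degenerate=degenerate,
    )


def assign_putative_taxon(totals, cutoff: float = 32) -> tuple[np.ndarray, float]:
    """Membership (total >= cutoff) and the observed base rate."""
    if not 0 <= cutoff <= 50:
        raise ValueError("cutoff must lie in [0, 50]")
    member = np.asarray(totals, dtype=float) >= cutoff
    return member, float(member.mean())
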