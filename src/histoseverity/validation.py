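"""Pairwise expert-agreement validation of the severity score.

The protocol shows an expert two cutouts and asks which looks more
severely inflamed.  Agreement is the fraction of (non-tied) pairs where
the expert picked the higher-scoring cutout.  Binning pairs by the score
difference |delta| gives the mismatch-ratio curve; the delta beyond which
mismatch stays below an acceptable threshold is the method's effective
resolution on the [0, 1] scale.

Real expert choices arrive as a CSV of recorded decisions; for testing
and calibration a simulated expert with a logistic error model
P(mistake) = 1 / (1 + exp(k * delta)) stands in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ComparisonRecord",
    "AgreementSummary",
    "sample_pairs",
    "simulate_expert",
    "build_records",
    "agreement_rate",
    "mismatch_curve",
    "resolution_estimate",
]


@dataclass(frozen=True)
class ComparisonRecord:
    """One pairwise trial: two scored cutouts and the expert's pick."""

    id_a: str
    id_b: str
    score_a: float
    score_b: float
    expert_choice: str  # "a" or "b"
    delta: float
    agree: bool | None  # None when score_a == score_b (tie)

    def __post_init__(self) -> None:
        if self.expert_choice not in ("a", "b"):
            raise ValueError("expert_choice must be 'a' or 'b'")


def sample_pairs(
    ids: Sequence[str], n_pairs: int, seed: int
) -> list[tuple[str, str]]:
    """Draw ``n_pairs`` unordered pairs of distinct ids, uniformly.

    Sampling is without replacement within a pair (a != b) and with
    replacement across pairs; reproducible for a given seed.
    """
    ids = list(ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 ids to form pairs")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_pairs):
        i, j = rng.choice(len(ids), size=2, replace=False)
        out.append((ids[i], ids[j]))
    return out


def simulate_expert(
    pairs: Sequence[tuple[str, str]],
    scores: Mapping[str, float],
    error_scale: float | None = None,
    seed: int = 0,
) -> list[str]:
    """Simulated expert choices for each pair.

    With ``error_scale=None`` the expert is perfect: always picks the
    higher-scoring cutout (ties broken 'a').  Otherwise the expert errs
    with logistic probability ``1 / (1 + exp(error_scale * delta))``,
    where delta is the absolute score difference — maximally confused
    (p = 0.5) on identical scores, increasingly reliable as the pair
    separates.
    """
    rng = np.random.default_rng(seed)
    choices = []
    for id_a, id_b in pairs:
        sa, sb = scores[id_a], scores[id_b]
        correct = "a" if sa >= sb else "b"
        if error_scale is None:
            choices.append(correct)
            continue
        delta = abs(sa - sb)
        p_mistake = 1.0 / (1.0 + np.exp(error_scale * delta))
        if rng.random() < p_mistake:
            choices.append("b" if correct == "a" else "a")
        else:
            choices.append(correct)
    return choices


def build_records(
    pairs: Sequence[tuple[str, str]],
    choices: Sequence[str],
    scores: Mapping[str, float],
) -> list[ComparisonRecord]:
    """Assemble ComparisonRecords from pairs, expert choices and scores."""
    if len(pairs) != len(choices):
        raise ValueError("pairs and choices lengths differ")
    records = []
    for (id_a, id_b), choice in zip(pairs, choices):
        sa, sb = float(scores[id_a]), float(scores[id_b])
        if sa == sb:
            agree = None
        else:
            higher = "a" if sa > sb else "b"
            agree = choice == higher
        records.append(
            ComparisonRecord(
                id_a=id_a,
                id_b=id_b,
                score_a=sa,
                score_b=sb,
                expert_choice=choice,
                delta=abs(sa - sb),
                agree=agree,
            )
        )
    return records


@dataclass(frozen=True)
class AgreementSummary:
    rate: float
    n_agree: int
    n_compared: int
    n_ties: int


def agreement_rate(records: Sequence[ComparisonRecord]) -> AgreementSummary:
    """Fraction of non-tie trials where the expert picked the higher score."""
    ties = sum(1 for r in records if r.agree is None)
    compared = [r for r in records if r.agree is not None]
    if not compared:
        raise ValueError("all records are ties; agreement rate undefined")
    n_agree = sum(1 for r in compared if r.agree)
    return AgreementSummary(
        rate=n_agree / len(compared),
        n_agree=n_agree,
        n_compared=len(compared),
        n_ties=ties,
    )


def mismatch_curve(records: Sequence[ComparisonRecord], n_bins: int = 20) -> pd.DataFrame:
    """Mismatch ratio (1 - agreement) binned by score difference.

    Bins are equal-width over [0, 1].  Empty bins carry count 0 and a NaN
    ratio.  Tied pairs are excluded, matching :func:`agreement_rate`.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(records) == 0:
        raise ValueError("no records")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    compared = [r for r in records if r.agree is not None]
    deltas = np.array([r.delta for r in compared])
    mism = np.array([not r.agree for r in compared], dtype=float)
    idx = np.clip(np.digitize(deltas, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=mism, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        ratio = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "mismatch": ratio,
            "count": counts,
        }
    )


def resolution_estimate(curve: pd.DataFrame, threshold: float) -> float | None:
    """Smallest delta beyond which every bin's mismatch stays <= threshold.

    Scans candidate bin lower edges from the left and returns the first
    edge such that all non-empty bins at or above it satisfy the
    threshold; ``None`` if even the last bin fails.  A non-monotone curve
    triggers a warning but is still scanned.
    """
    mism = curve["mismatch"].to_numpy()
    lo = curve["bin_lo"].to_numpy()
    filled = ~np.isnan(mism)
    vals = mism[filled]
    if vals.size >= 2 and np.any(np.diff(vals) > 0.25):
        warnings.warn("mismatch curve is strongly non-monotone", stacklevel=2)
    ok = np.where(filled, mism <= threshold, True)
    # suffix_ok[i]: all bins i.. satisfy the threshold
    suffix_ok = np.logical_and.accumulate(ok[::-1])[::-1]
    hits = np.flatnonzero(suffix_ok)
    if hits.size == 0:
        return None
    return float(lo[hits[0]])
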