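"""Descriptive statistics and rank tests for dyadic affiliation data.

Covers the per-category interaction rates (median and IQR of y/gamma across
dyads), per-focal partner counts per minute followed, focal-partner age
differences, the Kruskal-Wallis rank sum test with tie correction, and the
pre-model collinearity screen on covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .focal_data_io import DyadObservation, FocalFollow, InteractionEvent
from .population_model import FocalStatus, Registry

PARTNER_CATEGORIES = ("age_mate", "aunt", "bull", "calf", "matriarch", "mother", "sister")
COLLINEARITY_THRESHOLD = 0.7


def interaction_rate(dyads: Sequence[DyadObservation]) -> pd.DataFrame:
    """Median (IQR) per-dyad interaction rates by partner category.

    The rate of a dyad is its affiliative count divided by its co-occurrence
    exposure in minutes. A dyad contributes to every category whose flag is
    true; dyads matching no category are summarized under "uncategorized".
    Empty cells are simply absent from the output (no zero-filled rows).
    """
    rows = []
    groups: dict[tuple[str, str, str], list[float]] = {}
    for d in dyads:
        cats = d.flags.categories() or ["uncategorized"]
        for cat in cats:
            groups.setdefault((d.activity, d.stratum, cat), []).append(d.rate)
    for (activity, stratum, cat), rates in sorted(groups.items()):
        q1, med, q3 = np.percentile(rates, [25, 50, 75])
        rows.append({
            "activity": activity, "stratum": stratum, "category": cat,
            "n_dyads": len(rates), "median": med, "q1": q1, "q3": q3,
        })
    return pd.DataFrame(rows, columns=["activity", "stratum", "category",
                                       "n_dyads", "median", "q1", "q3"])


def partners_per_time(
    follows: Sequence[FocalFollow],
    interactions: Sequence[InteractionEvent],
    focal_id: str,
    activity: str,
) -> float:
    """Distinct affiliative partners per focal minute in one activity.

    Raises ValueError when the focal has no follow minutes in the activity
    (such focals are excluded from the test, not zero-scored).
    """
    fols = [f for f in follows if f.focal_id == focal_id and f.activity == activity]
    total_minutes = sum(f.duration_minutes for f in fols)
    if total_minutes <= 0:
        raise ValueError(f"focal {focal_id!r} has no {activity} follow minutes")
    follow_ids = {f.follow_id for f in fols}
    partners = {
        ev.partner_id for ev in interactions
        if ev.follow_id in follow_ids and ev.is_affiliative
    }
    return len(partners) / total_minutes


def partner_rates_by_stratum(
    follows: Sequence[FocalFollow],
    interactions: Sequence[InteractionEvent],
    statuses: dict[str, FocalStatus],
    activity: str,
) -> dict[str, list[float]]:
    """Per-focal partner-per-minute values grouped by stratum."""
    out: dict[str, list[float]] = {"orphan": [], "non_orphan": []}
    for focal_id, status in sorted(statuses.items()):
        try:
            rate = partners_per_time(follows, interactions, focal_id, activity)
        except ValueError:
            continue
        out[status.stratum].append(rate)
    return out


def age_differences(
    follows: Sequence[FocalFollow],
    interactions: Sequence[InteractionEvent],
    registry: Registry,
    statuses: dict[str, FocalStatus],
    activity: str,
    partner_filter: str = "all_partners",
    window: Optional[tuple[float, float]] = None,
) -> dict[str, list[float]]:
    """Per-focal mean age difference to affiliative partners, by stratum.

    For each focal, the partners with at least one affiliative event in the
    activity are collected; each contributes partner_age - focal_age (ages at
    the study midpoint). ``partner_filter`` is either ``all_partners`` or
    ``older_females_excluding_bulls`` (only female partners older than the
    focal). The per-focal statistic is the mean over retained partners, so
    focals are the independent replicates; focals with no retained partner
    are excluded.
    """
    if partner_filter not in ("all_partners", "older_females_excluding_bulls"):
        raise ValueError(f"unknown partner_filter {partner_filter!r}")
    from .focal_data_io import study_window
    if window is None:
        window = study_window(follows)
    mid = 0.5 * (window[0] + window[1])

    fols = [f for f in follows if f.activity == activity]
    by_follow = {f.follow_id: f for f in fols}
    partners_of: dict[str, set[str]] = {}
    for ev in interactions:
        fol = by_follow.get(ev.follow_id)
        if fol is not None and ev.is_affiliative:
            partners_of.setdefault(fol.focal_id, set()).add(ev.partner_id)

    out: dict[str, list[float]] = {"orphan": [], "non_orphan": []}
    for focal_id in sorted(partners_of):
        focal_rec = registry[focal_id]
        focal_age = focal_rec.age_at(mid)
        diffs = []
        for pid in sorted(partners_of[focal_id]):
            partner = registry[pid]
            diff = partner.age_at(mid) - focal_age
            if partner_filter == "older_females_excluding_bulls":
                if partner.sex != "F" or diff <= 0:
                    continue
            diffs.append(diff)
        if diffs:
            out[statuses[focal_id].stratum].append(float(np.mean(diffs)))
    return out


@dataclass(frozen=True)
class KruskalWallisResult:
    statistic: float  # tie-corrected H, chi-square distributed under H0
    pvalue: float
    df: int


def kruskal_wallis(*groups: Sequence[float], method: str = "chi2") -> KruskalWallisResult:
    """Kruskal-Wallis rank sum test across two or more groups.

    H = 12/(N(N+1)) * sum_k R_k^2/n_k - 3(N+1) on mid-ranks, divided by the
    tie-correction factor 1 - sum(t^3 - t)/(N^3 - N). When every pooled value
    is identical the correction denominator vanishes and H is defined as 0.

    ``method='chi2'`` takes the p-value from chi-square with (groups - 1)
    degrees of freedom; ``method='permutation'`` enumerates all assignments of
    the pooled values to group labels (two groups, small samples only) and
    reports the exact tail probability of the observed H.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("each group must be non-empty")
    h, df = _h_statistic(arrays)
    if method == "chi2":
        p = float(sps.chi2.sf(h, df)) if h > 0 else 1.0
        return KruskalWallisResult(h, p, df)
    if method == "permutation":
        if len(arrays) != 2:
            raise ValueError("exact permutation implemented for two groups")
        pooled = np.concatenate(arrays)
        n1 = arrays[0].size
        idx = range(pooled.size)
        count = total = 0
        for chosen in combinations(idx, n1):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(chosen)] = True
            h_perm, _ = _h_statistic([pooled[mask], pooled[~mask]])
            total += 1
            if h_perm >= h - 1e-12:
                count += 1
        return KruskalWallisResult(h, count / total, df)
    raise ValueError(f"unknown method {method!r}")


def _h_statistic(arrays: list[np.ndarray]) -> tuple[float, int]:
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start:start + a.size]
        h += r.sum() ** 2 / a.size
        start += a.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))
    denom = 1.0 - tie_term / (n_total ** 3 - n_total)
    if denom <= 0:
        return 0.0, len(arrays) - 1  # all pooled values identical
    return max(h / denom, 0.0), len(arrays) - 1


@dataclass(frozen=True)
class CollinearityReport:
    covariates: tuple[str, ...]
    corr: pd.DataFrame
    max_abs_r: float
    flagged_pairs: tuple[tuple[str, str, float], ...]
    degenerate: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.flagged_pairs


def collinearity_screen(
    X: np.ndarray,
    names: Sequence[str],
    threshold: float = COLLINEARITY_THRESHOLD,
) -> CollinearityReport:
    """Pairwise Pearson correlations among model covariates.

    Pairs with |r| strictly greater than ``threshold`` (default 0.7) are
    flagged. Zero-variance columns cannot enter a correlation; they are
    reported as degenerate and excluded from the pairwise computation.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(names):
        raise ValueError("X must be (n, p) with one name per column")
    sds = X.std(axis=0)
    keep = sds > 0
    degenerate = tuple(n for n, k in zip(names, keep) if not k)
    kept_names = [n for n, k in zip(names, keep) if k]
    if len(kept_names) < 2:
        corr = pd.DataFrame(np.eye(len(kept_names)), index=kept_names, columns=kept_names)
        return CollinearityReport(tuple(names), corr, 0.0, (), degenerate)
    r = np.corrcoef(X[:, keep], rowvar=False)
    corr = pd.DataFrame(r, index=kept_names, columns=kept_names)
    flagged = []
    max_abs = 0.0
    for i, j in combinations(range(len(kept_names)), 2):
        rij = float(r[i, j])
        max_abs = max(max_abs, abs(rij))
        if abs(rij) > threshold:
            flagged.append((kept_names[i], kept_names[j], rij))
    return CollinearityReport(tuple(names), corr, max_abs, tuple(flagged), degenerate)
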