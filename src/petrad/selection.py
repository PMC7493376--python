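"""Two-step feature reduction and selection.

Step 1 (de-duplication): walk the features in registry order; for each
not-yet-deleted feature, collect the features whose pairwise Pearson
correlation with it exceeds the threshold (|r| > 0.9 by default), keep the
group member with the largest absolute point-biserial correlation against the
binary outcome, delete the rest; repeat to a fixed point, so survivors are
pairwise below the threshold.

Step 2 (thresholding): recompute the point-biserial correlation for every
survivor and keep those with |r_pb| above the selection threshold (0.25 by
default), reporting each survivor's univariate ROC AUC with a DeLong
confidence interval.

Absolute correlations are used throughout: anti-correlated duplicates carry
the same information, and a strongly negative feature-outcome association is
as informative as a positive one.  Group ties on |r_pb| keep the feature
earlier in registry order, so the procedure is deterministic and row order
never matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    corr_threshold: float = 0.9
    rpb_threshold: float = 0.25
    ci_level: float = 0.95
    max_missing_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.corr_threshold < 1) or not (0 < self.rpb_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")


@dataclass
class SelectionResult:
    selected: list[str]
    rpb: dict[str, float]
    auc: dict[str, float]
    auc_ci: dict[str, tuple[float, float]]
    audit: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def point_biserial(x: np.ndarray, y: np.ndarray) -> float:
    """Point-biserial correlation = Pearson correlation of x with 0/1-coded y."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(x)
    x, y = x[ok], y[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if np.std(x) == 0:
        raise ValueError("feature is constant; point-biserial undefined")
    return float(np.corrcoef(x, y)[0, 1])


def _rpb_or_nan(x: np.ndarray, y: np.ndarray) -> float:
    try:
        return point_biserial(x, y)
    except ValueError:
        return float("nan")


def delong_auc_ci(y: np.ndarray, score: np.ndarray, level: float = 0.95
                  ) -> tuple[float, tuple[float, float]]:
    """ROC AUC with a DeLong (1988) confidence interval.

    Uses the mid-rank formulation of the AUC covariance estimator."""
    y = np.asarray(y).astype(int)
    score = np.asarray(score, dtype=np.float64)
    pos = score[y == 1]
    neg = score[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes required for AUC")

    def midrank(x):
        order = np.argsort(x)
        ranks = np.empty(len(x), dtype=np.float64)
        sx = x[order]
        i = 0
        while i < len(x):
            j = i
            while j < len(x) and sx[j] == sx[i]:
                j += 1
            ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
            i = j
        return ranks

    allv = np.concatenate([pos, neg])
    tx = midrank(pos)
    ty = midrank(neg)
    tz = midrank(allv)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    s = v01.var(ddof=1) / m + v10.var(ddof=1) / n if m > 1 and n > 1 else 0.0
    se = float(np.sqrt(max(s, 0.0)))
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return float(auc), (float(lo), float(hi))


def _prepare(table: pd.DataFrame, labels: pd.Series, cfg: SelectionConfig
             ) -> tuple[pd.DataFrame, list[dict]]:
    """Drop features with too many missing values or zero variance."""
    audit = []
    keep = []
    for col in table.columns:
        x = table[col].to_numpy(dtype=np.float64)
        frac_missing = float(np.mean(~np.isfinite(x)))
        if frac_missing > cfg.max_missing_fraction:
            audit.append({"feature": col, "action": "dropped",
                          "reason": f"{frac_missing:.0%} missing"})
            continue
        if np.nanstd(x) == 0:
            audit.append({"feature": col, "action": "dropped", "reason": "constant"})
            continue
        keep.append(col)
    return table[keep], audit


def correlation_dedupe(table: pd.DataFrame, labels: pd.Series,
                       cfg: SelectionConfig | None = None
                       ) -> tuple[pd.DataFrame, list[dict]]:
    """Step 1: remove correlated duplicates, keeping the best |r_pb| per group."""
    cfg = cfg or SelectionConfig()
    table, audit = _prepare(table, labels, cfg)
    y = labels.to_numpy()
    cols = list(table.columns)
    rpb = {c: abs(_rpb_or_nan(table[c].to_numpy(np.float64), y)) for c in cols}
    # pairwise-complete Pearson correlations (pandas handles NaN pairs)
    corr = table.corr().abs()

    alive = dict.fromkeys(cols, True)
    changed = True
    while changed:
        changed = False
        for f in cols:
            if not alive[f]:
                continue
            group = [g for g in cols
                     if alive[g] and g != f and corr.loc[f, g] > cfg.corr_threshold]
            if not group:
                continue
            group = [f] + group
            # keep the largest |r_pb|; ties keep the earliest in registry order
            best = max(group, key=lambda g: (np.nan_to_num(rpb[g], nan=-1.0),
                                             -cols.index(g)))
            for g in group:
                if g != best:
                    alive[g] = False
                    changed = True
                    audit.append({"feature": g, "action": "deleted",
                                  "reason": f"|r|>{cfg.corr_threshold} with group",
                                  "displaced_by": best})
    survivors = [c for c in cols if alive[c]]
    return table[survivors], audit


def threshold_select(table: pd.DataFrame, labels: pd.Series,
                     cfg: SelectionConfig | None = None,
                     audit: list[dict] | None = None) -> SelectionResult:
    """Step 2: keep survivors with |r_pb| above threshold; report AUC + CI."""
    cfg = cfg or SelectionConfig()
    y = labels.to_numpy()
    audit = list(audit or [])
    rpb, auc, ci = {}, {}, {}
    selected = []
    for col in table.columns:
        x = table[col].to_numpy(np.float64)
        r = _rpb_or_nan(x, y)
        rpb[col] = r
        if np.isfinite(r) and abs(r) > cfg.rpb_threshold:
            selected.append(col)
            ok = np.isfinite(x)
            a, (lo, hi) = delong_auc_ci(y[ok], x[ok], cfg.ci_level)
            # report the AUC of the discriminative orientation
            auc[col] = max(a, 1.0 - a)
            ci[col] = (lo, hi) if a >= 0.5 else (1.0 - hi, 1.0 - lo)
        else:
            audit.append({"feature": col, "action": "rejected",
                          "reason": f"|r_pb|={abs(r):.3f} <= {cfg.rpb_threshold}"})
    warnings_ = []
    if not selected:
        warnings_.append("no feature passed the point-biserial threshold; "
                         "consider relaxing rpb_threshold")
        log.warning(warnings_[-1])
    return SelectionResult(selected, rpb, auc, ci, audit, warnings_)


def select_features(table: pd.DataFrame, labels: pd.Series,
                    cfg: SelectionConfig | None = None) -> SelectionResult:
    """The full two-step procedure (de-duplication, then thresholding)."""
    cfg = cfg or SelectionConfig()
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present")
    reduced, audit = correlation_dedupe(table, labels, cfg)
    return threshold_select(reduced, labels, cfg, audit)
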