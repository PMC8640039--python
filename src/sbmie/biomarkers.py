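"""Biomarker screening and validation.

The screen ranks significant content-differential metabolites by VIP, takes
the top K per ion mode, merges the positive- and negative-mode lists by
metabolite name (a metabolite detected in both modes counts once), and
intersects the merged panels across soybean-meal dose levels into the "core
biomarker" set conserved at every substitution level. Candidate panels are
validated by z-scores against the control group, single-feature ROC/AUC
(computed as the normalized Mann-Whitney U statistic, ties at 0.5), and a
significance-masked Pearson correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import DifferentialRecord

__all__ = [
    "BiomarkerPanel",
    "CorePanel",
    "RocResult",
    "CorrelationMatrix",
    "top_vip",
    "merge_modes",
    "build_biomarker_panel",
    "intersect_levels",
    "zscore_vs_control",
    "roc_auc",
    "correlation_matrix",
]


@dataclass
class BiomarkerPanel:
    group: str
    mode_lists: dict[str, list[str]]  # ion mode -> top-K names, VIP descending
    merged: set[str]
    co_contained_modes: set[str]


@dataclass
class CorePanel:
    core: set[str]
    specific_per_level: dict[str, set[str]]


@dataclass
class RocResult:
    feature_id: str
    auc: float
    orientation: str  # "case_high" | "case_low"


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    mask: pd.DataFrame  # True where the correlation is blanked (p > alpha or undefined)


def top_vip(records: list[DifferentialRecord], k: int = 10) -> list[str]:
    """Top-k significant features by VIP; ties by smaller P, then id.

    Returns feature ids in rank order; if fewer than k features are
    significant, all of them are returned with a warning.
    """
    sig = [r for r in records if r.significant]
    ranked = sorted(sig, key=lambda r: (-r.vip, r.p_value, r.feature_id))
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} significant features available for top-{k}",
            stacklevel=2,
        )
    return [r.feature_id for r in ranked[:k]]


def merge_modes(pos_list: list[str], neg_list: list[str]) -> tuple[set[str], set[str]]:
    """Union of the per-mode panels by metabolite name; duplicates counted once.

    Returns (merged set, co-contained set); the co-contained set holds the
    names present in both ion modes.
    """
    pos, neg = set(pos_list), set(neg_list)
    return pos | neg, pos & neg


def build_biomarker_panel(
    group: str, mode_lists: dict[str, list[str]]
) -> BiomarkerPanel:
    """Assemble a per-dose-level panel from per-mode ranked name lists."""
    modes = list(mode_lists)
    if len(modes) == 1:
        merged, co = set(mode_lists[modes[0]]), set()
    else:
        merged, co = merge_modes(*(mode_lists[m] for m in modes[:2]))
        for m in modes[2:]:
            extra = set(mode_lists[m])
            co |= merged & extra
            merged |= extra
    return BiomarkerPanel(group=group, mode_lists=mode_lists, merged=merged, co_contained_modes=co)


def intersect_levels(panels: dict[str, set[str]]) -> CorePanel:
    """Core biomarkers = intersection of panels across dose levels.

    ``panels`` maps a dose-level label to its merged biomarker name set; the
    level-specific sets are each panel minus the core.
    """
    if len(panels) < 2:
        raise ValueError("need panels from at least 2 dose levels")
    sets = list(panels.values())
    core = set.intersection(*[set(s) for s in sets])
    specific = {level: set(s) - core for level, s in panels.items()}
    return CorePanel(core=core, specific_per_level=specific)


def zscore_vs_control(values, control_values) -> np.ndarray:
    """z = (x - mean(control)) / sd(control), sample (n-1) standard deviation."""
    x = np.asarray(values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    sd = c.std(ddof=1)
    if not sd > 0:
        raise ValueError("control group has zero standard deviation")
    return (x - c.mean()) / sd


def roc_auc(case_values, control_values, feature_id: str = "") -> RocResult:
    """AUC as the normalized Mann-Whitney U with ties counted 0.5.

    Orientation is auto-chosen so AUC >= 0.5 and recorded: ``case_high``
    means higher intensities indicate the case class.
    """
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both classes need at least one value")
    pooled = np.concatenate([case, ctrl])
    ranks = stats.rankdata(pooled)  # midranks handle ties as 1/2
    r_case = ranks[: case.size].sum()
    u = r_case - case.size * (case.size + 1) / 2.0
    auc = u / (case.size * ctrl.size)
    if auc >= 0.5:
        return RocResult(feature_id, float(auc), "case_high")
    return RocResult(feature_id, float(1.0 - auc), "case_low")


def correlation_matrix(
    panel: pd.DataFrame, method: str = "pearson", alpha: float = 0.05
) -> CorrelationMatrix:
    """Pairwise feature correlation across samples with a significance mask.

    ``panel`` is features × samples. P values come from the t-distribution
    transform t = r sqrt((n-2)/(1-r^2)); pairs with p > alpha are masked
    (blanked), as are pairs involving a constant feature (r undefined). The
    diagonal is r = 1, unmasked.
    """
    if panel.shape[1] < 3:
        raise ValueError("correlation needs at least 3 samples")
    if method == "spearman":
        data = pd.DataFrame(
            stats.rankdata(panel.to_numpy(dtype=float), axis=1),
            index=panel.index,
            columns=panel.columns,
        )
    elif method == "pearson":
        data = panel.astype(float)
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    X = data.to_numpy()
    m, n = X.shape
    sd = X.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{constant.sum()} constant feature(s): correlations undefined, masked",
            stacklevel=2,
        )
    centered = X - X.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / (n - 1)
    denom = np.outer(sd, sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / denom
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(t), 1.0, np.where(np.isinf(t), 0.0, p))
    np.fill_diagonal(p, 0.0)

    undefined = np.isnan(r) | constant[:, None] | constant[None, :]
    mask = (p > alpha) | undefined
    np.fill_diagonal(mask, False)
    idx = panel.index
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        mask=pd.DataFrame(mask, index=idx, columns=idx),
    )
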