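"""Per-feature two-group differential analysis and dose-trend profiling.

For each feature the stage computes the group-mean log2 fold change, a
two-sided univariate test P value, and a PLS-DA variable importance in
projection (VIP) score, then classifies features as up/down/none under either
the DEG rule (|log2FC| > 1 and P < 0.05) or the metabolite rule (P < alpha
and VIP >= vip_min). Trend profiling assigns features whose group means move
strictly monotonically along the full dose ladder (with a significant
extreme-group contrast) to profile A (increasing) or B (decreasing).

The VIP score is computed from a NIPALS PLS1 fit on the autoscaled matrix
with the class coded 0/1:

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a )

where SS_a = q_a^2 t_a't_a is the Y-variance explained by component a. The
normalization gives sum_j VIP_j^2 = p exactly, so VIP = 1 is the
"average importance" reference line used for biomarker screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable, RunConfig, SampleMetadata

__all__ = [
    "DifferentialRecord",
    "TrendProfile",
    "records_from_frame",
    "log2_fold_change",
    "group_test",
    "plsda_vip",
    "classify_differential",
    "differential_table",
    "assign_trend_profiles",
]


@dataclass
class DifferentialRecord:
    feature_id: str
    mean_control: float
    mean_treatment: float
    log2fc: float
    p_value: float
    vip: float = float("nan")
    trend: str = "none"  # up | down | none
    significant: bool | None = None  # None: not yet classified


def records_from_frame(frame: pd.DataFrame) -> list[DifferentialRecord]:
    """Rebuild DifferentialRecords from a table written by ``write_table``."""
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            DifferentialRecord(
                feature_id=str(row.feature_id),
                mean_control=float(row.mean_control),
                mean_treatment=float(row.mean_treatment),
                log2fc=float(row.log2fc),
                p_value=float(row.p_value),
                vip=float(row.vip),
                trend=str(row.trend),
                significant=bool(row.significant) if not pd.isna(row.significant) else None,
            )
        )
    return out


@dataclass
class TrendProfile:
    feature_id: str
    profile: str  # A | B | none
    group_means: tuple[float, ...]
    p_value: float


def log2_fold_change(
    control_values, treatment_values, pseudo_mean: float | None = None
) -> float:
    """log2 of the treatment/control group-mean intensity ratio.

    A zero control mean is replaced by ``pseudo_mean`` when configured;
    otherwise it is an error (the ratio is undefined).
    """
    c = np.asarray(control_values, dtype=float)
    t = np.asarray(treatment_values, dtype=float)
    if c.size == 0 or t.size == 0:
        raise ValueError("both groups must be non-empty")
    if (c < 0).any() or (t < 0).any():
        raise ValueError("intensities must be non-negative")
    mc, mt = c.mean(), t.mean()
    if mc == 0.0:
        if pseudo_mean is None:
            raise ValueError("control mean is zero and no pseudo-mean is configured")
        mc = pseudo_mean
    if mt == 0.0:
        if pseudo_mean is None:
            return float("-inf")
        mt = pseudo_mean
    return float(np.log2(mt / mc))


def group_test(control_values, treatment_values, method: str = "welch_t") -> float:
    """Two-sided two-group test P value.

    ``welch_t`` / ``student_t`` require n >= 2 per group; ``wilcoxon`` is the
    exact-when-feasible Wilcoxon rank-sum (Mann-Whitney) test. Two groups with
    zero variance and equal values give P = 1 by convention.
    """
    c = np.asarray(control_values, dtype=float)
    t = np.asarray(treatment_values, dtype=float)
    if method in ("welch_t", "student_t"):
        if c.size < 2 or t.size < 2:
            raise ValueError("t tests need at least 2 values per group")
        if c.std() == 0.0 and t.std() == 0.0:
            return 1.0 if c.mean() == t.mean() else 0.0
        res = stats.ttest_ind(t, c, equal_var=(method == "student_t"))
        return float(res.pvalue)
    if method == "wilcoxon":
        if c.size < 1 or t.size < 1:
            raise ValueError("rank test needs at least 1 value per group")
        if np.array_equal(np.sort(c), np.sort(t)):
            return 1.0
        res = stats.mannwhitneyu(t, c, alternative="two-sided")
        return float(res.pvalue)
    raise ValueError(f"unknown test method {method!r}")


def plsda_vip(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 2,
    scale: bool = True,
) -> np.ndarray:
    """VIP per feature from a NIPALS PLS1 fit of the 0/1 class membership.

    ``X`` is samples × features; ``y`` the binary class vector. Features are
    autoscaled (mean 0, unit variance) when ``scale``; constant features are
    excluded from scaling with a warning and receive VIP 0. If
    ``n_components`` exceeds the available rank the fit is truncated with a
    warning. Over the included features, sum(VIP^2) equals their count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("y length must match number of rows of X")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("plsda_vip needs exactly two classes")
    counts = [(y == c).sum() for c in classes]
    if min(counts) < 2:
        raise ValueError("need at least 2 samples per class")

    sd = X.std(axis=0, ddof=1)
    included = sd > 0
    if not included.all():
        warnings.warn(
            f"{(~included).sum()} constant feature(s) excluded from PLS-DA scaling; "
            "their VIP is 0",
            stacklevel=2,
        )
    Xw = X[:, included] - X[:, included].mean(axis=0)
    if scale:
        Xw = Xw / sd[included]
    yw = y - y.mean()

    p_inc = Xw.shape[1]
    max_comp = min(n - 1, p_inc)
    a_req = n_components
    if a_req > max_comp:
        warnings.warn(
            f"n_components reduced from {a_req} to {max_comp} (rank limit)",
            stacklevel=2,
        )
        a_req = max_comp

    W, SS = [], []
    Xa, ya = Xw.copy(), yw.copy()
    for _ in range(a_req):
        cov = Xa.T @ ya
        norm = np.linalg.norm(cov)
        if norm < 1e-12 * max(1.0, np.abs(Xa).max(initial=0.0)):
            break  # no covariance left to model
        w = cov / norm
        t = Xa @ w
        tt = t @ t
        if tt <= 0:
            break
        p_load = Xa.T @ t / tt
        q = ya @ t / tt
        Xa = Xa - np.outer(t, p_load)
        ya = ya - q * t
        W.append(w)
        SS.append(q * q * tt)

    vip_inc = np.zeros(p_inc)
    if W:
        Wm = np.column_stack(W)  # columns already unit norm
        SSa = np.asarray(SS)
        vip_inc = np.sqrt(p_inc * (Wm**2 @ SSa) / SSa.sum())

    vip = np.zeros(p)
    vip[included] = vip_inc
    return vip


def classify_differential(
    records: list[DifferentialRecord],
    mode: str = "metabolite",
    p_alpha: float = 0.05,
    vip_min: float = 1.0,
    lfc_min: float | None = None,
) -> list[DifferentialRecord]:
    """Set the ``significant`` flag and trend sign on each record in place.

    DEG mode: significant iff |log2FC| > lfc_min and P < p_alpha.
    Metabolite mode: significant iff P < p_alpha and VIP >= vip_min, with an
    optional |log2FC| > lfc_min gate.
    """
    if mode == "deg" and lfc_min is None:
        lfc_min = 1.0
    for r in records:
        if mode == "deg":
            sig = abs(r.log2fc) > lfc_min and r.p_value < p_alpha
        elif mode == "metabolite":
            sig = r.p_value < p_alpha and r.vip >= vip_min
            if lfc_min is not None:
                sig = sig and abs(r.log2fc) > lfc_min
        else:
            raise ValueError(f"unknown classification mode {mode!r}")
        r.significant = bool(sig)
        r.trend = "up" if sig and r.log2fc > 0 else "down" if sig and r.log2fc < 0 else "none"
    return records


def _normalize(values: np.ndarray, how: str) -> np.ndarray:
    """Per-sample total-intensity scaling and/or log2 transform (columns = samples)."""
    if how == "none":
        return values
    v = values.astype(float)
    if how == "tic_log":
        totals = v.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("a sample has zero total intensity")
        v = v / totals * totals.mean()
    elif how != "log":
        raise ValueError(f"unknown normalization {how!r}")
    # half-minimum floor keeps zeros finite on the log scale
    positive_min = v[v > 0].min() if (v > 0).any() else 1.0
    return np.log2(np.maximum(v, positive_min / 2.0))


def differential_table(
    table: FeatureTable,
    metadata: SampleMetadata,
    control: str,
    treatment: str,
    config: RunConfig | None = None,
    compartment: str | None = None,
    ion_mode: str | None = None,
    compute_vip: bool = True,
) -> list[DifferentialRecord]:
    """Run the full two-group differential stage over a feature table.

    Means and log2FC are reported on the raw intensity scale (matching how
    ion-intensity tables are published); the univariate test and the PLS-DA
    fit run on normalized log2 intensities per the configured normalization.
    Optional Benjamini-Hochberg correction replaces raw P values when
    ``config.multiple_testing == "bh"``.
    """
    config = config or RunConfig()
    ctrl_ids = metadata.samples_where(group=control, compartment=compartment, ion_mode=ion_mode)
    trt_ids = metadata.samples_where(group=treatment, compartment=compartment, ion_mode=ion_mode)
    ctrl_ids = [s for s in ctrl_ids if s in table.data.columns]
    trt_ids = [s for s in trt_ids if s in table.data.columns]
    if not ctrl_ids or not trt_ids:
        raise ValueError("control or treatment group has no samples in the table")

    raw_c = table.data[ctrl_ids].to_numpy(dtype=float)
    raw_t = table.data[trt_ids].to_numpy(dtype=float)
    sub = table.data[ctrl_ids + trt_ids].to_numpy(dtype=float)
    norm = _normalize(sub, config.normalization)
    nc = len(ctrl_ids)

    records = []
    for j, fid in enumerate(table.feature_ids):
        lfc = log2_fold_change(raw_c[j], raw_t[j], pseudo_mean=None)
        p = group_test(norm[j, :nc], norm[j, nc:], method=config.test)
        records.append(
            DifferentialRecord(
                feature_id=fid,
                mean_control=float(raw_c[j].mean()),
                mean_treatment=float(raw_t[j].mean()),
                log2fc=lfc,
                p_value=p,
            )
        )

    if config.multiple_testing == "bh":
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([r.p_value for r in records], method="fdr_bh")[1]
        for r, q in zip(records, adj):
            r.p_value = float(q)

    if compute_vip:
        y = np.r_[np.zeros(nc), np.ones(len(trt_ids))]
        vip = plsda_vip(norm.T, y, n_components=config.plsda_components)
        for r, v in zip(records, vip):
            r.vip = float(v)
    return records


def assign_trend_profiles(
    table: FeatureTable,
    metadata: SampleMetadata,
    p_alpha: float = 0.05,
    test: str = "welch_t",
    compartment: str | None = None,
    ion_mode: str | None = None,
) -> list[TrendProfile]:
    """Profile A/B assignment along the full dose ladder.

    Profile A: group means strictly increase across every step of the ladder
    and the extreme-group (lowest vs highest dose) test has P < p_alpha;
    profile B is the strictly decreasing mirror; anything else is none.
    """
    ladder = metadata.group_ladder
    if len(ladder) < 3:
        raise ValueError("trend profiling needs at least 3 dose levels")
    group_cols = []
    for g in ladder:
        ids = [
            s
            for s in metadata.samples_where(group=g, compartment=compartment, ion_mode=ion_mode)
            if s in table.data.columns
        ]
        if not ids:
            raise ValueError(f"group {g!r} has no samples in the table")
        group_cols.append(ids)

    out = []
    for fid in table.feature_ids:
        row = table.data.loc[fid]
        means = tuple(float(row[ids].mean()) for ids in group_cols)
        p = group_test(row[group_cols[0]].to_numpy(), row[group_cols[-1]].to_numpy(), method=test)
        increasing = all(a < b for a, b in zip(means, means[1:]))
        decreasing = all(a > b for a, b in zip(means, means[1:]))
        if increasing and p < p_alpha:
            profile = "A"
        elif decreasing and p < p_alpha:
            profile = "B"
        else:
            profile = "none"
        out.append(TrendProfile(fid, profile, means, p))
    return out
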