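"""Seeded synthetic multi-compartment metabolome and OTU data.

Emulates the feeding-trial design the pipeline targets: three diet groups on
an ordered soybean-meal dose ladder (FM < SBM20 < SBM40), twelve samples per
group per compartment, ~2,000 positive-mode and ~1,100 negative-mode LC–MS
features with log-normal ion intensities. Planted structure exercises every
downstream stage:

* ``differential`` features shift group means on the log2 scale
  (dose-proportionally along the ladder), for volcano/VIP screening;
* ``diet_derived`` features are differential in BOTH the diet and the content
  tables — either with the same trend and a log2FC variation range below the
  diet-filter threshold (so the filter must remove them) or with a contrary
  trend (so the filter must keep them);
* ``exchanged`` features shift with opposite signs in content vs tissue, for
  the inverse-correlation exchange analysis.

The ground-truth labels partition the feature set, enabling exact
parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FeatureTable, SampleMetadata

LABELS = (
    "null",
    "differential_up",
    "differential_down",
    "diet_derived_same_trend",
    "diet_derived_contrary",
    "exchanged_up_down",
    "exchanged_down_up",
)

__all__ = ["SimulationSpec", "SimulationResult", "simulate", "simulate_otu", "LABELS"]


@dataclass
class SimulationSpec:
    """Parameters of the synthetic feeding-trial metabolome.

    ``effect_log2`` is the full-dose log2 fold change of planted features;
    intermediate doses get dose-proportional fractions of it (``dose_scaling``).
    ``cv`` is the within-group coefficient of variation of intensities on the
    natural scale; the log-normal noise sd follows as sqrt(ln(1 + cv²)).
    ``diet_passage_factor`` attenuates a diet-derived feature's shift when it
    reappears in the content compartment (same-trend case), keeping the
    content/diet log2FC range inside the diet-filter threshold.
    """

    n_features: Mapping[str, int] = field(
        default_factory=lambda: {"positive": 2000, "negative": 1100}
    )
    n_samples: int = 12
    groups: tuple[str, ...] = ("FM", "SBM20", "SBM40")
    dose_scaling: tuple[float, ...] = (0.0, 0.5, 1.0)
    compartments: tuple[str, ...] = ("diet", "content", "tissue")
    effect_log2: float = 2.0
    frac_differential: float = 0.02
    frac_diet_derived: float = 0.01
    frac_exchanged: float = 0.01
    log2_mean: float = 17.0
    log2_sd: float = 2.0
    cv: float = 0.3
    diet_passage_factor: float = 0.6
    n_shared_names: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_differential, self.frac_diet_derived, self.frac_exchanged)
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("planted fractions must lie in [0, 1]")
        if sum(fracs) > 1.0 + 1e-12:
            raise ValueError("planted fractions must sum to at most 1")
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples per group")
        if not math.isfinite(self.effect_log2):
            raise ValueError("effect size must be finite")
        if len(self.dose_scaling) != len(self.groups):
            raise ValueError("dose_scaling must match groups")
        if not (0.0 < self.diet_passage_factor <= 1.0):
            raise ValueError("diet_passage_factor must be in (0, 1]")

    @property
    def noise_sd_log2(self) -> float:
        return math.sqrt(math.log1p(self.cv**2)) / math.log(2.0)


@dataclass
class SimulationResult:
    tables: dict[tuple[str, str], FeatureTable]  # (compartment, ion_mode) -> table
    metadata: SampleMetadata
    truth: pd.DataFrame  # feature_id, ion_mode, label, lfc_diet/content/tissue

    def table(self, compartment: str, ion_mode: str) -> FeatureTable:
        return self.tables[(compartment, ion_mode)]


def _assign_labels(m: int, spec: SimulationSpec, rng: np.random.Generator) -> list[str]:
    n_diff = round(spec.frac_differential * m)
    n_diet = round(spec.frac_diet_derived * m)
    n_exch = round(spec.frac_exchanged * m)
    if n_diff + n_diet + n_exch > m:
        raise ValueError("planted fractions infeasible for feature count")
    labels = (
        ["differential_up"] * (n_diff - n_diff // 2)
        + ["differential_down"] * (n_diff // 2)
        + ["diet_derived_same_trend"] * (n_diet - n_diet // 2)
        + ["diet_derived_contrary"] * (n_diet // 2)
        + ["exchanged_up_down"] * (n_exch - n_exch // 2)
        + ["exchanged_down_up"] * (n_exch // 2)
    )
    labels += ["null"] * (m - len(labels))
    return labels


def _true_lfc(label: str, spec: SimulationSpec) -> dict[str, float]:
    """Full-dose log2FC per compartment implied by a ground-truth label."""
    e = spec.effect_log2
    lfc = {"diet": 0.0, "content": 0.0, "tissue": 0.0}
    if label == "differential_up":
        lfc["content"] = e
    elif label == "differential_down":
        lfc["content"] = -e
    elif label == "diet_derived_same_trend":
        # same sign in diet and content, |content - diet| below the filter range
        lfc["diet"] = e
        lfc["content"] = e * spec.diet_passage_factor
    elif label == "diet_derived_contrary":
        lfc["diet"] = e
        lfc["content"] = -e
    elif label == "exchanged_up_down":
        lfc["content"] = e
        lfc["tissue"] = -e
    elif label == "exchanged_down_up":
        lfc["content"] = -e
        lfc["tissue"] = e
    return lfc


def simulate(spec: SimulationSpec) -> SimulationResult:
    """Draw the full synthetic dataset; identical seeds give identical bits.

    Intensities are log-normal: log2 X = baseline_j + dose·lfc_j + ε with
    ε ~ N(0, noise_sd_log2²), so the population group-mean log2 ratio equals
    the planted effect exactly.
    """
    rng = np.random.default_rng(spec.seed)
    tables: dict[tuple[str, str], FeatureTable] = {}
    truth_rows = []
    meta_rows = []

    for mode in spec.n_features:
        m = int(spec.n_features[mode])
        if m < 1:
            raise ValueError("each ion mode needs at least one feature")
        prefix = {"positive": "pos", "negative": "neg"}.get(mode, mode)
        feature_ids = [f"{prefix}_{j:05d}" for j in range(m)]
        labels = _assign_labels(m, spec, rng)
        baseline = rng.normal(spec.log2_mean, spec.log2_sd, size=m)

        names = list(feature_ids)
        n_shared = min(spec.n_shared_names, m)
        # shared display names across modes exercise cross-mode deduplication;
        # assigned to trailing (null) features so planted labels stay mode-local
        for k in range(n_shared):
            names[m - 1 - k] = f"SharedMet_{k + 1}"
        feature_names = pd.Series(names, index=feature_ids, dtype=object)

        lfc_full = {c: np.zeros(m) for c in ("diet", "content", "tissue")}
        for j, label in enumerate(labels):
            for comp, val in _true_lfc(label, spec).items():
                lfc_full[comp][j] = val
            truth_rows.append(
                {
                    "feature_id": feature_ids[j],
                    "feature_name": names[j],
                    "ion_mode": mode,
                    "label": label,
                    "lfc_diet": lfc_full["diet"][j],
                    "lfc_content": lfc_full["content"][j],
                    "lfc_tissue": lfc_full["tissue"][j],
                }
            )

        for comp in spec.compartments:
            sample_ids = []
            shifts = []
            for g, scale in zip(spec.groups, spec.dose_scaling):
                for i in range(spec.n_samples):
                    sample_ids.append(f"{g}.{comp}.{prefix}.{i + 1:02d}")
                    shifts.append(scale)
            shifts = np.asarray(shifts)  # (n_total,)
            noise = rng.normal(0.0, spec.noise_sd_log2, size=(m, len(sample_ids)))
            log2x = (
                baseline[:, None]
                + lfc_full[comp][:, None] * shifts[None, :]
                + noise
            )
            values = np.exp2(log2x)
            frame = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
            tables[(comp, mode)] = FeatureTable(frame, feature_names.copy())
            for sid, (g, _) in zip(
                sample_ids,
                [
                    (g, i)
                    for g in spec.groups
                    for i in range(spec.n_samples)
                ],
            ):
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "group": sid.split(".")[0],
                        "compartment": comp,
                        "ion_mode": mode,
                    }
                )

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    metadata = SampleMetadata(meta, group_ladder=spec.groups)
    truth = pd.DataFrame(truth_rows)
    return SimulationResult(tables=tables, metadata=metadata, truth=truth)


def simulate_otu(
    n_taxa: int,
    n_samples: int,
    depth: int,
    dysbiosis_gradient: Sequence[float],
    seed: int = 0,
    base_probs: Sequence[float] | None = None,
    groups: Sequence[str] | None = None,
) -> tuple[FeatureTable, SampleMetadata]:
    """Multinomial OTU counts per sample from group-specific taxon probabilities.

    The community for gradient g has taxon probabilities ∝ exp(-λ(1 - g)·rank),
    so g = 0 is a steep, low-diversity community and g = 1 is uniform; the
    expected Shannon index is monotone increasing in g. ``dysbiosis_gradient``
    gives one g per group; each group gets ``n_samples`` samples of ``depth``
    reads. ``base_probs`` overrides the rank-abundance model with explicit
    taxon probabilities shared by all groups.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if depth < 100:
        raise ValueError("sequencing depth must be at least 100")
    rng = np.random.default_rng(seed)
    grads = list(dysbiosis_gradient)
    if groups is None:
        groups = [f"G{i + 1}" for i in range(len(grads))]
    lam = 8.0 / n_taxa
    ranks = np.arange(n_taxa)

    counts = {}
    meta_rows = []
    for g_label, g in zip(groups, grads):
        if base_probs is not None:
            probs = np.asarray(base_probs, dtype=float)
            if len(probs) != n_taxa:
                raise ValueError("base_probs length must equal n_taxa")
            probs = probs / probs.sum()
        else:
            if not (0.0 <= g <= 1.0):
                raise ValueError("dysbiosis gradient values must lie in [0, 1]")
            w = np.exp(-lam * (1.0 - g) * ranks)
            probs = w / w.sum()
        for i in range(n_samples):
            sid = f"{g_label}.otu.{i + 1:02d}"
            counts[sid] = rng.multinomial(depth, probs)
            meta_rows.append(
                {"sample_id": sid, "group": g_label, "compartment": "content",
                 "ion_mode": "none"}
            )

    taxa = [f"OTU_{t + 1:04d}" for t in range(n_taxa)]
    frame = pd.DataFrame(counts, index=taxa)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    metadata = SampleMetadata(meta, group_ladder=tuple(groups))
    return FeatureTable(frame), metadata
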