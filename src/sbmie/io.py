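"""Data model and readers/writers shared by every pipeline stage.

A :class:`FeatureTable` is the universal input: a features × samples matrix of
non-negative intensities (LC–MS ion intensities) or integer counts (OTU
tables), paired with a sample-metadata table assigning each sample to a diet
group (an ordered dose ladder such as FM < SBM20 < SBM40), a compartment
(diet, intestinal content, or intestinal tissue) and an ionization mode.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

COMPARTMENTS = ("diet", "content", "tissue")
ION_MODES = ("positive", "negative", "none")

__all__ = [
    "FeatureTable",
    "SampleMetadata",
    "RunConfig",
    "read_feature_table",
    "read_annotation_map",
    "read_table",
    "write_table",
    "write_feature_table",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass
class FeatureTable:
    """Features × samples matrix with optional display names per feature.

    ``data`` is indexed by feature id (rows) and sample id (columns); values
    are non-negative and free of missing cells (the missing policy is applied
    at load time). ``feature_names`` maps feature ids to human-readable
    metabolite/taxon names and defaults to the ids themselves.
    """

    data: pd.DataFrame
    feature_names: pd.Series | None = None

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        values = self.data.to_numpy()
        if np.isnan(values.astype(float)).any():
            raise ValueError("FeatureTable contains missing cells after loading")
        if (values < 0).any():
            raise ValueError("FeatureTable values must be non-negative")
        if self.feature_names is None:
            self.feature_names = pd.Series(idx, index=idx, dtype=object)
        else:
            self.feature_names = self.feature_names.reindex(idx)
            if self.feature_names.isna().any():
                missing = self.feature_names.index[self.feature_names.isna()].tolist()
                raise ValueError(f"feature_names missing for: {missing}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.data[list(sample_ids)], self.feature_names)

    def name_of(self, feature_id: str) -> str:
        return str(self.feature_names.loc[feature_id])


@dataclass
class SampleMetadata:
    """Per-sample annotations: dose group, compartment, ion mode.

    ``group_ladder`` is the totally ordered dose ladder; groups present in the
    table must belong to it. Sample order in the metadata file is the
    canonical sample order for all outputs.
    """

    table: pd.DataFrame  # index: sample_id; columns: group, compartment, ion_mode
    group_ladder: tuple[str, ...] = ("FM", "SBM20", "SBM40")

    def __post_init__(self) -> None:
        required = {"group", "compartment", "ion_mode"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dupes}")
        bad_groups = set(self.table["group"]) - set(self.group_ladder)
        if bad_groups:
            raise ValueError(
                f"groups {sorted(bad_groups)} not in ladder {self.group_ladder}"
            )
        bad_comp = set(self.table["compartment"]) - set(COMPARTMENTS)
        if bad_comp:
            raise ValueError(f"unknown compartments: {sorted(bad_comp)}")
        bad_mode = set(self.table["ion_mode"]) - set(ION_MODES)
        if bad_mode:
            raise ValueError(f"unknown ion modes: {sorted(bad_mode)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_where(
        self,
        group: str | None = None,
        compartment: str | None = None,
        ion_mode: str | None = None,
    ) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if group is not None:
            mask &= self.table["group"] == group
        if compartment is not None:
            mask &= self.table["compartment"] == compartment
        if ion_mode is not None:
            mask &= self.table["ion_mode"] == ion_mode
        return list(self.table.index[mask])

    def dose_rank(self, group: str) -> int:
        return self.group_ladder.index(group)


@dataclass
class RunConfig:
    """Thresholds and method choices for a pipeline run.

    p_alpha / lfc_deg come from the study's significance rules (raw P < 0.05;
    |log2FC| > 1 for DEGs); vip_min is the customary VIP ≥ 1 biomarker cut;
    lfc_range is the diet-background filter's log2FC variation-range
    threshold; top_k is the per-mode biomarker panel depth.
    """

    p_alpha: float = 0.05
    lfc_deg: float = 1.0
    vip_min: float = 1.0
    lfc_range: float = 2.0
    top_k: int = 10
    test: str = "welch_t"  # welch_t | student_t | wilcoxon
    normalization: str = "tic_log"  # tic_log | log | none
    missing_policy: str = "halfmin"  # halfmin | drop
    range_definition: str = "difference"  # difference | content_abs
    multiple_testing: str = "none"  # none | bh
    plsda_components: int = 2
    log_base: float = 2.0  # Shannon entropy base
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_alpha", "lfc_deg", "vip_min", "lfc_range", "log_base"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.top_k <= 0 or self.plsda_components <= 0:
            raise ValueError("top_k and plsda_components must be > 0")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ValueError("seed must be a non-negative integer")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat TOML or YAML config; unknown keys are rejected."""
        path = Path(path)
        if path.suffix.lower() in {".toml", ".tml"}:
            import tomllib

            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        else:
            import yaml

            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def read_feature_table(
    path: str | Path,
    metadata_path: str | Path,
    missing_policy: str = "halfmin",
    group_ladder: tuple[str, ...] = ("FM", "SBM20", "SBM40"),
) -> tuple[FeatureTable, SampleMetadata]:
    """Read a features × samples TSV/CSV plus its sample-metadata table.

    The first column holds feature ids; an optional ``feature_name`` column
    holds display names; the remaining columns are samples. Missing cells are
    imputed to half the feature's minimum positive value (``halfmin``) or the
    feature is dropped (``drop``). Samples are reordered to metadata file
    order (the canonical order); a table sample absent from the metadata is a
    hard error.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=object)
    meta_raw = pd.read_csv(
        metadata_path, sep=_sep_for(metadata_path), index_col=0, dtype=object
    )
    metadata = SampleMetadata(meta_raw, group_ladder=group_ladder)

    feature_names = None
    if "feature_name" in raw.columns:
        feature_names = raw["feature_name"].astype(object)
        raw = raw.drop(columns=["feature_name"])

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at feature {raw.index[r]!r}, sample {raw.columns[c]!r}: "
            f"{raw.iat[r, c]!r}"
        )

    unknown = [s for s in numeric.columns if s not in metadata.table.index]
    if unknown:
        raise ValueError(f"samples missing from metadata: {unknown}")

    if numeric.isna().to_numpy().any():
        if missing_policy == "halfmin":
            numeric = numeric.apply(_impute_halfmin, axis=1)
        elif missing_policy == "drop":
            numeric = numeric.dropna(axis=0)
        else:
            raise ValueError(f"unknown missing policy {missing_policy!r}")

    order = [s for s in metadata.sample_ids if s in numeric.columns]
    table = FeatureTable(numeric[order], feature_names)
    return table, metadata


def _impute_halfmin(row: pd.Series) -> pd.Series:
    if not row.isna().any():
        return row
    positive = row[row > 0]
    if positive.empty:
        raise ValueError(
            f"feature {row.name!r} has missing cells but no positive value to impute from"
        )
    return row.fillna(positive.min() / 2.0)


def read_annotation_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (feature_id, pathway_id) TSV into a feature → pathways map."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("annotation map needs feature_id and pathway_id columns")
    fcol, pcol = frame.columns[:2]
    out: dict[str, set[str]] = {}
    for fid, pid in zip(frame[fcol], frame[pcol]):
        if not isinstance(pid, str) or not pid.strip():
            raise ValueError(f"empty pathway id for feature {fid!r}")
        out.setdefault(str(fid), set()).add(pid)
    return out


def write_table(
    records: pd.DataFrame | Iterable,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> Path:
    """Write a result table (DataFrame or sequence of dataclass records) as TSV.

    Reals are written with 12 significant digits so that a read-back
    reproduces them bit-for-bit at that precision; integers and ids are exact.
    An empty record sequence needs explicit ``columns`` and produces a
    header-only file.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        rows = list(records)
        if rows:
            if dataclasses.is_dataclass(rows[0]):
                frame = pd.DataFrame([dataclasses.asdict(r) for r in rows])
            else:
                frame = pd.DataFrame(rows)
        else:
            if columns is None:
                raise ValueError("empty record list requires explicit columns")
            frame = pd.DataFrame(columns=list(columns))
    frame.to_csv(path, sep=_sep_for(path), index=False, float_format="%.12g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`.

    Only empty cells count as missing: literal strings such as "null" (a
    ground-truth label) survive the round trip.
    """
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path), keep_default_na=False, na_values=[""])


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """Write a FeatureTable in the layout :func:`read_feature_table` expects."""
    path = Path(path)
    frame = table.data.copy()
    frame.insert(0, "feature_name", table.feature_names)
    frame.index.name = "feature_id"
    frame.to_csv(path, sep=_sep_for(path), float_format="%.12g")
    return path
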