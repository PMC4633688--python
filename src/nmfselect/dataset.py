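"""Clinical symptom dataset: in-memory container, CSV/TSV I/O, preprocessing.

The canonical in-memory orientation is samples as rows and symptoms as
columns.  Entries are small nonnegative integers (binary presence codes or
ordinal severity levels); a value of zero means the symptom is absent.
Each sample carries a coarse stage class in {1..C} and optionally a fine
substage code (``IA`` ... ``IIIB`` by default) plus a binary covariate
(``sex``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyDatasetError,
    FormatError,
    LabelingError,
    ValidationError,
)

#: Default fine-to-coarse relabeling: two substages per stage.
DEFAULT_SUBSTAGE_MAP: dict[str, int] = {
    "IA": 1,
    "IB": 1,
    "IIA": 2,
    "IIB": 2,
    "IIIA": 3,
    "IIIB": 3,
}

_LABEL_COLUMNS = ("substage", "stage", "sex")


@dataclass
class ClinicalDataset:
    """Sample x symptom matrix of nonnegative integers with per-sample labels.

    Parameters
    ----------
    values
        Integer array of shape ``(n_samples, n_symptoms)``; every entry >= 0.
    symptom_ids
        Unique symptom identifiers, one per column.
    sample_ids
        Unique sample identifiers, one per row.
    stage
        Per-sample coarse class labels (integers), or ``None`` if only
        substages are known (call :func:`relabel_substages` to derive them).
    substage
        Optional per-sample fine substage codes.
    sex
        Optional per-sample binary covariate (0/1).
    """

    values: np.ndarray
    symptom_ids: list[str]
    sample_ids: list[str]
    stage: np.ndarray | None = None
    substage: list[str] | None = None
    sex: np.ndarray | None = None
    substage_map: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTAGE_MAP)
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.symptom_ids = [str(s) for s in self.symptom_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.stage is not None:
            self.stage = np.asarray(self.stage)
        if self.sex is not None:
            self.sex = np.asarray(self.sex)
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if v.ndim != 2:
            raise ValidationError(f"values must be 2-D, got shape {v.shape}")
        if v.shape[0] == 0 or v.shape[1] == 0:
            raise EmptyDatasetError(f"dataset is empty: shape {v.shape}")
        if not np.issubdtype(v.dtype, np.integer):
            if np.issubdtype(v.dtype, np.floating):
                if np.isnan(v).any():
                    raise ValidationError("missing values are not supported")
                if not np.all(v == np.round(v)):
                    raise ValidationError("symptom values must be integers")
                self.values = v = v.astype(np.int64)
            else:
                raise ValidationError(f"non-numeric symptom values ({v.dtype})")
        if (v < 0).any():
            raise ValidationError("symptom values must be nonnegative")
        p, n = v.shape
        if len(self.symptom_ids) != n:
            raise ValidationError("symptom_ids length does not match columns")
        if len(self.sample_ids) != p:
            raise ValidationError("sample_ids length does not match rows")
        if len(set(self.symptom_ids)) != n:
            raise ValidationError("duplicate symptom ids")
        if len(set(self.sample_ids)) != p:
            raise ValidationError("duplicate sample ids")
        if self.substage is not None and len(self.substage) != p:
            raise ValidationError("substage length does not match samples")
        if self.stage is not None:
            if len(self.stage) != p:
                raise ValidationError("stage length does not match samples")
            if self.substage is not None:
                for code, st in zip(self.substage, self.stage):
                    mapped = self.substage_map.get(code)
                    if mapped is not None and mapped != st:
                        raise ValidationError(
                            f"stage {st} inconsistent with substage {code!r}"
                        )
        if self.sex is not None and len(self.sex) != p:
            raise ValidationError("sex length does not match samples")

    # -- convenience accessors ---------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_symptoms(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        if self.stage is None:
            raise ValidationError("stage labels are not populated")
        return np.unique(self.stage)

    def column(self, symptom_id: str) -> np.ndarray:
        try:
            j = self.symptom_ids.index(symptom_id)
        except ValueError:
            raise KeyError(symptom_id) from None
        return self.values[:, j]

    def select_symptoms(self, ids: Sequence[str]) -> "ClinicalDataset":
        """Return a copy restricted to ``ids`` (in the given order)."""
        idx = []
        for s in ids:
            try:
                idx.append(self.symptom_ids.index(s))
            except ValueError:
                raise KeyError(s) from None
        return replace(
            self, values=self.values[:, idx], symptom_ids=[self.symptom_ids[i] for i in idx]
        )

    def select_samples(self, indices: Sequence[int]) -> "ClinicalDataset":
        idx = list(indices)
        return replace(
            self,
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            stage=None if self.stage is None else self.stage[idx],
            substage=None if self.substage is None else [self.substage[i] for i in idx],
            sex=None if self.sex is None else self.sex[idx],
        )

    def select_sample_ids(self, ids: Sequence[str]) -> "ClinicalDataset":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return self.select_samples([pos[s] for s in ids])
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_dataset(
    path: str | Path,
    *,
    delimiter: str | None = None,
    orientation: str = "samples",
    substage_column: str = "substage",
    stage_column: str = "stage",
    sex_column: str = "sex",
    substage_map: Mapping[str, int] | None = None,
) -> ClinicalDataset:
    """Read a delimited-text dataset and return a validated :class:`ClinicalDataset`.

    The default on-disk layout has one sample per row, symptom columns, and
    label columns named ``substage`` / ``stage`` / ``sex`` (configurable).
    ``orientation="symptoms"`` accepts the transposed layout (symptoms as
    rows, samples as columns, label rows); it is normalized on read.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#", dtype=str)
    if orientation == "symptoms":
        df = df.T
    elif orientation != "samples":
        raise FormatError(f"unknown orientation {orientation!r}")

    labels: dict[str, pd.Series] = {}
    for name in (substage_column, stage_column, sex_column):
        if name in df.columns:
            labels[name] = df[name]
    if substage_column not in labels and stage_column not in labels:
        raise FormatError(
            f"no label column: expected {substage_column!r} or {stage_column!r}"
        )
    value_cols = [c for c in df.columns if c not in labels]
    if not value_cols:
        raise FormatError("no symptom columns found")
    raw = df[value_cols]
    if raw.isna().any().any():
        raise ValidationError("missing values are not supported")
    try:
        values = raw.astype(float).to_numpy()
    except ValueError as exc:
        raise ValidationError(f"non-numeric symptom value: {exc}") from None

    substage = None
    if substage_column in labels:
        sub = labels[substage_column]
        if sub.isna().any():
            raise ValidationError("missing substage labels")
        substage = [str(s) for s in sub]
    stage = None
    if stage_column in labels:
        st = labels[stage_column]
        if st.isna().any():
            raise ValidationError("missing stage labels")
        stage = st.astype(float).to_numpy()
        if not np.all(stage == np.round(stage)):
            raise ValidationError("stage labels must be integers")
        stage = stage.astype(np.int64)
    sex = None
    if sex_column in labels:
        sx = labels[sex_column]
        if sx.isna().any():
            raise ValidationError("missing sex labels")
        sex = sx.astype(float).to_numpy().astype(np.int64)

    ds = ClinicalDataset(
        values=values,
        symptom_ids=list(value_cols),
        sample_ids=[str(i) for i in df.index],
        stage=stage,
        substage=substage,
        sex=sex,
        substage_map=dict(substage_map) if substage_map else dict(DEFAULT_SUBSTAGE_MAP),
    )
    if ds.stage is None:
        ds = relabel_substages(ds, ds.substage_map)
    return ds


def write_dataset(
    ds: ClinicalDataset, path: str | Path, *, delimiter: str | None = None
) -> Path:
    """Write ``ds`` in the canonical samples-as-rows layout; returns the path."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.DataFrame(ds.values, index=ds.sample_ids, columns=ds.symptom_ids)
    if ds.substage is not None:
        df["substage"] = ds.substage
    if ds.stage is not None:
        df["stage"] = ds.stage
    if ds.sex is not None:
        df["sex"] = ds.sex
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)
    return path


def relabel_substages(
    ds: ClinicalDataset, mapping: Mapping[str, int] | None = None
) -> ClinicalDataset:
    """Populate coarse stage labels from fine substage codes.

    Under the default map the two ``A``/``B`` substages of each of the three
    phases collapse to classes 1, 2, 3.  Raises :class:`LabelingError` for a
    substage code absent from the map.  Values and shapes are untouched.
    """
    if ds.substage is None:
        raise LabelingError("dataset has no substage labels")
    mapping = dict(mapping) if mapping is not None else dict(DEFAULT_SUBSTAGE_MAP)
    missing = sorted({s for s in ds.substage if s not in mapping})
    if missing:
        raise LabelingError(f"substage codes not in map: {missing}")
    stage = np.array([mapping[s] for s in ds.substage], dtype=np.int64)
    return replace(ds, stage=stage, substage_map=mapping)


def drop_constant_features(
    ds: ClinicalDataset,
) -> tuple[ClinicalDataset, list[str]]:
    """Remove symptoms whose column is constant across all samples.

    Returns the reduced dataset and the removed symptom ids (in original
    order).  Constant columns carry no class information whatever the
    constant is.  Raises :class:`EmptyDatasetError` if nothing would remain.
    """
    v = ds.values
    constant = (v == v[0:1, :]).all(axis=0)
    removed = [s for s, c in zip(ds.symptom_ids, constant) if c]
    if len(removed) == ds.n_symptoms:
        raise EmptyDatasetError("all features are constant")
    if not removed:
        return ds, []
    keep = [s for s in ds.symptom_ids if s not in set(removed)]
    return ds.select_symptoms(keep), removed
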