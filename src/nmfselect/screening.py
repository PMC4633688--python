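"""Stage 1 of the filter: positive-frequency screening of irrelevant symptoms.

A symptom is *positive* for a patient when its ordinal value is strictly
greater than zero.  A symptom whose positive frequency is below a threshold
in **every** clinical stratum carries no class signal and is removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import ClinicalDataset
from .exceptions import EmptyDatasetError, StratificationError, ValidationError

__all__ = [
    "FrequencyTable",
    "positive_frequencies",
    "find_irrelevant",
    "remove_features",
]


@dataclass
class FrequencyTable:
    """Per-stratum positive frequencies, shape (n_symptoms, n_strata)."""

    freq: np.ndarray
    symptom_ids: list[str]
    strata_ids: list[str]
    counts: np.ndarray  # per-stratum sample counts

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.freq.shape != (len(self.symptom_ids), len(self.strata_ids)):
            raise ValidationError("frequency table shape mismatch")
        if (self.freq < 0).any() or (self.freq > 1).any():
            raise ValidationError("frequencies must lie in [0, 1]")


def _strata_labels(ds: ClinicalDataset, stratify_by: str) -> list:
    if stratify_by == "auto":
        stratify_by = "substage" if ds.substage is not None else "stage"
    if stratify_by == "substage":
        if ds.substage is None:
            raise StratificationError("dataset has no substage labels")
        return list(ds.substage)
    if stratify_by == "stage":
        if ds.stage is None:
            raise StratificationError("dataset has no stage labels")
        return list(ds.stage)
    raise StratificationError(f"unknown stratification {stratify_by!r}")


def positive_frequencies(
    ds: ClinicalDataset, stratify_by: str = "auto"
) -> FrequencyTable:
    """Fraction of samples with value > 0 per symptom within each stratum.

    ``stratify_by`` is ``"substage"``, ``"stage"`` or ``"auto"`` (finest
    available labels; substages when present).  Strata are ordered by sorted
    label.  Every stratum must be non-empty by construction of the labels.
    """
    labels = _strata_labels(ds, stratify_by)
    strata = sorted(set(labels))
    positive = ds.values > 0
    freq = np.empty((ds.n_symptoms, len(strata)), dtype=float)
    counts = np.empty(len(strata), dtype=np.int64)
    lab = np.asarray(labels)
    for j, s in enumerate(strata):
        mask = lab == s
        counts[j] = int(mask.sum())
        if counts[j] == 0:  # unreachable for labels drawn from the data
            raise StratificationError(f"empty stratum {s!r}")
        freq[:, j] = positive[mask].mean(axis=0)
    return FrequencyTable(
        freq=freq,
        symptom_ids=list(ds.symptom_ids),
        strata_ids=[str(s) for s in strata],
        counts=counts,
    )


def find_irrelevant(ft: FrequencyTable, threshold: float) -> list[str]:
    """Symptoms whose positive frequency is strictly below ``threshold`` in
    every stratum, in ``symptom_ids`` order.

    Ties at exactly the threshold are kept (strict inequality).
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"threshold must lie in (0, 1), got {threshold}")
    flagged = (ft.freq < threshold).all(axis=1)
    return [s for s, f in zip(ft.symptom_ids, flagged) if f]


def remove_features(ds: ClinicalDataset, ids: list[str]) -> ClinicalDataset:
    """Drop the listed symptom columns; labels untouched, order preserved."""
    id_set = set(ids)
    unknown = id_set - set(ds.symptom_ids)
    if unknown:
        raise KeyError(f"unknown symptom ids: {sorted(unknown)}")
    keep = [s for s in ds.symptom_ids if s not in id_set]
    if not keep:
        raise EmptyDatasetError("removing all symptoms would leave an empty dataset")
    if len(keep) == ds.n_symptoms:
        return ds
    return ds.select_symptoms(keep)
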