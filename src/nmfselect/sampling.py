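"""Class- and covariate-balanced representative sampling.

The representative subset used for factorization is drawn per class by
ranking samples on their Euclidean distance to the class centroid (the mean
symptom vector of the class) and taking the closest ones, optionally with
per-level quotas on a categorical covariate (e.g. 20 male : 20 female).
Ties in distance are broken by ascending sample id for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import ClinicalDataset
from .exceptions import QuotaError, StratificationError, ValidationError

__all__ = ["RepresentativeSelection", "class_centroids", "select_representatives"]


@dataclass
class RepresentativeSelection:
    """Outcome of representative sampling.

    ``selected_ids`` maps (class, covariate level) cells to the chosen sample
    ids; ``distances`` holds each chosen sample's Euclidean distance to its
    class centroid; ``subset`` is the selected dataset (samples in class
    order, then covariate-level order, then rank order).
    """

    selected_ids: dict[tuple, list[str]]
    centroids: dict[int, np.ndarray]
    distances: dict[str, float]
    subset: ClinicalDataset


def class_centroids(ds: ClinicalDataset) -> dict[int, np.ndarray]:
    """Mean symptom vector of each stage class."""
    if ds.stage is None:
        raise StratificationError("dataset has no stage labels")
    cents: dict[int, np.ndarray] = {}
    for c in np.unique(ds.stage):
        mask = ds.stage == c
        if not mask.any():  # pragma: no cover - unique() guarantees nonempty
            raise StratificationError(f"empty class {c}")
        cents[int(c)] = ds.values[mask].mean(axis=0)
    return cents


def _covariate_values(ds: ClinicalDataset, name: str) -> np.ndarray:
    if name == "sex":
        if ds.sex is None:
            raise StratificationError("dataset has no sex covariate")
        return ds.sex
    raise StratificationError(f"unknown covariate {name!r}")


def select_representatives(
    ds: ClinicalDataset,
    per_class: int,
    balance: str | None = None,
    ratio: dict | None = None,
) -> RepresentativeSelection:
    """Select the ``per_class`` samples closest to each class centroid.

    Parameters
    ----------
    per_class
        Number of samples to keep from every class.
    balance
        Optional categorical covariate name (currently ``"sex"``).
    ratio
        Per-level quotas, e.g. ``{0: 20, 1: 20}``; must sum to ``per_class``.
        Required when ``balance`` is given.

    Within each (class, level) cell samples are sorted by ascending distance
    to the class centroid, ties broken by ascending sample id, and the top
    quota is taken.  Raises :class:`QuotaError` naming any undersized cell.
    """
    if per_class < 1:
        raise ValidationError("per_class must be >= 1")
    cents = class_centroids(ds)
    if balance is not None:
        if ratio is None:
            raise ValidationError("ratio quotas are required when balancing")
        if sum(ratio.values()) != per_class:
            raise ValidationError(
                f"ratio quotas sum to {sum(ratio.values())}, expected {per_class}"
            )
        cov = _covariate_values(ds, balance)

    ids = np.asarray(ds.sample_ids, dtype=object)
    selected: dict[tuple, list[str]] = {}
    distances: dict[str, float] = {}
    order: list[int] = []
    for c in sorted(cents):
        cls_mask = ds.stage == c
        d = np.linalg.norm(ds.values - cents[c][None, :], axis=1)
        cells: list[tuple[tuple, np.ndarray, int]] = []
        if balance is None:
            cells.append(((c,), cls_mask, per_class))
        else:
            for level, quota in sorted(ratio.items()):
                cells.append(((c, level), cls_mask & (cov == level), quota))
        for key, mask, quota in cells:
            idx = np.flatnonzero(mask)
            if len(idx) < quota:
                raise QuotaError(
                    f"cell {key} has {len(idx)} samples, quota is {quota}"
                )
            # lexicographic (distance, sample id): sort by id, stable-sort by distance
            idx = idx[np.argsort(ids[idx], kind="stable")]
            idx = idx[np.argsort(d[idx], kind="stable")]
            chosen = idx[:quota]
            selected[key] = [ds.sample_ids[i] for i in chosen]
            for i in chosen:
                distances[ds.sample_ids[i]] = float(d[i])
            order.extend(int(i) for i in chosen)

    subset = ds.select_samples(order)
    return RepresentativeSelection(
        selected_ids=selected, centroids=cents, distances=distances, subset=subset
    )
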