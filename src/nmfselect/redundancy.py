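"""Stage 2 of the filter: redundancy detection on basis rows and compression.

Each original feature corresponds to one row of the basis matrix W, a
compressed representation of its distribution over samples.  Two features
are considered redundant when their W rows are simultaneously close
(distance similarity) and correlated (pattern similarity):

    sim_dist(i, j) = 1 - ||w_i - w_j||^2 / MaxD        (MaxD = max pair distance)
    sim_corr(i, j) = Pearson correlation of w_i and w_j
    SMX(i, j)      = (sim_dist + sim_corr) / 2

Redundant groups are the connected components (size >= 2) of the threshold
graph; by default an edge requires BOTH similarities >= theta and the two
features assigned to the same basis.  Each group is compressed into one
mixed feature (member mean, or a randomly chosen member).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform

from .dataset import ClinicalDataset
from .exceptions import ConfigError, DegenerateInputError, ValidationError

__all__ = [
    "SimilarityMatrices",
    "RedundantGroup",
    "RedundancyGroups",
    "FeatureSubset",
    "sim_dist_matrix",
    "sim_corr_matrix",
    "combined_similarity",
    "similarity_matrices",
    "find_redundant_groups",
    "build_mixed_feature",
    "assemble_subset",
]


@dataclass
class SimilarityMatrices:
    """Pairwise feature similarities computed from rows of W."""

    sim_dist: np.ndarray
    sim_corr: np.ndarray
    smx: np.ndarray
    max_d: float
    feature_ids: list[str]


@dataclass
class RedundantGroup:
    members: list[str]
    basis: int | None
    mean_sim_dist: float
    mean_sim_corr: float
    mixed_id: str


@dataclass
class RedundancyGroups:
    groups: list[RedundantGroup] = field(default_factory=list)

    def __iter__(self):
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def member_ids(self) -> set[str]:
        out: set[str] = set()
        for g in self.groups:
            out |= set(g.members)
        return out


def sim_dist_matrix(W: np.ndarray) -> tuple[np.ndarray, float]:
    """Distance similarity of W rows: 1 - squared distance / MaxD.

    Returns the n x n matrix and the normalizer MaxD (the maximal pairwise
    squared Euclidean distance).  All rows identical is a degenerate
    geometry (MaxD = 0) and raises.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValidationError("W must have at least 2 rows")
    sq = np.sum(W**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (W @ W.T)
    np.maximum(d2, 0.0, out=d2)  # clamp negative rounding noise
    d2 = (d2 + d2.T) / 2.0
    np.fill_diagonal(d2, 0.0)
    max_d = float(d2.max())
    if max_d == 0.0:
        raise DegenerateInputError("all basis rows identical: MaxD = 0")
    sd = 1.0 - d2 / max_d
    np.fill_diagonal(sd, 1.0)
    return sd, max_d


def sim_corr_matrix(W: np.ndarray) -> np.ndarray:
    """Pearson correlation between W rows (each centered by its own mean).

    Constant rows have undefined correlations; their off-diagonal entries
    are NaN and a warning is issued (such features are skipped by the
    grouping step).
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValidationError("W must have at least 2 rows")
    constant = np.ptp(W, axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant basis row(s): correlation undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        sc = np.corrcoef(W)
    sc = np.asarray(sc, dtype=float)
    sc[constant, :] = np.nan
    sc[:, constant] = np.nan
    np.fill_diagonal(sc, 1.0)
    return np.clip(sc, -1.0, 1.0)


def combined_similarity(sd: np.ndarray, sc: np.ndarray) -> np.ndarray:
    """Elementwise arithmetic mean of the two similarity matrices."""
    sd = np.asarray(sd, dtype=float)
    sc = np.asarray(sc, dtype=float)
    if sd.shape != sc.shape:
        raise ValidationError("similarity matrices must share a shape")
    return (sd + sc) / 2.0


def similarity_matrices(W: np.ndarray, feature_ids: list[str]) -> SimilarityMatrices:
    """Compute all three similarity matrices for the rows of W."""
    W = np.asarray(W, dtype=float)
    if len(feature_ids) != W.shape[0]:
        raise ValidationError("feature_ids length must match rows of W")
    sd, max_d = sim_dist_matrix(W)
    sc = sim_corr_matrix(W)
    return SimilarityMatrices(
        sim_dist=sd,
        sim_corr=sc,
        smx=combined_similarity(sd, sc),
        max_d=max_d,
        feature_ids=list(feature_ids),
    )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def find_redundant_groups(
    sims: SimilarityMatrices,
    basis_of: np.ndarray | dict | None,
    theta: float,
    rule: str = "dual",
    same_basis: bool = True,
) -> RedundancyGroups:
    """Infer redundant feature groups from the similarity threshold graph.

    Parameters
    ----------
    sims
        Similarity matrices over the features.
    basis_of
        Per-feature basis assignment (array aligned with ``sims.feature_ids``
        or an id-to-basis mapping); required when ``same_basis`` is true.
    theta
        Similarity threshold in (0, 1).
    rule
        ``"dual"`` (default): edge iff sim_dist >= theta AND sim_corr >=
        theta.  ``"smx"``: edge iff SMX > theta.
    same_basis
        Restrict edges to pairs assigned to the same basis.

    Groups are connected components of size >= 2, ordered by (basis, first
    member); mixed-feature ids follow the ``M<basis><ordinal>`` scheme.
    Pairs involving an undefined (NaN) correlation never form edges.
    """
    if not 0.0 < theta < 1.0:
        raise ConfigError(f"theta must lie in (0, 1), got {theta}")
    if rule not in {"dual", "smx"}:
        raise ConfigError(f"unknown grouping rule {rule!r}")
    ids = sims.feature_ids
    n = len(ids)
    if same_basis:
        if basis_of is None:
            raise ConfigError("basis assignment required when same_basis is set")
        if isinstance(basis_of, dict):
            basis = np.array([basis_of[i] for i in ids])
        else:
            basis = np.asarray(basis_of)
            if basis.shape[0] != n:
                raise ValidationError("basis assignment length mismatch")
    else:
        basis = None

    sd, sc, smx = sims.sim_dist, sims.sim_corr, sims.smx
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if np.isnan(sc[i, j]):
                continue
            if basis is not None and basis[i] != basis[j]:
                continue
            if rule == "dual":
                hit = sd[i, j] >= theta and sc[i, j] >= theta
            else:
                hit = smx[i, j] > theta
            if hit:
                uf.union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(uf.find(i), []).append(i)
    raw = [sorted(m) for m in components.values() if len(m) >= 2]

    def group_basis(members: list[int]) -> int | None:
        return int(basis[members[0]]) if basis is not None else None

    raw.sort(key=lambda m: (group_basis(m) if basis is not None else 0, m[0]))
    counters: dict[int | None, int] = {}
    groups: list[RedundantGroup] = []
    for members in raw:
        b = group_basis(members)
        counters[b] = counters.get(b, 0) + 1
        tag = f"M{b + 1}{counters[b]}" if b is not None else f"M0{counters[b]}"
        pair_sd = [sd[i, j] for k, i in enumerate(members) for j in members[k + 1 :]]
        pair_sc = [sc[i, j] for k, i in enumerate(members) for j in members[k + 1 :]]
        groups.append(
            RedundantGroup(
                members=[ids[i] for i in members],
                basis=b,
                mean_sim_dist=float(np.mean(pair_sd)),
                mean_sim_corr=float(np.mean(pair_sc)),
                mixed_id=tag,
            )
        )
    return RedundancyGroups(groups=groups)


def build_mixed_feature(
    ds: ClinicalDataset,
    group: list[str],
    strategy: str = "mean",
    seed: int | None = None,
    mixed_id: str = "M01",
) -> tuple[np.ndarray, str]:
    """Compress a redundant group into a single feature column.

    ``"mean"``: elementwise average of the member columns.
    ``"representative"``: a seeded uniform choice of one member column.
    """
    if len(group) < 2:
        raise ValidationError("a redundant group needs at least 2 members")
    cols = np.column_stack([ds.column(g) for g in group]).astype(float)
    if strategy == "mean":
        return cols.mean(axis=1), mixed_id
    if strategy == "representative":
        rng = np.random.default_rng(seed)
        pick = int(rng.integers(len(group)))
        return cols[:, pick], mixed_id
    raise ConfigError(f"unknown mixed-feature strategy {strategy!r}")


@dataclass
class FeatureSubset:
    """Selected features: kept originals plus one mixed feature per group.

    ``values`` holds the transformed matrix for the dataset the subset was
    assembled on; :meth:`transform` recomputes it for any dataset containing
    the required original columns (mixed features are rebuilt from the
    stored group definitions, so train and test sets stay comparable).
    """

    kept_ids: list[str]
    groups: RedundancyGroups
    strategy: str
    feature_ids: list[str]
    values: np.ndarray
    representative_choice: dict[str, str] = field(default_factory=dict)

    @property
    def mixed_ids(self) -> list[str]:
        return [g.mixed_id for g in self.groups]

    def transform(self, ds: ClinicalDataset) -> np.ndarray:
        """Project ``ds`` onto the subset's feature space (kept + mixed)."""
        if not self.feature_ids:
            raise ValidationError("empty feature subset")
        missing = [
            s
            for s in self.kept_ids + [m for g in self.groups for m in g.members]
            if s not in ds.symptom_ids
        ]
        if missing:
            raise ValidationError(f"dataset lacks subset columns: {missing}")
        cols = [ds.column(s).astype(float) for s in self.kept_ids]
        for g in self.groups:
            if self.strategy == "representative":
                cols.append(ds.column(self.representative_choice[g.mixed_id]).astype(float))
            else:
                mixed, _ = build_mixed_feature(ds, g.members, "mean", mixed_id=g.mixed_id)
                cols.append(mixed)
        return np.column_stack(cols)


def assemble_subset(
    ds: ClinicalDataset,
    groups: RedundancyGroups,
    strategy: str = "mean",
    seed: int | None = None,
) -> FeatureSubset:
    """Replace each redundant group by one mixed feature.

    The transformed matrix is all non-grouped original columns (order
    preserved) followed by one mixed column per group; the feature count is
    ``n - sum(group sizes) + #groups``.
    """
    if strategy not in {"mean", "representative"}:
        raise ConfigError(f"unknown mixed-feature strategy {strategy!r}")
    seen: set[str] = set()
    for g in groups:
        overlap = seen & set(g.members)
        if overlap:
            raise ValidationError(f"overlapping groups at {sorted(overlap)}")
        unknown = set(g.members) - set(ds.symptom_ids)
        if unknown:
            raise ValidationError(f"group members not in dataset: {sorted(unknown)}")
        seen |= set(g.members)

    kept = [s for s in ds.symptom_ids if s not in seen]
    rng = np.random.default_rng(seed)
    cols = [ds.values[:, ds.symptom_ids.index(s)].astype(float) for s in kept]
    feature_ids = list(kept)
    rep_choice: dict[str, str] = {}
    for g in groups:
        if strategy == "representative":
            pick = g.members[int(rng.integers(len(g.members)))]
            rep_choice[g.mixed_id] = pick
            cols.append(ds.column(pick).astype(float))
        else:
            mixed, _ = build_mixed_feature(ds, g.members, "mean", mixed_id=g.mixed_id)
            cols.append(mixed)
        feature_ids.append(g.mixed_id)
    return FeatureSubset(
        kept_ids=kept,
        groups=groups,
        strategy=strategy,
        feature_ids=feature_ids,
        values=np.column_stack(cols),
        representative_choice=rep_choice,
    )
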