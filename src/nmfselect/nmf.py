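"""Regularized KL-NMF with multiplicative updates and consensus rank selection.

The factorization approximates a nonnegative features x samples matrix
``X`` (n x p) as ``W @ H`` with ``W`` (n x r) the basis matrix and ``H``
(r x p) the mixture coefficient matrix.  The loss is the (generalized)
Kullback-Leibler divergence, optionally augmented with a smoothness penalty
on ``W`` and a sparsity penalty on ``H``:

    F1(W) = 1/2 * sum_ij (W_ij - c)^2
    F2(H) = 1/2 * sum over rows h of H of (||h||_2^2 - alpha^2 * ||h||_1^2)

With both weights at zero the updates are the classical Lee-Seung KL rules,
whose objective is non-increasing per iteration.  With nonzero weights the
penalty gradients are folded into the update denominators (a common
multiplicative heuristic; the monotonicity guarantee then no longer holds).

Note on F2: the source formulation indexes rows of ``H`` with a subscript
normally used for columns; the row reading is implemented here.  For
``alpha > 1`` the penalty rewards rather than penalizes L1 mass.

Rank selection surveys a range of ranks with multi-restart consensus
clustering (cophenetic correlation of the consensus matrix, Brunet-style)
alongside the residual-sum-of-squares curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from .exceptions import ConfigError, DegenerateInputError, NumericalError, ValidationError

__all__ = [
    "NMFConfig",
    "NMFFactorization",
    "RankSurvey",
    "kl_divergence",
    "regularization_value",
    "factorize",
    "rss",
    "connectivity_matrix",
    "consensus_matrix",
    "cophenetic_coefficient",
    "select_rank",
    "assign_sample_clusters",
    "assign_feature_basis",
]

_EPS = 1e-12


@dataclass
class NMFConfig:
    """Factorization hyperparameters.

    ``c`` is the smoothness target constant for W, ``alpha`` the sparsity
    constant for H; ``lambda_w`` / ``lambda_h`` weight the two penalties in
    the total objective (both default to 0 = plain Lee-Seung KL updates).
    """

    rank: int = 3
    c: float = 0.0
    alpha: float = 0.0
    lambda_w: float = 0.0
    lambda_h: float = 0.0
    max_iter: int = 2000
    tol: float = 1e-6
    seed: int = 0
    #: gauge fixing: "h-mean" rescales each basis so the corresponding H row
    #: has unit mean (WH unchanged); "none" returns the raw factors.  The
    #: factorization is indeterminate up to a per-basis scale, and downstream
    #: row similarities on W are not invariant to it, so a fixed gauge makes
    #: them well-defined.
    normalize: str = "h-mean"

    def __post_init__(self) -> None:
        if self.rank < 2:
            raise ConfigError("rank must be >= 2")
        if self.tol <= 0:
            raise ConfigError("tol must be > 0")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if self.c < 0 or self.alpha < 0 or self.lambda_w < 0 or self.lambda_h < 0:
            raise ConfigError("regularization constants must be nonnegative")
        if self.normalize not in {"h-mean", "none"}:
            raise ConfigError(f"unknown normalization {self.normalize!r}")


@dataclass
class NMFFactorization:
    W: np.ndarray  # (n_features, rank), nonnegative
    H: np.ndarray  # (rank, n_samples), nonnegative
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def rank(self) -> int:
        return self.W.shape[1]


@dataclass
class RankSurvey:
    """Per-rank diagnostics and the chosen rank."""

    ranks: list[int]
    cophenetic: list[float]
    rss_values: list[float]
    consensus: dict[int, np.ndarray]
    selected_rank: int | None
    selection_rule: str  # "cophenetic" or "inconclusive"
    cophenetic_candidate: int | None
    rss_candidate: int | None


def kl_divergence(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Generalized KL divergence D(X || WH), with the 0*log(0) = 0 convention.

    Returns ``inf`` when (WH)_ij = 0 at some entry with X_ij > 0.
    """
    X = np.asarray(X, dtype=float)
    WH = np.asarray(W, dtype=float) @ np.asarray(H, dtype=float)
    mask = X > 0
    if np.any(WH[mask] == 0):
        return float("inf")
    log_term = float(np.sum(X[mask] * np.log(X[mask] / WH[mask])))
    return log_term - float(X.sum()) + float(WH.sum())


def regularization_value(
    W: np.ndarray, H: np.ndarray, c: float, alpha: float
) -> tuple[float, float]:
    """Return (F1, F2): smoothness penalty on W and sparsity penalty on H."""
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    f1 = 0.5 * float(np.sum((W - c) ** 2))
    row_l2_sq = np.sum(H**2, axis=1)
    row_l1_sq = np.sum(np.abs(H), axis=1) ** 2
    f2 = 0.5 * float(np.sum(row_l2_sq - alpha**2 * row_l1_sq))
    return f1, f2


def _objective(X: np.ndarray, W: np.ndarray, H: np.ndarray, cfg: NMFConfig) -> float:
    obj = kl_divergence(X, W, H)
    if cfg.lambda_w or cfg.lambda_h:
        f1, f2 = regularization_value(W, H, cfg.c, cfg.alpha)
        obj += cfg.lambda_w * f1 + cfg.lambda_h * f2
    return obj


def factorize(X: np.ndarray, cfg: NMFConfig) -> NMFFactorization:
    """Run multiplicative KL updates from a seeded uniform initialization.

    Initial W, H entries are i.i.d. uniform on (0, 1], rescaled so that
    ``mean(WH) == mean(X)``.  Iteration stops when the relative change of
    the total objective falls below ``cfg.tol`` or ``cfg.max_iter`` is hit.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be a 2-D matrix")
    if (X < 0).any():
        raise ValidationError("X must be nonnegative")
    if not X.any():
        raise DegenerateInputError("all-zero matrix cannot be factorized")
    n, p = X.shape
    r = cfg.rank
    if r >= min(n, p):
        raise ValidationError(f"rank {r} must be < min(n, p) = {min(n, p)}")

    rng = np.random.default_rng(cfg.seed)
    W = 1.0 - rng.random((n, r))  # uniform on (0, 1]
    H = 1.0 - rng.random((r, p))
    scale = np.sqrt(X.mean() / (W @ H).mean())
    W *= scale
    H *= scale

    trace: list[float] = []
    prev = _objective(X, W, H, cfg)
    converged = False
    for it in range(cfg.max_iter):
        WH = np.maximum(W @ H, _EPS)
        ratio = X / WH
        num_w = ratio @ H.T
        den_w = np.broadcast_to(H.sum(axis=1)[None, :], W.shape).copy()
        if cfg.lambda_w:
            den_w += cfg.lambda_w * (W - cfg.c)
        W = W * num_w / np.maximum(den_w, _EPS)

        WH = np.maximum(W @ H, _EPS)
        ratio = X / WH
        num_h = W.T @ ratio
        den_h = np.broadcast_to(W.sum(axis=0)[:, None], H.shape).copy()
        if cfg.lambda_h:
            den_h = den_h + cfg.lambda_h * (
                H - cfg.alpha**2 * np.abs(H).sum(axis=1, keepdims=True)
            )
        H = H * num_h / np.maximum(den_h, _EPS)

        obj = _objective(X, W, H, cfg)
        if not np.isfinite(obj):
            raise NumericalError(f"non-finite objective at iteration {it}")
        trace.append(obj)
        denom = max(abs(prev), _EPS)
        if abs(prev - obj) / denom < cfg.tol:
            converged = True
            break
        prev = obj
    if cfg.normalize == "h-mean":
        scale = np.maximum(H.mean(axis=1), _EPS)
        W = W * scale[None, :]
        H = H / scale[:, None]
    return NMFFactorization(W=W, H=H, objective_trace=trace, converged=converged)


def kl_update_step(
    X: np.ndarray, W: np.ndarray, H: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One plain (unregularized) Lee-Seung KL update of W then H.

    W_ia <- W_ia * sum_j(H_aj * X_ij / (WH)_ij) / sum_j H_aj, then the
    symmetric update for H using the refreshed W.
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float).copy()
    H = np.asarray(H, dtype=float).copy()
    ratio = X / np.maximum(W @ H, _EPS)
    W = W * (ratio @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
    ratio = X / np.maximum(W @ H, _EPS)
    H = H * (W.T @ ratio) / np.maximum(W.sum(axis=0)[:, None], _EPS)
    return W, H


def rss(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Residual sum of squares of the reconstruction, sum_ij (X - WH)^2."""
    X = np.asarray(X, dtype=float)
    return float(np.sum((X - np.asarray(W) @ np.asarray(H)) ** 2))


def assign_sample_clusters(H: np.ndarray) -> np.ndarray:
    """Per-column argmax of H (0-based); ties go to the smallest index."""
    H = np.asarray(H)
    if (H < 0).any():
        raise ValidationError("H must be nonnegative")
    return np.argmax(H, axis=0)


def assign_feature_basis(W: np.ndarray) -> np.ndarray:
    """Per-row argmax of W (0-based); ties go to the smallest index."""
    W = np.asarray(W)
    if (W < 0).any():
        raise ValidationError("W must be nonnegative")
    return np.argmax(W, axis=1)


def connectivity_matrix(clusters: np.ndarray) -> np.ndarray:
    """Binary p x p matrix; entry (j, k) is 1 iff samples j, k share a cluster."""
    c = np.asarray(clusters)
    return (c[:, None] == c[None, :]).astype(float)


def _spawn_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0])


def consensus_matrix(
    X: np.ndarray,
    r: int,
    n_runs: int,
    seed: int,
    cfg: NMFConfig | None = None,
) -> np.ndarray:
    """Average connectivity matrix over ``n_runs`` random restarts at rank r."""
    if n_runs < 2:
        raise ConfigError("n_runs must be >= 2")
    base = cfg if cfg is not None else NMFConfig(rank=r)
    p = np.asarray(X).shape[1]
    acc = np.zeros((p, p))
    for k in range(n_runs):
        run_cfg = NMFConfig(
            rank=r,
            c=base.c,
            alpha=base.alpha,
            lambda_w=base.lambda_w,
            lambda_h=base.lambda_h,
            max_iter=base.max_iter,
            tol=base.tol,
            seed=_spawn_seed(seed, k),
        )
        fac = factorize(X, run_cfg)
        acc += connectivity_matrix(assign_sample_clusters(fac.H))
    return acc / n_runs


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation of the consensus matrix.

    Builds average-linkage hierarchical clustering on the dissimilarities
    ``1 - consensus`` and returns the Pearson correlation between the
    original and cophenetic distances.  A constant dissimilarity structure
    (perfectly reproducible clustering) is defined as 1.0.
    """
    C = np.asarray(consensus, dtype=float)
    if C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-10):
        raise ValidationError("consensus matrix must be square and symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-10):
        raise ValidationError("consensus matrix must have unit diagonal")
    D = 1.0 - (C + C.T) / 2.0
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    if condensed.size == 0 or np.ptp(condensed) == 0:
        return 1.0
    Z = average(condensed)
    coph = cophenet(Z)
    if np.ptp(coph) == 0:
        return 1.0
    return float(np.corrcoef(condensed, coph)[0, 1])


def _cophenetic_rule(ranks: list[int], coph: list[float]) -> int | None:
    """Smallest rank r with cophenetic(r+1) < cophenetic(r)."""
    for i in range(len(ranks) - 1):
        if coph[i + 1] < coph[i]:
            return ranks[i]
    return None


def _rss_rule(ranks: list[int], rss_values: list[float]) -> int | None:
    """First interior rank where the discrete second difference of the RSS
    curve changes sign."""
    if len(ranks) < 4:
        return None
    d2 = [
        rss_values[i + 1] - 2 * rss_values[i] + rss_values[i - 1]
        for i in range(1, len(ranks) - 1)
    ]
    signs = np.sign(d2)
    for i in range(1, len(d2)):
        if signs[i] != 0 and signs[i - 1] != 0 and signs[i] != signs[i - 1]:
            return ranks[i + 1]
    return None


def select_rank(
    X: np.ndarray,
    rank_range: tuple[int, int] = (2, 7),
    cfg: NMFConfig | None = None,
    n_runs: int = 30,
    seed: int | None = None,
) -> RankSurvey:
    """Survey ranks and choose one by consensus stability.

    For each rank the consensus matrix over ``n_runs`` restarts yields a
    cophenetic coefficient, and the restart with the lowest objective yields
    the RSS value.  The cophenetic rule (smallest rank whose successor's
    coefficient is lower) decides; the RSS-inflection candidate is reported
    alongside.  If the cophenetic curve never decreases the survey is
    flagged inconclusive.
    """
    lo, hi = rank_range
    X = np.asarray(X, dtype=float)
    if lo < 2 or hi >= min(X.shape):
        raise ValidationError(f"rank range {rank_range} outside (1, min(n, p))")
    base = cfg if cfg is not None else NMFConfig()
    seed = base.seed if seed is None else seed
    ranks = list(range(lo, hi + 1))
    coph: list[float] = []
    rss_values: list[float] = []
    consensus: dict[int, np.ndarray] = {}
    p = X.shape[1]
    for r in ranks:
        acc = np.zeros((p, p))
        best_obj = np.inf
        best = None
        for k in range(n_runs):
            run_cfg = NMFConfig(
                rank=r,
                c=base.c,
                alpha=base.alpha,
                lambda_w=base.lambda_w,
                lambda_h=base.lambda_h,
                max_iter=base.max_iter,
                tol=base.tol,
                seed=_spawn_seed(seed, r * 10007 + k),
            )
            fac = factorize(X, run_cfg)
            acc += connectivity_matrix(assign_sample_clusters(fac.H))
            obj = fac.objective_trace[-1] if fac.objective_trace else np.inf
            if obj < best_obj:
                best_obj = obj
                best = fac
        consensus[r] = acc / n_runs
        coph.append(cophenetic_coefficient(consensus[r]))
        rss_values.append(rss(X, best.W, best.H))

    coph_candidate = _cophenetic_rule(ranks, coph)
    rss_candidate = _rss_rule(ranks, rss_values)
    if coph_candidate is not None:
        selected, rule = coph_candidate, "cophenetic"
    else:
        selected, rule = None, "inconclusive"
    return RankSurvey(
        ranks=ranks,
        cophenetic=coph,
        rss_values=rss_values,
        consensus=consensus,
        selected_rank=selected,
        selection_rule=rule,
        cophenetic_candidate=coph_candidate,
        rss_candidate=rss_candidate,
    )
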