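"""Synthetic clinical-style datasets with planted ground truth.

Generates a sample x symptom ordinal matrix with three kinds of columns:

* *informative* symptoms, each with a signature stage where its positive
  probability is high and lower probabilities elsewhere;
* *redundant copies* of selected informative symptoms, perturbed by a small
  symmetric value-flip noise;
* *irrelevant* symptoms, rarely positive in every stage.

Positive entries draw their severity level from a truncated geometric
distribution (a free modeling choice; screening only depends on positivity).
Informative probability profiles are rejection-sampled to keep a minimum
separation between the per-stage mean-value vectors of distinct symptoms,
so planted redundancy is identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import ClinicalDataset
from .exceptions import ValidationError

__all__ = ["RedundantGroupSpec", "SyntheticSpec", "GroundTruth", "generate", "paper_shape_preset"]

_STAGE_SUBSTAGES = {1: ("IA", "IB"), 2: ("IIA", "IIB"), 3: ("IIIA", "IIIB")}


@dataclass
class RedundantGroupSpec:
    """One planted group: ``copies`` near-duplicates of informative symptom
    ``source`` (0-based index into the informative block) with flip noise
    ``epsilon``."""

    source: int
    copies: int
    epsilon: float = 0.02


@dataclass
class SyntheticSpec:
    n_per_stage: tuple[int, ...] = (82, 195, 130)
    n_informative: int = 20
    n_irrelevant: int = 4
    redundant: list[RedundantGroupSpec] = field(default_factory=list)
    high_prob_range: tuple[float, float] = (0.32, 0.95)
    low_prob_range: tuple[float, float] = (0.02, 0.95)
    irrelevant_prob: float = 0.03
    max_level: int = 3
    severity_q: float = 0.5  # geometric success prob for severity levels
    # profile-separation constraints (see _sample_profiles)
    profile_corr_cap: float = 0.80
    profile_dist_floor: float = 0.60
    # plant signatures at substage granularity (6 latent clusters, 3 stages)
    substage_signatures: bool = False
    substage_frac: tuple[float, ...] | None = None  # fraction of "A" per stage
    sex_male_frac: tuple[float, ...] | None = None
    seed: int = 0

    @property
    def n_stages(self) -> int:
        return len(self.n_per_stage)

    @property
    def n_copies(self) -> int:
        return sum(g.copies for g in self.redundant)

    @property
    def n_symptoms(self) -> int:
        return self.n_informative + self.n_copies + self.n_irrelevant

    def validate(self) -> None:
        if self.n_stages < 2:
            raise ValidationError("need at least 2 stages")
        if any(n < 1 for n in self.n_per_stage):
            raise ValidationError("every stage needs at least one sample")
        if self.n_informative < self.n_stages:
            raise ValidationError("need at least one informative symptom per stage")
        for r in (self.high_prob_range, self.low_prob_range):
            if not (0.0 <= r[0] <= r[1] <= 1.0):
                raise ValidationError(f"bad probability range {r}")
        if not 0.0 <= self.irrelevant_prob <= 1.0:
            raise ValidationError("irrelevant_prob must lie in [0, 1]")
        for g in self.redundant:
            if not 0 <= g.source < self.n_informative:
                raise ValidationError(f"group source {g.source} out of range")
            if g.copies < 1:
                raise ValidationError("each group needs at least one copy")
            if not 0.0 <= g.epsilon <= 1.0:
                raise ValidationError("epsilon must lie in [0, 1]")
        if len({g.source for g in self.redundant}) != len(self.redundant):
            raise ValidationError("duplicate group sources")


@dataclass
class GroundTruth:
    irrelevant_ids: list[str]
    redundant_groups: list[list[str]]  # each: [source id, copy ids...]
    signature_stage: dict[str, int]

    @property
    def redundant_pairs(self) -> set[frozenset]:
        pairs: set[frozenset] = set()
        for g in self.redundant_groups:
            for i, a in enumerate(g):
                for b in g[i + 1 :]:
                    pairs.add(frozenset((a, b)))
        return pairs


def _severity_levels(rng: np.random.Generator, size: int, q: float, L: int) -> np.ndarray:
    return np.minimum(rng.geometric(q, size=size), L)


def _expected_level(spec: SyntheticSpec) -> float:
    lv = np.arange(1, spec.max_level + 1)
    pmf = spec.severity_q * (1 - spec.severity_q) ** (lv - 1)
    pmf[-1] += (1 - spec.severity_q) ** spec.max_level  # lump the tail
    return float(np.sum(lv * pmf))


def _profiles_compatible(
    a: np.ndarray, b: np.ndarray, corr_cap: float, dist_floor: float
) -> bool:
    """Two mean-value profiles are distinguishable as non-redundant if they
    are either decorrelated or well separated in distance."""
    ca, cb = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(ca), np.linalg.norm(cb)
    corr = 1.0 if na == 0 or nb == 0 else float(ca @ cb / (na * nb))
    return corr < corr_cap or float(np.linalg.norm(a - b)) >= dist_floor


def _candidate_means(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Lattice of mean-value profiles, pairwise separated by construction.

    Profiles are parameterized as ``m = mu * 1 + rho * u(phi)`` with ``u`` a
    unit direction in the plane of zero-sum vectors.  The 9 direction
    families sit 40 degrees apart, so cross-family centered correlation is
    at most cos(40 deg) ~ 0.77 < ``profile_corr_cap``; within a family the
    (sqrt(3)*mu, rho) grid spacing equals ``profile_dist_floor``, so every
    same-family pair is at least the floor apart.  Only valid for 3 stages.
    """
    e_level = _expected_level(spec)
    floor = spec.profile_dist_floor
    lo = max(spec.low_prob_range[0], 0.02) * e_level
    hi = min(spec.low_prob_range[1], 0.95) * e_level
    peak_min = spec.high_prob_range[0] * e_level
    e1 = np.array([2.0, -1.0, -1.0]) / np.sqrt(6.0)
    e2 = np.array([0.0, 1.0, -1.0]) / np.sqrt(2.0)
    phi0 = rng.uniform(0.10, 0.60)  # keeps families clear of argmax boundaries
    cands = []
    for k in range(9):
        phi = phi0 + k * 2.0 * np.pi / 9.0
        u = np.cos(phi) * e1 + np.sin(phi) * e2
        for mu in np.arange(0.10, 1.66, floor / np.sqrt(3.0)):
            for rho in np.arange(0.30, 1.70, floor):
                m = mu + rho * u
                if m.min() < lo or m.max() > hi or m.max() < peak_min:
                    continue
                cands.append(m)
    return np.array(cands)


def _sample_profiles(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-informative-symptom positive probability per stage.

    Symptom ``i`` peaks in stage ``i mod n_stages``.  Profiles are chosen
    from a separated lattice (see :func:`_candidate_means`) so that every
    pair of distinct informative symptoms is either decorrelated (centered
    correlation below ``profile_corr_cap``) or separated in mean-value space
    by at least ``profile_dist_floor``; this keeps planted redundant copies
    identifiable against chance similarity in the low-rank basis space.
    For other than 3 stages, profiles fall back to rejection sampling.
    """
    s = spec.n_stages
    e_level = _expected_level(spec)
    if s == 3:
        cands = _candidate_means(spec, rng)
        order = rng.permutation(len(cands))
        by_sig: dict[int, list[np.ndarray]] = {k: [] for k in range(s)}
        for idx in order:
            by_sig[int(np.argmax(cands[idx]))].append(cands[idx])
        profiles = np.empty((spec.n_informative, s))
        means: list[np.ndarray] = []
        for i in range(spec.n_informative):
            sig = i % s
            pool = by_sig[sig]
            best, best_score = None, -np.inf
            for m in pool:
                ok = all(
                    _profiles_compatible(
                        m, prev, spec.profile_corr_cap, spec.profile_dist_floor
                    )
                    for prev in means
                )
                score = (
                    min((np.linalg.norm(m - prev) for prev in means), default=np.inf)
                    + (1000.0 if ok else 0.0)
                )
                if score > best_score:
                    best_score, best = score, m
            # small jitter for seed diversity, preserving the peak stage
            m = best + rng.uniform(-0.02, 0.02, size=s) * e_level
            m = np.clip(m, 0.02 * e_level, 0.95 * e_level)
            if np.argmax(m) != sig:
                m = best
            means.append(m)
            profiles[i] = m / e_level
        return profiles

    profiles = np.empty((spec.n_informative, s))
    for i in range(spec.n_informative):
        sig = i % s
        while True:
            p = rng.uniform(*spec.low_prob_range, size=s)
            p[sig] = rng.uniform(*spec.high_prob_range)
            if np.argmax(p) == sig:
                break
        profiles[i] = p
    return profiles


def _substage_profiles(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-informative-symptom positive probability per substage (6 strata).

    Symptom ``i`` peaks in substage ``i mod 6``, with a mild elevation on
    the same-stage sibling substage and a strong individual low/high
    baseline pattern over the four remaining substages, drawn from the
    even-weight binary code of length 4 (pairwise Hamming distance >= 2).
    The uniform high peak keeps every informative symptom's KL weight large
    (weakly expressed features are otherwise fit sloppily and collapse onto
    neighboring basis rows), while the 8 distinct patterns per family keep
    same-family symptoms well separated in mean-value space; planted copies
    stay nearly identical.
    """
    peak_levels = (0.95,)
    base_lo, base_hi = 0.05, 0.65
    sibling = 0.30  # elevation of the same-stage sibling substage
    cross_23 = 0.15  # mild stage-2/3 cross-elevation
    patterns = [
        tuple((w >> k) & 1 for k in range(4))
        for w in range(16)
        if bin(w).count("1") % 2 == 0
    ]
    combos = [(pk, pat) for pk in peak_levels for pat in patterns]

    per_family: dict[int, list] = {}
    for fam in range(6):
        order = rng.permutation(len(combos))
        per_family[fam] = [combos[i] for i in order]

    profiles = np.empty((spec.n_informative, 6))
    cursor = {fam: 0 for fam in range(6)}
    for i in range(spec.n_informative):
        fam = i % 6
        stage_of_fam = fam // 2
        sib = fam ^ 1
        peak, pat = per_family[fam][cursor[fam] % len(combos)]
        cursor[fam] += 1
        p = np.empty(6)
        k = 0
        for j in range(6):
            if j == fam:
                p[j] = peak
            elif j == sib:
                p[j] = sibling * peak
            else:
                p[j] = base_lo if pat[k] == 0 else base_hi
                k += 1
                if stage_of_fam >= 1 and j // 2 >= 1:
                    p[j] += cross_23 * peak  # additive: keeps pattern offsets
        p += rng.uniform(-0.02, 0.02, size=6)
        profiles[i] = np.clip(p, 0.02, 0.97)
    return profiles


def block_matrix(
    n_features: int = 49,
    n_samples: int = 120,
    n_blocks: int = 3,
    signal: float = 2.0,
    background: float = 0.3,
    noise: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative features x samples matrix with planted co-blocks.

    Features and samples are split evenly into ``n_blocks`` groups; entries
    where the groups coincide get ``background + signal``, others just
    ``background``, plus truncated Gaussian noise.  Returns the matrix and
    the per-sample block labels.  Used for factorization-rank recovery
    experiments.
    """
    rng = np.random.default_rng(seed)
    frow = np.arange(n_features) % n_blocks
    scol = np.arange(n_samples) % n_blocks
    X = background + signal * (frow[:, None] == scol[None, :])
    X = X + rng.normal(0.0, noise, size=X.shape)
    return np.maximum(X, 0.0), scol


def generate(spec: SyntheticSpec) -> tuple[ClinicalDataset, GroundTruth]:
    """Sample a dataset and its ground truth; deterministic given the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    s = spec.n_stages
    p_total = int(sum(spec.n_per_stage))
    n_total = spec.n_symptoms

    stage = np.concatenate(
        [np.full(n, k + 1, dtype=np.int64) for k, n in enumerate(spec.n_per_stage)]
    )
    substage: list[str] | None = None
    if s == 3:
        substage = []
        fracs = spec.substage_frac or (0.5,) * s
        for k, n in enumerate(spec.n_per_stage):
            a, b = _STAGE_SUBSTAGES[k + 1]
            n_a = int(round(fracs[k] * n))
            substage.extend([a] * n_a + [b] * (n - n_a))
    sex = np.empty(p_total, dtype=np.int64)
    fracs = spec.sex_male_frac or (0.5,) * s
    pos = 0
    for k, n in enumerate(spec.n_per_stage):
        n_male = int(round(fracs[k] * n))
        block = np.array([1] * n_male + [0] * (n - n_male))
        sex[pos : pos + n] = rng.permutation(block)
        pos += n

    if spec.substage_signatures:
        if s != 3 or substage is None:
            raise ValidationError("substage signatures require 3 stages")
        profiles = _substage_profiles(spec, rng)
        order = ["IA", "IB", "IIA", "IIB", "IIIA", "IIIB"]
        stratum = np.array([order.index(code) for code in substage])
        n_strata = 6
    else:
        profiles = _sample_profiles(spec, rng)
        stratum = stage - 1
        n_strata = s
    values = np.zeros((p_total, n_total), dtype=np.int64)
    # informative block
    for k in range(n_strata):
        mask = stratum == k
        n = int(mask.sum())
        for i in range(spec.n_informative):
            hit = rng.random(n) < profiles[i, k]
            col = np.zeros(n, dtype=np.int64)
            col[hit] = _severity_levels(rng, int(hit.sum()), spec.severity_q, spec.max_level)
            values[mask, i] = col
    # redundant copies
    j = spec.n_informative
    copy_cols: list[tuple[int, int]] = []  # (column index, source)
    for g in spec.redundant:
        for _ in range(g.copies):
            col = values[:, g.source].copy()
            flip = rng.random(p_total) < g.epsilon
            delta = rng.choice([-1, 1], size=int(flip.sum()))
            col[flip] = np.clip(col[flip] + delta, 0, spec.max_level)
            values[:, j] = col
            copy_cols.append((j, g.source))
            j += 1
    # irrelevant block
    for _ in range(spec.n_irrelevant):
        hit = rng.random(p_total) < spec.irrelevant_prob
        col = np.zeros(p_total, dtype=np.int64)
        col[hit] = _severity_levels(rng, int(hit.sum()), spec.severity_q, spec.max_level)
        values[:, j] = col
        j += 1

    symptom_ids = [f"V{i + 1}" for i in range(n_total)]
    sample_ids = [f"S{i + 1:04d}" for i in range(p_total)]
    ds = ClinicalDataset(
        values=values,
        symptom_ids=symptom_ids,
        sample_ids=sample_ids,
        stage=stage,
        substage=substage,
        sex=sex,
    )
    groups: list[list[str]] = []
    j = spec.n_informative
    for g in spec.redundant:
        members = [symptom_ids[g.source]] + [symptom_ids[j + k] for k in range(g.copies)]
        groups.append(members)
        j += g.copies
    truth = GroundTruth(
        irrelevant_ids=symptom_ids[spec.n_informative + spec.n_copies :],
        redundant_groups=groups,
        signature_stage={
            symptom_ids[i]: (i % (6 if spec.substage_signatures else s)) + 1
            for i in range(spec.n_informative)
        },
    )
    return ds, truth


def paper_shape_preset(seed: int = 0) -> SyntheticSpec:
    """Spec matching the reference cohort shape: 407 samples split 82/195/130
    over three stages, 57 symptoms of which 8 are planted irrelevant and 16
    belong to 6 planted redundant groups (sizes 3, 2, 2, 5, 2, 2).

    Signatures are planted at substage granularity (one redundant group per
    substage family) so the latent rank is 6 and redundancy is identifiable
    in the basis space; the sex imbalance follows the reference cohort.
    """
    groups = [
        RedundantGroupSpec(source=0, copies=2),   # size 3, substage family 1
        RedundantGroupSpec(source=1, copies=1),   # size 2, family 2
        RedundantGroupSpec(source=2, copies=1),   # size 2, family 3
        RedundantGroupSpec(source=3, copies=4),   # size 5, family 4
        RedundantGroupSpec(source=4, copies=1),   # size 2, family 5
        RedundantGroupSpec(source=5, copies=1),   # size 2, family 6
    ]
    return SyntheticSpec(
        n_per_stage=(82, 195, 130),
        n_informative=39,
        n_irrelevant=8,
        redundant=groups,
        irrelevant_prob=0.01,
        substage_signatures=True,
        substage_frac=(0.5, 0.5, 0.5),
        sex_male_frac=(60 / 82, 165 / 195, 105 / 130),
        seed=seed,
    )
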