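"""Food-web structure generators.

The cascade model orders species along a hierarchy (think body size) and
lets each consumer feed on any of its predecessors independently with
probability ``C``; the resulting directed graph (resource -> consumer) is
acyclic by construction.  The niche model instead assigns each species a
niche value and a diet *interval*, which produces interval webs that may
contain a handful of trophic cycles.  Three cascade variants isolate the
structural differences between the two models: matching the niche model's
consumer degree distribution, forcing interval diets, and both at once
(a cycle-less niche model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "FoodWeb",
    "generate_cascade",
    "generate_niche",
    "generate_cascade_degree_matched",
    "generate_cascade_interval",
    "generate_niche_cycleless",
    "connectance",
    "has_cycles",
    "is_interval",
]

SeedLike = Union[int, np.random.Generator, None]

_MODELS = {
    "cascade",
    "niche",
    "cascade_degree_matched",
    "cascade_interval",
    "niche_cycleless",
    "user",
}


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class FoodWeb:
    """Binary adjacency structure of a food web.

    ``K[i, j] == 1`` means species ``i`` (row, resource) is consumed by
    species ``j`` (column, consumer).  ``ordering_meta`` optionally stores
    per-species scalars of the generative ordering (e.g. niche values).
    """

    S: int
    K: np.ndarray
    model: str = "user"
    ordering_meta: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K)
        if self.K.shape != (self.S, self.S):
            raise ValueError(f"K must be {self.S}x{self.S}, got {self.K.shape}")
        if not np.isin(self.K, (0, 1)).all():
            raise ValueError("K must be binary")
        if np.diagonal(self.K).any():
            raise ValueError("K must have a zero diagonal (no cannibalism)")
        if self.model not in _MODELS:
            raise ValueError(f"unknown model tag {self.model!r}")
        self.K = self.K.astype(np.int8)

    @property
    def n_links(self) -> int:
        return int(self.K.sum())


def _check_SC(S: int, C: float, *, c_upper: float = 1.0) -> None:
    if not (isinstance(S, (int, np.integer)) and S >= 2):
        raise ValueError(f"S must be an integer >= 2, got {S!r}")
    if not (0.0 <= C <= 1.0):
        raise ValueError(f"C must be a probability, got {C!r}")
    if C >= c_upper and c_upper < 1.0:
        raise ValueError(
            f"C must be < {c_upper} for niche-type generality (Beta shape), got {C!r}"
        )


def generate_cascade(S: int, C: float, seed: SeedLike = None) -> FoodWeb:
    """Cascade-model web: each pair i < j is a link with probability C."""
    _check_SC(S, C)
    rng = _rng(seed)
    K = np.zeros((S, S), dtype=np.int8)
    iu, ju = np.triu_indices(S, k=1)
    K[iu, ju] = rng.random(iu.size) < C
    return FoodWeb(S, K, model="cascade", seed=seed if isinstance(seed, int) else None)


def _niche_values_and_ranges(
    S: int, C: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sorted niche values n and diet ranges r = n * x, x ~ Beta(1, (1-2C)/2C)."""
    n = np.sort(rng.random(S))
    beta_shape = (1.0 - 2.0 * C) / (2.0 * C)
    x = rng.beta(1.0, beta_shape, size=S)
    return n, n * x


def generate_niche(S: int, C: float, seed: SeedLike = None) -> FoodWeb:
    """Niche-model web (species returned sorted by niche value).

    Each species gets a niche value n ~ U(0,1), a diet range r = n*x with
    x ~ Beta(1, (1-2C)/(2C)) (so E[x] = 2C and expected directed
    connectance L/S^2 is calibrated to C), and a diet centre
    c ~ U(r/2, n).  Species j consumes every i whose niche value falls in
    [c_j - r_j/2, c_j + r_j/2]; self-links are removed.
    """
    _check_SC(S, C, c_upper=0.5)
    if C <= 0.0:
        raise ValueError("C must be > 0 for the niche model")
    rng = _rng(seed)
    n, r = _niche_values_and_ranges(S, C, rng)
    c = rng.uniform(r / 2.0, n)
    low, high = c - r / 2.0, c + r / 2.0
    K = ((n[:, None] >= low[None, :]) & (n[:, None] <= high[None, :])).astype(np.int8)
    np.fill_diagonal(K, 0)
    return FoodWeb(
        S, K, model="niche", ordering_meta=n, seed=seed if isinstance(seed, int) else None
    )


def _niche_diet_sizes(S: int, C: float, rng: np.random.Generator) -> np.ndarray:
    """Consumer diet sizes under the niche generality law, k_j = round(r_j*S),
    truncated to the number of predecessors [0, j-1]."""
    _, r = _niche_values_and_ranges(S, C, rng)
    k = np.rint(r * S).astype(int)
    return np.minimum(k, np.arange(S))


def generate_cascade_degree_matched(S: int, C: float, seed: SeedLike = None) -> FoodWeb:
    """Cascade variant with the niche model's consumer degree distribution.

    Diet sizes follow the niche generality law; prey are chosen uniformly
    at random among the predecessors, so the web stays acyclic.
    """
    _check_SC(S, C, c_upper=0.5)
    if C <= 0.0:
        raise ValueError("C must be > 0 (Beta shape undefined at C=0)")
    rng = _rng(seed)
    k = _niche_diet_sizes(S, C, rng)
    K = np.zeros((S, S), dtype=np.int8)
    for j in range(1, S):
        if k[j] > 0:
            prey = rng.choice(j, size=k[j], replace=False)
            K[prey, j] = 1
    return FoodWeb(
        S, K, model="cascade_degree_matched", seed=seed if isinstance(seed, int) else None
    )


def generate_cascade_interval(S: int, C: float, seed: SeedLike = None) -> FoodWeb:
    """Cascade variant producing interval webs.

    Diet sizes are Binomial(j-1, C) as in the cascade model, but each
    consumer's prey form one contiguous block of predecessors, placed
    uniformly at random.
    """
    _check_SC(S, C)
    rng = _rng(seed)
    K = np.zeros((S, S), dtype=np.int8)
    for j in range(1, S):
        kj = rng.binomial(j, C)
        if kj > 0:
            start = rng.integers(0, j - kj + 1)
            K[start : start + kj, j] = 1
    return FoodWeb(
        S, K, model="cascade_interval", seed=seed if isinstance(seed, int) else None
    )


def generate_niche_cycleless(S: int, C: float, seed: SeedLike = None) -> FoodWeb:
    """Cycle-less niche model: niche generality law + interval diets, acyclic."""
    _check_SC(S, C, c_upper=0.5)
    if C <= 0.0:
        raise ValueError("C must be > 0 (Beta shape undefined at C=0)")
    rng = _rng(seed)
    k = _niche_diet_sizes(S, C, rng)
    K = np.zeros((S, S), dtype=np.int8)
    for j in range(1, S):
        if k[j] > 0:
            start = rng.integers(0, j - k[j] + 1)
            K[start : start + k[j], j] = 1
    return FoodWeb(
        S, K, model="niche_cycleless", seed=seed if isinstance(seed, int) else None
    )


def connectance(web: FoodWeb, potential: str = "pairs") -> float:
    """Realized connectance of a web.

    potential="pairs" (default) divides the link count by S(S-1)/2, the
    per-pair convention under which the cascade model's C is defined;
    potential="directed" divides by S^2, the niche-model convention of
    Williams & Martinez under which E[L/S^2] = C.
    """
    L = web.n_links
    if potential == "pairs":
        return L / (web.S * (web.S - 1) / 2.0)
    if potential == "directed":
        return L / web.S**2
    raise ValueError("potential must be 'pairs' or 'directed'")


def has_cycles(web: FoodWeb) -> bool:
    """True iff the directed consumption graph contains a cycle (Kahn)."""
    K = web.K
    indeg = K.sum(axis=0).astype(np.int64)
    stack = list(np.flatnonzero(indeg == 0))
    removed = 0
    while stack:
        v = stack.pop()
        removed += 1
        out = np.flatnonzero(K[v])
        indeg[out] -= 1
        stack.extend(int(w) for w in out if indeg[w] == 0)
    return removed < web.S


def is_interval(web: FoodWeb, ordering: Optional[Sequence[int]] = None) -> bool:
    """True iff every consumer's prey set is contiguous in ``ordering``.

    ``ordering`` is a permutation listing species in display order
    (defaults to the generative ordering 0..S-1).  The consumer's own
    position is a permitted gap in its prey block: a niche-model diet
    interval may straddle the consumer's own niche value, and self-links
    are never recorded.
    """
    S = web.S
    if ordering is None:
        pos = np.arange(S)
    else:
        ordering = np.asarray(ordering)
        if sorted(ordering.tolist()) != list(range(S)):
            raise ValueError("ordering must be a permutation of 0..S-1")
        pos = np.empty(S, dtype=int)
        pos[ordering] = np.arange(S)
    for j in range(S):
        prey = np.flatnonzero(web.K[:, j])
        if prey.size >= 2:
            p = pos[prey]
            span = p.max() - p.min() + 1
            if span != p.size and not (
                span == p.size + 1 and p.min() < pos[j] < p.max()
            ):
                return False
    return True
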