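"""Alpha-diversity indices and rarefaction over taxon abundance profiles.

A profile is a mapping from taxon (or any discrete attribute value) to a
non-negative count. Provided statistics:

* Shannon entropy H = -sum p_i ln p_i (natural log by default);
* Simpson: the Gini-Simpson index 1 - sum p_i^2 by default, or the raw
  dominance sum p_i^2;
* Chao1 richness: S_obs + f1^2 / (2 f2), with the bias-corrected form
  S_obs + f1 (f1 - 1) / 2 when there are no doubletons;
* ACE richness (abundance-based coverage estimator) with the classic
  rare/abundant split at 10;
* rarefaction — the expected number of distinct taxa in a uniform random
  subsample of d individuals without replacement, exactly via the
  hypergeometric formula E[S_d] = sum_i (1 - C(n - n_i, d) / C(n, d))
  (computed in log-gamma space), or by seeded Monte-Carlo subsampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .io import ReadAssignment
from .taxonomy import TaxonomyTree


@dataclass(frozen=True)
class AbundanceProfile:
    counts: Mapping[Hashable, int]

    def __post_init__(self) -> None:
        for taxon, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {taxon!r}")

    @property
    def n(self) -> int:
        """Total number of individuals."""
        return sum(self.counts.values())

    @property
    def s_obs(self) -> int:
        """Observed richness (taxa with count > 0)."""
        return sum(1 for c in self.counts.values() if c > 0)

    def positive(self) -> list[int]:
        return [c for c in self.counts.values() if c > 0]


def profile_from_assignments(
    assignments: Iterable[ReadAssignment],
    tree: TaxonomyTree,
    rank: str = "genus",
) -> AbundanceProfile:
    """Build an abundance profile by projecting classified reads to `rank`.

    Unclassified reads and reads not resolvable at the rank are excluded.
    """
    counts: dict[int, int] = {}
    for a in assignments:
        if not a.is_classified or a.taxid not in tree:
            continue
        t = tree.ancestor_at_rank(a.taxid, rank)
        if t is not None:
            counts[t] = counts.get(t, 0) + 1
    return AbundanceProfile(counts)


def _check_nonempty(profile: AbundanceProfile) -> None:
    if profile.n == 0:
        raise ValueError("diversity index of an empty profile")


def shannon(profile: AbundanceProfile, base: float | None = None) -> float:
    """Shannon entropy; natural log unless `base` is given."""
    _check_nonempty(profile)
    n = profile.n
    h = -sum((c / n) * math.log(c / n) for c in profile.positive())
    if base is not None:
        h /= math.log(base)
    return h


def simpson(profile: AbundanceProfile, variant: str = "gini") -> float:
    """Simpson diversity: ``"gini"`` -> 1 - sum p_i^2, ``"dominance"`` -> sum p_i^2."""
    _check_nonempty(profile)
    n = profile.n
    d = sum((c / n) ** 2 for c in profile.positive())
    if variant == "gini":
        return 1.0 - d
    if variant == "dominance":
        return d
    raise ValueError(f"unknown simpson variant {variant!r}")


def _check_integer_counts(profile: AbundanceProfile) -> None:
    for c in profile.counts.values():
        if int(c) != c:
            raise ValueError("richness estimators require integer counts")


def chao1(profile: AbundanceProfile) -> float:
    """Chao1 richness estimate (>= observed richness)."""
    _check_nonempty(profile)
    _check_integer_counts(profile)
    counts = profile.positive()
    s_obs = len(counts)
    f1 = sum(1 for c in counts if c == 1)
    f2 = sum(1 for c in counts if c == 2)
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def ace(profile: AbundanceProfile, rare_threshold: int = 10) -> float:
    """ACE richness estimate with rare/abundant cut at `rare_threshold`.

    When every rare individual is a singleton the sample coverage estimate
    is zero and the estimator is undefined; the Chao1 value is returned
    instead (flagged by that degenerate condition, not an error).
    """
    _check_nonempty(profile)
    _check_integer_counts(profile)
    counts = profile.positive()
    rare = [c for c in counts if c <= rare_threshold]
    s_abund = sum(1 for c in counts if c > rare_threshold)
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = sum(rare)
    f1 = sum(1 for c in rare if c == 1)
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        return chao1(profile)
    # squared coefficient of variation of the rare-class abundances
    fk = [sum(1 for c in rare if c == k) for k in range(1, rare_threshold + 1)]
    num = sum(k * (k - 1) * fk[k - 1] for k in range(1, rare_threshold + 1))
    gamma2 = max(
        (s_rare / c_ace) * num / (n_rare * (n_rare - 1)) - 1.0 if n_rare > 1 else 0.0,
        0.0,
    )
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def rarefaction_curve(
    profile: AbundanceProfile,
    depths: Sequence[int],
    mode: str = "exact",
    seed: int | None = None,
    reps: int = 100,
) -> list[tuple[int, float]]:
    """Expected richness at each subsampling depth.

    Exact mode uses the hypergeometric expectation in log-gamma space;
    Monte-Carlo mode averages observed richness over `reps` (>= 100) seeded
    subsamples without replacement.
    """
    _check_nonempty(profile)
    n = profile.n
    counts = np.asarray(profile.positive(), dtype=np.int64)
    for d in depths:
        if d < 0 or d > n:
            raise ValueError(f"depth {d} outside [0, {n}]")

    if mode == "exact":
        out = []
        for d in depths:
            # log C(n - c_i, d) - log C(n, d); C(a, d) = 0 when a < d
            keep = (n - counts) >= d
            a = (n - counts)[keep]
            logp = (
                gammaln(a + 1) - gammaln(d + 1) - gammaln(a - d + 1)
                - (gammaln(n + 1) - gammaln(d + 1) - gammaln(n - d + 1))
            )
            expected = counts.size - float(np.exp(logp).sum())
            out.append((int(d), expected))
        return out

    if mode == "montecarlo":
        if reps < 100:
            raise ValueError("montecarlo mode needs >= 100 repetitions")
        rng = np.random.default_rng(seed)
        pool = np.repeat(np.arange(counts.size), counts)
        out = []
        for d in depths:
            rich = np.empty(reps)
            for r in range(reps):
                sub = rng.choice(pool, size=d, replace=False)
                rich[r] = np.unique(sub).size
            out.append((int(d), float(rich.mean())))
        return out

    raise ValueError(f"unknown rarefaction mode {mode!r}")
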