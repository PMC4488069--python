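"""Species-pool permutation null model for functional-group prevalence.

The question: is the fraction of sites lacking a focal functional group
(e.g. free-floating plants) surprising, or just what a random draw from the
regional species pool would produce?  The null: build a pseudo-group of S
species whose occupancy counts are sampled with replacement from the
observed occupancy frequencies of *all* taxa, place each pseudo-species in
that many sites uniformly at random (independent across species — no
competition, no environmental filtering), and record the proportion of
sites left empty of the pseudo-group.  Repeating B times gives a null
distribution whose mean and percentile interval the observed prevalence of
absence is compared against.

Because species are placed independently, the expectation conditional on the
drawn counts k_1..k_S has the closed form prod_i (1 - k_i / n) — used here
as an exact oracle for the Monte-Carlo machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import OccurrenceMatrix


@dataclass
class NullModelResult:
    """Monte-Carlo null distribution of the empty-site proportion."""

    pool_size: int
    iterations: int
    samples: np.ndarray = field(repr=False)
    mean: float
    ci_level: float
    ci_lo: float
    ci_hi: float
    seed: int | None = None
    observed: float | None = None
    p_value: float | None = None

    def summary(self) -> dict:
        out = {
            "S": self.pool_size, "B": self.iterations, "mean": self.mean,
            "ci_level": self.ci_level, "lo": self.ci_lo, "hi": self.ci_hi,
            "seed": self.seed,
        }
        if self.observed is not None:
            out["observed"] = self.observed
            out["p_value"] = self.p_value
        return out


def observed_empty_proportion(occ: OccurrenceMatrix, group: str) -> float:
    """Fraction of sites containing zero members of ``group``.

    A group with no member taxa is vacuously absent everywhere (returns 1).
    """
    members = occ.group_members(group)
    if not members:
        return 1.0
    return float((occ.presence[members].sum(axis=1) == 0).mean())


def expected_empty_exact(frequencies, n_sites: int) -> float:
    """Exact expected empty proportion for fixed occupancy counts.

    Each species independently occupies k_i uniform sites, so a given site
    escapes species i with probability 1 - k_i/n; independence across species
    gives prod_i (1 - k_i / n_sites).
    """
    k = np.asarray(frequencies, dtype=float)
    if np.any((k < 0) | (k > n_sites)):
        raise ValueError("occupancy counts must lie in [0, n_sites]")
    return float(np.prod(1.0 - k / n_sites))


def empirical_ci(samples, level: float = 0.95) -> tuple[float, float]:
    """Percentile interval: empirical quantiles at (1-level)/2 and 1-(1-level)/2.

    Linear interpolation between order statistics.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples for a percentile interval")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def permutation_null(freq_pool, pool_size: int, n_sites: int,
                     iterations: int = 2000,
                     seed: int | np.random.Generator | None = None,
                     observed: float | None = None,
                     ci_level: float = 0.95) -> NullModelResult:
    """Monte-Carlo null distribution of the empty-site proportion.

    Per iteration: draw ``pool_size`` occupancy counts with replacement from
    ``freq_pool`` (the occupancy frequencies of all taxa — focal group
    included), assign each pseudo-species to that many distinct sites
    uniformly at random, and record the fraction of sites with no
    pseudo-species.  When ``observed`` is given, a two-sided empirical p is
    computed as 2 * min(tail proportions) with add-one correction.
    """
    pool = np.asarray(freq_pool, dtype=int)
    if pool.size == 0:
        raise ValueError("empty frequency pool")
    if np.any((pool < 0) | (pool > n_sites)):
        raise ValueError("pool counts must lie in [0, n_sites]")
    if pool_size < 1 or iterations < 1:
        raise ValueError("pool_size and iterations must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    samples = np.empty(iterations)
    for b in range(iterations):
        ks = rng.choice(pool, size=pool_size, replace=True)
        empty = np.ones(n_sites, dtype=bool)
        for k in ks:
            if k:
                empty[rng.choice(n_sites, size=k, replace=False)] = False
        samples[b] = empty.mean()
    lo, hi = empirical_ci(samples, ci_level)
    p_value = None
    if observed is not None:
        b_le = np.sum(samples <= observed)
        b_ge = np.sum(samples >= observed)
        tail = min((b_le + 1) / (iterations + 1), (b_ge + 1) / (iterations + 1))
        p_value = float(min(1.0, 2.0 * tail))
    return NullModelResult(
        pool_size=pool_size, iterations=iterations, samples=samples,
        mean=float(samples.mean()), ci_level=ci_level, ci_lo=lo, ci_hi=hi,
        seed=seed if isinstance(seed, int) else None,
        observed=observed, p_value=p_value)


def null_model_curve(freq_pool, pool_sizes, n_sites: int,
                     iterations: int = 2000,
                     seed: int | np.random.Generator | None = None,
                     observed: float | None = None,
                     ci_level: float = 0.95) -> list[NullModelResult]:
    """Run the permutation null across several pool sizes (one RNG stream)."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return [permutation_null(freq_pool, s, n_sites, iterations, rng,
                             observed=observed, ci_level=ci_level)
            for s in pool_sizes]
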