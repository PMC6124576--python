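"""Conservation of differential expression: k-way overlap enrichment.

Given directional DE sets from several species (or from in vivo stages and
in vitro culture transitions) over a shared orthologue universe of size N,
the conservation statistic is

    enrichment = observed overlap / expected overlap,

where the expectation under independent uniform sampling of each set from
the universe is ``prod(n_i) / N^(k-1)`` for set sizes n_1..n_k.  For two
sets the null overlap is exactly hypergeometric and the upper-tail p-value
is computed from scipy's hypergeometric distribution.  For three (or more)
sets the null is realised by Monte Carlo: the overlap of k independent
uniform random sets can be drawn as a chain of hypergeometric variables
(the running intersection size against each next set), which makes each
null draw O(k) regardless of N, and the p-value is the add-one-smoothed
exceedance fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import prod
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError

NEG_INF = float("-inf")


@dataclass
class OverlapEnrichment:
    """Observed vs expected k-way overlap of gene sets over a universe."""

    labels: tuple[str, ...]
    universe_size: int
    set_sizes: tuple[int, ...]
    observed: int
    expected: float
    enrichment: float
    log2_enrichment: float
    p_value: float
    null_method: str            # hypergeometric_exact | monte_carlo
    n_draws: int = 0
    seed: int | None = None
    mc_se: float | None = None
    genes: frozenset = field(default_factory=frozenset)

    def as_row(self) -> dict:
        return {
            "comparison": " & ".join(self.labels),
            "N": self.universe_size,
            "sizes": ",".join(map(str, self.set_sizes)),
            "observed": self.observed,
            "expected": self.expected,
            "enrichment": self.enrichment,
            "log2_enrichment": self.log2_enrichment,
            "p": self.p_value,
            "method": self.null_method,
            "B": self.n_draws,
            "seed": self.seed if self.seed is not None else "",
        }


def expected_overlap(set_sizes: Sequence[int], universe_size: int) -> float:
    """Expected k-way overlap of independently sampled sets: prod(n)/N^(k-1)."""
    if universe_size <= 0:
        raise ValidationError("universe size must be positive")
    if any(n < 0 or n > universe_size for n in set_sizes):
        raise ValidationError("set sizes must lie in [0, N]")
    if not set_sizes:
        raise ValidationError("need at least one set size")
    k = len(set_sizes)
    return prod(set_sizes) / universe_size ** (k - 1)


def pairwise_pvalue(k_obs: int, n1: int, n2: int, universe_size: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k_obs) for a 2-set overlap."""
    if not (0 <= n1 <= universe_size and 0 <= n2 <= universe_size):
        raise ValidationError("set sizes must lie in [0, N]")
    if k_obs < 0 or k_obs > min(n1, n2):
        raise ValidationError(
            f"impossible overlap {k_obs} for sizes ({n1}, {n2})")
    if k_obs == 0:
        return 1.0
    return float(stats.hypergeom.sf(k_obs - 1, universe_size, n1, n2))


def sample_kway_overlaps(set_sizes: Sequence[int], universe_size: int,
                         n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Draw null k-way overlap sizes for independent uniform random sets.

    Uses the chain identity: the intersection of a fixed m-subset with an
    independent uniform n-subset is Hypergeometric(N, m, n), applied
    sequentially over the sets.
    """
    m = np.full(n_draws, set_sizes[0], dtype=np.int64)
    for n in set_sizes[1:]:
        # ngood = current intersection, nbad = rest of universe, nsample = n
        m = rng.hypergeometric(m, universe_size - m, n)
    return m


def kway_pvalue_mc(k_obs: int, set_sizes: Sequence[int], universe_size: int,
                   n_draws: int = 10_000,
                   seed: int | np.random.Generator = 0
                   ) -> tuple[float, float]:
    """Monte-Carlo upper-tail p-value for a k-way overlap, with its SE.

    p = (1 + #{null draws with overlap >= k_obs}) / (B + 1); the add-one
    smoothing keeps the estimate valid (never exactly zero).
    """
    if n_draws < 1000:
        raise ConfigurationError("n_draws must be >= 1000 for a stable p")
    if any(n < 0 or n > universe_size for n in set_sizes):
        raise ValidationError("set sizes must lie in [0, N]")
    if k_obs < 0 or (set_sizes and k_obs > min(set_sizes)):
        raise ValidationError("impossible observed overlap")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    draws = sample_kway_overlaps(set_sizes, universe_size, n_draws, rng)
    p = (1 + int((draws >= k_obs).sum())) / (n_draws + 1)
    se = float(np.sqrt(p * (1 - p) / n_draws))
    return p, se


def _enrichment(observed: int, expected: float) -> tuple[float, float]:
    if expected == 0:
        return float("nan"), float("nan")
    enr = observed / expected
    return enr, (np.log2(enr) if enr > 0 else NEG_INF)


def overlap_enrichment(sets: Mapping[str, set], universe: set,
                       n_draws: int = 10_000,
                       seed: int | np.random.Generator = 0
                       ) -> OverlapEnrichment:
    """Full enrichment record for the k-way intersection of labelled sets.

    Two sets get the exact hypergeometric p; three or more get the
    Monte-Carlo p.
    """
    if not universe:
        raise ValidationError("empty universe")
    labels = tuple(sets)
    clipped = {l: sets[l] & universe for l in labels}
    sizes = tuple(len(clipped[l]) for l in labels)
    inter = set.intersection(*clipped.values()) if labels else set()
    n = len(universe)
    e = expected_overlap(sizes, n)
    enr, lenr = _enrichment(len(inter), e)
    if len(labels) == 2:
        p = pairwise_pvalue(len(inter), sizes[0], sizes[1], n)
        return OverlapEnrichment(labels, n, sizes, len(inter), e, enr, lenr,
                                 p, "hypergeometric_exact",
                                 genes=frozenset(inter))
    used_seed = seed if isinstance(seed, int) else None
    p, se = kway_pvalue_mc(len(inter), sizes, n, n_draws, seed)
    return OverlapEnrichment(labels, n, sizes, len(inter), e, enr, lenr, p,
                             "monte_carlo", n_draws, used_seed, se,
                             frozenset(inter))


def conservation_profile(de_sets: Mapping[str, Mapping[str, dict[str, set]]],
                         universe: set, n_draws: int = 10_000, seed: int = 0,
                         combine_directions: bool = False
                         ) -> tuple[pd.DataFrame, dict]:
    """Pairwise and three-way conservation enrichment per transition.

    Parameters
    ----------
    de_sets:
        ``de_sets[species][transition][direction]`` -> set of group ids
        (direction in {"up", "down"}).
    combine_directions:
        When True, also analyse the union of up and down sets per species
        (direction label "any").

    Returns a long-format DataFrame (one row per comparison) and a dict
    mapping ``(transition, direction)`` to the three-way intersection gene
    list (the central Venn territory).
    """
    species = list(de_sets)
    if len(species) < 2:
        raise ValidationError("need at least two species")
    transitions = list(next(iter(de_sets.values())))
    rng = np.random.default_rng(seed)
    rows, central = [], {}
    for trans in transitions:
        directions = ["up", "down"] + (["any"] if combine_directions else [])
        for direction in directions:
            def get(sp):
                d = de_sets[sp][trans]
                if direction == "any":
                    return d["up"] | d["down"]
                return d[direction]
            labelled = {f"{sp}:{trans}:{direction}": get(sp) for sp in species}
            keys = list(labelled)
            for i in range(len(keys)):
                for j in range(i + 1, len(keys)):
                    enr = overlap_enrichment(
                        {k: labelled[k] for k in (keys[i], keys[j])}, universe)
                    r = enr.as_row()
                    r.update(transition=trans, direction=direction, k=2)
                    rows.append(r)
            enr3 = overlap_enrichment(labelled, universe, n_draws, rng)
            enr3.seed = seed
            r = enr3.as_row()
            r.update(transition=trans, direction=direction, k=len(keys),
                     seed=seed)
            rows.append(r)
            central[(trans, direction)] = sorted(enr3.genes)
    return pd.DataFrame(rows), central


def conserved_sets(de_sets: Mapping[str, Mapping[str, dict[str, set]]],
                   min_species: int | None = None
                   ) -> dict[tuple[str, str], set[str]]:
    """Genes DE in the same direction in >= min_species species.

    Default ``min_species`` is the number of species (full conservation).
    Returns ``{(transition, direction): set}``.
    """
    species = list(de_sets)
    if min_species is None:
        min_species = len(species)
    if not (2 <= min_species <= len(species)):
        raise ConfigurationError("min_species must be in [2, n_species]")
    transitions = list(next(iter(de_sets.values())))
    out: dict[tuple[str, str], set[str]] = {}
    for trans in transitions:
        for direction in ("up", "down"):
            counts: dict[str, int] = {}
            for sp in species:
                for g in de_sets[sp][trans][direction]:
                    counts[g] = counts.get(g, 0) + 1
            out[(trans, direction)] = {g for g, c in counts.items()
                                       if c >= min_species}
    return out


def invivo_invitro_overlap(in_vivo_sets: Mapping[tuple[str, str], set],
                           in_vitro_sets: Mapping[tuple[str, str], set],
                           universe: set) -> pd.DataFrame:
    """Grid of log2 enrichments of in vivo vs in vitro directional DE sets.

    Keys of both mappings are ``(transition, direction)``.  Directions are
    paired like-with-like (up x up, down x down), the separate-direction
    reading of the conservation heatmaps.  Cells with zero observed overlap
    but positive expectation carry a ``-inf`` log2 enrichment and p = 1.
    """
    if not universe:
        raise ValidationError("empty universe")
    n = len(universe)
    rows = []
    for (vt, vd), vivo in in_vivo_sets.items():
        for (ct, cd), vitro in in_vitro_sets.items():
            if vd != cd:
                continue
            a = vivo & universe
            b = vitro & universe
            obs = len(a & b)
            e = expected_overlap((len(a), len(b)), n)
            enr, lenr = _enrichment(obs, e)
            p = pairwise_pvalue(obs, len(a), len(b), n) if e > 0 else 1.0
            rows.append({
                "invivo_transition": vt, "invitro_transition": ct,
                "direction": vd, "N": n, "n_invivo": len(a),
                "n_invitro": len(b), "observed": obs, "expected": e,
                "enrichment": enr, "log2_enrichment": lenr, "p": p,
            })
    return pd.DataFrame(rows)
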