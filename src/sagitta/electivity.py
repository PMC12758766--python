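"""Odds-ratio (Kimmerer-Slaughter) diet electivity with Monte-Carlo intervals.

For each prey taxon *i* the index compares its proportion in predator guts,
``g_i = G_i / N_G``, with its proportion in the ambient habitat,
``a_i = A_i / N_A``, through the odds ratio

    O_i = [g_i / (1 - g_i)] / [a_i / (1 - a_i)],      X_i = O_i / (1 + O_i).

X lies in [0, 1]; 0.5 means the taxon is eaten in proportion to its
availability, values above 0.5 indicate positive selection and below 0.5
avoidance.  Uncertainty is propagated by Monte Carlo: gut and habitat
proportions are drawn from Beta posteriors of the observed counts (uniform
Bayes-Laplace prior, Beta(count+1, total-count+1), well-defined at zero
counts), X is recomputed per draw, and the 2.5/97.5 percentiles form a 95%
interval.  Selection is called significant only when that interval excludes
0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CompositionTable",
    "ElectivityResult",
    "odds",
    "electivity_index",
    "beta_mc_ci",
    "classify",
    "electivity_table",
    "results_to_frame",
]


@dataclass(frozen=True)
class CompositionTable:
    """Integer prey-taxon counts for one compartment (guts or habitat)."""

    taxa: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if len(self.taxa) != counts.size:
            raise ValueError("taxa and counts length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        if counts.size == 0:
            raise ValueError("composition table is empty")
        if np.any(counts < 0) or np.any(counts != np.floor(counts)):
            raise ValueError("counts must be non-negative integers")
        if counts.sum() < 1:
            raise ValueError("composition table has zero total count")
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(self, "counts", counts.astype(int))

    @classmethod
    def from_counts(cls, table: Mapping[str, int]) -> "CompositionTable":
        return cls(tuple(table.keys()), np.array(list(table.values())))

    @classmethod
    def from_percentages(
        cls, table: Mapping[str, float], total: int, tol: float = 0.05
    ) -> "CompositionTable":
        """Reconstruct integer counts from printed percentages and a known total.

        Each percentage is mapped to ``round(p/100 * total)`` and accepted only
        if the implied exact percentage agrees within ``tol`` percentage points
        (printed tables are rounded to one decimal).
        """
        if total < 1:
            raise ValueError("total must be >= 1")
        counts = {}
        for taxon, pct in table.items():
            if pct < 0 or pct > 100:
                raise ValueError(f"{taxon}: percentage {pct} outside [0, 100]")
            c = round(pct / 100.0 * total)
            implied = 100.0 * c / total
            if abs(implied - pct) > tol + 1e-9:
                raise ValueError(
                    f"{taxon}: {pct}% of {total} is not within {tol} points of an "
                    f"integer count (nearest {c} -> {implied:.3f}%)"
                )
            counts[taxon] = c
        return cls.from_counts(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.total

    def count(self, taxon: str) -> int:
        return int(self.counts[self.taxa.index(taxon)])


@dataclass(frozen=True)
class ElectivityResult:
    taxon: str
    gut_pct: float
    habitat_pct: float
    index: float | None
    ci_low: float | None
    ci_high: float | None
    classification: str  # positive | negative | none | undefined
    n_sims: int | None = None
    seed: int | None = None


def odds(p: float) -> float:
    """Odds p / (1 - p) of a proportion; p = 1 maps to +inf."""
    if p < 0 or p > 1:
        raise ValueError(f"proportion must lie in [0, 1], got {p}")
    if p == 1.0:
        return math.inf
    return p / (1.0 - p)


def electivity_index(g: float, a: float) -> float:
    """Electivity X = O/(1+O), O = odds(g)/odds(a), for gut proportion g and
    habitat proportion a.

    X = 0.5 iff g = a; strictly increasing in g and decreasing in a.
    Requires a > 0 (a taxon absent from the habitat sample has zero
    availability odds and its electivity is undefined).
    """
    if not 0 <= g <= 1:
        raise ValueError(f"gut proportion must lie in [0, 1], got {g}")
    if a <= 0 or a > 1:
        raise ValueError(f"habitat proportion must lie in (0, 1], got {a}")
    if g == 1.0:
        return 1.0
    if a == 1.0:
        return 0.0 if g < 1 else 0.5
    # X = g(1-a) / [g(1-a) + a(1-g)] — algebraically O/(1+O), stable at g=0
    num = g * (1.0 - a)
    return num / (num + a * (1.0 - g))


def beta_mc_ci(
    gut_count: int,
    gut_total: int,
    habitat_count: int,
    habitat_total: int,
    n_sims: int = 10_000,
    seed=None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Monte-Carlo confidence interval for the electivity index.

    Draws ``g* ~ Beta(G+1, N_G-G+1)`` and ``a* ~ Beta(A+1, N_A-A+1)``
    (posteriors of the two proportions under uniform priors), forms the
    index for each draw and returns the alpha/2 and 1-alpha/2 percentiles.
    Deterministic for a given ``seed`` (an int or a ``numpy.random.Generator``).
    """
    for name, c, t in (
        ("gut", gut_count, gut_total),
        ("habitat", habitat_count, habitat_total),
    ):
        if t < 1:
            raise ValueError(f"{name} total must be >= 1")
        if not 0 <= c <= t:
            raise ValueError(f"{name} count {c} outside [0, {t}]")
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = rng.beta(gut_count + 1, gut_total - gut_count + 1, size=n_sims)
    a = rng.beta(habitat_count + 1, habitat_total - habitat_count + 1, size=n_sims)
    num = g * (1.0 - a)
    x = num / (num + a * (1.0 - g))
    lo, hi = np.percentile(x, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def classify(index: float, ci_low: float, ci_high: float) -> str:
    """Selection call from the interval's position relative to 0.5."""
    if not (0 <= ci_low <= ci_high <= 1):
        raise ValueError(f"invalid interval ({ci_low}, {ci_high})")
    if ci_low > 0.5:
        return "positive"
    if ci_high < 0.5:
        return "negative"
    return "none"


def electivity_table(
    gut: CompositionTable,
    habitat: CompositionTable,
    n_sims: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> list[ElectivityResult]:
    """Per-taxon electivity over the union of gut and habitat taxa.

    Taxa present in both compartments (G_i > 0 and A_i > 0) get an index,
    Monte-Carlo interval and selection call; taxa found only in the habitat
    sample or only in guts get no index (classification ``"undefined"``),
    mirroring the blank cells of field diet tables.
    """
    taxa = list(gut.taxa) + [t for t in habitat.taxa if t not in gut.taxa]
    rng = np.random.default_rng(seed)
    results = []
    for taxon in taxa:
        g_count = gut.count(taxon) if taxon in gut.taxa else 0
        a_count = habitat.count(taxon) if taxon in habitat.taxa else 0
        gut_pct = 100.0 * g_count / gut.total
        hab_pct = 100.0 * a_count / habitat.total
        if g_count > 0 and a_count > 0:
            x = electivity_index(g_count / gut.total, a_count / habitat.total)
            lo, hi = beta_mc_ci(
                g_count, gut.total, a_count, habitat.total, n_sims=n_sims, seed=rng, alpha=alpha
            )
            results.append(
                ElectivityResult(
                    taxon, gut_pct, hab_pct, x, lo, hi, classify(x, lo, hi), n_sims, seed
                )
            )
        else:
            results.append(
                ElectivityResult(taxon, gut_pct, hab_pct, None, None, None, "undefined", None, seed)
            )
    return results


def results_to_frame(results: Sequence[ElectivityResult]):
    """Tidy DataFrame of electivity results (taxon, percentages, index, CI,
    classification)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "taxon": [r.taxon for r in results],
            "gut_pct": [r.gut_pct for r in results],
            "habitat_pct": [r.habitat_pct for r in results],
            "index": [r.index for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "classification": [r.classification for r in results],
        }
    )
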