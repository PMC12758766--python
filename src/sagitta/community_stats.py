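"""Permutation statistics: crossed two-factor PERMANOVA, BIOENV, size regression.

PERMANOVA partitions the total sum of squares implicit in a distance matrix
(McArdle-Anderson decomposition: Gower-center A = -d^2/2, then SS for a
projection P is tr(P G P)) across the two crossed factors and their
interaction, using sequential (Type I) sums of squares from nested design
matrices.  Pseudo-F per term is MS_term / MS_residual and its p-value comes
from unrestricted permutation of the sample labels.  For a univariate
response with Euclidean distances the decomposition coincides exactly with
classical two-way ANOVA.

BIOENV searches all non-empty subsets of (z-scored) environmental variables
for the one whose Euclidean inter-sample distances best rank-correlate
(Spearman) with the response distances.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress, spearmanr
from skbio import DistanceMatrix

__all__ = [
    "DistanceMatrix",
    "PermanovaTable",
    "BioenvResult",
    "SizeRegressionResult",
    "euclidean_distance_matrix",
    "permanova_two_way",
    "bioenv",
    "size_regression",
]

logger = logging.getLogger("sagitta")


def euclidean_distance_matrix(values, ids=None) -> DistanceMatrix:
    """Pairwise Euclidean distances between samples.

    ``values`` is (n_samples,) for a univariate response or
    (n_samples, n_variables); returns a validated ``skbio.DistanceMatrix``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a (n_samples,) or (n_samples, n_vars) array with n >= 2")
    if not np.all(np.isfinite(arr)):
        raise ValueError("response values must be finite")
    return DistanceMatrix(squareform(pdist(arr)), ids=ids)


@dataclass(frozen=True)
class PermanovaTable:
    """Sequential-SS permutation ANOVA table for a crossed two-factor design."""

    terms: tuple  # ordered term names (factor_a, factor_b, interaction)
    df: dict
    ss: dict
    ms: dict
    pseudo_f: dict
    p_perm: dict
    n_permutations: int
    n_unique_permutations: int
    seed: int | None = field(default=None, compare=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            rows.append(
                {
                    "source": t,
                    "df": self.df[t],
                    "ss": self.ss[t],
                    "ms": self.ms[t],
                    "pseudo_f": self.pseudo_f[t],
                    "p_perm": self.p_perm[t],
                    "perms": self.n_unique_permutations,
                }
            )
        rows.append(
            {
                "source": "residual",
                "df": self.df["residual"],
                "ss": self.ss["residual"],
                "ms": self.ms["residual"],
                "pseudo_f": np.nan,
                "p_perm": np.nan,
                "perms": np.nan,
            }
        )
        rows.append(
            {
                "source": "total",
                "df": self.df["total"],
                "ss": self.ss["total"],
                "ms": np.nan,
                "pseudo_f": np.nan,
                "p_perm": np.nan,
                "perms": np.nan,
            }
        )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        return self.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4f}")


def _as_square(d) -> np.ndarray:
    if isinstance(d, DistanceMatrix):
        return d.data
    arr = np.asarray(d, dtype=float)
    # validate through skbio (symmetry, hollowness)
    return DistanceMatrix(arr).data


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def _dummies(labels) -> np.ndarray:
    return pd.get_dummies(pd.Categorical(labels), drop_first=True).to_numpy(dtype=float)


def permanova_two_way(
    distances,
    factor_a,
    factor_b,
    n_perm: int = 9999,
    seed: int | None = None,
    factor_names: tuple[str, str] = ("factor_a", "factor_b"),
) -> PermanovaTable:
    """Two-factor crossed PERMANOVA on a distance matrix.

    Parameters
    ----------
    distances : skbio.DistanceMatrix or square array
    factor_a, factor_b : sequence of labels
        Crossed grouping factors, each with >= 2 levels; every combination
        of levels must be observed at least once.
    n_perm : int
        Number of random unrestricted permutations of the sample labels.
    seed : int, optional
        Seed for the permutation stream; identical seeds give identical
        tables.

    Returns
    -------
    PermanovaTable
        Sequential SS, pseudo-F and permutation p-value (with the (B+1)
        add-one convention, so p is in [1/(B+1), 1]) for the two main
        effects and the interaction.
    """
    d = _as_square(distances)
    n = d.shape[0]
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if a.size != n or b.size != n:
        raise ValueError("factor label lengths must match the distance matrix")
    for name, f in zip(factor_names, (a, b)):
        if len(set(f.tolist())) < 2:
            raise ValueError(f"factor {name!r} needs >= 2 levels")
    cells = pd.crosstab(pd.Series(a, name=factor_names[0]), pd.Series(b, name=factor_names[1]))
    if (cells == 0).any().any():
        i, j = np.argwhere(cells.to_numpy() == 0)[0]
        raise ValueError(
            f"confounded design: empty cell ({factor_names[0]}={cells.index[i]!r}, "
            f"{factor_names[1]}={cells.columns[j]!r})"
        )
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    xa, xb = _dummies(a), _dummies(b)
    xab = np.concatenate(
        [xa[:, [i]] * xb[:, [j]] for i in range(xa.shape[1]) for j in range(xb.shape[1])], axis=1
    )
    ones = np.ones((n, 1))
    designs = [
        ones,
        np.hstack([ones, xa]),
        np.hstack([ones, xa, xb]),
        np.hstack([ones, xa, xb, xab]),
    ]
    hats = [_hat(x) for x in designs]
    ranks = [np.linalg.matrix_rank(x) for x in designs]

    term_names = (factor_names[0], factor_names[1], "interaction")
    projections = {
        term_names[0]: hats[1] - hats[0],
        term_names[1]: hats[2] - hats[1],
        "interaction": hats[3] - hats[2],
        "residual": np.eye(n) - hats[3],
    }
    df = {
        term_names[0]: ranks[1] - ranks[0],
        term_names[1]: ranks[2] - ranks[1],
        "interaction": ranks[3] - ranks[2],
        "residual": n - ranks[3],
        "total": n - 1,
    }
    if df["residual"] < 1:
        raise ValueError("no residual degrees of freedom (need replication within cells)")

    # Gower-centered inner-product matrix: SS under projection P is tr(P G P) = tr(G P).
    g = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ g @ j

    def term_stats(gmat):
        ss = {t: float(np.sum(gmat * p)) for t, p in projections.items()}
        ms_res = ss["residual"] / df["residual"]
        f = {t: (ss[t] / df[t]) / ms_res for t in term_names}
        return ss, f

    ss_obs, f_obs = term_stats(g)
    rng = np.random.default_rng(seed)
    exceed = {t: 0 for t in term_names}
    seen = set()
    for _ in range(n_perm):
        perm = rng.permutation(n)
        seen.add(perm.tobytes())
        gp = g[np.ix_(perm, perm)]
        _, f_p = term_stats(gp)
        for t in term_names:
            if f_p[t] >= f_obs[t] - 1e-12:
                exceed[t] += 1

    p_perm = {t: (exceed[t] + 1) / (n_perm + 1) for t in term_names}
    ss = dict(ss_obs)
    ss["total"] = float(np.trace(g))
    ms = {t: ss[t] / df[t] for t in (*term_names, "residual")}
    return PermanovaTable(
        terms=term_names,
        df=df,
        ss=ss,
        ms=ms,
        pseudo_f=f_obs,
        p_perm=p_perm,
        n_permutations=n_perm,
        n_unique_permutations=len(seen),
        seed=seed,
    )


@dataclass(frozen=True)
class BioenvResult:
    """Best environmental-variable subset and its rank correlation."""

    best_vars: tuple
    rho: float
    trace: pd.DataFrame  # every searched subset with its rho
    p_perm: float | None = None


def bioenv(
    env: pd.DataFrame,
    response_distances,
    exclude=(),
    max_subset_size: int | None = None,
    n_perm: int = 0,
    seed: int | None = None,
) -> BioenvResult:
    """BIOENV/BEST: which subset of environmental variables best explains the
    response distance pattern.

    Each variable is z-scored; for every non-empty subset (up to
    ``max_subset_size``) Euclidean inter-sample distances are computed and
    Spearman-rank-correlated with the response distances; the subset with
    maximal rho wins.  Variables named in ``exclude`` are never searched
    (use for predictors collinear with the response by construction, e.g.
    prey density when the response already contains an encounter rate);
    constant variables are dropped with a warning.

    ``n_perm > 0`` adds a global permutation p-value for the best rho by
    shuffling sample identities of the environmental table and re-running
    the full search (the BEST test); expensive and off by default.
    """
    d = _as_square(response_distances)
    n = d.shape[0]
    if len(env) != n:
        raise ValueError("environmental table length must match the distance matrix")
    env = env.drop(columns=list(exclude), errors="ignore")
    keep = []
    for col in env.columns:
        v = env[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"environmental variable {col!r} contains non-finite values")
        if np.ptp(v) == 0:
            logger.warning("dropping constant environmental variable %r", col)
            continue
        keep.append(col)
    if not keep:
        raise ValueError("no usable environmental variables after exclusion")
    z = {c: (env[c] - env[c].mean()) / env[c].std(ddof=1) for c in keep}
    z = pd.DataFrame(z).to_numpy(dtype=float)

    resp = squareform(d, checks=False)
    k_max = max_subset_size or len(keep)

    def search(zmat):
        rows = []
        for k in range(1, k_max + 1):
            for combo in itertools.combinations(range(len(keep)), k):
                env_dist = pdist(zmat[:, combo])
                rho = spearmanr(resp, env_dist).statistic
                rows.append((combo, k, rho))
        return rows

    rows = search(z)
    best_combo, _, best_rho = max(rows, key=lambda r: r[2])
    trace = pd.DataFrame(
        {
            "subset": [tuple(keep[i] for i in combo) for combo, _, _ in rows],
            "size": [k for _, k, _ in rows],
            "rho": [r for _, _, r in rows],
        }
    ).sort_values("rho", ascending=False, ignore_index=True)

    p_perm = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            zp = z[rng.permutation(n)]
            rho_p = max(r for _, _, r in search(zp))
            if rho_p >= best_rho - 1e-12:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)

    return BioenvResult(
        best_vars=tuple(keep[i] for i in best_combo), rho=float(best_rho), trace=trace, p_perm=p_perm
    )


@dataclass(frozen=True)
class SizeRegressionResult:
    slope: float
    intercept: float
    t_statistic: float
    p_value: float
    r_value: float
    n: int


def size_regression(predator_lengths, prey_lengths) -> SizeRegressionResult:
    """OLS of prey length on predator length with a two-sided t-test on the
    slope (H0: slope = 0).

    Lengths in mm; needs >= 3 pairs and non-constant predator lengths.
    """
    x = np.asarray(predator_lengths, dtype=float)
    y = np.asarray(prey_lengths, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired predator/prey lengths")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("lengths must be finite")
    if np.ptp(x) == 0:
        raise ValueError("predator lengths are constant; slope is undefined")
    res = linregress(x, y)
    t_stat = np.inf if res.stderr == 0 else res.slope / res.stderr
    return SizeRegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        t_statistic=float(t_stat),
        p_value=float(res.pvalue),
        r_value=float(res.rvalue),
        n=int(x.size),
    )
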