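"""Community statistics implemented from first principles.

Shannon diversity, Jaccard dissimilarity, classical principal-coordinates
analysis, one-way PERMANOVA with permutation p-values, one-way ANOVA and
the Wilcoxon rank-sum test.  Only distribution functions (normal / F CDFs)
come from scipy; the test statistics and permutation machinery are local so
they can be checked against independent oracles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _spstats

from .profiles import PresenceMatrix, ValidationError

__all__ = [
    "DissimilarityMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "TestResult",
    "shannon_index",
    "jaccard_distance",
    "jaccard_matrix",
    "pcoa",
    "permanova",
    "one_way_anova",
    "wilcoxon_rank_sum",
]

_SYMMETRY_TOL = 1e-12


class DissimilarityMatrix:
    """Square symmetric distance matrix with a zero diagonal."""

    def __init__(self, ids: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        n = len(ids)
        if len(set(ids)) != n:
            raise ValidationError("duplicate sample ids in dissimilarity matrix")
        if values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {values.shape} does not match {n} ids"
            )
        if n and np.abs(values - values.T).max() > _SYMMETRY_TOL:
            raise ValidationError("dissimilarity matrix is not symmetric")
        if n and np.abs(np.diag(values)).max() > _SYMMETRY_TOL:
            raise ValidationError("dissimilarity matrix diagonal is not zero")
        if np.isnan(values).any():
            raise ValidationError("dissimilarity matrix contains NaN")
        self.ids = list(ids)
        self.values = values
        self._index = {s: i for i, s in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self._index[a], self._index[b]])

    def subset(self, ids: Sequence[str]) -> "DissimilarityMatrix":
        idx = [self._index[s] for s in ids]
        return DissimilarityMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def between(self, ids_a: Sequence[str], ids_b: Sequence[str]) -> np.ndarray:
        ia = [self._index[s] for s in ids_a]
        ib = [self._index[s] for s in ids_b]
        return self.values[np.ix_(ia, ib)]

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries, row-major (scipy ``squareform`` order)."""
        iu = np.triu_indices(len(self), k=1)
        return self.values[iu]

    def write(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="sample_id"
        )

    @classmethod
    def read(cls, path: str | Path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValidationError(f"{path}: row and column ids differ")
        return cls(list(df.index), df.to_numpy(dtype=float))


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding of a dissimilarity matrix."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # per retained axis, non-increasing
    proportion_explained: np.ndarray

    def coordinates_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "pseudo_f": self.pseudo_f,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str  # exact | normal_approx | permutation
    alternative: str  # two_sided | less | greater

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
            "alternative": self.alternative,
        }


# ---------------------------------------------------------------------------
# alpha diversity


def shannon_index(counts: Sequence[float], base: str = "e") -> float:
    """Shannon entropy H = -sum p_i log p_i over positive entries.

    ``base`` selects natural log (``"e"``, default) or ``"2"``.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValidationError("counts must be a 1-D vector")
    if (c < 0).any():
        raise ValidationError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValidationError("all-zero count vector has no diversity")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base == "2":
        h /= math.log(2)
    elif base != "e":
        raise ValidationError("base must be 'e' or '2'")
    return h


# ---------------------------------------------------------------------------
# Jaccard


def jaccard_distance(a: Sequence[int], b: Sequence[int]) -> float:
    """1 - |A n B| / |A u B| over the index sets where each vector is 1.

    Two all-zero profiles are defined as identical (distance 0, warned).
    """
    av = np.asarray(a) != 0
    bv = np.asarray(b) != 0
    if av.shape != bv.shape:
        raise ValidationError(
            f"profile length mismatch: {av.shape[0]} vs {bv.shape[0]}"
        )
    union = int((av | bv).sum())
    if union == 0:
        warnings.warn("both profiles empty; Jaccard distance defined as 0", stacklevel=2)
        return 0.0
    inter = int((av & bv).sum())
    return 1.0 - inter / union


def jaccard_matrix(presence: PresenceMatrix) -> DissimilarityMatrix:
    """Pairwise Jaccard distances over the sample columns of a presence matrix."""
    n = presence.shape[1]
    if n < 2:
        raise ValidationError("need at least two samples for a distance matrix")
    x = presence.values.astype(bool)
    inter = (x.T.astype(np.int64)) @ x.astype(np.int64)
    sizes = x.sum(axis=0).astype(np.int64)
    union = sizes[:, None] + sizes[None, :] - inter
    if (union == 0).any():
        warnings.warn(
            "empty-profile sample pair(s); Jaccard distance defined as 0", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float noise
    return DissimilarityMatrix(presence.samples, d)


# ---------------------------------------------------------------------------
# ordination


def pcoa(dist: DissimilarityMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical (metric) scaling of a dissimilarity matrix.

    Double-centres -0.5 * D^2, eigendecomposes, and scales eigenvectors by
    the square root of their (positive) eigenvalues.  Negative eigenvalues
    are reported but contribute zero coordinates; no correction is applied.
    """
    n = len(dist)
    if n < 2:
        raise ValidationError("need at least two samples for ordination")
    if n_axes is None:
        n_axes = n - 1
    if not 1 <= n_axes <= n - 1:
        raise ValidationError(f"n_axes must be in [1, {n - 1}]")
    d2 = dist.values**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ d2 @ centering
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    pos = np.clip(eigval, 0.0, None)
    coords = eigvec * np.sqrt(pos)[None, :]
    pos_sum = pos.sum()
    prop = pos / pos_sum if pos_sum > 0 else np.zeros(n)
    return OrdinationResult(
        sample_ids=list(dist.ids),
        coordinates=coords[:, :n_axes],
        eigenvalues=eigval[:n_axes],
        proportion_explained=prop[:n_axes],
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def _permanova_ss(d2: np.ndarray, group_idx: np.ndarray, n_groups: int) -> float:
    """Within-group sum of squared distances / group size, summed over groups."""
    ss = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(group_idx == g)
        if len(idx) > 1:
            ss += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ss


def permanova(
    dist: DissimilarityMatrix,
    grouping: Mapping[str, str] | Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA: pseudo-F from distance sums of squares, permutation p.

    p = (1 + #{permuted F >= observed F}) / (1 + n_permutations), with group
    labels permuted by a seeded generator.
    """
    if isinstance(grouping, Mapping):
        labels = [grouping[s] for s in dist.ids]
    else:
        labels = list(grouping)
        if len(labels) != len(dist):
            raise ValidationError("grouping length does not match matrix")
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    uniq, inv = np.unique(np.asarray(labels, dtype=object), return_inverse=True)
    n = len(dist)
    a = len(uniq)
    if a < 2:
        raise ValidationError("PERMANOVA needs at least two groups")
    if np.bincount(inv).max() == n:
        raise ValidationError("one group contains every sample")
    if n <= a:
        raise ValidationError("no residual degrees of freedom (n <= #groups)")
    d2 = dist.values**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = _permanova_ss(d2, inv, a)
    ss_between = ss_total - ss_within
    df_between = a - 1
    df_within = n - a
    if ss_within <= 0:
        f_obs = math.inf if ss_between > 0 else 0.0
    else:
        f_obs = (ss_between / df_between) / (ss_within / df_within)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(inv)
        ssw = _permanova_ss(d2, perm, a)
        ssb = ss_total - ssw
        if ssw <= 0:
            f_perm = math.inf if ssb > 0 else 0.0
        else:
            f_perm = (ssb / df_between) / (ssw / df_within)
        if f_perm >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ANOVA


def one_way_anova(values: Sequence[float], groups: Sequence) -> TestResult:
    """Classical one-way fixed-effects ANOVA (F statistic, F-distribution p)."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups, dtype=object)
    if y.shape != g.shape:
        raise ValidationError("values and groups must have the same length")
    uniq, inv = np.unique(g, return_inverse=True)
    a = len(uniq)
    n = len(y)
    if a < 2:
        raise ValidationError("ANOVA needs at least two groups")
    if n - a < 1:
        raise ValidationError("no residual degrees of freedom")
    grand = y.mean()
    ss_between = 0.0
    ss_within = 0.0
    for k in range(a):
        yk = y[inv == k]
        ss_between += len(yk) * (yk.mean() - grand) ** 2
        ss_within += ((yk - yk.mean()) ** 2).sum()
    if ss_within <= 0:
        raise ValidationError("zero within-group variance; F undefined")
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    p = float(_spstats.f.sf(f, a - 1, n - a))
    return TestResult(statistic=float(f), p_value=p, method="exact", alternative="greater")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _rank_sum_distribution(n_total: int, k: int) -> np.ndarray:
    """Counts of k-subsets of ranks {1..n_total} by rank sum (index = sum)."""
    max_sum = n_total * (n_total + 1) // 2
    table = np.zeros((k + 1, max_sum + 1))
    table[0, 0] = 1.0
    for v in range(1, n_total + 1):
        for kk in range(min(k, v), 0, -1):
            table[kk, v:] += table[kk - 1, : max_sum + 1 - v]
    return table[k]


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
    mode: str = "auto",
) -> TestResult:
    """Two-sample Wilcoxon rank-sum test on the rank sum of ``x``.

    ``mode="exact"`` enumerates the null rank-sum distribution (requires no
    ties); ``"auto"`` uses the exact path when min(n_x, n_y) <= 8 and the
    pooled data are tie-free, otherwise a tie-corrected normal approximation
    with continuity correction.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size == 0 or yv.size == 0:
        raise ValidationError("both samples must be non-empty")
    if alternative not in ("two_sided", "less", "greater"):
        raise ValidationError("alternative must be two_sided, less or greater")
    if mode not in ("auto", "exact", "normal_approx"):
        raise ValidationError("mode must be auto, exact or normal_approx")
    nx, ny = len(xv), len(yv)
    pooled = np.concatenate([xv, yv])
    n_total = nx + ny
    has_ties = len(np.unique(pooled)) < n_total
    ranks = _spstats.rankdata(pooled)
    w = float(ranks[:nx].sum())

    use_exact = mode == "exact" or (mode == "auto" and min(nx, ny) <= 8 and not has_ties)
    if mode == "exact" and has_ties:
        raise ValidationError("exact mode requires tie-free data")

    if use_exact:
        counts = _rank_sum_distribution(n_total, nx)
        total = counts.sum()
        wi = int(round(w))
        p_ge = counts[wi:].sum() / total
        p_le = counts[: wi + 1].sum() / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return TestResult(statistic=w, p_value=float(p), method="exact", alternative=alternative)

    mu = nx * (n_total + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n_total * (n_total - 1))
    var = nx * ny / 12.0 * ((n_total + 1) - tie_term)
    if var <= 0:
        # all observations tied: no evidence either way
        return TestResult(statistic=w, p_value=1.0, method="normal_approx", alternative=alternative)
    sd = math.sqrt(var)
    if alternative == "greater":
        z = (w - mu - 0.5) / sd
        p = float(_spstats.norm.sf(z))
    elif alternative == "less":
        z = (w - mu + 0.5) / sd
        p = float(_spstats.norm.cdf(z))
    else:
        z = (abs(w - mu) - 0.5) / sd
        p = float(min(1.0, 2.0 * _spstats.norm.sf(z)))
    return TestResult(statistic=w, p_value=p, method="normal_approx", alternative=alternative)
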