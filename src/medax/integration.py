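"""Cross-omics correlation networks and Mantel tests.

Links microbial taxa to metabolites (or metabolite-module eigenvalues) the
way microbiome-metabolome studies report them: all cross-table Pearson or
Spearman correlations with Benjamini-Hochberg control over the full pair
family, filtered to strong edges (|r| > 0.7, p < 0.05 by default), plus a
permutation Mantel test of agreement between two sample-distance
structures.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class OmicsTable:
    """A samples × features abundance (or eigenvalue) table."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    feature_kind: str = "taxon"  # taxon | metabolite | module_eigenvalue

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("duplicate feature_ids")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, feature_kind: str = "taxon") -> "OmicsTable":
        return cls(
            sample_ids=[str(s) for s in df.index],
            feature_ids=[str(f) for f in df.columns],
            values=df.to_numpy(dtype=float),
            feature_kind=feature_kind,
        )


@dataclass
class CorrelationResult:
    """All cross-table pairs with BH q-values, plus the filtered edge list."""

    table: pd.DataFrame          # FEATURE_A, FEATURE_B, R, P, Q_BH, RETAINED
    method: str
    r_min: float
    alpha: float

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["RETAINED"]].reset_index(drop=True)


def correlate(
    a: OmicsTable,
    b: OmicsTable,
    method: str = "spearman",
    r_min: float = 0.7,
    alpha: float = 0.05,
) -> CorrelationResult:
    """All pairwise feature correlations between two tables, BH-corrected.

    The BH adjustment runs over the full cross-table family before the
    |r| > ``r_min`` and p < ``alpha`` edge filter is applied (the filter
    flags rows; nothing is discarded from the output table).
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    if a.sample_ids != b.sample_ids:
        only_a = set(a.sample_ids) - set(b.sample_ids)
        only_b = set(b.sample_ids) - set(a.sample_ids)
        raise ValidationError(
            "sample_ids differ between tables "
            f"(only in a: {sorted(only_a)}; only in b: {sorted(only_b)}; "
            "or ordering differs)"
        )
    va = a.values if method == "pearson" else stats.rankdata(a.values, axis=0)
    vb = b.values if method == "pearson" else stats.rankdata(b.values, axis=0)
    n = va.shape[0]
    za = (va - va.mean(axis=0)) / va.std(axis=0, ddof=0)
    zb = (vb - vb.mean(axis=0)) / vb.std(axis=0, ddof=0)
    r = np.clip((za.T @ zb) / n, -1.0, 1.0)
    # two-sided p from the t transform, matching scipy's pearsonr/spearmanr
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)

    rows = []
    for i, fa in enumerate(a.feature_ids):
        for j, fb in enumerate(b.feature_ids):
            rows.append((fa, fb, float(r[i, j]), float(p[i, j])))
    df = pd.DataFrame(rows, columns=["FEATURE_A", "FEATURE_B", "R", "P"])
    df["Q_BH"] = multipletests(df["P"].to_numpy(), method="fdr_bh")[1]
    df["RETAINED"] = (df["R"].abs() > r_min) & (df["P"] < alpha)
    return CorrelationResult(table=df, method=method, r_min=r_min, alpha=alpha)


@dataclass(frozen=True)
class MantelResult:
    """Matrix correlation with its one-sided permutation p-value."""

    r: float
    pvalue: float
    n_perm: int
    seed: int | None
    method: str
    exact: bool = False


def _check_distance_matrix(d: np.ndarray, name: str) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError(f"{name}: distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError(f"{name}: distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValidationError(f"{name}: distance matrix diagonal must be zero")
    return d


def _tri_correlation(da: np.ndarray, db: np.ndarray, method: str) -> float:
    iu = np.triu_indices_from(da, k=1)
    x, y = da[iu], db[iu]
    if method == "spearman":
        x, y = stats.rankdata(x), stats.rankdata(y)
    x = x - x.mean()
    y = y - y.mean()
    denom = math.sqrt(float(x @ x) * float(y @ y))
    if denom == 0:
        raise ValidationError("mantel: a distance matrix is constant off-diagonal")
    return float(x @ y) / denom


def mantel(
    dist_a: np.ndarray,
    dist_b: np.ndarray,
    n_perm: int = 999,
    seed: int | None = 0,
    method: str = "pearson",
    exact: bool = False,
) -> MantelResult:
    """Mantel test of association between two distance matrices.

    The statistic is the Pearson (or Spearman) correlation of the
    off-diagonal upper-triangle entries.  The p-value is one-sided
    (greater), from simultaneous row/column permutations of the second
    matrix: ``(1 + #{r_perm >= r_obs}) / (n_perm + 1)``.  With
    ``exact=True`` all n! sample relabelings are enumerated instead
    (identity included) and the p-value is the exact fraction
    ``#{r_perm >= r_obs} / n!``; feasible for small n only.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown mantel method {method!r}")
    da = _check_distance_matrix(dist_a, "dist_a")
    db = _check_distance_matrix(dist_b, "dist_b")
    if da.shape != db.shape:
        raise ValidationError("mantel: distance matrices differ in dimension")
    n = da.shape[0]
    r_obs = _tri_correlation(da, db, method)
    if exact:
        if n > 8:
            raise ValidationError("exact mantel enumeration limited to n <= 8 samples")
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            p = np.asarray(perm)
            r_p = _tri_correlation(da, db[np.ix_(p, p)], method)
            count += r_p >= r_obs - 1e-12
            total += 1
        return MantelResult(
            r=r_obs, pvalue=count / total, n_perm=total, seed=None, method=method, exact=True
        )
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if _tri_correlation(da, db[np.ix_(p, p)], method) >= r_obs - 1e-12:
            count += 1
    return MantelResult(
        r=r_obs,
        pvalue=(1.0 + count) / (n_perm + 1.0),
        n_perm=n_perm,
        seed=seed,
        method=method,
    )


def euclidean_distance(table: OmicsTable) -> np.ndarray:
    """Euclidean sample-distance matrix from an omics table."""
    return squareform(pdist(table.values, metric="euclidean"))


def braycurtis_distance(table: OmicsTable) -> np.ndarray:
    """Bray-Curtis sample-dissimilarity matrix (non-negative abundances)."""
    if table.values.min() < 0:
        raise ValidationError("Bray-Curtis requires non-negative abundances")
    return squareform(pdist(table.values, metric="braycurtis"))
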