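"""Core coordination statistics.

For each gene, its *correlation profile* is the vector of Pearson R values
between its expression and every gene in the matrix across samples. The
*coordination* of two genes is the Pearson correlation of their two profiles
after removing both genes' own entries (the self-entries are identically 1
and would inflate the statistic). A panel scan aggregates each candidate
gene's coordination against a query panel and ranks candidates.

Significance of a Pearson R at sample size n uses the exact small-sample
t transform t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom;
an optional permutation null permutes one gene's sample labels and
recomputes its profile, preserving the rest of the correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from coordscan.expression_io import ExpressionMatrix


class CorrelationError(ValueError):
    """Raised for undefined or ill-posed correlation computations."""


@dataclass(frozen=True)
class CorrelationProfile:
    """One gene's vector of Pearson R values against every gene in a matrix."""

    gene: str
    gene_ids: tuple[str, ...]
    r_values: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "r_values", np.asarray(self.r_values, dtype=np.float64))
        if self.r_values.shape != (len(self.gene_ids),):
            raise CorrelationError("profile length does not match gene_ids")


@dataclass(frozen=True)
class CoordinationResult:
    """Coordination of a gene pair: correlation of their correlation profiles."""

    gene_a: str
    gene_b: str
    coordination_r: float
    n_points: int
    p_analytic: float
    p_permutation: float | None = None
    n_permutations: int = 0
    seed: int | None = None


@dataclass(frozen=True)
class PanelScanResult:
    """Ranked candidate table from coordination against a query panel.

    ``table`` has one row per non-panel candidate with columns
    ``candidate``, one ``coord_<panel gene>`` column per panel member,
    ``mean_coordination``, ``min_coordination``, ``rank`` (dense, descending
    mean, ties broken lexicographically on candidate id) and ``p_analytic``
    for the mean coordination at ``n_points`` profile entries.
    """

    panel: tuple[str, ...]
    table: pd.DataFrame

    @property
    def candidates(self) -> tuple[str, ...]:
        return tuple(self.table["candidate"])

    def top_candidate(self) -> str:
        return str(self.table.iloc[0]["candidate"])


def _as_vector(x: Sequence[float], name: str) -> np.ndarray:
    v = np.asarray(x, dtype=np.float64).ravel()
    if not np.all(np.isfinite(v)):
        raise CorrelationError(f"{name} contains non-finite values")
    return v


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation of two equal-length vectors (length >= 3)."""
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    if xv.shape != yv.shape:
        raise CorrelationError(f"length mismatch: {xv.size} vs {yv.size}")
    if xv.size < 3:
        raise CorrelationError(f"need at least 3 points, got {xv.size}")
    dx = xv - xv.mean()
    dy = yv - yv.mean()
    sx = float(dx @ dx)
    sy = float(dy @ dy)
    if sx == 0.0 or sy == 0.0:
        raise CorrelationError("correlation undefined for a constant vector")
    r = float(dx @ dy) / np.sqrt(sx * sy)
    return float(min(1.0, max(-1.0, r)))


def pearson_pvalue(r, n: int):
    """Two-sided p for Pearson R at sample size n via the t transform (df = n-2).

    Accepts a scalar or an array of r values; returns the matching shape.
    p = 0 exactly only at |r| = 1.
    """
    n = int(n)
    if n < 3:
        raise CorrelationError(f"need n >= 3, got {n}")
    r_arr = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(r_arr) > 1 + 1e-12):
        raise CorrelationError("|r| must be <= 1")
    r_arr = np.clip(r_arr, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = np.abs(r_arr) * np.sqrt(df / (1.0 - r_arr**2))
    p = np.where(np.abs(r_arr) >= 1.0, 0.0, 2.0 * stats.t.sf(t, df))
    p = np.minimum(p, 1.0)
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(p)
    return p


def critical_r(n: int, alpha: float) -> float:
    """The |r| at which the two-sided Pearson p equals alpha, for sample size n."""
    n = int(n)
    if n < 3:
        raise CorrelationError(f"need n >= 3, got {n}")
    if not 0 < alpha < 1:
        raise CorrelationError(f"alpha must be in (0, 1), got {alpha}")
    df = n - 2
    tc = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(tc / np.sqrt(df + tc**2))


def _check_nonconstant(matrix: ExpressionMatrix) -> None:
    constant = np.ptp(matrix.values, axis=1) == 0
    if np.any(constant):
        bad = [g for g, c in zip(matrix.gene_ids, constant) if c]
        raise CorrelationError(
            "matrix contains zero-variance gene(s) "
            f"({', '.join(bad[:5])}{'…' if len(bad) > 5 else ''}); "
            "apply filter_invariant_genes first"
        )


def _standardized_rows(values: np.ndarray) -> np.ndarray:
    """Rows centered and scaled to unit Euclidean norm, so r = z_a @ z_b."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    return centered / norms


def correlation_matrix(matrix: ExpressionMatrix) -> np.ndarray:
    """Full gene × gene Pearson correlation matrix with an exact unit diagonal."""
    if matrix.n_samples < 3:
        raise CorrelationError(f"need at least 3 samples, got {matrix.n_samples}")
    _check_nonconstant(matrix)
    r = np.corrcoef(matrix.values)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def correlation_profile(matrix: ExpressionMatrix, gene: str) -> CorrelationProfile:
    """Pearson R of ``gene`` against every gene in the matrix (self-entry = 1)."""
    if matrix.n_samples < 3:
        raise CorrelationError(f"need at least 3 samples, got {matrix.n_samples}")
    _check_nonconstant(matrix)
    idx = matrix.gene_index(gene)
    z = _standardized_rows(matrix.values)
    r = z @ z[idx]
    np.clip(r, -1.0, 1.0, out=r)
    r[idx] = 1.0
    return CorrelationProfile(
        gene=gene, gene_ids=matrix.gene_ids, r_values=r, n_samples=matrix.n_samples
    )


def _coordination_r(
    prof_a: np.ndarray, prof_b: np.ndarray, exclude: Sequence[int]
) -> tuple[float, int]:
    mask = np.ones(prof_a.size, dtype=bool)
    mask[list(exclude)] = False
    a = prof_a[mask]
    b = prof_b[mask]
    return pearson_r(a, b), int(a.size)


def coordination(
    profile_a: CorrelationProfile, profile_b: CorrelationProfile
) -> CoordinationResult:
    """Pearson correlation of two correlation profiles, self-entries excluded."""
    if profile_a.gene_ids != profile_b.gene_ids:
        raise CorrelationError("profiles come from matrices with different gene order")
    if profile_a.n_samples != profile_b.n_samples:
        raise CorrelationError("profiles computed at different sample sizes")
    ids = profile_a.gene_ids
    exclude = {ids.index(profile_a.gene), ids.index(profile_b.gene)}
    r, n_points = _coordination_r(profile_a.r_values, profile_b.r_values, exclude)
    return CoordinationResult(
        gene_a=profile_a.gene,
        gene_b=profile_b.gene,
        coordination_r=r,
        n_points=n_points,
        p_analytic=pearson_pvalue(r, n_points),
    )


def permutation_pvalue(
    matrix: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    n_permutations: int = 999,
    seed: int = 0,
) -> CoordinationResult:
    """Permutation p-value for the coordination of ``gene_a`` with ``gene_b``.

    Sample labels of gene_a's expression row are permuted; its profile is
    recomputed against the unpermuted matrix and correlated with gene_b's
    fixed profile. p = (1 + #{|null| >= |observed|}) / (B + 1).
    """
    if n_permutations < 99:
        raise CorrelationError(f"need at least 99 permutations, got {n_permutations}")
    _check_nonconstant(matrix)
    ia = matrix.gene_index(gene_a)
    ib = matrix.gene_index(gene_b)
    z = _standardized_rows(matrix.values)
    prof_b = z @ z[ib]
    np.clip(prof_b, -1.0, 1.0, out=prof_b)
    prof_b[ib] = 1.0
    prof_a = z @ z[ia]
    np.clip(prof_a, -1.0, 1.0, out=prof_a)
    prof_a[ia] = 1.0
    exclude = {ia, ib}
    observed, n_points = _coordination_r(prof_a, prof_b, exclude)

    rng = np.random.default_rng(seed)
    n = matrix.n_samples
    hits = 0
    for _ in range(n_permutations):
        za = z[ia][rng.permutation(n)]
        prof_null = z @ za
        null_r, _ = _coordination_r(prof_null, prof_b, exclude)
        if abs(null_r) >= abs(observed):
            hits += 1
    p_perm = (1 + hits) / (n_permutations + 1)
    return CoordinationResult(
        gene_a=gene_a,
        gene_b=gene_b,
        coordination_r=observed,
        n_points=n_points,
        p_analytic=pearson_pvalue(observed, n_points),
        p_permutation=p_perm,
        n_permutations=n_permutations,
        seed=seed,
    )


def coordination_scan(
    matrix: ExpressionMatrix, panel: Sequence[str]
) -> PanelScanResult:
    """Coordination of every non-panel gene against each panel member, ranked.

    Candidates are ranked by descending mean coordination across the panel
    (dense ranks; ties share a rank and are ordered lexicographically by id);
    the minimum across the panel is reported alongside.
    """
    panel = tuple(dict.fromkeys(str(g) for g in panel))
    if not panel:
        raise CorrelationError("panel must contain at least one gene")
    missing = [g for g in panel if g not in matrix.gene_ids]
    if missing:
        raise CorrelationError(f"panel gene(s) not in matrix: {', '.join(missing)}")

    r = correlation_matrix(matrix)
    gene_ids = matrix.gene_ids
    panel_idx = {g: gene_ids.index(g) for g in panel}
    panel_set = set(panel)
    candidates = [g for g in gene_ids if g not in panel_set]

    n_genes = len(gene_ids)
    rows = []
    for cand in candidates:
        ci = gene_ids.index(cand)
        coords = {}
        n_points = n_genes - 2
        for pg, pi in panel_idx.items():
            coords[pg], n_points = _coordination_r(r[:, ci], r[:, pi], (ci, pi))
        vals = np.array([coords[pg] for pg in panel])
        mean_r = float(vals.mean())
        rows.append(
            {
                "candidate": cand,
                **{f"coord_{pg}": coords[pg] for pg in panel},
                "mean_coordination": mean_r,
                "min_coordination": float(vals.min()),
                "p_analytic": pearson_pvalue(mean_r, n_points),
            }
        )

    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["mean_coordination", "candidate"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    # dense rank: equal mean scores share a rank
    table["rank"] = (
        table["mean_coordination"].rank(method="dense", ascending=False).astype(int)
    )
    cols = (
        ["candidate"]
        + [f"coord_{pg}" for pg in panel]
        + ["mean_coordination", "min_coordination", "rank", "p_analytic"]
    )
    return PanelScanResult(panel=panel, table=table[cols])


def correlated_gene_set(
    matrix: ExpressionMatrix,
    gene: str,
    alpha: float = 0.05,
    direction: str = "positive",
) -> list[str]:
    """Genes whose profile entry against ``gene`` is significant at ``alpha``.

    ``direction="positive"`` additionally requires R > 0. The query gene is
    excluded; results are ordered by descending R (ties lexicographic on id).
    """
    table = correlated_gene_table(matrix, gene, alpha, direction)
    return list(table["gene"])


def correlated_gene_table(
    matrix: ExpressionMatrix,
    gene: str,
    alpha: float = 0.05,
    direction: str = "positive",
) -> pd.DataFrame:
    """Like :func:`correlated_gene_set` but returns a table with R and p columns."""
    if direction not in ("positive", "both"):
        raise CorrelationError(f"direction must be 'positive' or 'both', got {direction!r}")
    if not 0 < alpha <= 1:
        raise CorrelationError(f"alpha must be in (0, 1], got {alpha}")
    profile = correlation_profile(matrix, gene)
    r = profile.r_values
    p = pearson_pvalue(r, matrix.n_samples)
    keep = p < alpha
    if direction == "positive":
        keep &= r > 0
    keep[matrix.gene_index(gene)] = False
    table = pd.DataFrame(
        {
            "gene": [g for g, k in zip(matrix.gene_ids, keep) if k],
            "r": r[keep],
            "p": np.atleast_1d(p)[keep],
        }
    )
    return table.sort_values(["r", "gene"], ascending=[False, True], kind="mergesort").reset_index(
        drop=True
    )
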