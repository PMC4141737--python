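"""Phosphoproteomic time-course analysis.

Input is a tidy phosphopeptide ratio table: one row per (peptide, replicate)
with SILAC-style abundance ratios at 5/15/30/60 s relative to unstimulated
(0 s) cells.  The pipeline stages are

  1. proline-content ratio correction (arginine-to-proline conversion in
     heavy-labeled cultures inflates the light channel of proline-containing
     peptides; off by default),
  2. collapse of multiple peptides covering one site to the least-modified
     peptide,
  3. replicate averaging (missing replicate values are skipped, not imputed),
  4. regulation filtering (>= theta-fold change, up or down, at >= 1 time
     point),
  5. fuzzy c-means clustering of the regulated, standardized log2 courses,
  6. PCA-based assignment of model-site courses to three dynamical classes,
  7. annotation-term enrichment per cluster (one-sided Fisher exact test
     against detected-but-unregulated proteins, Benjamini-Hochberg adjusted,
     terms must occur at least twice in the cluster).

Expected table columns: protein, residues, sequence, n_phospho, n_proline,
replicate, t5, t15, t30, t60 (ratio columns may hold NaN for undetected
values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TIME_COLUMNS",
    "ClusterResult",
    "correct_proline",
    "drop_undetected",
    "collapse_to_sites",
    "average_replicates",
    "filter_regulated",
    "fuzzy_cmeans",
    "cluster_timecourses",
    "assign_pca_classes",
    "enrich_terms",
    "fisher_pvalue",
    "bh_adjust",
    "read_peptide_table",
    "standardize_courses",
]

TIME_COLUMNS = ("t5", "t15", "t30", "t60")
TIMES_S = (5.0, 15.0, 30.0, 60.0)


def read_peptide_table(path) -> pd.DataFrame:
    """Read a tab-delimited phosphopeptide table (``#`` lines are comments)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"protein", "residues", "sequence", "n_phospho", "n_proline",
                "replicate", *TIME_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    return df


def drop_undetected(table: pd.DataFrame) -> pd.DataFrame:
    """Remove (peptide, replicate) rows with no ratio at any time point.

    Detection dropout leaves such rows in synthetic tables; real tables
    simply lack them.  Sites whose every row is undetected disappear.
    """
    detected = table[list(TIME_COLUMNS)].notna().any(axis=1)
    return table[detected].reset_index(drop=True)


def correct_proline(table: pd.DataFrame, conversion_fraction: float = 0.0) -> pd.DataFrame:
    """Correct ratios for arginine-to-proline conversion.

    With a converted fraction ``f`` of the heavy label, each proline residue
    deflates the measured heavy/light ratio by (1 - f); the correction
    multiplies every ratio by (1 - f) ** (-n_proline).  ``f = 0`` (default)
    is the identity.
    """
    if not 0.0 <= conversion_fraction < 1.0:
        raise ValueError("conversion fraction must lie in [0, 1)")
    out = table.copy()
    if conversion_fraction > 0.0:
        factor = (1.0 - conversion_fraction) ** (-out["n_proline"].to_numpy(float))
        for col in TIME_COLUMNS:
            out[col] = out[col] * factor
    return out


def collapse_to_sites(table: pd.DataFrame) -> pd.DataFrame:
    """Keep, per site, only the least-modified peptide covering it.

    A site is (protein, residues).  Among the peptides covering a site the one
    with minimal n_phospho is kept; ties break to the shortest, then
    lexicographically smallest, sequence.  All replicate rows of the chosen
    peptide are retained.
    """
    def _pick(group: pd.DataFrame) -> pd.DataFrame:
        key = group[["n_phospho", "sequence"]].drop_duplicates()
        best = min(
            key.itertuples(index=False),
            key=lambda r: (r.n_phospho, len(r.sequence), r.sequence),
        )
        return group[(group["n_phospho"] == best.n_phospho)
                     & (group["sequence"] == best.sequence)]

    parts = [
        _pick(g) for _, g in table.groupby(["protein", "residues"], sort=False)
    ]
    return pd.concat(parts, ignore_index=True)


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Average replicate ratios per site and time point.

    Returns one row per site with mean_t*, sd_t* and n_t* columns.  Missing
    replicate values are skipped; the SD is reported only where n >= 2.  A
    site with no value at any time point raises.
    """
    rows = []
    for (protein, residues), g in table.groupby(["protein", "residues"], sort=False):
        rec: dict = {"protein": protein, "residues": residues}
        any_value = False
        for col in TIME_COLUMNS:
            vals = g[col].dropna().to_numpy(float)
            n = len(vals)
            rec[f"mean_{col}"] = vals.mean() if n else np.nan
            rec[f"sd_{col}"] = vals.std(ddof=1) if n >= 2 else np.nan
            rec[f"n_{col}"] = n
            any_value = any_value or n > 0
        if not any_value:
            raise ValueError(f"site ({protein}, {residues}) has no values at any time point")
        rows.append(rec)
    return pd.DataFrame(rows)


def filter_regulated(
    site_table: pd.DataFrame,
    threshold: float = 2.0,
    comparator: str = ">=",
) -> pd.DataFrame:
    """Sites whose mean ratio crosses ``threshold``-fold (up or down) at least once.

    ``comparator`` selects >= (default) or > for the crossing test.  The
    returned frame adds ``direction`` (up / down / mixed) and
    ``earliest_time_s`` (first qualifying time point).
    """
    if threshold <= 1.0:
        raise ValueError("threshold must exceed 1")
    if comparator not in (">=", ">"):
        raise ValueError("comparator must be '>=' or '>'")
    ge = np.greater_equal if comparator == ">=" else np.greater

    means = site_table[[f"mean_{c}" for c in TIME_COLUMNS]].to_numpy(float)
    up = ge(means, threshold)
    down = ge(1.0 / means, threshold)
    hit = up | down
    keep = np.nansum(hit, axis=1) > 0

    out = site_table[keep].copy()
    directions, earliest = [], []
    for row_up, row_down, row_hit in zip(up[keep], down[keep], hit[keep]):
        has_up, has_down = bool(np.nansum(row_up)), bool(np.nansum(row_down))
        directions.append("mixed" if (has_up and has_down) else ("up" if has_up else "down"))
        earliest.append(TIMES_S[int(np.argmax(row_hit))])
    out["direction"] = directions
    out["earliest_time_s"] = earliest
    return out


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterResult:
    """Fuzzy partition of site time courses.

    ``memberships`` is sites x clusters, each row summing to 1; ``labels`` is
    the per-site argmax; ``centers`` live in the standardized log2 space.
    """

    site_ids: list
    memberships: np.ndarray
    centers: np.ndarray
    labels: np.ndarray
    objective: float
    n_clusters: int
    fuzzifier: float
    seed: int
    n_iter: int


def standardize_courses(means: np.ndarray) -> np.ndarray:
    """log2-transform and z-score each course (the shape-clustering space).

    Courses with zero variance standardize to all-zeros rather than dividing
    by zero.
    """
    X = np.log2(np.asarray(means, dtype=float))
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0.0] = 1.0
    return (X - mu) / sd


def fuzzy_cmeans(
    X: np.ndarray,
    c: int,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Fuzzy c-means (Bezdek alternating optimization) on row vectors of X.

    Returns (memberships U, centers V, final objective, iterations).  The
    objective sum_ik u_ik^m ||x_i - v_k||^2 is non-increasing across
    iterations; iteration stops when the membership change drops below
    ``tol``.  Deterministic for a fixed ``seed``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < c:
        raise ValueError(f"need at least c={c} rows, got {n}")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: all profiles identical")
    rng = np.random.Generator(np.random.PCG64(seed))
    U = rng.dirichlet(np.ones(c), size=n)

    last_obj = np.inf
    for it in range(1, max_iter + 1):
        Um = U ** m
        V = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - V[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0))  # u_ik proportional to d_ik^{-2/(m-1)}
        U_new = inv / inv.sum(axis=1, keepdims=True)
        obj = float((U_new ** m * d2).sum())
        shift = float(np.abs(U_new - U).max())
        U = U_new
        if shift < tol or abs(last_obj - obj) < tol * max(1.0, obj):
            last_obj = obj
            break
        last_obj = obj
    return U, V, last_obj, it


def cluster_timecourses(
    site_table: pd.DataFrame,
    c: int = 4,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ClusterResult:
    """Cluster regulated site courses (standardized log2) with fuzzy c-means."""
    means = site_table[[f"mean_{col}" for col in TIME_COLUMNS]].to_numpy(float)
    if np.isnan(means).any():
        raise ValueError("clustering requires complete mean courses (drop NaN sites first)")
    # the unstimulated baseline (ratio 1 at t=0) anchors each course so that
    # z-scoring preserves direction and rise timing, not just shape
    anchored = np.hstack([np.ones((means.shape[0], 1)), means])
    X = standardize_courses(anchored)
    U, V, obj, n_iter = fuzzy_cmeans(X, c=c, m=m, seed=seed, tol=tol, max_iter=max_iter)
    ids = list(zip(site_table["protein"], site_table["residues"]))
    return ClusterResult(
        site_ids=ids,
        memberships=U,
        centers=V,
        labels=U.argmax(axis=1) + 1,
        objective=obj,
        n_clusters=c,
        fuzzifier=m,
        seed=seed,
        n_iter=n_iter,
    )


def assign_pca_classes(
    courses: Mapping[str, Sequence[float]], seed: int = 0
) -> dict[str, int]:
    """Assign each (relative, ratio-scale) course to dynamical class 1, 2 or 3.

    PCA on standardized log2 courses, k-means (k=3, seeded) in the first two
    principal components, then semantic mapping of the three clusters:
    the cluster whose mean log2 course is lowest is the dephosphorylated
    class 3; of the remaining two, the one reaching the larger fraction of
    its final rise early (at the first time point) is the
    receptor-independent fast class 1, the other class 2.
    """
    names = list(courses)
    if len(names) < 3:
        raise ValueError("need at least 3 courses for 3 classes")
    M = np.asarray([np.asarray(courses[n], dtype=float) for n in names])
    X = standardize_courses(M)
    n_pc = min(2, X.shape[1])
    Z = PCA(n_components=n_pc, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=3, n_init=10, random_state=seed).fit(Z)

    logM = np.log2(M)
    cluster_ids = np.unique(km.labels_)
    mean_course = {k: logM[km.labels_ == k].mean(axis=0) for k in cluster_ids}
    down = min(cluster_ids, key=lambda k: mean_course[k].mean())
    rest = [k for k in cluster_ids if k != down]

    def earliness(k: int) -> float:
        mc = mean_course[k]
        final = mc[-1] if mc[-1] != 0 else 1e-9
        return mc[0] / final

    rest.sort(key=earliness, reverse=True)
    mapping = {down: 3, rest[0]: 1, rest[1]: 2}
    return {name: mapping[k] for name, k in zip(names, km.labels_)}


# ---------------------------------------------------------------------------
# enrichment


def fisher_pvalue(a: int, b: int, c: int, d: int) -> float:
    """One-sided (over-representation) Fisher exact p for the 2x2 table
    [[a, b], [c, d]] — the hypergeometric tail P[K >= a]."""
    return float(fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def enrich_terms(
    cluster_proteins: Iterable[str],
    background_proteins: Iterable[str],
    annotations: pd.DataFrame,
    alpha: float = 0.05,
    min_occurrence: int = 2,
    full: bool = False,
) -> pd.DataFrame:
    """Term over-representation in a cluster vs detected-but-unregulated background.

    ``annotations`` has columns (protein, term).  For each term the 2x2 table

        a = cluster proteins with the term      b = cluster without
        c = background proteins with the term   d = background without

    is tested with a one-sided Fisher exact test (greater); p-values are
    Benjamini-Hochberg adjusted across the terms of the cluster.  The default
    return keeps terms occurring >= ``min_occurrence`` times in the cluster
    with adjusted p < ``alpha``; ``full=True`` returns every tested term with
    a ``significant`` flag instead.
    """
    cluster = set(cluster_proteins)
    background = set(background_proteins)
    if not cluster or not background:
        raise ValueError("cluster and background must be non-empty")
    if cluster & background:
        raise ValueError("cluster and background must be disjoint")
    if not {"protein", "term"} <= set(annotations.columns):
        raise ValueError("annotation table needs columns (protein, term)")

    by_term: dict[str, set[str]] = {}
    for protein, term in annotations[["protein", "term"]].itertuples(index=False):
        by_term.setdefault(term, set()).add(protein)

    rows = []
    for term, prots in sorted(by_term.items()):
        a = len(cluster & prots)
        if a == 0:
            continue
        b = len(cluster) - a
        c = len(background & prots)
        d = len(background) - c
        p = fisher_pvalue(a, b, c, d)
        odds = (a * d) / (b * c) if b * c else np.inf
        rows.append({"term": term, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": odds, "p": p})
    if not rows:
        return pd.DataFrame(
            columns=["term", "a", "b", "c", "d", "odds_ratio", "p", "p_adj", "significant"]
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["a"] >= min_occurrence) & (out["p_adj"] < alpha)
    out = out.sort_values(["p_adj", "term"]).reset_index(drop=True)
    if full:
        return out
    return out[out["significant"]].reset_index(drop=True)
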