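"""Quality control: replicate correlation, tag agreement, spike-in linearity,
and hierarchical clustering of GI profiles."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .demux import CountTable
from .scoring import GITable, ScoringParams, normalize

__all__ = [
    "LinearityFit",
    "ClusterTree",
    "replicate_correlation",
    "tag_agreement",
    "spikein_fit",
    "uncentered_correlation",
    "cluster_profiles",
]


@dataclass(frozen=True)
class LinearityFit:
    """log10(normalized reads) vs log10(spike-in ratio) least-squares fit."""

    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass
class ClusterTree:
    """Average-linkage merge tree; ``merges`` is the scipy linkage matrix
    (left, right, height, size per row), ``labels`` the leaf names.
    Average linkage admits height inversions, so monotonicity is not a
    guarantee; heights are nonnegative up to rounding."""

    merges: np.ndarray
    labels: list[str]

    def to_newick(self) -> str:
        """Newick with branch lengths = height difference to the child
        (children at their own merge height; leaves at height 0)."""
        n = len(self.labels)

        def height(node: int) -> float:
            return 0.0 if node < n else float(self.merges[node - n, 2])

        def render(node: int) -> str:
            if node < n:
                return self.labels[node]
            left, right, h, _ = self.merges[node - n]
            parts = []
            for child in (int(left), int(right)):
                bl = max(h - height(child), 0.0)
                parts.append(f"{render(child)}:{bl:.6g}")
            return f"({','.join(parts)})"

        root = n + len(self.merges) - 1 if len(self.merges) else 0
        return render(root) + ";"

    def write_newick(self, path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def _shared_positive(norm_a: dict, norm_b: dict) -> tuple[np.ndarray, np.ndarray]:
    keys = sorted(
        k for k in set(norm_a) & set(norm_b) if norm_a[k] > 0 and norm_b[k] > 0
    )
    a = np.array([norm_a[k] for k in keys])
    b = np.array([norm_b[k] for k in keys])
    return a, b


def replicate_correlation(
    norm_a: dict, norm_b: dict, log_scale: bool = True
) -> float:
    """Pearson r between two samples' normalized counts over barcodes
    positive in both (log10 scale by default, matching how read-number
    scatter plots spanning orders of magnitude are read)."""
    a, b = _shared_positive(norm_a, norm_b)
    if a.size < 3:
        raise ValueError("need >= 3 barcodes positive in both samples")
    if log_scale:
        a, b = np.log10(a), np.log10(b)
    return float(stats.pearsonr(a, b).statistic)


def tag_agreement(
    counts: CountTable,
    control_sample: str,
    treatment_sample: str,
    min_control_reads: int = 12,
    params: ScoringParams = ScoringParams(),
) -> tuple[int, float]:
    """Agreement between uptag- and dntag-derived log ratios.

    Strains qualify when both tags have control reads >= ``min_control_reads``
    and both tags have treatment reads > 0.  Returns (n strains, Pearson r of
    the per-tag log2 control/treatment ratios of normalized counts).
    """
    norm = normalize(counts, params)
    genes = {g for (g, _c) in counts.counts.get(control_sample, {})}
    ratios_up, ratios_dn = [], []
    for gene in sorted(genes):
        raw_c = {c: counts.get(control_sample, gene, c) for c in ("up", "dn")}
        raw_t = {c: counts.get(treatment_sample, gene, c) for c in ("up", "dn")}
        if min(raw_c.values()) < min_control_reads or min(raw_t.values()) <= 0:
            continue
        for cls, out in (("up", ratios_up), ("dn", ratios_dn)):
            out.append(
                np.log2(
                    norm[control_sample][(gene, cls)]
                    / norm[treatment_sample][(gene, cls)]
                )
            )
    if len(ratios_up) < 3:
        raise ValueError("fewer than 3 strains satisfy the tag-agreement filter")
    r = float(stats.pearsonr(ratios_up, ratios_dn).statistic)
    return len(ratios_up), r


def spikein_fit(norm_reads: dict[float, float]) -> LinearityFit:
    """Least-squares fit of log10(normalized reads) on log10(spike-in cell
    ratio).  Levels with nonpositive reads are dropped; >= 2 distinct ratios
    must remain.  Proportional quantification gives slope 1."""
    pairs = [(r, v) for r, v in sorted(norm_reads.items()) if v > 0]
    if len({r for r, _ in pairs}) < 2:
        raise ValueError("need >= 2 spike-in levels with positive reads")
    x = np.log10([r for r, _ in pairs])
    y = np.log10([v for _, v in pairs])
    fit = stats.linregress(x, y)
    return LinearityFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(pairs),
    )


def uncentered_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Similarity about zero: sum(x*y) / sqrt(sum(x^2) * sum(y^2)); defined
    as 0 when either profile has zero norm."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx = np.sqrt((x * x).sum())
    ny = np.sqrt((y * y).sum())
    if nx == 0 or ny == 0:
        return 0.0
    return float((x * y).sum() / (nx * ny))


def _uncentered_distance_matrix(matrix: np.ndarray) -> np.ndarray:
    norms = np.sqrt((matrix * matrix).sum(axis=1))
    denom = np.outer(norms, norms)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (matrix @ matrix.T) / denom
    sim[~np.isfinite(sim)] = 0.0  # zero-norm profiles: similarity 0
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    return np.maximum(dist, 0.0)


def cluster_profiles(
    matrix: np.ndarray,
    row_labels: list[str],
    col_labels: list[str],
    impute_missing: bool = True,
) -> tuple[ClusterTree, ClusterTree]:
    """Agglomerative average-linkage clustering of rows and of columns of a
    genes x conditions GI matrix, with distance 1 - uncentered correlation.

    Missing values (NaN) are imputed as 0 — "no fitness change" — before
    clustering.  Ties in merge order break by input order (scipy's
    deterministic behaviour on the condensed matrix).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need a 2D matrix with >= 2 rows and >= 2 columns")
    if impute_missing:
        matrix = np.where(np.isfinite(matrix), matrix, 0.0)
    elif not np.all(np.isfinite(matrix)):
        raise ValueError("matrix contains missing values")
    trees = []
    for mat, labels in ((matrix, row_labels), (matrix.T, col_labels)):
        dist = _uncentered_distance_matrix(mat)
        merges = linkage(squareform(dist, checks=False), method="average")
        trees.append(ClusterTree(merges=merges, labels=list(labels)))
    return trees[0], trees[1]


def write_qc_report(rows: list[tuple[str, float, int, str]], path) -> None:
    """QC summary TSV: (statistic, value, n, parameters) per row."""
    lines = ["statistic\tvalue\tn\tparameters"]
    for stat, value, n, params in rows:
        lines.append(f"{stat}\t{value:.6g}\t{n}\t{params}")
    Path(path).write_text("\n".join(lines) + "\n")
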