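"""Robust cutoffs, G-test filtering, and hit calling.

Sensitive hits are genes whose deletion strains are depleted under a
treatment.  Cutoffs are set from each experiment's own GI distribution using
robust location/scale estimates: the median and the normalized interquartile
range NIQR = IQR x 0.7413, which equals the standard deviation for normal
data.  A gene passes an experiment when its GI clears the cutoff (single-tag
genes: median + 3 NIQR; dual-tag genes: mean GI above median + 2.5 NIQR and
each tag above median + 2 NIQR) and at least one of its barcodes has a
G-test p-value below 0.005 on the control-vs-treatment read counts, and it
is called a hit when it passes in at least two of the three independent
experiments.  Resistant mutants (enriched under treatment, negative GI) are
reported as a ranking with a descriptive GI <= -0.5 flag rather than a
formal test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats
from scipy.special import xlogy

from .scoring import GITable, TAG_CLASSES

__all__ = [
    "RobustStats",
    "GTestResult",
    "HitCallParams",
    "Experiment",
    "HitTable",
    "robust_stats",
    "g_test",
    "gi_cutoffs",
    "call_sensitive",
    "rank_resistant",
]


@dataclass(frozen=True)
class RobustStats:
    median: float
    iqr: float

    @property
    def niqr(self) -> float:
        return 0.7413 * self.iqr


@dataclass(frozen=True)
class GTestResult:
    g: float
    p: float
    df: int = 1


@dataclass(frozen=True)
class HitCallParams:
    single_tag_multiplier: float = 3.0
    averaged_multiplier: float = 2.5
    per_tag_multiplier: float = 2.0
    p_cutoff: float = 0.005
    min_experiments: int = 2
    resistant_flag_cutoff: float = -0.5
    williams_correction: bool = False

    def __post_init__(self):
        if min(self.single_tag_multiplier, self.averaged_multiplier,
               self.per_tag_multiplier) <= 0:
            raise ValueError("cutoff multipliers must be > 0")
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must be in (0, 1)")
        if self.min_experiments < 1:
            raise ValueError("min_experiments must be >= 1")


@dataclass
class Experiment:
    """One profiling experiment: its GI table plus the raw counts feeding the
    G-test — per (gene_id, tag_class): (control count, treatment count,
    control tag-class total, treatment tag-class total) at the final weighted
    generation."""

    gi_table: GITable
    tag_counts: dict[tuple[str, str], tuple[int, int, int, int]]
    label: str = "A"

    @classmethod
    def from_counts(cls, gi_table: GITable, counts, catalog, label: str = "A"):
        """Assemble the G-test count table from the experiment's final
        weighted generation."""
        design = gi_table.design
        g = design.final_generation()
        c_sample = design.control_samples[g]
        t_sample = design.treatment_samples[g]
        tag_counts = {}
        for rec in catalog.records:
            for tag_class, seq in rec.tags():
                if seq not in catalog.lookup:
                    continue
                tag_counts[(rec.gene_id, tag_class)] = (
                    counts.get(c_sample, rec.gene_id, tag_class),
                    counts.get(t_sample, rec.gene_id, tag_class),
                    counts.total(c_sample, tag_class),
                    counts.total(t_sample, tag_class),
                )
        return cls(gi_table=gi_table, tag_counts=tag_counts, label=label)


def robust_stats(values) -> RobustStats:
    """Median and IQR (linear-interpolation quartiles) of >= 2 finite values."""
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("robust_stats needs at least two finite values")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return RobustStats(median=float(med), iqr=float(q3 - q1))


def g_test(
    a: int, b: int, total_a: int, total_b: int, williams: bool = False
) -> GTestResult:
    """Likelihood-ratio (G) test on the 2x2 table

        [[a, total_a - a], [b, total_b - b]]

    G = 2 sum O ln(O/E) with expectations from the marginals; zero observed
    cells contribute zero.  p is the upper chi-square tail with 1 df.  The
    plain uncorrected statistic is the default; ``williams`` divides G by
    the Williams small-sample factor.
    """
    if not (0 <= a <= total_a and 0 <= b <= total_b):
        raise ValueError("counts must satisfy 0 <= count <= total")
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be > 0")
    obs = np.array([[a, total_a - a], [b, total_b - b]], dtype=float)
    grand = obs.sum()
    if grand == 0:
        raise ValueError("all-zero table")
    col = obs.sum(axis=0)
    if col[0] == 0 or col[1] == 0:
        # degenerate margin: both samples identical on this axis, no evidence
        return GTestResult(g=0.0, p=1.0)
    expected = np.outer(obs.sum(axis=1), col) / grand
    g = float(2.0 * xlogy(obs, obs / expected).sum())
    g = max(g, 0.0)  # guard tiny negative rounding
    if williams:
        row = obs.sum(axis=1)
        q = 1.0 + (
            (grand / row[0] + grand / row[1] - 1.0)
            * (grand / col[0] + grand / col[1] - 1.0)
        ) / (6.0 * grand)
        g /= q
    return GTestResult(g=g, p=float(stats.chi2.sf(g, df=1)))


def gi_cutoffs(gi_values, params: HitCallParams = HitCallParams()):
    """(single-tag, averaged, per-tag) thresholds = median + k * NIQR of one
    experiment's combined strain GI distribution."""
    rs = robust_stats(gi_values)
    return (
        rs.median + params.single_tag_multiplier * rs.niqr,
        rs.median + params.averaged_multiplier * rs.niqr,
        rs.median + params.per_tag_multiplier * rs.niqr,
    )


@dataclass
class HitTable:
    """Per-gene hit status across experiments."""

    genes: list[str]
    experiment_labels: list[str]
    gi: dict[str, list[Optional[float]]]  # gene -> per-experiment combined GI
    gi_pass: dict[str, list[bool]]
    p_pass: dict[str, list[bool]]
    n_passing: dict[str, int]
    status: dict[str, str]  # "sensitive" | "none"

    def hits(self) -> list[str]:
        return [g for g in self.genes if self.status[g] == "sensitive"]

    def write_tsv(self, path) -> None:
        labels = self.experiment_labels
        cols = ["gene_id"]
        cols += [f"gi_{l}" for l in labels]
        cols += [f"gi_pass_{l}" for l in labels]
        cols += [f"p_pass_{l}" for l in labels]
        cols += ["n_passing", "hit_status"]
        lines = ["\t".join(cols)]
        for gene in self.genes:
            row = [gene]
            row += ["NA" if v is None else f"{v:.6g}" for v in self.gi[gene]]
            row += [str(int(v)) for v in self.gi_pass[gene]]
            row += [str(int(v)) for v in self.p_pass[gene]]
            row += [str(self.n_passing[gene]), self.status[gene]]
            lines.append("\t".join(row))
        Path(path).write_text("\n".join(lines) + "\n")


def _gene_passes_gi(record, cutoffs) -> bool:
    cut_single, cut_avg, cut_tag = cutoffs
    tag_gis = [v for v in (record.gi_up, record.gi_dn) if v is not None]
    if not tag_gis:
        return False
    if len(tag_gis) == 1:
        return tag_gis[0] >= cut_single
    return record.gi >= cut_avg and all(v >= cut_tag for v in tag_gis)


def _gene_passes_p(
    gene: str, experiment: Experiment, params: HitCallParams
) -> bool:
    for tag_class in TAG_CLASSES:
        entry = experiment.tag_counts.get((gene, tag_class))
        if entry is None:
            continue
        a, b, ta, tb = entry
        if a == 0 and b == 0:
            continue
        if g_test(a, b, ta, tb, williams=params.williams_correction).p < params.p_cutoff:
            return True
    return False


def call_sensitive(
    experiments: list[Experiment],
    params: HitCallParams = HitCallParams(),
    frozen_cutoffs: Optional[list[tuple]] = None,
) -> HitTable:
    """Call sensitive hits across replicate experiments (2-of-3 rule).

    Cutoffs are recomputed per experiment from its own GI distribution unless
    ``frozen_cutoffs`` supplies them.  A gene is a hit iff it passes both the
    GI filter and the G-test p filter in >= ``params.min_experiments``
    experiments.
    """
    if not experiments:
        raise ValueError("need at least one experiment")
    genes = [r.gene_id for r in experiments[0].gi_table.records]
    labels = [e.label for e in experiments]
    if frozen_cutoffs is None:
        cutoffs = [gi_cutoffs(e.gi_table.gi_values(), params) for e in experiments]
    else:
        cutoffs = list(frozen_cutoffs)
    gi: dict[str, list[Optional[float]]] = {g: [] for g in genes}
    gi_pass: dict[str, list[bool]] = {g: [] for g in genes}
    p_pass: dict[str, list[bool]] = {g: [] for g in genes}
    for exp, cuts in zip(experiments, cutoffs):
        for gene in genes:
            rec = exp.gi_table[gene]
            gi[gene].append(rec.gi)
            gi_pass[gene].append(_gene_passes_gi(rec, cuts))
            p_pass[gene].append(_gene_passes_p(gene, exp, params))
    n_passing = {
        g: sum(a and b for a, b in zip(gi_pass[g], p_pass[g])) for g in genes
    }
    status = {
        g: "sensitive" if n_passing[g] >= params.min_experiments else "none"
        for g in genes
    }
    return HitTable(
        genes=genes, experiment_labels=labels, gi=gi,
        gi_pass=gi_pass, p_pass=p_pass, n_passing=n_passing, status=status,
    )


def rank_resistant(
    gi_table: GITable, params: HitCallParams = HitCallParams()
) -> list[tuple[int, str, float, bool]]:
    """Rank strains by ascending GI (most enriched under treatment first).

    Returns (rank, gene_id, GI, flagged) rows; ties break by gene id; the
    flag marks GI <= resistant_flag_cutoff (inclusive, default -0.5).
    """
    defined = [(r.gi, r.gene_id) for r in gi_table.records if r.gi is not None]
    if not defined:
        raise ValueError("no defined GI values to rank")
    defined.sort(key=lambda t: (t[0], t[1]))
    return [
        (rank, gene, gi, gi <= params.resistant_flag_cutoff)
        for rank, (gi, gene) in enumerate(defined, start=1)
    ]


def write_resistant_tsv(ranking, path) -> None:
    lines = ["rank\tgene_id\tgi\tflagged"]
    for rank, gene, gi, flagged in ranking:
        lines.append(f"{rank}\t{gene}\t{gi:.6g}\t{int(flagged)}")
    Path(path).write_text("\n".join(lines) + "\n")
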