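"""Normalization, fold change, and growth-inhibition (GI) scoring.

Read counts are normalized to one million matched reads per tag class per
sample.  For each strain and tag class the normalized control-versus-
treatment fold change FC_g is formed at every sampled pool generation g (a
pseudocount of 1 on raw reads keeps FC finite and positive), and the GI
score is the generation-weighted average per-doubling log ratio

    GI = sum_g a_g * log2(FC_g) / g,        sum_g a_g = 1.

An unaffected strain tracks the pool (FC_g = 1, GI = 0); a fully arrested
strain is diluted two-fold per pool doubling (FC_g = 2**g, GI = 1); a strain
enriched under treatment scores negative.  Tags whose raw control reads fall
below a floor (12 by default) at any weighted generation are excluded as too
noisy; a strain's score is the mean of its defined tag scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .catalog import Catalog
from .demux import CountTable

__all__ = [
    "ScoringParams",
    "ExperimentDesign",
    "GIRecord",
    "GITable",
    "normalize",
    "compute_fc",
    "gi_score",
    "strain_gi",
    "score_experiment",
]

TAG_CLASSES = ("up", "dn")


@dataclass(frozen=True)
class ScoringParams:
    pseudocount: float = 1.0
    min_control_reads: int = 12
    normalization_total: float = 1_000_000.0

    def __post_init__(self):
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.min_control_reads < 0:
            raise ValueError("min_control_reads must be >= 0")
        if self.normalization_total <= 0:
            raise ValueError("normalization_total must be > 0")


@dataclass
class ExperimentDesign:
    """Which samples form one control-vs-treatment experiment.

    ``control_samples``/``treatment_samples`` map pool generation g to the
    sample label carrying that condition at that generation.  ``weights``
    assigns a_g per generation; weights must be nonnegative and sum to 1,
    and every positively weighted generation needs both samples.
    """

    control: str
    treatment: str
    control_samples: dict[float, str]
    treatment_samples: dict[float, str]
    weights: dict[float, float]
    replicate: str = "A"

    def __post_init__(self):
        total = sum(self.weights.values())
        if any(a < 0 for a in self.weights.values()):
            raise ValueError("weights must be >= 0")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {total}, expected 1")
        for g, a in self.weights.items():
            if a > 0 and (
                g not in self.control_samples or g not in self.treatment_samples
            ):
                raise ValueError(f"generation {g} weighted but lacks samples")

    @classmethod
    def single_timepoint(
        cls, control: str, treatment: str, g: float,
        control_sample: str, treatment_sample: str, replicate: str = "A",
    ) -> "ExperimentDesign":
        """The drug-treatment design: cells collected only after g doublings,
        so GI = log2(FC_g)/g."""
        return cls(
            control=control, treatment=treatment,
            control_samples={g: control_sample},
            treatment_samples={g: treatment_sample},
            weights={g: 1.0}, replicate=replicate,
        )

    def weighted_generations(self) -> list[float]:
        return sorted(g for g, a in self.weights.items() if a > 0)

    def final_generation(self) -> float:
        return max(self.weighted_generations())


@dataclass
class GIRecord:
    gene_id: str
    gi_up: Optional[float] = None
    gi_dn: Optional[float] = None
    gi: Optional[float] = None
    status: str = "ok"
    fc: dict = field(default_factory=dict)  # (tag_class, g) -> FC

    def tag_gi(self, tag_class: str) -> Optional[float]:
        return self.gi_up if tag_class == "up" else self.gi_dn


class GITable:
    """Per-strain GI records for one experiment, in catalog order."""

    def __init__(self, records: list[GIRecord], design: ExperimentDesign):
        self.records = records
        self.design = design
        self._by_gene = {r.gene_id: r for r in records}

    def __len__(self):
        return len(self.records)

    def __getitem__(self, gene_id: str) -> GIRecord:
        return self._by_gene[gene_id]

    def defined(self) -> list[GIRecord]:
        return [r for r in self.records if r.gi is not None]

    def gi_values(self) -> list[float]:
        return [r.gi for r in self.records if r.gi is not None]

    def write_tsv(self, path) -> None:
        gens = self.design.weighted_generations()
        cols = ["gene_id", "gi_up", "gi_dn", "gi", "status"]
        cols += [f"fc_{c}_g{g:g}" for c in TAG_CLASSES for g in gens]
        lines = ["\t".join(cols)]

        def fmt(x):
            return "NA" if x is None else f"{x:.6g}"

        for r in self.records:
            row = [r.gene_id, fmt(r.gi_up), fmt(r.gi_dn), fmt(r.gi), r.status]
            row += [fmt(r.fc.get((c, g))) for c in TAG_CLASSES for g in gens]
            lines.append("\t".join(row))
        Path(path).write_text("\n".join(lines) + "\n")


def normalize(
    table: CountTable, params: ScoringParams = ScoringParams()
) -> dict[str, dict[tuple[str, str], float]]:
    """Scale each sample's counts so each tag class totals one million reads.

    Returns sample -> {(gene_id, tag_class): normalized count}.  A tag class
    with zero matched reads cannot be normalized and raises, naming the
    sample and class.
    """
    out: dict[str, dict[tuple[str, str], float]] = {}
    for sample in table.samples():
        bucket = table.counts[sample]
        present_classes = {c for (_, c) in bucket}
        totals = {c: table.total(sample, c) for c in present_classes}
        for cls, tot in totals.items():
            if tot <= 0:
                raise ValueError(f"sample {sample}: zero matched {cls}-tag reads")
        out[sample] = {
            key: n * params.normalization_total / totals[key[1]]
            for key, n in bucket.items()
        }
    return out


def compute_fc(
    raw_control: float,
    raw_treatment: float,
    control_total: float,
    treatment_total: float,
    params: ScoringParams = ScoringParams(),
) -> float:
    """Normalized control/treatment fold change with pseudocount.

    Scale factors come from the raw (un-pseudocounted) tag-class totals; the
    pseudocount is added to the two counts only, guaranteeing FC > 0.
    """
    if control_total <= 0 or treatment_total <= 0:
        raise ValueError("tag-class totals must be > 0")
    s_c = params.normalization_total / control_total
    s_t = params.normalization_total / treatment_total
    return ((raw_control + params.pseudocount) * s_c) / (
        (raw_treatment + params.pseudocount) * s_t
    )


def gi_score(
    fc_by_generation: dict[float, float], weights: dict[float, float]
) -> Optional[float]:
    """GI = sum_g a_g * log2(FC_g) / g; None if a weighted FC is missing."""
    total = 0.0
    for g, a in weights.items():
        if a == 0:
            continue
        fc = fc_by_generation.get(g)
        if fc is None:
            return None
        total += a * math.log2(fc) / g
    return total


def strain_gi(
    gi_up: Optional[float], gi_dn: Optional[float]
) -> Optional[float]:
    """Combine the two tag scores: mean if both defined, the defined one if
    only one, None if neither."""
    defined = [v for v in (gi_up, gi_dn) if v is not None]
    if not defined:
        return None
    return sum(defined) / len(defined)


def score_experiment(
    counts: CountTable,
    catalog: Catalog,
    design: ExperimentDesign,
    params: ScoringParams = ScoringParams(),
) -> GITable:
    """Compute one GIRecord per catalogued strain for one experiment.

    Per strain and tag class: the tag is skipped if the barcode is ambiguous
    or absent; it is excluded (flag ``insufficient_control_reads``) if any
    weighted generation's raw control count falls below
    ``params.min_control_reads``; otherwise FC_g and the tag GI are computed
    and the strain score is the tag average.
    """
    gens = design.weighted_generations()
    for g in gens:
        for cond, mapping in (
            (design.control, design.control_samples),
            (design.treatment, design.treatment_samples),
        ):
            if mapping[g] not in counts.counts:
                raise ValueError(
                    f"design references missing sample {mapping[g]!r} "
                    f"({cond}, g={g:g})"
                )
    totals = {
        (sample, cls): counts.total(sample, cls)
        for g in gens
        for sample in (design.control_samples[g], design.treatment_samples[g])
        for cls in TAG_CLASSES
    }
    records = []
    for rec in catalog.records:
        usable = {cls for cls, seq in rec.tags() if seq in catalog.lookup}
        gi_by_class: dict[str, Optional[float]] = {}
        fc_store: dict = {}
        low_control = False
        for cls in TAG_CLASSES:
            if cls not in usable:
                continue
            fc_by_g: dict[float, float] = {}
            ok = True
            for g in gens:
                c_sample = design.control_samples[g]
                t_sample = design.treatment_samples[g]
                raw_c = counts.get(c_sample, rec.gene_id, cls)
                raw_t = counts.get(t_sample, rec.gene_id, cls)
                if raw_c < params.min_control_reads:
                    ok = False
                    low_control = True
                    break
                fc = compute_fc(
                    raw_c, raw_t, totals[(c_sample, cls)], totals[(t_sample, cls)],
                    params,
                )
                fc_by_g[g] = fc
                fc_store[(cls, g)] = fc
            if ok:
                gi_by_class[cls] = gi_score(fc_by_g, design.weights)
        gi_up = gi_by_class.get("up")
        gi_dn = gi_by_class.get("dn")
        combined = strain_gi(gi_up, gi_dn)
        if not usable:
            status = "no_barcode"
        elif combined is None:
            status = "insufficient_control_reads" if low_control else "no_barcode"
        elif low_control:
            status = "insufficient_control_reads"  # one tag dropped, one kept
        else:
            status = "ok"
        records.append(
            GIRecord(
                gene_id=rec.gene_id, gi_up=gi_up, gi_dn=gi_dn,
                gi=combined, status=status, fc=fc_store,
            )
        )
    return GITable(records, design)
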