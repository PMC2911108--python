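"""Multiplex index design and read-to-count demultiplexing.

Each 42-nt read is laid out as a 4-nt sample index (cycles 1-4), an 18-nt
universal primer identifying the tag class (cycles 5-22), and the 20-nt
strain barcode (cycles 23-42).  Matching is three-step: the index must match
a sample exactly; the primer region may carry at most two mismatches to one
of the two universal primers; the barcode must match the catalog exactly.
Sample indexes form a Hamming-distance->=2 code so a single sequencing error
in the index can never silently reassign a read to another sample.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .catalog import Catalog

__all__ = [
    "ReadLayout",
    "IndexSet",
    "CountTable",
    "DISCARD_REASONS",
    "design_indexes",
    "validate_indexes",
    "assign_read",
    "count_reads",
]

UP_PRIMER = "GAGGCAAGCTAAGATATC"
DN_PRIMER = "CCAGTGTCGAAAAGTATC"

DISCARD_REASONS = (
    "unknown_index",
    "primer_fail",
    "barcode_unmatched",
    "ambiguous_barcode",
    "malformed",
)


@dataclass(frozen=True)
class ReadLayout:
    """Fixed coordinates of the 42-cycle read (0-based half-open internally;
    cycle k maps to position k-1)."""

    index_len: int = 4
    primer_len: int = 18
    barcode_len: int = 20
    up_primer: str = UP_PRIMER
    dn_primer: str = DN_PRIMER
    max_primer_mismatch: int = 2

    def __post_init__(self):
        if len(self.up_primer) != self.primer_len or len(self.dn_primer) != self.primer_len:
            raise ValueError("primer length inconsistent with layout")

    @property
    def read_len(self) -> int:
        return self.index_len + self.primer_len + self.barcode_len


@dataclass
class IndexSet:
    """Ordered sample-index assignment with a pairwise distance >=2 guarantee."""

    indexes: list[str]
    samples: list[str]

    def __post_init__(self):
        if len(self.indexes) != len(self.samples):
            raise ValueError("one sample label per index required")
        if len(set(self.indexes)) != len(self.indexes):
            raise ValueError("duplicate indexes")
        if len(self.indexes) > 1 and validate_indexes(self.indexes) < 2:
            raise ValueError("index set has pairwise Hamming distance < 2")
        self._by_index = dict(zip(self.indexes, self.samples))

    def sample_of(self, index: str) -> Optional[str]:
        return self._by_index.get(index)

    def write_tsv(self, path) -> None:
        lines = ["sample\tindex"]
        lines += [f"{s}\t{i}" for s, i in zip(self.samples, self.indexes)]
        Path(path).write_text("\n".join(lines) + "\n")


class CountTable:
    """Per-sample read counts keyed by (gene_id, tag_class), plus discard
    counters.  Conservation holds by construction: every processed read either
    increments one assigned count or one discard counter."""

    def __init__(self):
        self.counts: dict[str, dict[tuple[str, str], int]] = {}
        self.discards: dict[str, dict[str, int]] = {}

    def _sample(self, sample: str) -> dict[tuple[str, str], int]:
        if sample not in self.counts:
            self.counts[sample] = {}
            self.discards[sample] = {r: 0 for r in DISCARD_REASONS}
        return self.counts[sample]

    def add(self, sample: str, gene_id: str, tag_class: str, n: int = 1) -> None:
        if n < 0:
            raise ValueError("counts must be nonnegative")
        bucket = self._sample(sample)
        bucket[(gene_id, tag_class)] = bucket.get((gene_id, tag_class), 0) + n

    def discard(self, sample: str, reason: str, n: int = 1) -> None:
        self._sample(sample)
        self.discards[sample][reason] += n

    def samples(self) -> list[str]:
        return sorted(self.counts)

    def get(self, sample: str, gene_id: str, tag_class: str) -> int:
        return self.counts.get(sample, {}).get((gene_id, tag_class), 0)

    def total(self, sample: str, tag_class: Optional[str] = None) -> int:
        bucket = self.counts.get(sample, {})
        return sum(
            n for (g, c), n in bucket.items() if tag_class is None or c == tag_class
        )

    def total_discarded(self, sample: str) -> int:
        return sum(self.discards.get(sample, {}).values())

    def write_tsv(self, path) -> None:
        lines = ["sample\tgene_id\ttag_class\tcount"]
        for sample in self.samples():
            for (gene, cls), n in sorted(self.counts[sample].items()):
                lines.append(f"{sample}\t{gene}\t{cls}\t{n}")
        Path(path).write_text("\n".join(lines) + "\n")

    def write_discard_tsv(self, path) -> None:
        lines = ["sample\treason\tcount"]
        for sample in sorted(self.discards):
            for reason in DISCARD_REASONS:
                lines.append(f"{sample}\t{reason}\t{self.discards[sample][reason]}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_tsv(cls, path) -> "CountTable":
        table = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("sample\t"):
                raise ValueError(f"{path}: not a count TSV")
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                sample, gene, tag_class, n = line.rstrip("\n").split("\t")
                table.add(sample, gene, tag_class, int(n))
        return table


def design_indexes(n: int, samples: Optional[list[str]] = None) -> IndexSet:
    """Deterministically pick ``n`` 4-mers with pairwise Hamming distance >= 2.

    Uses the parity code {x : sum of base digits == 0 mod 4}, a perfect
    distance-2 quaternary code of size 64 (the maximum: any 65 4-mers must
    contain a pair at distance 1).  The first ``n`` members in lexicographic
    A<C<G<T order are returned.
    """
    if not 1 <= n <= 64:
        raise ValueError(f"cannot design {n} indexes: 1 <= n <= 64 required")
    alphabet = "ACGT"
    code = [
        "".join(alphabet[d] for d in digits)
        for digits in product(range(4), repeat=4)
        if sum(digits) % 4 == 0
    ]
    indexes = code[:n]
    if samples is None:
        samples = [f"S{i + 1}" for i in range(n)]
    return IndexSet(indexes=indexes, samples=samples)


def validate_indexes(indexes: list[str]) -> int:
    """Exact minimum pairwise Hamming distance; 0 for duplicates."""
    if len(indexes) < 2:
        raise ValueError("need at least two indexes")
    if len({len(i) for i in indexes}) != 1:
        raise ValueError("indexes must share one length")
    best = len(indexes[0])
    for i, a in enumerate(indexes):
        for b in indexes[i + 1 :]:
            d = sum(x != y for x, y in zip(a, b))
            best = min(best, d)
    return best


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def assign_read(
    seq: str,
    indexes: IndexSet,
    layout: ReadLayout,
    catalog: Catalog,
) -> Union[tuple[str, str, str], str]:
    """Classify one read; returns (sample, gene_id, tag_class) or a discard
    reason from ``DISCARD_REASONS``.  Pure function of its inputs."""
    if len(seq) < layout.read_len:
        return "malformed"
    seq = seq.upper()
    index = seq[: layout.index_len]
    sample = indexes.sample_of(index)
    if sample is None:
        return "unknown_index"
    primer_region = seq[layout.index_len : layout.index_len + layout.primer_len]
    d_up = _hamming(primer_region, layout.up_primer)
    d_dn = _hamming(primer_region, layout.dn_primer)
    best = min(d_up, d_dn)
    if best > layout.max_primer_mismatch or d_up == d_dn:
        # tie branch is defensive: the two primers differ at >4 positions,
        # so <=2-mismatch matches are mutually exclusive
        return "primer_fail"
    tag_class = "up" if d_up < d_dn else "dn"
    barcode = seq[layout.index_len + layout.primer_len : layout.read_len]
    if barcode in catalog.ambiguous:
        return "ambiguous_barcode"
    hit = catalog.lookup.get(barcode)
    if hit is None:
        return "barcode_unmatched"
    gene_id, catalog_class = hit
    if catalog_class != tag_class:
        # primer says one tag class, catalog the other: cannot be this strain's read
        return "barcode_unmatched"
    return sample, gene_id, tag_class


def _open_fastq(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def count_reads(
    fastq_paths: Iterable,
    indexes: IndexSet,
    layout: ReadLayout,
    catalog: Catalog,
) -> CountTable:
    """Aggregate assign_read over FASTQ files (plain or gzip) into a CountTable.

    Reads failing before sample assignment (unknown index, malformed) are
    tallied under the pseudo-sample ``_unassigned`` so that
    assigned + discarded == processed holds over the whole batch.
    """
    table = CountTable()
    for sample in indexes.samples:
        table._sample(sample)  # materialize all samples even if empty
    table._sample("_unassigned")
    for path in fastq_paths:
        with _open_fastq(path) as fh:
            try:
                for _title, seq, _qual in FastqGeneralIterator(fh):
                    result = assign_read(seq, indexes, layout, catalog)
                    if isinstance(result, tuple):
                        table.add(*result)
                    elif result in ("unknown_index", "malformed"):
                        table.discard("_unassigned", result)
                    else:
                        sample = indexes.sample_of(seq[: layout.index_len].upper())
                        table.discard(sample, result)
            except ValueError as exc:
                raise ValueError(f"{path}: invalid FASTQ: {exc}") from exc
    return table
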