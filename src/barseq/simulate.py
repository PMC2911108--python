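"""Pooled-growth and sequencing simulator.

Models a barcoded deletion pool under competitive exponential growth: a pool
"generation" is one doubling of total culture mass, and a strain with
relative fitness f completes f doublings per pool doubling, so its abundance
fraction evolves as

    p_i(g) = p_i(0) * 2**(f_i * g) / sum_j p_j(0) * 2**(f_j * g).

Wild-type growth is f = 1; f = 0 emulates a fully arrested strain whose cell
number never increases; f > 1 a growth advantage.  Sequencing is a
multinomial draw per tag class at a configured depth, with an optional
per-barcode log-normal amplification bias (drawn once, shared by all samples,
as PCR efficiency differences are) and per-base substitution errors applied
at FASTQ emission.  Spike-in strains carrying barcodes absent from the
catalog can be injected at known cell ratios to probe quantification
linearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .demux import CountTable, ReadLayout

__all__ = [
    "FitnessProfile",
    "SimConfig",
    "simulate_abundances",
    "simulate_counts",
    "inject_spikeins",
    "emit_fastq",
    "initial_abundances",
    "tag_bias",
    "barcode_map",
    "random_catalog",
    "simulate_pool_counts",
]


@dataclass
class FitnessProfile:
    """Ground-truth relative fitness per strain per condition (dimensionless,
    >= 0; wild type = 1)."""

    strains: list[str]
    fitness: dict[str, np.ndarray]  # condition -> per-strain f

    def __post_init__(self):
        n = len(self.strains)
        for cond, f in self.fitness.items():
            f = np.asarray(f, dtype=float)
            if f.shape != (n,):
                raise ValueError(f"{cond}: fitness length != number of strains")
            if np.any(f < 0) or not np.all(np.isfinite(f)):
                raise ValueError(f"{cond}: fitness must be finite and >= 0")
            self.fitness[cond] = f

    @classmethod
    def uniform(cls, strains: list[str], conditions: list[str]) -> "FitnessProfile":
        return cls(strains, {c: np.ones(len(strains)) for c in conditions})

    def set_fitness(self, condition: str, strain: str, f: float) -> None:
        self.fitness[condition][self.strains.index(strain)] = f


@dataclass
class SimConfig:
    """Simulation conditions.

    depth is reads per tag class per sample (the study sequences each barcode
    class to ~1e6 reads); spike_ins are (uptag, dntag, cell ratio) triples
    with ratios in (0, 1).
    """

    n_strains: int = 2500
    abundance_sigma: float = 1.0  # log-normal sigma of initial pool dispersion
    generations: tuple = (3, 4, 5)
    depth: int = 1_000_000
    tag_bias_sigma: float = 0.5  # log-normal sigma of per-barcode PCR bias
    error_rate: float = 0.0
    seed: int = 0
    spike_ins: list = field(default_factory=list)

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        for up, dn, ratio in self.spike_ins:
            if not 0 < ratio < 1:
                raise ValueError(f"spike-in ratio {ratio} outside (0, 1)")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def initial_abundances(config: SimConfig, rng=None) -> np.ndarray:
    """Draw initial pool fractions from a log-normal and normalize to 1."""
    rng = rng or config.rng(stream=1)
    raw = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=config.n_strains)
    return raw / raw.sum()


def tag_bias(config: SimConfig, n: int, rng=None) -> np.ndarray:
    """Per-barcode multiplicative amplification weights, drawn once."""
    rng = rng or config.rng(stream=2)
    if config.tag_bias_sigma == 0:
        return np.ones(n)
    return rng.lognormal(mean=0.0, sigma=config.tag_bias_sigma, size=n)


def simulate_abundances(
    p0: np.ndarray, fitness: np.ndarray, g: float
) -> np.ndarray:
    """Abundance fractions after g pool doublings of competitive growth."""
    p0 = np.asarray(p0, dtype=float)
    f = np.asarray(fitness, dtype=float)
    if g < 0:
        raise ValueError("generations must be >= 0")
    growth = p0 * np.exp2(f * g)
    total = growth.sum()
    if total <= 0:
        raise ValueError("empty pool: no strain has positive abundance")
    return growth / total


def simulate_counts(
    abundances: np.ndarray,
    depth: int,
    bias: dict[str, np.ndarray],
    strains: list[str],
    sample: str,
    rng: np.random.Generator,
) -> CountTable:
    """One sequencing sample: an independent multinomial draw of ``depth``
    reads per tag class, with probabilities proportional to abundance times
    the class's per-barcode bias weight."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    abundances = np.asarray(abundances, dtype=float)
    if abs(abundances.sum() - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1")
    table = CountTable()
    table._sample(sample)
    for tag_class in ("up", "dn"):
        w = abundances * bias[tag_class]
        probs = w / w.sum()
        counts = rng.multinomial(depth, probs)
        for strain, n in zip(strains, counts):
            if n:
                table.add(sample, strain, tag_class, int(n))
    return table


def inject_spikeins(
    table: CountTable,
    spike_ins: list,
    rng: np.random.Generator,
    sample: str | None = None,
) -> CountTable:
    """Add spike-in reads on top of library reads.

    A spike-in at cell ratio r (relative to total cells including all
    spike-ins) contributes reads in expectation r/(1 - sum of ratios) times
    the library read count, sampled binomially per tag class.  Library counts
    are left untouched.
    """
    if not spike_ins:
        return table
    total_ratio = sum(r for _, _, r in spike_ins)
    if total_ratio >= 1:
        raise ValueError("spike-in ratios sum to >= 1")
    samples = [sample] if sample is not None else table.samples()
    for smp in samples:
        for i, (up, dn, ratio) in enumerate(spike_ins):
            p = ratio / (1.0 - total_ratio)
            for tag_class in ("up", "dn"):
                n_lib = table.total(smp, tag_class)
                n_spike = int(rng.binomial(n_lib, p)) if n_lib > 0 else 0
                if n_spike:
                    table.add(smp, f"spikein_{i + 1}", tag_class, n_spike)
    return table


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _apply_errors(seq_matrix: np.ndarray, error_rate: float, rng) -> np.ndarray:
    """Substitute each base independently with probability error_rate,
    uniformly over the three alternative bases."""
    if error_rate == 0:
        return seq_matrix
    mask = rng.random(seq_matrix.shape) < error_rate
    n_err = int(mask.sum())
    if n_err == 0:
        return seq_matrix
    # shift by 1..3 positions in the ACGT cycle: never the original base
    base_idx = np.searchsorted(_BASES, seq_matrix[mask])
    shifted = (base_idx + rng.integers(1, 4, size=n_err)) % 4
    seq_matrix = seq_matrix.copy()
    seq_matrix[mask] = _BASES[shifted]
    return seq_matrix


def emit_fastq(
    table: CountTable,
    sample: str,
    layout: ReadLayout,
    index: str,
    barcodes: dict[tuple[str, str], str],
    error_rate: float,
    rng: np.random.Generator,
    path,
) -> int:
    """Write one read per count as 42-nt FASTQ records and return the number
    written.

    Each read is index + tag-class universal primer + barcode; substitution
    errors are applied per base; quality is a constant 'I' string (the
    pipeline never reads qualities); read order is shuffled by the generator.
    """
    if len(index) != layout.index_len:
        raise ValueError(f"index {index!r} is not a {layout.index_len}-mer")
    primers = {"up": layout.up_primer, "dn": layout.dn_primer}
    templates: list[bytes] = []
    mults: list[int] = []
    for (gene, tag_class), n in sorted(table.counts.get(sample, {}).items()):
        if n == 0:
            continue
        barcode = barcodes.get((gene, tag_class))
        if barcode is None:
            raise ValueError(f"no barcode sequence for ({gene}, {tag_class})")
        templates.append((index + primers[tag_class] + barcode).encode())
        mults.append(n)
    n_reads = int(sum(mults))
    path = Path(path)
    if n_reads == 0:
        path.write_text("")
        return 0
    matrix = np.frombuffer(b"".join(templates), dtype=np.uint8).reshape(
        len(templates), layout.read_len
    )
    reads = np.repeat(matrix, mults, axis=0)
    reads = _apply_errors(reads, error_rate, rng)
    order = rng.permutation(n_reads)
    reads = reads[order]
    qual = "I" * layout.read_len
    with open(path, "w") as fh:
        for i in range(n_reads):
            fh.write(
                f"@{sample}_read{i}\n{reads[i].tobytes().decode()}\n+\n{qual}\n"
            )
    return n_reads


def barcode_map(catalog) -> dict[tuple[str, str], str]:
    """(gene_id, tag_class) -> barcode sequence, from unambiguous catalog entries."""
    return {assoc: seq for seq, assoc in catalog.lookup.items()}


def random_catalog(n_strains: int, rng: np.random.Generator):
    """A synthetic strain catalog with distinct random 20-nt up/dn tags,
    gene ids gene0001.. and row-major 96-well positions."""
    from .catalog import Catalog, StrainRecord

    needed = 2 * n_strains
    seen: set[str] = set()
    tags: list[str] = []
    while len(tags) < needed:
        draw = rng.integers(0, 4, size=(needed, 20))
        for row in draw:
            seq = "".join("ACGT"[d] for d in row)
            if seq not in seen:
                seen.add(seq)
                tags.append(seq)
                if len(tags) == needed:
                    break
    records = []
    for i in range(n_strains):
        plate, rem = divmod(i, 96)
        row, col = divmod(rem, 12)
        records.append(
            StrainRecord(
                gene_id=f"gene{i + 1:04d}",
                well_position=f"P{plate + 1}-{'ABCDEFGH'[row]}{col + 1:02d}",
                position_flag="OK",
                uptag=tags[2 * i],
                dntag=tags[2 * i + 1],
            )
        )
    return Catalog.from_records(records)


def simulate_pool_counts(
    config: SimConfig,
    fitness: FitnessProfile,
    conditions: list[str],
) -> CountTable:
    """Counts-level simulation of a whole experiment.

    One initial pool is drawn, grown under each condition's fitness vector,
    and sequenced (multinomial per tag class, shared per-barcode bias) at
    every generation in ``config.generations``; samples are named
    ``{condition}_g{g}``.  Spike-ins from the config are injected into every
    sample.
    """
    p0 = initial_abundances(config)
    bias = {
        "up": tag_bias(config, config.n_strains, rng=config.rng(stream=2)),
        "dn": tag_bias(config, config.n_strains, rng=config.rng(stream=3)),
    }
    rng = config.rng(stream=4)
    table = CountTable()
    for cond in conditions:
        f = fitness.fitness[cond]
        for g in config.generations:
            sample = f"{cond}_g{g:g}"
            p = simulate_abundances(p0, f, g)
            one = simulate_counts(
                p, config.depth, bias, fitness.strains, sample, rng
            )
            for key, n in one.counts[sample].items():
                table.add(sample, key[0], key[1], n)
    if config.spike_ins:
        inject_spikeins(table, config.spike_ins, config.rng(stream=5))
    return table
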