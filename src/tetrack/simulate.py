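"""Synthetic genomes, TE families and dated sample series with known truth.

The generator emulates the statistical structure that the downstream
analysis assumes:

* a TE family has a *consensus* (the active, recently invading element) and
  a *degraded ancestor* — a single anciently diverged variant of the
  consensus (default 8% substitution divergence) from which all degraded
  copies descend.  Sharing one ancestor is what creates family-level
  diagnostic alleles: every degraded copy carries the ancestor's private
  substitutions, while canonical copies carry the consensus allele.
* canonical copies are consensus plus a little private noise (default 0.5%),
  staying below the 1.5% canonical/degraded classification boundary;
  degraded copies are the ancestor plus the same level of private noise and
  stay above it.
* old samples carry only degraded copies; young samples additionally carry
  canonical copies at a controllable population fraction.

Reads are single-end, uniformly positioned, with i.i.d. per-base
substitution errors.  All outputs are bit-identical for a fixed config and
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .seqio import Read, revcomp

BASES = np.array(list("ACGT"))

CANONICAL_BOUNDARY = 0.015  # divergence boundary between canonical and degraded copies

RngLike = Union[int, np.random.Generator]


def as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimConfig:
    """Study conditions for the synthetic data generator.

    Defaults mirror the scale of the real study: a ~3 kb DNA transposon,
    short reads at 20-fold depth, canonical copies at 0.5% divergence and
    degraded copies derived from an 8% diverged ancestor.
    """

    seed: int = 0
    genome_length: int = 100_000
    te_length: int = 3_000
    n_canonical: int = 5
    n_degraded: int = 3
    canonical_divergence: float = 0.005
    degraded_divergence: float = 0.08
    read_length: int = 100
    depth: float = 20.0
    error_rate: float = 0.002
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.canonical_divergence <= CANONICAL_BOUNDARY):
            raise ValueError("canonical_divergence must lie in [0, 0.015]")
        if self.degraded_divergence <= CANONICAL_BOUNDARY:
            raise ValueError("degraded_divergence must exceed 0.015")
        for name in ("genome_length", "te_length", "n_canonical", "n_degraded", "read_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("error_rate", "indel_rate"):
            if not (0 <= getattr(self, name) < 1):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass(frozen=True)
class TruthInsertion:
    contig: str
    start: int  # 0-based inclusive, coordinates of the final assembly
    end: int  # exclusive
    te_id: str
    is_canonical: bool
    divergence: float  # realized substitution divergence from the consensus


@dataclass
class SimTruth:
    insertions: List[TruthInsertion] = field(default_factory=list)
    invasion_date: Optional[float] = None
    canonical_fraction: Dict[str, float] = field(default_factory=dict)  # sample id -> fraction


def random_sequence(length: int, rng: RngLike) -> str:
    return "".join(as_rng(rng).choice(BASES, size=length))


def make_te_family(length: int, seed: RngLike) -> str:
    """A uniformly random TE consensus sequence of exactly ``length`` bases."""
    if length < 100:
        raise ValueError("TE consensus must be at least 100 bp to anchor alignments")
    return random_sequence(length, seed)


def mutate_sequence(
    seq: str,
    divergence: float,
    indel_rate: float = 0.0,
    seed: RngLike = 0,
) -> Tuple[str, float]:
    """Mutate a sequence by i.i.d. substitutions and optional indels.

    Each position is substituted to a *different* base with probability
    ``divergence``; afterwards single-base insertions/deletions occur at
    ``indel_rate`` per position (half insertions, half deletions).  Returns
    the mutated sequence and the realized substitution fraction
    (substitutions / original length).
    """
    if not (0 <= divergence < 0.75):
        raise ValueError("divergence must lie in [0, 0.75)")
    if not (0 <= indel_rate < 1):
        raise ValueError("indel_rate must lie in [0, 1)")
    rng = as_rng(seed)
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < divergence
    n_sub = int(hit.sum())
    if n_sub:
        # draw a uniformly chosen different base at each hit site
        shift = rng.integers(1, 4, size=n_sub)
        base_idx = np.searchsorted(BASES, arr[hit])
        arr[hit] = BASES[(base_idx + shift) % 4]
    out = arr.tolist()
    if indel_rate > 0:
        result: List[str] = []
        for ch in out:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            result.append(ch)
            if indel_rate / 2 <= r < indel_rate:
                result.append(str(rng.choice(BASES)))  # insertion after this base
        out = result
    return "".join(out), (n_sub / len(seq) if seq else 0.0)


def _hamming_fraction(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b)) / len(a)


@dataclass
class TEFamily:
    """A TE consensus together with its anciently diverged degraded ancestor."""

    te_id: str
    consensus: str
    degraded_ancestor: str
    ancestor_divergence: float

    @classmethod
    def generate(
        cls,
        te_id: str,
        te_length: int,
        degraded_divergence: float,
        seed: RngLike,
    ) -> "TEFamily":
        rng = as_rng(seed)
        consensus = make_te_family(te_length, rng)
        # ancestor is substitution-only so truth divergence stays a Hamming fraction
        ancestor, realized = mutate_sequence(consensus, degraded_divergence, 0.0, rng)
        return cls(te_id, consensus, ancestor, realized)

    def draw_canonical(self, noise: float, rng: np.random.Generator, indel_rate: float = 0.0,
                       max_tries: int = 100) -> Tuple[str, float]:
        """A fresh canonical copy: consensus + private noise, below the 1.5% boundary."""
        for _ in range(max_tries):
            seq, realized = mutate_sequence(self.consensus, noise, indel_rate, rng)
            if realized <= CANONICAL_BOUNDARY:
                return seq, realized
        raise RuntimeError("could not draw a canonical copy below the divergence boundary")

    def draw_degraded(self, noise: float, rng: np.random.Generator,
                      max_tries: int = 100) -> Tuple[str, float]:
        """A fresh degraded copy: ancestor + private noise, above the 1.5% boundary."""
        for _ in range(max_tries):
            seq, _ = mutate_sequence(self.degraded_ancestor, noise, 0.0, rng)
            realized = _hamming_fraction(self.consensus, seq)
            if realized > CANONICAL_BOUNDARY:
                return seq, realized
        raise RuntimeError("could not draw a degraded copy above the divergence boundary")


def build_strain_genome(
    base: Dict[str, str],
    insert_spec: Sequence[Tuple[str, bool, int]],
    te_library: Mapping[str, TEFamily],
    config: SimConfig,
    seed: RngLike,
    min_separation: Optional[int] = None,
    end_margin: Optional[int] = None,
    max_tries: int = 1000,
) -> Tuple[Dict[str, str], SimTruth]:
    """Insert TE copies into a base assembly at non-overlapping positions.

    ``insert_spec`` lists (te_id, is_canonical, count).  Insertion points are
    uniform over the base assembly, kept ``min_separation`` apart (default
    2 x read length + 300 bp, so that coverage gaps of neighbouring
    insertions stay distinct) and ``end_margin`` away from contig ends.
    Truth coordinates are 0-based half-open in the *returned* assembly.
    """
    rng = as_rng(seed)
    if min_separation is None:
        min_separation = 2 * config.read_length + 300
    if end_margin is None:
        end_margin = config.read_length + 100
    total = sum(count for _, _, count in insert_spec)
    # choose insertion points in base coordinates
    contigs = list(base)
    lengths = np.array([len(base[c]) for c in contigs], dtype=float)
    usable = lengths - 2 * end_margin
    if total and (usable <= 0).all():
        raise ValueError("base contigs too short to host insertions")
    chosen: List[Tuple[str, int]] = []
    tries = 0
    while len(chosen) < total:
        tries += 1
        if tries > max_tries * max(1, total):
            raise ValueError("could not place insertions without overlap; base too small")
        ci = int(rng.choice(len(contigs), p=np.clip(usable, 0, None) / np.clip(usable, 0, None).sum()))
        contig = contigs[ci]
        pos = int(rng.integers(end_margin, len(base[contig]) - end_margin))
        if all(c != contig or abs(p - pos) >= min_separation for c, p in chosen):
            chosen.append((contig, pos))
    # draw copy sequences in spec order, assign to points in order drawn
    copies: List[Tuple[str, bool, str, float]] = []
    for te_id, is_canonical, count in insert_spec:
        family = te_library[te_id]
        for _ in range(count):
            if is_canonical:
                seq, realized = family.draw_canonical(
                    config.canonical_divergence, rng, config.indel_rate
                )
            else:
                seq, realized = family.draw_degraded(config.canonical_divergence, rng)
            copies.append((te_id, is_canonical, seq, realized))
    # splice copies into contigs, tracking final coordinates
    per_contig: Dict[str, List[Tuple[int, Tuple[str, bool, str, float]]]] = {c: [] for c in contigs}
    for (contig, pos), copy in zip(chosen, copies):
        per_contig[contig].append((pos, copy))
    assembly: Dict[str, str] = {}
    truth = SimTruth()
    for contig in contigs:
        pieces: List[str] = []
        cursor = 0
        offset = 0
        for pos, (te_id, is_canonical, seq, realized) in sorted(per_contig[contig], key=lambda t: t[0]):
            pieces.append(base[contig][cursor:pos])
            truth.insertions.append(
                TruthInsertion(contig, pos + offset, pos + offset + len(seq), te_id, is_canonical, realized)
            )
            pieces.append(seq)
            offset += len(seq)
            cursor = pos
        pieces.append(base[contig][cursor:])
        assembly[contig] = "".join(pieces)
    return assembly, truth


def simulate_reads(genome: Dict[str, str], config: SimConfig, seed: RngLike) -> List[Read]:
    """Uniformly positioned single-end reads with i.i.d. substitution errors.

    The number of reads is ``round(depth * genome_length / read_length)``;
    half the reads are reverse-strand (emitted as reverse complements).
    """
    rng = as_rng(seed)
    L = config.read_length
    contigs = list(genome)
    shortest = min(len(genome[c]) for c in contigs)
    if L > shortest:
        raise ValueError("read_length exceeds the shortest contig")
    total = sum(len(genome[c]) for c in contigs)
    n_reads = round(config.depth * total / L)
    n_starts = np.array([len(genome[c]) - L + 1 for c in contigs], dtype=float)
    contig_idx = rng.choice(len(contigs), size=n_reads, p=n_starts / n_starts.sum())
    reads: List[Read] = []
    n_err = rng.binomial(L, config.error_rate, size=n_reads)
    flip = rng.random(n_reads) < 0.5
    for i in range(n_reads):
        contig = contigs[contig_idx[i]]
        start = int(rng.integers(0, len(genome[contig]) - L + 1))
        seq = genome[contig][start : start + L]
        if n_err[i]:
            arr = np.array(list(seq))
            pos = rng.choice(L, size=n_err[i], replace=False)
            shift = rng.integers(1, 4, size=n_err[i])
            base_idx = np.searchsorted(BASES, arr[pos])
            arr[pos] = BASES[(base_idx + shift) % 4]
            seq = "".join(arr)
        if flip[i]:
            seq = revcomp(seq)
        reads.append(Read(f"read_{contig}_{start}_{i}", seq))
    return reads


# ---------------------------------------------------------------------------
# dated sample series


@dataclass
class SamplePointInputs:
    """Raw material for one dated, located sample: its pooled read set."""

    sample_id: str
    date: float
    region: str
    reads: List[Read]
    true_fraction: float  # realized canonical fraction among TE copies
    n_canonical: int
    n_degraded: int


@dataclass
class InvasionSeries:
    family: TEFamily
    genes: Dict[str, str]  # single-copy normalizer genes
    samples: List[SamplePointInputs]
    truth: SimTruth


def _copy_counts(fraction: float, n_degraded: int, cap: int = 30) -> Tuple[int, int]:
    """Canonical/degraded copy counts realizing a target canonical fraction.

    Degraded copies are always present (remnants of the ancient invasion);
    the canonical count is chosen so canonical/(canonical+degraded) is as
    close to the target as the integer counts allow, capped at ``cap``.
    """
    n_d = max(1, n_degraded)
    if fraction <= 0:
        return 0, n_d
    if fraction >= 1:
        return cap, n_d
    return min(cap, round(fraction * n_d / (1 - fraction))), n_d


def draw_degraded_loci(family: TEFamily, n: int, noise: float, seed: RngLike) -> List[str]:
    """The family's ancient, population-fixed degraded insertion loci.

    Degraded insertions predate every sample, so their sequences (ancestor
    plus the locus's own mutations) are identical in all samples of a
    population; they are drawn once per family and shared.
    """
    rng = as_rng(seed)
    return [family.draw_degraded(noise, rng)[0] for _ in range(max(1, n))]


def simulate_pooled_sample(
    family: TEFamily,
    genes: Dict[str, str],
    config: SimConfig,
    canonical_fraction: float,
    seed: RngLike,
    sample_id: str = "pool",
    date: float = 0.0,
    region: str = "pop",
    degraded_loci: Optional[List[str]] = None,
) -> SamplePointInputs:
    """One pooled sample: reads over genes, neutral background and TE copies.

    The sample's haploid genomes all share the same copy composition, so the
    realized canonical fraction is deterministic.  Canonical copies are
    recent insertions and are drawn fresh per sample; degraded copies are
    ancient fixed loci — pass ``degraded_loci`` (see
    :func:`draw_degraded_loci`) to share them across the samples of a
    population, as in real data.
    """
    rng = as_rng(seed)
    n_c, n_d = _copy_counts(canonical_fraction, config.n_degraded)
    if degraded_loci is None:
        degraded_loci = draw_degraded_loci(family, n_d, config.canonical_divergence, rng)
    n_d = len(degraded_loci)
    segments: Dict[str, str] = dict(genes)
    if config.genome_length >= config.read_length:
        segments["background"] = random_sequence(config.genome_length, rng)
    for i in range(n_c):
        segments[f"can_{i}"], _ = family.draw_canonical(config.canonical_divergence, rng)
    for i, locus in enumerate(degraded_loci):
        segments[f"deg_{i}"] = locus
    reads = simulate_reads(segments, config, rng)
    realized = n_c / (n_c + n_d)
    return SamplePointInputs(sample_id, date, region, reads, realized, n_c, n_d)


def make_single_copy_genes(
    n_genes: int = 3, gene_length: int = 2000, seed: RngLike = 0
) -> Dict[str, str]:
    rng = as_rng(seed)
    return {f"gene_{i}": random_sequence(gene_length, rng) for i in range(n_genes)}


def simulate_invasion_series(
    config: SimConfig,
    dates: Sequence[float],
    trajectory: Mapping[float, float],
    region: str = "pop",
    family: Optional[TEFamily] = None,
    genes: Optional[Dict[str, str]] = None,
    degraded_loci: Optional[List[str]] = None,
) -> InvasionSeries:
    """Dated pooled samples following a canonical-fraction trajectory.

    ``trajectory`` maps each date to the target canonical fraction (values
    in [0, 1], non-decreasing over time).  Degraded copies are present at
    every date; canonical copies only at dates with fraction > 0.  The truth
    invasion date is the earliest date with a positive fraction.
    """
    rng = as_rng(config.seed)
    fracs = [trajectory[d] for d in dates]
    if any(not (0 <= f <= 1) for f in fracs):
        raise ValueError("trajectory fractions must lie in [0, 1]")
    order = np.argsort(dates)
    if any(fracs[order[i]] > fracs[order[i + 1]] for i in range(len(dates) - 1)):
        raise ValueError("trajectory must be non-decreasing in time")
    if family is None:
        family = TEFamily.generate("te1", config.te_length, config.degraded_divergence, rng)
    if genes is None:
        genes = make_single_copy_genes(seed=rng)
    if degraded_loci is None:
        degraded_loci = draw_degraded_loci(
            family, config.n_degraded, config.canonical_divergence, rng
        )
    truth = SimTruth()
    positive = [d for d, f in zip(dates, fracs) if f > 0]
    truth.invasion_date = min(positive) if positive else None
    samples: List[SamplePointInputs] = []
    for i, (date, frac) in enumerate(zip(dates, fracs)):
        sample_id = f"{region}_{date:g}"
        sp = simulate_pooled_sample(
            family, genes, config, frac, rng, sample_id=sample_id, date=date, region=region,
            degraded_loci=degraded_loci,
        )
        truth.canonical_fraction[sample_id] = sp.true_fraction
        samples.append(sp)
    return InvasionSeries(family, genes, samples, truth)


def simulate_geographic_series(
    config: SimConfig,
    dates: Sequence[float],
    region_trajectories: Mapping[str, Mapping[float, float]],
) -> InvasionSeries:
    """Multi-region sampling: one trajectory per region, a shared TE family."""
    rng = as_rng(config.seed)
    family = TEFamily.generate("te1", config.te_length, config.degraded_divergence, rng)
    genes = make_single_copy_genes(seed=rng)
    degraded_loci = draw_degraded_loci(family, config.n_degraded, config.canonical_divergence, rng)
    combined = InvasionSeries(family, genes, [], SimTruth())
    first_dates = []
    for region in sorted(region_trajectories):
        sub = SimConfig(**{**config.__dict__, "seed": int(rng.integers(2**31))})
        series = simulate_invasion_series(
            sub, dates, region_trajectories[region], region=region, family=family, genes=genes,
            degraded_loci=degraded_loci,
        )
        combined.samples.extend(series.samples)
        combined.truth.canonical_fraction.update(series.truth.canonical_fraction)
        if series.truth.invasion_date is not None:
            first_dates.append(series.truth.invasion_date)
    combined.truth.invasion_date = min(first_dates) if first_dates else None
    return combined


def write_truth_tsv(truth: SimTruth, path) -> None:
    """Truth insertions as TSV (contig, start, end, te_id, canonical, divergence; 0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("#contig\tstart\tend\tte_id\tis_canonical\tdivergence\t(0-based half-open)\n")
        for ins in truth.insertions:
            fh.write(
                f"{ins.contig}\t{ins.start}\t{ins.end}\t{ins.te_id}\t"
                f"{int(ins.is_canonical)}\t{ins.divergence:.5f}\n"
            )
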