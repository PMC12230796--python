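"""TE copy number and per-position allele counts on consensus coordinates.

Reads are aligned to a joint reference of TE consensus sequences and
single-copy genes; the mean depth over a TE consensus divided by the mean
depth over the genes gives the copy number per haploid genome, and the
per-position base counts are the substrate for diagnostic-SNP statistics.

Conventions: the TE mean depth includes uncovered consensus positions as
zeros (a fragmentary family yields a fractional copy number); the gene mean
is taken over the concatenated positions of all genes, weighting them by
length.  Alignment is permissive (identity >= 0.8, 13 bp seeds) so reads
from degraded copies at up to ~20% divergence still contribute.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Union

import numpy as np

from .align import AlignmentRecord, map_reads, parse_cigar
from .seqio import Read

BASE_TO_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
IDX_TO_BASE = "ACGT"


@dataclass
class TEPileup:
    te_id: str
    depth: np.ndarray  # aligned depth per consensus position (includes deletion columns)
    counts: np.ndarray  # shape (4, L): A/C/G/T counts per position

    @property
    def length(self) -> int:
        return self.depth.size

    @property
    def total_depth(self) -> int:
        return int(self.depth.sum())

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if self.depth.size else 0.0


@dataclass
class CopyNumberEstimate:
    te_id: str
    sample_id: str
    copies_per_haploid: float
    te_mean_depth: float
    gene_mean_depth: float


def align_to_references(
    reads: Iterable[Read],
    references: Dict[str, str],
    min_identity: float = 0.8,
    min_seed: int = 13,
    n_seeds: int = 14,
) -> List[AlignmentRecord]:
    """Best-reference placement of each read, permissive enough for degraded copies.

    Seeds are short (13 bp) and densely sampled so that reads from copies at
    up to ~20% divergence still anchor somewhere along their length.
    """
    if not references:
        raise ValueError("reference set is empty")
    return map_reads(reads, references, min_seed=min_seed, min_identity=min_identity, n_seeds=n_seeds)


def pileup(
    alignments: Sequence[AlignmentRecord],
    references: Mapping[str, str],
    end_mask: int = 0,
) -> Dict[str, TEPileup]:
    """Per-position depth and base counts for every reference sequence.

    Match/mismatch columns contribute depth and a base count; reference
    positions deleted in a read contribute depth only; read insertions
    contribute nothing on reference coordinates.  With ``end_mask`` > 0 the
    first and last that many read bases contribute depth but no base count —
    alignment placement is least reliable at read ends, so masking them
    keeps misplacement noise out of allele counts (set 0 to disable).
    """
    piles = {
        name: TEPileup(name, np.zeros(len(seq), dtype=np.int64), np.zeros((4, len(seq)), dtype=np.int64))
        for name, seq in references.items()
    }
    for rec in alignments:
        if rec.contig_id not in piles:
            raise ValueError(f"alignment on unknown reference {rec.contig_id!r}")
        pile = piles[rec.contig_id]
        if not (0 <= rec.start <= rec.end <= pile.length):
            raise ValueError(f"alignment out of bounds on {rec.contig_id!r}")
        if not rec.cigar:
            pile.depth[rec.start : rec.end] += 1
            continue
        rpos, qpos = rec.start, 0
        qlen = len(rec.read_seq)
        for n, op in parse_cigar(rec.cigar):
            if op in ("=", "X", "M"):
                pile.depth[rpos : rpos + n] += 1
                for j in range(n):
                    q = qpos + j
                    if q < end_mask or q >= qlen - end_mask:
                        continue
                    b = BASE_TO_IDX.get(rec.read_seq[q])
                    if b is not None:
                        pile.counts[b, rpos + j] += 1
                rpos += n
                qpos += n
            elif op == "D":
                pile.depth[rpos : rpos + n] += 1  # deleted positions stay covered
                rpos += n
            elif op == "I":
                qpos += n
    return piles


def copy_number(
    te_pileup: TEPileup,
    gene_pileups: Sequence[TEPileup],
    sample_id: str = "",
) -> CopyNumberEstimate:
    """Copies per haploid genome = TE mean depth / single-copy-gene mean depth."""
    gene_positions = sum(p.length for p in gene_pileups)
    if gene_positions == 0:
        raise ValueError("no gene positions available")
    gene_mean = sum(p.total_depth for p in gene_pileups) / gene_positions
    if gene_mean <= 0:
        raise ValueError("zero single-copy-gene depth; sample unusable for normalization")
    te_mean = te_pileup.mean_depth
    return CopyNumberEstimate(
        te_id=te_pileup.te_id,
        sample_id=sample_id,
        copies_per_haploid=te_mean / gene_mean,
        te_mean_depth=te_mean,
        gene_mean_depth=gene_mean,
    )


def allele_frequencies(pile: TEPileup, position: int) -> Dict[str, float]:
    """Base -> frequency at one consensus position (counts / total counts)."""
    if not (0 <= position < pile.length):
        raise ValueError(f"position {position} outside consensus of length {pile.length}")
    col = pile.counts[:, position]
    total = int(col.sum())
    if total == 0:
        raise ValueError(f"no aligned bases at position {position}")
    return {IDX_TO_BASE[i]: int(col[i]) / total for i in range(4) if col[i] > 0}


def read_pileup_tsv(path: Union[str, Path]) -> Dict[str, TEPileup]:
    """Read a pileup table written by :func:`write_pileup_tsv`."""
    rows: Dict[str, List[List[int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            name, pos, depth, a, c, g, t = line.rstrip("\n").split("\t")
            rows.setdefault(name, []).append([int(pos), int(depth), int(a), int(c), int(g), int(t)])
    piles: Dict[str, TEPileup] = {}
    for name, data in rows.items():
        data.sort()
        length = data[-1][0]
        depth = np.zeros(length, dtype=np.int64)
        counts = np.zeros((4, length), dtype=np.int64)
        for pos, d, a, c, g, t in data:
            depth[pos - 1] = d
            counts[:, pos - 1] = (a, c, g, t)
        piles[name] = TEPileup(name, depth, counts)
    return piles


def write_pileup_tsv(piles: Mapping[str, TEPileup], path: Union[str, Path]) -> Path:
    """Pileup table (reference, position 1-based, depth, A, C, G, T)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#reference\tpos_1based\tdepth\tA\tC\tG\tT\n")
        for name, pile in piles.items():
            for i in range(pile.length):
                a, c, g, t = (int(pile.counts[j, i]) for j in range(4))
                fh.write(f"{name}\t{i + 1}\t{int(pile.depth[i])}\t{a}\t{c}\t{g}\t{t}\n")
    return path
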