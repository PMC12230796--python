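"""Horizontal-transfer support test.

A TE that entered a genome by recent horizontal transfer is far less
diverged between donor and recipient than the bulk of their orthologous
genes, whose divergence reflects the full speciation depth.  The test
compares the divergence of the two most similar full-length TE insertions
across the two genomes with the empirical ortholog divergence
distribution: transfer is supported when the TE divergence is lower than
that of at least 95% of the genes.

Divergence is nucleotide substitution divergence over aligned (non-gap)
columns of a global alignment; terminal overhangs (e.g. truncated LTRs) are
excluded from the column count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import edlib

from .align import parse_cigar

MIN_ORTHOLOG_PAIRS = 20
UNALIGNABLE_DIVERGENCE = 0.25  # above this, identity is indistinguishable from random


@dataclass
class OrthologPair:
    gene_id: str
    seq_a: str
    seq_b: str
    divergence: float = float("nan")


@dataclass
class HTTestResult:
    te_id: str
    te_divergence: float
    gene_divergences: List[float]
    quantile_rank: float  # fraction of genes less diverged than the TE (ties count 1/2)
    supported: bool


def pairwise_divergence(seq_a: str, seq_b: str, max_divergence: float = UNALIGNABLE_DIVERGENCE) -> float:
    """Substitution divergence over aligned columns of a global alignment.

    Terminal gap runs are trimmed before counting, so length differences at
    the ends do not inflate the estimate.  Pairs whose divergence exceeds
    ``max_divergence`` are considered unalignable (random nucleotide pairs
    land near 0.3 under this metric) and raise :class:`ValueError`.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    res = edlib.align(seq_a, seq_b, mode="NW", task="path")
    runs = parse_cigar(res["cigar"])
    while runs and runs[0][1] in "ID":
        runs.pop(0)
    while runs and runs[-1][1] in "ID":
        runs.pop()
    matches = sum(n for n, op in runs if op == "=")
    mismatches = sum(n for n, op in runs if op == "X")
    if matches + mismatches == 0:
        raise ValueError("no aligned columns between the sequences")
    divergence = mismatches / (matches + mismatches)
    if divergence > max_divergence:
        raise ValueError(
            f"sequences are unalignable (divergence {divergence:.2f} > {max_divergence})"
        )
    return divergence


def best_cross_species_pair(
    full_length_a: Mapping[str, str], full_length_b: Mapping[str, str]
) -> Tuple[str, str, float]:
    """The least-diverged pair with one insertion from each genome.

    Scans all pairs; unalignable pairs are skipped.  Ties break by sequence
    id order.  Returns (id_a, id_b, divergence).
    """
    if not full_length_a or not full_length_b:
        raise ValueError("both insertion sets must be non-empty")
    best: Tuple[float, str, str] = None
    for id_a in sorted(full_length_a):
        for id_b in sorted(full_length_b):
            try:
                d = pairwise_divergence(full_length_a[id_a], full_length_b[id_b])
            except ValueError:
                continue
            if best is None or (d, id_a, id_b) < best:
                best = (d, id_a, id_b)
    if best is None:
        raise ValueError("no alignable cross-species pair found")
    d, id_a, id_b = best
    return id_a, id_b, d


def ortholog_divergences(pairs: Sequence[OrthologPair]) -> List[OrthologPair]:
    """Fill in the divergence of each ortholog pair (in place) and return them."""
    for pair in pairs:
        pair.divergence = pairwise_divergence(pair.seq_a, pair.seq_b)
    return list(pairs)


def match_ortholog_files(genes_a: Mapping[str, str], genes_b: Mapping[str, str]) -> List[OrthologPair]:
    """Pair ortholog sequences by shared id across two FASTA dicts (1:1 ids required)."""
    ids = sorted(set(genes_a) & set(genes_b))
    if not ids:
        raise ValueError("no shared ortholog ids between the two files")
    return [OrthologPair(g, genes_a[g], genes_b[g]) for g in ids]


def ht_test(
    te_divergence: float,
    gene_divergences: Sequence[float],
    alpha: float = 0.05,
    te_id: str = "",
) -> HTTestResult:
    """Rank the TE divergence within the ortholog divergence distribution.

    quantile_rank = (#genes with divergence < TE + 0.5 * #exact ties) / n;
    transfer is supported when the rank is <= alpha, i.e. the TE is less
    diverged than at least a (1 - alpha) share of the genes.  The result is
    invariant to the order (and whole-set duplication) of the gene list.
    """
    n = len(gene_divergences)
    if n < MIN_ORTHOLOG_PAIRS:
        raise ValueError(f"need at least {MIN_ORTHOLOG_PAIRS} ortholog pairs, got {n}")
    less = sum(1 for d in gene_divergences if d < te_divergence)
    ties = sum(1 for d in gene_divergences if d == te_divergence)
    rank = (less + 0.5 * ties) / n
    return HTTestResult(
        te_id=te_id,
        te_divergence=te_divergence,
        gene_divergences=sorted(gene_divergences),
        quantile_rank=rank,
        supported=rank <= alpha,
    )
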