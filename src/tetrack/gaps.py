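"""Coverage-gap discovery and consensus inference of candidate novel TEs.

Short reads of an *old* sample aligned to the assembly of a *young* strain
leave zero-coverage gaps at the insertion sites of any TE family that
invaded between the two collection dates.  The gap sequences are extracted,
clustered by homology (single linkage on local-alignment bit-scores, default
threshold 1,000 bits), aligned and collapsed to a majority consensus — the
candidate invader.

Bit-scores use match +2 / mismatch -3 / gap existence 5 / gap extension 2
and the Karlin-Altschul conversion bits = (lambda*S - ln K) / ln 2 with
lambda = 0.625, K = 0.41 (standard nucleotide-search constants).
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align

from .align import CoverageTrack
from .seqio import write_fasta

KA_LAMBDA = 0.625
KA_LNK = math.log(0.41)

MATCH = 2
MISMATCH = -3
GAP_OPEN = 5  # gap existence cost
GAP_EXTEND = 2  # per-base gap cost


@dataclass
class GapCandidate:
    contig_id: str
    start: int  # 0-based inclusive, gap coordinates (without flank)
    end: int  # exclusive
    sequence: str = ""  # assembly substring of [start-flank, end+flank), clipped
    flank: int = 0

    @property
    def name(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}"


@dataclass
class GapCluster:
    members: List[GapCandidate]
    pairwise_bitscores: Optional[np.ndarray] = None
    msa: List[str] = field(default_factory=list)
    consensus: str = ""


def find_gaps(
    track: CoverageTrack, max_depth: int = 0, min_gap_length: int = 500
) -> List[GapCandidate]:
    """Maximal runs of positions with depth <= max_depth, length >= min_gap_length.

    Runs are reported left to right and never overlap.
    """
    low = np.asarray(track.depth) <= max_depth
    if low.size == 0:
        return []
    padded = np.concatenate([[False], low, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [
        GapCandidate(track.contig_id, int(s), int(e))
        for s, e in zip(starts, ends)
        if e - s >= min_gap_length
    ]


def merge_nearby_gaps(gaps: Sequence[GapCandidate], max_separation: int = 50) -> List[GapCandidate]:
    """Merge adjacent gaps separated by fewer than ``max_separation`` covered bases.

    A single stray read inside a true insertion should not split the
    candidate in two.
    """
    merged: List[GapCandidate] = []
    for gap in sorted(gaps, key=lambda g: (g.contig_id, g.start)):
        if (
            merged
            and merged[-1].contig_id == gap.contig_id
            and gap.start - merged[-1].end < max_separation
        ):
            merged[-1] = GapCandidate(gap.contig_id, merged[-1].start, gap.end)
        else:
            merged.append(GapCandidate(gap.contig_id, gap.start, gap.end))
    return merged


def extract_gap_sequences(
    assembly: Dict[str, str], gaps: Sequence[GapCandidate], flank: int = 0
) -> List[GapCandidate]:
    """Extract gap sequences with flank padding, clipped at contig boundaries."""
    out: List[GapCandidate] = []
    for gap in gaps:
        if gap.contig_id not in assembly:
            raise ValueError(f"gap on unknown contig {gap.contig_id!r}")
        seq = assembly[gap.contig_id]
        if not (0 <= gap.start < gap.end <= len(seq)):
            raise ValueError(f"gap [{gap.start},{gap.end}) out of bounds on {gap.contig_id!r}")
        lo = max(0, gap.start - flank)
        hi = min(len(seq), gap.end + flank)
        out.append(GapCandidate(gap.contig_id, gap.start, gap.end, seq[lo:hi], flank))
    return out


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    # BLAST-style: a gap of length L costs GAP_OPEN + GAP_EXTEND * L
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def raw_to_bits(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - KA_LNK) / math.log(2)


def pairwise_bitscore(a: str, b: str) -> float:
    """Best local-alignment score between two sequences, in bits (symmetric)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return raw_to_bits(_local_aligner().score(a, b))


def cluster_by_homology(
    candidates: Sequence[GapCandidate], min_bitscore: float = 1000.0
) -> List[GapCluster]:
    """Single-linkage clusters over the bit-score >= threshold graph.

    Singletons are retained as size-1 clusters.  The result does not depend
    on the input order beyond the ordering of cluster members.
    """
    n = len(candidates)
    if n == 0:
        return []
    scores = np.zeros((n, n))
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    aligner = _local_aligner()
    for i in range(n):
        for j in range(i + 1, n):
            bits = raw_to_bits(aligner.score(candidates[i].sequence, candidates[j].sequence))
            scores[i, j] = scores[j, i] = bits
            if bits >= min_bitscore:
                parent[find(i)] = find(j)
    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for idx in sorted(groups.values(), key=lambda g: g[0]):
        clusters.append(
            GapCluster(
                members=[candidates[i] for i in idx],
                pairwise_bitscores=scores[np.ix_(idx, idx)],
            )
        )
    return clusters


def build_cluster_msa(cluster: GapCluster) -> List[str]:
    """Multiple sequence alignment of cluster members (MAFFT).

    Members are passed longest first so the alignment is anchored on the
    most complete copy; the gapped rows are returned in that order.
    """
    if not cluster.members:
        raise ValueError("cluster is empty")
    if len(cluster.members) == 1:
        cluster.msa = [cluster.members[0].sequence]
        return cluster.msa
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft executable not found on PATH")
    ordered = sorted(cluster.members, key=lambda m: (-len(m.sequence), m.name))
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "members.fa"
        write_fasta({f"m{i}": m.sequence for i, m in enumerate(ordered)}, inp)
        res = subprocess.run(
            ["mafft", "--retree", "2", "--maxiterate", "0", "--quiet", "--thread", "1", str(inp)],
            capture_output=True,
            text=True,
            check=True,
        )
    aligned: Dict[str, str] = {}
    name = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            aligned[name] = ""
        elif name is not None:
            aligned[name] += line.strip().upper()
    cluster.msa = [aligned[f"m{i}"] for i in range(len(ordered))]
    return cluster.msa


def call_consensus(msa: Sequence[str], max_gap_fraction: float = 0.5) -> str:
    """Majority-vote consensus of a gapped alignment.

    Columns with more than ``max_gap_fraction`` gap characters are dropped
    (flanking genomic context, present in a minority of members, votes
    itself out); ties between bases break by fixed order A < C < G < T.
    """
    if not msa:
        raise ValueError("empty alignment")
    if len({len(row) for row in msa}) != 1:
        raise ValueError("alignment rows must have equal length")
    n = len(msa)
    out: List[str] = []
    for col in zip(*msa):
        gaps = sum(c == "-" for c in col)
        if gaps > max_gap_fraction * n:
            continue
        counts = {b: 0 for b in "ACGT"}
        for c in col:
            if c in counts:
                counts[c] += 1
        best = max("ACGT", key=lambda b: (counts[b], -ord(b)))
        if counts[best] > 0:
            out.append(best)
    return "".join(out)


@dataclass
class DiscoveryResult:
    gaps: List[GapCandidate]
    clusters: List[GapCluster]

    @property
    def consensi(self) -> Dict[str, str]:
        return {f"cluster_{i}": c.consensus for i, c in enumerate(self.clusters) if c.consensus}


def discover(
    assembly: Dict[str, str],
    tracks: Dict[str, CoverageTrack],
    max_depth: int = 0,
    min_gap_length: int = 500,
    min_bitscore: float = 1000.0,
    merge_within: int = 50,
    flank: int = 0,
) -> DiscoveryResult:
    """Coverage gaps -> extracted sequences -> clusters -> consensus per cluster."""
    gaps: List[GapCandidate] = []
    for track in tracks.values():
        gaps.extend(find_gaps(track, max_depth=max_depth, min_gap_length=min_gap_length))
    gaps = merge_nearby_gaps(gaps, max_separation=merge_within)
    candidates = extract_gap_sequences(assembly, gaps, flank=flank)
    clusters = cluster_by_homology(candidates, min_bitscore=min_bitscore)
    for cluster in clusters:
        build_cluster_msa(cluster)
        cluster.consensus = call_consensus(cluster.msa)
    return DiscoveryResult(candidates, clusters)
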