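"""Read mapping, SAM import and coverage tracks.

The internal mapper is seed-and-extend: exact k-mer seeds (default k=31)
looked up in a hash index of the reference, candidate loci ranked by seed
votes, and each candidate scored by banded edit-distance alignment (edlib).
Coordinates are 0-based half-open throughout; SAM input is converted at the
boundary.  Reverse-strand reads are aligned as their reverse complement and
reported on the forward reference strand; coverage is strand-agnostic, and
positions deleted in a read's alignment still count as covered.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import edlib
import numpy as np
import pysam

from .seqio import Read, revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

# alignment run: (length, op) with edlib extended ops
# '=' match, 'X' mismatch, 'I' insertion in query, 'D' deletion in query
Runs = List[Tuple[int, str]]


def parse_cigar(cigar: str) -> Runs:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def runs_stats(runs: Runs) -> Tuple[int, int, int, int]:
    """Return (matches, mismatches, query_gap_cols, target_gap_cols)."""
    m = sum(n for n, op in runs if op == "=")
    x = sum(n for n, op in runs if op == "X")
    ins = sum(n for n, op in runs if op == "I")
    dele = sum(n for n, op in runs if op == "D")
    return m, x, ins, dele


def score_runs(runs: Runs, match: int = 2, mismatch: int = -3, gap_open: int = 5, gap_extend: int = 2) -> float:
    """Affine-gap alignment score of a parsed cigar (+2/-3, gap 5+2L)."""
    score = 0.0
    for n, op in runs:
        if op == "=":
            score += match * n
        elif op in ("X", "M"):
            score += mismatch * n
        else:
            score -= gap_open + gap_extend * n
    return score


def _gapless_cigar(read_seq: str, ref_seg: str) -> Tuple[str, int]:
    """Run-length =/X cigar of an ungapped alignment, plus the mismatch count."""
    out: List[str] = []
    mismatches = 0
    prev_op, run = "", 0
    for a, b in zip(read_seq, ref_seg):
        op = "=" if a == b else "X"
        if op == "X":
            mismatches += 1
        if op == prev_op:
            run += 1
        else:
            if run:
                out.append(f"{run}{prev_op}")
            prev_op, run = op, 1
    if run:
        out.append(f"{run}{prev_op}")
    return "".join(out), mismatches


@dataclass
class AlignmentRecord:
    """One read placed on one contig (best-scoring locus)."""

    read_id: str
    contig_id: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str  # '+' or '-'
    matches: int
    aligned_length: int  # alignment columns (=, X, I, D)
    cigar: str = ""  # extended cigar of the oriented read vs the forward reference
    read_seq: str = ""  # read sequence oriented to the forward reference strand

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_length if self.aligned_length else 0.0


@dataclass
class CoverageTrack:
    contig_id: str
    depth: np.ndarray  # int array, one entry per base


class KmerIndex:
    """Exact k-mer index over a set of reference sequences."""

    def __init__(self, references: Dict[str, str], k: int = 31):
        if k < 8:
            raise ValueError("k must be >= 8")
        self.k = k
        self.references = references
        index: Dict[str, list] = {}
        for name, seq in references.items():
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((name, i))
        self._index = index

    def lookup(self, kmer: str):
        return self._index.get(kmer, ())


def _align_candidate(
    read_seq: str, ref_seq: str, ref_start_guess: int, pad: int
) -> Optional[Tuple[int, int, int, str, int]]:
    """Fit a read into a padded reference window around a seed-implied start.

    Returns (edit_distance, start, end, cigar) on the reference, or None.
    """
    lo = max(0, ref_start_guess - pad)
    hi = min(len(ref_seq), ref_start_guess + len(read_seq) + pad)
    window = ref_seq[lo:hi]
    if not window:
        return None
    res = edlib.align(read_seq, window, mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    s, e = res["locations"][0]
    cigar, edits = res["cigar"], res["editDistance"]
    runs = parse_cigar(cigar)
    if any(op in "ID" for _, op in runs):
        # Unit-cost edit paths trade two substitutions for an indel pair,
        # shifting read bases and corrupting pileups; prefer a gapless
        # placement whenever it scores at least as well under affine gaps.
        L = len(read_seq)
        best_gapless = None
        for off in {s, e + 1 - L}:
            if 0 <= off <= len(window) - L:
                g_cigar, g_mismatch = _gapless_cigar(read_seq, window[off : off + L])
                g_score = score_runs(parse_cigar(g_cigar))
                if best_gapless is None or g_score > best_gapless[0]:
                    best_gapless = (g_score, off, g_cigar, g_mismatch)
        if best_gapless is not None and best_gapless[0] >= score_runs(runs):
            _, off, g_cigar, g_mismatch = best_gapless
            return g_mismatch, lo + off, lo + off + L, g_cigar, lo
    return edits, lo + s, lo + e + 1, cigar, lo


def map_reads(
    reads: Iterable[Read],
    references: Dict[str, str],
    min_seed: int = 31,
    min_identity: float = 0.9,
    max_candidates: int = 8,
    n_seeds: int = 5,
    pad: int = 12,
) -> List[AlignmentRecord]:
    """Map reads to reference sequences, reporting each read's best locus.

    A read is placed at the candidate locus with the lowest edit distance
    provided its identity (1 - edits/read length) reaches ``min_identity``;
    otherwise it is unmapped and simply absent from the output.  Ties are
    broken deterministically (fewest edits, then contig id, position and
    forward strand).  Error-free reads copied from a unique locus are
    guaranteed to map back to their origin.
    """
    index = KmerIndex(references, k=min_seed)
    k = min_seed
    out: List[AlignmentRecord] = []
    for read in reads:
        L = len(read.sequence)
        if L < k:
            continue
        best = None  # (edits, contig, start, strand, end, cigar, oriented_seq)
        for strand, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
            # vote for candidate (contig, start) from a handful of spaced seeds
            votes: Dict[Tuple[str, int], int] = {}
            stride = max(1, (L - k) // max(1, n_seeds - 1)) if L > k else 1
            for qpos in range(0, L - k + 1, stride):
                for contig, rpos in index.lookup(seq[qpos : qpos + k]):
                    key = (contig, rpos - qpos)
                    votes[key] = votes.get(key, 0) + 1
            if not votes:
                continue
            # collapse near-identical diagonals, keep top candidates by votes
            ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
            seen: List[Tuple[str, int]] = []
            for (contig, diag), _ in ranked:
                if any(c == contig and abs(d - diag) <= pad for c, d in seen):
                    continue
                seen.append((contig, diag))
                if len(seen) >= max_candidates:
                    break
            for contig, diag in seen:
                hit = _align_candidate(seq, references[contig], diag, pad)
                if hit is None:
                    continue
                edits, s, e, cigar, _ = hit
                cand = (edits, contig, s, strand, e, cigar, seq)
                if best is None or cand[:4] < best[:4]:
                    best = cand
        if best is None:
            continue
        edits, contig, s, strand, e, cigar, oriented = best
        if 1.0 - edits / L < min_identity:
            continue
        runs = parse_cigar(cigar)
        m, x, ins, dele = runs_stats(runs)
        out.append(
            AlignmentRecord(
                read_id=read.id,
                contig_id=contig,
                start=s,
                end=e,
                strand=strand,
                matches=m,
                aligned_length=m + x + ins + dele,
                cigar=cigar,
                read_seq=oriented,
            )
        )
    return out


def read_sam(path: Union[str, Path], assembly: Dict[str, str]) -> List[AlignmentRecord]:
    """Import primary alignments from a SAM file.

    Coordinates are converted from SAM 1-based to 0-based half-open.
    Unmapped, secondary and supplementary records are skipped; a reference
    name absent from ``assembly`` raises :class:`ValueError`.
    """
    records: List[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            contig = aln.reference_name
            if contig not in assembly:
                raise ValueError(f"SAM reference {contig!r} not present in assembly")
            stats = aln.get_cigar_stats()[0]
            aligned_cols = stats[0] + stats[1] + stats[2] + stats[7] + stats[8]  # M,I,D,=,X
            try:
                nm = aln.get_tag("NM")
            except KeyError:
                nm = 0
            matched_cols = stats[0] + stats[7] + stats[8]
            matches = max(0, matched_cols - nm)
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    contig_id=contig,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                    matches=matches,
                    aligned_length=aligned_cols,
                    read_seq=aln.query_sequence or "",
                )
            )
    return records


def coverage_from_alignments(
    alignments: Sequence[AlignmentRecord], assembly: Dict[str, str]
) -> Dict[str, CoverageTrack]:
    """Per-base depth per contig: depth[i] = #records whose [start, end) spans i."""
    diffs = {name: np.zeros(len(seq) + 1, dtype=np.int64) for name, seq in assembly.items()}
    for rec in alignments:
        if rec.contig_id not in diffs:
            raise ValueError(f"alignment on unknown contig {rec.contig_id!r}")
        n = len(assembly[rec.contig_id])
        if not (0 <= rec.start < rec.end <= n):
            raise ValueError(
                f"alignment [{rec.start},{rec.end}) out of bounds for contig "
                f"{rec.contig_id!r} of length {n}"
            )
        diffs[rec.contig_id][rec.start] += 1
        diffs[rec.contig_id][rec.end] -= 1
    return {
        name: CoverageTrack(name, np.cumsum(d[:-1])) for name, d in diffs.items()
    }


def write_bedgraph(tracks: Dict[str, CoverageTrack], path: Union[str, Path]) -> Path:
    """Export coverage as BedGraph-style TSV (contig, start, end, depth; 0-based half-open)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#contig\tstart\tend\tdepth\t(0-based half-open)\n")
        for name, track in tracks.items():
            d = track.depth
            if d.size == 0:
                continue
            edges = np.flatnonzero(np.diff(d)) + 1
            starts = np.concatenate([[0], edges])
            ends = np.concatenate([edges, [d.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{name}\t{s}\t{e}\t{d[s]}\n")
    return path
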