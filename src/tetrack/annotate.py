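"""Repeat annotation of assemblies against a TE consensus library.

Each consensus is located in the assembly by exact k-mer seeding on both
strands, seed chains are refined by edit-distance alignment (edlib), and the
alignment ends are trimmed to the maximum-scoring local segment under the
package-wide +2/-3/5/2 scheme, so raw scores are comparable across modules
and assemblies.  Divergence counts substitutions only, over aligned
(non-gap) columns; indels reduce the covered consensus span instead.

Hits are classified canonical (divergence <= 1.5%) or degraded (> 1.5%) —
the operational boundary between copies of a recent invasion and remnants
of ancient ones — and filtered at a minimum length of 300 bp and a maximum
divergence of 20%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import edlib
import numpy as np

from .align import Runs, parse_cigar, score_runs
from .gaps import GAP_EXTEND, GAP_OPEN, MATCH, MISMATCH
from .seqio import revcomp

DEFAULT_MIN_LENGTH = 300
DEFAULT_MAX_DIVERGENCE = 20.0
CANONICAL_THRESHOLD = 1.5  # percent divergence
MERGE_RADIUS = 100  # same-TE hits closer than this merge into one insertion


@dataclass
class RepeatHit:
    contig_id: str
    start: int  # 0-based inclusive on the assembly
    end: int  # exclusive
    strand: str
    te_id: str
    raw_score: float
    divergence: float  # percent mismatches over aligned columns
    te_span: float  # fraction of the consensus covered by aligned columns
    is_canonical: Optional[bool] = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimilarityScore:
    assembly_id: str
    te_id: str
    rms_best: float
    s: float  # rms_best / rms_max over the comparison set


def _score_runs(runs: Runs) -> float:
    return score_runs(runs, MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND)


def _trim_runs_local(runs: Runs) -> Tuple[Runs, int, int]:
    """Maximum-scoring contiguous run segment (Kadane at run granularity).

    Returns the trimmed runs plus the number of leading/trailing target
    (assembly) columns removed.
    """
    scores = [_score_runs([r]) for r in runs]
    best, best_i, best_j = float("-inf"), 0, -1
    cur, cur_i = 0.0, 0
    for j, s in enumerate(scores):
        if cur <= 0:
            cur, cur_i = s, j
        else:
            cur += s
        if cur > best:
            best, best_i, best_j = cur, cur_i, j
    trimmed = runs[best_i : best_j + 1]

    def target_cols(rs: Runs) -> int:
        return sum(n for n, op in rs if op in ("=", "X", "D", "M"))

    return trimmed, target_cols(runs[:best_i]), target_cols(runs[best_j + 1 :])


def _chain_seeds(matches: List[Tuple[int, int]], max_jump: int = 800) -> List[List[Tuple[int, int]]]:
    """Group (contig_pos, te_pos) seed matches into candidate loci.

    Matches are sorted by contig position; a new chain starts when the
    contig position jumps by more than ``max_jump`` or the consensus offset
    moves backwards substantially (a new copy).
    """
    chains: List[List[Tuple[int, int]]] = []
    for g, t in sorted(matches):
        if chains:
            lg, lt = chains[-1][-1]
            if g - lg <= max_jump and t >= lt - 50:
                chains[-1].append((g, t))
                continue
        chains.append([(g, t)])
    return chains


def _align_chain(
    contig_seq: str,
    consensus: str,
    chain: List[Tuple[int, int]],
    k: int,
    contig_id: str,
    te_id: str,
    strand: str,
    boundary_slack: int = 50,
) -> Optional[RepeatHit]:
    telen = len(consensus)
    gmin = chain[0][0]
    gmax = chain[-1][0] + k
    tmin = min(t for _, t in chain)
    tmax = max(t for _, t in chain) + k
    lo = max(0, gmin - min(tmin, boundary_slack) - 10)
    hi = min(len(contig_seq), gmax + min(telen - tmax, boundary_slack) + 10)
    window = contig_seq[lo:hi]
    oriented = window if strand == "+" else revcomp(window)
    res = edlib.align(consensus, oriented, mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    tstart = res["locations"][0][0]
    runs = parse_cigar(res["cigar"])
    trimmed, lead_t, tail_t = _trim_runs_local(runs)
    m = sum(n for n, op in trimmed if op == "=")
    x = sum(n for n, op in trimmed if op == "X")
    if m + x == 0:
        return None
    # oriented-window coordinates of the trimmed alignment
    o_start = tstart + lead_t
    o_end = tstart + sum(n for n, op in runs if op in ("=", "X", "D")) - tail_t
    if strand == "+":
        start, end = lo + o_start, lo + o_end
    else:
        start, end = lo + len(window) - o_end, lo + len(window) - o_start
    return RepeatHit(
        contig_id=contig_id,
        start=start,
        end=end,
        strand=strand,
        te_id=te_id,
        raw_score=_score_runs(trimmed),
        divergence=100.0 * x / (m + x),
        te_span=min(1.0, (m + x) / telen),
    )


def _merge_hits(hits: List[RepeatHit]) -> List[RepeatHit]:
    """Merge same-TE, same-strand neighbours within MERGE_RADIUS into one insertion."""
    out: List[RepeatHit] = []
    for hit in sorted(hits, key=lambda h: (h.contig_id, h.te_id, h.strand, h.start)):
        prev = out[-1] if out else None
        if (
            prev is not None
            and prev.contig_id == hit.contig_id
            and prev.te_id == hit.te_id
            and prev.strand == hit.strand
            and hit.start - prev.end <= MERGE_RADIUS
        ):
            w_prev = prev.end - prev.start
            w_hit = hit.end - hit.start
            prev.divergence = (prev.divergence * w_prev + hit.divergence * w_hit) / (w_prev + w_hit)
            prev.te_span = min(1.0, prev.te_span + hit.te_span)
            prev.raw_score += hit.raw_score
            prev.end = max(prev.end, hit.end)
        else:
            out.append(hit)
    out.sort(key=lambda h: (h.contig_id, h.start, h.te_id))
    return out


def scan_assembly(
    assembly: Mapping[str, str],
    te_library: Mapping[str, str],
    min_length: int = DEFAULT_MIN_LENGTH,
    max_divergence: float = DEFAULT_MAX_DIVERGENCE,
    k: int = 13,
) -> List[RepeatHit]:
    """Annotate an assembly against a TE consensus library (both strands).

    Overlapping or near-adjacent (<= 100 bp) hits of the same TE merge into
    a single insertion; hits shorter than ``min_length`` or more diverged
    than ``max_divergence`` percent are removed.
    """
    if not te_library:
        raise ValueError("TE library is empty")
    # index consensus k-mers, forward and reverse-complement
    index: Dict[str, List[Tuple[str, str, int]]] = {}
    for te_id, consensus in te_library.items():
        for strand, seq in (("+", consensus), ("-", revcomp(consensus))):
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((te_id, strand, i))
    hits: List[RepeatHit] = []
    for contig_id, contig_seq in assembly.items():
        per_locus: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
        for g in range(len(contig_seq) - k + 1):
            for te_id, strand, tpos in index.get(contig_seq[g : g + k], ()):
                # tpos is on the strand-oriented consensus, so it increases
                # with g within one copy on either strand
                per_locus.setdefault((te_id, strand), []).append((g, tpos))
        for (te_id, strand), matches in per_locus.items():
            consensus = te_library[te_id]
            for chain in _chain_seeds(matches):
                if len(chain) < 2 and len(chain) * k < 30:
                    continue
                hit = _align_chain(
                    contig_seq, consensus, chain, k, contig_id, te_id, strand
                )
                if hit is not None:
                    hits.append(hit)
    merged = _merge_hits(hits)
    return [
        h
        for h in merged
        if h.length >= min_length and h.divergence <= max_divergence and h.te_span > 0
    ]


def classify_canonical(
    hits: Sequence[RepeatHit], threshold: float = CANONICAL_THRESHOLD
) -> List[RepeatHit]:
    """Flag each hit canonical iff divergence <= threshold (inclusive)."""
    for hit in hits:
        hit.is_canonical = hit.divergence <= threshold
    return list(hits)


def count_canonical(hits: Sequence[RepeatHit]) -> Dict[str, Tuple[int, int]]:
    """Per-TE (canonical_count, degraded_count) over merged insertions."""
    counts: Dict[str, Tuple[int, int]] = {}
    for hit in hits:
        if hit.is_canonical is None:
            raise ValueError("hits must be classified before counting")
        can, deg = counts.get(hit.te_id, (0, 0))
        if hit.is_canonical:
            can += 1
        else:
            deg += 1
        counts[hit.te_id] = (can, deg)
    return counts


def extract_full_length(
    hits: Sequence[RepeatHit], assembly: Mapping[str, str], min_span: float = 0.8
) -> Dict[str, str]:
    """Sequences of insertions covering > min_span of the consensus,
    oriented to the consensus strand (minus-strand hits reverse-complemented)."""
    out: Dict[str, str] = {}
    for hit in hits:
        if hit.te_span <= min_span:
            continue
        seq = assembly[hit.contig_id][hit.start : hit.end]
        if hit.strand == "-":
            seq = revcomp(seq)
        out[f"{hit.te_id}_{hit.contig_id}:{hit.start}-{hit.end}"] = seq
    return out


def similarity_scores(best_hits: Mapping[str, float], te_id: str = "") -> List[SimilarityScore]:
    """Cross-assembly similarity s = rms_best / rms_max.

    ``best_hits`` maps assembly id to the best raw hit score in that
    assembly (0 for assemblies with no hit).  Fails if every assembly is
    hitless, since the ratio is then undefined.
    """
    if not best_hits:
        raise ValueError("no assemblies supplied")
    rms_max = max(best_hits.values())
    if rms_max <= 0:
        raise ValueError("no assembly has a hit; similarity undefined")
    return [
        SimilarityScore(assembly_id, te_id, score, score / rms_max)
        for assembly_id, score in best_hits.items()
    ]


def read_repeatmasker_out(path) -> List[RepeatHit]:
    """Adapter for genuine RepeatMasker ``.out`` tables.

    Parses score, divergence, query coordinates (converted to 0-based
    half-open), strand (``C`` = minus) and repeat id; te_span is estimated
    from the repeat coordinate columns.
    """
    hits: List[RepeatHit] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 14 or not parts[0].isdigit():
                continue
            score = float(parts[0])
            div = float(parts[1])
            contig, qbeg, qend = parts[4], int(parts[5]), int(parts[6])
            strand = "-" if parts[8] in ("C", "-") else "+"
            te_id = parts[9]
            if strand == "+":
                rbeg, rend, rleft = int(parts[11]), int(parts[12]), parts[13]
            else:
                rleft, rend, rbeg = parts[11], int(parts[12]), int(parts[13])
            rleft_n = int(str(rleft).strip("()"))
            te_len = rend + rleft_n
            span = (rend - rbeg + 1) / te_len if te_len > 0 else 0.0
            hits.append(
                RepeatHit(
                    contig_id=contig,
                    start=qbeg - 1,
                    end=qend,
                    strand=strand,
                    te_id=te_id,
                    raw_score=score,
                    divergence=div,
                    te_span=min(1.0, max(span, 1e-9)),
                )
            )
    return hits
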