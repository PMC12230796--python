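"""Diagnostic SNPs, canonical fractions and invasion-window reconstruction.

A SNP is *diagnostic* for canonical insertions when an old (pre-invasion)
sample is near-fixed (> 0.95) for one allele while the young sample carries
an alternative allele at frequency > 0.1: the alternative allele is private
to the canonical copies, so its population frequency estimates the fraction
of the family's insertions that are canonical.  Averaging over all
diagnostic sites gives one number per sample; together with the TE copy
number it dates the invasion: the window runs from the last sampled date at
which no sample shows canonical copies to the first date at which one does.

For families without diagnostic SNPs (no reads align to the consensus in
the old sample at all) the presence/absence of aligned reads stands in as a
1.0/0.0 fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .quantify import IDX_TO_BASE, TEPileup

YOUNG_MIN = 0.1
OLD_MIN = 0.95
MIN_DEPTH = 10
PRESENCE_THRESHOLD = 0.1  # canonical_fraction at/above which a sample counts as invaded
COPY_THRESHOLD = 0.5  # copies per haploid at/above which a sample counts as invaded


@dataclass
class DiagnosticSNP:
    te_id: str
    position: int  # 0-based consensus coordinate
    degraded_allele: str  # near-fixed in the old sample
    canonical_allele: str  # private to canonical insertions
    f_old: float
    f_young: float


@dataclass
class SamplePoint:
    sample_id: str
    date: Optional[float]
    region: str
    sample_type: str  # 'strain' or 'pool'
    copies_per_haploid: float
    canonical_fraction: float
    n_diagnostic_snps_used: int

    @property
    def used_fallback(self) -> bool:
        return self.n_diagnostic_snps_used == 0


@dataclass
class InvasionWindow:
    te_id: str
    last_absent_date: Optional[float]
    first_present_date: Optional[float]
    epicenters: List[str] = field(default_factory=list)


def _freqs(pile: TEPileup, position: int) -> Tuple[np.ndarray, int]:
    col = pile.counts[:, position]
    total = int(col.sum())
    return (col / total if total else col.astype(float)), total


def find_diagnostic_snps(
    old_pileup: TEPileup,
    young_pileup: TEPileup,
    young_min: float = YOUNG_MIN,
    old_min: float = OLD_MIN,
    min_depth: int = MIN_DEPTH,
) -> List[DiagnosticSNP]:
    """Sites near-fixed in the old sample with an alternative allele in the young.

    A site qualifies when some allele *a* has frequency > ``old_min`` in the
    old sample, the summed frequency of alleles other than *a* exceeds
    ``young_min`` in the young sample, and both samples have at least
    ``min_depth`` aligned bases there.  The canonical allele is the most
    frequent non-*a* allele in the young sample (ties break A < C < G < T).
    """
    if old_pileup.length != young_pileup.length:
        raise ValueError("pileups must be on the same consensus")
    snps: List[DiagnosticSNP] = []
    for pos in range(old_pileup.length):
        f_old, n_old = _freqs(old_pileup, pos)
        f_young, n_young = _freqs(young_pileup, pos)
        if n_old < min_depth or n_young < min_depth:
            continue
        a = int(np.argmax(f_old))  # ties resolve to the first base in ACGT order
        if f_old[a] <= old_min:
            continue
        alt_sum = 1.0 - f_young[a]
        if alt_sum <= young_min:
            continue
        alt_freqs = f_young.copy()
        alt_freqs[a] = -1.0
        b = int(np.argmax(alt_freqs))
        snps.append(
            DiagnosticSNP(
                te_id=old_pileup.te_id,
                position=pos,
                degraded_allele=IDX_TO_BASE[a],
                canonical_allele=IDX_TO_BASE[b],
                f_old=float(f_old[a]),
                f_young=float(f_young[b]),
            )
        )
    return snps


def presence_absence_fallback(sample_pileup: TEPileup) -> float:
    """1.0 if any read aligns to the TE consensus, else 0.0."""
    return 1.0 if sample_pileup.total_depth > 0 else 0.0


def canonical_fraction(
    sample_pileup: TEPileup,
    snps: Sequence[DiagnosticSNP],
    min_depth: int = MIN_DEPTH,
) -> Tuple[float, int]:
    """Mean canonical-allele frequency over usable diagnostic sites.

    Sites with fewer than ``min_depth`` aligned bases in this sample are
    skipped; with no usable site the presence/absence fallback applies and
    n_used is reported as 0.
    """
    freqs: List[float] = []
    for snp in snps:
        f, n = _freqs(sample_pileup, snp.position)
        if n < min_depth:
            continue
        freqs.append(float(f["ACGT".index(snp.canonical_allele)]))
    if not freqs:
        return presence_absence_fallback(sample_pileup), 0
    return float(np.mean(freqs)), len(freqs)


def is_invaded(
    point: SamplePoint,
    presence_threshold: float = PRESENCE_THRESHOLD,
    copy_threshold: float = COPY_THRESHOLD,
) -> bool:
    """Both key metrics must exceed their thresholds: canonical fraction and copy number."""
    return (
        point.canonical_fraction >= presence_threshold
        and point.copies_per_haploid >= copy_threshold
    )


def build_timeline(
    points: Sequence[SamplePoint],
    te_id: str = "",
    presence_threshold: float = PRESENCE_THRESHOLD,
    copy_threshold: float = COPY_THRESHOLD,
) -> Tuple[InvasionWindow, List[SamplePoint]]:
    """Date the invasion from a dated sample series.

    The window spans (last date at which every sample is non-invaded before
    the first invaded date, first invaded date).  Samples without a date are
    excluded from window inference.  Either end may be undefined (never
    invaded / invaded from the first sample on).
    """
    dated = sorted((p for p in points if p.date is not None), key=lambda p: p.date)
    if not dated:
        raise ValueError("at least one dated sample is required")
    invaded_dates = [p.date for p in dated if is_invaded(p, presence_threshold, copy_threshold)]
    first_present = min(invaded_dates) if invaded_dates else None
    if first_present is None:
        last_absent = max(p.date for p in dated)
    else:
        before = [p.date for p in dated if p.date < first_present]
        last_absent = max(before) if before else None
    window = InvasionWindow(te_id, last_absent, first_present)
    return window, dated


def geographic_table(
    points: Sequence[SamplePoint],
    year_bin: int = 1,
    presence_threshold: float = PRESENCE_THRESHOLD,
    copy_threshold: float = COPY_THRESHOLD,
) -> Tuple[pd.DataFrame, List[str]]:
    """Region x year aggregation of canonical fractions, plus epicenters.

    Epicenters are the regions invaded in the earliest year any region is
    invaded.  Returns (table, epicenters); the table holds the mean
    canonical fraction, sample count and invaded flag per (region, year).
    """
    rows = []
    for p in points:
        if p.date is None:
            continue
        year = int(np.floor(p.date / year_bin)) * year_bin
        rows.append(
            {
                "region": p.region,
                "year": year,
                "canonical_fraction": p.canonical_fraction,
                "invaded": is_invaded(p, presence_threshold, copy_threshold),
            }
        )
    if not rows:
        return (
            pd.DataFrame(columns=["region", "year", "mean_canonical_fraction", "n_samples", "invaded"]),
            [],
        )
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["region", "year"])
        .agg(
            mean_canonical_fraction=("canonical_fraction", "mean"),
            n_samples=("canonical_fraction", "size"),
            invaded=("invaded", "any"),
        )
        .reset_index()
    )
    invaded_years = table.loc[table["invaded"], "year"]
    epicenters: List[str] = []
    if not invaded_years.empty:
        first_year = int(invaded_years.min())
        epicenters = sorted(table.loc[(table["year"] == first_year) & table["invaded"], "region"])
    return table, epicenters


def write_timeline_tsv(
    points: Sequence[SamplePoint], te_id: str, path: Union[str, Path]
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#sample\tdate\tregion\tte\tcopies_per_haploid\tcanonical_fraction\tn_snps\tinvaded\n")
        for p in points:
            fh.write(
                f"{p.sample_id}\t{'' if p.date is None else p.date}\t{p.region}\t{te_id}\t"
                f"{p.copies_per_haploid:.3f}\t{p.canonical_fraction:.4f}\t"
                f"{p.n_diagnostic_snps_used}\t{int(is_invaded(p))}\n"
            )
    return path


def write_snp_tsv(snps: Sequence[DiagnosticSNP], path: Union[str, Path]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#te\tpos_1based\tdegraded_allele\tcanonical_allele\tf_old\tf_young\n")
        for s in snps:
            fh.write(
                f"{s.te_id}\t{s.position + 1}\t{s.degraded_allele}\t{s.canonical_allele}\t"
                f"{s.f_old:.4f}\t{s.f_young:.4f}\n"
            )
    return path
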