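"""High-level analysis workflows over simulated or real sample series.

These functions wire the pipeline stages together on in-memory objects:
align pooled reads to the TE + single-copy-gene reference, build pileups,
call diagnostic SNPs between a pre- and post-invasion reference sample, and
summarize every sample into a dated :class:`~tetrack.timeline.SamplePoint`.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

from . import quantify, timeline
from .simulate import (
    InvasionSeries,
    SamplePointInputs,
    SimConfig,
    TEFamily,
    as_rng,
    draw_degraded_loci,
    make_single_copy_genes,
    simulate_pooled_sample,
)
from .quantify import TEPileup


def sample_pileups(
    sample: SamplePointInputs,
    references: Dict[str, str],
    min_identity: float = 0.8,
    end_mask: int = 5,
) -> Dict[str, TEPileup]:
    alignments = quantify.align_to_references(sample.reads, references, min_identity=min_identity)
    return quantify.pileup(alignments, references, end_mask=end_mask)


def analyze_series(
    series: InvasionSeries,
    old_sample: Optional[str] = None,
    young_sample: Optional[str] = None,
    min_depth: int = timeline.MIN_DEPTH,
) -> Tuple[List[timeline.DiagnosticSNP], List[timeline.SamplePoint]]:
    """Full tracking workflow on a simulated series.

    Diagnostic SNPs are called between ``old_sample`` (default: the earliest
    sample) and ``young_sample`` (default: the latest); every sample then
    gets a copy-number estimate and an averaged diagnostic-SNP canonical
    fraction.
    """
    te_id = series.family.te_id
    references = {te_id: series.family.consensus, **series.genes}
    piles = {sp.sample_id: sample_pileups(sp, references) for sp in series.samples}
    ordered = sorted(series.samples, key=lambda sp: sp.date)
    old_id = old_sample or ordered[0].sample_id
    young_id = young_sample or ordered[-1].sample_id
    snps = timeline.find_diagnostic_snps(
        piles[old_id][te_id], piles[young_id][te_id], min_depth=min_depth
    )
    # The presence/absence fallback is only meaningful for families with no
    # aligned reads in the pre-invasion sample (otherwise an old degraded
    # background would masquerade as a canonical invasion); with old-sample
    # coverage but no diagnostic site, the canonical signal is absent.
    fallback_valid = piles[old_id][te_id].total_depth == 0
    points: List[timeline.SamplePoint] = []
    for sp in series.samples:
        frac, n_used = timeline.canonical_fraction(piles[sp.sample_id][te_id], snps, min_depth=min_depth)
        if n_used == 0 and not fallback_valid:
            frac = 0.0
        est = quantify.copy_number(
            piles[sp.sample_id][te_id],
            [piles[sp.sample_id][g] for g in series.genes],
            sample_id=sp.sample_id,
        )
        points.append(
            timeline.SamplePoint(
                sp.sample_id, sp.date, sp.region, "pool", est.copies_per_haploid, frac, n_used
            )
        )
    return snps, points


def canonical_fraction_experiment(
    seed: int,
    fraction: float = 0.8,
    config: Optional[SimConfig] = None,
) -> float:
    """Recover the canonical fraction of one simulated pooled sample.

    Simulates a TE family whose insertions are ``fraction`` canonical (the
    rest degraded), plus an all-degraded old reference sample; calls
    diagnostic SNPs between the two and returns the averaged
    canonical-allele frequency in the mixed sample.
    """
    if config is None:
        config = SimConfig(seed=seed, genome_length=10_000, n_degraded=3)
    rng = as_rng(seed)
    family = TEFamily.generate("te1", config.te_length, config.degraded_divergence, rng)
    genes = make_single_copy_genes(seed=rng)
    references = {"te1": family.consensus, **genes}
    loci = draw_degraded_loci(family, config.n_degraded, config.canonical_divergence, rng)
    old = simulate_pooled_sample(family, genes, config, 0.0, rng, sample_id="old", degraded_loci=loci)
    young = simulate_pooled_sample(
        family, genes, config, fraction, rng, sample_id="young", degraded_loci=loci
    )
    old_piles = sample_pileups(old, references)
    young_piles = sample_pileups(young, references)
    snps = timeline.find_diagnostic_snps(old_piles["te1"], young_piles["te1"])
    frac, _ = timeline.canonical_fraction(young_piles["te1"], snps)
    return frac
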