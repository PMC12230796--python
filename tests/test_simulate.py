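"""Synthetic-data generator: determinism, mutation statistics, truth bookkeeping."""

import numpy as np
import pytest

from tetrack import simulate as sim
from tetrack.ht import pairwise_divergence
from tetrack.simulate import CANONICAL_BOUNDARY


class TestMakeTeFamily:
    def test_deterministic_given_seed(self):
        assert sim.make_te_family(3030, 5) == sim.make_te_family(3030, 5)

    def test_exact_length_and_alphabet(self):
        seq = sim.make_te_family(3030, 1)
        assert len(seq) == 3030
        assert set(seq) <= set("ACGT")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sim.make_te_family(99, 0)

    def test_independent_families_near_random_identity(self):
        # positional identity of two i.i.d. uniform sequences is Binomial(n, 1/4)
        a = sim.make_te_family(3030, 1)
        b = sim.make_te_family(3030, 2)
        ident = sum(x == y for x, y in zip(a, b)) / 3030
        sd = np.sqrt(0.25 * 0.75 / 3030)
        assert abs(ident - 0.25) < 4 * sd


class TestMutateSequence:
    def test_zero_rates_identity(self):
        seq = sim.make_te_family(500, 3)
        out, realized = sim.mutate_sequence(seq, 0.0, 0.0, 7)
        assert out == seq and realized == 0.0

    def test_divergence_within_binomial_noise(self):
        seq = sim.make_te_family(3000, 4)
        out, realized = sim.mutate_sequence(seq, 0.08, 0.0, 11)
        sd = np.sqrt(0.08 * 0.92 / 3000)
        assert abs(realized - 0.08) < 3 * sd
        # alignment-based estimate agrees with the recorded truth (the
        # edit-distance alignment may explain a few substitutions as indel
        # pairs, so it can sit slightly below the planted rate)
        assert abs(pairwise_divergence(seq, out) - realized) < 0.015

    def test_canonical_rate_stays_below_boundary(self):
        seq = sim.make_te_family(3000, 5)
        realized = [sim.mutate_sequence(seq, 0.005, 0.0, s)[1] for s in range(30)]
        assert all(r <= CANONICAL_BOUNDARY for r in realized)

    def test_indels_change_length(self):
        seq = sim.make_te_family(2000, 6)
        out, _ = sim.mutate_sequence(seq, 0.0, 0.05, 8)
        assert out != seq

    def test_invalid_divergence(self):
        with pytest.raises(ValueError):
            sim.mutate_sequence("ACGT", 0.8, 0.0, 0)


class TestBuildStrainGenome:
    def test_empty_spec_identity(self, family):
        base = {"chr1": sim.make_te_family(20000, 9)}
        out, truth = sim.build_strain_genome(base, [], {"te1": family}, sim.SimConfig(), 1)
        assert out == base and truth.insertions == []

    def test_count_and_length_bookkeeping(self, family):
        base = {"chr1": sim.make_te_family(60000, 9)}
        cfg = sim.SimConfig()
        out, truth = sim.build_strain_genome(base, [("te1", True, 5)], {"te1": family}, cfg, 1)
        assert len(truth.insertions) == 5
        assert all(t.is_canonical for t in truth.insertions)
        inserted = sum(t.end - t.start for t in truth.insertions)
        assert len(out["chr1"]) == len(base["chr1"]) + inserted

    def test_truth_coordinates_match_assembly(self, family):
        base = {"chr1": sim.make_te_family(60000, 10)}
        cfg = sim.SimConfig()
        out, truth = sim.build_strain_genome(
            base, [("te1", True, 3), ("te1", False, 2)], {"te1": family}, cfg, 2
        )
        for t in truth.insertions:
            copy = out[t.contig][t.start : t.end]
            # realized divergence of the spliced copy agrees with truth
            assert abs(pairwise_divergence(family.consensus, copy) - t.divergence) < 0.01

    def test_divergence_respects_canonical_boundary(self, family):
        base = {"chr1": sim.make_te_family(80000, 11)}
        out, truth = sim.build_strain_genome(
            base, [("te1", True, 4), ("te1", False, 4)], {"te1": family}, sim.SimConfig(), 3
        )
        for t in truth.insertions:
            if t.is_canonical:
                assert t.divergence <= CANONICAL_BOUNDARY
            else:
                assert t.divergence > CANONICAL_BOUNDARY

    def test_infeasible_placement_fails(self, family):
        base = {"chr1": sim.make_te_family(3000, 12)}
        with pytest.raises(ValueError):
            sim.build_strain_genome(base, [("te1", True, 50)], {"te1": family}, sim.SimConfig(), 4)


class TestSimulateReads:
    def test_read_count_formula(self):
        cfg = sim.SimConfig(depth=20, read_length=100)
        genome = {"chr1": sim.make_te_family(10000, 13)}
        reads = sim.simulate_reads(genome, cfg, 5)
        assert len(reads) == round(20 * 10000 / 100)

    def test_error_free_reads_are_substrings(self):
        cfg = sim.SimConfig(depth=5, read_length=80, error_rate=0.0)
        genome = {"chr1": sim.make_te_family(5000, 14)}
        fwd = genome["chr1"]
        rev = sim.revcomp(fwd)
        for r in sim.simulate_reads(genome, cfg, 6):
            assert r.sequence in fwd or r.sequence in rev

    def test_mean_depth_near_target(self):
        cfg = sim.SimConfig(depth=20, read_length=100, error_rate=0.0)
        genome = {"chr1": sim.make_te_family(100_000, 15)}
        reads = sim.simulate_reads(genome, cfg, 7)
        total = sum(len(r.sequence) for r in reads)
        mean_depth = total / 100_000
        assert abs(mean_depth - 20) < 3 * np.sqrt(20 / 1000)  # loose Poisson-scale bound

    def test_read_longer_than_contig_rejected(self):
        cfg = sim.SimConfig(read_length=200)
        with pytest.raises(ValueError):
            sim.simulate_reads({"chr1": "ACGT" * 10}, cfg, 0)

    def test_determinism(self):
        cfg = sim.SimConfig(depth=3)
        genome = {"chr1": sim.make_te_family(5000, 16)}
        r1 = sim.simulate_reads(genome, cfg, 8)
        r2 = sim.simulate_reads(genome, cfg, 8)
        assert r1 == r2


class TestInvasionSeries:
    def test_all_zero_trajectory_has_no_canonical_reads(self):
        cfg = sim.SimConfig(seed=1, genome_length=3000, depth=5)
        dates = [2000.0, 2001.0]
        series = sim.simulate_invasion_series(cfg, dates, {d: 0.0 for d in dates})
        assert series.truth.invasion_date is None
        for sp in series.samples:
            assert sp.n_canonical == 0 and sp.n_degraded >= 1
            assert not any(r.id.startswith("read_can") for r in sp.reads)

    def test_step_trajectory_sets_invasion_date(self):
        cfg = sim.SimConfig(seed=2, genome_length=3000, depth=5)
        dates = [2000.0, 2001.0, 2002.0]
        series = sim.simulate_invasion_series(cfg, dates, {2000.0: 0.0, 2001.0: 0.8, 2002.0: 0.8})
        assert series.truth.invasion_date == 2001.0

    def test_mixture_fraction_realized_in_reads(self):
        cfg = sim.SimConfig(seed=3, genome_length=0, depth=20, n_degraded=4)
        series = sim.simulate_invasion_series(cfg, [2000.0], {2000.0: 0.5})
        sp = series.samples[0]
        assert sp.true_fraction == 0.5
        te_reads = [r for r in sp.reads if "can_" in r.id or "deg_" in r.id]
        can = sum(1 for r in te_reads if "can_" in r.id)
        frac = can / len(te_reads)
        sd = np.sqrt(0.25 / len(te_reads))
        assert abs(frac - 0.5) < 3 * sd

    def test_decreasing_trajectory_rejected(self):
        cfg = sim.SimConfig(seed=4, genome_length=3000)
        with pytest.raises(ValueError):
            sim.simulate_invasion_series(cfg, [2000.0, 2001.0], {2000.0: 0.5, 2001.0: 0.2})
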