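"""Repeat annotation: scanning, classification, counting, similarity scores."""

import numpy as np
import pytest

from tetrack import annotate
from tetrack import simulate as sim
from tetrack.seqio import revcomp


def plant(rng, copies, spacer=4000):
    """Assembly with the given copy sequences separated by random spacers."""
    parts = [sim.random_sequence(spacer, rng)]
    coords = []
    for seq in copies:
        coords.append((sum(map(len, parts)), sum(map(len, parts)) + len(seq)))
        parts.append(seq)
        parts.append(sim.random_sequence(spacer, rng))
    return {"chr1": "".join(parts)}, coords


class TestScanAssembly:
    def test_exact_copy_found_with_zero_divergence(self, family, rng):
        assembly, coords = plant(rng, [family.consensus])
        (hit,) = annotate.scan_assembly(assembly, {"te1": family.consensus})
        assert hit.divergence == 0.0 and hit.te_span == 1.0 and hit.strand == "+"
        assert abs(hit.start - coords[0][0]) <= 10 and abs(hit.end - coords[0][1]) <= 10

    def test_diverged_copy_divergence_recovered(self, family, rng):
        copy, realized = sim.mutate_sequence(family.consensus, 0.08, 0, rng)
        assembly, _ = plant(rng, [copy])
        (hit,) = annotate.scan_assembly(assembly, {"te1": family.consensus})
        sd = 100 * np.sqrt(0.08 * 0.92 / 3000)
        assert abs(hit.divergence - 100 * realized) < 3 * sd
        assert hit.divergence < 20.0

    def test_short_fragment_filtered(self, family, rng):
        assembly, _ = plant(rng, [family.consensus[:200]])
        assert annotate.scan_assembly(assembly, {"te1": family.consensus}) == []

    def test_partial_copy_te_span(self, family, rng):
        assembly, _ = plant(rng, [family.consensus[:1500]])
        (hit,) = annotate.scan_assembly(assembly, {"te1": family.consensus})
        assert abs(hit.te_span - 0.5) < 0.02

    def test_minus_strand_copy_found(self, family, rng):
        assembly, coords = plant(rng, [revcomp(family.consensus)])
        (hit,) = annotate.scan_assembly(assembly, {"te1": family.consensus})
        assert hit.strand == "-" and hit.divergence == 0.0
        assert abs(hit.start - coords[0][0]) <= 10 and abs(hit.end - coords[0][1]) <= 10

    def test_strand_symmetry(self, family, rng):
        copy, _ = sim.mutate_sequence(family.consensus, 0.01, 0, rng)
        assembly, _ = plant(rng, [copy])
        fwd = annotate.scan_assembly(assembly, {"te1": family.consensus})
        rc = {"chr1": revcomp(assembly["chr1"])}
        rev = annotate.scan_assembly(rc, {"te1": family.consensus})
        assert len(fwd) == len(rev) == 1
        n = len(assembly["chr1"])
        assert rev[0].strand != fwd[0].strand
        assert (rev[0].start, rev[0].end) == (n - fwd[0].end, n - fwd[0].start)

    def test_every_planted_insertion_recovered(self, family, rng):
        cfg = sim.SimConfig()
        base = {"chr1": sim.random_sequence(60_000, rng)}
        genome, truth = sim.build_strain_genome(
            base, [("te1", True, 3), ("te1", False, 3)], {"te1": family}, cfg, rng
        )
        hits = annotate.scan_assembly(genome, {"te1": family.consensus})
        assert len(hits) == 6
        got = sorted((h.start, h.end) for h in hits)
        want = sorted((t.start, t.end) for t in truth.insertions)
        for (gs, ge), (ws, we) in zip(got, want):
            assert abs(gs - ws) <= 10 and abs(ge - we) <= 10

    def test_empty_library_rejected(self, rng):
        with pytest.raises(ValueError):
            annotate.scan_assembly({"c": "ACGT" * 100}, {})


def hit(div, te="te1", span=1.0):
    return annotate.RepeatHit("c", 0, 3000, "+", te, 1000.0, div, span)


class TestClassifyCount:
    @pytest.mark.parametrize(
        "divergence,expect_canonical",
        [(0.5, True), (5.0, False), (1.5, True), (1.50001, False), (0.0, True)],
    )
    def test_boundary_is_inclusive(self, divergence, expect_canonical):
        (h,) = annotate.classify_canonical([hit(divergence)])
        assert h.is_canonical is expect_canonical

    def test_counts_by_flag(self):
        hits = annotate.classify_canonical([hit(0.5)] * 0 + [hit(d) for d in (0.1, 1.0, 0.9, 2.0, 8.0)])
        assert annotate.count_canonical(hits) == {"te1": (3, 2)}

    def test_empty_hits(self):
        assert annotate.count_canonical([]) == {}

    def test_unclassified_hits_rejected(self):
        with pytest.raises(ValueError):
            annotate.count_canonical([hit(0.5)])


class TestExtractFullLength:
    def test_span_filter_and_orientation(self, family, rng):
        copy = family.consensus
        assembly, coords = plant(rng, [revcomp(copy), copy[:1200]])
        hits = annotate.scan_assembly(assembly, {"te1": family.consensus})
        out = annotate.extract_full_length(hits, assembly, min_span=0.8)
        assert len(out) == 1  # the 40%-span fragment is excluded
        (seq,) = out.values()
        # minus-strand insertion comes out oriented to the consensus strand
        ident = sum(a == b for a, b in zip(seq, copy)) / min(len(seq), len(copy))
        assert ident > 0.98


class TestSimilarity:
    def test_ratio_definition(self):
        scores = annotate.similarity_scores({"a1": 1000.0, "a2": 500.0, "a3": 0.0})
        by_id = {s.assembly_id: s.s for s in scores}
        assert by_id == {"a1": 1.0, "a2": 0.5, "a3": 0.0}

    def test_scale_invariance(self):
        base = {"a": 800.0, "b": 200.0}
        s1 = {x.assembly_id: x.s for x in annotate.similarity_scores(base)}
        s2 = {x.assembly_id: x.s for x in annotate.similarity_scores({k: 7 * v for k, v in base.items()})}
        assert s1 == s2

    def test_all_hitless_rejected(self):
        with pytest.raises(ValueError):
            annotate.similarity_scores({"a": 0.0, "b": 0.0})

    def test_exact_consensus_scores_one(self, family, rng):
        assembly, _ = plant(rng, [family.consensus])
        copy, _ = sim.mutate_sequence(family.consensus, 0.05, 0, rng)
        other, _ = plant(rng, [copy])
        best = {}
        for name, asm in (("exact", assembly), ("diverged", other)):
            hits = annotate.scan_assembly(asm, {"te1": family.consensus})
            best[name] = max(h.raw_score for h in hits)
        scores = {s.assembly_id: s.s for s in annotate.similarity_scores(best)}
        assert scores["exact"] == 1.0 and 0 < scores["diverged"] < 1


REPEATMASKER_OUT = """\
   SW   perc perc perc  query     position in query                matching       repeat            position in repeat
score   div. del. ins.  sequence  begin  end          (left)    repeat         class/family      begin  end    (left)   ID

 2500    1.2  0.0  0.0  chr1        101    3100 (96900) +  te1            Unknown                1  3000    (0)      1
 1200   12.5  0.5  0.1  chr1       5001    6500 (93500) C  te1            Unknown             (500) 2000     501      2
"""


class TestRepeatMaskerAdapter:
    def test_parses_coordinates_and_strand(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(REPEATMASKER_OUT)
        hits = annotate.read_repeatmasker_out(p)
        assert len(hits) == 2
        assert (hits[0].start, hits[0].end, hits[0].strand) == (100, 3100, "+")
        assert hits[0].divergence == 1.2 and hits[0].te_span == 1.0
        assert hits[1].strand == "-" and hits[1].raw_score == 1200.0
        assert abs(hits[1].te_span - 0.6) < 1e-9
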