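"""Operon joining, sub-operon detection and five-group reference comparison."""

import numpy as np
import pytest

from txarch.io_formats import CoverageTrack, GeneModel
from txarch.operons import (
    FIVE_GROUPS,
    OperonCall,
    OperonParams,
    call_operons,
    compare_to_reference,
    detect_suboperons,
    group_counts,
)
from txarch.quantify import phase_rpkm
from txarch.synthetic_data import generate_genome
from txarch.tss import TssCall, detect_tss


def _scene(rpkm_a, rpkm_b, gap_depth=5):
    """Two adjacent + strand genes (gap 101..110) with configurable gap depth."""
    genes = [GeneModel("a", "+", 1, 100), GeneModel("b", "+", 111, 210)]
    depth = np.zeros(300, dtype=int)
    depth[100:110] = gap_depth
    track = CoverageTrack("p", "16h", 0, "+", depth, total_mapped=10**5)
    minus = CoverageTrack("p", "16h", 0, "-", np.zeros(300, dtype=int), total_mapped=10**5)
    pooled = {"16h": {"+": track, "-": minus}}
    rpkm = {"16h": {"a": rpkm_a, "b": rpkm_b}}
    return genes, pooled, rpkm


class TestCallOperons:
    def test_ratio_below_two_joins(self):
        genes, pooled, rpkm = _scene(10.0, 19.0)
        units = call_operons(genes, pooled, rpkm)
        assert [u.genes for u in units] == [("a", "b")]

    def test_ratio_exactly_two_does_not_join(self):
        genes, pooled, rpkm = _scene(10.0, 20.0)
        units = call_operons(genes, pooled, rpkm)
        assert [u.genes for u in units] == [("a",), ("b",)]

    def test_single_uncovered_gap_base_blocks_the_join(self):
        genes, pooled, rpkm = _scene(10.0, 10.0, gap_depth=5)
        pooled["16h"]["+"].depth[105] = 0
        units = call_operons(genes, pooled, rpkm)
        assert [u.genes for u in units] == [("a",), ("b",)]

    def test_abutting_genes_join_without_gap_evidence(self):
        genes = [GeneModel("a", "+", 1, 100), GeneModel("b", "+", 101, 200)]
        depth = np.zeros(300, dtype=int)
        pooled = {
            "16h": {
                "+": CoverageTrack("p", "16h", 0, "+", depth, total_mapped=10**5),
                "-": CoverageTrack("p", "16h", 0, "-", depth.copy(), total_mapped=10**5),
            }
        }
        units = call_operons(genes, pooled, {"16h": {"a": 8.0, "b": 9.0}})
        assert [u.genes for u in units] == [("a", "b")]

    def test_both_silent_genes_never_join(self):
        genes, pooled, rpkm = _scene(0.0, 0.0)
        units = call_operons(genes, pooled, rpkm)
        assert [u.genes for u in units] == [("a",), ("b",)]

    def test_opposite_strands_never_join(self):
        genes = [GeneModel("a", "+", 1, 100), GeneModel("b", "-", 111, 210)]
        depth = np.full(300, 10, dtype=int)
        pooled = {
            "16h": {
                s: CoverageTrack("p", "16h", 0, s, depth.copy(), total_mapped=10**5)
                for s in "+-"
            }
        }
        units = call_operons(genes, pooled, {"16h": {"a": 10.0, "b": 10.0}})
        assert [u.genes for u in units] == [("a",), ("b",)]

    def test_join_decision_is_scale_invariant(self):
        """Multiplying every RPKM by c (and epsilon accordingly) changes nothing."""
        for ra, rb in [(10.0, 19.0), (10.0, 20.0), (3.0, 1.6)]:
            genes, pooled, rpkm = _scene(ra, rb)
            base = [u.genes for u in call_operons(genes, pooled, rpkm)]
            c = 13.0
            scaled_rpkm = {"16h": {g: v * c for g, v in rpkm["16h"].items()}}
            scaled = [
                u.genes
                for u in call_operons(genes, pooled, scaled_rpkm, OperonParams(epsilon=0.1 * c))
            ]
            assert base == scaled

    def test_unsorted_genes_rejected(self):
        genes, pooled, rpkm = _scene(10.0, 12.0)
        with pytest.raises(ValueError, match="sorted"):
            call_operons(list(reversed(genes)), pooled, rpkm)

    def test_missing_phase_rpkm_rejected(self):
        genes, pooled, rpkm = _scene(10.0, 12.0)
        del rpkm["16h"]["b"]
        with pytest.raises(ValueError, match="lacks RPKM"):
            call_operons(genes, pooled, rpkm)


class TestDetectSuboperons:
    def _unit(self, genes, strand="+"):
        return OperonCall(unit_id="u", genes=genes, strand=strand)

    def test_internal_tss_recorded_for_non_first_gene(self):
        calls = [
            TssCall(position=10, strand="+", gene_id="g1", step_score=5.0),
            TssCall(position=200, strand="+", gene_id="g2", step_score=5.0),
        ]
        (u,) = detect_suboperons([self._unit(("g1", "g2"))], calls)
        assert u.primary_tss == 10 and u.internal_tss == {"g2": 200}

    def test_first_gene_only_leaves_internal_empty(self):
        calls = [TssCall(position=10, strand="+", gene_id="g1", step_score=5.0)]
        (u,) = detect_suboperons([self._unit(("g1", "g2", "g3"))], calls)
        assert u.primary_tss == 10 and u.internal_tss == {}

    def test_minus_strand_first_gene_is_rightmost(self):
        calls = [TssCall(position=900, strand="-", gene_id="g2", step_score=5.0)]
        (u,) = detect_suboperons([self._unit(("g1", "g2"), strand="-")], calls)
        assert u.primary_tss == 900 and u.internal_tss == {}

    def test_monocistron_has_no_internal_tss(self):
        (u,) = detect_suboperons([self._unit(("g1",))], [])
        assert u.internal_tss == {}


def _unit(genes, internal=None, strand="+"):
    return OperonCall(
        unit_id="u_" + "_".join(genes),
        genes=tuple(genes),
        strand=strand,
        internal_tss=dict(internal or {}),
    )


class TestCompareToReference:
    def test_equal_sets_confirmed(self):
        (c,) = compare_to_reference([_unit(["g1", "g2"])], [("g1", "g2")])
        assert c.label == "confirmed"

    def test_reference_nested_in_call_extended(self):
        (c,) = compare_to_reference([_unit(["g1", "g2", "g3"])], [("g1", "g2")])
        assert c.label == "extended"

    def test_call_nested_in_reference_dismissed(self):
        (c,) = compare_to_reference([_unit(["g2", "g3"])], [("g1", "g2", "g3")])
        assert c.label == "dismissed" and not c.crossing_flag

    def test_no_overlap_is_new(self):
        (c,) = compare_to_reference([_unit(["g7", "g8"])], [("g1", "g2")])
        assert c.label == "new"

    def test_internal_tss_wins_as_alternative(self):
        (c,) = compare_to_reference(
            [_unit(["g1", "g2"], internal={"g2": 500})], [("g1", "g2")]
        )
        assert c.label == "alternative"

    def test_crossing_overlap_dismissed_with_flag(self):
        (c,) = compare_to_reference([_unit(["g2", "g3"])], [("g1", "g2")])
        assert c.label == "dismissed" and c.crossing_flag

    def test_monocistron_inside_reference_operon_dismissed(self):
        (c,) = compare_to_reference([_unit(["g2"])], [("g1", "g2")])
        assert c.label == "dismissed"

    def test_free_monocistron_unlabeled(self):
        (c,) = compare_to_reference([_unit(["g9"])], [("g1", "g2")])
        assert c.label == "unlabeled"

    def test_duplicate_reference_membership_rejected(self):
        with pytest.raises(ValueError, match="multiple reference"):
            compare_to_reference([_unit(["g1", "g2"])], [("g1", "g2"), ("g2", "g3")])

    def test_matches_brute_force_set_relation_classifier(self):
        """Randomized unit/reference layouts over <= 8-gene universes agree
        with a from-scratch set-relation classifier, and every multi-gene
        unit receives exactly one of the five labels."""
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(8)]
        for _ in range(300):
            n_unit = int(rng.integers(2, 6))
            unit_genes = list(rng.choice(universe, size=n_unit, replace=False))
            with_internal = bool(rng.random() < 0.3)
            internal = {unit_genes[-1]: 100} if with_internal else {}
            # partition some of the remaining genes into reference operons
            pool = list(rng.permutation(universe))
            refs = []
            while pool and len(refs) < 3:
                size = int(rng.integers(1, min(4, len(pool)) + 1))
                chunk, pool = pool[:size], pool[size:]
                if len(chunk) > 1 or rng.random() < 0.5:
                    refs.append(tuple(chunk))
            unit = _unit(unit_genes, internal=internal)
            (got,) = compare_to_reference([unit], refs)

            # independent oracle
            uset = frozenset(unit_genes)
            overlapping = [frozenset(r) for r in refs if uset & frozenset(r)]
            if internal:
                expected = "alternative"
            elif not overlapping:
                expected = "new"
            else:
                best = max(overlapping, key=lambda r: len(uset & r) / len(uset | r))
                if best == uset:
                    expected = "confirmed"
                elif best < uset:
                    expected = "extended"
                else:
                    expected = "dismissed"  # nested or crossing
            assert got.label == expected
            assert sum(got.label == lab for lab in FIVE_GROUPS) == 1

    def test_group_counts_cover_all_five_labels(self):
        units = [
            _unit(["g1", "g2"]),
            _unit(["g3", "g4", "g5"]),
            _unit(["g6", "g7"], internal={"g7": 5}),
            _unit(["a1", "a2"]),
        ]
        refs = [("g1", "g2"), ("g3", "g4"), ("g6", "g7")]
        counts = group_counts(compare_to_reference(units, refs))
        assert counts == {
            "confirmed": 1,
            "extended": 1,
            "dismissed": 0,
            "new": 1,
            "alternative": 1,
        }


class TestOnSyntheticTruth:
    def test_called_units_equal_planted_units(self, noiseless_dataset):
        _, truth, tracks = noiseless_dataset
        genes = sorted(truth.genes, key=lambda g: g.start)
        pooled = _pool(tracks)
        rpkm = phase_rpkm(tracks, genes)
        units = call_operons(genes, pooled, rpkm)
        assert sorted(u.genes for u in units) == sorted(truth.operons)
        # every gene in exactly one unit
        members = [g for u in units for g in u.genes]
        assert sorted(members) == sorted(g.gene_id for g in genes)

    def test_planted_internal_tss_yield_alternative_labels(self, noiseless_dataset):
        _, truth, tracks = noiseless_dataset
        genes = sorted(truth.genes, key=lambda g: g.start)
        units = call_operons(genes, _pool(tracks), phase_rpkm(tracks, genes))
        calls = [c for c in detect_tss(tracks, genes) if c.gene_id is not None]
        units = detect_suboperons(units, calls)
        multi_ref = [m for m in truth.operons if len(m) > 1]
        comparisons = {c.unit_id: c for c in compare_to_reference(units, multi_ref)}
        planted_alt_units = {truth.unit_of_gene[g] for g in truth.sub_operon_tss}
        got_alt = {u.unit_id for u in units if comparisons[u.unit_id].label == "alternative"}
        assert len(got_alt) == len(planted_alt_units)
        # all remaining multi-gene units are confirmed (reference is the truth)
        for u in units:
            if len(u.genes) > 1 and u.unit_id not in got_alt:
                assert comparisons[u.unit_id].label == "confirmed"


def _pool(tracks):
    from txarch.report import _pool_by_phase

    return _pool_by_phase(tracks)
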