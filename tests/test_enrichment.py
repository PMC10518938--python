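"""Fisher tests, BH correction, library enrichment and antigen collapse."""

import math
from math import comb

import numpy as np
import pytest

from dartf import (
    DARSet,
    GenomicInterval,
    bh_adjust,
    collapse_by_antigen,
    enrich,
    fisher_exact_two_tailed,
    filter_by_cell_type_class,
    simulate_condition,
    simulate_library,
    SimConfig,
)
from dartf.enrichment import EnrichmentResult

from conftest import make_peakset
from oracles import bh_oracle, fisher_two_tailed_oracle


class TestFisherExactTwoTailed:
    def test_mode_table_gives_one(self):
        assert fisher_exact_two_tailed(5, 5, 5, 5) == pytest.approx(1.0)

    def test_balanced_margins_enumeration(self):
        # margins (4,4)/(4,4): P(a) = C(4,a) C(4,4-a) / C(8,4); observed a=3
        # has P=16/70 and tables a in {0,1,3,4} qualify -> 34/70
        assert fisher_exact_two_tailed(3, 1, 1, 3) == pytest.approx(34 / 70, rel=1e-9)

    def test_perfectly_separated_table(self):
        # only a=0 and a=10 have point probability <= observed
        assert fisher_exact_two_tailed(0, 10, 10, 0) == pytest.approx(
            2 / comb(20, 10), rel=1e-9
        )

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_tailed(-1, 2, 3, 4)

    def test_degenerate_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_two_tailed(0, 0, 3, 4) == 1.0

    def test_matches_enumeration_oracle_small_margins(self):
        for n1 in range(1, 9):
            for n0 in range(1, 9):
                for a in range(n1 + 1):
                    for c in range(n0 + 1):
                        if a + c == 0 or (n1 - a) + (n0 - c) == 0:
                            continue
                        got = fisher_exact_two_tailed(a, n1 - a, c, n0 - c)
                        assert got == pytest.approx(
                            fisher_two_tailed_oracle(a, n1 - a, c, n0 - c), rel=1e-9
                        )

    def test_two_sided_symmetry_under_row_swap(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 30, size=4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            assert fisher_exact_two_tailed(a, b, c, d) == pytest.approx(
                fisher_exact_two_tailed(c, d, a, b), rel=1e-9
            )


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_hand_worked_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_adjust([0.5, 0.6]) == pytest.approx([0.6, 0.6])

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.1], [-0.1], [float("nan")]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)

    def test_matches_oracle_and_is_monotone_bounded(self, rng):
        for _ in range(200):
            p = rng.uniform(1e-12, 1.0, size=rng.integers(1, 40))
            q = bh_adjust(p)
            assert q == pytest.approx(bh_oracle(p), rel=1e-12)
            assert np.all(q <= 1.0) and np.all(q >= p)
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-15)


def _darset(opened, closed, condition="c1", genome="toy1"):
    return DARSet(condition_id=condition, genome=genome, opened=opened, closed=closed)


def _interval_row(chrom, i, hit):
    # queries at 1000-bp spacing; "hit" peaks sit on top of them
    return GenomicInterval(chrom, i * 1000, i * 1000 + 100)


class TestEnrich:
    def make_inputs(self):
        opened = tuple(GenomicInterval("chr1", i * 1000, i * 1000 + 100) for i in range(20))
        closed = tuple(GenomicInterval("chr2", i * 1000, i * 1000 + 100) for i in range(20))
        return _darset(opened, closed)

    def peaks_over(self, intervals, n, experiment_id, antigen):
        return make_peakset(
            [GenomicInterval(iv.chrom, iv.start, iv.end, 200) for iv in intervals[:n]],
            experiment_id=experiment_id,
            antigen=antigen,
        )

    def test_margins_conserved_and_counts_correct(self):
        dars = self.make_inputs()
        lib = [self.peaks_over(dars.opened, 15, "e1", "TFA"),
               self.peaks_over(dars.closed, 5, "e2", "TFB")]
        results = enrich(dars, lib)
        for r in results:
            assert r.a + r.b == len(dars.opened)
            assert r.c + r.d == len(dars.closed)
        by_id = {r.experiment_id: r for r in results}
        assert (by_id["e1"].a, by_id["e1"].c) == (15, 0)
        assert (by_id["e2"].a, by_id["e2"].c) == (0, 5)

    def test_no_overlap_experiment_is_null(self):
        dars = self.make_inputs()
        far = make_peakset([GenomicInterval("chr9", 0, 100, 200)], "e0", "TFZ")
        r = enrich(dars, [far])[0]
        assert (r.a, r.c) == (0, 0)
        assert r.p_value == 1.0
        assert r.enrichment_score == 0.0
        assert r.log2_fold_enrichment == 0.0

    def test_empty_side_refused(self):
        dars = _darset((), (GenomicInterval("chr1", 0, 10),))
        with pytest.raises(ValueError, match="cannot be tested"):
            enrich(dars, [make_peakset([GenomicInterval("chr1", 0, 10, 200)])])

    def test_mismatched_genome_build_refused(self):
        dars = self.make_inputs()
        lib = [make_peakset([GenomicInterval("chr1", 0, 10, 200)], genome="mm10")]
        with pytest.raises(ValueError, match="genome"):
            enrich(dars, lib)

    def test_library_order_does_not_change_q_values(self):
        dars = self.make_inputs()
        lib = [
            self.peaks_over(dars.opened, n, f"e{n}", f"TF{n}")
            for n in (3, 8, 12, 18)
        ]
        q1 = {r.experiment_id: r.q_value for r in enrich(dars, lib)}
        q2 = {r.experiment_id: r.q_value for r in enrich(dars, lib[::-1])}
        assert q1 == q2

    def test_swapping_sides_preserves_p_and_negates_fold_enrichment(self):
        dars = self.make_inputs()
        lib = [self.peaks_over(dars.opened, 15, "e1", "TFA")]
        fwd = enrich(dars, lib)[0]
        rev = enrich(_darset(dars.closed, dars.opened), lib)[0]
        assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-9)
        assert fwd.log2_fold_enrichment == pytest.approx(-rev.log2_fold_enrichment)

    def test_fold_enrichment_sign_tracks_rates(self):
        dars = self.make_inputs()
        enriched = enrich(dars, [self.peaks_over(dars.opened, 15, "e1", "A")])[0]
        depleted = enrich(dars, [self.peaks_over(dars.closed, 15, "e2", "B")])[0]
        assert enriched.log2_fold_enrichment > 0
        assert depleted.log2_fold_enrichment < 0

    def test_planted_experiment_attains_maximal_score(self, tiny_config):
        exposed, control, truth = simulate_condition(tiny_config)
        from dartf import intersect_replicates, detect_dars
        dars = detect_dars(
            intersect_replicates(exposed), intersect_replicates(control),
            tiny_config.condition_id, tiny_config.genome,
        )
        results = enrich(dars, simulate_library(tiny_config, truth))
        best = max(results, key=lambda r: r.enrichment_score)
        planted_ids = {
            r.experiment_id for r in results
            if r.antigen in truth.planted_tfs
        }
        assert best.experiment_id in planted_ids
        # per-experiment Fisher oracle agreement on the planted winner
        assert best.p_value == pytest.approx(
            fisher_two_tailed_oracle(best.a, best.b, best.c, best.d), rel=1e-6
        )


def _res(exp, antigen, score, lfe=1.0, q=0.5):
    return EnrichmentResult(exp, antigen, "all", 1, 1, 1, 1, q, q, score, lfe)


class TestCollapseByAntigen:
    def test_highest_score_adopted(self):
        out = collapse_by_antigen([_res("e1", "X", 5.0), _res("e2", "X", 8.0)])
        assert [r.experiment_id for r in out] == ["e2"]

    def test_single_result_identity(self):
        out = collapse_by_antigen([_res("e1", "X", 5.0)])
        assert [r.experiment_id for r in out] == ["e1"]

    def test_tie_breaks_on_abs_fold_enrichment_then_id(self):
        out = collapse_by_antigen(
            [_res("e1", "X", 3.0, lfe=0.4), _res("e2", "X", 3.0, lfe=-1.2)]
        )
        assert out[0].experiment_id == "e2"
        out = collapse_by_antigen(
            [_res("e2", "X", 3.0, lfe=1.2), _res("e1", "X", 3.0, lfe=1.2)]
        )
        assert out[0].experiment_id == "e1"

    def test_output_size_equals_distinct_antigens(self, rng):
        results = [
            _res(f"e{i}", f"TF{int(rng.integers(0, 7))}", float(rng.uniform(0, 10)))
            for i in range(40)
        ]
        out = collapse_by_antigen(results)
        assert len(out) == len({r.antigen for r in results})


def test_cell_type_class_filter_passthrough_and_subset():
    lib = [make_peakset([], experiment_id="e1", cell_type_class="Blood"),
           make_peakset([], experiment_id="e2", cell_type_class="Liver")]
    assert len(filter_by_cell_type_class(lib, None)) == 2
    assert [ps.experiment_id for ps in filter_by_cell_type_class(lib, "Liver")] == ["e2"]
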