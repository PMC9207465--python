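"""Gene-level carrier collapsing and the three-part candidate criteria."""

import numpy as np
import pytest

from pdascreen.burden import (
    BurdenCriteria,
    burden_test,
    collapse_carriers,
    top_burden_heatmap_data,
)
from pdascreen.cohort_io import CohortGenotypes
from pdascreen.stats import ContingencyTable2x2, fisher_exact_2x2


def build_cohort(n_cases, n_controls, rows, variant_genes, variant_factory):
    samples = [f"CA{i}" for i in range(n_cases)] + [f"CO{i}" for i in range(n_controls)]
    groups = ["case"] * n_cases + ["control"] * n_controls
    vids = [f"v{i}" for i in range(len(rows))]
    cohort = CohortGenotypes(vids, samples, groups, np.array(rows, dtype=np.int8))
    ann = [
        variant_factory(variant_id=vid, gene=g, pos=100 + i)
        for i, (vid, g) in enumerate(zip(vids, variant_genes))
    ]
    return cohort, ann


class TestCollapse:
    def test_carrier_deduplication(self, variant_factory):
        # case0 carries v0 and v1, case1 carries v1 -> 2 distinct carriers
        rows = [
            [1, 0, 0, 0, 0, 0],
            [1, 1, 0, 0, 0, 0],
        ]
        cohort, ann = build_cohort(3, 3, rows, ["G1", "G1"], variant_factory)
        col = collapse_carriers(cohort, ann)
        assert col["G1"].table.a == 2
        assert col["G1"].max_case_hits_single_variant == 2
        assert col["G1"].n_variants_in_gene == 2

    def test_margins_conserved(self, variant_factory):
        rows = [[1, 0, 1, 0, 1, 0], [0, 1, 0, 0, 0, 1]]
        cohort, ann = build_cohort(3, 3, rows, ["G1", "G2"], variant_factory)
        for col in collapse_carriers(cohort, ann).values():
            assert col.table.a + col.table.b == 3
            assert col.table.c + col.table.d == 3

    def test_zero_control_cohort_table(self, variant_factory):
        row = [1] * 4 + [0] * 35 + [0] * 100
        cohort, ann = build_cohort(39, 100, [row], ["G1"], variant_factory)
        col = collapse_carriers(cohort, ann)
        assert col["G1"].table == ContingencyTable2x2(4, 35, 0, 100)

    def test_missing_never_counts_as_carrier(self, variant_factory):
        rows = [[-1, 1, 0, 0, 0, 0]]
        cohort, ann = build_cohort(3, 3, rows, ["G1"], variant_factory)
        assert collapse_carriers(cohort, ann)["G1"].table.a == 1

    def test_unmapped_variant_rejected(self, variant_factory):
        rows = [[1, 0, 0, 0, 0, 0]]
        cohort, ann = build_cohort(3, 3, rows, ["G1"], variant_factory)
        with pytest.raises(ValueError, match="v0"):
            collapse_carriers(cohort, [])


class TestBurdenTest:
    def _cohort(self, variant_factory):
        """Four genes: PASS satisfies everything; LOWHITS has only 2 case
        hits on its best variant; CTRL has a control carrier; WEAK has an
        insignificant p."""
        n_cases, n_controls = 39, 100
        pass_row = [1] * 4 + [0] * (n_cases - 4) + [0] * n_controls
        lowhits_rows = [
            [1, 1] + [0] * (n_cases - 2) + [0] * n_controls,
            [0, 0, 1, 1] + [0] * (n_cases - 4) + [0] * n_controls,
        ]
        ctrl_row = [1] * 5 + [0] * (n_cases - 5) + [1] + [0] * (n_controls - 1)
        weak_row = [1] * 3 + [0] * (n_cases - 3) + [1] * 6 + [0] * (n_controls - 6)
        rows = [pass_row] + lowhits_rows + [ctrl_row, weak_row]
        genes = ["PASS", "LOWHITS", "LOWHITS", "CTRL", "WEAK"]
        return build_cohort(n_cases, n_controls, rows, genes, variant_factory)

    def test_three_part_criteria(self, variant_factory):
        cohort, ann = self._cohort(variant_factory)
        results = {r.gene: r for r in burden_test(collapse_carriers(cohort, ann))}
        assert results["PASS"].passes
        assert results["PASS"].p == pytest.approx(0.005523, abs=1e-5)
        # 4 carriers but no single variant hit in >= 3 cases
        assert results["LOWHITS"].table.a == 4
        assert not results["LOWHITS"].passes
        # control carrier present
        assert not results["CTRL"].passes
        # p above alpha
        assert results["WEAK"].p >= 0.05 and not results["WEAK"].passes

    def test_per_gene_hit_unit_switch(self, variant_factory):
        cohort, ann = self._cohort(variant_factory)
        results = {
            r.gene: r
            for r in burden_test(
                collapse_carriers(cohort, ann), BurdenCriteria(hit_unit="per_gene")
            )
        }
        # 4 distinct case carriers satisfy the per-gene reading
        assert results["LOWHITS"].passes

    def test_zero_control_closed_form(self, variant_factory):
        """With no control carriers the upper-tail p collapses to
        prod_{i<a} (n_cases - i) / (N - i)."""
        n_cases, n_controls = 39, 100
        for a in (1, 3, 5, 10):
            row = [1] * a + [0] * (n_cases - a) + [0] * n_controls
            cohort, ann = build_cohort(n_cases, n_controls, [row], ["G"], variant_factory)
            p = burden_test(collapse_carriers(cohort, ann))[0].p
            closed = np.prod(
                [(n_cases - i) / (n_cases + n_controls - i) for i in range(a)]
            )
            assert p == pytest.approx(closed, rel=1e-12)

    def test_sorted_by_p_then_gene(self, variant_factory):
        cohort, ann = self._cohort(variant_factory)
        results = burden_test(collapse_carriers(cohort, ann))
        keys = [(r.p, r.gene) for r in results]
        assert keys == sorted(keys)

    def test_q_from_bh_over_all_genes(self, variant_factory):
        cohort, ann = self._cohort(variant_factory)
        results = burden_test(collapse_carriers(cohort, ann))
        assert all(r.q >= r.p - 1e-12 for r in results)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            burden_test({})


class TestHeatmap:
    def test_rows_normalized_per_gene(self, variant_factory):
        # case0 carries two of G1's variants, case1 carries one
        rows = [
            [1, 0, 0, 0, 0, 0],
            [1, 1, 0, 0, 0, 0],
        ]
        cohort, ann = build_cohort(3, 3, rows, ["G1", "G1"], variant_factory)
        results = burden_test(collapse_carriers(cohort, ann))
        genes, cases, mat = top_burden_heatmap_data(results, cohort, ann, k=10)
        assert genes == ["G1"]
        assert len(cases) == 3
        assert mat[0].tolist() == [1.0, 0.5, 0.0]

    def test_k_larger_than_genes_returns_all(self, variant_factory):
        rows = [[1, 0, 0, 0, 0, 0], [0, 1, 0, 0, 0, 0]]
        cohort, ann = build_cohort(3, 3, rows, ["G1", "G2"], variant_factory)
        results = burden_test(collapse_carriers(cohort, ann))
        genes, _, _ = top_burden_heatmap_data(results, cohort, ann, k=99)
        assert sorted(genes) == ["G1", "G2"]

    def test_single_carrier_rows_are_unit(self, variant_factory):
        row = [1, 1, 1, 0, 0, 0, 0, 0]
        cohort, ann = build_cohort(4, 4, [row], ["G1"], variant_factory)
        results = burden_test(collapse_carriers(cohort, ann))
        _, _, mat = top_burden_heatmap_data(results, cohort, ann)
        assert mat[0].tolist() == [1.0, 1.0, 1.0, 0.0]
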