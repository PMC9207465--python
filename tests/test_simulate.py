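"""Synthetic cohort generator: shape, determinism, and calibration."""

import numpy as np
import pytest

from pdascreen.cohort_io import annotations_to_frame
from pdascreen.filters import filter_rare_damaging, is_damaging, is_rare
from pdascreen.simulate import (
    InvalidConfigError,
    SimulationConfig,
    generate_cohort,
    generate_resources,
)
from pdascreen.stats import variant_association


def small_cfg(**kw):
    base = dict(n_null_genes=20, n_planted_genes=3, seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_cases": 0},
            {"variants_per_gene": 0},
            {"case_carrier_prob": 1.5},
            {"control_carrier_prob": -0.1},
            {"maf_range_rare": (0.001, 0.01)},
            {"maf_range_rare": (0.004, 0.002)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(**kwargs)

    def test_substitution_weights_normalized(self):
        cfg = SimulationConfig(substitution_weights={"C>T": 2.0, "G>A": 2.0})
        assert sum(cfg.substitution_weights.values()) == pytest.approx(1.0)


class TestCohortGeneration:
    def test_dimensions_forced_by_config(self):
        cfg = SimulationConfig(
            n_cases=39, n_controls=100, n_null_genes=1000,
            n_planted_genes=5, variants_per_gene=1, seed=7,
        )
        cohort, records, truth = generate_cohort(cfg)
        assert cohort.genotypes.shape == (1005, 139)
        assert len(records) == 1005
        assert cohort.n_cases == 39 and cohort.n_controls == 100
        assert len(truth.planted_genes) == 5

    def test_identical_seed_identical_output(self):
        a = generate_cohort(small_cfg())
        b = generate_cohort(small_cfg())
        assert np.array_equal(a[0].genotypes, b[0].genotypes)
        assert a[1] == b[1]
        assert a[2] == b[2]

    def test_different_seed_differs(self):
        a = generate_cohort(small_cfg(seed=1))
        b = generate_cohort(small_cfg(seed=2))
        assert not np.array_equal(a[0].genotypes, b[0].genotypes)

    def test_zero_control_prob_means_zero_control_carriers(self):
        for seed in range(5):
            _, _, truth = generate_cohort(small_cfg(seed=seed, control_carrier_prob=0.0))
            assert all(v == 0 for v in truth.control_carriers.values())

    def test_planted_variants_all_rare_damaging(self):
        cohort, records, truth = generate_cohort(small_cfg(damaging_fraction=0.5))
        planted = set(truth.planted_genes)
        for rec in records:
            if rec.gene in planted:
                assert is_rare(rec) and is_damaging(rec)
        gt, kept = filter_rare_damaging(cohort, records)
        assert planted <= {r.gene for r in kept}

    def test_case_carrier_mean_matches_binomial(self):
        """Realized case carriers per planted gene average n_cases * p."""
        p, n_cases, n_seeds = 0.12, 39, 400
        counts = []
        for seed in range(n_seeds):
            _, _, truth = generate_cohort(
                small_cfg(seed=seed, case_carrier_prob=p, n_null_genes=2)
            )
            counts.extend(truth.case_carriers.values())
        mean = np.mean(counts)
        se = np.sqrt(n_cases * p * (1 - p) / len(counts))
        assert abs(mean - n_cases * p) < 3 * se

    def test_substitution_spectrum_majority_transition(self):
        """C>T plus G>A fraction matches the configured joint weight."""
        cohort, records, _ = generate_cohort(
            SimulationConfig(n_null_genes=2000, n_planted_genes=5, seed=3)
        )
        frac = np.mean([r.snv_class in ("C>T", "G>A") for r in records])
        n = len(records)
        se = np.sqrt(0.6 * 0.4 / n)
        assert abs(frac - 0.6) < 3 * se
        assert frac > 0.5  # jointly the majority

    def test_snv_class_consistent_with_alleles(self):
        _, records, _ = generate_cohort(small_cfg())
        for rec in records:
            assert rec.snv_class == f"{rec.ref}>{rec.alt}"

    def test_mafs_inside_rare_range(self):
        _, records, _ = generate_cohort(small_cfg(maf_range_rare=(0.001, 0.003)))
        mafs = np.array([r.maf for r in records])
        assert np.all((mafs >= 0.001) & (mafs < 0.003))

    def test_missing_rate_honored_and_never_carrier(self):
        cohort, _, _ = generate_cohort(small_cfg(missing_rate=0.2, n_null_genes=200))
        frac_missing = np.mean(cohort.genotypes == -1)
        assert 0.15 < frac_missing < 0.25

    def test_annotation_frame_matches_matrix_order(self):
        cohort, records, _ = generate_cohort(small_cfg())
        frame = annotations_to_frame(records)
        assert list(frame["variant_id"]) == cohort.variant_ids


class TestNullExchangeability:
    def test_label_permutation_leaves_significance_rate_unchanged(self):
        """Under the global null the case/control labels are exchangeable:
        the significant fraction is statistically indistinguishable after
        permuting group labels (Monte-Carlo over seeds)."""
        rng = np.random.default_rng(0)
        orig, perm = [], []
        for seed in range(30):
            cfg = small_cfg(
                seed=seed, n_null_genes=60,
                case_carrier_prob=0.05, control_carrier_prob=0.05, null_carrier_prob=0.05,
            )
            cohort, _, _ = generate_cohort(cfg)
            res = variant_association(cohort, mode="carrier")
            orig.append(np.mean([r.p < 0.05 for r in res]))
            labels = list(cohort.group_labels)
            rng.shuffle(labels)
            cohort.group_labels = labels
            res_p = variant_association(cohort, mode="carrier")
            perm.append(np.mean([r.p < 0.05 for r in res_p]))
        # both are tiny under the null; difference must be within MC noise
        diff = abs(np.mean(orig) - np.mean(perm))
        pooled_se = np.sqrt((np.var(orig) + np.var(perm)) / 30)
        assert diff <= 3 * max(pooled_se, 1e-3)


class TestResources:
    def test_planted_genes_fill_cardiac_set(self):
        cfg = small_cfg()
        _, _, truth = generate_cohort(cfg)
        res = generate_resources(cfg, truth)
        _, members = res.gene_sets.sets[res.cardiac_term_id]
        assert set(truth.planted_genes) <= members
        n_genes = cfg.n_planted_genes + cfg.n_null_genes
        assert len(members) == min(cfg.cardiac_set_size, n_genes)

    def test_expression_has_seven_stage_columns(self):
        cfg = small_cfg()
        _, _, truth = generate_cohort(cfg)
        res = generate_resources(cfg, truth)
        assert res.expression.stages == [f"S{i}" for i in range(10, 17)]

    def test_planted_vs_null_known_degree(self):
        """Edge probabilities 0.5 vs 0.02 to 20 known genes give mean
        planted degree near 10 and null near 0.4 over seeds."""
        planted_deg, null_deg = [], []
        for seed in range(20):
            cfg = small_cfg(seed=seed, n_null_genes=50)
            _, _, truth = generate_cohort(cfg)
            res = generate_resources(cfg, truth)
            known = frozenset().union(*res.known_lists.values())
            deg = {}
            for a, b, _ in res.edges:
                if b in known and a not in known:
                    deg[a] = deg.get(a, 0) + 1
            for g in truth.planted_genes:
                planted_deg.append(deg.get(g, 0))
            for g in [f"GENE{i + 1:05d}" for i in range(50)]:
                null_deg.append(deg.get(g, 0))
        n_known = 2 * cfg.n_known_per_list
        se_planted = np.sqrt(n_known * 0.5 * 0.5 / len(planted_deg))
        se_null = np.sqrt(n_known * 0.02 * 0.98 / len(null_deg))
        assert abs(np.mean(planted_deg) - 0.5 * n_known) < 3 * se_planted
        assert abs(np.mean(null_deg) - 0.02 * n_known) < 3 * se_null

    def test_planted_expression_elevated(self):
        cfg = small_cfg()
        _, _, truth = generate_cohort(cfg)
        res = generate_resources(cfg, truth)
        means = res.expression.values.mean(axis=1)
        planted_mean = means.loc[list(truth.planted_genes)].min()
        null_median = means.drop(list(truth.planted_genes)).median()
        assert planted_mean > null_median

    def test_empty_truth_rejected(self):
        from pdascreen.simulate import TruthSet

        with pytest.raises(ValueError):
            generate_resources(small_cfg(), TruthSet((), {}, {}, {}))

    def test_resources_deterministic(self):
        cfg = small_cfg()
        _, _, truth = generate_cohort(cfg)
        r1 = generate_resources(cfg, truth)
        r2 = generate_resources(cfg, truth)
        assert r1.edges == r2.edges
        assert r1.gene_sets.sets == r2.gene_sets.sets
        assert r1.expression.values.equals(r2.expression.values)
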