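import numpy as np
import pytest

from pdascreen.cohort_io import CohortGenotypes, VariantRecord


def make_variant(**kwargs) -> VariantRecord:
    defaults = dict(
        variant_id="v1",
        chrom="1",
        pos=1000,
        ref="C",
        alt="T",
        gene="GENEA",
        func_class="missense",
        snv_class="C>T",
        maf=0.001,
        predictor_verdicts={"sift": "damaging", "polyphen": "damaging", "mutationtaster": "damaging"},
        acmg_class="VUS",
    )
    defaults.update(kwargs)
    return VariantRecord(**defaults)


@pytest.fixture
def variant_factory():
    return make_variant


@pytest.fixture
def small_cohort():
    """4 cases / 6 controls, 3 variants in 2 genes with known carrier layout.

    v1 (GENEA): cases 1,2 het;  v2 (GENEA): case 1 het, control 1 het;
    v3 (GENEB): case 3 hom-alt, one control genotype missing.
    """
    samples = [f"CASE{i}" for i in range(1, 5)] + [f"CTRL{i}" for i in range(1, 7)]
    groups = ["case"] * 4 + ["control"] * 6
    genotypes = np.array(
        [
            [1, 1, 0, 0, 0, 0, 0, 0, 0, 0],
            [1, 0, 0, 0, 1, 0, 0, 0, 0, 0],
            [0, 0, 2, 0, -1, 0, 0, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    cohort = CohortGenotypes(["v1", "v2", "v3"], samples, groups, genotypes)
    annotations = [
        make_variant(variant_id="v1", gene="GENEA", pos=100),
        make_variant(variant_id="v2", gene="GENEA", pos=200, func_class="nonsense", snv_class="G>A", ref="G", alt="A"),
        make_variant(variant_id="v3", gene="GENEB", pos=300, chrom="2"),
    ]
    return cohort, annotations
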