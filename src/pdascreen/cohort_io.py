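"""Reading and writing the cohort's on-disk formats.

Genotypes arrive as a minimal VCFv4.2 (GT-only FORMAT honoured) or as a
variant x sample dosage matrix TSV, always with a case/control sample
sheet; per-variant annotations are a TSV standing in for an annotator's
output. Coordinates are 1-based, VCF convention. Multi-allelic sites are
split into one biallelic record per alt allele at read time, and gzip
input is transparent.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1  # matrix code for a missing genotype

FUNC_CLASSES = ("splice_site", "nonsense", "frameshift", "missense", "synonymous", "other")
ACMG_CLASSES = ("pathogenic", "likely_pathogenic", "VUS", "likely_benign", "benign")
PREDICTOR_VERDICTS = ("damaging", "tolerated", "unknown")
BASES = "ACGT"
SNV_CLASSES = tuple(f"{r}>{a}" for r in BASES for a in BASES if r != a) + ("indel",)

ANNOTATION_COLUMNS = [
    "variant_id", "chrom", "pos", "ref", "alt", "gene", "func_class",
    "maf", "sift", "polyphen", "mutationtaster", "acmg_class", "snv_class",
]
_REQUIRED_ANNOTATION_COLUMNS = [
    "variant_id", "gene", "func_class", "maf",
    "sift", "polyphen", "mutationtaster", "acmg_class", "snv_class",
]


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant: locus, alleles, and the fields the screen uses."""

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    func_class: str
    snv_class: str
    maf: float
    predictor_verdicts: dict[str, str] = field(default_factory=dict)
    acmg_class: str = "VUS"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1")
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"{self.variant_id}: maf {self.maf} outside [0, 1]")

    @property
    def n_damaging_predictors(self) -> int:
        return sum(1 for v in self.predictor_verdicts.values() if v == "damaging")


@dataclass
class CohortGenotypes:
    """Variant x sample alt-dosage matrix with case/control labels.

    Entries are 0/1/2 alt-allele dosage; missing genotypes are coded -1
    and never count as carriers.
    """

    variant_ids: list[str]
    sample_ids: list[str]
    group_labels: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.variant_ids), len(self.sample_ids)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.variant_ids)} variants x {len(self.sample_ids)} samples"
            )
        if len(self.group_labels) != len(self.sample_ids):
            raise ValueError("every sample needs a group label")
        bad = sorted(set(self.group_labels) - {"case", "control"})
        if bad:
            raise ValueError(f"unknown group labels: {bad}")

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([g == "case" for g in self.group_labels])

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_controls(self) -> int:
        return len(self.sample_ids) - self.n_cases

    def subset_variants(self, keep: Sequence[int]) -> "CohortGenotypes":
        idx = list(keep)
        return CohortGenotypes(
            [self.variant_ids[i] for i in idx],
            list(self.sample_ids),
            list(self.group_labels),
            self.genotypes[idx, :],
        )


@dataclass(frozen=True)
class CohortSummary:
    """Per-group carried-variant counts by functional and SNV class.

    A variant counts for a group if at least one sample of that group
    carries at least one alt allele; a variant carried in both groups
    counts once in each.
    """

    n_cases: int
    n_controls: int
    case_func_counts: dict[str, int]
    control_func_counts: dict[str, int]
    case_snv_counts: dict[str, int]
    control_snv_counts: dict[str, int]
    n_associated_defects: int | None = None  # cases with an additional cardiac defect

    @property
    def associated_defect_proportion(self) -> float | None:
        if self.n_associated_defects is None or self.n_cases == 0:
            return None
        return self.n_associated_defects / self.n_cases


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """sample_id -> group ('case' | 'control') from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"sample sheet missing required column '{col}'")
    bad = sorted(set(df["group"]) - {"case", "control"})
    if bad:
        raise ValueError(f"sample sheet has unknown groups: {bad}")
    return dict(zip(df["sample_id"], df["group"]))


def _gt_to_dosage(alleles: list, alt_index: int) -> int:
    called = [a for a in alleles if a >= 0]
    if not called:
        return MISSING
    return sum(1 for a in called if a == alt_index)


def read_vcf_genotypes(vcf_path: str | Path, sheet_path: str | Path) -> CohortGenotypes:
    """Parse GT fields of a VCF as alt-allele dosage, splitting multi-allelics.

    0/0 -> 0, 0/1 -> 1, 1/1 -> 2, ./. -> missing; a record with ALT "A,T"
    yields two rows whose variant ids carry an allele suffix.
    """
    groups = read_sample_sheet(sheet_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in groups]
    if unknown:
        raise ValueError(f"VCF sample(s) missing from sample sheet: {', '.join(unknown)}")
    variant_ids: list[str] = []
    rows: list[list[int]] = []
    for var in vcf:
        base_id = var.ID or f"{var.CHROM}:{var.POS}:{var.REF}"
        gts = var.genotypes  # [[a1, a2, phased], ...]
        for ai, alt in enumerate(var.ALT, start=1):
            vid = base_id if len(var.ALT) == 1 else f"{base_id}_alt{ai}"
            variant_ids.append(vid)
            rows.append([_gt_to_dosage(g[:-1], ai) for g in gts])
    return CohortGenotypes(
        variant_ids, samples, [groups[s] for s in samples], np.array(rows, dtype=np.int8)
    )


def read_matrix_genotypes(matrix_path: str | Path, sheet_path: str | Path) -> CohortGenotypes:
    """Dosage matrix TSV (variant_id column + one column per sample)."""
    groups = read_sample_sheet(sheet_path)
    df = pd.read_csv(matrix_path, sep="\t", dtype=str).set_index("variant_id")
    unknown = [s for s in df.columns if s not in groups]
    if unknown:
        raise ValueError(f"matrix sample(s) missing from sample sheet: {', '.join(unknown)}")
    mat = np.full(df.shape, MISSING, dtype=np.int8)
    for i, (vid, row) in enumerate(df.iterrows()):
        for j, val in enumerate(row):
            if val in (".", "NA", "", None) or (isinstance(val, float) and np.isnan(val)):
                continue
            try:
                dosage = int(val)
            except (TypeError, ValueError):
                raise ValueError(
                    f"malformed genotype {val!r} for variant {vid} (matrix line {i + 2})"
                ) from None
            if dosage not in (0, 1, 2, MISSING):
                raise ValueError(
                    f"genotype dosage {dosage} out of range for variant {vid} (matrix line {i + 2})"
                )
            mat[i, j] = dosage
    samples = list(df.columns)
    return CohortGenotypes(list(df.index), samples, [groups[s] for s in samples], mat)


def read_genotypes(path: str | Path, sheet_path: str | Path) -> CohortGenotypes:
    """Dispatch on extension: .vcf[.gz] -> VCF reader, else matrix TSV."""
    name = Path(path).name
    if name.endswith((".vcf", ".vcf.gz")):
        return read_vcf_genotypes(path, sheet_path)
    return read_matrix_genotypes(path, sheet_path)


def write_sample_sheet(genotypes: CohortGenotypes, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": genotypes.sample_ids, "group": genotypes.group_labels}
    ).to_csv(path, sep="\t", index=False)


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    genotypes: CohortGenotypes, annotations: Sequence[VariantRecord], path: str | Path
) -> None:
    """Minimal VCFv4.2: CHROM POS ID REF ALT QUAL=. FILTER=PASS INFO=. FORMAT=GT."""
    by_id = {rec.variant_id: rec for rec in annotations}
    missing = [vid for vid in genotypes.variant_ids if vid not in by_id]
    if missing:
        raise ValueError(f"no annotation for variant(s): {', '.join(missing[:5])}")
    def _chrom_key(c: str) -> tuple[int, str]:
        return (0, c.zfill(2)) if c.isdigit() else (1, c)

    contigs = sorted({rec.chrom for rec in by_id.values()}, key=_chrom_key)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        # coordinate-ordered output
        keyed = sorted(
            range(len(genotypes.variant_ids)),
            key=lambda i: (
                _chrom_key(by_id[genotypes.variant_ids[i]].chrom),
                by_id[genotypes.variant_ids[i]].pos,
            ),
        )
        for i in keyed:
            rec = by_id[genotypes.variant_ids[i]]
            gts = "\t".join(_DOSAGE_TO_GT[int(g)] for g in genotypes.genotypes[i])
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.variant_id}\t{rec.ref}\t{rec.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_matrix(genotypes: CohortGenotypes, path: str | Path) -> None:
    df = pd.DataFrame(
        genotypes.genotypes, index=genotypes.variant_ids, columns=genotypes.sample_ids
    )
    df = df.astype(object).where(df != MISSING, ".")
    df.index.name = "variant_id"
    df.to_csv(path, sep="\t")


def annotations_to_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "gene": r.gene,
                "func_class": r.func_class,
                "maf": r.maf,
                "sift": r.predictor_verdicts.get("sift", "unknown"),
                "polyphen": r.predictor_verdicts.get("polyphen", "unknown"),
                "mutationtaster": r.predictor_verdicts.get("mutationtaster", "unknown"),
                "acmg_class": r.acmg_class,
                "snv_class": r.snv_class,
            }
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotations(records: Iterable[VariantRecord], path: str | Path) -> None:
    annotations_to_frame(records).to_csv(path, sep="\t", index=False)


def _coerce_enum(value, allowed: tuple, fallback: str, counter: dict) -> str:
    text = str(value).strip() if value is not None and not pd.isna(value) else ""
    if text in allowed:
        return text
    counter["n"] += 1
    return fallback


def read_annotations(path: str | Path) -> list[VariantRecord]:
    """Annotation TSV -> VariantRecords.

    Empty/NA MAF is read as 0.0 (absent from every reference panel counts
    as rare); unrecognized enum strings map to other/unknown with a logged
    warning count.
    """
    df = pd.read_csv(_open_text(path), sep="\t", dtype={"chrom": str})
    missing = [c for c in _REQUIRED_ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing required column(s): {', '.join(missing)}")
    unknown = {"n": 0}
    records = []
    for _, row in df.iterrows():
        maf = row["maf"]
        maf = 0.0 if pd.isna(maf) or maf == "" else float(maf)
        verdicts = {
            tool: _coerce_enum(row[tool], PREDICTOR_VERDICTS, "unknown", unknown)
            for tool in ("sift", "polyphen", "mutationtaster")
        }
        records.append(
            VariantRecord(
                variant_id=str(row["variant_id"]),
                chrom=str(row.get("chrom", "1")),
                pos=int(row.get("pos", 1)),
                ref=str(row.get("ref", "N")),
                alt=str(row.get("alt", "N")),
                gene=str(row["gene"]),
                func_class=_coerce_enum(row["func_class"], FUNC_CLASSES, "other", unknown),
                snv_class=_coerce_enum(row["snv_class"], SNV_CLASSES, "indel", unknown),
                maf=maf,
                predictor_verdicts=verdicts,
                acmg_class=_coerce_enum(row["acmg_class"], ACMG_CLASSES, "VUS", unknown),
            )
        )
    if unknown["n"]:
        logger.warning("read_annotations: %d unrecognized enum value(s) mapped to fallback", unknown["n"])
    return records


def summarize_cohort(
    genotypes: CohortGenotypes,
    annotations: Sequence[VariantRecord],
    n_associated_defects: int | None = None,
) -> CohortSummary:
    """Count group-carried variants by functional class and SNV class."""
    by_id = {r.variant_id: r for r in annotations}
    missing = [v for v in genotypes.variant_ids if v not in by_id]
    if missing:
        raise ValueError(f"no annotation for carried variant(s): {', '.join(missing[:5])}")
    case_mask = genotypes.case_mask
    case_func: dict[str, int] = {c: 0 for c in FUNC_CLASSES}
    ctrl_func: dict[str, int] = {c: 0 for c in FUNC_CLASSES}
    case_snv: dict[str, int] = {c: 0 for c in SNV_CLASSES}
    ctrl_snv: dict[str, int] = {c: 0 for c in SNV_CLASSES}
    for i, vid in enumerate(genotypes.variant_ids):
        rec = by_id[vid]
        row = genotypes.genotypes[i]
        carried = row >= 1
        if np.any(carried & case_mask):
            case_func[rec.func_class] += 1
            case_snv[rec.snv_class] += 1
        if np.any(carried & ~case_mask):
            ctrl_func[rec.func_class] += 1
            ctrl_snv[rec.snv_class] += 1
    return CohortSummary(
        n_cases=genotypes.n_cases,
        n_controls=genotypes.n_controls,
        case_func_counts=case_func,
        control_func_counts=ctrl_func,
        case_snv_counts=case_snv,
        control_snv_counts=ctrl_snv,
        n_associated_defects=n_associated_defects,
    )
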