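"""Genotype ingestion and per-variant quality control.

Reads biallelic SNP genotypes from VCF, PLINK text (.ped/.map) or a plain
dosage table into a subjects x variants effect-allele dosage matrix, and
applies the three standard per-variant QC filters used for array/WGS
genotype panels:

* call missingness (fail when > ``max_missingness``),
* minor allele frequency (fail when < ``min_maf``),
* Hardy-Weinberg equilibrium exact-test p-value (fail when < ``min_hwe_p``).

Dosage is always counted with respect to ``allele_b`` (the ALT allele for
VCF input). Missing calls are stored as ``numpy.nan``. The HWE test is the
two-sided conditional exact test (sum of the probabilities of all
heterozygote counts, given the allele counts, that are no more probable
than the observed count), computed in exact integer arithmetic.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class GenotypeParseError(ValueError):
    """Raised when an input genotype file cannot be parsed."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant; dosage in the matrix counts ``allele_b``."""

    variant_id: str
    chromosome: str
    position: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.variant_id}: allele_a == allele_b")
        if self.position < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1")


@dataclass
class GenotypeMatrix:
    """Subjects x variants dosage matrix (values 0/1/2 or nan for missing)."""

    subjects: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.subjects), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.variants)} variants"
            )
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = self.dosage[~ok].flat[0]
            raise ValueError(f"dosage values must be 0/1/2/nan, found {bad!r}")
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            dup = pd.Index(ids)
            raise ValueError(
                f"duplicate variant ids: {sorted(dup[dup.duplicated()].unique())}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def variant_index(self) -> dict[str, int]:
        return {v.variant_id: i for i, v in enumerate(self.variants)}

    def subset_variants(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            subjects=list(self.subjects),
            variants=[self.variants[i] for i in keep],
            dosage=self.dosage[:, keep].copy(),
        )


@dataclass(frozen=True)
class QCThresholds:
    """Per-variant QC cutoffs. Equality always passes (strict comparisons)."""

    max_missingness: float = 0.02
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("max_missingness", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Per-variant QC statistics, fail flags, and sequential stage counts."""

    table: pd.DataFrame
    n_before: int
    n_after_missingness: int
    n_after_maf: int
    n_after_hwe: int
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    @property
    def n_after(self) -> int:
        return self.n_after_hwe

    @property
    def retained_ids(self) -> list[str]:
        return self.table.loc[self.table["retained"], "variant_id"].tolist()

    @property
    def failed_ids(self) -> list[str]:
        return self.table.loc[~self.table["retained"], "variant_id"].tolist()

    def summary(self) -> dict:
        return {
            "n_before": self.n_before,
            "n_after_missingness": self.n_after_missingness,
            "n_after_maf": self.n_after_maf,
            "n_after_hwe": self.n_after_hwe,
            "n_after": self.n_after,
            "thresholds": {
                "max_missingness": self.thresholds.max_missingness,
                "min_maf": self.thresholds.min_maf,
                "min_hwe_p": self.thresholds.min_hwe_p,
            },
            "filter_order": ["missingness", "maf", "hwe"],
        }

    def write(self, out_prefix: str | Path) -> tuple[Path, Path]:
        """Write the per-variant table as TSV and the stage counts as JSON."""
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        tsv = out_prefix.with_name(out_prefix.name + ".qc_report.tsv")
        js = out_prefix.with_name(out_prefix.name + ".qc_summary.json")
        self.table.to_csv(tsv, sep="\t", index=False, na_rep="NA")
        js.write_text(json.dumps(self.summary(), indent=2) + "\n")
        return tsv, js


# ---------------------------------------------------------------------------
# Per-variant statistics
# ---------------------------------------------------------------------------

def variant_missingness(m: GenotypeMatrix, v: int) -> float:
    """Fraction of subjects with a missing call at variant index ``v``."""
    col = m.dosage[:, v]
    return float(np.isnan(col).mean())


def variant_maf(m: GenotypeMatrix, v: int) -> float:
    """Minor allele frequency at variant ``v`` among non-missing calls."""
    col = m.dosage[:, v]
    col = col[~np.isnan(col)]
    if col.size == 0:
        raise ValueError(
            f"MAF undefined for all-missing variant {m.variants[v].variant_id}"
        )
    f = col.sum() / (2.0 * col.size)
    return float(min(f, 1.0 - f))


def genotype_counts(m: GenotypeMatrix, v: int) -> tuple[int, int, int]:
    """(n_aa, n_ab, n_bb) non-missing genotype counts at variant ``v``."""
    col = m.dosage[:, v]
    col = col[~np.isnan(col)]
    return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value for one biallelic variant.

    Conditions on the observed allele counts and sums, over every feasible
    heterozygote count, the probabilities that are no larger than that of
    the observed heterozygote count. The conditional probability of ``h``
    heterozygotes given ``n`` diploid subjects with ``n_a`` copies of allele
    a is ``n! / (n_aa! h! n_bb!) * 2**h * n_a! n_b! / (2n)!``; only the
    numerator varies with ``h``, so the test reduces to exact integer
    weights ``w(h) = n! / (((n_a-h)/2)! h! ((n_b-h)/2)!) * 2**h``.

    Computed in exact rational arithmetic; the returned float is the
    correctly rounded p-value.
    """
    counts = (n_aa, n_ab, n_bb)
    if any(int(c) != c or c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers: {counts}")
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:  # monomorphic: single feasible configuration
        return 1.0
    w_obs = _hwe_weight(n, n_a, n_ab)
    num = 0
    den = 0
    for h in _feasible_het_counts(n_a, n_b):
        w = _hwe_weight(n, n_a, h)
        den += w
        if w <= w_obs:
            num += w
    return float(Fraction(num, den))


def _feasible_het_counts(n_a: int, n_b: int) -> Iterable[int]:
    start = n_a % 2  # heterozygote count shares parity with the allele count
    return range(start, min(n_a, n_b) + 1, 2)


def _hwe_weight(n: int, n_a: int, h: int) -> int:
    aa = (n_a - h) // 2
    bb = n - aa - h
    return (math.factorial(n) // (math.factorial(aa) * math.factorial(h) * math.factorial(bb))) << h


def hwe_chisq_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """One-degree-of-freedom chi-square HWE test (optional alternative)."""
    from scipy import stats

    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype required")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def apply_qc(
    m: GenotypeMatrix, t: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter variants by missingness, MAF and HWE (in that order).

    A variant is retained iff missingness <= max_missingness AND
    maf >= min_maf AND hwe_p >= min_hwe_p; boundary equality passes.
    All three statistics are reported for every variant (MAF and HWE on
    non-missing calls); all-missing variants are assigned MAF 0 and fail
    the MAF filter rather than raising. Stage counts are sequential:
    ``n_after_maf`` counts variants passing both missingness and MAF.
    """
    if t is None:
        t = QCThresholds()
    if m.n_variants == 0 or m.n_subjects == 0:
        raise ValueError("cannot QC an empty genotype matrix")

    rows = []
    for v in range(m.n_variants):
        miss = variant_missingness(m, v)
        n_aa, n_ab, n_bb = genotype_counts(m, v)
        n_called = n_aa + n_ab + n_bb
        if n_called == 0:
            maf, hwe_p = 0.0, 1.0  # all-missing: fails MAF by convention
        else:
            maf = variant_maf(m, v)
            hwe_p = hwe_exact_p(n_aa, n_ab, n_bb)
        rows.append(
            {
                "variant_id": m.variants[v].variant_id,
                "missingness": miss,
                "maf": maf,
                "hwe_p": hwe_p,
                "fail_missingness": miss > t.max_missingness,
                "fail_maf": maf < t.min_maf,
                "fail_hwe": hwe_p < t.min_hwe_p,
            }
        )
    table = pd.DataFrame(rows)
    table["retained"] = ~(
        table["fail_missingness"] | table["fail_maf"] | table["fail_hwe"]
    )

    pass_miss = ~table["fail_missingness"]
    pass_maf = pass_miss & ~table["fail_maf"]
    report = QCReport(
        table=table,
        n_before=m.n_variants,
        n_after_missingness=int(pass_miss.sum()),
        n_after_maf=int(pass_maf.sum()),
        n_after_hwe=int(table["retained"].sum()),
        thresholds=t,
    )
    keep = np.flatnonzero(table["retained"].to_numpy())
    logger.info(
        "QC: %d -> %d variants (missingness %d, maf %d, hwe %d removed at stage)",
        report.n_before,
        report.n_after,
        report.n_before - report.n_after_missingness,
        report.n_after_missingness - report.n_after_maf,
        report.n_after_maf - report.n_after_hwe,
    )
    return m.subset_variants(keep), report


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from ``vcf``, ``plink_text`` (.ped/.map) or
    ``dosage_table`` (TSV) into a :class:`GenotypeMatrix`.

    Dosage counts allele_b (ALT for VCF). Phased and unphased calls are
    treated identically; half-calls and non-diploid calls become missing.
    Multi-allelic VCF sites are skipped with a warning.
    """
    readers = {
        "vcf": _read_vcf,
        "plink_text": _read_plink_text,
        "dosage_table": read_dosage_table,
    }
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(readers)}")
    return readers[format](Path(path))


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    seen: set[str] = set()
    for rec in vcf:
        if len(rec.ALT) != 1:
            warnings.warn(
                f"skipping multi-allelic site {rec.CHROM}:{rec.POS} "
                f"({rec.REF}/{','.join(rec.ALT) or '.'})"
            )
            continue
        vid = rec.ID if rec.ID not in (None, ".") else (
            f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        )
        if vid in seen:
            raise GenotypeParseError(f"duplicate variant id {vid!r} in {path}")
        seen.add(vid)
        col = np.full(len(subjects), MISSING)
        for i, call in enumerate(rec.genotypes):
            alleles = call[:-1]  # trailing element is the phasing flag
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                continue  # half-call or non-diploid -> missing
            col[i] = float(sum(1 for a in alleles if a == 1))
        variants.append(
            VariantRecord(vid, str(rec.CHROM), int(rec.POS), rec.REF, rec.ALT[0])
        )
        columns.append(col)
    dosage = (
        np.column_stack(columns) if columns else np.empty((len(subjects), 0))
    )
    return GenotypeMatrix(subjects=subjects, variants=variants, dosage=dosage)


def _read_plink_text(path: Path) -> GenotypeMatrix:
    """Read a PLINK text pair. ``path`` may point at either file or the stem.

    .map: chrom, variant_id, cM, position. .ped: FID IID PAT MAT SEX PHENO
    then two allele columns per variant ('0' = missing). Allele_b is taken
    as the minor allele observed in the file (ties broken alphabetically),
    matching PLINK's A1 convention.
    """
    stem = path.with_suffix("") if path.suffix in (".ped", ".map") else path
    ped, mapf = stem.with_suffix(".ped"), stem.with_suffix(".map")
    for f in (ped, mapf):
        if not f.exists():
            raise FileNotFoundError(f)

    variants_meta = []
    for lineno, line in enumerate(mapf.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise GenotypeParseError(f"{mapf}:{lineno}: expected 4 columns")
        variants_meta.append((parts[0], parts[1], int(parts[3])))
    ids = [v[1] for v in variants_meta]
    if len(set(ids)) != len(ids):
        raise GenotypeParseError(f"{mapf}: duplicate variant ids")
    n_var = len(variants_meta)

    subjects: list[str] = []
    geno_rows: list[list[tuple[str, str]]] = []
    for lineno, line in enumerate(ped.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_var:
            raise GenotypeParseError(
                f"{ped}:{lineno}: expected {6 + 2 * n_var} fields, got {len(parts)}"
            )
        subjects.append(parts[1])
        geno_rows.append(
            [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_var)]
        )

    variants: list[VariantRecord] = []
    dosage = np.full((len(subjects), n_var), MISSING)
    for j, (chrom, vid, pos) in enumerate(variants_meta):
        counts: dict[str, int] = {}
        for row in geno_rows:
            for a in row[j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        alleles = sorted(counts, key=lambda a: (-counts[a], a))
        if len(alleles) > 2:
            raise GenotypeParseError(f"{ped}: variant {vid} has >2 alleles {alleles}")
        if len(alleles) == 0:
            alleles = ["A", "B"]  # all-missing variant; placeholder alleles
        elif len(alleles) == 1:
            alleles = alleles + ["B" if alleles[0] != "B" else "b"]
        allele_a, allele_b = alleles[0], alleles[1]
        for i, row in enumerate(geno_rows):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                continue
            dosage[i, j] = float((a1 == allele_b) + (a2 == allele_b))
        variants.append(VariantRecord(vid, chrom, pos, allele_a, allele_b))
    return GenotypeMatrix(subjects=subjects, variants=variants, dosage=dosage)


def read_dosage_table(path: Path) -> GenotypeMatrix:
    """Read a TSV dosage table: header ``subject_id`` then variant ids,
    cells 0/1/2/NA. Variant ids of the form chrom:pos:ref:alt carry their
    own metadata; otherwise placeholder alleles A/B are assigned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA"])
    if df.columns[0] != "subject_id":
        raise GenotypeParseError(
            f"{path}: first column must be 'subject_id', got {df.columns[0]!r}"
        )
    vids = list(df.columns[1:])
    if len(set(vids)) != len(vids):
        raise GenotypeParseError(f"{path}: duplicate variant ids in header")
    variants = []
    for k, vid in enumerate(vids):
        parts = vid.split(":")
        if len(parts) == 4 and parts[1].isdigit():
            variants.append(VariantRecord(vid, parts[0], int(parts[1]), parts[2], parts[3]))
        else:
            variants.append(VariantRecord(vid, "0", k + 1, "A", "B"))
    dosage = df.iloc[:, 1:].to_numpy(dtype=float)
    bad = np.nonzero(~(np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0))))
    if bad[0].size:
        i, j = bad[0][0], bad[1][0]
        raise GenotypeParseError(
            f"{path}: invalid dosage {dosage[i, j]!r} for subject "
            f"{df.iloc[i, 0]!r}, variant {vids[j]!r}"
        )
    return GenotypeMatrix(
        subjects=df["subject_id"].astype(str).tolist(),
        variants=variants,
        dosage=dosage,
    )


def write_dosage_table(m: GenotypeMatrix, path: str | Path) -> Path:
    """Write the matrix as a TSV dosage table (round-trips through
    :func:`read_dosage_table`)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(m.dosage, columns=m.variant_ids)
    df = df.map(lambda x: "NA" if np.isnan(x) else str(int(x)))
    df.insert(0, "subject_id", m.subjects)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_vcf(m: GenotypeMatrix, path: str | Path) -> Path:
    """Write the matrix as a minimal plain-text VCF (GT only, unphased)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen_contigs: list[str] = []
        for v in m.variants:
            if v.chromosome not in seen_contigs:
                seen_contigs.append(v.chromosome)
        for c in seen_contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.subjects)
            + "\n"
        )
        for j in range(m.n_variants):  # matrix order, so round-trips preserve it
            v = m.variants[j]
            calls = "\t".join(
                "./." if np.isnan(d) else gt_map[d] for d in m.dosage[:, j]
            )
            fh.write(
                f"{v.chromosome}\t{v.position}\t{v.variant_id}\t{v.allele_a}\t"
                f"{v.allele_b}\t.\tPASS\t.\tGT\t{calls}\n"
            )
    return path


def is_strand_ambiguous(allele_a: str, allele_b: str) -> bool:
    """True for A/T and C/G SNPs, whose strand cannot be resolved."""
    return _COMPLEMENT.get(allele_a.upper()) == allele_b.upper()
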