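"""Dosage call-set container, VCF/TSV round-trips and variant inclusion rules.

The association analyses operate on genotype *dosages* — expected minor-allele
counts in [0, 2] produced by imputation — together with per-variant metadata
(position, alleles, MAF, MAC, imputation quality).  Variants enter association
testing only if biallelic, with minor allele count >= 4 and imputation
quality r^2 > 0.7 (strict); retained variants are binned as common
(MAF >= 5%), low-frequency (< 5%) with an additional rare flag below 1%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import MonomorphicError, VcfFormatError

__all__ = [
    "DosageMatrix",
    "FilterReport",
    "estimate_imputation_quality",
    "maf_bin",
    "filter_variants",
    "read_dosage_vcf",
    "write_dosage_vcf",
    "read_phenotype_table",
    "write_phenotype_table",
]

#: metadata columns every DosageMatrix carries
VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "rsq", "is_biallelic", "kind"]

COMMON = "common"
LOW_FREQUENCY = "low_frequency"

MAF_COMMON_MIN = 0.05  # inclusive: MAF >= 5% is common
MAF_RARE_MAX = 0.01  # exclusive: MAF < 1% is additionally flagged rare


@dataclass
class DosageMatrix:
    """Variants x samples dosages in [0, 2] plus per-variant metadata.

    ``variants`` holds at least :data:`VARIANT_COLUMNS`; ``maf`` and ``mac``
    are (re)computed from the dosages on construction.  MAC is counted on
    dosages rounded to the nearest hard genotype, which keeps the count stable
    under small dosage noise; MAF is the folded mean dosage / 2.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (variants x samples) array")
        if self.dosages.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        if self.dosages.size and (
            np.nanmin(self.dosages) < -1e-9 or np.nanmax(self.dosages) > 2 + 1e-9
        ):
            raise ValueError("dosages must lie in [0, 2]")
        self.variants = self.variants.reset_index(drop=True)
        self.recompute_stats()

    # -- derived statistics ------------------------------------------------
    def recompute_stats(self) -> None:
        """Refresh the maf/mac columns from the current dosages."""
        if len(self.variants) == 0:
            self.variants["maf"] = pd.Series(dtype=float)
            self.variants["mac"] = pd.Series(dtype=int)
            return
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            af = np.nanmean(self.dosages, axis=1) / 2.0
        maf = np.minimum(af, 1.0 - af)
        hard = np.rint(np.nan_to_num(self.dosages, nan=0.0))
        alt_count = hard.sum(axis=1)
        total = 2.0 * np.sum(~np.isnan(self.dosages), axis=1)
        mac = np.minimum(alt_count, total - alt_count)
        self.variants["maf"] = maf
        self.variants["mac"] = mac.astype(int)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take(self, indices: np.ndarray) -> "DosageMatrix":
        """Row subset (variants) as a new matrix."""
        idx = np.asarray(indices)
        return DosageMatrix(
            dosages=self.dosages[idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
        )


@dataclass
class FilterReport:
    """Bookkeeping for the variant inclusion rules.

    Removal counts are attributed sequentially (biallelic, then MAC, then
    quality) so they add up with the retained count to the input count.
    """

    n_input: int
    n_removed_not_biallelic: int
    n_removed_mac: int
    n_removed_quality: int
    n_retained: int
    n_common: int
    n_low_frequency: int
    n_rare: int  # subset of low-frequency with MAF < 1%
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_not_biallelic + self.n_removed_mac + self.n_removed_quality
        )
        assert self.n_input == removed + self.n_retained
        assert self.n_common + self.n_low_frequency == self.n_retained


def estimate_imputation_quality(dosages: np.ndarray) -> float:
    """MaCH-style variance-ratio imputation quality of one dosage vector.

    r^2 = empirical dosage variance / 2p(1-p) with p the mean dosage / 2,
    clipped to [0, 1].  A fully informative dosage vector (hard genotypes in
    Hardy-Weinberg proportions) scores ~1; a constant vector at 2p scores 0.
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size < 2:
        raise ValueError("need at least 2 non-missing dosages")
    p = d.mean() / 2.0
    if p <= 0.0 or p >= 1.0:
        raise MonomorphicError("imputation quality undefined for a monomorphic variant")
    return float(np.clip(d.var(ddof=1) / (2.0 * p * (1.0 - p)), 0.0, 1.0))


def maf_bin(maf: float) -> tuple[str, bool]:
    """Bin a variant by minor allele frequency.

    Returns ``(label, rare_flag)`` with label ``"common"`` for MAF >= 5% and
    ``"low_frequency"`` below; the flag marks MAF < 1%.
    """
    m = float(maf)
    if m <= 0.0:
        raise MonomorphicError("monomorphic variant is untestable")
    if m > 0.5:
        raise ValueError(f"minor allele frequency cannot exceed 0.5, got {m}")
    if m >= MAF_COMMON_MIN:
        return COMMON, False
    return LOW_FREQUENCY, m < MAF_RARE_MAX


def filter_variants(
    matrix: DosageMatrix,
    mac_min: int = 4,
    quality_min: float = 0.7,
    require_biallelic: bool = True,
) -> tuple[DosageMatrix, FilterReport]:
    """Apply the variant inclusion rules and report the bookkeeping.

    Rules (boundaries verbatim): biallelic only, MAC >= ``mac_min``
    (inclusive), imputation quality strictly > ``quality_min``.
    """
    v = matrix.variants
    n_input = len(v)
    ok = np.ones(n_input, dtype=bool)

    bad_biallelic = np.zeros(n_input, dtype=bool)
    if require_biallelic:
        bad_biallelic = ~v["is_biallelic"].to_numpy(dtype=bool)
        ok &= ~bad_biallelic

    bad_mac = ok & (v["mac"].to_numpy() < mac_min)
    ok &= ~bad_mac

    bad_quality = ok & ~(v["rsq"].to_numpy(dtype=float) > quality_min)
    ok &= ~bad_quality

    kept = matrix.take(np.flatnonzero(ok))
    maf = kept.variants["maf"].to_numpy()
    n_common = int(np.sum(maf >= MAF_COMMON_MIN))
    n_low = int(np.sum(maf < MAF_COMMON_MIN))
    n_rare = int(np.sum(maf < MAF_RARE_MAX))
    report = FilterReport(
        n_input=n_input,
        n_removed_not_biallelic=int(bad_biallelic.sum()),
        n_removed_mac=int(bad_mac.sum()),
        n_removed_quality=int(bad_quality.sum()),
        n_retained=int(ok.sum()),
        n_common=n_common,
        n_low_frequency=n_low,
        n_rare=n_rare,
        params={
            "mac_min": mac_min,
            "quality_min": quality_min,
            "require_biallelic": require_biallelic,
        },
    )
    return kept, report


# ---------------------------------------------------------------------------
# VCF round-trip
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=RSQ,Number=1,Type=Float,Description="Imputation quality (variance ratio r2)">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">
"""


def write_dosage_vcf(matrix: DosageMatrix, path: str) -> None:
    """Write a VCF 4.2 with per-sample DS and an RSQ INFO key."""
    v = matrix.variants
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in pd.unique(v["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i in range(matrix.n_variants):
            row = v.iloc[i]
            info = f"RSQ={row['rsq']:.4f}"
            ds = "\t".join(f"{d:.3f}" for d in matrix.dosages[i])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t{info}\tDS\t{ds}\n"
            )


def read_dosage_vcf(path: str) -> DosageMatrix:
    """Read a dosage VCF (per-sample DS FORMAT field) into a DosageMatrix.

    Multi-allelic sites are readable but flagged ``is_biallelic=False`` (the
    first ALT's dosage is kept).  Missing DS entries become NaN.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VcfFormatError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    rows, dos = [], []
    for line_no, rec in enumerate(vcf, start=1):
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is None:
            raise VcfFormatError(
                f"record {line_no} ({rec.CHROM}:{rec.POS}) has no DS field"
            )
        ds = np.asarray(ds, dtype=float)
        if ds.ndim == 2:
            ds = ds[:, 0]
        ds = np.where((ds < -0.5) | (ds > 2.5), np.nan, np.clip(ds, 0.0, 2.0))
        alts = rec.ALT
        rsq = rec.INFO.get("RSQ", rec.INFO.get("R2", rec.INFO.get("DR2", np.nan)))
        ref, alt = rec.REF, (alts[0] if alts else ".")
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": ref,
                "alt": alt,
                "rsq": float(rsq) if rsq is not None else np.nan,
                "is_biallelic": len(alts) == 1,
                "kind": "snp" if len(ref) == 1 and len(alt) == 1 else "indel",
            }
        )
        dos.append(ds)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = np.vstack(dos) if dos else np.empty((0, len(samples)))
    return DosageMatrix(dosages=dosages, variants=variants, samples=samples)


# ---------------------------------------------------------------------------
# Phenotype / covariate tables
# ---------------------------------------------------------------------------


def write_phenotype_table(table: pd.DataFrame, path: str) -> None:
    """Write a samples x columns table as TSV with a ``sample_id`` column."""
    out = table.copy()
    out.insert(0, "sample_id", table.index)
    out.to_csv(path, sep="\t", index=False)


def read_phenotype_table(path: str) -> pd.DataFrame:
    """Read a TSV phenotype/covariate table indexed by ``sample_id``."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise VcfFormatError(f"{path!r} has no sample_id column")
    return df.set_index("sample_id")
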