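"""Synthetic low-pass-sequencing cohorts with known causal architecture.

Every downstream stage of the pipeline (filtering, association, multiplicity,
conditional classification, QC) is exercised on cohorts generated here, so the
generator emulates the features of an imputed low-pass call set that those
stages actually consume:

* an allele-frequency spectrum mixing common (MAF >= 5%) and low-frequency
  (< 5%) variants, by default in equal proportion — mirroring a call set in
  which low-frequency variants are roughly as numerous as common ones;
* block-structured linkage disequilibrium: within an LD block every haplotype
  carries one of a small number of founder lineages, and variant carrier sets
  are unions of (prefixes of) lineages, so r^2 is elevated within a block and
  near zero across block boundaries;
* per-variant imputation quality: genotypes are degraded to dosages whose
  variance-ratio r^2 matches a target, the way an imputation tool's reported
  metric behaves;
* additive cis effects of specified variance explained, covariate effects
  (age, sex, batches), an optional polygenic component tied to a kinship
  matrix, and Gaussian noise topping variance up to 1.

Nothing here models reads, recombination within blocks, or coalescent
genealogies; see the methods note for what that does and does not buy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CapacityError
from .io_filters import VARIANT_COLUMNS, DosageMatrix

__all__ = [
    "AlleleFrequencySpectrum",
    "HaplotypePool",
    "QualitySpec",
    "SibshipSpec",
    "Cohort",
    "PhenotypeTable",
    "simulate_haplotype_pool",
    "sample_cohort",
    "degrade_to_dosages",
    "make_truth_table",
    "simulate_traits",
    "make_covariates",
    "make_probe_annotation",
    "simulate_tagged_locus",
    "write_truth_table",
]

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ["C", "T"],
    "G": ["C", "T"],
    "C": ["A", "G"],
    "T": ["A", "G"],
}


@dataclass(frozen=True)
class AlleleFrequencySpectrum:
    """Mixture AFS: a low-frequency component below 5% and a common component.

    Each variant draws its component with probability ``low_fraction`` and its
    frequency from a Beta stretched over the component's range.  The low
    component is skewed toward its lower end (rare variants outnumber those
    near 5%); the common component is mildly U-shaped over [5%, 50%].
    """

    low_fraction: float = 0.5
    low_range: tuple[float, float] = (0.003, 0.05)
    low_beta: tuple[float, float] = (0.7, 1.4)
    common_range: tuple[float, float] = (0.05, 0.5)
    common_beta: tuple[float, float] = (0.9, 0.9)

    def draw(self, rng: np.random.Generator, size: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (frequencies, is_low flags)."""
        is_low = rng.random(size) < self.low_fraction
        lo, hi = self.low_range
        low = lo + (hi - lo) * rng.beta(*self.low_beta, size=size)
        lo, hi = self.common_range
        common = lo + (hi - lo) * rng.beta(*self.common_beta, size=size)
        return np.where(is_low, low, common), is_low


@dataclass
class HaplotypePool:
    """Phased binary haplotypes with founder-based LD blocks."""

    n_haplotypes: int
    variants: pd.DataFrame  # chrom, pos, ref, alt, kind, af_target, is_low, block
    alleles: np.ndarray  # bool, (n_haplotypes, n_variants)
    block_boundaries: np.ndarray  # positions starting each block

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_frequencies(self) -> np.ndarray:
        return self.alleles.mean(axis=0)


@dataclass(frozen=True)
class QualitySpec:
    """Target imputation quality for dosage degradation.

    ``target_rsq`` is a scalar or per-variant array in (0, 1]; the emitted
    dosages have expected variance-ratio quality ~= target (exact up to the
    [0, 2] clipping).  ``extra_noise_sd`` adds unstructured jitter on top.
    """

    target_rsq: float | np.ndarray = 1.0
    extra_noise_sd: float = 0.0

    def per_variant(self, n_variants: int) -> np.ndarray:
        q = np.broadcast_to(np.asarray(self.target_rsq, dtype=float), (n_variants,))
        if np.any((q <= 0.0) | (q > 1.0)):
            raise ValueError("target_rsq must lie in (0, 1]")
        return np.array(q)


@dataclass(frozen=True)
class SibshipSpec:
    """Relatedness request: ``n_sib_pairs`` full-sib pairs, rest unrelated."""

    n_sib_pairs: int = 0


@dataclass
class Cohort:
    """Diploid genotypes plus a pedigree kinship matrix.

    Kinship uses the coefficient-of-relationship scale: self 1.0, full sibs
    0.5, unrelated 0.0 (the scale a one-variance-component mixed model accepts
    up to rescaling of the genetic variance).
    """

    genotypes: np.ndarray  # int8, (n_variants, n_individuals)
    kinship: np.ndarray  # (n, n)
    samples: list[str]
    sib_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_individuals(self) -> int:
        return len(self.samples)


@dataclass
class PhenotypeTable:
    """Raw trait values and covariates over the same sample index."""

    traits: pd.DataFrame  # samples x traits
    covariates: pd.DataFrame  # samples x covariates


def simulate_haplotype_pool(
    n_hap: int,
    n_variants: int,
    afs: AlleleFrequencySpectrum | None = None,
    block_len: int = 50_000,
    seed: int = 0,
    n_founders: int = 20,
    mean_spacing: int = 500,
    chrom: str = "1",
    start_pos: int = 1,
    titv: float = 2.19,
    indel_fraction: float = 0.13,
) -> HaplotypePool:
    """Simulate a pool of phased haplotypes with block LD structure.

    Within each ``block_len`` window, every haplotype is assigned one of
    ``n_founders`` founder lineages (balanced, reshuffled per block).  A
    variant's carriers are the first ``round(af * n_hap)`` haplotypes of a
    per-variant random ordering of whole lineages, so carrier sets of variants
    in the same block overlap strongly (LD) while blocks are independent.
    Low-frequency variants occupy a prefix of a single lineage — a recent
    mutation on one founder background.

    Ti/Tv of emitted SNPs is controlled by ``titv``; ``indel_fraction`` of
    variants get multi-base allele labels (no sequence realism).
    """
    if n_hap < 4 or n_variants < 1:
        raise ValueError("need n_hap >= 4 and n_variants >= 1")
    if block_len <= 0 or mean_spacing <= 0:
        raise ValueError("block_len and mean_spacing must be positive")
    afs = afs or AlleleFrequencySpectrum()
    rng = np.random.default_rng(seed)

    gaps = rng.integers(1, 2 * mean_spacing, size=n_variants)
    pos = start_pos + np.cumsum(gaps) - gaps[0]
    block = ((pos - start_pos) // block_len).astype(int)
    block_ids = np.unique(block)
    block_boundaries = np.array(
        [start_pos + b * block_len for b in range(block.max() + 1)]
    )

    af, is_low = afs.draw(rng, n_variants)

    # per-block balanced founder assignment and a fixed within-lineage order
    founder_of: dict[int, np.ndarray] = {}
    lineage_order: dict[int, list[np.ndarray]] = {}
    n_f = min(n_founders, max(2, n_hap // 2))
    for b in block_ids:
        assign = np.tile(np.arange(n_f), n_hap // n_f + 1)[:n_hap]
        rng.shuffle(assign)
        founder_of[b] = assign
        lineage_order[b] = [np.flatnonzero(assign == f) for f in range(n_f)]

    alleles = np.zeros((n_hap, n_variants), dtype=bool)
    max_low = max(1, int(np.ceil(0.05 * n_hap)) - 1)  # keep MAF < 5% realizable
    for j in range(n_variants):
        m = int(np.rint(af[j] * n_hap))
        m = min(max(m, 1), n_hap - 1)
        if is_low[j]:
            m = min(m, max_low)
        lineages = lineage_order[block[j]]
        order = rng.permutation(n_f)
        carriers = np.concatenate([lineages[f] for f in order])[:m]
        alleles[carriers, j] = True
        af[j] = m / n_hap

    ref = rng.choice(_BASES, size=n_variants)
    is_indel = rng.random(n_variants) < indel_fraction
    p_transition = titv / (1.0 + titv)
    alt = []
    for j in range(n_variants):
        r = ref[j]
        if is_indel[j]:
            alt.append(r + "".join(rng.choice(_BASES, size=rng.integers(1, 4))))
        elif rng.random() < p_transition:
            alt.append(_TRANSITION[r])
        else:
            alt.append(rng.choice(_TRANSVERSIONS[r]))

    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "kind": np.where(is_indel, "indel", "snp"),
            "af_target": af,
            "is_low": is_low,
            "block": block,
        }
    )
    return HaplotypePool(
        n_haplotypes=n_hap,
        variants=variants,
        alleles=alleles,
        block_boundaries=block_boundaries,
    )


def sample_cohort(
    pool: HaplotypePool,
    n_ind: int,
    relatedness: SibshipSpec | None = None,
    seed: int = 0,
) -> Cohort:
    """Draw diploid individuals (without replacement) from a haplotype pool.

    Sib pairs draw four parental haplotypes; each sib inherits one haplotype
    from each parent, re-drawn independently per LD block (so realized sharing
    averages the pedigree expectation across blocks).  The returned kinship is
    the pedigree coefficient-of-relationship matrix.
    """
    if n_ind < 0:
        raise ValueError("n_ind must be non-negative")
    rel = relatedness or SibshipSpec(0)
    n_pairs = rel.n_sib_pairs
    if 2 * n_pairs > n_ind:
        raise ValueError("more sib-pair members than individuals requested")
    n_unrel = n_ind - 2 * n_pairs
    need = 2 * n_unrel + 4 * n_pairs
    if need > pool.n_haplotypes:
        raise CapacityError(
            f"cohort needs {need} haplotypes, pool has {pool.n_haplotypes}"
        )
    rng = np.random.default_rng(seed)
    n_var = pool.n_variants
    geno = np.zeros((n_var, n_ind), dtype=np.int8)
    hap_ids = rng.choice(pool.n_haplotypes, size=need, replace=False)
    A = pool.alleles  # (n_hap, n_var)
    blocks = pool.variants["block"].to_numpy() if n_var else np.empty(0, dtype=int)

    cursor = 0
    col = 0
    sib_pairs: list[tuple[int, int]] = []
    for _ in range(n_unrel):
        h1, h2 = hap_ids[cursor], hap_ids[cursor + 1]
        cursor += 2
        geno[:, col] = A[h1].astype(np.int8) + A[h2].astype(np.int8)
        col += 1
    block_ids = np.unique(blocks) if n_var else []
    for _ in range(n_pairs):
        parents = hap_ids[cursor : cursor + 4]  # father 0/1, mother 2/3
        cursor += 4
        for child in range(2):
            gamete = np.zeros(n_var, dtype=np.int8)
            for b in block_ids:
                mask = blocks == b
                pa = parents[rng.integers(0, 2)]
                ma = parents[2 + rng.integers(0, 2)]
                gamete[mask] = A[pa, mask].astype(np.int8) + A[ma, mask].astype(
                    np.int8
                )
            geno[:, col + child] = gamete
        sib_pairs.append((col, col + 1))
        col += 2

    kinship = np.eye(n_ind)
    for i, j in sib_pairs:
        kinship[i, j] = kinship[j, i] = 0.5
    samples = [f"S{i:05d}" for i in range(n_ind)]
    return Cohort(genotypes=geno, kinship=kinship, samples=samples, sib_pairs=sib_pairs)


def degrade_to_dosages(
    cohort: Cohort,
    pool: HaplotypePool,
    quality: QualitySpec,
    seed: int = 0,
) -> DosageMatrix:
    """Degrade hard genotypes to imputation-like dosages of target quality.

    Two-step emulation of an imputed dosage of reported r^2 = q:

    1. carrier miscalls — each entry keeps the true genotype with probability
       ``sqrt(q)`` and is otherwise replaced by an independent Hardy-Weinberg
       draw at the variant's frequency (so rare variants lose carriers the
       way poorly imputed rare variants do);
    2. shrinkage toward the variant mean 2p with a per-variant scale solved
       in closed form so the realized MaCH-style variance ratio —
       ``var(d, ddof=1) / (2 p_hat (1 - p_hat))`` with ``p_hat`` from the
       emitted dosages — equals the target ``q`` exactly.

    The emitted mean equals the true allele frequency, dosages stay inside
    [0, 2] by construction, and with ``q = 1`` they equal the genotypes
    bit-for-bit.
    """
    g = cohort.genotypes.astype(float)
    n_var, n_ind = g.shape
    q = quality.per_variant(n_var)
    rng = np.random.default_rng(seed)

    p = g.mean(axis=1, keepdims=True) / 2.0
    keep = rng.random(size=g.shape) < np.sqrt(q)[:, None]
    hw_draw = rng.binomial(2, np.broadcast_to(p, g.shape)).astype(float)
    mix = np.where(keep, g, hw_draw)

    mc = mix.mean(axis=1, keepdims=True)
    v = mix.var(axis=1, ddof=1)
    hw_var = (2.0 * p * (1.0 - p)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.sqrt(np.where(v > 0, q * hw_var / v, 0.0))
    # keep d inside [0, 2] (binds only in degenerate corners)
    dev_hi = mix.max(axis=1) - mc.ravel()
    dev_lo = mc.ravel() - mix.min(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s_hi = np.where(dev_hi > 0, (2.0 - 2.0 * p.ravel()) / dev_hi, np.inf)
        s_lo = np.where(dev_lo > 0, 2.0 * p.ravel() / dev_lo, np.inf)
    s = np.minimum(s, np.minimum(s_hi, s_lo))
    d = 2.0 * p + s[:, None] * (mix - mc)
    if quality.extra_noise_sd > 0:
        d = np.clip(
            d + rng.normal(0.0, quality.extra_noise_sd, size=d.shape), 0.0, 2.0
        )
    d[q == 1.0] = g[q == 1.0]
    d = np.clip(d, 0.0, 2.0)

    variants = pool.variants[["chrom", "pos", "ref", "alt", "kind"]].copy()
    variants["rsq"] = q
    variants["is_biallelic"] = True
    return DosageMatrix(
        dosages=d, variants=variants[VARIANT_COLUMNS], samples=list(cohort.samples)
    )


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------


def make_covariates(n_ind: int, seed: int = 0) -> pd.DataFrame:
    """Age, sex and two binary batch covariates for ``n_ind`` samples."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "age": np.clip(rng.normal(64.0, 12.0, n_ind), 23, 90),
            "sex": rng.binomial(1, 0.45, n_ind).astype(float),
            "amp_batch": rng.binomial(1, 0.5, n_ind).astype(float),
            "hyb_batch": rng.binomial(1, 0.5, n_ind).astype(float),
        },
        index=[f"S{i:05d}" for i in range(n_ind)],
    )
    return df


def make_truth_table(
    cohort: Cohort,
    pool: HaplotypePool,
    n_traits: int,
    variance_explained: float | tuple[float, float] = 0.10,
    causal_bin: str = "any",
    covariate_variance: dict[str, float] | None = None,
    polygenic_h2: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each trait a causal variant and an effect size.

    ``variance_explained`` may be a scalar or a (lo, hi) uniform range;
    ``causal_bin`` restricts the causal draw to ``"common"``, ``"low"`` or
    ``"any"`` variants (bins from realized cohort frequencies).  The effect in
    phenotype-SD units is ``beta = sqrt(V / (2p(1-p)))`` at the causal's
    realized frequency p.
    """
    rng = np.random.default_rng(seed)
    af = cohort.genotypes.mean(axis=1) / 2.0
    maf = np.minimum(af, 1 - af)
    polymorphic = (maf > 0) & (maf < 0.5 + 1e-9)
    if causal_bin == "common":
        candidates = np.flatnonzero(polymorphic & (maf >= 0.05))
    elif causal_bin == "low":
        candidates = np.flatnonzero(polymorphic & (maf < 0.05) & (maf > 0))
    else:
        candidates = np.flatnonzero(polymorphic)
    if candidates.size == 0:
        raise ValueError(f"no candidate causal variants in bin {causal_bin!r}")
    causal = rng.choice(candidates, size=n_traits, replace=n_traits > candidates.size)
    if np.isscalar(variance_explained):
        V = np.full(n_traits, float(variance_explained))
    else:
        lo, hi = variance_explained
        V = rng.uniform(lo, hi, size=n_traits)
    cov_var = covariate_variance or {}
    total = V + sum(cov_var.values()) + polygenic_h2
    if np.any(total >= 1.0):
        raise ValueError("causal + covariate + polygenic variance must stay < 1")
    p = af[causal]
    beta = np.sqrt(V / (2.0 * p * (1.0 - p)))
    truth = pd.DataFrame(
        {
            "trait": [f"T{i:04d}" for i in range(n_traits)],
            "causal_index": causal,
            "causal_pos": pool.variants["pos"].to_numpy()[causal],
            "causal_af": p,
            "causal_maf": np.minimum(p, 1 - p),
            "variance_explained": V,
            "beta_sd": beta,
            "polygenic_h2": polygenic_h2,
        }
    )
    for name, v in cov_var.items():
        truth[f"covvar_{name}"] = v
    return truth


def simulate_traits(
    cohort: Cohort,
    truth: pd.DataFrame,
    covariates: pd.DataFrame,
    seed: int = 0,
) -> PhenotypeTable:
    """Generate unit-variance traits with the architecture given by ``truth``.

    Each trait is beta * (g - 2p) + covariate effects + optional polygenic
    component (MVN with covariance h2 * kinship) + Gaussian noise sized so the
    total variance is 1.  Covariate effects act on standardized covariates
    with coefficient sqrt(assigned variance fraction).
    """
    rng = np.random.default_rng(seed)
    n = cohort.n_individuals
    cov_cols = [c.removeprefix("covvar_") for c in truth.columns if c.startswith("covvar_")]
    Z = {}
    for c in cov_cols:
        z = covariates[c].to_numpy(dtype=float)
        sd = z.std()
        Z[c] = (z - z.mean()) / sd if sd > 0 else np.zeros(n)

    h2 = float(truth["polygenic_h2"].iloc[0]) if len(truth) else 0.0
    L = None
    if h2 > 0:
        # kinship is PSD by construction; jitter guards numerical zeros
        L = np.linalg.cholesky(cohort.kinship + 1e-10 * np.eye(n))

    traits = {}
    for _, row in truth.iterrows():
        g = cohort.genotypes[int(row["causal_index"])].astype(float)
        p = row["causal_af"]
        y = row["beta_sd"] * (g - 2.0 * p)
        used = row["variance_explained"]
        for c in cov_cols:
            v = row[f"covvar_{c}"]
            y = y + np.sqrt(v) * Z[c]
            used += v
        if h2 > 0:
            y = y + np.sqrt(h2) * (L @ rng.standard_normal(n))
            used += h2
        if used >= 1.0:
            raise ValueError("total explained variance must be < 1")
        y = y + rng.normal(0.0, np.sqrt(1.0 - used), size=n)
        traits[row["trait"]] = y
    traits_df = pd.DataFrame(traits, index=list(cohort.samples))
    return PhenotypeTable(traits=traits_df, covariates=covariates.loc[traits_df.index])


def make_probe_annotation(
    truth: pd.DataFrame,
    pool: HaplotypePool,
    tss_jitter: int = 400_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Probe annotation (trait, chrom, tss) placing each causal in its window.

    The TSS is jittered around the causal position by up to ``tss_jitter`` bp
    (< 1 Mb, so the causal stays inside the +/- 1 Mb cis window).
    """
    rng = np.random.default_rng(seed)
    chrom = pool.variants["chrom"].iloc[0] if len(pool.variants) else "1"
    tss = truth["causal_pos"].to_numpy() + rng.integers(
        -tss_jitter, tss_jitter + 1, size=len(truth)
    )
    return pd.DataFrame(
        {"trait": truth["trait"], "chrom": chrom, "tss": np.maximum(tss, 1)}
    )


def simulate_tagged_locus(
    n_ind: int,
    maf_causal: float = 0.04,
    maf_tag: float = 0.12,
    variance_explained: float = 0.15,
    n_background: int = 8,
    causal_is_low: bool = True,
    seed: int = 0,
) -> tuple[DosageMatrix, np.ndarray, dict]:
    """One locus where a common variant partially tags a low-frequency causal.

    With ``causal_is_low=True`` (the planted architecture): haplotype carriers
    of the low-frequency causal (row 0) are nested inside the common tag's
    carriers (row 1), so r^2(tag, causal) = p_c (1 - p_t) / (p_t (1 - p_c))
    ~= 0.3 at the default frequencies, and the phenotype is driven by the
    causal alone — the common "signal" is pure tagging.

    With ``causal_is_low=False`` (the control architecture): the common
    variant (row 1) is causal and the low-frequency variant (row 0) is drawn
    independently, carrying no association of its own.

    Returns (dosage matrix, phenotype, info dict with the planted rows).
    """
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_ind
    tag_h = np.zeros(n_hap, dtype=bool)
    m_tag = max(2, int(round(maf_tag * n_hap)))
    tag_idx = rng.choice(n_hap, size=m_tag, replace=False)
    tag_h[tag_idx] = True
    m_causal = max(2, int(round(maf_causal * n_hap)))
    low_h = np.zeros(n_hap, dtype=bool)
    if causal_is_low:
        low_h[rng.choice(tag_idx, size=min(m_causal, m_tag), replace=False)] = True
    else:
        low_h[rng.choice(n_hap, size=m_causal, replace=False)] = True

    hap_cols = [low_h, tag_h]
    for _ in range(n_background):
        maf_b = rng.uniform(0.05, 0.4)
        bg = np.zeros(n_hap, dtype=bool)
        bg[rng.choice(n_hap, size=int(round(maf_b * n_hap)), replace=False)] = True
        hap_cols.append(bg)
    H = np.array(hap_cols)  # (n_var, n_hap)
    geno = (H[:, ::2].astype(np.int8) + H[:, 1::2].astype(np.int8)).astype(float)

    causal_row = 0 if causal_is_low else 1
    g = geno[causal_row]
    p = g.mean() / 2.0
    beta = np.sqrt(variance_explained / (2 * p * (1 - p)))
    y = beta * (g - 2 * p) + rng.normal(
        0.0, np.sqrt(1 - variance_explained), size=n_ind
    )

    tag_row = 1 if causal_is_low else 0
    n_var = geno.shape[0]
    pos = 1_000_000 + np.arange(n_var) * 5_000
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "rsq": 1.0,
            "is_biallelic": True,
            "kind": "snp",
        }
    )
    dm = DosageMatrix(
        dosages=geno,
        variants=variants[VARIANT_COLUMNS],
        samples=[f"S{i:05d}" for i in range(n_ind)],
    )
    info = {"causal_row": causal_row, "tag_row": tag_row, "beta_sd": beta}
    return dm, y, info


def write_truth_table(truth: pd.DataFrame, path: str) -> None:
    """TSV dump of the causal-architecture truth table (test oracle)."""
    truth.to_csv(path, sep="\t", index=False)
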