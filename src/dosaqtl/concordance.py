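"""Call-set comparison QC: site overlap, genotype concordance, Ti/Tv, swaps.

A query call set (e.g. low-pass sequencing genotypes) is compared against a
truth set (deep sequencing or a genotyping array).  Site-level agreement uses
three filters applied to both sets before the overlap is computed: mask out
excluded regions, drop sites where any truth genotype was called below the
depth threshold, drop non-biallelic sites.  Genotype-level agreement is a
3x3 hom-ref/het/hom-alt matrix over overlapping sites and shared samples;
per-sample concordance drives sample-swap detection (a swapped sample shows
roughly the concordance of two unrelated genomes, ~50%, instead of >98%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyCallSetError

__all__ = [
    "CallSet",
    "ConcordanceReport",
    "site_overlap",
    "genotype_concordance",
    "titv_ratio",
    "detect_sample_swaps",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class CallSet:
    """Hard-called genotypes at a set of sites.

    ``genotypes`` holds 0/1/2 alternate-allele counts (-1 = missing), one row
    per site in ``variants`` (chrom, pos, ref, alt); ``depth`` (optional) has
    the same shape.  Dosage-derived sets should be rounded to the nearest
    integer before construction — comparisons are against hard calls.
    """

    variants: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str]
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.shape != (len(self.variants), len(self.samples)):
            raise ValueError("genotype shape does not match variants x samples")
        self.variants = self.variants.reset_index(drop=True)

    def keys(self) -> pd.Index:
        v = self.variants
        return pd.Index(
            list(zip(v["chrom"].astype(str), v["pos"], v["ref"], v["alt"]))
        )

    def subset_sites(self, keep: np.ndarray) -> "CallSet":
        keep = np.asarray(keep)
        return CallSet(
            variants=self.variants.loc[keep].reset_index(drop=True),
            genotypes=self.genotypes[keep],
            samples=list(self.samples),
            depth=None if self.depth is None else self.depth[keep],
        )


@dataclass
class ConcordanceReport:
    """Site- and genotype-level agreement between a query and a truth set."""

    tp_proportion: float | None = None  # query sites confirmed in truth
    fn_rate: float | None = None  # truth sites missed by the query
    n_query: int = 0
    n_truth: int = 0
    n_overlap: int = 0
    matrix: np.ndarray | None = None  # 3x3 counts, rows = truth class
    overall_concordance: float | None = None
    nonref_concordance: float | None = None
    per_sample: pd.Series | None = None
    flags: dict = field(default_factory=dict)


def _apply_site_filters(
    cs: CallSet,
    mask: pd.DataFrame | None,
    low_depth_keys: pd.Index | None,
) -> CallSet:
    keep = np.ones(len(cs.variants), dtype=bool)
    v = cs.variants
    if mask is not None and len(mask):
        pos = v["pos"].to_numpy()
        chrom = v["chrom"].astype(str).to_numpy()
        for _, m in mask.iterrows():
            # BED semantics: 0-based half-open [start, end)
            keep &= ~((chrom == str(m["chrom"])) & (pos > m["start"]) & (pos <= m["end"]))
    if low_depth_keys is not None and len(low_depth_keys):
        keep &= ~cs.keys().isin(low_depth_keys)
    if "is_biallelic" in v.columns:
        keep &= v["is_biallelic"].to_numpy(dtype=bool)
    return cs.subset_sites(keep)


def site_overlap(
    query: CallSet,
    truth: CallSet,
    mask: pd.DataFrame | None = None,
    min_truth_depth: int | None = 20,
) -> ConcordanceReport:
    """Two-way site overlap after the three QC filters.

    Filters, applied in order to *both* sets: (1) drop sites inside ``mask``
    regions (BED-style chrom/start/end); (2) drop sites where any truth
    genotype was called below ``min_truth_depth``; (3) drop non-biallelic
    sites.  Then TP = |query AND truth| / |query| and FN = |truth MINUS
    query| / |truth|.
    """
    low_depth = None
    if min_truth_depth is not None and truth.depth is not None:
        bad = (truth.depth < min_truth_depth).any(axis=1)
        low_depth = truth.keys()[bad]
    q = _apply_site_filters(query, mask, low_depth)
    t = _apply_site_filters(truth, mask, low_depth)
    qk, tk = q.keys(), t.keys()
    if len(tk) == 0:
        raise EmptyCallSetError("truth set empty after filtering")
    if len(qk) == 0:
        raise EmptyCallSetError("query set empty after filtering")
    n_overlap = int(qk.isin(tk).sum())
    return ConcordanceReport(
        tp_proportion=n_overlap / len(qk),
        fn_rate=(len(tk) - n_overlap) / len(tk),
        n_query=len(qk),
        n_truth=len(tk),
        n_overlap=n_overlap,
    )


def genotype_concordance(query: CallSet, truth: CallSet) -> ConcordanceReport:
    """3x3 genotype concordance over overlapping sites and shared samples.

    Matrix rows index the truth class, columns the query class.  Overall
    concordance is the diagonal fraction; non-reference concordance excludes
    the truth-hom-ref/query-hom-ref cell from numerator and denominator (a
    pile of concordant hom-refs says little about call quality).  Missing
    genotypes (-1) on either side are excluded.
    """
    shared_samples = [s for s in query.samples if s in set(truth.samples)]
    if not shared_samples:
        raise EmptyCallSetError("no shared samples between query and truth")
    qi = [query.samples.index(s) for s in shared_samples]
    ti = [truth.samples.index(s) for s in shared_samples]

    qk, tk = query.keys(), truth.keys()
    common = qk.intersection(tk)
    if len(common) == 0:
        raise EmptyCallSetError("no overlapping sites")
    q_rows = pd.Series(np.arange(len(qk)), index=qk)[common].to_numpy()
    t_rows = pd.Series(np.arange(len(tk)), index=tk)[common].to_numpy()

    Q = query.genotypes[np.ix_(q_rows, qi)]
    T = truth.genotypes[np.ix_(t_rows, ti)]
    valid = (Q >= 0) & (T >= 0)

    matrix = np.zeros((3, 3), dtype=int)
    for a in range(3):
        for b in range(3):
            matrix[a, b] = int(np.sum(valid & (T == a) & (Q == b)))
    total = matrix.sum()
    if total == 0:
        raise EmptyCallSetError("no comparable genotypes")
    overall = float(np.trace(matrix)) / total

    nonref_den = total - matrix[0, 0]
    flags = {}
    if nonref_den == 0:
        nonref = None
        flags["nonref_undefined"] = True
    else:
        nonref = float(matrix[1, 1] + matrix[2, 2]) / nonref_den

    per_sample = {}
    for k, s in enumerate(shared_samples):
        v = valid[:, k]
        if v.sum() == 0:
            per_sample[s] = np.nan
        else:
            per_sample[s] = float(np.mean(Q[v, k] == T[v, k]))
    return ConcordanceReport(
        n_overlap=len(common),
        matrix=matrix,
        overall_concordance=overall,
        nonref_concordance=nonref,
        per_sample=pd.Series(per_sample),
        flags=flags,
    )


def titv_ratio(variants: pd.DataFrame) -> float:
    """Transition/transversion ratio of the SNPs in ``variants`` (ref, alt).

    Indels (multi-base alleles) are excluded; zero transversions raise.
    """
    ref = variants["ref"].astype(str)
    alt = variants["alt"].astype(str)
    snp = (ref.str.len() == 1) & (alt.str.len() == 1) & (ref != alt)
    pairs = list(zip(ref[snp], alt[snp]))
    ti = sum(1 for p in pairs if p in _TRANSITIONS)
    tv = len(pairs) - ti
    if tv == 0:
        raise ZeroDivisionError("no transversions; Ti/Tv undefined")
    return ti / tv


def detect_sample_swaps(
    per_sample_concordance: pd.Series,
    keep_threshold: float = 0.98,
    swap_band: tuple[float, float] = (0.4, 0.6),
) -> pd.DataFrame:
    """Flag samples whose chip concordance is consistent with a swap.

    Samples are kept only above ``keep_threshold`` (strict: exactly 98% is
    flagged).  Flagged samples whose concordance falls in ``swap_band`` —
    around the ~50% agreement two unrelated genomes show — are additionally
    labelled swap-like.
    """
    conc = per_sample_concordance.astype(float)
    if ((conc < 0) | (conc > 1)).any():
        raise ValueError("concordances must lie in [0, 1]")
    excluded = ~(conc > keep_threshold)
    lo, hi = swap_band
    swap_like = excluded & (conc >= lo) & (conc <= hi)
    return pd.DataFrame(
        {"concordance": conc, "excluded": excluded, "swap_like": swap_like}
    )
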