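"""Effective number of independent tests via greedy LD binning.

Dense call sets carry massive redundancy: nearby variants are correlated, so
a Bonferroni correction over raw variant counts is far too harsh.  The
procedure here estimates the number of *independent* variants by greedy LD
binning (the LDSelect algorithm) inside 2 Mb windows sampled across the
genome, then extrapolates: a 2 Mb window is ~1/1500 of the genome, so
genome-wide independent variants ~= per-window count x 1500, and the
family-wise threshold is 0.05 divided by (independent variants x number of
phenotypes tested).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import MonomorphicError
from .io_filters import DosageMatrix

__all__ = [
    "LDBin",
    "LDBinSet",
    "ThresholdSpec",
    "pairwise_r2",
    "ldselect_bins",
    "estimate_independent_per_window",
    "effective_tests",
    "estimate_fdr",
]

GENOME_MULTIPLIER = 1500  # 2 Mb windows per genome, approximately
WINDOW_LEN = 2_000_000


@dataclass(frozen=True)
class LDBin:
    """One LD bin: a tag variant plus the members it captured."""

    tag: int
    members: tuple[int, ...]  # includes the tag


@dataclass
class LDBinSet:
    """Greedy LD binning of one window; bin count = independent variants."""

    window_id: str
    bins: list[LDBin]
    r2_threshold: float

    @property
    def n_independent(self) -> int:
        return len(self.bins)

    def membership(self) -> dict[int, int]:
        """variant index -> bin ordinal."""
        return {m: i for i, b in enumerate(self.bins) for m in b.members}


@dataclass
class ThresholdSpec:
    """Independent-test bookkeeping and the implied Bonferroni threshold."""

    per_window: int
    mode: str  # "cis" | "genome"
    n_phenotypes: int
    genome_multiplier: int | None
    total_tests: int
    alpha_family: float = 0.05
    bonferroni_p: float = field(init=False)

    def __post_init__(self) -> None:
        if self.total_tests <= 0:
            raise ValueError("total independent tests must be positive")
        self.bonferroni_p = self.alpha_family / self.total_tests


def pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    mask = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[mask], b[mask]
    if a.std() == 0 or b.std() == 0:
        raise MonomorphicError("r2 undefined for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(np.clip(r * r, 0.0, 1.0))


def _r2_matrix(G: np.ndarray) -> np.ndarray:
    """All-pairs dosage r^2; rows with zero variance get NaN."""
    G = np.asarray(G, dtype=float)
    sd = G.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(G)
    C = np.atleast_2d(C)
    C[sd == 0, :] = np.nan
    C[:, sd == 0] = np.nan
    return np.clip(C * C, 0.0, 1.0)


def ldselect_bins(
    G: np.ndarray,
    positions: np.ndarray | None = None,
    r2_threshold: float = 0.8,
    window_id: str = "",
) -> LDBinSet:
    """Greedy LD binning of the variants in ``G`` (rows = variants).

    Repeatedly pick the unbinned variant with the most unbinned companions at
    r^2 > threshold, bin it with those companions, and remove them; singletons
    (and monomorphic variants) become their own bins.  Ties on companion
    count break to the lowest genomic position (row order when positions are
    not given), making the result invariant to input ordering.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    m = G.shape[0]
    if m == 0:
        return LDBinSet(window_id=window_id, bins=[], r2_threshold=r2_threshold)
    pos = np.arange(m) if positions is None else np.asarray(positions)
    R2 = _r2_matrix(G)
    companion = np.nan_to_num(R2, nan=0.0) > r2_threshold
    np.fill_diagonal(companion, False)

    unbinned = np.ones(m, dtype=bool)
    bins: list[LDBin] = []
    while unbinned.any():
        counts = (companion & unbinned[None, :]).sum(axis=1)
        counts = np.where(unbinned, counts, -1)
        best = counts.max()
        if best == 0:  # everything left is a singleton bin
            for i in np.flatnonzero(unbinned)[np.argsort(pos[unbinned], kind="stable")]:
                bins.append(LDBin(tag=int(i), members=(int(i),)))
            break
        cand = np.flatnonzero(counts == best)
        tag = cand[np.argmin(pos[cand])]
        members = np.flatnonzero(companion[tag] & unbinned)
        group = np.concatenate([[tag], members])
        unbinned[group] = False
        bins.append(LDBin(tag=int(tag), members=tuple(int(i) for i in np.sort(group))))
    return LDBinSet(window_id=window_id, bins=bins, r2_threshold=r2_threshold)


def estimate_independent_per_window(
    dm: DosageMatrix,
    n_windows: int = 22,
    window_len: int = WINDOW_LEN,
    r2_threshold: float = 0.8,
    quality_min: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean independent-variant counts from randomly placed 2 Mb windows.

    Draws one window per chromosome when several chromosomes are present,
    otherwise ``n_windows`` windows from the single chromosome (flagged in
    the output).  Only variants with imputation quality > ``quality_min``
    participate.  Each window is binned three ways — all variants, the
    low-frequency subset, the common subset — matching how per-bin
    independent counts are reported.

    Returns a per-window frame with counts plus a ``mean`` summary row.
    """
    rng = np.random.default_rng(seed)
    v = dm.variants
    usable = v["rsq"].to_numpy(dtype=float) > quality_min
    chroms = list(pd.unique(v["chrom"]))
    single_chrom = len(chroms) == 1
    draws: list[tuple[str, int]] = []
    if single_chrom:
        c = chroms[0]
        lo = int(v["pos"].min())
        hi = max(lo, int(v["pos"].max()) - window_len)
        for _ in range(n_windows):
            draws.append((c, int(rng.integers(lo, hi + 1))))
    else:
        for c in chroms[:n_windows]:
            sub = v.loc[v["chrom"] == c, "pos"]
            lo = int(sub.min())
            hi = max(lo, int(sub.max()) - window_len)
            draws.append((c, int(rng.integers(lo, hi + 1))))

    rows = []
    for i, (c, start) in enumerate(draws):
        in_win = (
            usable
            & (v["chrom"] == c).to_numpy()
            & (v["pos"].to_numpy() >= start)
            & (v["pos"].to_numpy() < start + window_len)
        )
        idx = np.flatnonzero(in_win)
        maf = v["maf"].to_numpy()[idx]
        pos = v["pos"].to_numpy()[idx]
        G = dm.dosages[idx]
        counts = {}
        for name, sel in (
            ("all", np.ones(idx.size, dtype=bool)),
            ("low_frequency", maf < 0.05),
            ("common", maf >= 0.05),
        ):
            if sel.sum() == 0:
                counts[name] = 0
            else:
                counts[name] = ldselect_bins(
                    G[sel], pos[sel], r2_threshold, window_id=f"w{i}"
                ).n_independent
        rows.append(
            {
                "window": f"w{i}",
                "chrom": c,
                "start": start,
                "n_variants": int(idx.size),
                "n_independent": counts["all"],
                "n_independent_low": counts["low_frequency"],
                "n_independent_common": counts["common"],
                "single_chrom_fallback": single_chrom,
                "empty": idx.size == 0,
            }
        )
    out = pd.DataFrame(rows)
    mean_row = {
        "window": "mean",
        "chrom": "",
        "start": -1,
        "n_variants": out["n_variants"].mean(),
        "n_independent": out["n_independent"].mean(),
        "n_independent_low": out["n_independent_low"].mean(),
        "n_independent_common": out["n_independent_common"].mean(),
        "single_chrom_fallback": single_chrom,
        "empty": bool(out["empty"].any()),
    }
    return pd.concat([out, pd.DataFrame([mean_row])], ignore_index=True)


def effective_tests(
    per_window: int,
    mode: str,
    n_phenotypes: int = 1,
    genome_multiplier: int = GENOME_MULTIPLIER,
    alpha_family: float = 0.05,
) -> ThresholdSpec:
    """Total independent tests and the Bonferroni threshold.

    cis mode: independent variants per 2 Mb window x number of phenotypes
    (each trait is scanned over one such window).  genome mode: per-window
    count x ~1500 windows per genome x number of phenotypes.
    """
    if per_window <= 0 or n_phenotypes <= 0:
        raise ValueError("counts must be positive")
    if mode == "cis":
        total = per_window * n_phenotypes
        mult = None
    elif mode == "genome":
        total = per_window * genome_multiplier * n_phenotypes
        mult = genome_multiplier
    else:
        raise ValueError(f"mode must be 'cis' or 'genome', got {mode!r}")
    return ThresholdSpec(
        per_window=per_window,
        mode=mode,
        n_phenotypes=n_phenotypes,
        genome_multiplier=mult,
        total_tests=total,
        alpha_family=alpha_family,
    )


def estimate_fdr(p_threshold: float, total_tests: int, n_observed_hits: int) -> float:
    """FDR estimate: expected false positives / observed hits.

    expected false positives = p_threshold x total independent tests.
    """
    if n_observed_hits <= 0:
        raise ValueError("FDR undefined with zero observed hits")
    if p_threshold < 0:
        raise ValueError("p_threshold must be non-negative")
    return p_threshold * total_tests / n_observed_hits
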