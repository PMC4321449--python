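"""Conditional classification of signals by opposing allele-frequency bin.

For each association signal the question is whether the index variant carries
independent information or merely tags a variant in the *opposing* MAF bin
(common vs low-frequency).  The procedure: find the most significant variant
of the opposite bin in the region (the cis window for expression traits, or
index +/- 1 Mb for biomarkers), re-test the index with that variant's dosage
as a covariate, and classify:

* conditional p > 0.05          -> fully_explained (all evidence lost)
* conditional p <= discovery thr -> retained
* otherwise                     -> attenuated

A stricter variant of the analysis conditions on *all* independent
(r^2 < 0.2) opposing-bin variants with p < 1e-4 in the region, obtained by
greedy p-value clumping.  A final operation compares detection of the same
signals between two dosage sets (e.g. sequencing-based vs reference-panel
imputation), counting a signal as captured in the other set if any variant
within +/- 250 kb of the index reaches the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssocResult
from .io_filters import COMMON, LOW_FREQUENCY, MAF_COMMON_MIN

__all__ = [
    "SignalRecord",
    "ClumpSet",
    "best_opposing_variant",
    "conditional_test",
    "clump",
    "classify_signal",
    "classify_scan",
    "compare_detection",
]

FULLY_EXPLAINED = "fully_explained"
RETAINED = "retained"
ATTENUATED = "attenuated"
COLLINEAR = "collinear"

LOSS_P = 0.05  # conditional p above this = all evidence of association lost
COLLINEAR_R2 = 0.999
PROXY_WINDOW = 250_000


@dataclass
class SignalRecord:
    """An index signal with its conditional outcome."""

    trait: str
    index_row: int
    index_bin: str
    p_unconditional: float
    conditioning_rows: tuple[int, ...]
    p_conditional: float | None
    classification: str
    region: tuple[int, int] | None = None


@dataclass
class ClumpSet:
    """Greedy p-ordered clumping output: mutually quasi-independent indices."""

    indices: list[int]  # positions into the supplied results frame
    p_max: float
    r2_max: float
    region: tuple[int, int] | None = None


def best_opposing_variant(
    region_results: pd.DataFrame,
    index_bin: str,
) -> pd.Series | None:
    """Most significant variant of the opposite MAF bin within the region.

    ``region_results`` needs columns (maf, p, pos).  Returns None when the
    opposing bin is empty.  Ties on p break to the lower position.
    """
    if index_bin == COMMON:
        sel = region_results["maf"] < MAF_COMMON_MIN
    elif index_bin == LOW_FREQUENCY:
        sel = region_results["maf"] >= MAF_COMMON_MIN
    else:
        raise ValueError(f"unknown bin {index_bin!r}")
    sub = region_results[sel & np.isfinite(region_results["p"])]
    if sub.empty:
        return None
    sub = sub.sort_values(["p", "pos"], kind="mergesort")
    return sub.iloc[0]


def conditional_test(
    phenotype: np.ndarray,
    index_dosage: np.ndarray,
    conditioning_dosages: np.ndarray | None,
    variant: str = "",
    trait: str = "",
) -> AssocResult:
    """Partial effect of the index variant given the conditioning dosages.

    Multiple regression of the phenotype on [1, index, conditioners]; reports
    the index's partial slope and two-sided t p-value with df = n - 2 - k.
    A conditioner with r^2 > 0.999 against the index makes the contrast
    unidentifiable: the result is flagged ``collinear``.  Conditioners that
    are collinear among themselves are dropped.  An empty conditioning set
    reproduces the unconditional test exactly.
    """
    y = np.asarray(phenotype, dtype=float)
    g = np.asarray(index_dosage, dtype=float)
    if conditioning_dosages is None or np.size(conditioning_dosages) == 0:
        C = np.empty((0, y.size))
    else:
        C = np.atleast_2d(np.asarray(conditioning_dosages, dtype=float))
    if any(np.shares_memory(g, C[i]) and np.array_equal(g, C[i]) for i in range(C.shape[0])):
        raise ValueError("conditioning on the index variant itself is not allowed")

    mask = ~np.isnan(y) & ~np.isnan(g)
    for row in C:
        mask &= ~np.isnan(row)
    y, g, C = y[mask], g[mask], C[:, mask]
    n = y.size
    if g.std() == 0:
        return AssocResult(variant, trait, np.nan, np.nan, np.nan, n,
                           "ols", (), "untestable")
    # guard: index identifiable only if not an (almost) exact copy of a conditioner
    gc = g - g.mean()
    for row in C:
        rc = row - row.mean()
        den = float(gc @ gc) * float(rc @ rc)
        if den > 0 and (float(gc @ rc) ** 2) / den > COLLINEAR_R2:
            return AssocResult(variant, trait, np.nan, np.nan, np.nan, n,
                               "ols", (), COLLINEAR)
    # drop conditioners redundant among themselves (keeps design full rank)
    keep: list[np.ndarray] = []
    for row in C:
        trial = np.column_stack([np.ones(n)] + keep + [row])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(row)
    X = np.column_stack([np.ones(n), g] + keep)
    k = len(keep)
    df = n - 2 - k
    if df < 1:
        raise ValueError("not enough samples for the conditioning set")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(s2 * xtx_inv[1, 1]))
    if se == 0:
        p = 0.0
    else:
        p = max(2.0 * stats.t.sf(abs(beta[1] / se), df), 5e-324)
    return AssocResult(variant, trait, float(beta[1]), se, p, n, "ols",
                       tuple(f"c{i}" for i in range(k)))


def clump(
    region_results: pd.DataFrame,
    dosages: np.ndarray,
    p_max: float = 1e-4,
    r2_max: float = 0.2,
) -> ClumpSet:
    """Greedy p-value clumping: surviving indices are mutually r^2 < r2_max.

    ``region_results`` rows align with ``dosages`` rows.  Among variants with
    p < ``p_max``, repeatedly take the smallest-p variant as a clump index and
    remove everything at r^2 >= ``r2_max`` with it (ties on p break to lower
    position).
    """
    res = region_results.reset_index(drop=True)
    cand = res[np.isfinite(res["p"]) & (res["p"] < p_max)]
    order = cand.sort_values(["p", "pos"], kind="mergesort").index.to_list()
    alive = set(order)
    indices: list[int] = []
    G = np.asarray(dosages, dtype=float)
    for i in order:
        if i not in alive:
            continue
        indices.append(int(i))
        alive.discard(i)
        gi = G[i] - G[i].mean()
        sii = float(gi @ gi)
        for j in list(alive):
            gj = G[j] - G[j].mean()
            den = sii * float(gj @ gj)
            if den == 0 or (float(gi @ gj) ** 2) / den >= r2_max:
                alive.discard(j)
    return ClumpSet(indices=indices, p_max=p_max, r2_max=r2_max)


def classify_signal(
    p_unconditional: float,
    p_conditional: float | None,
    discovery_threshold: float,
    status: str = "ok",
) -> str:
    """Apply the classification rule to one conditional outcome."""
    if status == COLLINEAR:
        return COLLINEAR
    if p_conditional is None or not np.isfinite(p_conditional):
        raise ValueError("conditional p undefined")
    if p_conditional > LOSS_P:
        return FULLY_EXPLAINED
    if p_conditional <= discovery_threshold:
        return RETAINED
    return ATTENUATED


def classify_scan(
    phenotype: np.ndarray,
    region_results: pd.DataFrame,
    dosages: np.ndarray,
    discovery_threshold: float,
    mode: str = "single",
    p_max: float = 1e-4,
    r2_max: float = 0.2,
    trait: str = "",
    index_bin: str | None = None,
) -> SignalRecord | None:
    """Condition a region's index signal on the opposing MAF bin and classify.

    ``region_results`` (columns maf, p, pos, ranked or not) aligns row-wise
    with ``dosages``.  ``mode="single"`` conditions on the single best
    opposing-bin variant; ``mode="full"`` conditions on all clumped opposing
    variants with p < ``p_max``.  ``index_bin`` restricts the index to one
    MAF bin (e.g. classify the region's best *common* signal); by default the
    overall index is classified.  Returns None when the region has no
    testable index at the discovery threshold.
    """
    res = region_results.reset_index(drop=True)
    finite = res[np.isfinite(res["p"])]
    if index_bin == COMMON:
        finite = finite[finite["maf"] >= MAF_COMMON_MIN]
    elif index_bin == LOW_FREQUENCY:
        finite = finite[finite["maf"] < MAF_COMMON_MIN]
    elif index_bin is not None:
        raise ValueError(f"unknown bin {index_bin!r}")
    if finite.empty:
        return None
    idx = finite.sort_values(["p", "pos"], kind="mergesort").index[0]
    p_unc = float(res.loc[idx, "p"])
    if p_unc > discovery_threshold:
        return None
    index_bin = COMMON if res.loc[idx, "maf"] >= MAF_COMMON_MIN else LOW_FREQUENCY

    if mode == "single":
        best = best_opposing_variant(res.drop(index=idx), index_bin)
        cond_rows = [] if best is None else [int(best.name)]
    elif mode == "full":
        opp = res["maf"] < MAF_COMMON_MIN if index_bin == COMMON else res["maf"] >= MAF_COMMON_MIN
        opp_res = res[opp & (res.index != idx)]
        cs = clump(opp_res, np.asarray(dosages)[opp_res.index.to_numpy()],
                   p_max=p_max, r2_max=r2_max)
        cond_rows = [int(opp_res.index[i]) for i in cs.indices]
    else:
        raise ValueError(f"mode must be 'single' or 'full', got {mode!r}")

    if not cond_rows:
        rec = conditional_test(phenotype, np.asarray(dosages)[idx], None, trait=trait)
    else:
        rec = conditional_test(
            phenotype, np.asarray(dosages)[idx],
            np.asarray(dosages)[cond_rows], trait=trait,
        )
    label = classify_signal(p_unc, rec.p, discovery_threshold, status=rec.status)
    return SignalRecord(
        trait=trait,
        index_row=int(idx),
        index_bin=index_bin,
        p_unconditional=p_unc,
        conditioning_rows=tuple(cond_rows),
        p_conditional=rec.p if rec.status == "ok" else None,
        classification=label,
    )


def compare_detection(
    signals_a: pd.DataFrame,
    results_b: pd.DataFrame,
    strict_threshold: float,
    loose_threshold: float = 1e-4,
    proxy_window: int = PROXY_WINDOW,
) -> pd.DataFrame:
    """How well call set B recaptures the signals discovered in call set A.

    ``signals_a``: one row per A-signal with (trait, chrom, pos, p).
    ``results_b``: per-variant tests in B with (trait, chrom, pos, p).
    For each A-signal the best B p-value among variants within
    +/- ``proxy_window`` of the index is found; the output row records
    detection at the strict and loose thresholds and whether the B evidence
    is weaker or absent.  A trait missing from B counts as no proxy.
    """
    rows = []
    for _, sig in signals_a.iterrows():
        sub = results_b[
            (results_b["trait"] == sig["trait"])
            & (results_b["chrom"].astype(str) == str(sig["chrom"]))
            & ((results_b["pos"] - sig["pos"]).abs() <= proxy_window)
        ]
        best_p = float(sub["p"].min()) if not sub.empty else np.nan
        has_proxy = np.isfinite(best_p)
        rows.append(
            {
                "trait": sig["trait"],
                "pos": sig["pos"],
                "p_a": sig["p"],
                "best_p_b": best_p,
                "has_proxy": has_proxy,
                "detected_strict": bool(has_proxy and best_p < strict_threshold),
                "detected_loose": bool(has_proxy and best_p < loose_threshold),
                "weaker_or_absent": bool(not has_proxy or best_p > sig["p"]),
            }
        )
    return pd.DataFrame(rows)
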