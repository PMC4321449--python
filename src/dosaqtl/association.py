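"""Single-variant additive association tests on genotype dosages.

Two models cover the two study designs:

* ordinary least squares for unrelated individuals (the cis-eQTL scans):
  simple linear regression of the prepared phenotype on the dosage, two-sided
  p from the t distribution with n - 2 degrees of freedom;
* a one-variance-component linear mixed model for related samples (the
  genome-wide biomarker scans): the null model ``y ~ N(mu, sg2*K + se2*I)``
  is fitted by REML via the eigendecomposition of the kinship matrix, and
  each variant is tested by generalized least squares on the decorrelated
  data (the EMMAX approximation: variance components fixed at their null
  estimates).

Dosages are used as-is in the regressions, never rounded to hard calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_filters import COMMON, LOW_FREQUENCY, MAF_COMMON_MIN, DosageMatrix

__all__ = [
    "AssocResult",
    "CisWindow",
    "MixedNullModel",
    "CisScanResult",
    "test_variant_ols",
    "fit_null_mixed",
    "test_variant_mixed",
    "scan_cis",
    "scan_genome",
    "bulk_ols",
]

CIS_HALF_WINDOW = 1_000_000  # +/- 1 Mb around the probe TSS


@dataclass
class AssocResult:
    """One variant-trait test."""

    variant: str
    trait: str
    beta: float
    se: float
    p: float
    n: int
    model: str = "ols"
    conditioning: tuple[str, ...] = ()
    status: str = "ok"  # ok | untestable | collinear

    @property
    def testable(self) -> bool:
        return self.status == "ok"


@dataclass(frozen=True)
class CisWindow:
    """The cis search region: +/- 1 Mb around a probe's TSS, clipped at 1."""

    trait: str
    chrom: str
    tss: int
    half_window: int = CIS_HALF_WINDOW

    @property
    def start(self) -> int:
        return max(1, self.tss - self.half_window)

    @property
    def end(self) -> int:
        return self.tss + self.half_window

    def contains(self, pos: np.ndarray) -> np.ndarray:
        return (pos >= self.start) & (pos <= self.end)


@dataclass
class MixedNullModel:
    """REML-fitted null of ``y ~ N(mu, sg2*K + se2*I)`` plus its whitener.

    ``transform`` maps a length-n vector into the decorrelated space where the
    residual covariance is the identity (up to total variance): rows are
    ``U.T / sqrt(h2*s + 1 - h2)``.
    """

    sigma_g2: float
    sigma_e2: float
    h2: float
    transform: np.ndarray  # (n, n)
    y_t: np.ndarray  # transformed phenotype
    ones_t: np.ndarray  # transformed intercept column
    boundary: bool  # sg2 pinned at the 0 boundary
    n: int


def _ols_from_arrays(g: np.ndarray, y: np.ndarray) -> tuple[float, float, float, int]:
    """Simple-regression (beta, se, p, n) on complete pairs; p from t(n-2)."""
    mask = ~np.isnan(g) & ~np.isnan(y)
    g, y = g[mask], y[mask]
    n = g.size
    gc = g - g.mean()
    yc = y - y.mean()
    sxx = float(gc @ gc)
    if sxx <= 0:
        return np.nan, np.nan, np.nan, n
    beta = float(gc @ yc) / sxx
    resid = yc - beta * gc
    df = n - 2
    s2 = float(resid @ resid) / df
    se = np.sqrt(s2 / sxx)
    if se == 0:
        return beta, 0.0, 0.0, n
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return beta, se, max(p, 5e-324), n


def test_variant_ols(
    dosage: np.ndarray,
    phenotype: np.ndarray,
    variant: str = "",
    trait: str = "",
) -> AssocResult:
    """OLS additive test of one dosage vector against a prepared phenotype."""
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    mask = ~np.isnan(g) & ~np.isnan(y)
    if mask.sum() < 10:
        raise ValueError("need at least 10 complete dosage/phenotype pairs")
    if np.nanstd(g[mask]) == 0:
        return AssocResult(variant, trait, np.nan, np.nan, np.nan,
                           int(mask.sum()), "ols", (), "untestable")
    beta, se, p, n = _ols_from_arrays(g, y)
    return AssocResult(variant, trait, beta, se, p, n, "ols")


def bulk_ols(G: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Vectorized simple regression of ``y`` on each row of ``G``.

    Returns a frame with beta, se, p, n per variant; constant rows get NaN.
    Assumes no missing dosages (the synthetic pipeline's case); falls back to
    the per-variant path when ``y`` has missing entries.
    """
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y)
    yv = y[mask]
    Gv = np.asarray(G, dtype=float)[:, mask]
    n = yv.size
    gc = Gv - Gv.mean(axis=1, keepdims=True)
    yc = yv - yv.mean()
    sxx = (gc**2).sum(axis=1)
    syy = float(yc @ yc)
    sxy = gc @ yc
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        beta = sxy / sxx
        rss = syy - sxy**2 / sxx
        df = n - 2
        se = np.sqrt(np.clip(rss, 0, None) / df / sxx)
        t2 = np.where(se > 0, (beta / se) ** 2, np.inf)
    p = stats.f.sf(t2, 1, df)
    p = np.where(sxx > 0, np.maximum(p, 5e-324), np.nan)
    beta = np.where(sxx > 0, beta, np.nan)
    se = np.where(sxx > 0, se, np.nan)
    return pd.DataFrame({"beta": beta, "se": se, "p": p, "n": n})


# ---------------------------------------------------------------------------
# Mixed model (EMMAX approximation)
# ---------------------------------------------------------------------------


def fit_null_mixed(phenotype: np.ndarray, kinship: np.ndarray) -> MixedNullModel:
    """REML fit of the single-variance-component null model.

    Profiles out the total variance and maximizes the restricted likelihood
    over the heritability ratio h2 = sg2/(sg2+se2) on the eigenbasis of K.
    A fit pinned at h2 = 0 is flagged ``boundary`` (kinship uninformative).
    """
    y = np.asarray(phenotype, dtype=float)
    K = np.asarray(kinship, dtype=float)
    n = y.size
    if K.shape != (n, n):
        raise ValueError("kinship shape does not match phenotype length")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship must be symmetric")
    s, U = np.linalg.eigh(K)
    if s.min() < -1e-6:
        raise ValueError("kinship must be positive semi-definite")
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def reml_neglog(h2: float) -> float:
        d = h2 * s + (1.0 - h2)
        xdx = float((xt**2 / d).sum())
        bhat = float((xt * yt / d).sum()) / xdx
        r = yt - bhat * xt
        rss = float((r**2 / d).sum())
        # restricted log-likelihood up to constants
        return 0.5 * ((n - 1) * np.log(rss) + np.log(d).sum() + np.log(xdx))

    res = optimize.minimize_scalar(
        reml_neglog, bounds=(0.0, 1.0 - 1e-6), method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(res.x)
    # check the boundary explicitly: bounded Brent can sit near but not at 0
    if reml_neglog(0.0) <= res.fun:
        h2 = 0.0
    d = h2 * s + (1.0 - h2)
    xdx = float((xt**2 / d).sum())
    bhat = float((xt * yt / d).sum()) / xdx
    r = yt - bhat * xt
    sigma2 = float((r**2 / d).sum()) / (n - 1)
    W = (U / np.sqrt(d)).T  # rows: U.T scaled by 1/sqrt(d)
    return MixedNullModel(
        sigma_g2=h2 * sigma2,
        sigma_e2=(1.0 - h2) * sigma2,
        h2=h2,
        transform=W,
        y_t=W @ y,
        ones_t=W @ np.ones(n),
        boundary=h2 < 1e-4,
        n=n,
    )


def test_variant_mixed(
    dosage: np.ndarray,
    null: MixedNullModel,
    variant: str = "",
    trait: str = "",
) -> AssocResult:
    """EMMAX-style Wald test: GLS of the whitened phenotype on the dosage."""
    g = np.asarray(dosage, dtype=float)
    if g.size != null.n:
        raise ValueError("dosage length does not match the fitted null model")
    if np.std(g) == 0:
        return AssocResult(variant, trait, np.nan, np.nan, np.nan,
                           null.n, "mixed", (), "untestable")
    gt = null.transform @ g
    X = np.column_stack([null.ones_t, gt])
    beta_hat, _, _, _ = np.linalg.lstsq(X, null.y_t, rcond=None)
    resid = null.y_t - X @ beta_hat
    df = null.n - 2
    s2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(s2 * xtx_inv[1, 1]))
    t = beta_hat[1] / se if se > 0 else np.inf
    p = max(2.0 * stats.t.sf(abs(t), df), 5e-324)
    return AssocResult(variant, trait, float(beta_hat[1]), se, p, null.n, "mixed")


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------


@dataclass
class CisScanResult:
    """All tests in a cis window plus the index variants."""

    trait: str
    window: CisWindow | None
    results: pd.DataFrame  # variant metadata + beta/se/p/n, ranked by p
    index: pd.Series | None = None  # best row overall
    index_by_bin: dict = field(default_factory=dict)  # bin label -> best row


def _rank_and_index(res: pd.DataFrame) -> tuple[pd.Series | None, dict]:
    """Index variant and per-bin bests under the (p, -|beta|, pos) tie-break."""
    testable = res[np.isfinite(res["p"])].copy()
    if testable.empty:
        return None, {}
    testable["_absbeta"] = -testable["beta"].abs()
    testable = testable.sort_values(["p", "_absbeta", "pos"], kind="mergesort")
    index = testable.iloc[0].drop("_absbeta")
    by_bin = {}
    for label, sel in (
        (COMMON, testable["maf"] >= MAF_COMMON_MIN),
        (LOW_FREQUENCY, testable["maf"] < MAF_COMMON_MIN),
    ):
        sub = testable[sel]
        if not sub.empty:
            by_bin[label] = sub.iloc[0].drop("_absbeta")
    return index, by_bin


def _scan_frame(dm: DosageMatrix, rows: np.ndarray, phenotype: np.ndarray,
                null: MixedNullModel | None) -> pd.DataFrame:
    meta = dm.variants.iloc[rows].reset_index(drop=True)
    G = dm.dosages[rows]
    if null is None:
        stats_df = bulk_ols(G, phenotype)
        stats_df["model"] = "ols"
    else:
        recs = [test_variant_mixed(G[i], null) for i in range(G.shape[0])]
        stats_df = pd.DataFrame(
            {
                "beta": [r.beta for r in recs],
                "se": [r.se for r in recs],
                "p": [r.p for r in recs],
                "n": [r.n for r in recs],
                "model": "mixed",
            }
        )
    out = pd.concat([meta, stats_df], axis=1)
    out["row"] = rows
    return out


def scan_cis(
    trait: str,
    phenotype: np.ndarray,
    annotation: pd.DataFrame,
    dm: DosageMatrix,
    half_window: int = CIS_HALF_WINDOW,
) -> CisScanResult:
    """Test every variant within +/- 1 Mb of the trait's TSS against it.

    ``annotation`` needs columns (trait, chrom, tss).  Returns all results
    ranked by p, the overall index variant, and the best variant per MAF bin.
    """
    ann = annotation.loc[annotation["trait"] == trait]
    if ann.empty:
        raise KeyError(f"trait {trait!r} has no TSS annotation")
    chrom, tss = str(ann["chrom"].iloc[0]), int(ann["tss"].iloc[0])
    window = CisWindow(trait=trait, chrom=chrom, tss=tss, half_window=half_window)
    v = dm.variants
    in_win = (v["chrom"].astype(str) == chrom).to_numpy() & window.contains(
        v["pos"].to_numpy()
    )
    rows = np.flatnonzero(in_win)
    if rows.size == 0:
        empty = pd.DataFrame()
        return CisScanResult(trait=trait, window=window, results=empty)
    res = _scan_frame(dm, rows, phenotype, null=None)
    res = res.sort_values("p", kind="mergesort").reset_index(drop=True)
    index, by_bin = _rank_and_index(res)
    return CisScanResult(trait=trait, window=window, results=res,
                         index=index, index_by_bin=by_bin)


def scan_genome(
    trait: str,
    phenotype: np.ndarray,
    dm: DosageMatrix,
    model: str = "mixed",
    kinship: np.ndarray | None = None,
) -> CisScanResult:
    """Genome-wide scan of one (biomarker) trait, mixed model by default."""
    null = None
    if model == "mixed":
        if kinship is None:
            raise ValueError("mixed model requires a kinship matrix")
        null = fit_null_mixed(phenotype, kinship)
    elif model != "ols":
        raise ValueError(f"unknown model {model!r}")
    rows = np.arange(dm.n_variants)
    if rows.size == 0:
        return CisScanResult(trait=trait, window=None, results=pd.DataFrame())
    res = _scan_frame(dm, rows, phenotype, null=null)
    res = res.sort_values("p", kind="mergesort").reset_index(drop=True)
    index, by_bin = _rank_and_index(res)
    return CisScanResult(trait=trait, window=None, results=res,
                         index=index, index_by_bin=by_bin)


def results_to_frame(results: list[AssocResult]) -> pd.DataFrame:
    """Flatten AssocResult records into the standard TSV column layout."""
    return pd.DataFrame(
        {
            "variant": [r.variant for r in results],
            "trait": [r.trait for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "p": [r.p for r in results],
            "n": [r.n for r in results],
            "model": [r.model for r in results],
            "status": [r.status for r in results],
        }
    )
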