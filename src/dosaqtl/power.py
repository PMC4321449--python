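"""Analytic power for single-variant quantitative-trait association.

For an additive variant with minor allele frequency ``p`` and a per-allele
effect of ``beta`` phenotype standard deviations, the fraction of phenotypic
variance explained is approximately ``V = beta**2 * 2*p*(1 - p)``.  Power to
detect the variant in a linear-regression scan depends on the sample size and
on ``V`` only — not on ``p`` and ``beta`` separately — which is why a power
grid over (MAF, V) has constant power down each V column while the required
SD effect size grows as the allele becomes rarer.

The analytic power uses the noncentral distribution of the 1-df association
test statistic with noncentrality ``n*V/(1 - V)``.  The default reference
distribution is the noncentral F with (1, n-2) degrees of freedom, i.e. the
exact finite-sample distribution of the squared regression t statistic; the
large-sample noncentral chi-square forms are available via ``convention``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerCell",
    "DiscoveryExpectation",
    "effect_from_variance",
    "variance_from_effect",
    "analytic_power",
    "empirical_power",
    "expected_discoveries",
    "power_table",
]

#: recognised noncentrality / reference-distribution conventions
CONVENTIONS = ("f", "chi2", "chi2-nv")


@dataclass(frozen=True)
class PowerCell:
    """One cell of a power grid: (MAF, V, n, alpha) -> (SD effect, power)."""

    maf: float
    variance_explained: float
    n: int
    alpha: float
    effect_sd: float
    power: float


@dataclass(frozen=True)
class DiscoveryExpectation:
    """Expected number of hits from a per-variant hit rate applied to a count."""

    rate: float
    n_variants: int
    expected: float = field(init=False)
    expected_rounded: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "expected", self.rate * self.n_variants)
        # round half away from zero so printed integers match manual arithmetic
        object.__setattr__(
            self, "expected_rounded", int(np.floor(self.expected + 0.5))
        )


def effect_from_variance(variance_explained: float, maf: float) -> float:
    """Per-allele effect size (in phenotype SD) explaining ``V`` at frequency ``maf``.

    Inverts ``V = beta**2 * 2p(1-p)``:  ``beta = sqrt(V / (2p(1-p)))``.
    """
    p = float(maf)
    v = float(variance_explained)
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must be in (0, 1), got {p}")
    if not 0.0 <= v < 1.0:
        raise ValueError(f"variance explained must be in [0, 1), got {v}")
    return float(np.sqrt(v / (2.0 * p * (1.0 - p))))


def variance_from_effect(effect_sd: float, maf: float) -> float:
    """Phenotypic variance explained by a per-allele effect of ``effect_sd`` SD."""
    p = float(maf)
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must be in (0, 1), got {p}")
    return float(effect_sd**2 * 2.0 * p * (1.0 - p))


def analytic_power(
    n: int,
    variance_explained: float,
    alpha: float,
    convention: str = "f",
) -> float:
    """Power of the 1-df additive association test at significance ``alpha``.

    Parameters
    ----------
    n
        Sample size (number of individuals), ``n >= 2``.
    variance_explained
        Fraction of phenotypic variance explained by the variant, in [0, 1).
    alpha
        Two-sided significance threshold, in (0, 1).
    convention
        ``"f"`` (default): noncentral F(1, n-2) with ncp ``n*V/(1-V)`` — the
        exact distribution of the squared regression t statistic.
        ``"chi2"``: noncentral chi-square(1) with the same ncp.
        ``"chi2-nv"``: noncentral chi-square(1) with ncp ``n*V``.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    v = float(variance_explained)
    if not 0.0 <= v < 1.0:
        raise ValueError(f"variance explained must be in [0, 1), got {v}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; one of {CONVENTIONS}")

    if convention == "chi2-nv":
        ncp = n * v
    else:
        ncp = n * v / (1.0 - v)
    if convention == "f":
        crit = stats.f.ppf(1.0 - alpha, 1, n - 2)
        if ncp == 0.0:  # central case; ncf.sf is numerically unreliable at 0
            return float(stats.f.sf(crit, 1, n - 2))
        return float(stats.ncf.sf(crit, 1, n - 2, ncp))
    crit = stats.chi2.ppf(1.0 - alpha, 1)
    if ncp == 0.0:
        return float(stats.chi2.sf(crit, 1))
    return float(stats.ncx2.sf(crit, 1, ncp))


def empirical_power(
    n: int,
    variance_explained: float,
    maf: float,
    alpha: float,
    n_reps: int = 2000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the OLS scan: fraction of replicates with p < alpha.

    Each replicate draws Hardy–Weinberg genotypes at frequency ``maf``, builds
    a unit-variance trait with the causal variant explaining ``V``, and runs
    simple linear regression.  Serves as the simulation cross-check of
    :func:`analytic_power`.
    """
    if n_reps < 100:
        raise ValueError("need at least 100 replicates for a stable estimate")
    rng = np.random.default_rng(seed)
    beta = effect_from_variance(variance_explained, maf)
    resid_sd = np.sqrt(1.0 - variance_explained)

    g = rng.binomial(2, maf, size=(n_reps, n)).astype(float)
    y = beta * (g - 2.0 * maf) + rng.normal(0.0, resid_sd, size=(n_reps, n))

    gc = g - g.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = (gc**2).sum(axis=1)
    syy = (yc**2).sum(axis=1)
    sxy = (gc * yc).sum(axis=1)
    ok = (sxx > 0) & (syy > 0)
    r2 = np.zeros(n_reps)
    r2[ok] = sxy[ok] ** 2 / (sxx[ok] * syy[ok])
    r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
    tstat2 = r2 * (n - 2) / (1.0 - r2)
    pvals = stats.f.sf(tstat2, 1, n - 2)
    return float(np.mean(pvals < alpha))


def expected_discoveries(rate: float, n_variants: int) -> DiscoveryExpectation:
    """Expected hits when a per-variant hit rate applies to ``n_variants``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    return DiscoveryExpectation(rate=float(rate), n_variants=int(n_variants))


def power_table(
    n: int = 450,
    alpha: float = 1e-6,
    mafs: tuple[float, ...] = (0.01, 0.02, 0.03, 0.04, 0.05, 0.1, 0.2),
    variances: tuple[float, ...] = (0.05, 0.06, 0.07, 0.08, 0.09, 0.10),
    convention: str = "f",
) -> pd.DataFrame:
    """Power/effect grid over (MAF, variance explained) at fixed n and alpha.

    One row per (MAF, V) pair with the SD effect size required to explain V at
    that MAF and the (MAF-independent) analytic power.
    """
    rows = []
    for v in variances:
        pw = analytic_power(n, v, alpha, convention=convention)
        for p in mafs:
            rows.append(
                PowerCell(
                    maf=p,
                    variance_explained=v,
                    n=n,
                    alpha=alpha,
                    effect_sd=effect_from_variance(v, p),
                    power=pw,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
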