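"""Rank-based inverse-normal transformation with covariate residualization.

Expression intensities and circulating biomarkers are mapped to normal scores
before association testing: inverse-normalize the raw values, regress out the
covariates (age, sex and batches for expression traits; age and sex for
biomarkers), and inverse-normalize the residuals — the "double
inverse-normalization".  The second transform keeps the error around the
linear model close to normal without changing the ranking of the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .exceptions import CollinearityError

__all__ = ["PreparedPhenotype", "inverse_normal", "double_inverse_normal_residualize"]

#: quantile-offset rules: transformed = ndtri((rank - c) / (n - 2c + 1))
OFFSETS = {"blom": 3.0 / 8.0, "vanderwaerden": 0.0, "tukey": 1.0 / 3.0}


@dataclass
class PreparedPhenotype:
    """An analysis-ready trait vector and a record of how it was prepared."""

    values: pd.Series  # normal scores, NaN where input missing
    covariates_removed: list[str]
    offset_rule: str
    tie_policy: str


def inverse_normal(
    values,
    offset_rule: str = "blom",
    tie_policy: str = "average",
) -> np.ndarray:
    """Map values to normal scores via ranks: ``ndtri((r - c) / (n - 2c + 1))``.

    Blom's offset (c = 3/8) is the default; ties share average ranks so the
    result is deterministic and order-independent.  Missing values (NaN) are
    passed through untouched and excluded from ranking.
    """
    x = np.asarray(values, dtype=float)
    if offset_rule not in OFFSETS:
        raise ValueError(f"unknown offset rule {offset_rule!r}")
    c = OFFSETS[offset_rule]
    out = np.full(x.shape, np.nan)
    mask = ~np.isnan(x)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    obs = x[mask]
    if np.all(obs == obs[0]):
        raise ValueError("all values equal; ranks are degenerate")
    ranks = stats.rankdata(obs, method=tie_policy)
    out[mask] = ndtri((ranks - c) / (n - 2.0 * c + 1.0))
    return out


def double_inverse_normal_residualize(
    values,
    covariates: pd.DataFrame | None = None,
    offset_rule: str = "blom",
    tie_policy: str = "average",
) -> PreparedPhenotype:
    """Inverse-normalize, residualize on covariates, inverse-normalize again.

    With no covariates this reduces to a single inverse-normal transform
    (the second pass is rank-preserving on already-transformed values).
    Raises :class:`CollinearityError` naming the redundant columns when the
    covariate design is rank-deficient.
    """
    if isinstance(values, pd.Series):
        index = values.index
        x = values.to_numpy(dtype=float)
    else:
        x = np.asarray(values, dtype=float)
        index = pd.RangeIndex(len(x))

    z = inverse_normal(x, offset_rule, tie_policy)
    removed: list[str] = []
    if covariates is not None and covariates.shape[1] > 0:
        C = covariates.to_numpy(dtype=float)
        mask = ~np.isnan(z) & ~np.isnan(C).any(axis=1)
        X = np.column_stack([np.ones(int(mask.sum())), C[mask]])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify offending columns by incremental rank
            bad = []
            cols = [np.ones(int(mask.sum()))]
            for name, col in zip(covariates.columns, C[mask].T):
                trial = np.column_stack(cols + [col])
                if np.linalg.matrix_rank(trial) == len(cols):
                    bad.append(str(name))
                else:
                    cols.append(col)
            raise CollinearityError(f"rank-deficient covariates: {', '.join(bad)}")
        beta, *_ = np.linalg.lstsq(X, z[mask], rcond=None)
        resid = np.full_like(z, np.nan)
        resid[mask] = z[mask] - X @ beta
        z = resid
        removed = [str(c) for c in covariates.columns]
    out = inverse_normal(z, offset_rule, tie_policy)
    return PreparedPhenotype(
        values=pd.Series(out, index=index),
        covariates_removed=removed,
        offset_rule=offset_rule,
        tie_policy=tie_policy,
    )
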