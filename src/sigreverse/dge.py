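"""Two-group differential expression for log2-scale expression matrices.

Implements the classic microarray workflow: per-gene log2 fold change
(disease − normal), either a Welch two-sample t or a moderated t with
empirical-Bayes variance shrinkage (the limma model: per-gene residual
variances are shrunk toward a prior estimated by method of moments on the
log variances), two-sided p-values, and Benjamini–Hochberg FDR adjustment.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError

log = logging.getLogger(__name__)

GROUP_NORMAL = "normal"
GROUP_DISEASE = "disease"

#: columns of a differential-expression table, in output order
DGE_COLUMNS = ("gene_id", "log2fc", "tstat", "pvalue", "adj_pvalue")


@dataclass
class ExpressionMatrix:
    """A log2-scale gene × sample matrix with a two-group sample assignment.

    Parameters
    ----------
    values
        DataFrame with gene IDs as index and sample IDs as columns; all
        entries must be finite.
    groups
        Series mapping every sample ID to ``"normal"`` or ``"disease"``;
        both groups must be non-empty.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise InputError(f"duplicate gene IDs: {list(dup[:5])}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].unique()
            raise InputError(f"duplicate sample IDs: {list(dup[:5])}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise InputError(f"samples without a group assignment: {missing}")
        bad = set(self.groups.unique()) - {GROUP_NORMAL, GROUP_DISEASE}
        if bad:
            raise InputError(f"unknown group labels: {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise InputError("expression values must all be finite")
        for g in (GROUP_NORMAL, GROUP_DISEASE):
            if not any(self.groups.get(s) == g for s in self.values.columns):
                raise InputError(f"group {g!r} has no samples")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


def auto_log_check(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Log2-transform the matrix if it looks like raw (unlogged) intensities.

    If the 99th percentile of the values exceeds 50 the matrix is judged
    unlogged and every value is replaced by ``log2(x + 1)`` (with a logged
    warning); otherwise the matrix is returned unchanged.

    Raises
    ------
    InputError
        If a matrix judged unlogged contains negative values.
    """
    vals = matrix.values.to_numpy()
    if np.percentile(vals, 99) <= 50:
        return matrix
    if (vals < 0).any():
        raise InputError("matrix judged unlogged but contains negative values")
    log.warning("values look unlogged (q99 > 50); applying log2(x + 1)")
    return ExpressionMatrix(np.log2(matrix.values + 1.0), matrix.groups)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order of input preserved.

    Raises
    ------
    InputError
        If any p-value lies outside (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.all((p > 0) & (p <= 1)):
        raise InputError("p-values must lie in (0, 1]")
    return np.minimum(multipletests(p, method="fdr_bh")[1], 1.0)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior for residual variances.

    Returns ``(prior_df, prior_var)``; ``prior_df`` may be ``inf`` when the
    observed spread of log variances is no larger than expected under a
    single common variance.
    """
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(polygamma(1, df / 2.0)) if e.size > 1 else 0.0
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0 = float(np.exp(emean))
    return d0, s0


def _moderated_t(
    lfc: np.ndarray,
    s2: np.ndarray,
    df: float,
    se_factor: float,
    prior_df: float,
    prior_var: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Moderated t given pooled variances and a (prior_df, prior_var) prior.

    ``se_factor`` is 1/n1 + 1/n2. Returns (t, p, total_df)."""
    if np.isinf(prior_df):
        s2_post = np.full_like(s2, prior_var)
        df_total = np.inf
    else:
        s2_post = (prior_df * prior_var + df * s2) / (prior_df + df)
        df_total = df + prior_df
    t = lfc / np.sqrt(s2_post * se_factor)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, np.clip(p, np.finfo(float).tiny, 1.0), df_total


def _floor_variances(*variances: np.ndarray) -> tuple[np.ndarray, ...]:
    """Replace exactly-zero variances by (smallest positive variance) × 1e-3."""
    stacked = np.concatenate([v.ravel() for v in variances])
    positive = stacked[stacked > 0]
    if positive.size == 0:
        raise InputError("all per-gene variances are zero; nothing to test")
    floor = positive.min() * 1e-3
    out = []
    n_floored = 0
    for v in variances:
        mask = v == 0
        n_floored += int(mask.sum())
        out.append(np.where(mask, floor, v))
    if n_floored:
        log.warning("floored %d zero variances at %.3g", n_floored, floor)
    return tuple(out)


def differential_expression(
    matrix: ExpressionMatrix, mode: str = "moderated"
) -> pd.DataFrame:
    """Per-gene two-group differential expression.

    Parameters
    ----------
    matrix
        Validated expression matrix (log2 scale).
    mode
        ``"moderated"`` (default) for the empirical-Bayes moderated t;
        ``"welch"`` for the Welch unequal-variance t with
        Welch–Satterthwaite degrees of freedom.

    Returns
    -------
    DataFrame with one row per input gene (input order preserved) and
    columns ``gene_id, log2fc, tstat, pvalue, adj_pvalue``. log2fc is
    disease mean − normal mean, so positive means up-regulated in disease.
    """
    if mode not in ("welch", "moderated"):
        raise InputError(f"unknown mode {mode!r}; expected 'welch' or 'moderated'")
    normal = matrix.values[matrix.samples_in_group(GROUP_NORMAL)].to_numpy()
    disease = matrix.values[matrix.samples_in_group(GROUP_DISEASE)].to_numpy()
    n1, n2 = normal.shape[1], disease.shape[1]
    if n1 < 2 or n2 < 2:
        raise InputError(
            f"need >=2 samples per group, got normal={n1}, disease={n2}"
        )

    lfc = disease.mean(axis=1) - normal.mean(axis=1)
    v1 = normal.var(axis=1, ddof=1)
    v2 = disease.var(axis=1, ddof=1)

    if mode == "welch":
        v1f, v2f = _floor_variances(v1, v2)
        se2 = v1f / n1 + v2f / n2
        t = lfc / np.sqrt(se2)
        df = se2**2 / ((v1f / n1) ** 2 / (n1 - 1) + (v2f / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    else:
        df_resid = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
        (s2,) = _floor_variances(s2)
        prior_df, prior_var = _fit_variance_prior(s2, df_resid)
        se_factor = 1.0 / n1 + 1.0 / n2
        t, p, _ = _moderated_t(lfc, s2, df_resid, se_factor, prior_df, prior_var)

    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "log2fc": lfc,
            "tstat": t,
            "pvalue": p,
            "adj_pvalue": bh_adjust(p),
        }
    ).reset_index(drop=True)
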