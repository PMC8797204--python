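"""TMM normalization and two-group differential expression on count libraries.

TMM (trimmed mean of M-values) follows the published method: a reference
sample chosen by upper-quartile proximity to the mean, gene-wise log ratios
(M) and average log abundances (A) against the reference, double trimming,
and a precision-weighted mean of the surviving M values; factors are rescaled
to geometric mean 1. Testing is a per-gene two-sided Welch t on log2 CPM with
Benjamini-Hochberg correction — a deliberately plain engine whose contract is
calibration and power, not a moderated-t replica.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TMMConfig",
    "tmm_factors",
    "log_cpm",
    "filter_low_counts",
    "de_test",
    "bh_adjust",
    "differential_expression",
    "read_counts",
    "write_counts",
]


@dataclass
class TMMConfig:
    logratio_trim: float = 0.3
    abs_trim: float = 0.05
    prior_count: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.logratio_trim < 0.5 and 0 <= self.abs_trim < 0.5):
            raise ValueError("trim fractions must lie in [0, 0.5)")


def _as_matrix(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    m = counts.to_numpy() if isinstance(counts, pd.DataFrame) else np.asarray(counts)
    if (m < 0).any():
        raise ValueError("counts must be nonnegative")
    return m.astype(float)


def tmm_factors(counts: pd.DataFrame | np.ndarray, cfg: TMMConfig | None = None) -> np.ndarray:
    """Per-sample TMM normalization factors (geometric mean 1)."""
    cfg = cfg or TMMConfig()
    y = _as_matrix(counts)
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample must have a positive library size")
    # reference: sample whose upper-quartile count fraction is closest to the mean
    uq = np.array([np.percentile(col[col > 0], 75) for col in y.T]) / lib
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array(
        [_tmm_pair(y[:, k], y[:, ref], lib[k], lib[ref], cfg) for k in range(y.shape[1])]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float, cfg: TMMConfig) -> float:
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        logger.warning("tmm: no genes positive in both samples; factor = 1")
        return 1.0
    o, r = obs[ok], ref[ok]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # delta-method asymptotic variance of M
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.allclose(m, m[0], atol=1e-10):
        return float(2 ** m[0])
    # double trim: keep ranks inside [trim, 1 - trim] for both M and A
    n = len(m)
    lo_m, hi_m = np.floor(n * cfg.logratio_trim) + 1, n + 1 - (np.floor(n * cfg.logratio_trim) + 1)
    lo_a, hi_a = np.floor(n * cfg.abs_trim) + 1, n + 1 - (np.floor(n * cfg.abs_trim) + 1)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        logger.warning("tmm: no genes survive trimming; factor = 1")
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2**f)


def log_cpm(
    counts: pd.DataFrame | np.ndarray,
    factors: np.ndarray | None = None,
    prior: float = 0.5,
) -> pd.DataFrame | np.ndarray:
    """log2 counts-per-million on effective library sizes.

    ``log2((count + prior) / (libsize * factor + 2 * prior) * 1e6)``
    """
    y = _as_matrix(counts)
    lib = y.sum(axis=0)
    factors = np.ones(y.shape[1]) if factors is None else np.asarray(factors, dtype=float)
    if (factors <= 0).any():
        raise ValueError("factors must be positive")
    eff = lib * factors
    out = np.log2((y + prior) / (eff + 2 * prior) * 1e6)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def filter_low_counts(
    counts: pd.DataFrame, groups: pd.Series | np.ndarray, min_cpm: float = 1.0
) -> pd.DataFrame:
    """Keep genes with CPM > min_cpm in at least min-group-size samples."""
    groups = np.asarray(groups)
    min_n = min(np.sum(groups == g) for g in np.unique(groups))
    cpm = _as_matrix(counts) / _as_matrix(counts).sum(axis=0) * 1e6
    keep = (cpm > min_cpm).sum(axis=1) >= min_n
    return counts.loc[keep]


def bh_adjust(pvalues: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1.

    ``m`` may exceed ``len(pvalues)`` to account for untested hypotheses whose
    p-value is 1 by construction.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    m = n if m is None else int(m)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def de_test(logcpm: pd.DataFrame, groups: pd.Series | np.ndarray) -> pd.DataFrame:
    """Per-gene two-sided Welch t on logCPM, case vs control.

    ``groups`` carries exactly two labels; the lexicographically larger label
    is the case group unless labels are ("control", "case")-like ordered by
    first appearance. logFC = mean(case) - mean(control). Genes with zero
    variance in both groups and equal means get p = 1; zero variance with
    unequal means is maximally significant (p = 0).
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    control, case = labels[0], labels[1]
    a = logcpm.loc[:, groups == case].to_numpy()
    b = logcpm.loc[:, groups == control].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")
    logfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate & (logfc == 0), 1.0, p)
    p = np.where(degenerate & (logfc != 0), 0.0, p)
    t = np.where(np.isfinite(t), t, 0.0)
    res = pd.DataFrame(
        {
            "logFC": logfc,
            "AveExpr": logcpm.mean(axis=1).to_numpy(),
            "t": t,
            "p": p,
            "q": bh_adjust(p),
        },
        index=logcpm.index,
    )
    res.index.name = "gene_id"
    return res


def differential_expression(
    counts: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    cfg: TMMConfig | None = None,
    min_cpm: float = 1.0,
) -> pd.DataFrame:
    """Filter -> TMM -> logCPM -> Welch t -> BH, end to end."""
    cfg = cfg or TMMConfig()
    filtered = filter_low_counts(counts, groups, min_cpm=min_cpm)
    factors = tmm_factors(filtered, cfg)
    lc = log_cpm(filtered, factors, prior=cfg.prior_count)
    return de_test(lc, groups)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
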