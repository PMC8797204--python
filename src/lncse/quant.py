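"""Bench-side quantification formulas and clinical-table statistics.

Two-sided Fisher exact test (minimum-likelihood definition, log-space
hypergeometric), Welch t from summary statistics (mean, SEM, n), relative
qPCR quantification (2^-ddCt), 3C nearest-fragment normalization, ChIP fold
enrichment over IgG, and a driver that routes the rows of a clinical
characteristics table to the right test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "SummaryStat",
    "fisher_exact_two_sided",
    "welch_t_from_summary",
    "ddct_fold_change",
    "c3_relative_interaction",
    "chip_fold_enrichment",
    "reconstruct_counts",
    "clinical_table_compare",
]

_REL_TIE_TOL = 1e-7  # probabilities within this relative tolerance count as <=


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are groups, columns trait present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table total must be >= 1")


@dataclass(frozen=True)
class SummaryStat:
    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("SEM must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by the minimum-likelihood criterion.

    Sums the hypergeometric probability of every table with the observed
    margins whose probability is <= that of the observed table (with a small
    relative tolerance for floating ties). Degenerate margins give p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, col1, n = a + b, a + c, a + b + c + d
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return 1.0
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    logp = stats.hypergeom.logpmf(support, n, col1, row1)
    log_obs = float(stats.hypergeom.logpmf(a, n, col1, row1))
    keep = logp <= log_obs + math.log1p(_REL_TIE_TOL)
    # log-sum-exp over the kept tables
    m = logp[keep].max()
    total = float(np.exp(m) * np.exp(logp[keep] - m).sum())
    return min(1.0, total)


def welch_t_from_summary(g1: SummaryStat, g2: SummaryStat) -> tuple[float, float, float]:
    """Welch t, Welch-Satterthwaite df and two-sided p from (mean, SEM, n)."""
    se2 = g1.sem**2 + g2.sem**2
    if se2 == 0:
        raise ValueError("both SEMs are zero; t undefined")
    t = (g1.mean - g2.mean) / math.sqrt(se2)
    df = se2**2 / (g1.sem**4 / (g1.n - 1) + g2.sem**4 / (g2.n - 1))
    p = float(2 * stats.t.sf(abs(t), df))
    return t, df, p


def ddct_fold_change(
    qpcr: pd.DataFrame, control_condition: str
) -> dict[str, float]:
    """2^-ddCt relative quantification per condition.

    ``qpcr`` columns: condition, ct_target, ct_reference (one row per sample).
    dCt = Ct_target - Ct_reference per sample; fold(condition) =
    2^-(mean dCt_condition - mean dCt_control). The control maps to 1.0.
    """
    required = {"condition", "ct_target", "ct_reference"}
    if not required.issubset(qpcr.columns):
        raise ValueError(f"qpcr frame needs columns {sorted(required)}")
    if qpcr[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing reference or target Ct")
    dct = qpcr["ct_target"] - qpcr["ct_reference"]
    means = dct.groupby(qpcr["condition"]).mean()
    if control_condition not in means.index:
        raise ValueError(f"control condition {control_condition!r} absent")
    return {
        cond: float(2 ** -(means[cond] - means[control_condition])) for cond in means.index
    }


def c3_relative_interaction(
    ligation_qty: float,
    gapdh_ctrl_qty: float,
    nearest_frag_qty: float,
    nearest_gapdh_qty: float | None = None,
) -> float:
    """3C relative interaction frequency.

    Each ligation quantity is scaled by its sample's undigested genomic
    control, then by the anchor's nearest downstream restriction fragment
    (which therefore maps to 1.0). When both quantities share the control
    sample the genomic scaling cancels exactly.
    """
    if nearest_gapdh_qty is None:
        nearest_gapdh_qty = gapdh_ctrl_qty
    if min(ligation_qty, gapdh_ctrl_qty, nearest_frag_qty, nearest_gapdh_qty) <= 0:
        raise ValueError("all quantities must be > 0")
    return (ligation_qty / gapdh_ctrl_qty) / (nearest_frag_qty / nearest_gapdh_qty)


def chip_fold_enrichment(
    signal_qty: float,
    igg_qty: float,
    input_signal: float | None = None,
    input_igg: float | None = None,
) -> float:
    """Quantitative-ChIP fold enrichment over the IgG control.

    Optionally per-input normalized first (percent-of-input on each side).
    """
    if igg_qty <= 0:
        raise ValueError("IgG quantity must be > 0")
    if (input_signal is None) != (input_igg is None):
        raise ValueError("provide both input quantities or neither")
    if input_signal is not None:
        if input_signal <= 0 or input_igg <= 0:
            raise ValueError("input quantities must be > 0")
        return (signal_qty / input_signal) / (igg_qty / input_igg)
    return signal_qty / igg_qty


def reconstruct_counts(pct: float, n: int, decimals: int = 1) -> tuple[int, bool]:
    """Reconstruct the trait-positive count from a printed percentage.

    Returns (count, consistent): count = round(pct * n / 100); consistent is
    False when no integer count reproduces the printed percentage within half
    a unit in its last printed decimal place.
    """
    k = int(round(pct * n / 100.0))
    tol = 0.5 * 10.0 ** (-decimals) + 1e-9
    consistent = abs(100.0 * k / n - pct) <= tol
    return k, consistent


def clinical_table_compare(rows: Sequence[Mapping]) -> pd.DataFrame:
    """Per-row statistics for a clinical characteristics table.

    Each row mapping needs: ``variable``; ``type`` ("categorical" or
    "continuous"); for categorical: ``pct1``, ``n1``, ``pct2``, ``n2`` and an
    optional ``decimals`` (printed precision, default 1 if the pct has a
    fractional part else 0); for continuous: ``mean1``, ``sem1``, ``n1``,
    ``mean2``, ``sem2``, ``n2``.

    Categorical rows are routed to the two-sided Fisher exact test on counts
    reconstructed from the printed percentages; rows whose percentages cannot
    be reconciled with any integer count are flagged rather than coerced.
    Continuous rows are routed to the Welch t from summaries (nonparametric
    routing is impossible without the raw measurements; such rows carry a
    note).
    """
    out = []
    for row in rows:
        var, typ = row["variable"], row["type"]
        if typ == "categorical":
            n1, n2 = int(row["n1"]), int(row["n2"])
            pct1, pct2 = float(row["pct1"]), float(row["pct2"])
            dec = int(
                row.get("decimals", 1 if (pct1 % 1 or pct2 % 1) else 0)
            )
            k1, ok1 = reconstruct_counts(pct1, n1, dec)
            k2, ok2 = reconstruct_counts(pct2, n2, dec)
            flagged = not (ok1 and ok2)
            p = fisher_exact_two_sided(
                ContingencyTable2x2(k1, n1 - k1, k2, n2 - k2)
            )
            out.append(
                {
                    "variable": var, "test": "fisher_exact", "statistic": float(k2),
                    "p": p, "flagged": flagged,
                    "note": "counts inconsistent with printed %" if flagged else "",
                }
            )
        elif typ == "continuous":
            t, df, p = welch_t_from_summary(
                SummaryStat(float(row["mean1"]), float(row["sem1"]), int(row["n1"])),
                SummaryStat(float(row["mean2"]), float(row["sem2"]), int(row["n2"])),
            )
            out.append(
                {
                    "variable": var, "test": "welch_t", "statistic": t, "p": p,
                    "flagged": False,
                    "note": "raw data unavailable; normality routing not applied",
                }
            )
        else:
            raise ValueError(f"unknown row type {typ!r}")
    return pd.DataFrame(out)
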