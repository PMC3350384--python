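"""Scoring of wet-lab validation summaries.

Two kinds of table are scored:

* IHC tissue-array score tables — per cancer type, case counts at three
  staining levels (``-``, ``+``, and the pooled ``++``/``+++`` level
  treated as overexpression).  Summaries report per-type and pooled
  percentages; group comparisons use a frequency-weighted Welch t-test.

* qRT-PCR knockdown tables — for each gene predicted to correlate with
  the anchor, the expression level in anchor-knockdown (shR) cells
  relative to control (shN) cells normalized to 1.  The knockdown fold
  change is the reciprocal of that relative value; a fold above 1 means
  the gene fell with the anchor (positive correlation confirmed), below
  1 the opposite.  Each record is scored consistent / inconsistent /
  unchanged against its predicted correlation sign, and the share of
  consistent calls summarizes the panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._util import round_half_up

log = logging.getLogger(__name__)

SCORE_LEVELS = ("neg", "plus", "plusplus")


@dataclass
class IHCScoreTable:
    cancer_type: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(SCORE_LEVELS)
        if unknown:
            raise ValueError(f"unknown score levels {unknown}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be >= 0")
        self.counts = {lvl: int(self.counts.get(lvl, 0)) for lvl in SCORE_LEVELS}

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class IHCSummaryRow:
    cancer_type: str
    total: int
    pct_neg: float
    pct_plus: float
    pct_plusplus: float

    @property
    def overexpression_rate(self) -> float:
        """++/+++ share, the operational overexpression rate."""
        return self.pct_plusplus


def ihc_summary(tables: list[IHCScoreTable]) -> list[IHCSummaryRow]:
    """Per-type and pooled score-level percentages (half-up, 1 decimal)."""
    if not tables:
        raise ValueError("no score tables given")
    rows = []
    pooled = {lvl: 0 for lvl in SCORE_LEVELS}
    for tab in tables:
        if tab.total == 0:
            raise ValueError(f"{tab.cancer_type}: zero total")
        rows.append(_summary_row(tab.cancer_type, tab.counts, tab.total))
        for lvl in SCORE_LEVELS:
            pooled[lvl] += tab.counts[lvl]
    rows.append(_summary_row("total", pooled, sum(pooled.values())))
    return rows


def _summary_row(name: str, counts: dict[str, int], total: int) -> IHCSummaryRow:
    pct = {lvl: round_half_up(100.0 * counts[lvl] / total, 1) for lvl in SCORE_LEVELS}
    return IHCSummaryRow(
        cancer_type=name,
        total=total,
        pct_neg=pct["neg"],
        pct_plus=pct["plus"],
        pct_plusplus=pct["plusplus"],
    )


def ihc_group_test(
    values_a, values_b, weights_a=None, weights_b=None
) -> tuple[float, float, float]:
    """Frequency-weighted Welch t-test on per-case scores.

    Weighted means and variances (frequency-weight convention, variance
    denominator ``sum(w) - 1``) replace the unweighted moments in the
    Welch statistic and Welch-Satterthwaite df.  With unit weights this
    reproduces the unweighted Welch test exactly.  Returns (t, df,
    two-tailed p).
    """
    stats_a = _weighted_moments(values_a, weights_a)
    stats_b = _weighted_moments(values_b, weights_b)
    ma, va, na = stats_a
    mb, vb, nb = stats_b
    sa, sb = va / na, vb / nb
    if sa + sb == 0:
        return (0.0, na + nb - 2, 1.0) if ma == mb else (
            float(np.sign(ma - mb) * np.inf), na + nb - 2, 0.0)
    t = (ma - mb) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _weighted_moments(values, weights):
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 cases per group")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != x.shape or np.any(w <= 0):
        raise ValueError("weights must be positive and match the values")
    n = float(w.sum())
    mean = float((w * x).sum() / n)
    var = float((w * (x - mean) ** 2).sum() / (n - 1.0))
    return mean, var, n


@dataclass
class QPCRRecord:
    """One gene's knockdown qRT-PCR readout and its predicted sign.

    ``rel_value_shr`` is the expression in knockdown (shR) cells relative
    to control (shN) cells normalized to 1; the knockdown fold change is
    its reciprocal.
    """

    gene: str
    tissue: str
    rel_value_shr: float
    predicted_sign: str
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.rel_value_shr <= 0:
            raise ValueError(f"{self.gene}: relative PCR value must be > 0")
        if self.predicted_sign not in ("positive", "negative"):
            raise ValueError(f"{self.gene}: predicted_sign must be positive|negative")

    @property
    def fold_change(self) -> float:
        return 1.0 / self.rel_value_shr


def qpcr_consistency(record: QPCRRecord, unchanged_band: float = 0.1) -> str:
    """Score one knockdown readout against the predicted correlation sign.

    fold = 1 / rel_value_shr; |fold - 1| <= ``unchanged_band`` is scored
    ``unchanged``; otherwise fold > 1 confirms a positive prediction and
    fold < 1 a negative one (``consistent``), anything else is
    ``inconsistent``.
    """
    fold = record.fold_change
    if abs(fold - 1.0) <= unchanged_band:
        return "unchanged"
    observed_sign = "positive" if fold > 1.0 else "negative"
    return "consistent" if observed_sign == record.predicted_sign else "inconsistent"


@dataclass
class ConsistencySummary:
    n_total: int
    n_consistent: int
    n_inconsistent: int
    n_unchanged: int
    pct_consistent: float
    pct_inconsistent: float


def consistency_rate(
    records: list[QPCRRecord], unchanged_band: float = 0.1
) -> ConsistencySummary:
    """Share of knockdown readouts consistent with the predicted signs
    (percentages rounded half-up to one decimal)."""
    if not records:
        raise ValueError("no qPCR records given")
    statuses = [qpcr_consistency(rec, unchanged_band) for rec in records]
    n = len(statuses)
    n_con = statuses.count("consistent")
    n_inc = statuses.count("inconsistent")
    return ConsistencySummary(
        n_total=n,
        n_consistent=n_con,
        n_inconsistent=n_inc,
        n_unchanged=statuses.count("unchanged"),
        pct_consistent=round_half_up(100.0 * n_con / n, 1),
        pct_inconsistent=round_half_up(100.0 * n_inc / n, 1),
    )
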