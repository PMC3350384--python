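"""Anchor-gene differential expression across datasets.

Each dataset contributes up to three two-group comparisons of the anchor
gene (cancer vs normal, disease vs normal, cancer vs disease).  A paired
t-test is used when explicit cancer/normal pairing metadata exists,
otherwise Welch's unequal-variance t-test; the dispatcher records which
test ran.  Per-dataset significance calls (p < alpha, default 0.05) are
then tallied across datasets into "k of d significant" summaries.

Only the anchor gene is tested — this mirrors a single-gene survey, so
no multiple-testing correction across genes is involved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ExpressionDataset
from ._util import pct_half_up
from .preprocess import group_log2_ratio

log = logging.getLogger(__name__)

COMPARISONS = (
    ("cancer_vs_normal", "cancer", "normal"),
    ("disease_vs_normal", "disease", "normal"),
    ("cancer_vs_disease", "cancer", "disease"),
)


@dataclass
class DiffExprResult:
    dataset_id: str
    comparison: str
    anchor_log2fc: float
    fold_change: float
    t_stat: float
    df: float
    p_value: float
    significant: bool
    test_used: str


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch's two-sample t-test; returns (t, Welch-Satterthwaite df, two-tailed p).

    Degenerate inputs are resolved deterministically: if both groups have
    zero variance, p = 1 when the means are equal and p = 0 (with a
    warning) when they differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"need >= 2 observations per group, got {len(a)} and {len(b)}")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        df = float(len(a) + len(b) - 2)
        if np.mean(a) == np.mean(b):
            return 0.0, df, 1.0
        warnings.warn("zero variance in both groups with unequal means; p set to 0")
        return float(np.sign(np.mean(a) - np.mean(b)) * np.inf), df, 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def paired_t_test(a, b, pairing=None) -> tuple[float, float, float]:
    """Paired two-sample t-test (one-sample t on differences, df = n-1).

    ``a`` and ``b`` may be aligned vectors, or dicts keyed by sample id
    with ``pairing`` a map from keys of ``a`` to keys of ``b``.  All-zero
    differences give p = 1; zero-variance nonzero differences give p = 0
    with a warning.
    """
    if pairing is not None:
        try:
            pairs = [(a[x], b[y]) for x, y in pairing.items() if x in a]
        except KeyError as exc:
            raise ValueError(f"unmatched sample in pairing: {exc}") from None
        if len(pairs) != len(a):
            raise ValueError("pairing does not cover every sample in the first group")
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired groups must have equal size")
    if len(a) < 2:
        raise ValueError("need >= 2 pairs")
    diff = a - b
    df = float(len(diff) - 1)
    if np.var(diff, ddof=1) == 0:
        if np.mean(diff) == 0:
            return 0.0, df, 1.0
        warnings.warn("zero-variance nonzero differences; p set to 0")
        return float(np.sign(np.mean(diff)) * np.inf), df, 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.df), float(res.pvalue)


def anchor_diffexpr(
    dataset: ExpressionDataset, anchor_symbol: str, alpha: float = 0.05
) -> list[DiffExprResult]:
    """Test the anchor gene in every available two-class comparison.

    The paired test is dispatched iff the dataset carries pairing
    metadata for the comparison's classes (only cancer/normal pairs are
    representable); all other comparisons use Welch.  Requires log2-scale
    data so the reported log2 fold change is a difference of means.
    """
    if not dataset.is_log2:
        raise ValueError("anchor_diffexpr expects log2-scale data; call to_log2 first")
    if anchor_symbol not in dataset.values.index:
        raise ValueError(
            f"anchor {anchor_symbol!r} absent from {dataset.metadata.dataset_id}"
        )
    anchor = dataset.values.loc[anchor_symbol]
    present = {c for c in ("cancer", "disease", "normal") if dataset.samples_of_class(c)}
    if len(present) < 2:
        raise ValueError(
            f"{dataset.metadata.dataset_id}: need >= 2 sample classes, have {present}"
        )
    results = []
    for name, num, den in COMPARISONS:
        if num not in present or den not in present:
            continue
        x = anchor[dataset.samples_of_class(num)].to_numpy()
        y = anchor[dataset.samples_of_class(den)].to_numpy()
        use_paired = (
            dataset.paired_with is not None
            and {num, den} == {"cancer", "normal"}
        )
        if use_paired:
            a_map = {s: anchor[s] for s in dataset.samples_of_class("cancer")}
            b_map = {s: anchor[s] for s in dataset.samples_of_class("normal")}
            pairing = {
                s: dataset.paired_with[s]
                for s in a_map
                if s in dataset.paired_with
            }
            if len(pairing) != len(a_map):
                raise ValueError("pairing metadata does not cover all cancer samples")
            t, df, p = paired_t_test(a_map, b_map, pairing)
            if num == "normal":  # not reachable with current comparisons, kept for safety
                t = -t
        else:
            t, df, p = welch_t_test(x, y)
        log2fc = float(group_log2_ratio(dataset, num, den).loc[anchor_symbol])
        results.append(
            DiffExprResult(
                dataset_id=dataset.metadata.dataset_id,
                comparison=name,
                anchor_log2fc=log2fc,
                fold_change=float(2.0**log2fc),
                t_stat=t,
                df=df,
                p_value=p,
                significant=bool(p < alpha),
                test_used="paired" if use_paired else "welch",
            )
        )
        log.info(
            "%s %s: log2fc=%.3f t=%.3f p=%.3g (%s)",
            dataset.metadata.dataset_id, name, log2fc, t, p,
            "paired" if use_paired else "welch",
        )
    return results


@dataclass
class SignificanceSummary:
    group: str
    n_significant: int
    n_datasets: int
    percentage: int


def summarize_significance(
    results: list[DiffExprResult],
    tissues: dict[str, str] | None = None,
    comparison: str = "cancer_vs_normal",
) -> list[SignificanceSummary]:
    """Tally datasets with a significant anchor change (k of d, integer %).

    One summary row per tissue when a dataset_id -> tissue map is given,
    plus an ``overall`` row.  Percentages are rounded half-up to the
    nearest integer (14 of 21 -> 67%).
    """
    rows = [r for r in results if r.comparison == comparison]
    if not rows:
        raise ValueError(f"no results for comparison {comparison!r}")
    groups: dict[str, list[DiffExprResult]] = {"overall": rows}
    if tissues:
        for r in rows:
            groups.setdefault(tissues.get(r.dataset_id, "other"), []).append(r)
    out = []
    for name in sorted(groups):
        if name == "overall":
            continue
        out.append(_summary_row(name, groups[name]))
    out.append(_summary_row("overall", groups["overall"]))
    return out


def _summary_row(name: str, rows: list[DiffExprResult]) -> SignificanceSummary:
    k = sum(r.significant for r in rows)
    return SignificanceSummary(
        group=name,
        n_significant=k,
        n_datasets=len(rows),
        percentage=int(pct_half_up(k, len(rows))),
    )
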