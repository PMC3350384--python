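"""Genome-wide Pearson correlation of every gene with the anchor.

Per dataset: each non-anchor gene gets a pairwise-complete Pearson r
with the anchor, a two-tailed p-value from the Fisher z transformation
(z = atanh r; under independence z*sqrt(n-3) is approximately standard
normal), and a rank by ascending p (ties by descending |r|, then gene
symbol).  Candidate selection keeps genes with p below a cutoff (0.001
by default, chosen so real collections yield several hundred candidates
per dataset) and flags the top tissue-specific fraction of those
candidates as selected.

The Fisher z p-value is a large-sample approximation; its relative
agreement with the exact t-based test degrades in the far tail (large
|r|), which does not affect ranking (both are monotone in |r| at fixed
n) but matters when p-values are interpreted literally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionDataset

log = logging.getLogger(__name__)

#: genes with fewer pairwise-complete observations are dropped from ranking
MIN_PAIRWISE_N = 6

#: per-tissue "top fraction of candidates" selection quotas
DEFAULT_TOP_FRACTION = {"thyroid": 0.20, "colon": 0.15, "liver": 0.10, "lung": 0.05}


@dataclass
class CorrelationRecord:
    gene: str
    dataset_id: str
    r: float
    n_eff: int
    p_value: float
    rank: int
    selected: bool = False


@dataclass(frozen=True)
class SelectionPolicy:
    """Candidate-selection thresholds.

    ``top_fraction`` is interpreted as a fraction of the candidates
    passing ``p_cutoff`` (``fraction_base="candidates"``); the alternate
    reading, a fraction of all ranked genes, is available as
    ``fraction_base="all_genes"``.  A warning is logged when fewer than
    ``min_candidates`` genes pass the cutoff.
    """

    p_cutoff: float = 0.001
    top_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TOP_FRACTION)
    )
    min_candidates: int = 600
    fraction_base: str = "candidates"

    def __post_init__(self) -> None:
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must be in (0,1)")
        for tissue, f in self.top_fraction.items():
            if not 0 < f <= 1:
                raise ValueError(f"top_fraction[{tissue!r}] must be in (0,1]")
        if self.fraction_base not in ("candidates", "all_genes"):
            raise ValueError("fraction_base must be 'candidates' or 'all_genes'")

    def fraction_for(self, tissue: str) -> float:
        try:
            return self.top_fraction[tissue]
        except KeyError:
            raise KeyError(f"no top_fraction configured for tissue {tissue!r}") from None


def pearson_r(x, y) -> float:
    """Product-moment correlation on pairwise-complete observations."""
    r, n_eff = _pairwise_r(np.asarray(x, float), np.asarray(y, float))
    if n_eff < 2:
        raise ValueError("need >= 2 pairwise-complete observations")
    if math.isnan(r):
        raise ValueError("zero variance: correlation undefined")
    return r


def _pairwise_r(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    m = np.isfinite(x) & np.isfinite(y)
    n = int(m.sum())
    if n < 2:
        return float("nan"), n
    xv, yv = x[m], y[m]
    xd = xv - xv.mean()
    yd = yv - yv.mean()
    den = math.sqrt(float(xd @ xd) * float(yd @ yd))
    if den == 0:
        return float("nan"), n
    return float(np.clip((xd @ yd) / den, -1.0, 1.0)), n


def correlation_pvalue(r: float, n_eff: int) -> float:
    """Two-tailed Fisher-z p-value for a Pearson correlation.

    p = 2 * (1 - Phi(|atanh r| * sqrt(n_eff - 3))); |r| = 1 gives p = 0
    by convention.
    """
    if n_eff < 4:
        raise ValueError(f"need n_eff >= 4, got {n_eff}")
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1:
        return 0.0
    z = math.atanh(r)
    return float(2.0 * stats.norm.sf(abs(z) * math.sqrt(n_eff - 3)))


def _matrix_pairwise_r(X: np.ndarray, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pairwise-complete Pearson r of matrix rows against ``a``."""
    finite_a = np.isfinite(a)
    M = np.isfinite(X) & finite_a[np.newaxis, :]
    Xz = np.where(np.isfinite(X), X, 0.0) * M
    az = np.where(finite_a, a, 0.0)
    n = M.sum(axis=1)
    sx = Xz.sum(axis=1)
    sa = M @ az
    sxx = (Xz * Xz).sum(axis=1)
    saa = M @ (az * az)
    sxa = Xz @ az
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxa - sx * sa / np.maximum(n, 1)
        vx = sxx - sx * sx / np.maximum(n, 1)
        va = saa - sa * sa / np.maximum(n, 1)
        r = cov / np.sqrt(vx * va)
    r = np.where((vx <= 0) | (va <= 0) | (n < 2), np.nan, r)
    return np.clip(r, -1.0, 1.0), n.astype(int)


def correlate_anchor(
    dataset: ExpressionDataset, anchor_symbol: str
) -> list[CorrelationRecord]:
    """Correlate every non-anchor gene with the anchor in one dataset.

    Correlations pool all samples of the dataset (cancer, disease and
    normal alike).  Genes with fewer than 6 pairwise-complete
    observations or zero variance are dropped with a logged count.
    Records are returned in rank order: ascending p, ties broken by
    descending |r|, then lexicographic gene symbol.
    """
    if not dataset.is_log2:
        raise ValueError("correlate_anchor expects log2-scale data; call to_log2 first")
    if anchor_symbol not in dataset.values.index:
        raise ValueError(
            f"anchor {anchor_symbol!r} absent from {dataset.metadata.dataset_id}"
        )
    values = dataset.values.drop(index=anchor_symbol)
    anchor = dataset.values.loc[anchor_symbol].to_numpy(dtype=float)
    r, n_eff = _matrix_pairwise_r(values.to_numpy(dtype=float), anchor)

    usable = np.isfinite(r) & (n_eff >= MIN_PAIRWISE_N)
    n_dropped = int((~usable).sum())
    if n_dropped:
        log.info(
            "%s: dropped %d/%d genes (undefined r or n_eff < %d)",
            dataset.metadata.dataset_id, n_dropped, len(values), MIN_PAIRWISE_N,
        )
    genes = values.index.to_numpy()[usable]
    r = r[usable]
    n_eff = n_eff[usable]
    with np.errstate(divide="ignore"):
        z = np.abs(np.arctanh(np.where(np.abs(r) < 1, r, np.sign(r))))
    p = np.where(np.abs(r) >= 1, 0.0, 2.0 * stats.norm.sf(z * np.sqrt(n_eff - 3)))

    order = np.lexsort((genes, -np.abs(r), p))
    dataset_id = dataset.metadata.dataset_id
    return [
        CorrelationRecord(
            gene=str(genes[i]),
            dataset_id=dataset_id,
            r=float(r[i]),
            n_eff=int(n_eff[i]),
            p_value=float(p[i]),
            rank=rank,
        )
        for rank, i in enumerate(order, start=1)
    ]


def select_candidates(
    records: list[CorrelationRecord], policy: SelectionPolicy, tissue: str
) -> list[CorrelationRecord]:
    """Flag the selected genes of one ranked dataset.

    Candidates are the records with p below the policy cutoff; the top
    ``ceil(fraction * base)`` of them by rank are flagged selected, where
    ``base`` is the candidate count (default) or the full record count.
    Returns new records in the input order.
    """
    fraction = policy.fraction_for(tissue)
    candidates = [rec for rec in records if rec.p_value < policy.p_cutoff]
    if len(candidates) < policy.min_candidates:
        log.warning(
            "%s: only %d candidates at p<%g (floor %d)",
            records[0].dataset_id if records else "?",
            len(candidates), policy.p_cutoff, policy.min_candidates,
        )
    base = len(candidates) if policy.fraction_base == "candidates" else len(records)
    n_select = min(math.ceil(fraction * base), len(candidates))
    chosen = {rec.gene for rec in sorted(candidates, key=lambda rec: rec.rank)[:n_select]}
    return [replace(rec, selected=rec.gene in chosen) for rec in records]


def records_to_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    """Tabular view (gene, dataset_id, r, n_eff, p_value, rank, selected)."""
    return pd.DataFrame(
        [
            {
                "gene": rec.gene,
                "dataset_id": rec.dataset_id,
                "r": rec.r,
                "n_eff": rec.n_eff,
                "p_value": rec.p_value,
                "rank": rec.rank,
                "selected": rec.selected,
            }
            for rec in records
        ]
    )
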