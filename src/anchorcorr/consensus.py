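"""Cross-dataset consensus calls of anchor-correlated genes.

Within one cancer type (tissue), a gene is called highly correlated with
the anchor when it was selected in at least ``min_presence`` datasets
(2 by default) and reached |Pearson r| >= ``pcc_cutoff`` (0.6) in at
least one of them.  Each call carries a binomial presence p-value:
the chance that a background gene, independently selected with
probability f per dataset (the per-dataset selection fraction), appears
in >= k of d datasets, P(X >= k) with X ~ Binomial(d, f).

With the per-tissue fractions in common use the binomial p-value can
exceed 0.05 even at k=2 (e.g. k=2, d=3, f=0.20 gives 0.104), so the
presence rule governs calling by default and the p-value is reported;
``strict_binomial=True`` additionally requires p < alpha.

Sign classes: a called gene is positive if every qualifying record
(|r| >= cutoff) is positive, negative if all are negative, and "both"
when qualifying correlations of both signs occur — which can happen
across tissues, so the global tally classifies over all tissues'
qualifying records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

from .correlation import CorrelationRecord
from ._util import pct_half_up

log = logging.getLogger(__name__)


@dataclass
class ConsensusGene:
    gene: str
    tissue: str
    n_present: int
    n_datasets: int
    binomial_p: float
    max_r: float
    min_r: float
    sign_class: str
    binomial_ok: bool


def binomial_presence_pvalue(k: int, d: int, f: float) -> float:
    """P(X >= k) for X ~ Binomial(d, f): the null chance a background
    gene is selected in at least k of d independent datasets when each
    dataset selects a fraction f of genes."""
    if not 0 <= k <= d:
        raise ValueError(f"need 0 <= k <= d, got k={k}, d={d}")
    if not 0 < f < 1:
        raise ValueError(f"need 0 < f < 1, got {f}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, d, f))


def classify_sign(r_values, pcc_cutoff: float = 0.6) -> str:
    """Sign class over a called gene's qualifying correlations."""
    qual = [r for r in r_values if abs(r) >= pcc_cutoff]
    if not qual:
        raise ValueError("no qualifying correlations at the given cutoff")
    if all(r > 0 for r in qual):
        return "positive"
    if all(r < 0 for r in qual):
        return "negative"
    return "both"


def call_consensus(
    selected_records: dict[str, list[CorrelationRecord]],
    tissue: str,
    f: float,
    pcc_cutoff: float = 0.6,
    alpha: float = 0.05,
    min_presence: int = 2,
    strict_binomial: bool = False,
) -> list[ConsensusGene]:
    """Call consensus genes for one tissue.

    ``selected_records`` maps dataset id -> that dataset's correlation
    records with selection flags; ``f`` is the per-dataset selection
    probability of a background gene under the null (the tissue's top
    fraction when selection uses per-tissue quotas, or the p cutoff when
    selection is by p-value alone).
    """
    d = len(selected_records)
    if d < 2:
        raise ValueError(f"need >= 2 datasets in tissue {tissue!r}, got {d}")
    by_gene: dict[str, list[CorrelationRecord]] = {}
    for records in selected_records.values():
        for rec in records:
            if rec.selected:
                by_gene.setdefault(rec.gene, []).append(rec)
    calls: list[ConsensusGene] = []
    for gene in sorted(by_gene):
        recs = by_gene[gene]
        k = len(recs)
        if k < min_presence:
            continue
        p = binomial_presence_pvalue(k, d, f)
        binomial_ok = p < alpha
        if strict_binomial and not binomial_ok:
            continue
        rs = [rec.r for rec in recs]
        if max(abs(r) for r in rs) < pcc_cutoff:
            continue
        calls.append(
            ConsensusGene(
                gene=gene,
                tissue=tissue,
                n_present=k,
                n_datasets=d,
                binomial_p=p,
                max_r=max(rs),
                min_r=min(rs),
                sign_class=classify_sign(rs, pcc_cutoff),
                binomial_ok=binomial_ok,
            )
        )
    log.info("%s: %d consensus genes from %d datasets", tissue, len(calls), d)
    return calls


def global_sign_tally(
    consensus_by_tissue: dict[str, list[ConsensusGene]], pcc_cutoff: float = 0.6
) -> dict[str, int]:
    """Classify every called gene over all tissues' qualifying records.

    A gene positive in one tissue and negative in another counts as
    "both"; positive + negative + both partitions the called union.
    """
    r_by_gene: dict[str, list[float]] = {}
    for calls in consensus_by_tissue.values():
        for c in calls:
            # max_r/min_r bound the qualifying records of this tissue
            r_by_gene.setdefault(c.gene, []).extend([c.max_r, c.min_r])
    tally = {"positive": 0, "negative": 0, "both": 0, "total": 0}
    for gene, rs in r_by_gene.items():
        qual = [r for r in rs if abs(r) >= pcc_cutoff]
        cls = classify_sign(qual, pcc_cutoff) if qual else None
        if cls is None:
            # qualifying record exists in some tissue by construction
            raise AssertionError(f"called gene {gene} has no qualifying r")
        tally[cls] += 1
        tally["total"] += 1
    return tally


def sharing_histogram(
    consensus_by_tissue: dict[str, list[ConsensusGene]]
) -> dict[int, tuple[int, float]]:
    """How many genes are called in 1, 2, ... tissues.

    Returns {n_tissues: (count, percentage of the called union)}; the
    percentage is rounded half-up to the nearest integer.  Bins run from
    1 to the number of tissues even when empty.
    """
    n_tissues = len(consensus_by_tissue)
    membership: dict[str, set[str]] = {}
    for tissue, calls in consensus_by_tissue.items():
        for c in calls:
            membership.setdefault(c.gene, set()).add(tissue)
    total = len(membership)
    hist: dict[int, tuple[int, float]] = {}
    for m in range(1, max(n_tissues, 1) + 1):
        count = sum(1 for ts in membership.values() if len(ts) == m)
        pct = pct_half_up(count, total) if total else 0.0
        hist[m] = (count, pct)
    return hist
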