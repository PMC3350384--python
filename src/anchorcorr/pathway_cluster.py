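"""Keyword-rule clustering of annotated pathways.

Pathways carrying bio-function terms are assigned to one of five fine
clusters — cancer, cell_cycle, growth, death, other — by case-insensitive
keyword matching with a fixed precedence (cancer > cell_cycle > growth >
death; anything unmatched is "other").  cell_cycle, growth and death are
reported jointly as the "cancer related" cluster.  The keyword families
live in an editable YAML rules file; the packaged default covers the
common bio-function vocabulary of tumor-biology annotation systems.

Composition reports filter to significant pathways (enrichment p < 0.01
by default) and print integer percentages rounded half-up.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .io_formats import PathwayRecord
from ._util import pct_half_up

log = logging.getLogger(__name__)

CANCER_RELATED = ("cell_cycle", "growth", "death")


@dataclass(frozen=True)
class ClusterRules:
    """Compiled keyword families with matching precedence."""

    patterns: dict[str, list[re.Pattern]]
    precedence: tuple[str, ...]

    def match(self, text: str) -> str:
        for cluster in self.precedence:
            if any(p.search(text) for p in self.patterns[cluster]):
                return cluster
        return "other"


def load_rules(path: str | Path | None = None) -> ClusterRules:
    """Load (and compile) a keyword rules file; packaged default if None."""
    if path is None:
        raw = resources.files("anchorcorr").joinpath("data/pathway_rules.yaml").read_text()
    else:
        raw = Path(path).read_text()
    spec = yaml.safe_load(raw)
    boundary = {k.lower() for k in spec.get("word_boundary", [])}
    patterns: dict[str, list[re.Pattern]] = {}
    for cluster, keywords in spec["clusters"].items():
        pats = []
        for kw in keywords:
            kw = kw.lower()
            esc = re.escape(kw)
            pats.append(re.compile(rf"\b{esc}\b" if kw in boundary else esc))
        patterns[cluster] = pats
    precedence = tuple(spec.get("precedence", list(spec["clusters"])))
    unknown = set(precedence) - set(patterns)
    if unknown:
        raise ValueError(f"precedence names unknown clusters: {unknown}")
    return ClusterRules(patterns=patterns, precedence=precedence)


def classify_pathway(record: PathwayRecord, rules: ClusterRules | None = None) -> str:
    """Assign one fine cluster to a pathway from its bio-function terms."""
    if not record.bio_function_terms:
        raise ValueError(f"pathway {record.name!r} has no bio-function terms")
    if rules is None:
        rules = load_rules()
    text = "; ".join(t.lower() for t in record.bio_function_terms)
    cluster = rules.match(text)
    log.debug("pathway %r -> %s", record.name, cluster)
    return cluster


@dataclass
class ClusterReport:
    counts: dict[str, int]                 # fine clusters + "cancer_related" rollup
    percentages: dict[str, float]          # integer % over cancer/cancer_related/other
    gene_membership: dict[str, set[str]]   # coarse cluster -> member gene union
    n_significant: int
    significant_only: bool
    p_threshold: float


def cluster_composition(
    records: list[PathwayRecord],
    p_threshold: float = 0.01,
    rules: ClusterRules | None = None,
    significant_only: bool = True,
) -> ClusterReport:
    """Cluster counts and percentages over significant pathways.

    Pathways with enrichment p < ``p_threshold`` are classified; counts
    are reported per fine cluster and jointly for the cancer-related
    rollup; percentages (half-up integers) cover the three coarse
    clusters cancer / cancer_related / other.
    """
    if rules is None:
        rules = load_rules()
    kept = [r for r in records if (not significant_only) or r.p_value < p_threshold]
    counts = {c: 0 for c in ("cancer", *CANCER_RELATED, "other")}
    membership: dict[str, set[str]] = {"cancer": set(), "cancer_related": set(), "other": set()}
    for rec in kept:
        cluster = classify_pathway(rec, rules)
        rec.cluster = cluster
        counts[cluster] += 1
        coarse = "cancer_related" if cluster in CANCER_RELATED else cluster
        membership[coarse].update(rec.genes)
    counts["cancer_related"] = sum(counts[c] for c in CANCER_RELATED)
    total = len(kept)
    percentages = (
        {
            c: pct_half_up(counts[c], total)
            for c in ("cancer", "cancer_related", "other")
        }
        if total
        else {c: 0.0 for c in ("cancer", "cancer_related", "other")}
    )
    return ClusterReport(
        counts=counts,
        percentages=percentages,
        gene_membership=membership,
        n_significant=total,
        significant_only=significant_only,
        p_threshold=p_threshold,
    )


@dataclass
class GeneOverlap:
    sets: dict[str, set[str]]
    pairwise: dict[tuple[str, str], set[str]]
    triple: set[str]


def gene_overlap(
    records: list[PathwayRecord],
    consensus_genes: set[str] | None = None,
    rules: ClusterRules | None = None,
    p_threshold: float = 0.01,
) -> GeneOverlap:
    """Member-gene sets per coarse cluster with pairwise/triple overlaps.

    Gene symbols are uppercased on record construction; when a consensus
    gene set is given, cluster memberships are intersected with it.
    """
    report = cluster_composition(records, p_threshold=p_threshold, rules=rules)
    sets = {
        name: (genes & {g.upper() for g in consensus_genes} if consensus_genes else genes)
        for name, genes in report.gene_membership.items()
    }
    names = ("cancer", "cancer_related", "other")
    pairwise = {
        (a, b): sets[a] & sets[b]
        for i, a in enumerate(names)
        for b in names[i + 1:]
    }
    triple = sets["cancer"] & sets["cancer_related"] & sets["other"]
    return GeneOverlap(sets=sets, pairwise=pairwise, triple=triple)
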