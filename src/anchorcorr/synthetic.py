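"""Synthetic multi-dataset expression collections with known ground truth.

The generator emulates the statistical structure of a cross-dataset
anchor-gene survey: several datasets per tissue type, each a genes x
samples matrix whose samples split into cancer / non-cancer disease /
normal classes.  One anchor gene carries a planted cancer-vs-normal
fold change; a configurable set of planted genes carries a specified
population Pearson correlation with the anchor; all remaining background
genes are independent noise.  A :class:`TruthTable` records what was
planted so recovery can be scored exactly.

Values are simulated on log2 scale.  By default the matrices are emitted
as linear-scale mono-channel intensities (``2**log2``) so the generated
files exercise the same log2 preprocessing step real mono-channel data
needs; ``output_scale="log2"`` emits analysis-ready values directly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import DatasetMetadata, ExpressionDataset, ProbeGeneMap, SAMPLE_CLASSES

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "planted_effect_size",
    "simulate_dataset",
    "simulate_collection",
    "probe_map_for",
    "example_screening_metadata",
]

#: datasets per tissue matching a 13-dataset four-tissue collection
DEFAULT_DATASETS_PER_TISSUE = {"colon": 3, "liver": 4, "lung": 3, "thyroid": 3}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic collection.

    ``anchor_fold_change`` is a linear-scale fold (cancer over normal);
    the planted log2 shift is ``log2(anchor_fold_change)``.  Published
    anchor fold changes in the motivating surveys fall in the 1.25-2.43
    range; the default 1.75 sits mid-range.  ``noise_sd`` is the per-gene
    log2-scale residual SD (1.0 by default, a typical magnitude for
    normalized microarray log-intensities); ``batch_sd`` adds an optional
    per-sample offset shared by all genes (0 by default).
    """

    n_datasets_per_tissue: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_DATASETS_PER_TISSUE)
    )
    n_genes: int = 1000
    n_samples: Mapping[str, int] = field(
        default_factory=lambda: {"cancer": 50, "disease": 0, "normal": 50}
    )
    anchor_symbol: str = "PSME3"
    anchor_fold_change: float = 1.75
    anchor_disease_fold: float = 1.0
    planted_genes: tuple[tuple[str, float], ...] = ()
    noise_sd: float = 1.0
    batch_sd: float = 0.0
    baseline_log2: float = 8.0
    center_by_class: bool = False
    paired: bool = False
    duplicate_probes: bool = False
    output_scale: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be >= 0")
        if self.anchor_fold_change <= 0:
            raise ValueError("anchor_fold_change must be a positive linear fold")
        if self.output_scale not in ("linear", "log2"):
            raise ValueError("output_scale must be 'linear' or 'log2'")
        for sym, r in self.planted_genes:
            if not abs(r) < 1:
                raise ValueError(f"planted gene {sym!r}: |target_r| must be < 1, got {r}")
        for cls, n in self.n_samples.items():
            if cls not in SAMPLE_CLASSES:
                raise ValueError(f"unknown sample class {cls!r}")
            if n != 0 and n < 3:
                raise ValueError(f"class {cls!r}: need >= 3 samples (or 0 to omit)")
        if self.paired and self.n_samples.get("cancer", 0) != self.n_samples.get("normal", 0):
            raise ValueError("paired design needs equal cancer and normal counts")


@dataclass
class TruthTable:
    """Ground truth of a simulated collection.

    ``anchor`` has one row per dataset (dataset_id, tissue, planted
    anchor log2 fold change); ``planted`` one row per (dataset, planted
    gene) with the target and achieved pooled Pearson r on the log2
    scale; ``background_genes`` lists the independent genes.
    """

    anchor_symbol: str
    anchor: pd.DataFrame
    planted: pd.DataFrame
    background_genes: list[str]


def planted_effect_size(target_r: float, anchor_sd: float, noise_sd: float) -> float:
    """Regression coefficient that plants a population Pearson r.

    For ``gene = beta * anchor + eps`` with ``eps ~ N(0, noise_sd^2)``
    and ``SD(anchor) = anchor_sd``, the population correlation is
    ``beta*anchor_sd / sqrt(beta^2*anchor_sd^2 + noise_sd^2)``; solving
    for beta gives ``target_r * noise_sd / (anchor_sd * sqrt(1 - r^2))``.
    """
    if not abs(target_r) < 1:
        raise ValueError(f"|target_r| must be < 1, got {target_r}")
    if anchor_sd <= 0 or noise_sd <= 0:
        raise ValueError("anchor_sd and noise_sd must be > 0")
    return target_r * noise_sd / (anchor_sd * np.sqrt(1.0 - target_r**2))


def _dataset_seed(master_seed: int, dataset_id: str) -> np.random.SeedSequence:
    """Stable per-dataset seed: CRC32 of the dataset id mixed with the
    master seed through a SeedSequence (platform-independent)."""
    key = zlib.crc32(dataset_id.encode("utf8"))
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key])


def _sample_frame(config: SimulationConfig, dataset_id: str):
    classes: list[str] = []
    for cls in ("cancer", "disease", "normal"):
        classes += [cls] * int(config.n_samples.get(cls, 0))
    if len(set(classes)) < 2:
        raise ValueError("need at least two sample classes with nonzero counts")
    sample_ids = [f"{dataset_id}.s{i + 1:03d}" for i in range(len(classes))]
    return sample_ids, np.array(classes)


def simulate_dataset(
    config: SimulationConfig,
    tissue: str = "other",
    dataset_id: str | None = None,
    seed: int | None = None,
) -> tuple[ExpressionDataset, TruthTable]:
    """Simulate one dataset; deterministic for a fixed (config, seed).

    The anchor gene gets a class-dependent mean shift of
    ``log2(anchor_fold_change)`` in cancer (and ``log2(anchor_disease_fold)``
    in disease) samples.  Planted genes are regressed on the anchor's
    deviations — pooled deviations by default, matching a correlation
    computed across all samples of a dataset; within-class deviations if
    ``center_by_class`` — with the coefficient from
    :func:`planted_effect_size`, so the population Pearson r equals the
    target exactly.  Background genes are independent normal noise.
    """
    if dataset_id is None:
        dataset_id = f"{tissue}01"
    sseq = _dataset_seed(config.seed if seed is None else seed, dataset_id)
    rng = np.random.default_rng(sseq)

    sample_ids, classes = _sample_frame(config, dataset_id)
    n = len(sample_ids)

    background = [f"G{i + 1:06d}" for i in range(config.n_genes)]
    planted_syms = [sym for sym, _ in config.planted_genes]
    collide = (set(planted_syms) | {config.anchor_symbol}) & set(background)
    if collide:
        raise ValueError(f"planted/anchor symbols collide with background ids: {collide}")
    if config.anchor_symbol in planted_syms:
        raise ValueError("anchor symbol cannot also be a planted gene")
    if len(set(planted_syms)) != len(planted_syms):
        raise ValueError("duplicate planted gene symbols")

    delta_c = np.log2(config.anchor_fold_change)
    delta_d = np.log2(config.anchor_disease_fold)
    class_mu = {
        "cancer": config.baseline_log2 + delta_c,
        "disease": config.baseline_log2 + delta_d,
        "normal": config.baseline_log2,
    }
    mu = np.array([class_mu[c] for c in classes])

    anchor = mu + rng.normal(0.0, config.noise_sd, n)
    if config.center_by_class:
        anchor_dev = anchor - mu
        anchor_sd = config.noise_sd
    else:
        pop_mean = mu.mean()
        between_var = float(np.mean((mu - pop_mean) ** 2))
        anchor_dev = anchor - pop_mean
        anchor_sd = float(np.sqrt(config.noise_sd**2 + between_var))

    rows = [anchor]
    gene_ids = [config.anchor_symbol]
    truth_rows = []
    for sym, target_r in config.planted_genes:
        beta = planted_effect_size(target_r, anchor_sd, config.noise_sd)
        gene = config.baseline_log2 + beta * anchor_dev + rng.normal(0.0, config.noise_sd, n)
        rows.append(gene)
        gene_ids.append(sym)
        achieved = float(np.corrcoef(gene, anchor)[0, 1])
        truth_rows.append(
            {"dataset_id": dataset_id, "gene": sym, "target_r": target_r, "achieved_r": achieved}
        )
    bg = config.baseline_log2 + rng.normal(0.0, config.noise_sd, (config.n_genes, n))
    matrix = np.vstack([np.array(rows), bg])
    gene_ids = gene_ids + background

    paired_with = None
    if config.paired:
        cancer_ids = [s for s, c in zip(sample_ids, classes) if c == "cancer"]
        normal_ids = [s for s, c in zip(sample_ids, classes) if c == "normal"]
        paired_with = {}
        for a, b in zip(cancer_ids, normal_ids):
            paired_with[a] = b
            paired_with[b] = a

    if config.batch_sd > 0:
        batch = rng.normal(0.0, config.batch_sd, n)
        if paired_with:
            # paired samples share their batch offset (same array run)
            idx = {s: i for i, s in enumerate(sample_ids)}
            for a, b in paired_with.items():
                if classes[idx[a]] == "cancer":
                    batch[idx[b]] = batch[idx[a]]
        matrix = matrix + batch[np.newaxis, :]

    if config.duplicate_probes:
        # probe-level mode for collapse tests: two probes per gene, the
        # second dimmer copy with independent measurement noise
        probe_ids = []
        probe_rows = []
        for gid, row in zip(gene_ids, matrix):
            probe_ids += [f"{gid}_p1", f"{gid}_p2"]
            probe_rows.append(row)
            probe_rows.append(row - 0.5 + rng.normal(0.0, 0.1 * config.noise_sd, n))
        gene_ids = probe_ids
        matrix = np.array(probe_rows)

    is_log2 = config.output_scale == "log2"
    values = pd.DataFrame(
        matrix if is_log2 else np.exp2(matrix), index=gene_ids, columns=sample_ids
    )
    meta = DatasetMetadata(dataset_id=dataset_id, tissue=tissue, channel="mono", n_samples=n)
    dataset = ExpressionDataset(
        metadata=meta,
        values=values,
        sample_class=dict(zip(sample_ids, classes)),
        paired_with=paired_with,
        is_log2=is_log2,
    )
    truth = TruthTable(
        anchor_symbol=config.anchor_symbol,
        anchor=pd.DataFrame(
            [{"dataset_id": dataset_id, "tissue": tissue, "anchor_log2fc": delta_c}]
        ),
        planted=pd.DataFrame(
            truth_rows, columns=["dataset_id", "gene", "target_r", "achieved_r"]
        ),
        background_genes=background,
    )
    return dataset, truth


def simulate_collection(config: SimulationConfig) -> tuple[list[ExpressionDataset], TruthTable]:
    """Simulate one dataset per (tissue, index) with shared planted gene
    identities, independent noise, and per-dataset seeds derived from the
    master seed."""
    datasets: list[ExpressionDataset] = []
    anchors = []
    planted = []
    background: list[str] = []
    for tissue in sorted(config.n_datasets_per_tissue):
        for i in range(config.n_datasets_per_tissue[tissue]):
            dataset_id = f"{tissue}{i + 1:02d}"
            ds, truth = simulate_dataset(config, tissue=tissue, dataset_id=dataset_id)
            datasets.append(ds)
            anchors.append(truth.anchor)
            planted.append(truth.planted)
            background = truth.background_genes
    truth = TruthTable(
        anchor_symbol=config.anchor_symbol,
        anchor=pd.concat(anchors, ignore_index=True),
        planted=pd.concat(planted, ignore_index=True)
        if planted
        else pd.DataFrame(columns=["dataset_id", "gene", "target_r", "achieved_r"]),
        background_genes=background,
    )
    return datasets, truth


def probe_map_for(dataset: ExpressionDataset) -> ProbeGeneMap:
    """Probe->gene map for a dataset generated in duplicate-probe mode."""
    entries = {}
    for fid in dataset.feature_ids:
        base, _, tag = fid.rpartition("_")
        if not base or not tag.startswith("p"):
            raise ValueError(f"{fid!r} is not a simulated probe id")
        entries[fid] = base.upper()
    return ProbeGeneMap(entries=entries)


def example_screening_metadata() -> list[DatasetMetadata]:
    """A deterministic 49-entry metadata collection for screening demos.

    Mirrors the shape of a public-repository search in a four-tissue
    anchor-gene survey: 16 colon, 15 liver, 11 lung, and 7 thyroid
    collections, of which 23 satisfy all six inclusion predicates and 26
    fail exactly one rule each (6, 5, 5, 4, 3, 3 failures of rules 1-6).
    """
    per_tissue = {"colon": 16, "liver": 15, "lung": 11, "thyroid": 7}
    included_per_tissue = {"colon": 8, "liver": 7, "lung": 5, "thyroid": 3}
    rule_fields = [
        ("has_control_samples", False),
        ("has_anchor_probe", False),
        ("has_publication", False),
        ("is_time_course", True),
        ("has_hgnc_symbols", False),
        ("has_anchor_data", False),
    ]
    # 26 exclusions spread over the six rules, assigned round-robin
    exclusion_rules = [1] * 6 + [2] * 5 + [3] * 5 + [4] * 4 + [5] * 3 + [6] * 3
    metas: list[DatasetMetadata] = []
    k = 0
    for tissue in ("colon", "liver", "lung", "thyroid"):
        for i in range(per_tissue[tissue]):
            dataset_id = f"{tissue.upper()}{i + 1:03d}"
            kwargs = dict(
                dataset_id=dataset_id,
                tissue=tissue,
                channel="mono" if i % 2 == 0 else "two_channel",
                n_samples=40 + 7 * i,
            )
            if i >= included_per_tissue[tissue]:
                fld, bad_value = rule_fields[exclusion_rules[k] - 1]
                kwargs[fld] = bad_value
                k += 1
            metas.append(DatasetMetadata(**kwargs))
    assert k == len(exclusion_rules)
    return metas
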