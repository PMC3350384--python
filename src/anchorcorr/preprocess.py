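"""Dataset screening, probe collapsing, log2 scaling, and group ratios.

Screening applies six inclusion/exclusion rules to dataset metadata:

1. no control (normal) tissue,
2. no probe for the anchor gene on the platform,
3. no corresponding publication,
4. samples collected in a time course,
5. no HGNC gene-symbol annotation for the probes,
6. no anchor measurements in the data.

A dataset is excluded iff any rule fires; the recorded reason is the
lowest-numbered firing rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import DatasetMetadata, ExpressionDataset, ProbeGeneMap

log = logging.getLogger(__name__)

EXCLUSION_RULES: list[tuple[int, str]] = [
    (1, "no control tissue"),
    (2, "no anchor probe on platform"),
    (3, "no corresponding publication"),
    (4, "time-course sampling"),
    (5, "no HGNC gene symbol annotation"),
    (6, "no anchor data"),
]


@dataclass
class ScreeningReport:
    included: list[str]
    excluded: list[tuple[str, int]]

    @property
    def n_included(self) -> int:
        return len(self.included)


def _firing_rule(meta: DatasetMetadata) -> int | None:
    checks = [
        not meta.has_control_samples,
        not meta.has_anchor_probe,
        not meta.has_publication,
        meta.is_time_course,
        not meta.has_hgnc_symbols,
        not meta.has_anchor_data,
    ]
    for (code, _), fired in zip(EXCLUSION_RULES, checks):
        if fired:
            return code
    return None


def screen_datasets(metadata: list[DatasetMetadata]) -> ScreeningReport:
    """Partition datasets into included/excluded by the six rules.

    Order-independent: results are sorted by dataset id.  Duplicate
    dataset ids are rejected.
    """
    ids = [m.dataset_id for m in metadata]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate dataset_id {dup!r}")
    included: list[str] = []
    excluded: list[tuple[str, int]] = []
    for meta in sorted(metadata, key=lambda m: m.dataset_id):
        code = _firing_rule(meta)
        if code is None:
            included.append(meta.dataset_id)
        else:
            excluded.append((meta.dataset_id, code))
    log.info(
        "screening: %d included, %d excluded of %d datasets",
        len(included), len(excluded), len(metadata),
    )
    return ScreeningReport(included=included, excluded=excluded)


def collapse_probes(
    dataset: ExpressionDataset,
    probe_map: ProbeGeneMap,
    anchor_symbol: str | None = None,
) -> ExpressionDataset:
    """Collapse probe rows to one row per gene symbol.

    For genes measured by several probes the probe with the highest mean
    value across samples is kept (ties broken by lexicographically
    smallest probe id, for determinism).  Probes absent from the map are
    dropped with a logged count.  If ``anchor_symbol`` is given and the
    symbol is absent after collapsing, a hard error is raised.
    """
    symbols = pd.Series(
        [probe_map.entries.get(p) for p in dataset.feature_ids],
        index=dataset.values.index,
        dtype=object,
    )
    unmapped = int(symbols.isna().sum())
    if unmapped:
        log.info(
            "%s: dropping %d/%d probes without a gene symbol",
            dataset.metadata.dataset_id, unmapped, len(symbols),
        )
    mapped = dataset.values.loc[symbols.notna()]
    mapped_symbols = symbols.dropna()

    means = mapped.mean(axis=1, skipna=True)
    order = pd.DataFrame(
        {"symbol": mapped_symbols.values, "mean": means.values, "probe": mapped.index}
    )
    # highest mean wins; ties -> lexicographically smallest probe id
    order = order.sort_values(
        ["symbol", "mean", "probe"], ascending=[True, False, True], kind="mergesort"
    )
    keep = order.drop_duplicates("symbol", keep="first")["probe"]
    collapsed = mapped.loc[keep]
    collapsed.index = order.set_index("probe").loc[keep, "symbol"].values

    if anchor_symbol is not None and anchor_symbol.upper() not in collapsed.index:
        raise ValueError(
            f"{dataset.metadata.dataset_id}: anchor symbol {anchor_symbol!r} "
            "absent after probe collapse"
        )
    return dataset.copy(values=collapsed)


def to_log2(dataset: ExpressionDataset, floor: float = 1e-3) -> ExpressionDataset:
    """Place mono-channel intensities on log2 scale.

    Two-channel data are already log2 ratios and pass through unchanged,
    as do datasets previously transformed.  Mono-channel values <= 0
    (possible in normalized array output) are clipped to ``floor`` before
    the transform, with a logged count.
    """
    if dataset.is_log2 or dataset.metadata.channel == "two_channel":
        return dataset.copy(is_log2=True)
    values = dataset.values
    n_clipped = int((values.to_numpy() <= 0).sum())
    if n_clipped:
        log.warning(
            "%s: clipped %d non-positive values to %g before log2",
            dataset.metadata.dataset_id, n_clipped, floor,
        )
        values = values.clip(lower=floor)
    return dataset.copy(values=np.log2(values), is_log2=True)


def median_center(dataset: ExpressionDataset) -> ExpressionDataset:
    """Optional per-sample median centering for un-normalized log2 inputs."""
    if not dataset.is_log2:
        raise ValueError("median_center expects log2-scale data")
    values = dataset.values - dataset.values.median(axis=0, skipna=True)
    return dataset.copy(values=values)


def group_log2_ratio(
    dataset: ExpressionDataset, numerator_class: str, denominator_class: str
) -> pd.Series:
    """Per-gene log2 ratio of two sample classes.

    Computed as mean log2 value in the numerator class minus mean in the
    denominator class (the log2 of the ratio of geometric means).
    Requires log2-scale data.
    """
    if not dataset.is_log2:
        raise ValueError("group_log2_ratio expects log2-scale data; call to_log2 first")
    num = dataset.samples_of_class(numerator_class)
    den = dataset.samples_of_class(denominator_class)
    if not num:
        raise ValueError(f"no samples of class {numerator_class!r}")
    if not den:
        raise ValueError(f"no samples of class {denominator_class!r}")
    return dataset.values[num].mean(axis=1, skipna=True) - dataset.values[den].mean(
        axis=1, skipna=True
    )
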