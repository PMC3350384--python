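"""On-disk artifacts of the anchor-correlation pipeline.

Expression matrices are plain tab-delimited text modeled on GEO Series
Matrix layout: features (probes or gene symbols) in rows, samples in
columns, with a sidecar ``<stem>.classes.tsv`` file assigning each sample
to one of the three study classes (``cancer``, ``disease``, ``normal``)
plus optional stage labels and cancer/normal pair identifiers.  Pathway
annotation tables are tab-delimited (name, semicolon-joined bio-function
terms, comma-joined member genes, enrichment p-value); GMT is accepted as
an alternate pathway reader.

Missing expression values are encoded as an empty cell or ``NA`` and kept
as missing — downstream statistics are pairwise-complete, nothing is
imputed.  Gene symbols are uppercased at read time.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, fields, is_dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TISSUES = ("colon", "liver", "lung", "thyroid", "other")
CHANNELS = ("mono", "two_channel")
SAMPLE_CLASSES = ("cancer", "disease", "normal")
#: fine-grained pathway clusters; cell_cycle/growth/death roll up to "cancer related"
PATHWAY_CLUSTERS = ("cancer", "cell_cycle", "growth", "death", "other")

#: serialization format for floats in result tables (6 significant digits)
FLOAT_FORMAT = "%.6g"


@dataclass(frozen=True)
class DatasetMetadata:
    """Screening-relevant facts about one expression dataset.

    The boolean fields mirror the six exclusion rules applied when
    collecting public microarray datasets for an anchor-gene survey:
    a usable dataset must have control tissue, a probe for the anchor
    gene, a supporting publication, no time-course sampling design,
    HGNC gene-symbol annotation, and actual measurements for the anchor.
    """

    dataset_id: str
    tissue: str = "other"
    channel: str = "mono"
    has_anchor_probe: bool = True
    has_control_samples: bool = True
    has_publication: bool = True
    is_time_course: bool = False
    has_hgnc_symbols: bool = True
    has_anchor_data: bool = True
    n_samples: int = 1

    def __post_init__(self) -> None:
        if not self.dataset_id:
            raise ValueError("dataset_id must be non-empty")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class ExpressionDataset:
    """One dataset's feature x sample matrix plus sample annotations.

    ``values`` is a pandas DataFrame indexed by feature id with one column
    per sample.  ``is_log2`` records whether values are already on log2
    scale (two-channel log-ratio files and preprocessed mono-channel data)
    so the log transform is applied exactly once.
    """

    metadata: DatasetMetadata
    values: pd.DataFrame
    sample_class: dict[str, str]
    stage: dict[str, str] | None = None
    paired_with: dict[str, str] | None = None
    is_log2: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        missing = [s for s in self.values.columns if s not in self.sample_class]
        if missing:
            raise ValueError(f"sample {missing[0]!r} has no class assignment")
        bad = {s: c for s, c in self.sample_class.items() if c not in SAMPLE_CLASSES}
        if bad:
            raise ValueError(f"unknown sample class(es): {bad}")
        if self.paired_with:
            for a, b in self.paired_with.items():
                if self.paired_with.get(b) != a:
                    raise ValueError(f"pairing not symmetric for {a!r}/{b!r}")
                ca, cb = self.sample_class.get(a), self.sample_class.get(b)
                if {ca, cb} != {"cancer", "normal"}:
                    raise ValueError(
                        f"pair ({a!r},{b!r}) must match one cancer with one normal sample"
                    )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of_class(self, cls: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_class[s] == cls]

    def copy(self, **changes) -> "ExpressionDataset":
        base = dict(
            metadata=self.metadata,
            values=self.values.copy(),
            sample_class=dict(self.sample_class),
            stage=dict(self.stage) if self.stage else None,
            paired_with=dict(self.paired_with) if self.paired_with else None,
            is_log2=self.is_log2,
        )
        base.update(changes)
        return ExpressionDataset(**base)


@dataclass(frozen=True)
class ProbeGeneMap:
    """Mapping probe id -> HGNC gene symbol (uppercase, no empty symbols)."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {p: s for p, s in self.entries.items() if not s or s != s.upper()}
        if bad:
            raise ValueError(f"symbols must be uppercase and non-empty: {bad}")


@dataclass
class PathwayRecord:
    """One annotated pathway: bio-function terms, member genes, p-value."""

    name: str
    bio_function_terms: list[str]
    genes: list[str]
    p_value: float
    cluster: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"pathway {self.name!r}: p-value {self.p_value} outside [0,1]")
        if not self.genes:
            raise ValueError(f"pathway {self.name!r}: empty gene list")
        self.genes = [g.upper() for g in self.genes]


# ---------------------------------------------------------------------------
# expression matrices


def _classes_path(path: Path) -> Path:
    return path.with_name(path.stem + ".classes.tsv")


def read_expression_matrix(path: str | Path, dialect: str = "mono") -> ExpressionDataset:
    """Read a tab-delimited expression matrix plus its class sidecar.

    First column holds feature ids, header row holds sample ids.  A
    sidecar file ``<stem>.classes.tsv`` (columns: sample_id, class,
    optional stage, optional pair_id) must exist next to the matrix.
    Empty cells and ``NA`` are read as missing values.
    """
    if dialect not in CHANNELS:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    feature_ids: list[str] = []
    data = np.empty((len(rows) - 1, len(sample_ids)), dtype=float)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ValueError(
                f"{path}: row {i} ({row[0] if row else '<empty>'!r}) has "
                f"{len(row) - 1} values, expected {len(sample_ids)}"
            )
        feature_ids.append(row[0])
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell in ("", "NA", "NaN", "nan"):
                data[i - 2, j] = np.nan
                continue
            try:
                data[i - 2, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at row {i}, "
                    f"column {sample_ids[j]!r}"
                ) from None
    values = pd.DataFrame(data, index=feature_ids, columns=sample_ids)

    sample_class, stage, paired_with = _read_class_sidecar(_classes_path(path), sample_ids)
    meta = DatasetMetadata(dataset_id=path.stem, channel=dialect, n_samples=len(sample_ids))
    ds = ExpressionDataset(
        metadata=meta,
        values=values,
        sample_class=sample_class,
        stage=stage or None,
        paired_with=paired_with or None,
        is_log2=(dialect == "two_channel"),
    )
    log.info(
        "read %s: %d features x %d samples (%s)",
        path.name, len(feature_ids), len(sample_ids), dialect,
    )
    return ds


def _read_class_sidecar(path: Path, sample_ids: Sequence[str]):
    if not path.exists():
        raise FileNotFoundError(f"class sidecar {path} not found")
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ValueError(f"{path}: empty sidecar")
    header = [h.lower() for h in rows[0]]
    if header[:2] != ["sample_id", "class"]:
        raise ValueError(f"{path}: sidecar must start with columns sample_id, class")
    col = {name: k for k, name in enumerate(header)}
    sample_class: dict[str, str] = {}
    stage: dict[str, str] = {}
    pair_groups: dict[str, list[str]] = {}
    for row in rows[1:]:
        if not row or not row[0]:
            continue
        sid = row[0]
        if sid in sample_class:
            raise ValueError(f"{path}: duplicate sample id {sid!r}")
        sample_class[sid] = row[col["class"]]
        if "stage" in col and len(row) > col["stage"] and row[col["stage"]]:
            stage[sid] = row[col["stage"]]
        if "pair_id" in col and len(row) > col["pair_id"] and row[col["pair_id"]]:
            pair_groups.setdefault(row[col["pair_id"]], []).append(sid)
    missing = [s for s in sample_ids if s not in sample_class]
    if missing:
        raise ValueError(f"{path}: missing class for sample {missing[0]!r}")
    paired_with: dict[str, str] = {}
    for pid, members in pair_groups.items():
        if len(members) != 2:
            raise ValueError(f"{path}: pair {pid!r} has {len(members)} members, expected 2")
        a, b = members
        paired_with[a] = b
        paired_with[b] = a
    return sample_class, stage, paired_with


def write_expression_dataset(ds: ExpressionDataset, path: str | Path) -> None:
    """Write the matrix and its class sidecar (inverse of the reader)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["feature_id", *ds.sample_ids])
        for fid, row in zip(ds.feature_ids, ds.values.to_numpy()):
            w.writerow([fid] + ["NA" if not math.isfinite(v) else FLOAT_FORMAT % v for v in row])
    # invert the symmetric pair map back into stable group labels
    pair_id: dict[str, str] = {}
    if ds.paired_with:
        n = 0
        for s in ds.sample_ids:
            partner = ds.paired_with.get(s)
            if partner and s not in pair_id:
                n += 1
                pair_id[s] = pair_id[partner] = f"p{n:03d}"
    with open(_classes_path(path), "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "class", "stage", "pair_id"])
        for s in ds.sample_ids:
            w.writerow([
                s,
                ds.sample_class[s],
                (ds.stage or {}).get(s, ""),
                pair_id.get(s, ""),
            ])


# ---------------------------------------------------------------------------
# probe maps and pathway tables


def read_probe_gene_map(path: str | Path) -> ProbeGeneMap:
    """Read a two-column probe->symbol table; probes with an empty symbol
    are dropped (with a logged count) and symbols are uppercased."""
    entries: dict[str, str] = {}
    dropped = 0
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].lower() in ("probe_id", "probe"):
                continue
            probe = row[0]
            symbol = row[1].strip().upper() if len(row) > 1 else ""
            if not symbol:
                dropped += 1
                continue
            entries[probe] = symbol
    if dropped:
        log.info("probe map %s: dropped %d probes without a gene symbol", path, dropped)
    return ProbeGeneMap(entries=entries)


def read_pathway_table(path: str | Path) -> list[PathwayRecord]:
    """Read a tab-delimited pathway annotation table.

    Columns: name, semicolon-joined bio-function terms, comma-joined
    member genes, enrichment p-value.  Records are returned in file order.
    """
    records: list[PathwayRecord] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (i == 1 and row[0].lower() in ("name", "pathway")):
                continue
            if len(row) < 4:
                raise ValueError(f"{path}: row {i} has {len(row)} columns, expected 4")
            name, terms, genes, p = row[0], row[1], row[2], row[3]
            try:
                p_value = float(p)
            except ValueError:
                raise ValueError(f"{path}: row {i}: non-numeric p-value {p!r}") from None
            records.append(
                PathwayRecord(
                    name=name,
                    bio_function_terms=[t.strip() for t in terms.split(";") if t.strip()],
                    genes=[g.strip() for g in genes.split(",") if g.strip()],
                    p_value=p_value,
                )
            )
    return records


def read_gmt(path: str | Path) -> list[PathwayRecord]:
    """Alternate pathway reader for GMT files (name, description, genes...).

    GMT carries no enrichment p-value; records get p_value 0.0 so they
    survive any significance filter, and the description becomes the
    single bio-function term.
    """
    records: list[PathwayRecord] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if len(row) < 3:
                continue
            records.append(
                PathwayRecord(
                    name=row[0],
                    bio_function_terms=[row[1]] if row[1] else [row[0]],
                    genes=[g for g in row[2:] if g],
                    p_value=0.0,
                )
            )
    return records


# ---------------------------------------------------------------------------
# generic result tables


def _to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    records = list(records)
    if records and is_dataclass(records[0]):
        cols = [f.name for f in fields(records[0])]
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
    return pd.DataFrame(records)


def write_results(records, path: str | Path) -> None:
    """Write any result table (DataFrame or dataclass sequence) as TSV.

    Floats are serialized with 6 significant digits; column order is the
    table's own order and stable across runs.  An empty table yields a
    header-only file.
    """
    frame = _to_frame(records)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT,
        na_rep="NA", lineterminator="\n",
    )
    log.info("wrote %d records to %s", len(frame), path)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a table produced by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
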