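"""Loading, probe collapsing and detection filtering of expression matrices.

Expression data enter the pipeline as a genes x samples matrix of log2
expression values (RMA-like scale), either as a delimited text table with a
sidecar label file, or as a GEO Series Matrix text file.  The positive class
is always "cancer"; every downstream confusion-table metric counts cancer
samples as positives.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "cancer"
NEGATIVE_LABEL = "normal"

#: accepted spellings for each class in label files / GEO characteristics
_POSITIVE_ALIASES = {"cancer", "tumor", "tumour", "carcinoma", "bc", "positive", "1"}
_NEGATIVE_ALIASES = {"normal", "healthy", "control", "negative", "0"}


class ExpressionDataError(ValueError):
    """Raised for malformed or inconsistent expression inputs."""


def encode_labels(raw: Iterable[str]) -> np.ndarray:
    """Map free-text class labels onto {1 = cancer/positive, 0 = normal}."""
    out = []
    for value in raw:
        token = str(value).strip().lower()
        if token in _POSITIVE_ALIASES:
            out.append(1)
        elif token in _NEGATIVE_ALIASES:
            out.append(0)
        else:
            raise ExpressionDataError(f"unrecognized class label {value!r}")
    return np.asarray(out, dtype=np.int8)


@dataclass
class ExpressionMatrix:
    """log2 expression values with gene/sample identity and class labels.

    ``values`` is genes x samples.  ``labels`` holds 1 for cancer (positive)
    and 0 for normal; ``batch`` is an optional per-sample batch identifier.
    The number of genes is the feature universe AF used by the fitness
    penalty downstream.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray | None = None
    batch: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ExpressionDataError("values must be a 2-D genes x samples array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ExpressionDataError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes / {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ExpressionDataError("non-finite expression values")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ExpressionDataError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ExpressionDataError("duplicate sample ids")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (len(self.sample_ids),):
                raise ExpressionDataError("labels length mismatch")
            if not np.isin(self.labels, (0, 1)).all():
                raise ExpressionDataError("labels must be binary {0,1}")
        if self.batch is not None:
            self.batch = np.asarray(self.batch)
            if self.batch.shape != (len(self.sample_ids),):
                raise ExpressionDataError("batch length mismatch")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_genes(self) -> int:
        """Total feature count AF."""
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_labels(self) -> np.ndarray:
        if self.labels is None:
            raise ExpressionDataError("operation requires class labels")
        if len(np.unique(self.labels)) < 2:
            raise ExpressionDataError("labels must cover both classes")
        return self.labels

    # -- subsetting --------------------------------------------------------
    def select_genes(self, index: Sequence[int] | np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return ExpressionMatrix(
            values=self.values[index, :],
            gene_ids=[self.gene_ids[i] for i in index],
            sample_ids=list(self.sample_ids),
            labels=None if self.labels is None else self.labels.copy(),
            batch=None if self.batch is None else self.batch.copy(),
        )

    def select_samples(self, index: Sequence[int] | np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return ExpressionMatrix(
            values=self.values[:, index],
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in index],
            labels=None if self.labels is None else self.labels[index],
            batch=None if self.batch is None else self.batch[index],
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            labels=None if self.labels is None else self.labels.copy(),
            batch=None if self.batch is None else self.batch.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def samples_by_class(self) -> tuple[np.ndarray, np.ndarray]:
        """(positive indices, negative indices)."""
        y = self.require_labels()
        return np.flatnonzero(y == 1), np.flatnonzero(y == 0)


@dataclass
class ProbeMap:
    """Many-to-one probe -> gene-symbol mapping; unmapped probes are absent."""

    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mapping = dict(self.mapping)

    def symbol_for(self, probe: str) -> str | None:
        sym = self.mapping.get(probe)
        if sym is None or str(sym).strip() in ("", "nan", "NA", "---"):
            return None
        return str(sym)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_labels_table(path: str | Path) -> pd.DataFrame:
    """Sidecar label file: ``sample_id<TAB>label[<TAB>batch]`` with header."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if "sample_id" not in df.columns or "label" not in df.columns:
        raise ExpressionDataError(
            f"{path}: label file needs 'sample_id' and 'label' columns"
        )
    if df["sample_id"].duplicated().any():
        raise ExpressionDataError(f"{path}: duplicate sample ids in label file")
    return df.set_index("sample_id")


def read_expression_table(
    path: str | Path,
    format: str = "delimited",
    labels_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples expression table.

    ``format='delimited'``: first column probe/gene id, header row of sample
    ids, one numeric row per feature.  ``format='geo_series_matrix'``: GEO
    Series Matrix text; class labels are parsed from the
    ``!Sample_characteristics_ch1`` rows when recognizable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        m = _read_delimited(path)
    elif format == "geo_series_matrix":
        m = _read_series_matrix(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    if labels_path is not None:
        lab = read_labels_table(labels_path)
        missing = [s for s in m.sample_ids if s not in lab.index]
        if missing:
            raise ExpressionDataError(f"samples without labels: {missing[:5]}")
        m.labels = encode_labels(lab.loc[m.sample_ids, "label"])
        if "batch" in lab.columns:
            m.batch = lab.loc[m.sample_ids, "batch"].to_numpy()
    return m


def _read_delimited(path: Path) -> ExpressionMatrix:
    sep = _sniff_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ExpressionDataError(f"{path}: duplicated sample columns {dupes}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.index.duplicated().any():
        raise ExpressionDataError(f"{path}: duplicated feature rows")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            row = df.index[int(np.flatnonzero(converted.isna())[0])]
            raise ExpressionDataError(
                f"{path}: non-numeric value at row {row!r}, column {col!r}"
            )
        values[:, j] = converted.to_numpy()
    return ExpressionMatrix(values, list(df.index), list(df.columns))


def _read_series_matrix(path: Path) -> ExpressionMatrix:
    """Parse the table block and per-sample characteristics of a GEO Series
    Matrix text file."""
    header: list[str] | None = None
    rows: list[list[str]] = []
    characteristics: list[list[str]] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                fields = [f.strip().strip('"') for f in line.split("\t")]
                if header is None:
                    header = fields
                else:
                    rows.append(fields)
            elif line.startswith("!Sample_characteristics_ch1"):
                fields = [f.strip().strip('"') for f in line.split("\t")[1:]]
                characteristics.append(fields)
    if header is None or not rows:
        raise ExpressionDataError(f"{path}: no series matrix table block found")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ExpressionDataError(f"{path}: duplicated sample columns")
    gene_ids = [r[0] for r in rows]
    try:
        values = np.array([[float(v) for v in r[1:]] for r in rows], dtype=float)
    except ValueError as exc:
        raise ExpressionDataError(f"{path}: non-numeric cell in table ({exc})")
    labels = _labels_from_characteristics(characteristics, len(sample_ids))
    return ExpressionMatrix(values, gene_ids, sample_ids, labels=labels)


def _labels_from_characteristics(
    characteristics: list[list[str]], n_samples: int
) -> np.ndarray | None:
    pos_re = re.compile("|".join(sorted(_POSITIVE_ALIASES - {"1"})), re.I)
    neg_re = re.compile("|".join(sorted(_NEGATIVE_ALIASES - {"0"})), re.I)
    for row in characteristics:
        if len(row) != n_samples:
            continue
        labels = []
        for cell in row:
            if pos_re.search(cell):
                labels.append(1)
            elif neg_re.search(cell):
                labels.append(0)
            else:
                break
        else:
            return np.asarray(labels, dtype=np.int8)
    return None


def write_expression_table(m: ExpressionMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def write_labels_table(m: ExpressionMatrix, path: str | Path) -> None:
    y = m.require_labels()
    df = pd.DataFrame(
        {
            "sample_id": m.sample_ids,
            "label": [POSITIVE_LABEL if v else NEGATIVE_LABEL for v in y],
        }
    )
    if m.batch is not None:
        df["batch"] = m.batch
    df.to_csv(path, sep="\t", index=False)


def read_probe_map(path: str | Path) -> ProbeMap:
    """Two-column delimited table ``probe_id<TAB>gene_symbol``."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    probe_col, sym_col = df.columns[:2]
    if df[probe_col].duplicated().any():
        raise ExpressionDataError(f"{path}: a probe appears more than once")
    return ProbeMap(dict(zip(df[probe_col], df[sym_col])))


# ---------------------------------------------------------------------------
# probe collapsing and detection filtering
# ---------------------------------------------------------------------------

def collapse_probes(m: ExpressionMatrix, pm: ProbeMap) -> ExpressionMatrix:
    """Average probes that share a gene symbol; drop unmapped probes.

    Output genes are sorted lexicographically by symbol so the collapsed
    matrix is reproducible regardless of probe order.
    """
    groups: dict[str, list[int]] = {}
    n_unmapped = 0
    for i, probe in enumerate(m.gene_ids):
        sym = pm.symbol_for(probe)
        if sym is None:
            n_unmapped += 1
            continue
        groups.setdefault(sym, []).append(i)
    if not groups:
        raise ExpressionDataError("no probes could be mapped to gene symbols")
    if n_unmapped:
        logger.warning("collapse_probes: removed %d unmapped probes", n_unmapped)
    symbols = sorted(groups)
    values = np.vstack([m.values[groups[s], :].mean(axis=0) for s in symbols])
    return ExpressionMatrix(
        values,
        symbols,
        list(m.sample_ids),
        labels=None if m.labels is None else m.labels.copy(),
        batch=None if m.batch is None else m.batch.copy(),
    )


def filter_unexpressed(
    m: ExpressionMatrix, tau: float | None = None
) -> ExpressionMatrix:
    """Drop features carrying no detectable signal.

    RMA-scale matrices contain no zeros, so "unexpressed" needs an
    operational definition; two are provided.  Default (``tau=None``): drop
    zero-variance rows.  Threshold mode (``tau`` given): drop rows whose
    values all fall below ``tau``.  Row order is preserved.
    """
    if tau is None:
        keep = m.values.var(axis=1) > 0.0
        mode = "zero-variance"
    else:
        if tau < 0:
            raise ValueError("tau must be >= 0")
        keep = (m.values >= tau).any(axis=1)
        mode = f"all-below-{tau}"
    if not keep.any():
        raise ExpressionDataError("detection filter removed every feature")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_unexpressed(%s): dropped %d features", mode, n_dropped)
    return m.select_genes(keep)
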