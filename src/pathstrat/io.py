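"""Readers and writers for GMT gene-set files, expression/clinical TSV tables,
and the light domain containers used throughout the package.

Conventions
-----------
* Gene symbols are uppercased on ingest everywhere; matching across files is
  exact string comparison after uppercasing.
* Expression values are assumed to be on a log2 scale and already normalized;
  no normalization is performed here.
* GMT dialect: tab-separated, ``name<TAB>description<TAB>gene...``; the
  description is free text (a URL or ``na`` are both fine).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("pathstrat")

#: label -> single-character collection code, following the MSigDB-style
#: shorthand ("canonical" pathways = C2CP -> "2", "oncogenic" = C6 -> "6").
COLLECTION_CODES = {"canonical": "2", "oncogenic": "6"}


def configure_logging(level: str = "INFO") -> None:
    """Set up line-oriented logging for the package."""
    logging.basicConfig(format="%(asctime)s %(levelname)s %(name)s: %(message)s")
    logging.getLogger("pathstrat").setLevel(level.upper())


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered, duplicate-free list of gene symbols."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.name:
            raise ValueError("gene set name must be nonempty")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely named gene sets."""

    sets: list[GeneSet]
    label: str = ""

    def __post_init__(self):
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set name(s): {', '.join(dup)}")

    @property
    def code(self) -> str:
        """Single-character collection code used in signature names."""
        if self.label in COLLECTION_CODES:
            return COLLECTION_CODES[self.label]
        return self.label[:1] if self.label else "X"

    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class ExpressionMatrix:
    """Genes x samples (or genes x cells) matrix of log2 expression values."""

    values: pd.DataFrame  # rows = genes (uppercase symbols), columns = samples

    def __post_init__(self):
        v = self.values
        if v.index.has_duplicates:
            dup = sorted(v.index[v.index.duplicated()].unique())
            raise ValueError(f"duplicate gene identifier(s): {', '.join(map(str, dup))}")
        if v.columns.has_duplicates:
            dup = sorted(v.columns[v.columns.duplicated()].unique())
            raise ValueError(f"duplicate sample identifier(s): {', '.join(map(str, dup))}")
        if v.shape[1] < 2:
            raise ValueError("expression matrix needs at least 2 samples")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        self.values = v.astype(float)
        self.values.index = self.values.index.astype(str).str.upper()

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SurvivalTable:
    """Per-sample right-censored survival data.

    ``time`` is a non-negative follow-up time (unit recorded, default months);
    ``event`` is 1 for an observed event and 0 for censoring; ``group`` is an
    optional stratum label (e.g. a cluster id).
    """

    data: pd.DataFrame  # columns: sample, time, event[, group]
    time_unit: str = "months"

    def __post_init__(self):
        d = self.data
        required = {"sample", "time", "event"}
        missing = required - set(d.columns)
        if missing:
            raise ValueError(f"clinical table missing column(s): {', '.join(sorted(missing))}")
        if d["sample"].duplicated().any():
            dup = sorted(d.loc[d["sample"].duplicated(), "sample"].unique())
            raise ValueError(f"duplicate sample identifier(s): {', '.join(map(str, dup))}")
        times = d["time"].to_numpy(dtype=float)
        if not np.isfinite(times).all() or (times < 0).any():
            raise ValueError("survival times must be finite and non-negative")
        events = d["event"].to_numpy()
        if not np.isin(events, [0, 1]).all():
            bad = sorted(set(events) - {0, 1})
            raise ValueError(f"event values outside {{0,1}}: {bad}")
        self.data = d.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, label: str = "") -> GeneSetCollection:
    """Read a Broad-dialect GMT file into a :class:`GeneSetCollection`.

    Each line is ``name<TAB>description<TAB>gene[<TAB>gene...]``.  Gene symbols
    are uppercased; duplicates within a line are dropped with a warning.  A
    line with fewer than 3 fields is a parse error naming the line number.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line (<3 tab-separated fields)")
            name, desc, *genes = fields
            genes = [g.upper() for g in genes if g]
            seen: dict[str, None] = {}
            for g in genes:
                if g in seen:
                    logger.warning("%s:%d: duplicate gene %s in set %s dropped", path, lineno, g, name)
                else:
                    seen[g] = None
            sets.append(GeneSet(name=name, description=desc, genes=tuple(seen)))
    if not sets:
        logger.warning("%s: empty GMT file", path)
    return GeneSetCollection(sets=sets, label=label)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection in canonical GMT form (tab-separated, newline-terminated)."""
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, kind: str = "expression") -> ExpressionMatrix | SurvivalTable:
    """Read a TSV table as a typed object.

    ``kind='expression'`` or ``'single_cell'``: first column is the gene symbol,
    remaining columns are numeric sample/cell values.  ``kind='clinical'``:
    columns ``sample``, ``time``, ``event`` (and optionally ``group``).
    """
    path = Path(path)
    if kind == "clinical":
        df = pd.read_csv(path, sep="\t")
        return SurvivalTable(data=df)
    if kind not in ("expression", "single_cell"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}")
    return ExpressionMatrix(values=numeric)


def write_matrix(obj: ExpressionMatrix | SurvivalTable, path: str | Path) -> None:
    """Write a typed table back to TSV, preserving identifier order and precision."""
    if isinstance(obj, ExpressionMatrix):
        out = obj.values.copy()
        out.index.name = out.index.name or "gene"
        out.to_csv(path, sep="\t", float_format="%.17g")
    elif isinstance(obj, SurvivalTable):
        obj.data.to_csv(path, sep="\t", index=False, float_format="%.17g")
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
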