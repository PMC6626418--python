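"""Readers and writers for gene panels, expression matrices and phenotype tables.

Panels are exchanged as GMT (one tab-separated gene set per line: name,
description, gene IDs).  Expression matrices are TSV with samples on rows and
genes on columns (a ``transpose`` flag accepts the genes-by-samples layout of
common portal exports).  Gene identity is exact NCBI Gene ID string match;
no symbol aliasing is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOG2P1 = "log2p1"
FPKM_UQ = "fpkm_uq"
_SCALES = (LOG2P1, FPKM_UQ)

REFERENCE_PANELS_RESOURCE = "panels12.gmt"


class PanelFormatError(ValueError):
    """Malformed GMT content."""


class RegistryError(ValueError):
    """Inconsistent panel registry (e.g. duplicate panel names)."""


class MatrixFormatError(ValueError):
    """Malformed or inconsistent expression/phenotype table."""


@dataclass(frozen=True)
class PathwayPanel:
    """A named, ordered gene set defining one pattern space."""

    name: str
    gene_ids: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise PanelFormatError("panel name must be non-empty")
        if not self.gene_ids:
            raise PanelFormatError(f"panel {self.name!r} has no gene IDs")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise PanelFormatError(f"panel {self.name!r} contains duplicate gene IDs")

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def n(self) -> int:
        """Pattern-space dimensionality."""
        return len(self.gene_ids)


@dataclass(frozen=True)
class PanelRegistry:
    panels: tuple[PathwayPanel, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.panels]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise RegistryError(f"duplicate panel names: {dupes}")

    def __len__(self) -> int:
        return len(self.panels)

    def __iter__(self):
        return iter(self.panels)

    def get(self, name: str) -> PathwayPanel:
        for p in self.panels:
            if p.name == name:
                return p
        raise KeyError(f"no panel named {name!r}")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.panels]

    def union_gene_ids(self) -> set[str]:
        out: set[str] = set()
        for p in self.panels:
            out.update(p.gene_ids)
        return out

    def total_entries(self) -> int:
        """Sum of panel sizes, counting shared genes multiply."""
        return sum(len(p) for p in self.panels)


def panel_overlap(a: PathwayPanel, b: PathwayPanel) -> int:
    """Number of gene IDs common to both panels (exact string match)."""
    return len(set(a.gene_ids) & set(b.gene_ids))


def read_panels(path: str | Path) -> PanelRegistry:
    """Parse a GMT file into a panel registry.

    Duplicate IDs within one line are collapsed (order preserved) with a
    logged warning; duplicate panel names raise :class:`RegistryError`.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise PanelFormatError(f"{path}: empty GMT file")
    panels = []
    for i, ln in enumerate(lines, start=1):
        fields = ln.split("\t")
        if len(fields) < 3:
            raise PanelFormatError(
                f"{path}:{i}: expected name, description and >=1 gene ID"
            )
        name, desc, ids = fields[0], fields[1], [g for g in fields[2:] if g]
        if not ids:
            raise PanelFormatError(f"{path}:{i}: panel {name!r} has no gene IDs")
        deduped = list(dict.fromkeys(ids))
        if len(deduped) != len(ids):
            logger.warning(
                "panel %r: collapsed %d duplicate gene IDs", name, len(ids) - len(deduped)
            )
        panels.append(PathwayPanel(name=name, gene_ids=tuple(deduped), source=desc))
    return PanelRegistry(panels=tuple(panels))


def write_panels(registry: PanelRegistry, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in registry.panels:
            fh.write("\t".join([p.name, p.source, *p.gene_ids]) + "\n")


def load_reference_panels() -> PanelRegistry:
    """The bundled 12-panel registry (212 unique gene IDs)."""
    ref = resources.files("patternsurv.data") / REFERENCE_PANELS_RESOURCE
    with resources.as_file(ref) as path:
        return read_panels(path)


@dataclass
class ExpressionMatrix:
    """Dense samples x genes expression matrix with a declared value scale."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    scale: str = LOG2P1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise MatrixFormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if self.scale not in _SCALES:
            raise MatrixFormatError(f"unknown scale {self.scale!r}")
        if not np.all(np.isfinite(self.values)):
            raise MatrixFormatError("expression values must be finite")
        if self.values.size and self.values.min() < 0:
            raise MatrixFormatError(f"negative values not allowed under scale {self.scale}")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.gene_ids, "gene")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


def _check_unique(ids: Iterable[str], kind: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})[:5]
        raise MatrixFormatError(f"duplicate {kind} IDs: {dupes}")


def read_expression(
    path: str | Path, scale: str = LOG2P1, transpose: bool = False
) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column = row IDs, header = column IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        raise MatrixFormatError(f"{path}: duplicated row IDs")
    if df.columns.has_duplicates:
        raise MatrixFormatError(f"{path}: duplicated column IDs")
    if transpose:
        df = df.T
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise MatrixFormatError(f"{path}: non-numeric cell: {exc}") from exc
    return ExpressionMatrix(
        sample_ids=[str(s) for s in df.index],
        gene_ids=[str(g) for g in df.columns],
        values=values,
        scale=scale,
    )


def _float_repr(v) -> str:
    # shortest representation that round-trips the exact float64 value
    return repr(float(v))


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write TSV; repr-based float formatting round-trips values bit-exactly."""
    m.to_frame().to_csv(path, sep="\t", index_label="sample_id", float_format=_float_repr)


@dataclass
class PhenotypeTable:
    """Per-sample overall-survival data plus arbitrary categorical covariates."""

    sample_ids: list[str]
    os_time: np.ndarray
    os_event: np.ndarray
    covariates: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.os_time = np.asarray(self.os_time, dtype=float)
        self.os_event = np.asarray(self.os_event, dtype=int)
        n = len(self.sample_ids)
        if self.os_time.shape != (n,) or self.os_event.shape != (n,):
            raise MatrixFormatError("os_time/os_event length must match sample_ids")
        if np.any(self.os_time < 0):
            raise MatrixFormatError("os_time must be non-negative")
        if not np.isin(self.os_event, (0, 1)).all():
            raise MatrixFormatError("os_event must be 0/1")
        _check_unique(self.sample_ids, "sample")
        self.covariates = {k: np.asarray(v) for k, v in self.covariates.items()}
        for k, v in self.covariates.items():
            if v.shape != (n,):
                raise MatrixFormatError(f"covariate {k!r} length must match sample_ids")

    def to_frame(self) -> pd.DataFrame:
        data = {"os_time": self.os_time, "os_event": self.os_event}
        data.update(self.covariates)
        return pd.DataFrame(data, index=pd.Index(self.sample_ids, name="sample_id"))

    def subset(self, sample_ids: list[str]) -> "PhenotypeTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples absent from phenotype table: {missing[:5]}")
        take = [idx[s] for s in sample_ids]
        return PhenotypeTable(
            sample_ids=list(sample_ids),
            os_time=self.os_time[take],
            os_event=self.os_event[take],
            covariates={k: v[take] for k, v in self.covariates.items()},
        )


def read_phenotype(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    required = {"sample_id", "os_time", "os_event"}
    if not required.issubset(df.columns):
        raise MatrixFormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    covars = {
        c: df[c].to_numpy()
        for c in df.columns
        if c not in ("sample_id", "os_time", "os_event")
    }
    return PhenotypeTable(
        sample_ids=[str(s) for s in df["sample_id"]],
        os_time=df["os_time"].to_numpy(dtype=float),
        os_event=df["os_event"].to_numpy(dtype=int),
        covariates=covars,
    )


def write_phenotype(p: PhenotypeTable, path: str | Path) -> None:
    p.to_frame().to_csv(path, sep="\t", float_format=_float_repr)


def subset_to_panel(
    m: ExpressionMatrix, panel: PathwayPanel, allow_missing: bool = False
) -> ExpressionMatrix:
    """Restrict columns to the panel's genes, in panel order.

    Missing panel genes raise unless ``allow_missing`` is set, in which case
    they are dropped with a warning.  Zero overlap always raises.
    """
    col = {g: i for i, g in enumerate(m.gene_ids)}
    present = [g for g in panel.gene_ids if g in col]
    if not present:
        raise MatrixFormatError(
            f"no genes of panel {panel.name!r} present in the expression matrix"
        )
    missing = [g for g in panel.gene_ids if g not in col]
    if missing:
        if not allow_missing:
            raise MatrixFormatError(
                f"panel {panel.name!r}: genes absent from matrix: {missing}"
            )
        logger.warning(
            "panel %r: dropping %d absent genes (n %d -> %d)",
            panel.name, len(missing), panel.n, len(present),
        )
    take = [col[g] for g in present]
    return ExpressionMatrix(
        sample_ids=list(m.sample_ids),
        gene_ids=present,
        values=m.values[:, take].copy(),
        scale=m.scale,
    )
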