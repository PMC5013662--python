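"""Expression-matrix IO, probe→gene collapsing, and gene-panel handling.

Expression tables are tab-delimited text: first column = feature id, header
row = sample ids.  Optional ``#key=value`` comment lines before the header
carry metadata (``scale``, ``roles``).  Gene and sample identifiers are
opaque, case-sensitive strings.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SCALE_LINEAR = "linear"
SCALE_LOG2 = "log2"
_SCALES = (SCALE_LINEAR, SCALE_LOG2)

ROLE_NORMAL = "normal"
ROLE_TUMOUR = "tumour"
ROLE_CELL_LINE = "cell_line"
ROLE_UNKNOWN = "unknown"
_ROLES = (ROLE_NORMAL, ROLE_TUMOUR, ROLE_CELL_LINE, ROLE_UNKNOWN)

BUILTIN_PANELS = ("cenkt31", "ces14", "ces9")


class ExpressionParseError(ValueError):
    """Malformed expression table (ragged rows, duplicates, non-numeric cells)."""


class PanelError(ValueError):
    """Invalid gene panel (unknown name, empty, or duplicated entries)."""


@dataclass(frozen=True)
class GenePanel:
    """An ordered, duplicate-free list of gene identifiers."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise PanelError(f"panel {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if list(self.genes).count(g) > 1})
            raise PanelError(f"panel {self.name!r} has duplicate genes: {dupes}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class ExpressionMatrix:
    """Genes × samples numeric matrix with scale and per-sample role metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    scale
        ``"linear"`` or ``"log2"``.
    sample_roles
        Per-sample role (``normal``/``tumour``/``cell_line``/``unknown``),
        aligned with ``values.columns``.  Defaults to ``unknown``.
    """

    values: pd.DataFrame
    scale: str
    sample_roles: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique().tolist())
            raise ExpressionParseError(f"duplicate gene ids: {dupes}")
        if cols.duplicated().any():
            dupes = sorted(cols[cols.duplicated()].unique().tolist())
            raise ExpressionParseError(f"duplicate sample ids: {dupes}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ExpressionParseError("expression values must be numeric")
        if not np.isfinite(arr).all():
            gi, si = np.argwhere(~np.isfinite(arr))[0]
            raise ExpressionParseError(
                f"non-finite value at gene {idx[gi]!r}, sample {cols[si]!r}"
            )
        if self.scale == SCALE_LINEAR and (arr < 0).any():
            gi, si = np.argwhere(arr < 0)[0]
            raise ExpressionParseError(
                f"negative linear-scale value at gene {idx[gi]!r}, sample {cols[si]!r}"
            )
        if self.sample_roles is None:
            self.sample_roles = pd.Series(ROLE_UNKNOWN, index=cols)
        else:
            self.sample_roles = pd.Series(self.sample_roles).reindex(cols)
            if self.sample_roles.isna().any():
                missing = self.sample_roles.index[self.sample_roles.isna()].tolist()
                raise ValueError(f"samples without a role: {missing}")
            bad = sorted(set(self.sample_roles) - set(_ROLES))
            if bad:
                raise ValueError(f"unknown sample roles: {bad}")

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_with_role(self, role: str) -> list[str]:
        return list(self.sample_roles.index[self.sample_roles == role])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[:, list(sample_ids)].copy(),
            scale=self.scale,
            sample_roles=self.sample_roles.loc[list(sample_ids)].copy(),
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[list(gene_ids)].copy(),
            scale=self.scale,
            sample_roles=self.sample_roles.copy(),
        )

    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2-scale view; linear input is mapped via log2(x + 1)."""
        if self.scale == SCALE_LOG2:
            return self
        return ExpressionMatrix(
            values=np.log2(self.values + 1.0),
            scale=SCALE_LOG2,
            sample_roles=self.sample_roles.copy(),
        )


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a genes × samples tab-delimited table with metadata header lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"#scale={matrix.scale}\n")
        fh.write("#roles=" + "\t".join(matrix.sample_roles.tolist()) + "\n")
        matrix.values.to_csv(fh, sep="\t", index_label="gene_id", lineterminator="\n")


def read_expression_table(
    path: str | Path,
    dialect: str = "genes_by_samples",
    scale: str | None = None,
    roles: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a tab-delimited expression table into a genes × samples matrix.

    ``dialect`` declares the file orientation (``genes_by_samples`` or
    ``samples_by_genes``); the result is always genes × samples.  ``scale``
    overrides any ``#scale=`` header; one of the two must be present.
    """
    if dialect not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if not body_lines and line.startswith("#") and "=" in line:
                key, _, val = line[1:].rstrip("\n").partition("=")
                meta[key.strip()] = val
            elif line.strip():
                body_lines.append(line.rstrip("\n"))
    if not body_lines:
        raise ExpressionParseError(f"{path}: no table content")

    header = body_lines[0].split("\t")
    ids = header[1:]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ExpressionParseError(f"{path}: duplicate header ids: {dupes}")
    ncol = len(header)
    for lineno, line in enumerate(body_lines[1:], start=2):
        if len(line.split("\t")) != ncol:
            raise ExpressionParseError(
                f"{path}: ragged row at line {lineno} "
                f"({len(line.split(chr(9)))} fields, expected {ncol})"
            )
    try:
        df = pd.read_csv(_io.StringIO("\n".join(body_lines)), sep="\t", index_col=0)
    except ValueError as exc:  # pragma: no cover - pandas-level failure
        raise ExpressionParseError(f"{path}: {exc}") from exc
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            raise ExpressionParseError(
                f"{path}: non-numeric cell(s) in column {col!r} at row(s) {bad[:5]}"
            )

    if dialect == "samples_by_genes":
        df = df.T

    eff_scale = scale or meta.get("scale")
    if eff_scale is None:
        raise ExpressionParseError(f"{path}: scale not declared (header or argument)")

    role_series: pd.Series | None = None
    if roles is not None:
        role_series = pd.Series(dict(roles))
    elif "roles" in meta and dialect == "genes_by_samples":
        role_list = meta["roles"].split("\t")
        if len(role_list) == df.shape[1]:
            role_series = pd.Series(role_list, index=df.columns)

    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    return ExpressionMatrix(values=df, scale=eff_scale, sample_roles=role_series)


@dataclass
class CollapseResult:
    """Gene-level matrix plus the genes that had no mapped probe present."""

    matrix: ExpressionMatrix
    missing_genes: list[str]


def collapse_probes(
    matrix: ExpressionMatrix,
    probe_map: Mapping[str, str],
    method: str = "mean_log2",
) -> CollapseResult:
    """Collapse a probe-level matrix to gene level.

    ``mean_log2`` averages a gene's probes on the log2 scale; ``max_mean_probe``
    keeps the single probe with the highest across-sample mean.  Genes in the
    map with no probe present in the matrix are reported, never silently
    dropped.
    """
    if method not in ("mean_log2", "max_mean_probe"):
        raise ValueError(f"unknown collapse method {method!r}")
    log2 = matrix.to_log2()
    requested = sorted(set(probe_map.values()))
    present_probes = [p for p in log2.gene_ids if p in probe_map]
    by_gene: dict[str, list[str]] = {}
    for probe in present_probes:
        by_gene.setdefault(probe_map[probe], []).append(probe)
    missing = [g for g in requested if g not in by_gene]

    rows = {}
    for gene in sorted(by_gene):
        sub = log2.values.loc[by_gene[gene]]
        if method == "mean_log2":
            rows[gene] = sub.mean(axis=0)
        else:
            rows[gene] = sub.loc[sub.mean(axis=1).idxmax()]
    if not rows:
        raise ExpressionParseError("no mapped probes present in matrix")
    collapsed = pd.DataFrame(rows).T
    collapsed.columns = log2.values.columns
    out = ExpressionMatrix(
        values=collapsed, scale=SCALE_LOG2, sample_roles=log2.sample_roles.copy()
    )
    return CollapseResult(matrix=out, missing_genes=missing)


def _read_panel_lines(lines: Iterable[str], name: str) -> GenePanel:
    genes = [ln.strip() for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    if not genes:
        raise PanelError(f"panel {name!r} is empty")
    return GenePanel(name=name, genes=tuple(genes))


def load_gene_panel(source: str | Path) -> GenePanel:
    """Load a gene panel by built-in name (cenkt31, ces14, ces9) or file path."""
    if isinstance(source, str) and source in BUILTIN_PANELS:
        text = (
            resources.files("cescore.data.panels").joinpath(f"{source}.txt").read_text()
        )
        return _read_panel_lines(text.splitlines(), source)
    path = Path(source)
    if not path.exists():
        raise PanelError(
            f"unknown panel {source!r}: not a built-in {BUILTIN_PANELS} and not a file"
        )
    return _read_panel_lines(path.read_text(encoding="utf-8").splitlines(), path.stem)
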