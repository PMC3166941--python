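"""Dataset container, delimited-text I/O and provenance headers.

The canonical on-disk form is a pair of delimited text files: an expression
matrix (samples in rows by default, a ``genes-in-rows`` orientation flag for
the transposed dialect common with microarray exports) and a phenotype table
holding the continuous outcome, joined on sample identifiers.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "read_dataset",
    "write_dataset",
    "read_vim_table",
    "write_vim_table",
    "read_correlation_matrix",
]


@dataclass
class ExpressionDataset:
    """A continuous outcome ``y`` plus an ``n x p`` variable matrix ``v``.

    ``truth`` optionally flags the columns that generated the outcome in a
    simulation (used by the benchmark metrics); ``noise`` stores the residual
    draws of a generator so that the outcome can be reconstructed exactly in
    audits. Neither is written to disk.
    """

    y: np.ndarray
    v: np.ndarray
    ids: list[str]
    outcome_name: str = "outcome"
    truth: np.ndarray | None = None
    provenance: str = ""
    noise: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 2:
            raise ValueError("v must be a 2-d matrix")
        n, p = self.v.shape
        if n < 1 or p < 1:
            raise ValueError("dataset needs at least one sample and one variable")
        if self.y.shape[0] != n:
            raise ValueError(
                f"outcome length {self.y.shape[0]} does not match {n} samples"
            )
        self.ids = [str(i) for i in self.ids]
        if len(self.ids) != p:
            raise ValueError(f"{len(self.ids)} identifiers for {p} variables")
        if len(set(self.ids)) != p:
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate variable identifiers: {dupes[:5]}")
        if not np.isfinite(self.y).all() or not np.isfinite(self.v).all():
            raise ValueError("dataset contains non-finite values")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=bool).ravel()
            if self.truth.shape[0] != p:
                raise ValueError("truth flags must have one entry per variable")

    @property
    def n(self) -> int:
        return self.v.shape[0]

    @property
    def p(self) -> int:
        return self.v.shape[1]

    def column(self, identifier: str) -> int:
        try:
            return self.ids.index(identifier)
        except ValueError:
            raise KeyError(f"unknown variable identifier {identifier!r}") from None


def _sniff_sep(path: Path, override: str | None) -> str:
    if override is not None:
        return override
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if line.count("\t") >= line.count(",") else ","
    raise ValueError(f"{path} is empty")


def _read_table(path: str | Path, sep: str | None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path, sep), index_col=0, comment="#")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: zero samples")
    return df


def read_dataset(
    matrix_path: str | Path,
    phenotype_path: str | Path,
    orientation: str = "samples-in-rows",
    outcome: str | None = None,
    sep: str | None = None,
    impute_missing: bool = False,
) -> ExpressionDataset:
    """Load an expression matrix and a phenotype table into a dataset.

    Sample identifiers are matched between the two files; any mismatch is a
    hard error listing the offending samples. Missing matrix cells are
    rejected unless ``impute_missing`` asks for column-mean imputation.
    """
    if orientation not in ("samples-in-rows", "genes-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    mat = _read_table(matrix_path, sep)
    if orientation == "genes-in-rows":
        mat = mat.T
    pheno = _read_table(phenotype_path, sep)

    missing = [s for s in mat.index if s not in pheno.index]
    extra = [s for s in pheno.index if s not in mat.index]
    if missing or extra:
        raise ValueError(
            "sample identifiers do not match between matrix and phenotype; "
            f"matrix-only={list(map(str, missing))[:10]} "
            f"phenotype-only={list(map(str, extra))[:10]}"
        )
    pheno = pheno.loc[mat.index]

    if outcome is None:
        outcome = pheno.columns[0]
    if outcome not in pheno.columns:
        raise ValueError(f"outcome column {outcome!r} not in phenotype table")

    values = mat.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        if not impute_missing:
            bad = values.columns[values.isna().any()].tolist()
            raise ValueError(
                f"non-numeric or missing cells in matrix columns {bad[:10]}; "
                "pass impute_missing=True to mean-impute"
            )
        warnings.warn("imputing missing matrix cells by column mean")
        values = values.fillna(values.mean())

    y = pd.to_numeric(pheno[outcome], errors="raise").to_numpy(dtype=float)
    return ExpressionDataset(
        y=y,
        v=values.to_numpy(dtype=float),
        ids=[str(c) for c in values.columns],
        outcome_name=str(outcome),
        provenance=f"file:{matrix_path}",
    )


def _provenance_header(seed: int | None, config: dict | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    digest = hashlib.sha256(payload.encode()).hexdigest()[:12]
    lines = [f"# config_hash: {digest}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config:
        lines.append(f"# config: {payload}")
    return "\n".join(lines) + "\n"


def write_dataset(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    phenotype_path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> None:
    """Write matrix + phenotype TSVs with a provenance comment header."""
    samples = [f"S{i + 1}" for i in range(dataset.n)]
    header = _provenance_header(seed, config)
    mat = pd.DataFrame(dataset.v, index=samples, columns=dataset.ids)
    with open(matrix_path, "w") as fh:
        fh.write(header)
        mat.to_csv(fh, sep="\t", index_label="sample")
    pheno = pd.DataFrame({dataset.outcome_name: dataset.y}, index=samples)
    with open(phenotype_path, "w") as fh:
        fh.write(header)
        pheno.to_csv(fh, sep="\t", index_label="sample")


VIM_COLUMNS = [
    "id",
    "beta",
    "se",
    "t",
    "p",
    "p_adj",
    "rank",
    "selected",
    "n_confounders",
    "delta_used",
    "flags",
]


def write_vim_table(
    table: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> None:
    """Write a VIM table as TSV, rows ordered by rank, full float precision."""
    missing = [c for c in VIM_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"VIM table is missing columns {missing}")
    out = table[VIM_COLUMNS].sort_values("rank", kind="stable")
    with open(path, "w") as fh:
        fh.write(_provenance_header(seed, config))
        out.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_vim_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["id"] = df["id"].astype(str)
    df["flags"] = df["flags"].fillna("").astype(str)
    return df


def read_correlation_matrix(path: str | Path, sep: str | None = None) -> np.ndarray:
    """Read a square numeric correlation matrix from delimited text.

    Accepts either a bare numeric grid or one with a header row and an index
    column (the pandas round-trip form).
    """
    path = Path(path)
    use_sep = _sniff_sep(path, sep)
    try:
        arr = np.loadtxt(path, delimiter=use_sep, comments="#")
    except ValueError:
        arr = pd.read_csv(path, sep=use_sep, index_col=0, comment="#").to_numpy(
            dtype=float
        )
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{path}: correlation matrix must be square, got {arr.shape}")
    return arr
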