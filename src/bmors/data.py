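"""Data containers and text I/O for phenotypes, markers, kernels and reports.

Phenotype tables hold the complete J×I grid of (line, environment) cells for
L traits; cells absent from the input file are kept in the grid but flagged
missing so downstream code never has to special-case ragged trials.  Cell
order is environment-major (all lines of the first environment, then the
second, ...), which matches the stacking used to build design matrices.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeTable",
    "MarkerMatrix",
    "GenomicRelationship",
    "read_phenotypes",
    "write_phenotypes",
    "read_markers",
    "read_grm",
    "write_grm",
    "write_report",
]

NA_TOKEN = "NA"


@dataclass
class PhenotypeTable:
    """Complete grid of J lines × I environments × L traits.

    Parameters
    ----------
    line_ids, env_ids, trait_names
        Unique identifiers; J, I and L are their lengths.
    values : (N, L) float array
        Trait measurements in environment-major cell order
        (``cell = i * J + j`` for environment ``i``, line ``j``);
        ``nan`` where missing.
    mask : (N, L) bool array
        True where the value is observed.  Masked (hidden) values are never
        read by any fitting operation.
    """

    line_ids: list
    env_ids: list
    trait_names: list
    values: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self):
        self.line_ids = list(self.line_ids)
        self.env_ids = list(self.env_ids)
        self.trait_names = list(self.trait_names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_cells, self.n_traits):
            raise ValueError(
                f"values has shape {self.values.shape}, expected "
                f"({self.n_cells}, {self.n_traits})"
            )
        if self.mask is None:
            self.mask = ~np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        for name, ids in (("line", self.line_ids), ("env", self.env_ids),
                          ("trait", self.trait_names)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} identifiers")
        if self.n_traits < 1:
            raise ValueError("need at least one trait")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_envs(self) -> int:
        return len(self.env_ids)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def n_cells(self) -> int:
        return self.n_lines * self.n_envs

    def cell_index(self, line, env) -> int:
        """Row index of cell (line, env) in the environment-major order."""
        try:
            j = self.line_ids.index(line)
            i = self.env_ids.index(env)
        except ValueError as exc:
            raise KeyError(f"unknown cell ({line}, {env})") from exc
        return i * self.n_lines + j

    def cells(self) -> list:
        """All (line, env) pairs in cell order."""
        return [(l, e) for e in self.env_ids for l in self.line_ids]

    def cell_line_env_index(self):
        """(env_idx, line_idx) integer arrays of length N in cell order."""
        env_idx = np.repeat(np.arange(self.n_envs), self.n_lines)
        line_idx = np.tile(np.arange(self.n_lines), self.n_envs)
        return env_idx, line_idx


@dataclass
class MarkerMatrix:
    """J lines × p biallelic markers coded as reference-allele dosage 0/1/2."""

    line_ids: list
    marker_ids: list
    dosages: np.ndarray  # (J, p) float, nan = missing

    def __post_init__(self):
        self.line_ids = list(self.line_ids)
        self.marker_ids = list(self.marker_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("dosages shape inconsistent with identifiers")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line identifiers")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclass
class GenomicRelationship:
    """J×J genomic relationship kernel with its line identifiers."""

    line_ids: list
    G: np.ndarray

    def __post_init__(self):
        self.line_ids = list(self.line_ids)
        self.G = np.asarray(self.G, dtype=float)
        J = len(self.line_ids)
        if self.G.shape != (J, J):
            raise ValueError("G must be square and match line_ids")
        if not np.allclose(self.G, self.G.T, atol=1e-8):
            raise ValueError("G is not symmetric")

    def check_psd(self, tol_rel: float = 1e-8):
        """Raise if G has an eigenvalue below -tol_rel * lambda_max."""
        w = np.linalg.eigvalsh(self.G)
        lam_max = max(w.max(), 0.0)
        if w.min() < -tol_rel * max(lam_max, 1.0):
            raise ValueError(
                f"G is not PSD within tolerance (min eigenvalue {w.min():.3g})"
            )


def read_phenotypes(path, dialect: str = "long") -> PhenotypeTable:
    """Read a long-format phenotype CSV: columns Line, Env, <Trait1>, ...

    Cells absent from the file are retained in the J×I grid and flagged
    missing.  Line and environment identifiers are sorted lexicographically
    so the result is invariant to the row order of the input file.
    """
    if dialect != "long":
        raise NotImplementedError("only the long phenotype dialect is supported")
    df = pd.read_csv(path, dtype={0: str, 1: str}, na_values=[NA_TOKEN],
                     keep_default_na=False, skipinitialspace=True)
    if df.shape[1] < 3:
        raise ValueError("phenotype file needs Line, Env and >=1 trait column")
    line_col, env_col = df.columns[0], df.columns[1]
    trait_names = list(df.columns[2:])
    dup = df.duplicated(subset=[line_col, env_col])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate cell (line={row[line_col]}, env={row[env_col]})"
        )
    for t in trait_names:
        coerced = pd.to_numeric(df[t], errors="coerce")
        bad = coerced.isna() & df[t].notna() & (df[t].astype(str).str.strip() != "")
        if bad.any():
            rownum = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(f"non-numeric value for trait {t!r} at row {rownum}")
        df[t] = coerced
    line_ids = sorted(df[line_col].unique())
    env_ids = sorted(df[env_col].unique())
    J, L = len(line_ids), len(trait_names)
    values = np.full((J * len(env_ids), L), np.nan)
    lpos = {l: j for j, l in enumerate(line_ids)}
    epos = {e: i for i, e in enumerate(env_ids)}
    rows = df[env_col].map(epos).to_numpy() * J + df[line_col].map(lpos).to_numpy()
    values[rows] = df[trait_names].to_numpy(dtype=float)
    return PhenotypeTable(line_ids, env_ids, trait_names, values)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    """Write the observed cells of a PhenotypeTable as a long CSV."""
    env_idx, line_idx = pheno.cell_line_env_index()
    df = pd.DataFrame({
        "Line": [pheno.line_ids[j] for j in line_idx],
        "Env": [pheno.env_ids[i] for i in env_idx],
    })
    vals = np.where(pheno.mask, pheno.values, np.nan)
    for k, t in enumerate(pheno.trait_names):
        df[t] = vals[:, k]
    keep = pheno.mask.any(axis=1)
    df = df.loc[keep]
    df.to_csv(path, index=False, na_rep=NA_TOKEN)


_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_markers(path, dialect: str = "csv", strict: bool = True) -> MarkerMatrix:
    """Read a marker dosage matrix.

    dialect "csv": first column line IDs, then one column per marker.
    dialect "plink_raw": whitespace-delimited PLINK .raw additive coding;
    the six fixed metadata columns are dropped and line IDs come from IID.

    In strict mode non-missing dosages must be exactly 0, 1 or 2.
    """
    if dialect == "csv":
        df = pd.read_csv(path, dtype={0: str}, na_values=[NA_TOKEN],
                         keep_default_na=False)
        line_ids = df.iloc[:, 0].tolist()
        body = df.iloc[:, 1:]
    elif dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype={1: str}, na_values=[NA_TOKEN],
                         keep_default_na=False)
        missing_meta = [c for c in _PLINK_META if c not in df.columns]
        if missing_meta:
            raise ValueError(f".raw file lacks metadata columns {missing_meta}")
        line_ids = df["IID"].tolist()
        body = df.drop(columns=_PLINK_META)
    else:
        raise ValueError(f"unknown marker dialect {dialect!r}")
    marker_ids = list(body.columns)
    try:
        dosages = body.apply(pd.to_numeric).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric dosage in marker file: {exc}") from exc
    if strict:
        finite = ~np.isnan(dosages)
        ok = np.isin(dosages[finite], (0.0, 1.0, 2.0))
        if not ok.all():
            j, k = np.argwhere(finite)[~ok][0]
            raise ValueError(
                f"dosage {dosages[j, k]!r} outside {{0,1,2}} for marker "
                f"{marker_ids[k]!r}, line {line_ids[j]!r}"
            )
    return MarkerMatrix(line_ids, marker_ids, dosages)


def write_markers(markers: MarkerMatrix, path) -> None:
    df = pd.DataFrame(markers.dosages, columns=markers.marker_ids)
    df.insert(0, "Line", markers.line_ids)
    df.to_csv(path, index=False, na_rep=NA_TOKEN)


def read_grm(path) -> GenomicRelationship:
    """Read a square GRM CSV whose first row and column are line IDs."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ValueError("GRM row and column line IDs disagree")
    return GenomicRelationship(list(df.columns.astype(str)), df.to_numpy(dtype=float))


def write_grm(grm: GenomicRelationship, path) -> None:
    pd.DataFrame(grm.G, index=grm.line_ids, columns=grm.line_ids).to_csv(path)


def write_report(metrics: pd.DataFrame, predictions: pd.DataFrame | None,
                 out_dir) -> dict:
    """Write the metrics table (one row per model × trait [× env]) and the
    per-cell prediction records under ``out_dir``.

    Returns the paths written.  Metrics must be non-empty.
    """
    if metrics is None or len(metrics) == 0:
        raise ValueError("empty metrics report")
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    mpath = os.path.join(out_dir, "metrics.csv")
    metrics.to_csv(mpath, index=False, float_format="%.6f")
    paths["metrics"] = mpath
    if predictions is not None and len(predictions):
        ppath = os.path.join(out_dir, "predictions.csv")
        predictions.to_csv(ppath, index=False, float_format="%.6f")
        paths["predictions"] = ppath
    return paths
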