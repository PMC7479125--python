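"""Reading, writing and validation of connectome inputs.

The analysis starts from per-subject connectivity matrices: a 90x90
matrix of mean fractional-anisotropy (FA) edge weights and a matching
matrix of streamline (fiber) counts, plus a node table mapping the 90
normalized-AAL regions to hemispheres and a phenotype table with group
membership, covariates and clinical scores. Everything here validates
the structural invariants (symmetry, nonnegativity, zero diagonal,
hemisphere/homologue bookkeeping) before any graph computation runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "WeightedNetwork",
    "FiberCountMatrix",
    "NodeTable",
    "PhenotypeTable",
    "read_matrix",
    "read_fiber_counts",
    "write_matrix",
    "read_node_table",
    "default_node_table",
    "read_phenotypes",
    "read_manifest",
]

SYMMETRY_TOL = 1e-10

VALID_GROUPS = ("NC", "BD")


class MatrixDimensionError(ValueError):
    """Matrix is not square or does not match the expected size."""


class NodeTableError(ValueError):
    """Node table violates hemisphere / homologue structure."""


@dataclass
class WeightedNetwork:
    """Symmetric nonnegative weighted network (FA-weighted connectome).

    Parameters
    ----------
    weights : (n, n) float array
        Symmetric, nonnegative, zero-diagonal edge weights (mean FA,
        dimensionless).
    node_ids : sequence of str
        Unique region labels, one per row.
    hemisphere_tags : sequence of str
        Per-node hemisphere label in {"L", "R"}; a hemispheric network
        carries a single constant tag.
    """

    weights: np.ndarray
    node_ids: list[str]
    hemisphere_tags: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.node_ids = list(self.node_ids)
        self.hemisphere_tags = list(self.hemisphere_tags)
        self.validate()

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def validate(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise MatrixDimensionError(f"weights must be square, got {w.shape}")
        n = w.shape[0]
        if len(self.node_ids) != n:
            raise ValueError("node_ids length must match matrix dimension")
        if len(set(self.node_ids)) != n:
            raise ValueError("node_ids must be unique")
        if len(self.hemisphere_tags) != n:
            raise ValueError("hemisphere_tags length must match matrix dimension")
        if np.isnan(w).any():
            raise ValueError("weights contain NaN")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        asym = np.abs(w - w.T).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"weights asymmetric beyond tolerance ({asym:.3g})")
        if n and np.abs(np.diagonal(w)).max() > SYMMETRY_TOL:
            raise ValueError("diagonal must be zero")
        # normalize exactly: symmetrize and zero the diagonal
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = w

    def copy(self) -> "WeightedNetwork":
        return WeightedNetwork(
            self.weights.copy(), list(self.node_ids), list(self.hemisphere_tags)
        )


@dataclass
class FiberCountMatrix:
    """Symmetric integer streamline-count matrix."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise MatrixDimensionError(f"counts must be square, got {c.shape}")
        if np.isnan(np.asarray(c, dtype=float)).any():
            raise ValueError("counts contain NaN")
        if not np.allclose(c, np.round(np.asarray(c, dtype=float))):
            raise ValueError("counts must be integer-valued")
        c = np.asarray(np.round(np.asarray(c, dtype=float)), dtype=int)
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        if (c != c.T).any():
            raise ValueError("counts must be symmetric")
        if c.shape[0] and np.abs(np.diagonal(c)).max() != 0:
            raise ValueError("diagonal must be zero")
        self.counts = c

    @property
    def n_nodes(self) -> int:
        return self.counts.shape[0]


@dataclass
class NodeTable:
    """Region table: id, AAL abbreviation, hemisphere, homologue index.

    The homologue map must be an involution that crosses hemispheres
    (each left region maps to its right mirror and back), and both
    hemispheres must contain the same number of regions.
    """

    table: pd.DataFrame

    REQUIRED = ("region_id", "region_name", "hemisphere", "homologue_id")

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise NodeTableError(f"node table missing columns: {missing}")
        hemis = sorted(t["hemisphere"].unique())
        if hemis != ["L", "R"]:
            raise NodeTableError(f"expected exactly hemispheres L and R, got {hemis}")
        n_l = int((t["hemisphere"] == "L").sum())
        n_r = int((t["hemisphere"] == "R").sum())
        if n_l != n_r:
            raise NodeTableError(f"unequal hemisphere counts: {n_l} L vs {n_r} R")
        ids = t["region_id"].to_numpy()
        if len(set(ids)) != len(ids):
            raise NodeTableError("region_id not unique")
        pos = {rid: i for i, rid in enumerate(ids)}
        homol = t["homologue_id"].to_numpy()
        for i, h in enumerate(homol):
            if h not in pos:
                raise NodeTableError(f"homologue_id {h} not a region_id")
            j = pos[h]
            if t["hemisphere"].iloc[i] == t["hemisphere"].iloc[j]:
                raise NodeTableError("homologue map does not cross hemispheres")
            if pos[homol[j]] != i:
                raise NodeTableError("homologue map is not an involution")
        self.table = t

    @property
    def n_regions(self) -> int:
        return len(self.table)

    def hemisphere_index(self, hemi: str) -> np.ndarray:
        """Row positions of the given hemisphere, in table order."""
        return np.flatnonzero((self.table["hemisphere"] == hemi).to_numpy())

    def homologue_positions(self) -> np.ndarray:
        """For each row position, the row position of its mirror region."""
        pos = {rid: i for i, rid in enumerate(self.table["region_id"])}
        return np.array([pos[h] for h in self.table["homologue_id"]])

    def node_labels(self) -> list[str]:
        return [
            f"{name}.{h}"
            for name, h in zip(self.table["region_name"], self.table["hemisphere"])
        ]


@dataclass
class PhenotypeTable:
    """Subject phenotypes: group, covariates and clinical scores."""

    table: pd.DataFrame

    REQUIRED = ("subject_id", "group", "age", "sex", "handscore")

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        if t["subject_id"].duplicated().any():
            dup = t.loc[t["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise KeyError(f"duplicate subject_id: {dup}")
        bad = set(t["group"]) - set(VALID_GROUPS)
        if bad or t["group"].isna().any():
            raise ValueError(f"unknown group labels: {sorted(map(str, bad))}")
        for col in ("ymrs", "hamd"):
            if col not in t.columns:
                t[col] = np.nan
            t[col] = pd.to_numeric(t[col], errors="coerce")
            miss_bd = t.loc[(t["group"] == "BD") & t[col].isna(), "subject_id"]
            if len(miss_bd):
                warnings.warn(
                    f"{len(miss_bd)} BD subject(s) missing {col.upper()} "
                    f"(e.g. {miss_bd.iloc[0]}); records retained with missing flag",
                    stacklevel=2,
                )
        t["age"] = pd.to_numeric(t["age"])
        t["handscore"] = pd.to_numeric(t["handscore"])
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    def group_ids(self, group: str) -> list:
        return list(self.table.loc[self.table["group"] == group, "subject_id"])


def _load_dense(path) -> np.ndarray:
    """Dense numeric matrix from a whitespace- or comma-delimited file."""
    text = Path(path).read_text()
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    delim = "," if "," in first else None
    rows = [ln for ln in text.splitlines() if ln.strip()]
    parsed = []
    for ln in rows:
        fields = ln.split(",") if delim else ln.split()
        parsed.append([float(x) for x in fields])
    lengths = {len(r) for r in parsed}
    if len(lengths) != 1:
        raise MatrixDimensionError("ragged rows in matrix file")
    return np.array(parsed, dtype=float)


def read_matrix(path, expected_n: int | None = None) -> WeightedNetwork:
    """Read an FA connectivity matrix and validate all invariants.

    Node ids default to ``n0..n{N-1}`` and hemisphere tags to the
    L-first / R-second packaged convention when the size matches the
    default 90-region table, otherwise a constant tag.
    """
    w = _load_dense(path)
    if w.shape[0] != w.shape[1]:
        raise MatrixDimensionError(f"matrix in {path} is {w.shape}, not square")
    n = w.shape[0]
    if expected_n is not None and n != expected_n:
        raise MatrixDimensionError(f"expected {expected_n} nodes, got {n}")
    if n % 2 == 0 and n > 0:
        tags = ["L"] * (n // 2) + ["R"] * (n // 2)
    else:
        tags = ["L"] * n
    return WeightedNetwork(w, [f"n{i}" for i in range(n)], tags)


def read_fiber_counts(path, expected_n: int | None = None) -> FiberCountMatrix:
    c = _load_dense(path)
    if c.shape[0] != c.shape[1]:
        raise MatrixDimensionError(f"matrix in {path} is {c.shape}, not square")
    if expected_n is not None and c.shape[0] != expected_n:
        raise MatrixDimensionError(f"expected {expected_n} nodes, got {c.shape[0]}")
    return FiberCountMatrix(c)


def write_matrix(net: WeightedNetwork | FiberCountMatrix | np.ndarray, path) -> None:
    """Write a dense matrix as tab-separated text (full float precision)."""
    if isinstance(net, WeightedNetwork):
        m = net.weights
        fmt = "%.17g"
    elif isinstance(net, FiberCountMatrix):
        m = net.counts
        fmt = "%d"
    else:
        m = np.asarray(net)
        fmt = "%.17g" if np.issubdtype(m.dtype, np.floating) else "%d"
    np.savetxt(path, m, fmt=fmt, delimiter="\t")


def read_node_table(path) -> NodeTable:
    return NodeTable(pd.read_csv(path, sep="\t"))


def default_node_table() -> NodeTable:
    """The packaged 90-region normalized-AAL table (45 per hemisphere)."""
    ref = resources.files("hemirc").joinpath("data/aal90_nodes.tsv")
    with resources.as_file(ref) as p:
        return read_node_table(p)


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t"))


def read_manifest(path) -> dict:
    """YAML manifest mapping subject_id -> {fa_path, fn_path}.

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "subjects" not in raw:
        raise ValueError("manifest must be a mapping with a 'subjects' key")
    out = {}
    for sid, entry in raw["subjects"].items():
        fa = path.parent / entry["fa_path"]
        fn = path.parent / entry["fn_path"]
        out[str(sid)] = {"fa_path": fa, "fn_path": fn}
    return out
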