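"""Gene-eigenvalue feature fusion.

Each diagnostic group's gene-level association evidence is packed into a
fixed 24 x 24 matrix of SNP p-values (one row per candidate gene, short rows
zero-padded). The dominant eigenvalue of that non-negative matrix — its
Perron root, real and non-negative — serves as a single group-level scalar
``alpha``. Scaling every participant's voxel-feature row by the group's
alpha amplifies between-group contrast before classification; pairs of
scaled groups are stacked into two-class datasets with labels +1 / -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GENE_MATRIX_SIZE",
    "STAGE_ORDER",
    "GenePMatrix",
    "FusionScalar",
    "FusedDataset",
    "build_gene_p_matrix",
    "compute_alpha",
    "fuse",
    "build_pair_dataset",
    "read_gene_p_lists",
]

#: Fixed dimension of the gene p-value matrix (24 candidate genes, each
#: contributing at most 24 SNP p-values).
GENE_MATRIX_SIZE = 24

#: Disease-stage ranks used by the pairwise label convention.
STAGE_ORDER = {"HC": 0, "EMCI": 1, "LMCI": 2, "AD": 3}

_PAD = ""


@dataclass
class GenePMatrix:
    """24 x 24 zero-padded matrix of per-gene SNP p-values."""

    values: np.ndarray
    gene_ids: list[str]
    snp_ids: list[list[str]] | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (GENE_MATRIX_SIZE, GENE_MATRIX_SIZE):
            raise ValueError(f"gene p-value matrix must be {GENE_MATRIX_SIZE}x{GENE_MATRIX_SIZE}")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("p-values must lie in [0, 1]")


@dataclass
class FusionScalar:
    """The fusion scalar alpha (Perron root) and the full spectrum it came from."""

    alpha: float
    spectrum: np.ndarray
    group: str | None = None

    def __post_init__(self) -> None:
        self.spectrum = np.asarray(self.spectrum, dtype=complex)
        if abs(self.alpha - np.abs(self.spectrum).max()) > 1e-8 * max(1.0, abs(self.alpha)):
            raise ValueError("alpha must equal the maximum modulus of the spectrum")


@dataclass
class FusedDataset:
    """Alpha-scaled voxel features with two-class +1 / -1 labels."""

    features: np.ndarray
    labels: np.ndarray
    ids: np.ndarray
    alpha_used: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.ids = np.asarray(self.ids)
        self.alpha_used = np.asarray(self.alpha_used, dtype=float)
        n = self.features.shape[0]
        if not (len(self.labels) == len(self.ids) == len(self.alpha_used) == n):
            raise ValueError("features, labels, ids, alpha_used must have equal row counts")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1 or -1")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def take(self, rows: np.ndarray, name: str | None = None) -> "FusedDataset":
        return FusedDataset(
            self.features[rows], self.labels[rows], self.ids[rows],
            self.alpha_used[rows], name if name is not None else self.name,
        )

    def restrict_features(self, cols: Sequence[int], name: str | None = None) -> "FusedDataset":
        cols = np.asarray(cols, dtype=int)
        return FusedDataset(
            self.features[:, cols], self.labels, self.ids, self.alpha_used,
            name if name is not None else self.name,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, index=pd.Index(self.ids, name="participant_id"))
        df.columns = [f"f{j}" for j in range(self.n_features)]
        df["label"] = self.labels
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_col: str = "label", name: str = "") -> "FusedDataset":
        labels = df[label_col].to_numpy()
        feats = df.drop(columns=[label_col]).to_numpy(dtype=float)
        ids = df.index.to_numpy()
        return cls(feats, labels, ids, np.full(len(df), np.nan), name)


def build_gene_p_matrix(
    gene_p_lists: Mapping[str, Sequence[float]], group: str | None = None
) -> GenePMatrix:
    """Stack per-gene p-value lists into the fixed 24 x 24 matrix.

    Row *i* holds gene *i*'s p-values left-aligned and zero-padded to 24
    columns. A gene with more than 24 SNPs contributes its 24 smallest
    p-values in ascending order.
    """
    if len(gene_p_lists) != GENE_MATRIX_SIZE:
        raise ValueError(f"expected exactly {GENE_MATRIX_SIZE} genes, got {len(gene_p_lists)}")
    values = np.zeros((GENE_MATRIX_SIZE, GENE_MATRIX_SIZE))
    gene_ids = list(gene_p_lists)
    snp_ids: list[list[str]] = []
    for i, gene in enumerate(gene_ids):
        p = np.asarray(list(gene_p_lists[gene]), dtype=float)
        if p.size and ((p < 0).any() or (p > 1).any() or not np.isfinite(p).all()):
            raise ValueError(f"gene {gene!r} has p-values outside [0, 1]")
        if p.size > GENE_MATRIX_SIZE:
            p = np.sort(p)[:GENE_MATRIX_SIZE]
        values[i, : p.size] = p
        snp_ids.append([f"{gene}:{j}" for j in range(p.size)] + [_PAD] * (GENE_MATRIX_SIZE - p.size))
    return GenePMatrix(values=values, gene_ids=gene_ids, snp_ids=snp_ids, group=group)


def compute_alpha(mp: GenePMatrix | np.ndarray, group: str | None = None) -> FusionScalar:
    """All 24 eigenvalues of the gene matrix; alpha is the max-modulus one.

    For a non-negative matrix the Perron-Frobenius theorem guarantees the
    max-modulus eigenvalue is real and non-negative, so alpha is returned as
    a real scalar.
    """
    if isinstance(mp, GenePMatrix):
        values = mp.values
        group = group if group is not None else mp.group
    else:
        values = np.asarray(mp, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("gene p-value matrix contains non-finite entries")
    spectrum = np.linalg.eigvals(values)
    alpha = float(np.abs(spectrum).max())
    return FusionScalar(alpha=alpha, spectrum=spectrum, group=group)


def fuse(voxels: np.ndarray, alpha: FusionScalar | float) -> np.ndarray:
    """Scale a voxel-feature matrix by the group eigenvalue (elementwise)."""
    a = alpha.alpha if isinstance(alpha, FusionScalar) else float(alpha)
    voxels = np.asarray(voxels, dtype=float)
    if not np.isfinite(voxels).all() or not np.isfinite(a):
        raise ValueError("fuse requires finite inputs")
    return a * voxels


def _stage_rank(group: str) -> int:
    if group not in STAGE_ORDER:
        raise ValueError(f"unknown diagnostic group {group!r}; expected one of {sorted(STAGE_ORDER)}")
    return STAGE_ORDER[group]


def build_pair_dataset(
    group_a_scaled: np.ndarray,
    group_b_scaled: np.ndarray,
    pair_name: str,
    ids_a: np.ndarray | None = None,
    ids_b: np.ndarray | None = None,
    alpha_a: float = np.nan,
    alpha_b: float = np.nan,
) -> FusedDataset:
    """Stack two alpha-scaled groups into one labelled two-class dataset.

    ``pair_name`` is "A-B" naming the first- and second-listed group (for
    example "AD-HC"); rows of the first-listed group come first. The
    more-advanced disease stage (HC < EMCI < LMCI < AD) takes label -1 and
    the other group +1, generalising the AD = -1 / HC = +1 convention.
    """
    name_a, name_b = pair_name.split("-")
    a = np.asarray(group_a_scaled, dtype=float)
    b = np.asarray(group_b_scaled, dtype=float)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"feature-count mismatch: {a.shape[1]} vs {b.shape[1]}")
    rank_a, rank_b = _stage_rank(name_a), _stage_rank(name_b)
    if rank_a == rank_b:
        raise ValueError(f"pair {pair_name!r} must name two distinct stages")
    label_a, label_b = (-1, 1) if rank_a > rank_b else (1, -1)
    if ids_a is None:
        ids_a = np.array([f"{name_a}{i + 1:05d}" for i in range(a.shape[0])])
    if ids_b is None:
        ids_b = np.array([f"{name_b}{i + 1:05d}" for i in range(b.shape[0])])
    return FusedDataset(
        features=np.vstack([a, b]),
        labels=np.concatenate([np.full(a.shape[0], label_a), np.full(b.shape[0], label_b)]),
        ids=np.concatenate([np.asarray(ids_a), np.asarray(ids_b)]),
        alpha_used=np.concatenate([np.full(a.shape[0], alpha_a), np.full(b.shape[0], alpha_b)]),
        name=pair_name,
    )


def read_gene_p_lists(path: str | Path) -> dict[str, list[float]]:
    """Read per-gene p-value lists from TSV.

    Accepts either the two-column dialect (gene_id, comma-separated
    p-values) or long format (gene_id, snp_id, p).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    out: dict[str, list[float]] = {}
    if len(df.columns) == 2:
        for gene, plist in zip(df.iloc[:, 0], df.iloc[:, 1]):
            out[gene] = [float(v) for v in str(plist).split(",") if v != ""]
    elif "p" in cols:
        pcol = df.columns[cols.index("p")]
        gcol = df.columns[0]
        for gene, sub in df.groupby(gcol, sort=False):
            out[str(gene)] = [float(v) for v in sub[pcol]]
    else:
        raise ValueError("unrecognised gene p-value table layout")
    return out
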