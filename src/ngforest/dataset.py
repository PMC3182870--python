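"""Expression/label I/O, bootstrap resampling and label permutation.

Also home of the seed-derivation rule: every random draw in the package flows
from a single master seed through :func:`derive_seed` / :func:`derive_rng`,
keyed by a purpose tag and an index, so whole forests are bit-reproducible
and embarrassingly parallel (tree ``i`` sees the same stream regardless of
build order).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("ngforest")

__all__ = [
    "LabeledExpression",
    "BootstrapSplit",
    "load_expression",
    "write_expression",
    "bootstrap",
    "permute_labels",
    "derive_seed",
    "derive_rng",
]


def derive_seed(master: int, tag: str, index: int = 0) -> int:
    """Deterministically derive a child seed from (master, purpose-tag, index).

    Hash-based so that streams for different purposes (bootstraps, candidate
    sampling, importance permutations, null runs...) are independent even when
    their indices coincide. The result fits in 31 bits.
    """
    payload = f"{master}:{tag}:{index}".encode()
    digest = hashlib.blake2b(payload, digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


def derive_rng(master: int, tag: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, tag, index))


@dataclass
class LabeledExpression:
    """Gene x sample continuous expression matrix with per-sample class labels."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float
    labels: np.ndarray  # shape (n_samples,), dtype=object/str
    target_class: str | None = None

    gene_index: dict[str, int] = field(init=False, repr=False)
    classes: list[str] = field(init=False)
    y: np.ndarray = field(init=False, repr=False)  # integer class codes

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if self.labels.shape[0] != len(self.samples):
            raise ValueError("one label per sample required")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values after load")
        self.classes = sorted(set(self.labels))
        if len(self.classes) < 2:
            raise ValueError(f"need >=2 classes, found {len(self.classes)}")
        if self.target_class is None:
            # default: lexicographically last class plays the positive/aggressive role
            self.target_class = self.classes[-1]
            logger.warning(
                "no target class specified; defaulting to lexicographically last class %r",
                self.target_class,
            )
        elif self.target_class not in self.classes:
            raise ValueError(f"target class {self.target_class!r} not among labels {self.classes}")
        code = {c: i for i, c in enumerate(self.classes)}
        self.y = np.array([code[l] for l in self.labels], dtype=np.intp)
        self.gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def target_code(self) -> int:
        return self.classes.index(self.target_class)

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index[gene]]

    def with_labels(self, labels: np.ndarray) -> "LabeledExpression":
        return LabeledExpression(self.genes, self.samples, self.values, labels, self.target_class)


@dataclass(frozen=True)
class BootstrapSplit:
    """In-bag multiset (as an index array with repeats) and out-of-bag index set."""

    in_bag: np.ndarray  # shape (n_samples,), sample indices drawn with replacement
    out_of_bag: np.ndarray  # sorted distinct indices never drawn

    def __post_init__(self):
        in_set = set(self.in_bag.tolist())
        oob_set = set(self.out_of_bag.tolist())
        if in_set & oob_set:
            raise ValueError("in-bag and out-of-bag overlap")


def load_expression(
    matrix_path: str | Path,
    labels_path: str | Path,
    target_class: str | None = None,
) -> LabeledExpression:
    """Read a TSV expression matrix (rows = genes, header = sample IDs) and a
    two-column sample/class TSV.

    Samples without a label are dropped with a warning; genes with any missing
    value are dropped with a warning. Non-numeric cells raise with coordinates.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    for j, col in enumerate(mat.columns):
        converted = pd.to_numeric(mat[col], errors="coerce")
        bad = converted.isna() & mat[col].notna() & (mat[col].astype(str).str.upper() != "NA")
        if bad.any():
            gene = mat.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{matrix_path}: non-numeric value {mat.loc[gene, col]!r} at gene {gene!r}, sample {col!r}"
            )
        mat[col] = converted
    lab = pd.read_csv(labels_path, sep="\t", header=None, names=["sample", "class"], dtype=str)
    lab = lab.set_index("sample")["class"]

    labeled = [s for s in mat.columns if s in lab.index]
    dropped_samples = [s for s in mat.columns if s not in lab.index]
    if dropped_samples:
        logger.warning("dropping %d samples without labels: %s", len(dropped_samples), dropped_samples[:5])
    if not labeled:
        raise ValueError("no sample in the expression header has a label")
    mat = mat[labeled]

    missing = mat.isna().any(axis=1)
    if missing.any():
        logger.warning("dropping %d genes with missing values", int(missing.sum()))
        mat = mat.loc[~missing]

    return LabeledExpression(
        genes=list(mat.index),
        samples=list(mat.columns),
        values=mat.to_numpy(dtype=float),
        labels=lab.loc[labeled].to_numpy(),
        target_class=target_class,
    )


def write_expression(data: LabeledExpression, matrix_path: str | Path, labels_path: str | Path) -> None:
    """Writers mirroring :func:`load_expression`."""
    pd.DataFrame(data.values, index=data.genes, columns=data.samples).to_csv(matrix_path, sep="\t")
    pd.DataFrame({"sample": data.samples, "class": list(data.labels)}).to_csv(
        labels_path, sep="\t", header=False, index=False
    )


def bootstrap(data: LabeledExpression, seed: int, stratified: bool = False) -> BootstrapSplit:
    """Draw ``n_samples`` indices with replacement; the complement is out-of-bag.

    With ``stratified=True`` the draw is done within each class, preserving
    class sizes exactly in the bag.
    """
    n = data.n_samples
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    if stratified:
        parts = []
        for c in range(data.n_classes):
            idx = np.flatnonzero(data.y == c)
            parts.append(rng.choice(idx, size=len(idx), replace=True))
        in_bag = np.concatenate(parts)
    else:
        in_bag = rng.integers(0, n, size=n)
    oob = np.setdiff1d(np.arange(n), in_bag)
    return BootstrapSplit(in_bag=in_bag, out_of_bag=oob)


def permute_labels(data: LabeledExpression, seed: int) -> LabeledExpression:
    """Uniformly permute class labels across samples; the matrix is untouched."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n_samples)
    return data.with_labels(data.labels[perm])
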