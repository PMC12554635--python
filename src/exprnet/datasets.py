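"""Synthetic expression datasets with planted markers.

Every downstream stage of the pipeline (prefiltering, clustering, graph
construction, marker selection, classification) is exercised against data
generated here, so the generators carry an explicit ground truth:
``truth_markers`` records exactly which genes were planted with a
class-conditional shift.

The generative model is log-normal: expression is Gaussian on the log2
scale and exponentiated back to a raw non-negative scale, so that the
pipeline's own ``log2(x + 1)`` transform recovers the Gaussian world.
Marker genes have their class-2 log2-mean shifted by ``effect_size``;
class 1 is the reference class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "generate_unpaired",
    "generate_paired",
    "generate_null",
    "write_dataset",
    "read_dataset",
]

CLASS1 = "class1"
CLASS2 = "class2"

# Typical bulk RNA-seq log2 expression sits in roughly [3, 9] after
# library normalization; baselines are drawn uniformly from that band.
_BASELINE_LO = 3.0
_BASELINE_HI = 9.0


@dataclass
class ExpressionDataset:
    """Genes x samples expression with per-sample class (and optional pair) metadata.

    Attributes
    ----------
    values : ndarray, shape (n_genes, n_samples)
        Raw-scale, non-negative expression.
    gene_ids, sample_ids : list of str
        Unique identifiers for rows / columns.
    class_labels : list of str
        One of two class names per sample.
    pair_ids : list of str or None
        Subject identifier per sample; present iff the design is paired,
        in which case every pair id occurs exactly twice with opposite
        classes.
    truth_markers : frozenset of str
        Planted marker gene ids (synthetic data only; empty otherwise).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    class_labels: list[str]
    pair_ids: list[str] | None = None
    truth_markers: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D genes x samples matrix")
        g, n = self.values.shape
        if len(self.gene_ids) != g or len(self.sample_ids) != n:
            raise ValueError("id lists must match matrix dimensions")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(self.class_labels) != n:
            raise ValueError("one class label per sample required")
        if len(set(self.class_labels)) > 2:
            raise ValueError("at most two classes supported")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("values must be finite and non-negative")
        if self.pair_ids is not None:
            if len(self.pair_ids) != n:
                raise ValueError("one pair id per sample required")
            by_pair: dict[str, list[str]] = {}
            for pid, cls in zip(self.pair_ids, self.class_labels):
                by_pair.setdefault(pid, []).append(cls)
            for pid, classes in by_pair.items():
                if sorted(classes) != sorted({CLASS1, CLASS2}):
                    raise ValueError(
                        f"pair {pid!r} must have exactly one sample of each class"
                    )
        unknown = self.truth_markers - set(self.gene_ids)
        if unknown:
            raise ValueError(f"truth markers not in gene ids: {sorted(unknown)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def is_paired(self) -> bool:
        return self.pair_ids is not None

    def class_of(self) -> dict[str, str]:
        """Mapping sample id -> class label."""
        return dict(zip(self.sample_ids, self.class_labels))

    def samples_of_class(self, cls: str) -> list[str]:
        return [s for s, c in zip(self.sample_ids, self.class_labels) if c == cls]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionDataset":
        """Restrict to the given samples (order preserved as given)."""
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        cols = [idx[s] for s in sample_ids]
        return ExpressionDataset(
            values=self.values[:, cols],
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            class_labels=[self.class_labels[i] for i in cols],
            pair_ids=None if self.pair_ids is None else [self.pair_ids[i] for i in cols],
            truth_markers=self.truth_markers,
        )


def _check_dims(**kwargs: int) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")


def _raw_from_log2(log2_values: np.ndarray) -> np.ndarray:
    # inverse of log2(x + 1); clip guards against float underflow near 0
    return np.clip(np.exp2(log2_values) - 1.0, 0.0, None)


def generate_unpaired(
    n_genes: int,
    n_per_class: int,
    n_markers: int,
    effect_size: float = 2.0,
    dispersion: float = 0.3,
    seed: int = 0,
) -> ExpressionDataset:
    """Two independent groups of samples with ``n_markers`` planted genes.

    Background genes are i.i.d. log-normal around a per-gene baseline;
    the first ``n_markers`` genes get their class-2 log2-mean shifted by
    ``effect_size``.  ``dispersion`` is the within-class log2-scale
    standard deviation.
    """
    _check_dims(n_genes=n_genes, n_per_class=n_per_class)
    if n_per_class < 2:
        raise ValueError("n_per_class must be at least 2")
    if n_markers < 0 or n_markers > n_genes:
        raise ValueError("n_markers must lie in [0, n_genes]")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")

    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    baseline = rng.uniform(_BASELINE_LO, _BASELINE_HI, size=n_genes)
    log2v = baseline[:, None] + rng.normal(0.0, dispersion, size=(n_genes, n))
    # columns: first n_per_class are class1, rest class2
    log2v[:n_markers, n_per_class:] += effect_size

    gene_ids = [f"gene{i:04d}" for i in range(n_genes)]
    sample_ids = [f"s{i:03d}" for i in range(n)]
    classes = [CLASS1] * n_per_class + [CLASS2] * n_per_class
    return ExpressionDataset(
        values=_raw_from_log2(log2v),
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        class_labels=classes,
        truth_markers=frozenset(gene_ids[:n_markers]),
    )


def generate_paired(
    n_genes: int,
    n_pairs: int,
    n_markers: int,
    effect_size: float = 2.0,
    subject_sd: float = 0.5,
    dispersion: float = 0.3,
    seed: int = 0,
) -> ExpressionDataset:
    """Matched class1/class2 samples per subject with a shared random intercept.

    Each subject contributes one sample of each class; both share a
    subject-level intercept with standard deviation ``subject_sd`` on the
    log2 scale, which makes within-pair contrasts more powerful than
    between-sample ones, as in matched tumor designs.
    """
    _check_dims(n_genes=n_genes, n_pairs=n_pairs)
    if n_pairs < 2:
        raise ValueError("n_pairs must be at least 2")
    if n_markers < 0 or n_markers > n_genes:
        raise ValueError("n_markers must lie in [0, n_genes]")
    if effect_size < 0 or subject_sd < 0:
        raise ValueError("effect_size and subject_sd must be non-negative")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")

    rng = np.random.default_rng(seed)
    baseline = rng.uniform(_BASELINE_LO, _BASELINE_HI, size=n_genes)
    intercept = rng.normal(0.0, subject_sd, size=(n_genes, n_pairs))

    # sample layout: p000_c1, p000_c2, p001_c1, ...
    n = 2 * n_pairs
    log2v = np.empty((n_genes, n))
    noise = rng.normal(0.0, dispersion, size=(n_genes, n))
    for p in range(n_pairs):
        for k, cls_shift in enumerate((0.0, effect_size)):
            col = 2 * p + k
            log2v[:, col] = baseline + intercept[:, p] + noise[:, col]
            if cls_shift:
                log2v[:n_markers, col] += cls_shift

    gene_ids = [f"gene{i:04d}" for i in range(n_genes)]
    sample_ids = [f"p{p:03d}_{c}" for p in range(n_pairs) for c in (CLASS1, CLASS2)]
    classes = [CLASS1, CLASS2] * n_pairs
    pair_ids = [f"p{p:03d}" for p in range(n_pairs) for _ in range(2)]
    return ExpressionDataset(
        values=_raw_from_log2(log2v),
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        class_labels=classes,
        pair_ids=pair_ids,
        truth_markers=frozenset(gene_ids[:n_markers]),
    )


def generate_null(
    n_genes: int,
    n_samples: int,
    dispersion: float = 0.3,
    seed: int = 0,
) -> ExpressionDataset:
    """Exchangeable null: i.i.d. genes, labels assigned arbitrarily.

    With no planted effect the class labels carry no information, so any
    downstream test should reject at its nominal rate. ``truth_markers``
    is always empty.
    """
    _check_dims(n_genes=n_genes, n_samples=n_samples)
    if n_samples % 2 != 0:
        raise ValueError("n_samples must be even")
    ds = generate_unpaired(
        n_genes=n_genes,
        n_per_class=n_samples // 2,
        n_markers=0,
        effect_size=0.0,
        dispersion=dispersion,
        seed=seed,
    )
    return ds


# -- plain-text round trip -----------------------------------------------------


def write_dataset(ds: ExpressionDataset, directory: str | Path) -> None:
    """Write expression, metadata and truth tables as TSV under ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ds.to_frame().to_csv(d / "expression.tsv", sep="\t", index_label="gene_id",
                         float_format="%.17g")
    meta = pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "class": ds.class_labels,
            "pair_id": ds.pair_ids if ds.pair_ids is not None else [""] * ds.n_samples,
        }
    )
    meta.to_csv(d / "metadata.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": sorted(ds.truth_markers)}).to_csv(
        d / "truth_markers.tsv", sep="\t", index=False
    )


def read_dataset(directory: str | Path) -> ExpressionDataset:
    """Read back a dataset written by :func:`write_dataset` (bit-exact values)."""
    d = Path(directory)
    expr = pd.read_csv(d / "expression.tsv", sep="\t", index_col="gene_id",
                       float_precision="round_trip")
    meta = pd.read_csv(d / "metadata.tsv", sep="\t", dtype=str).fillna("")
    truth_path = d / "truth_markers.tsv"
    truth: frozenset[str] = frozenset()
    if truth_path.exists():
        t = pd.read_csv(truth_path, sep="\t", dtype=str)
        if len(t):
            truth = frozenset(t["gene_id"])
    pair_ids: list[str] | None = None
    if meta["pair_id"].str.len().gt(0).any():
        pair_ids = meta["pair_id"].tolist()
    if list(meta["sample_id"]) != list(expr.columns):
        warnings.warn("metadata order differs from expression columns; reordering")
        meta = meta.set_index("sample_id").loc[list(expr.columns)].reset_index()
    return ExpressionDataset(
        values=expr.to_numpy(dtype=float),
        gene_ids=[str(g) for g in expr.index],
        sample_ids=[str(s) for s in expr.columns],
        class_labels=meta["class"].tolist(),
        pair_ids=pair_ids,
        truth_markers=truth,
    )
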