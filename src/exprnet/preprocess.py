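"""Normalization paths and the differential-expression prefilter.

Two normalization routes feed the one-dimensional clustering stage:

* paired designs:   ``log2(x+1)`` -> per-class, per-gene rescale to [1, 2]
  -> class2/class1 ratio per subject pair (ratio values lie in [0.5, 2]);
* unpaired designs: ``log2(x+1)`` -> per-class, per-gene z-scores.

Each transform is order-locked through ``scale_tag`` and recorded in
``provenance`` so that mis-composed pipelines fail loudly rather than
silently producing nonsense.

The prefilter stands in for a count-based differential-expression step:
nonparametric rank tests (Wilcoxon signed-rank for paired designs,
Mann-Whitney U otherwise) with Benjamini-Hochberg adjustment, or a
user-supplied external gene list for users who ran their own DE tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import CLASS1, CLASS2, ExpressionDataset

__all__ = [
    "NormalizedMatrix",
    "log2_normalize",
    "rescale_1_2",
    "paired_ratio",
    "zscore_per_class",
    "normalize_for_clustering",
    "prefilter_genes",
    "GenePrefilter",
    "read_gene_list",
]


@dataclass
class NormalizedMatrix:
    """A genes x columns matrix tagged with its position in the transform chain.

    ``columns`` are sample ids, or pair ids after :func:`paired_ratio`.
    ``scale_tag`` is one of ``log2``, ``rescaled_1_2``, ``ratio``,
    ``zscore``; ``provenance`` lists the transforms applied in order.
    """

    values: np.ndarray
    gene_ids: list[str]
    columns: list[str]
    scale_tag: str
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.columns)):
            raise ValueError("matrix shape must match id lists")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.columns)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


def _require_tag(m: NormalizedMatrix, expected: str, op: str) -> None:
    if m.scale_tag != expected:
        raise ValueError(
            f"{op} requires a {expected!r} matrix, got {m.scale_tag!r} "
            f"(provenance: {m.provenance})"
        )


def log2_normalize(data: ExpressionDataset) -> NormalizedMatrix:
    """Entrywise ``log2(x + 1)``; the entry point of every transform chain."""
    if np.any(data.values < 0):
        raise ValueError("expression values must be non-negative")
    return NormalizedMatrix(
        values=np.log2(data.values + 1.0),
        gene_ids=list(data.gene_ids),
        columns=list(data.sample_ids),
        scale_tag="log2",
        provenance=["log2"],
    )


def rescale_1_2(m: NormalizedMatrix, classes: dict[str, str]) -> NormalizedMatrix:
    """Min-max rescale each gene row to [1, 2] within each sample class.

    The per-gene scope keeps the subsequent per-gene ratio clustering
    meaningful. Rows constant within a class map to the midpoint 1.5.
    """
    _require_tag(m, "log2", "rescale_1_2")
    out = np.empty_like(m.values)
    labels = np.array([classes[c] for c in m.columns])
    for cls in dict.fromkeys(labels):  # preserves first-seen order
        mask = labels == cls
        if not mask.any():
            raise ValueError(f"empty sample class {cls!r}")
        block = m.values[:, mask]
        lo = block.min(axis=1, keepdims=True)
        hi = block.max(axis=1, keepdims=True)
        span = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = 1.0 + (block - lo) / span
        scaled[np.broadcast_to(span == 0, scaled.shape)] = 1.5
        out[:, mask] = scaled
    return NormalizedMatrix(
        values=out,
        gene_ids=list(m.gene_ids),
        columns=list(m.columns),
        scale_tag="rescaled_1_2",
        provenance=m.provenance + ["rescale_1_2"],
    )


def paired_ratio(m: NormalizedMatrix, pairing: dict[str, str],
                 classes: dict[str, str]) -> NormalizedMatrix:
    """Collapse paired samples to one class2/class1 ratio column per subject.

    Requires rescaled input, so ratios are bounded in [0.5, 2].
    """
    _require_tag(m, "rescaled_1_2", "paired_ratio")
    by_pair: dict[str, dict[str, int]] = {}
    for j, sample in enumerate(m.columns):
        by_pair.setdefault(pairing[sample], {})[classes[sample]] = j
    pair_ids = sorted(by_pair)
    cols = np.empty((m.values.shape[0], len(pair_ids)))
    for k, pid in enumerate(pair_ids):
        members = by_pair[pid]
        if set(members) != {CLASS1, CLASS2}:
            raise ValueError(f"pair {pid!r} is missing a member of one class")
        cols[:, k] = m.values[:, members[CLASS2]] / m.values[:, members[CLASS1]]
    return NormalizedMatrix(
        values=cols,
        gene_ids=list(m.gene_ids),
        columns=pair_ids,
        scale_tag="ratio",
        provenance=m.provenance + ["paired_ratio"],
    )


def zscore_per_class(m: NormalizedMatrix, classes: dict[str, str]) -> NormalizedMatrix:
    """Per gene, per class: center and scale by the sample (n-1) deviation.

    Rows with zero within-class deviation become 0; a class of size 1
    cannot be scaled and is zeroed with a warning.
    """
    _require_tag(m, "log2", "zscore_per_class")
    out = np.empty_like(m.values)
    labels = np.array([classes[c] for c in m.columns])
    for cls in dict.fromkeys(labels):
        mask = labels == cls
        block = m.values[:, mask]
        if block.shape[1] == 1:
            warnings.warn(f"class {cls!r} has a single sample; z-scores set to 0")
            out[:, mask] = 0.0
            continue
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (block - mu) / sd
        z[np.broadcast_to(sd == 0, z.shape)] = 0.0
        out[:, mask] = z
    return NormalizedMatrix(
        values=out,
        gene_ids=list(m.gene_ids),
        columns=list(m.columns),
        scale_tag="zscore",
        provenance=m.provenance + ["zscore_per_class"],
    )


def normalize_for_clustering(data: ExpressionDataset,
                             design: str = "unpaired") -> NormalizedMatrix:
    """The design-specific chain feeding one-dimensional clustering.

    Unpaired: ``log2 -> per-class z-scores`` (columns stay samples).
    Paired:   ``log2 -> per-class [1,2] rescale -> class2/class1 ratios``
    (columns become subject pairs).
    """
    logm = log2_normalize(data)
    classes = data.class_of()
    if design == "unpaired":
        return zscore_per_class(logm, classes)
    if design == "paired":
        if data.pair_ids is None:
            raise ValueError("paired design requires pair_ids")
        pairing = dict(zip(data.sample_ids, data.pair_ids))
        return paired_ratio(rescale_1_2(logm, classes), pairing, classes)
    raise ValueError("design must be 'unpaired' or 'paired'")


# -- prefilter -----------------------------------------------------------------

_METHODS = ("wilcoxon_paired", "mannwhitney", "none", "external_list")


def prefilter_genes(
    data: ExpressionDataset,
    train_samples: list[str],
    method: str = "mannwhitney",
    alpha: float = 0.05,
    max_genes: int = 500,
    external_genes: list[str] | None = None,
) -> list[str]:
    """Select differentially expressed genes on the training samples only.

    Genes with BH-adjusted p below ``alpha`` are kept, truncated to
    ``max_genes`` by raw p-value.  If nothing passes, the top
    ``max_genes`` genes by absolute mean log2 difference are returned
    with a warning rather than an empty panel.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    if method == "external_list":
        if not external_genes:
            raise ValueError("external_list requires external_genes")
        known = set(data.gene_ids)
        return [g for g in external_genes if g in known][:max_genes]
    if method == "none":
        return list(data.gene_ids)[:max_genes] if max_genes else list(data.gene_ids)

    train = data.subset_samples(train_samples)
    logm = log2_normalize(train)
    labels = np.array(train.class_labels)
    a = logm.values[:, labels == CLASS1]
    b = logm.values[:, labels == CLASS2]
    effect = b.mean(axis=1) - a.mean(axis=1)

    if method == "wilcoxon_paired":
        if train.pair_ids is None:
            raise ValueError("wilcoxon_paired requires a paired dataset")
        order = {}
        for j, pid in enumerate(train.pair_ids):
            order.setdefault(pid, {})[train.class_labels[j]] = j
        c1 = [order[p][CLASS1] for p in sorted(order)]
        c2 = [order[p][CLASS2] for p in sorted(order)]
        diffs = logm.values[:, c2] - logm.values[:, c1]
        pvals = np.ones(data.n_genes)
        for i, d in enumerate(diffs):
            if np.allclose(d, 0):
                continue
            pvals[i] = stats.wilcoxon(d, zero_method="wilcox").pvalue
    else:  # mannwhitney
        res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
        pvals = np.asarray(res.pvalue)

    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")[:4]
    hits = np.flatnonzero(reject)
    if hits.size == 0:
        warnings.warn(
            "no genes pass the BH-adjusted threshold; "
            f"falling back to top {max_genes} by |effect|"
        )
        order_ix = np.argsort(-np.abs(effect), kind="stable")[:max_genes]
        return [data.gene_ids[i] for i in order_ix]
    order_ix = hits[np.argsort(pvals[hits], kind="stable")][:max_genes]
    return [data.gene_ids[i] for i in order_ix]


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


class GenePrefilter:
    """Sklearn-style wrapper for :func:`prefilter_genes`.

    Parameters mirror the function; ``fit`` takes the dataset plus the
    training sample ids and exposes ``selected_genes_``.
    """

    def __init__(self, method: str = "mannwhitney", alpha: float = 0.05,
                 max_genes: int = 500, external_genes: list[str] | None = None):
        self.method = method
        self.alpha = alpha
        self.max_genes = max_genes
        self.external_genes = external_genes

    def get_params(self, deep: bool = True) -> dict:
        return {
            "method": self.method,
            "alpha": self.alpha,
            "max_genes": self.max_genes,
            "external_genes": self.external_genes,
        }

    def set_params(self, **params) -> "GenePrefilter":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, data: ExpressionDataset, train_samples: list[str] | None = None
            ) -> "GenePrefilter":
        train_samples = train_samples or list(data.sample_ids)
        self.selected_genes_ = prefilter_genes(
            data, train_samples, method=self.method, alpha=self.alpha,
            max_genes=self.max_genes, external_genes=self.external_genes,
        )
        return self

    def get_support(self) -> list[str]:
        return list(self.selected_genes_)

    def transform(self, data: ExpressionDataset) -> pd.DataFrame:
        """Expression frame restricted to the selected genes."""
        return data.to_frame().loc[self.selected_genes_]
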