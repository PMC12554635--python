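"""End-to-end orchestration: split, prefilter, select markers, classify.

One evaluation iteration draws a stratified 80/20 split (subject pairs
are never divided between train and test), selects markers on the
training portion only, builds the prediction network from those markers,
extracts per-sample subgraphs, trains a graph classifier, and scores the
held-out samples.  The procedure repeats for ``n_iterations`` fresh
splits and reports mean and standard deviation of accuracy and AUC.

All randomness flows from a single master seed through
``numpy.random.SeedSequence(master_seed).spawn``, so a rerun with the
same seed reproduces every number bit-for-bit in single-threaded
execution.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif, mutual_info_classif, \
    mutual_info_regression

from .cluster import cluster_gene
from .datasets import CLASS1, ExpressionDataset, read_dataset
from .graph import assign_heldout_sample, build_expression_graph, \
    export_graph, extract_sample_subgraph, normalize_graph_features
from .metrics import evaluate
from .nn.model import GraphNetClassifier, save_checkpoint
from .preprocess import log2_normalize, prefilter_genes
from .select import GraphMarkerSelector

__all__ = [
    "PipelineConfig",
    "EvalReport",
    "evaluate",
    "stratified_split",
    "run_iteration",
    "run_pipeline",
    "baseline_feature_select",
    "build_prediction_subgraphs",
]


@dataclass
class PipelineConfig:
    """Flat, text-serializable configuration of one pipeline run."""

    design: str = "unpaired"
    n_iterations: int = 10
    test_fraction: float = 0.2
    # prefilter
    prefilter_method: str = "auto"  # auto -> paired/unpaired rank test
    alpha: float = 0.05
    max_genes: int = 500
    # clustering / graph
    min_size: int = 2
    fraction: float = 0.1
    min_shared: int = 1
    # feature selection
    fs_iterations: int = 10000
    fs_bootstrap: int = 1000
    top_k: int = 20
    # classifier
    model: str = "gcn"
    feature_mode: str = "all"
    hidden_dim: int = 64
    n_layers: int = 2
    n_heads: int = 4
    lr: float = 0.01
    epochs: int = 50
    pooling: str = "mean"
    weighted_adjacency: bool = True
    master_seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat ``key = value`` text format; unknown keys rejected."""
        fields = {f: t for f, t in cls.__annotations__.items()}
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            ann = fields[key]
            if ann == "int":
                kwargs[key] = int(raw)
            elif ann == "float":
                kwargs[key] = float(raw)
            elif ann == "bool":
                kwargs[key] = raw.lower() in ("1", "true", "yes")
            else:
                kwargs[key] = raw
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class EvalReport:
    """Per-iteration metrics plus aggregates and the config snapshot."""

    iterations: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def add(self, row: dict) -> None:
        self.iterations.append(row)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r["accuracy"] for r in self.iterations]))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std([r["accuracy"] for r in self.iterations], ddof=0))

    @property
    def mean_auc(self) -> float:
        aucs = [r["auc"] for r in self.iterations if r["auc"] is not None]
        return float(np.mean(aucs)) if aucs else float("nan")

    @property
    def sd_auc(self) -> float:
        aucs = [r["auc"] for r in self.iterations if r["auc"] is not None]
        return float(np.std(aucs, ddof=0)) if aucs else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [{k: (";".join(v) if isinstance(v, list) else v)
                 for k, v in r.items()} for r in self.iterations]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "n_iterations": len(self.iterations),
        }


def _spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-iteration seeds below 2**31."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


def stratified_split(data: ExpressionDataset, test_fraction: float = 0.2,
                     seed: int = 0) -> tuple[list[str], list[str]]:
    """80/20-style split stratified by class; pairs are never divided."""
    rng = np.random.default_rng(seed)
    if data.is_paired:
        pairs = sorted(set(data.pair_ids))
        perm = rng.permutation(len(pairs))
        n_test = max(1, round(test_fraction * len(pairs)))
        test_pairs = {pairs[i] for i in perm[:n_test]}
        test = [s for s, p in zip(data.sample_ids, data.pair_ids)
                if p in test_pairs]
        train = [s for s in data.sample_ids if s not in set(test)]
        return train, test
    train, test = [], []
    for cls in sorted(set(data.class_labels)):
        members = data.samples_of_class(cls)
        perm = rng.permutation(len(members))
        n_test = max(1, round(test_fraction * len(members)))
        test.extend(members[i] for i in perm[:n_test])
        chosen = {members[i] for i in perm[:n_test]}
        train.extend(s for s in members if s not in chosen)
    order = {s: i for i, s in enumerate(data.sample_ids)}
    return sorted(train, key=order.get), sorted(test, key=order.get)


def build_prediction_subgraphs(
    train_data: ExpressionDataset,
    full_data: ExpressionDataset,
    markers: list[str],
    test_samples: list[str],
    config: PipelineConfig,
) -> tuple[list, object]:
    """Cluster the markers on training data and induce per-sample subgraphs.

    Prediction networks always use per-sample (unpaired-style)
    clustering, whatever the feature-selection design, because each
    held-out sample needs its own subgraph.  Clustering values are
    per-gene z-scores against POOLED training statistics — not per-class
    ones — so that held-out samples (whose class is unknown) can be
    normalized onto the same scale without touching labels.  Training
    samples join clusters by membership; held-out samples are routed to
    the nearest cluster median within one training standard deviation.
    """
    # pooled train stats on the log2 scale; one scale for train and test
    train_log = log2_normalize(train_data)
    marker_rows = {g: train_log.gene_ids.index(g) for g in markers}
    pooled_mean = {g: float(train_log.values[i].mean())
                   for g, i in marker_rows.items()}
    pooled_sd = {g: float(train_log.values[i].std(ddof=1))
                 for g, i in marker_rows.items()}

    selected = {}
    radius = {}
    for gene in markers:
        sd = pooled_sd[gene]
        if sd == 0:
            continue
        zrow = (train_log.values[marker_rows[gene]] - pooled_mean[gene]) / sd
        clusters = cluster_gene(zrow, train_log.columns, gene,
                                min_size=config.min_size,
                                fraction=config.fraction)
        if clusters:
            selected[gene] = clusters
            radius[gene] = float(zrow.std(ddof=1)) or 1.0
    graph = build_expression_graph(selected, min_shared=config.min_shared)

    class_of = full_data.class_of()
    full_log = log2_normalize(full_data)
    full_rows = {g: full_log.gene_ids.index(g) for g in markers}
    full_cols = {s: j for j, s in enumerate(full_log.columns)}

    def pooled_expr(sample: str) -> dict[str, float]:
        # one scale for train and test: z against pooled training stats
        col = full_cols[sample]
        out = {}
        for g in selected:
            sd = pooled_sd[g]
            x = full_log.values[full_rows[g], col]
            out[g] = 0.0 if sd == 0 else float((x - pooled_mean[g]) / sd)
        return out

    subgraphs = []
    for s in train_data.sample_ids:
        subgraphs.append(extract_sample_subgraph(
            graph, s, feature_mode=config.feature_mode,
            expression=pooled_expr(s), label=class_of[s]))
    for s in test_samples:
        expr = pooled_expr(s)
        membership = assign_heldout_sample(graph, expr, radius)
        subgraphs.append(extract_sample_subgraph(
            graph, s, feature_mode=config.feature_mode, expression=expr,
            label=class_of[s], membership=membership))
    return subgraphs, graph


def run_iteration(data: ExpressionDataset, config: PipelineConfig,
                  seed: int) -> dict:
    """One split -> prefilter -> marker selection -> GNN evaluation round."""
    train_ids, test_ids = stratified_split(data, config.test_fraction, seed)
    train_data = data.subset_samples(train_ids)

    method = config.prefilter_method
    if method == "auto":
        method = "wilcoxon_paired" if config.design == "paired" else "mannwhitney"
    genes = prefilter_genes(data, train_ids, method=method,
                            alpha=config.alpha, max_genes=config.max_genes)

    selector = GraphMarkerSelector(
        design=config.design, min_size=config.min_size,
        fraction=config.fraction, min_shared=config.min_shared,
        n_iterations=config.fs_iterations, n_boot=config.fs_bootstrap,
        top_k=config.top_k, random_state=seed,
    ).fit(train_data, genes=genes)
    markers = selector.selected_genes_

    subgraphs, graph = build_prediction_subgraphs(
        train_data, data, markers, test_ids, config)
    subgraphs = normalize_graph_features(subgraphs, fit_on=train_ids)
    train_subs = [s for s in subgraphs if s.sample_id in set(train_ids)]
    test_subs = [s for s in subgraphs if s.sample_id in set(test_ids)]

    clf = GraphNetClassifier(
        model=config.model, hidden_dim=config.hidden_dim,
        n_layers=config.n_layers, n_heads=config.n_heads, lr=config.lr,
        epochs=config.epochs, pooling=config.pooling,
        weighted_adjacency=config.weighted_adjacency, random_state=seed,
    ).fit(train_subs)
    probs = clf.predict_proba(test_subs)
    pos = clf.classes_[1]
    pos_col = 1
    accuracy, auc = evaluate(probs[:, pos_col],
                             [s.label for s in test_subs], positive_class=pos)
    return {
        "seed": seed,
        "accuracy": accuracy,
        "auc": auc,
        "n_markers": len(markers),
        "markers": markers,
        "train_ids": train_ids,
        "test_ids": test_ids,
        "_selector": selector,
        "_classifier": clf,
        "_graph": graph,
    }


def run_pipeline(data: ExpressionDataset | str | Path,
                 config: PipelineConfig,
                 out_dir: str | Path | None = None) -> EvalReport:
    """Repeat :func:`run_iteration` over fresh splits and aggregate.

    When ``out_dir`` is given, every artifact (config snapshot, seed
    ledger, per-iteration marker tables, prediction graphs, model
    checkpoints, report) is written beneath it.
    """
    if not isinstance(data, ExpressionDataset):
        data = read_dataset(data)
    report = EvalReport(config=asdict(config))
    seeds = _spawn_seeds(config.master_seed, config.n_iterations)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_file(out / "config.txt")
        (out / "seeds.json").write_text(json.dumps(
            {"master_seed": config.master_seed, "iteration_seeds": seeds}))

    for i, seed in enumerate(seeds):
        t0 = time.time()
        try:
            row = run_iteration(data, config, seed)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed in iteration {i}: {exc}"
                               ) from exc
        if out is not None:
            it_dir = out / f"iteration_{i:02d}"
            it_dir.mkdir(exist_ok=True)
            row["_selector"].marker_table_.to_tsv(it_dir / "marker_table.tsv")
            export_graph(row["_graph"], it_dir / "prediction_graph.graphml")
            save_checkpoint(row["_classifier"], it_dir / "model.json")
            (it_dir / "split.json").write_text(json.dumps(
                {"train": row["train_ids"], "test": row["test_ids"]}))
        report.add({
            "iteration": i,
            "seed": row["seed"],
            "accuracy": row["accuracy"],
            "auc": row["auc"],
            "n_markers": row["n_markers"],
            "markers": row["markers"],
            "elapsed_s": round(time.time() - t0, 2),
        })

    if out is not None:
        report.to_frame().to_csv(out / "report.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(report.summary()))
    return report


# -- light comparator feature selection ----------------------------------------


def baseline_feature_select(data: ExpressionDataset, train_ids: list[str],
                            method: str = "anova", k: int = 20,
                            seed: int = 0) -> list[str]:
    """ANOVA F-test or greedy mRMR (MID difference form) gene panels.

    ANOVA ranks genes by one-way F-test p-value between classes;
    constant genes (undefined F) rank last.  mRMR greedily adds the gene
    maximizing mutual-information relevance minus mean redundancy with
    the already-selected genes.
    """
    if k > data.n_genes:
        raise ValueError("k exceeds the gene count")
    train = data.subset_samples(train_ids)
    x = np.log2(train.values + 1.0).T  # samples x genes
    y = np.array([0 if c == CLASS1 else 1 for c in train.class_labels])

    if method == "anova":
        with np.errstate(invalid="ignore", divide="ignore"):
            f, p = f_classif(x, y)
        p = np.where(np.isfinite(p), p, 1.1)  # constant genes rank last
        order = np.argsort(p, kind="stable")
        return [train.gene_ids[i] for i in order[:k]]

    if method == "mrmr":
        relevance = mutual_info_classif(x, y, random_state=seed)
        selected: list[int] = [int(np.argmax(relevance))]
        redundancy = np.zeros((data.n_genes,))
        mi_cache: dict[int, np.ndarray] = {}
        while len(selected) < k:
            last = selected[-1]
            if last not in mi_cache:
                mi_cache[last] = mutual_info_regression(
                    x, x[:, last], random_state=seed)
            redundancy += mi_cache[last]
            score = relevance - redundancy / len(selected)
            score[selected] = -np.inf
            selected.append(int(np.argmax(score)))
        return [train.gene_ids[i] for i in selected]

    raise ValueError("method must be 'anova' or 'mrmr'")
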