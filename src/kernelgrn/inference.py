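"""Genome-wide inference: per-TF subproblems, cross-validation, parallelism.

The genome-wide problem decomposes into one binary classification
subproblem per TF.  Scores are produced by the out-of-fold scheme: genes
are split once into k folds (default 10, shared across all TFs of a run);
for each fold, an SVM is trained on the genes outside it and the fold's
genes receive their decision scores from that model.  Every gene thus
gets exactly one score from a model that never saw its label.

TF subproblems are independent, so they are distributed over a worker
pool in equal contiguous chunks; workers share nothing but the output
store, and the assembled score matrix is identical for any worker count.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .data_io import RegulationMatrix, ScoreMatrix
from .kernels import KernelMatrix
from .svm import SvmParams, decision_scores, train

__all__ = [
    "CvPlan",
    "ParallelPlan",
    "InferenceConfig",
    "make_cv_plan",
    "score_tf",
    "plan_partition",
    "infer_network",
]


@dataclass
class CvPlan:
    """A fixed gene -> fold assignment (fold sizes differ by at most 1)."""

    n_folds: int
    seed: int
    fold_of_gene: dict[str, int]

    def fold_indices(self, gene_ids: list[str]) -> list[np.ndarray]:
        assignment = np.array([self.fold_of_gene[g] for g in gene_ids])
        return [np.flatnonzero(assignment == f) for f in range(self.n_folds)]


@dataclass
class ParallelPlan:
    """Static equal split of the TF list into contiguous chunks."""

    n_workers: int
    chunks: list[list[str]]


@dataclass
class InferenceConfig:
    svm: SvmParams = field(default_factory=SvmParams)
    n_folds: int = 10
    seed: int = 0
    n_workers: int = 1
    min_pos: int = 2
    skip_policy: str = "skip"  # "skip" | "all-data"
    class_weighting: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if self.skip_policy not in ("skip", "all-data"):
            raise ValueError(f"unknown skip_policy {self.skip_policy!r}")


def make_cv_plan(gene_ids: list[str], n_folds: int = 10, seed: int = 0) -> CvPlan:
    """Seeded uniform random partition of genes into n_folds balanced folds."""
    n = len(gene_ids)
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds {n} genes")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    # round-robin over the permutation: sizes differ by <= 1
    folds[perm] = np.arange(n) % n_folds
    return CvPlan(n_folds, seed, {g: int(f) for g, f in zip(gene_ids, folds)})


def score_tf(
    tf_id: str,
    K: KernelMatrix,
    R: RegulationMatrix,
    cv: CvPlan,
    p: SvmParams | None = None,
    min_pos: int = 2,
    skip_policy: str = "skip",
    class_weighting: bool = True,
) -> tuple[np.ndarray, str, list[str]]:
    """Out-of-fold decision scores of every gene for one TF.

    Returns ``(scores, status, events)``: status "ok", "skipped" (too few
    positives under policy "skip") or "all-data" (fallback trained on all
    genes, scores not out-of-fold).  Folds whose training split collapses
    to a single class reuse the nearest valid fold's model; the event is
    logged.
    """
    if K.gene_ids != R.gene_ids:
        raise ValueError("kernel and regulation matrix are not aligned")
    p = p or SvmParams()
    # canonicalize the working order so scores are invariant to the
    # caller's gene ordering (the SMO solver is weakly order-sensitive)
    input_genes = K.gene_ids
    perm = np.argsort(np.asarray(input_genes, dtype=object))
    genes = [input_genes[i] for i in perm]
    Kv = K.values[np.ix_(perm, perm)]
    K = type(K)(genes, Kv, K.kind, K.params)
    y = R.training_labels(tf_id)[perm]
    n_pos = int((y == 1).sum())
    events: list[str] = []
    nan = np.full(len(genes), np.nan)
    folds = cv.fold_indices(genes)
    pos_folds = {cv.fold_of_gene[g] for g, lab in zip(genes, y) if lab == 1}
    if n_pos < min_pos or len(pos_folds) < 2:
        if skip_policy == "skip":
            events.append(
                f"{tf_id}: {n_pos} positive(s) in {len(pos_folds)} fold(s); skipped"
            )
            return nan, "skipped", events
        if n_pos == 0:
            events.append(f"{tf_id}: no positives; skipped despite all-data policy")
            return nan, "skipped", events
        model = train(K.values, y, p, ids=genes, class_weighting=class_weighting)
        events.append(f"{tf_id}: all-data fallback ({n_pos} positives)")
        out = np.empty(len(genes))
        out[perm] = decision_scores(model, K.values)
        return out, "all-data", events

    scores = nan.copy()
    models: dict[int, tuple] = {}
    deferred: list[int] = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(genes)), test_idx)
        y_tr = y[train_idx]
        if len(set(y_tr)) < 2:
            deferred.append(f)
            continue
        model = train(
            K.block(train_idx, train_idx),
            y_tr,
            p,
            ids=[genes[i] for i in train_idx],
            class_weighting=class_weighting,
        )
        models[f] = (model, train_idx)
        scores[test_idx] = decision_scores(model, K.block(test_idx, train_idx))
    for f in deferred:
        # nearest valid fold, preferring earlier ones on ties
        donor = min(models, key=lambda g: (abs(g - f), g))
        model, train_idx = models[donor]
        test_idx = folds[f]
        scores[test_idx] = decision_scores(model, K.block(test_idx, train_idx))
        events.append(f"{tf_id}: fold {f} training split single-class; reused fold {donor}'s model")
    out = np.empty(len(genes))
    out[perm] = scores
    return out, "ok", events


def plan_partition(tf_ids: list[str], n_workers: int) -> ParallelPlan:
    """Split TFs into contiguous chunks whose sizes differ by at most 1."""
    if not tf_ids:
        raise ValueError("empty TF list")
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    n_chunks = min(n_workers, len(tf_ids))
    chunks = [list(c) for c in np.array_split(np.asarray(tf_ids, dtype=object), n_chunks)]
    return ParallelPlan(n_workers, chunks)


def _run_chunk(chunk, K, R, cv, cfg):
    """Stateless worker: score a chunk of TFs, emit (tf, scores, ...) records."""
    out = []
    for tf in chunk:
        t0 = time.perf_counter()
        try:
            scores, status, events = score_tf(
                tf, K, R, cv, cfg.svm, cfg.min_pos, cfg.skip_policy, cfg.class_weighting
            )
        except Exception as exc:  # noqa: BLE001 - one TF must not sink the run
            scores = np.full(len(K.gene_ids), np.nan)
            status, events = "failed", [f"{tf}: {exc!r}"]
        out.append((tf, scores, status, events, time.perf_counter() - t0))
    return out


def infer_network(
    kernel: KernelMatrix, R: RegulationMatrix, cfg: InferenceConfig | None = None
) -> ScoreMatrix:
    """Assemble the genes x TFs decision-score matrix DS.

    Builds one shared CV plan, partitions the TFs over ``cfg.n_workers``
    and collects per-TF score vectors into canonical TF order.  Output is
    independent of the worker count for a fixed seed.
    """
    cfg = cfg or InferenceConfig()
    if kernel.gene_ids != R.gene_ids:
        raise ValueError("kernel and regulation matrix are not aligned; run align_universe")
    cv = make_cv_plan(kernel.gene_ids, cfg.n_folds, cfg.seed)
    plan = plan_partition(R.tf_ids, cfg.n_workers)
    if cfg.n_workers == 1:
        chunk_results = [_run_chunk(c, kernel, R, cv, cfg) for c in plan.chunks]
    else:
        chunk_results = Parallel(n_jobs=cfg.n_workers)(
            delayed(_run_chunk)(c, kernel, R, cv, cfg) for c in plan.chunks
        )
    store = {rec[0]: rec for results in chunk_results for rec in results}
    scores = np.column_stack([store[tf][1] for tf in R.tf_ids])
    status = {tf: store[tf][2] for tf in R.tf_ids}
    events = [e for tf in R.tf_ids for e in store[tf][3]]
    timings = {tf: store[tf][4] for tf in R.tf_ids}
    n_train = len(kernel.gene_ids) - len(kernel.gene_ids) // cfg.n_folds
    ops = sum(cfg.n_folds * n_train * n_train for tf in R.tf_ids if status[tf] == "ok")
    return ScoreMatrix(
        list(kernel.gene_ids),
        list(R.tf_ids),
        scores,
        column_status=status,
        provenance={
            "seed": cfg.seed,
            "n_folds": cfg.n_folds,
            "n_workers": cfg.n_workers,
            "svm": {"C": cfg.svm.C, "epsilon": cfg.svm.epsilon, "norm": cfg.svm.norm},
            "class_weighting": cfg.class_weighting,
            "skip_policy": cfg.skip_policy,
            "events": events,
            "tf_seconds": timings,
            "op_count": ops,
        },
    )
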