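"""Seeded synthetic genomes with planted TF->target structure.

Real inputs for this kind of inference (expression compendia, PPI
networks, gold-standard regulations) are large external downloads; this
module generates desk-scale stand-ins that preserve their statistical
structure so the whole pipeline is testable end to end:

* each TF has a latent activity profile across samples (standard normal);
* its target genes' expression is a weighted sum of their regulators'
  activities plus Gaussian noise, with regulatory weights of random sign
  (the method is sign-agnostic); non-targets are pure noise;
* the PPI graph is enriched for co-regulated gene pairs (edge probability
  p_in if two genes share a regulator, p_out otherwise);
* an optional methylation layer anti-correlates with expression at
  target genes;
* the regulation matrix reveals only a fraction ``frac_known`` of the
  true edges as +1 (the rest stay -1), so hidden true edges exist to
  recover.

Everything is a deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .data_io import FeatureMatrix, GeneGraph, RegulationMatrix
from .evaluation import cv_report
from .inference import InferenceConfig, infer_network
from .kernels import KernelWeights, combine_kernels, diffusion_kernel, normalize_kernel, rbf_kernel

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "recovery_experiment"]


@dataclass
class SyntheticConfig:
    """Generator settings; defaults define the standard benchmark condition
    (300 genes x 100 samples, 10 TFs with 20 targets each, noise_sd 0.5,
    informative PPI with p_in 0.3 / p_out 0.01, 60% of edges revealed)."""

    n_genes: int = 300
    n_samples: int = 100
    n_tfs: int = 10
    targets_per_tf: int = 20
    effect_low: float = 0.75
    effect_high: float = 1.5
    noise_sd: float = 0.5
    p_in: float = 0.3
    p_out: float = 0.01
    frac_known: float = 0.6
    with_methylation: bool = False
    seed: int = 7

    def __post_init__(self) -> None:
        if self.targets_per_tf > self.n_genes:
            raise ValueError("targets_per_tf exceeds n_genes")
        if not (0 <= self.p_out <= self.p_in <= 1):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if not (0 < self.frac_known <= 1):
            raise ValueError("frac_known must be in (0, 1]")
        if not (0 < self.effect_low <= self.effect_high):
            raise ValueError("need 0 < effect_low <= effect_high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if min(self.n_genes, self.n_samples, self.n_tfs) < 1:
            raise ValueError("dimensions must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated instance: all planted TF->gene edges and
    the subset revealed to the learner, plus generator provenance."""

    true_edges: set[tuple[str, str]]
    revealed_edges: set[tuple[str, str]]
    config: SyntheticConfig

    @property
    def hidden_edges(self) -> set[tuple[str, str]]:
        return self.true_edges - self.revealed_edges


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{str(i + 1).zfill(width)}" for i in range(n)]


def _tf_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"TF{str(j + 1).zfill(width)}" for j in range(n)]


def generate(cfg: SyntheticConfig):
    """Generate (expression, methylation | None, ppi, R, truth)."""
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    tfs = _tf_names(cfg.n_tfs)

    activity = rng.standard_normal((cfg.n_tfs, cfg.n_samples))
    membership = np.zeros((cfg.n_genes, cfg.n_tfs), dtype=bool)
    weights = np.zeros((cfg.n_genes, cfg.n_tfs))
    for j in range(cfg.n_tfs):
        targets = rng.choice(cfg.n_genes, size=cfg.targets_per_tf, replace=False)
        membership[targets, j] = True
        w = rng.uniform(cfg.effect_low, cfg.effect_high, size=cfg.targets_per_tf)
        w *= rng.choice((-1.0, 1.0), size=cfg.targets_per_tf)
        weights[targets, j] = w

    is_target = membership.any(axis=1)
    expr = rng.standard_normal((cfg.n_genes, cfg.n_samples))  # background
    signal = weights @ activity
    expr[is_target] = signal[is_target] + cfg.noise_sd * rng.standard_normal(
        (int(is_target.sum()), cfg.n_samples)
    )
    expression = FeatureMatrix(genes, [f"s{i + 1}" for i in range(cfg.n_samples)], expr)

    methylation = None
    if cfg.with_methylation:
        meth = rng.standard_normal((cfg.n_genes, cfg.n_samples))
        meth[is_target] += -0.5 * expr[is_target]
        methylation = FeatureMatrix(genes, expression.sample_ids, meth)

    co_reg = (membership.astype(int) @ membership.T.astype(int)) > 0
    iu = np.triu_indices(cfg.n_genes, k=1)
    p_edge = np.where(co_reg[iu], cfg.p_in, cfg.p_out)
    draws = rng.random(len(p_edge)) < p_edge
    g = nx.Graph()
    g.add_nodes_from(genes)
    g.add_edges_from(
        (genes[i], genes[j])
        for i, j, hit in zip(iu[0], iu[1], draws)
        if hit
    )
    ppi = GeneGraph(g)

    true_edges: set[tuple[str, str]] = set()
    revealed: set[tuple[str, str]] = set()
    labels = -np.ones((cfg.n_genes, cfg.n_tfs), dtype=np.int8)
    mask = np.zeros_like(labels, dtype=bool)
    for j, tf in enumerate(tfs):
        targets = np.flatnonzero(membership[:, j])
        true_edges.update((tf, genes[i]) for i in targets)
        n_reveal = int(round(cfg.frac_known * len(targets)))
        shown = rng.choice(targets, size=n_reveal, replace=False)
        revealed.update((tf, genes[i]) for i in shown)
        labels[shown, j] = 1
        mask[shown, j] = True
    R = RegulationMatrix(genes, tfs, labels, mask)
    truth = SyntheticTruth(true_edges, revealed, cfg)
    return expression, methylation, ppi, R, truth


def truth_regulations(truth: SyntheticTruth, gene_ids, tf_ids) -> RegulationMatrix:
    """RegulationMatrix of the full planted truth, with revealed edges marked
    in ``known_mask`` so evaluation can exclude the training positives."""
    gidx = {g: i for i, g in enumerate(gene_ids)}
    tidx = {t: j for j, t in enumerate(tf_ids)}
    labels = -np.ones((len(gene_ids), len(tf_ids)), dtype=np.int8)
    mask = np.zeros_like(labels, dtype=bool)
    for tf, g in truth.true_edges:
        if g in gidx and tf in tidx:
            labels[gidx[g], tidx[tf]] = 1
    for tf, g in truth.revealed_edges:
        if g in gidx and tf in tidx:
            mask[gidx[g], tidx[tf]] = True
    return RegulationMatrix(list(gene_ids), list(tf_ids), labels, mask)


def recovery_experiment(
    cfg: SyntheticConfig | None = None,
    inf_cfg: InferenceConfig | None = None,
    use_ppi: bool = True,
    use_methylation: bool = False,
    gamma: float | str = "median",
    beta: float = 1.0,
    normalize: bool = True,
):
    """Run the full pipeline on generated data and score hidden-edge recovery.

    Builds the RBF kernel from expression (plus optional methylation RBF
    and PPI diffusion kernels), fuses them, infers the score matrix, and
    evaluates each TF's scores against the *hidden* true edges (revealed
    training positives excluded).  Returns a dict with mean out-of-fold
    AUC/AUPR over TFs, the per-TF report, the score matrix and the truth.
    """
    cfg = cfg or SyntheticConfig()
    if cfg.frac_known >= 1:
        raise ValueError("recovery needs frac_known < 1 so hidden edges exist")
    if use_methylation and not cfg.with_methylation:
        cfg = replace(cfg, with_methylation=True)
    expression, methylation, ppi, R, truth = generate(cfg)
    inf_cfg = inf_cfg or InferenceConfig(seed=cfg.seed + 1)

    ks = [rbf_kernel(expression, gamma=gamma)]
    if use_methylation:
        ks.append(rbf_kernel(methylation, gamma=gamma))
    if use_ppi:
        ks.append(diffusion_kernel(ppi, beta=beta, order=expression.gene_ids))
    if normalize:
        ks = [normalize_kernel(k) for k in ks]
    fused = combine_kernels(ks, KernelWeights.uniform(len(ks)))

    ds = infer_network(fused, R, inf_cfg)
    truth_R = truth_regulations(truth, ds.gene_ids, ds.tf_ids)
    report = cv_report(ds, truth_R, threshold=0.0, exclude_training_positives=True)
    return {
        "mean_auc": report.averages["auc"],
        "mean_aupr": report.averages["aupr"],
        "report": report,
        "scores": ds,
        "truth": truth,
    }
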