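"""Synthetic end-to-end benchmark: how well does the pipeline recover
the ground-truth network it was fed?

The benchmark simulates the full study design, runs counts →
normalisation → activity estimation → differential activity → DA
selection → forest inference → correlation network → consensus, and
scores the consensus against the scoped ground-truth edges:

* **AUPR** over all ordered non-self TF pairs, scoring a pair by its
  consensus weight (0 if absent); the reference is the network's edge
  density, i.e. the precision of a random ranking.
* **Sign accuracy** over the true-positive consensus edges: the
  fraction whose correlation-derived sign matches the ground-truth
  edge sign.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from . import activity as act
from . import grn, preprocess
from ._rng import child_seed
from .config import AnalysisConfig
from .datamodel import AUTOLOGOUS, MONOCULTURE
from .simulate import GroundTruthNet, SimulationConfig, simulate_dataset


@dataclasses.dataclass
class BenchmarkResult:
    aupr: float
    density_baseline: float
    fold_over_baseline: float
    sign_accuracy: float          # NaN if the consensus has no true positives
    n_true_edges: int
    n_da_tfs: int
    n_consensus_nodes: int
    n_consensus_edges: int
    n_true_positive_edges: int
    consensus: object             # NetworkEdgeTable
    truth: GroundTruthNet
    diff_table: pd.DataFrame
    da_set: act.DaTfSet


def score_consensus(consensus, truth: GroundTruthNet) -> dict:
    """AUPR and sign accuracy of a consensus network against ground truth."""
    tfs = truth.tfs
    true_pairs = truth.scoped_pairs(None)
    signs = truth.sign_of()
    weights = {
        (s, t): w for s, t, w in zip(
            consensus.edges["source"], consensus.edges["target"], consensus.edges["weight"]
        )
    }
    y_true, y_score = [], []
    for a in tfs:
        for b in tfs:
            if a == b:
                continue
            y_true.append((a, b) in true_pairs)
            y_score.append(weights.get((a, b), 0.0))
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score)
    baseline = y_true.mean()
    aupr = float(average_precision_score(y_true, y_score)) if y_true.any() else float("nan")
    tp = [
        row for row in consensus.edges.itertuples(index=False)
        if (row.source, row.target) in true_pairs
    ]
    signed_tp = [row for row in tp if pd.notna(getattr(row, "sign", None))]
    if signed_tp:
        correct = sum(
            1 for row in signed_tp if int(row.sign) == signs[(row.source, row.target)]
        )
        sign_acc = correct / len(signed_tp)
    else:
        sign_acc = float("nan")
    return {
        "aupr": aupr,
        "density_baseline": float(baseline),
        "fold_over_baseline": aupr / baseline if baseline > 0 else float("nan"),
        "sign_accuracy": float(sign_acc),
        "n_true_positive_edges": len(tp),
    }


def run_benchmark(
    sim_cfg: SimulationConfig | None = None, cfg: AnalysisConfig | None = None, seed: int = 0
) -> BenchmarkResult:
    """Simulate one study and run the full recovery pipeline in memory."""
    sim_cfg = sim_cfg or SimulationConfig(seed=seed)
    cfg = cfg or AnalysisConfig(seed=seed, n_trees=300)
    truth, design, _, regulon, _, counts = simulate_dataset(sim_cfg)

    filtered = preprocess.filter_genes(counts, cfg.min_count, cfg.min_count_samples)
    factors = preprocess.size_factors(filtered)
    norm = preprocess.normalise(filtered, factors)
    std = preprocess.standardise_genes(norm)
    regulon_measured = regulon.restrict_targets(std.genes)

    amat = act.activity_matrix(std, regulon_measured, min_targets=cfg.min_targets)
    diff = act.differential_activity(
        norm, design, regulon_measured, alpha=cfg.da_p, n_perm=cfg.n_perm,
        seed=child_seed(cfg.seed, "differential-activity"), min_targets=cfg.min_targets,
    )
    da = act.select_da_tfs(diff, alpha=cfg.da_p)

    sub = amat.loc[[tf for tf in amat.index if tf in set(da.tfs)]]
    decay = grn.estimate_decay(sub, design)
    nets = {
        cond: grn.infer_condition_network(
            sub, design, cond, decay.pooled,
            n_runs=cfg.n_runs, n_trees=cfg.n_trees, w_min=cfg.edge_w,
            seed=child_seed(cfg.seed, "infer", cond), tree_method=cfg.tree_method,
        )
        for cond in (AUTOLOGOUS, MONOCULTURE)
    }
    merged = grn.merge_conditions(nets[AUTOLOGOUS], nets[MONOCULTURE])
    corr = grn.merge_corr_networks([
        grn.diff_corr_network(diff, cond, da.members_in(cond), cor_min=cfg.edge_cor)
        for cond in (AUTOLOGOUS, MONOCULTURE)
    ])
    cons = grn.consensus(merged, corr)

    metrics = score_consensus(cons, truth)
    return BenchmarkResult(
        aupr=metrics["aupr"],
        density_baseline=metrics["density_baseline"],
        fold_over_baseline=metrics["fold_over_baseline"],
        sign_accuracy=metrics["sign_accuracy"],
        n_true_edges=len(truth),
        n_da_tfs=len(da),
        n_consensus_nodes=len(cons.nodes),
        n_consensus_edges=len(cons),
        n_true_positive_edges=metrics["n_true_positive_edges"],
        consensus=cons,
        truth=truth,
        diff_table=diff,
        da_set=da,
    )
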