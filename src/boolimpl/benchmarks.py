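"""Planted-truth benchmark measurements for the synthetic pipeline.

Each function runs a pipeline stage on generated data and scores the
result against the generator's ground truth: implication-edge recovery
and cluster agreement on the planted network, false-call calibration on
independent null genes, and signature recovery across training trios.
These power both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import implication as impl
from . import network as net
from . import synthetic as syn
from . import training as tr
from .stepminer import discretize, threshold_matrix

__all__ = [
    "network_recovery",
    "null_call_rate",
    "signature_trial",
]

_CONVERSE = net._CONVERSE


def network_recovery(seed: int, config: syn.SynthConfig | None = None):
    """Run thresholds -> states -> pair scan -> clustering on the planted
    network benchmark and score against truth.

    Returns ``(edge_recovery, symmetric_confusions, ari)``: the fraction
    of planted gene-level relationships recovered with the correct type,
    the number of planted symmetric edges recovered as the *wrong*
    symmetric type (equivalent vs opposite confusion), and the adjusted
    Rand index of the cluster partition against block membership over
    genes passing the dynamic-range filter.
    """
    config = config or syn.network_benchmark_config()
    matrix, truth = syn.simulate_cohort(config, seed=seed)
    est = net.BooleanImplicationNetwork().fit(matrix.T)
    found = {
        (r.gene_a, r.gene_b): r.relationship for r in est.edges_.itertuples()
    }
    found.update(
        {(b, a): _CONVERSE[rel] for (a, b), rel in list(found.items())}
    )
    planted = truth.planted_gene_edges()
    hits = 0
    confusions = 0
    symmetric = {impl.Relationship.EQUIVALENT, impl.Relationship.OPPOSITE}
    for r in planted.itertuples():
        got = found.get((r.gene_a, r.gene_b))
        if got == r.relationship:
            hits += 1
        elif r.relationship in symmetric and got in symmetric:
            confusions += 1
    labels = est.cluster_labels_()
    blocks = truth.block_membership.loc[labels.index]
    informative = blocks != "BG"
    ari = adjusted_rand_score(blocks[informative], labels[informative])
    return hits / len(planted), confusions, float(ari)


def null_call_rate(
    n_pairs: int = 200,
    n_samples: int = 200,
    n_seeds: int = 50,
    seed: int = 0,
    s_thr: float = impl.DEFAULT_S_THR,
    p_thr: float = impl.DEFAULT_P_THR,
) -> float:
    """Fraction of independent balanced-ternary gene pairs called non-NONE.

    Under independence the sparsity statistic is approximately standard
    normal, so at the default thresholds almost no pair should be called.
    """
    calls = 0
    total = 0
    children = np.random.SeedSequence(seed).spawn(n_seeds)
    for child in children:
        states = syn.random_ternary_states(
            2 * n_pairs, n_samples, seed=child.generate_state(1)[0] % (2**31)
        )
        x = states.to_numpy()
        a = x[0::2]
        b = x[1::2]
        low_a, high_a = a == -1, a == 1
        low_b, high_b = b == -1, b == 1
        a00 = (low_a & low_b).sum(axis=1)
        a01 = (low_a & high_b).sum(axis=1)
        a10 = (high_a & low_b).sum(axis=1)
        a11 = (high_a & high_b).sum(axis=1)
        codes = impl._classify_codes(a00, a01, a10, a11, s_thr, p_thr)
        calls += int((codes != 0).sum())
        total += n_pairs
    return calls / total


def signature_trial(seed: int, config: syn.SynthConfig | None = None):
    """One full training run on a synthetic trio plus held-out evaluation.

    Returns a dict with the signature sizes, gene-level precision against
    the planted signature, and the composite ROC-AUC on an independent
    held-out cohort.
    """
    config = config or syn.SynthConfig()
    datasets, truths = syn.simulate_training_trio(config, seed=seed)
    truth = truths[0]
    primary, _ = datasets[0]
    network = net.BooleanImplicationNetwork().fit(primary.T)
    selected = tr.select_clusters(network.clusters_, datasets, positive=1)
    model = tr.train_signature(selected, datasets, positive=1)
    up_true = set(truth.signature_up)
    down_true = set(truth.signature_down)
    n_correct = sum(g in up_true for g in model.up_genes) + sum(
        g in down_true for g in model.down_genes
    )
    precision = n_correct / (len(model.up_genes) + len(model.down_genes))
    held_matrix, held_truth = syn.simulate_cohort(
        config, seed=seed + 500_000, n_samples=150, offset=0.25, noise_mult=1.1
    )
    report = tr.evaluate_model(
        model, held_matrix, held_truth.labels, positive=1, keep_scores=True
    )
    return {
        "n_up": len(model.up_genes),
        "n_down": len(model.down_genes),
        "precision": precision,
        "holdout_auc": report.roc_auc,
        "holdout_p": report.p_value,
        "scores": report.scores,
        "labels": held_truth.labels,
        "model": model,
        "datasets": datasets,
        "truth": truth,
    }
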