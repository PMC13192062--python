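"""End-to-end pipeline runner with reproducibility manifest.

``run_pipeline`` chains every stage on a synthetic training trio
(simulate -> fit thresholds -> discretize -> implications -> network ->
train -> score -> evaluate), writing each stage's artifact as text into a
run directory together with a manifest recording the configuration, seed,
package versions and a checksum per artifact.  Re-running with the same
configuration reproduces identical text outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import implication as impl
from . import io as bio
from . import network as net
from . import scoring, synthetic, training
from .stepminer import discretize, threshold_matrix, DEFAULT_MARGIN

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("boolimpl")

@dataclass
class RunConfig:
    """Stage parameters of one pipeline run (defaults = printed parameters)."""

    margin: float = DEFAULT_MARGIN
    s_thr: float = impl.DEFAULT_S_THR
    p_thr: float = impl.DEFAULT_P_THR
    min_frac: float = impl.DEFAULT_MIN_FRAC
    jaccard_threshold: float = net.DEFAULT_JACCARD
    n_reps: int = net.DEFAULT_N_REPS
    majority: float = net.DEFAULT_MAJORITY
    auc_up: float = training.DEFAULT_AUC_UP
    auc_down: float = training.DEFAULT_AUC_DOWN
    k_cap: int = training.DEFAULT_K_CAP
    n_clusters: int = training.DEFAULT_N_CLUSTERS
    n_perm: int = 3
    seed: int = 1729
    synth: dict = field(default_factory=dict)  # SynthConfig overrides

    def validate(self) -> "RunConfig":
        checks = [
            ("margin", self.margin >= 0),
            ("s_thr", self.s_thr > 0),
            ("p_thr", 0 < self.p_thr <= 1),
            ("min_frac", 0 <= self.min_frac < 1),
            ("jaccard_threshold", 0 <= self.jaccard_threshold <= 1),
            ("majority", 0 < self.majority <= 1),
            ("auc_up", 0 <= self.auc_up <= 1),
            ("auc_down", 0 <= self.auc_down <= 1),
            ("k_cap", self.k_cap >= 1),
            ("n_reps", self.n_reps >= 1),
            ("n_clusters", self.n_clusters >= 1),
            ("n_perm", self.n_perm >= 1),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ValueError(f"invalid configuration value(s): {bad}")
        return self

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**mapping).validate()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_states(states: pd.DataFrame, path: Path) -> None:
    bio.write_states(states, path)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage on the default synthetic trio; return the manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "version": __version__,
        "stages": {},
    }
    artifacts: dict[str, list[Path]] = {}
    stage = "simulate"
    try:
        synth_cfg = synthetic.SynthConfig(**config.synth)
        datasets, truths = synthetic.simulate_training_trio(
            synth_cfg, seed=config.seed
        )
        paths = []
        for i, (matrix, labels) in enumerate(datasets, start=1):
            mp = out / f"cohort{i}.tsv"
            lp = out / f"cohort{i}.labels.tsv"
            bio.write_matrix(matrix, mp)
            bio.write_labels(labels, lp)
            paths += [mp, lp]
        tp = out / "truth.json"
        truth = truths[0]
        tp.write_text(json.dumps({
            "blocks": {
                b: truth.block_membership.index[
                    truth.block_membership == b
                ].tolist()
                for b in truth.block_membership.unique()
            },
            "block_edges": [list(e) for e in truth.block_edges],
            "signature_up": truth.signature_up,
            "signature_down": truth.signature_down,
        }, indent=1))
        paths.append(tp)
        artifacts[stage] = paths
        primary, primary_labels = datasets[0]

        stage = "fit-thresholds"
        thresholds = threshold_matrix(primary)
        p = out / "thresholds.tsv"
        thresholds.to_frame().to_csv(p, sep="\t")
        artifacts[stage] = [p]

        stage = "discretize"
        states = discretize(primary, thresholds, margin=config.margin)
        p = out / "states.tsv"
        _write_states(states, p)
        artifacts[stage] = [p]

        stage = "implications"
        kept = impl.dynamic_range_filter(states, config.min_frac)
        edges = impl.all_pairs(states.loc[kept], config.s_thr, config.p_thr)
        p = out / "edges.tsv"
        edges.to_csv(p, sep="\t", index=False)
        artifacts[stage] = [p]

        stage = "network"
        eq = net.build_equivalence_graph(edges)
        clusters = net.cluster_by_pruned_mst(
            eq, config.jaccard_threshold, all_genes=kept, n_reps=config.n_reps
        )
        cbin_graph = net.cbin(
            clusters, states.loc[kept], config.s_thr, config.p_thr,
            n_reps=config.n_reps, majority=config.majority,
            jaccard_threshold=config.jaccard_threshold,
        )
        p = out / "cbin.json"
        net.write_cbin_json(cbin_graph, p)
        g = out / "cbin.graphml"
        net.write_cbin_graphml(cbin_graph, g)
        artifacts[stage] = [p, g]

        stage = "train"
        selected = training.select_clusters(
            clusters, datasets, positive=1, n_clusters=config.n_clusters
        )
        model = training.train_signature(
            selected, datasets, positive=1,
            auc_up=config.auc_up, auc_down=config.auc_down,
            k_cap=config.k_cap,
        )
        p = out / "model.tsv"
        bio.write_signature(model.to_frame(), p)
        artifacts[stage] = [p]

        stage = "score"
        normalized = scoring.normalize(primary, thresholds)
        scores = scoring.composite(normalized, model.gene_sets())
        p = out / "scores.tsv"
        ordered = scores.loc[scoring.sample_ordering(scores)].rename("score")
        ordered.index.name = "sample_id"
        ordered.to_csv(p, sep="\t")
        artifacts[stage] = [p]

        stage = "evaluate"
        reports = {}
        for i, (matrix, labels) in enumerate(datasets, start=1):
            rep = training.evaluate_model(
                model, matrix, labels, positive=1, keep_scores=False
            )
            reports[f"cohort{i}"] = {
                "roc_auc": rep.roc_auc, "t": rep.t_stat, "df": rep.df,
                "p": rep.p_value, "n_pos": rep.n_pos, "n_neg": rep.n_neg,
            }
        p = out / "evaluation.json"
        p.write_text(json.dumps(reports, indent=1))
        artifacts[stage] = [p]
    except Exception as exc:
        for paths in artifacts.values():
            for path in paths:
                if path.exists():
                    path.rename(path.with_suffix(path.suffix + ".partial"))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for name, paths in artifacts.items():
        manifest["stages"][name] = {
            str(path.name): _checksum(path) for path in paths
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline complete: %d stages in %s", len(artifacts), out)
    return manifest
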