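"""Synthetic expression cohorts with planted Boolean structure.

The generator emulates the statistical structure Boolean implication
analysis assumes in real transcriptomes, with machine-readable ground
truth for every pipeline stage:

* *logic blocks* — groups of equivalent genes sharing a latent Boolean
  state per sample; root-block states are Bernoulli draws and child
  blocks follow a planted implication edge in a DAG, with an optional
  violation (flip) rate epsilon;
* *signature blocks* — an up block whose latent state equals the class
  label and a down block equal to its complement (an extreme shift of
  the Bernoulli rates between cases and controls, optionally softened
  by a flip probability), giving signature genes a clean location shift
  of ``delta`` between classes: case values N(mu + delta, sigma^2) vs
  control N(mu, sigma^2), hence per-gene ROC-AUC Phi(delta/(sigma*sqrt2))
  in closed form when the flip probability is 0;
* *background genes* — unimodal, low-dynamic-range noise genes that the
  5% dynamic-range filter should remove;
* *cohorts* — multiple datasets sharing blocks and signature but with
  their own additive offset, noise multiplier and sample size.

Expression of a gene in Boolean state 0/1 is N(mu_lo, sigma^2) /
N(mu_hi, sigma^2) plus the cohort offset; the true threshold is the mode
midpoint.  All randomness flows from one master seed through named
independent streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .implication import Relationship

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "simulate_latent_states",
    "emit_expression",
    "simulate_cohort",
    "simulate_training_trio",
    "simulate_cohorts",
    "random_ternary_states",
    "network_benchmark_config",
]

_ASYM = {
    # relationship -> (parent state that constrains, forced child state)
    Relationship.HIHI: (1, 1),
    Relationship.LOLO: (0, 0),
    Relationship.LOHI: (0, 1),
    Relationship.HILO: (1, 0),
}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic benchmark.

    Defaults are the desk-scale conditions every stage is tested under:
    six logic blocks of bimodal genes (modes 2/6, sigma 0.5) wired by one
    edge of each implication type, 30 up / 30 down signature genes with a
    class shift of delta = 2 sigma, and unimodal background genes whose
    spread is small against the 0.5 discretization margin.
    """

    n_samples: int = 300
    block_sizes: tuple = (10, 8, 8, 6, 6, 5)
    logic_edges: tuple = (
        (0, 1, Relationship.HIHI),
        (0, 2, Relationship.LOLO),
        (1, 3, Relationship.LOHI),
        (2, 4, Relationship.HILO),
        (3, 5, Relationship.OPPOSITE),
    )
    epsilon: float = 0.0  # implication violation (flip) rate
    f_hi: float = 0.5  # Bernoulli rate of root-block high states
    mu_lo: float = 2.0
    mu_hi: float = 6.0
    sigma: float = 0.5
    n_sig_up: int = 30
    n_sig_down: int = 30
    delta: float = 1.0  # class shift of signature genes (2 sigma)
    mu_sig: float = 4.0  # signature low-mode mean; high mode = mu_sig + delta
    signature_flip: float = 0.0
    case_frac: float = 0.5
    noise_rho: float = 0.5  # within-block shared fraction of noise variance
    n_background: int = 60
    mu_bg: float = 4.0
    sigma_bg: float = 0.25
    cohort_offsets: tuple = (0.0, 0.5, -0.4)
    cohort_noise: tuple = (1.0, 1.2, 0.9)
    cohort_sizes: tuple = (400, 300, 240)

    def __post_init__(self):
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must lie in [0, 1)")
        if not 0 < self.case_frac < 1:
            raise ValueError("case_frac must lie in (0, 1)")

    @property
    def block_names(self) -> list:
        names = [f"B{i + 1}" for i in range(len(self.block_sizes))]
        if self.n_sig_up:
            names.append("UP")
        if self.n_sig_down:
            names.append("DN")
        return names


def network_benchmark_config(**overrides) -> SynthConfig:
    """The planted-network benchmark: logic blocks and background only.

    Signature blocks are class-driven and belong to the signature
    benchmark; the network-recovery conditions are the six bimodal logic
    blocks (modes 2/6, sigma 0.5, epsilon 0, n = 300).
    """
    return replace(SynthConfig(), n_sig_up=0, n_sig_down=0, **overrides)


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed the way each stage needs it."""

    block_membership: pd.Series  # gene -> block name ("BG" for background)
    true_thresholds: pd.Series  # NaN for background genes
    true_states: pd.DataFrame  # genes x samples in {0,1} (background NaN)
    block_edges: list  # (block_a, block_b, relationship)
    signature_up: list
    signature_down: list
    labels: pd.Series  # sample -> 0 (control) / 1 (case)

    def planted_gene_edges(self) -> pd.DataFrame:
        """Gene-level planted relationships: within-block equivalences and
        every cross pair of directly connected blocks."""
        by_block: dict = {}
        for g, b in self.block_membership.items():
            by_block.setdefault(b, []).append(g)
        rows = []
        for block, genes in by_block.items():
            if block == "BG":
                continue
            for i, ga in enumerate(genes):
                for gb in genes[i + 1:]:
                    rows.append((ga, gb, Relationship.EQUIVALENT))
        for ba, bb, rel in self.block_edges:
            for ga in by_block.get(ba, ()):
                for gb in by_block.get(bb, ()):
                    rows.append((ga, gb, rel))
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "relationship"])


def _master(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _child_streams(seed, names):
    """Named independent generators derived from one master seed."""
    children = _master(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _logic_dag(config: SynthConfig) -> nx.DiGraph:
    dag = nx.DiGraph()
    dag.add_nodes_from(range(len(config.block_sizes)))
    for a, b, rel in config.logic_edges:
        if rel not in _ASYM and rel not in (
            Relationship.EQUIVALENT, Relationship.OPPOSITE
        ):
            raise ValueError(f"unknown logic edge type {rel!r}")
        dag.add_edge(a, b, relationship=rel)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("logic edges must form a DAG over blocks")
    for b in dag.nodes:
        if dag.in_degree(b) > 1:
            raise ValueError(f"block {b} has multiple logic parents")
    return dag


def simulate_latent_states(
    config: SynthConfig, n_samples: int | None = None, seed: int = 0
):
    """Latent Boolean block states and class labels for one cohort.

    Root blocks draw Bernoulli(f_hi); each child block copies the state
    its planted implication forces when the parent constrains it (an
    unconstrained child draws Bernoulli(f_hi)), then flips independently
    with probability epsilon.  Signature blocks track the class label
    (up: state = label, down: complement), flipped with probability
    ``signature_flip``.

    Returns ``(block_states, labels)``: a blocks x samples 0/1 DataFrame
    and a 0/1 Series (1 = case).
    """
    n = config.n_samples if n_samples is None else n_samples
    rng = _child_streams(seed, ["labels", "states", "flips"])
    labels = (rng["labels"].random(n) < config.case_frac).astype(np.int8)
    dag = _logic_dag(config)
    states = {}
    for block in nx.topological_sort(dag):
        parents = list(dag.predecessors(block))
        if not parents:
            states[block] = (rng["states"].random(n) < config.f_hi).astype(np.int8)
            continue
        parent = parents[0]
        rel = dag.edges[parent, block]["relationship"]
        ps = states[parent]
        if rel == Relationship.EQUIVALENT:
            child = ps.copy()
        elif rel == Relationship.OPPOSITE:
            child = 1 - ps
        else:
            trigger, forced = _ASYM[rel]
            free = (rng["states"].random(n) < config.f_hi).astype(np.int8)
            child = np.where(ps == trigger, forced, free).astype(np.int8)
        flips = rng["flips"].random(n) < config.epsilon
        states[block] = np.where(flips, 1 - child, child).astype(np.int8)
    rows = {f"B{b + 1}": states[b] for b in sorted(states)}
    if config.n_sig_up:
        up = labels.copy()
        flips = rng["flips"].random(n) < config.signature_flip
        rows["UP"] = np.where(flips, 1 - up, up).astype(np.int8)
    if config.n_sig_down:
        down = 1 - labels
        flips = rng["flips"].random(n) < config.signature_flip
        rows["DN"] = np.where(flips, 1 - down, down).astype(np.int8)
    sample_ids = [f"s{i + 1:04d}" for i in range(n)]
    block_states = pd.DataFrame(rows, index=sample_ids).T
    return block_states, pd.Series(labels, index=sample_ids, name="label")


def _block_modes(config: SynthConfig, block: str):
    if block in ("UP", "DN"):
        return config.mu_sig, config.mu_sig + config.delta
    return config.mu_lo, config.mu_hi


def emit_expression(
    block_states: pd.DataFrame,
    labels: pd.Series,
    config: SynthConfig,
    seed: int = 0,
    offset: float = 0.0,
    noise_mult: float = 1.0,
):
    """Expression matrix and ground truth from latent block states.

    Every gene of a block copies the block state and draws
    N(mu_state, (sigma * noise_mult)^2) + offset; background genes draw
    N(mu_bg, (sigma_bg * noise_mult)^2) + offset.  Genes of one block are
    co-regulated: a fraction ``noise_rho`` of their noise variance is a
    latent per-sample block factor shared by the block's genes (residual
    correlation, as co-expressed genes show), the rest is private.  The
    per-gene marginal distribution is unchanged by the split.
    """
    rng = _child_streams(seed, ["noise"])["noise"]
    n = block_states.shape[1]
    sizes = dict(zip([f"B{i + 1}" for i in range(len(config.block_sizes))],
                     config.block_sizes))
    if config.n_sig_up:
        sizes["UP"] = config.n_sig_up
    if config.n_sig_down:
        sizes["DN"] = config.n_sig_down
    gene_ids, membership, thresholds, state_rows, value_rows = [], [], [], [], []
    rho = config.noise_rho
    if not 0 <= rho < 1:
        raise ValueError("noise_rho must lie in [0, 1)")
    for block in block_states.index:
        mu_pair = _block_modes(config, block)
        s = block_states.loc[block].to_numpy()
        mu = np.where(s == 1, mu_pair[1], mu_pair[0])
        sd = config.sigma * noise_mult
        shared = rng.normal(0.0, sd * np.sqrt(rho), n)
        for g in range(sizes[block]):
            gid = f"{block}_g{g + 1:03d}"
            gene_ids.append(gid)
            membership.append(block)
            thresholds.append((mu_pair[0] + mu_pair[1]) / 2.0 + offset)
            state_rows.append(s.astype(float))
            value_rows.append(
                mu + shared
                + rng.normal(0.0, sd * np.sqrt(1.0 - rho), n)
                + offset
            )
    for g in range(config.n_background):
        gid = f"BG_g{g + 1:03d}"
        gene_ids.append(gid)
        membership.append("BG")
        thresholds.append(np.nan)
        state_rows.append(np.full(n, np.nan))
        value_rows.append(
            rng.normal(config.mu_bg, config.sigma_bg * noise_mult, n) + offset
        )
    matrix = pd.DataFrame(
        np.asarray(value_rows), index=gene_ids, columns=block_states.columns
    )
    truth = GroundTruth(
        block_membership=pd.Series(membership, index=gene_ids, name="block"),
        true_thresholds=pd.Series(thresholds, index=gene_ids, name="threshold"),
        true_states=pd.DataFrame(
            np.asarray(state_rows), index=gene_ids, columns=block_states.columns
        ),
        block_edges=_planted_block_edges(config),
        signature_up=[g for g, b in zip(gene_ids, membership) if b == "UP"],
        signature_down=[g for g, b in zip(gene_ids, membership) if b == "DN"],
        labels=labels,
    )
    return matrix, truth


def _planted_block_edges(config: SynthConfig) -> list:
    edges = [
        (f"B{a + 1}", f"B{b + 1}", rel) for a, b, rel in config.logic_edges
    ]
    if config.n_sig_up and config.n_sig_down and config.signature_flip == 0:
        edges.append(("UP", "DN", Relationship.OPPOSITE))
    return edges


def simulate_cohort(
    config: SynthConfig,
    seed: int = 0,
    n_samples: int | None = None,
    offset: float = 0.0,
    noise_mult: float = 1.0,
):
    """One cohort: ``(matrix, labels, truth)``. Deterministic in seed."""
    state_seed, noise_seed = _master(seed).spawn(2)
    block_states, labels = simulate_latent_states(
        config, n_samples=n_samples, seed=state_seed
    )
    matrix, truth = emit_expression(
        block_states, labels, config,
        seed=noise_seed, offset=offset, noise_mult=noise_mult,
    )
    return matrix, truth


def simulate_cohorts(config: SynthConfig, n_cohorts: int, seed: int = 0):
    """Several cohorts sharing blocks and signature but with their own
    offset, noise multiplier and sample size (cycled from the config)."""
    out = []
    children = _master(seed).spawn(n_cohorts)
    for i in range(n_cohorts):
        offset = config.cohort_offsets[i % len(config.cohort_offsets)]
        noise = config.cohort_noise[i % len(config.cohort_noise)]
        size = config.cohort_sizes[i % len(config.cohort_sizes)]
        matrix, truth = simulate_cohort(
            config,
            seed=children[i],
            n_samples=size,
            offset=offset,
            noise_mult=noise,
        )
        matrix.columns = [f"c{i + 1}_{s}" for s in matrix.columns]
        truth.labels.index = matrix.columns
        truth.true_states.columns = matrix.columns
        out.append((matrix, truth))
    return out


def simulate_training_trio(config: SynthConfig, seed: int = 0):
    """Three cohorts sharing the signature: ``([(matrix, labels)] * 3, truths)``."""
    cohorts = simulate_cohorts(config, 3, seed=seed)
    datasets = [(m, t.labels) for m, t in cohorts]
    return datasets, [t for _, t in cohorts]


def random_ternary_states(
    n_genes: int,
    n_samples: int,
    p_low: float = 0.45,
    p_high: float = 0.45,
    seed: int = 0,
) -> pd.DataFrame:
    """Independent balanced ternary genes: the null for calibration checks."""
    rng = np.random.default_rng(seed)
    u = rng.random((n_genes, n_samples))
    states = np.zeros((n_genes, n_samples), dtype=np.int8)
    states[u < p_low] = -1
    states[u > 1 - p_high] = 1
    return pd.DataFrame(
        states,
        index=[f"g{i + 1}" for i in range(n_genes)],
        columns=[f"s{j + 1}" for j in range(n_samples)],
    )
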