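"""Training and evaluation of Boolean composite-score signatures.

A signature is trained on several case/control cohorts sharing gene ids:
clusters of the Boolean implication network are ranked by how well their
average composite score separates the classes; within the selected
clusters, genes must discriminate in *every* training cohort (per-gene
ROC-AUC > 0.6 for upregulated candidates, < 0.3 for downregulated, with
"higher expression => disease" orientation); candidates are ranked by the
absolute Welch t-statistic on the primary cohort, and the top 20 of each
direction enter the model with weights +1 / -1.  A model is evaluated on
a cohort by its composite score's ROC-AUC and a Welch two-sample t-test
between classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from . import network as net
from . import scoring
from .stepminer import threshold_matrix, DEFAULT_MARGIN

__all__ = [
    "SignatureModel",
    "EvalReport",
    "gene_auc",
    "welch_t",
    "bh_fdr",
    "select_clusters",
    "train_signature",
    "evaluate_model",
    "BooleanSignatureClassifier",
]

DEFAULT_AUC_UP = 0.6
DEFAULT_AUC_DOWN = 0.3
DEFAULT_K_CAP = 20
DEFAULT_N_CLUSTERS = 3


@dataclass
class SignatureModel:
    """Up/down gene lists with +1/-1 weights and training provenance."""

    up_genes: list
    down_genes: list
    source_clusters: list = field(default_factory=list)
    aucs: pd.DataFrame | None = None  # candidate genes x training cohorts
    t_stats: pd.Series | None = None  # ranking statistic (primary cohort)

    def gene_sets(self):
        sets = []
        if self.up_genes:
            sets.append((list(self.up_genes), 1.0))
        if self.down_genes:
            sets.append((list(self.down_genes), -1.0))
        return sets

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.up_genes) + list(self.down_genes),
                "weight": [1] * len(self.up_genes) + [-1] * len(self.down_genes),
            }
        )

    @classmethod
    def from_frame(cls, table: pd.DataFrame) -> "SignatureModel":
        up = table.loc[table["weight"] > 0, "gene_id"].tolist()
        down = table.loc[table["weight"] < 0, "gene_id"].tolist()
        return cls(up_genes=up, down_genes=down)


@dataclass
class EvalReport:
    """Discrimination report for a model on one cohort."""

    roc_auc: float
    t_stat: float
    df: float
    p_value: float
    n_pos: int
    n_neg: int
    scores: pd.Series | None = None
    degraded: bool = False  # a whole signature direction was missing
    fdr_q: float | None = None


def _binarize(labels, positive) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool and positive is None:
        return labels
    if positive is None:
        raise ValueError("positive class must be given for non-boolean labels")
    return labels == positive


def gene_auc(values, labels, positive=None) -> float:
    """ROC-AUC of one gene's values for the positive (disease) class.

    Uses the rank-sum identity AUC = U / (n1 * n0) with midranks, so tied
    values contribute 1/2; orientation is "higher value => positive".
    """
    y = _binarize(labels, positive)
    x = np.asarray(values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("values and labels differ in length")
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = sps.rankdata(x)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def welch_t(x, y):
    """Welch's two-sample t-test (unpaired, unequal variance).

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of
    freedom and a two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _dataset_normalized(matrix: pd.DataFrame, thresholds=None) -> pd.DataFrame:
    if thresholds is None:
        thresholds = threshold_matrix(matrix)
    return scoring.normalize(matrix, thresholds)


def select_clusters(
    clusters,
    training: list[tuple[pd.DataFrame, pd.Series]],
    positive=None,
    n_clusters: int = DEFAULT_N_CLUSTERS,
) -> list:
    """Rank clusters by class-separating ability of their average score.

    For each training cohort the cluster-average composite score (equal
    +1 weight on the cluster's genes) is computed on that cohort's own
    thresholds, and the cluster's merit is the mean over cohorts of
    |AUC - 0.5|.  Returns the ``n_clusters`` best clusters (all of them
    when fewer exist).

    ``clusters`` may be a list of :class:`~boolimpl.network.Cluster` or a
    fitted :class:`~boolimpl.network.BooleanImplicationNetwork`.
    """
    if isinstance(clusters, net.BooleanImplicationNetwork):
        clusters = clusters.clusters_
    if not training:
        raise ValueError("at least one training cohort is required")
    merits = []
    normalized = [
        (_dataset_normalized(m), _binarize(lab.loc[m.columns], positive))
        for m, lab in training
    ]
    for cluster in clusters:
        seps = []
        for norm, y in normalized:
            present = [g for g in cluster.members if g in norm.index]
            if not present:
                continue
            score = norm.loc[present].mean(axis=0).to_numpy()
            seps.append(abs(gene_auc(score, y) - 0.5))
        merits.append(np.mean(seps) if seps else 0.0)
    order = np.argsort([-m for m in merits], kind="stable")
    return [clusters[i] for i in order[:n_clusters]]


def train_signature(
    clusters,
    training: list[tuple[pd.DataFrame, pd.Series]],
    positive=None,
    auc_up: float = DEFAULT_AUC_UP,
    auc_down: float = DEFAULT_AUC_DOWN,
    k_cap: int = DEFAULT_K_CAP,
    rank_dataset_index: int = 0,
) -> SignatureModel:
    """Train the +1/-1 composite signature from selected clusters.

    Candidate up genes must have AUC > ``auc_up`` in *every* training
    cohort and candidate down genes AUC < ``auc_down`` in every cohort
    (same "higher => disease" orientation, no flipping).  Candidates are
    ranked by |Welch t| on the cohort at ``rank_dataset_index`` (the
    primary training set) and the top ``k_cap`` per direction retained.
    """
    if isinstance(clusters, net.BooleanImplicationNetwork):
        clusters = clusters.clusters_
    if not training:
        raise ValueError("at least one training cohort is required")
    candidate_genes = sorted(
        {g for c in clusters for g in c.members}, key=str
    )
    if not candidate_genes:
        raise ValueError("selected clusters contain no genes")
    aucs = {}
    survivors_up, survivors_down = [], []
    per_cohort_up, per_cohort_down = [], []
    for idx, (matrix, labels) in enumerate(training):
        y = _binarize(labels.loc[matrix.columns], positive)
        present = [g for g in candidate_genes if g in matrix.index]
        values = matrix.loc[present].to_numpy()
        col = pd.Series(
            [gene_auc(row, y) for row in values], index=present, name=f"cohort{idx}"
        )
        aucs[f"cohort{idx}"] = col
        per_cohort_up.append(int((col > auc_up).sum()))
        per_cohort_down.append(int((col < auc_down).sum()))
    auc_table = pd.DataFrame(aucs)
    up_mask = (auc_table > auc_up).all(axis=1)
    down_mask = (auc_table < auc_down).all(axis=1)
    survivors_up = auc_table.index[up_mask].tolist()
    survivors_down = auc_table.index[down_mask].tolist()
    if not survivors_up or not survivors_down:
        raise ValueError(
            "no candidate genes survive the AUC filters in some direction; "
            f"per-cohort survivors up={per_cohort_up}, down={per_cohort_down}"
        )
    rank_matrix, rank_labels = training[rank_dataset_index]
    y = _binarize(rank_labels.loc[rank_matrix.columns], positive)
    t_stats = {}
    for g in survivors_up + survivors_down:
        v = rank_matrix.loc[g].to_numpy(dtype=float)
        t, _, _ = welch_t(v[y], v[~y])
        t_stats[g] = t
    t_series = pd.Series(t_stats, name="t")

    def top(genes):
        ranked = sorted(genes, key=lambda g: (-abs(t_series[g]), str(g)))
        return ranked[:k_cap]

    return SignatureModel(
        up_genes=top(survivors_up),
        down_genes=top(survivors_down),
        source_clusters=[c.id for c in clusters],
        aucs=auc_table,
        t_stats=t_series,
    )


def evaluate_model(
    model: SignatureModel,
    matrix: pd.DataFrame,
    labels: pd.Series,
    positive=None,
    thresholds: pd.Series | None = None,
    keep_scores: bool = True,
) -> EvalReport:
    """Composite-score ROC-AUC and Welch t-test of a model on one cohort.

    Thresholds default to StepMiner fits on the evaluation cohort itself
    (per-dataset normalization).  If an entire signature direction is
    absent from the matrix, the report is flagged ``degraded`` and the
    remaining direction is used alone.
    """
    present = set(matrix.index)
    up = [g for g in model.up_genes if g in present]
    down = [g for g in model.down_genes if g in present]
    if not up and not down:
        raise ValueError("no signature gene overlaps the matrix")
    degraded = (bool(model.up_genes) and not up) or (
        bool(model.down_genes) and not down
    )
    sets = []
    if up:
        sets.append((up, 1.0))
    if down:
        sets.append((down, -1.0))
    normalized = _dataset_normalized(matrix, thresholds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = scoring.composite(normalized, sets)
    y = _binarize(labels.loc[scores.index], positive)
    auc = gene_auc(scores.to_numpy(), y)
    t, df, p = welch_t(scores.to_numpy()[y], scores.to_numpy()[~y])
    return EvalReport(
        roc_auc=auc,
        t_stat=t,
        df=df,
        p_value=p,
        n_pos=int(y.sum()),
        n_neg=int((~y).sum()),
        scores=scores if keep_scores else None,
        degraded=degraded,
    )


class BooleanSignatureClassifier(ClassifierMixin, BaseEstimator):
    """Case/control classifier built on a Boolean implication network.

    scikit-learn style: ``X`` is samples x genes (a DataFrame with gene
    ids as columns lets the signature transfer across cohorts), ``y`` the
    class labels.  ``fit`` builds the implication network on the primary
    cohort, selects the most discriminative clusters, applies the
    per-cohort AUC filters and t-ranking, and stores the +1/-1 signature.
    ``decision_function`` returns the composite score (thresholds fitted
    on the scored data itself); ``predict`` thresholds it at 0.

    Parameters
    ----------
    positive_class : label or None
        Label treated as disease; defaults to ``classes_[1]``.
    n_clusters, auc_up, auc_down, k_cap : signature-training parameters.
    margin, s_thr, p_thr, min_frac, jaccard_threshold, n_reps, majority :
        forwarded to :class:`~boolimpl.network.BooleanImplicationNetwork`.

    Attributes
    ----------
    classes_ : ndarray of the two class labels.
    network_ : the fitted BooleanImplicationNetwork (primary cohort).
    signature_ : the trained SignatureModel.
    up_genes_, down_genes_ : the signature gene lists.
    """

    def __init__(
        self,
        positive_class=None,
        n_clusters: int = DEFAULT_N_CLUSTERS,
        auc_up: float = DEFAULT_AUC_UP,
        auc_down: float = DEFAULT_AUC_DOWN,
        k_cap: int = DEFAULT_K_CAP,
        rank_cohort: int = 0,
        margin: float = DEFAULT_MARGIN,
        s_thr: float = 3.0,
        p_thr: float = 0.1,
        min_frac: float = 0.05,
        jaccard_threshold: float = 0.5,
        n_reps: int = 3,
        majority: float = 0.67,
    ):
        self.positive_class = positive_class
        self.n_clusters = n_clusters
        self.auc_up = auc_up
        self.auc_down = auc_down
        self.k_cap = k_cap
        self.rank_cohort = rank_cohort
        self.margin = margin
        self.s_thr = s_thr
        self.p_thr = p_thr
        self.min_frac = min_frac
        self.jaccard_threshold = jaccard_threshold
        self.n_reps = n_reps
        self.majority = majority

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"g{i}" for i in range(X.shape[1])])

    def fit(self, X, y, cohorts=None):
        """Fit network and signature.

        ``cohorts`` optionally assigns each sample to a training cohort
        (first-appearance order; cohort of index ``rank_cohort`` is the
        primary one used for network construction and t-ranking).
        """
        X = self._as_frame(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"need exactly 2 classes, got {len(self.classes_)}")
        positive = (
            self.positive_class if self.positive_class is not None
            else self.classes_[1]
        )
        if positive not in self.classes_:
            raise ValueError(f"positive_class {positive!r} not among classes")
        self.positive_ = positive
        if cohorts is None:
            cohorts = np.zeros(len(X), dtype=int)
        cohorts = np.asarray(cohorts)
        cohort_ids = list(pd.unique(cohorts))
        datasets = []
        for cid in cohort_ids:
            mask = cohorts == cid
            sub = X.loc[mask]
            sub.index = [f"{cid}:{i}" for i in range(mask.sum())]
            matrix = sub.T  # genes x samples
            labels = pd.Series(y[mask], index=sub.index)
            datasets.append((matrix, labels))
        primary_matrix = datasets[self.rank_cohort][0]
        network = net.BooleanImplicationNetwork(
            margin=self.margin, s_thr=self.s_thr, p_thr=self.p_thr,
            min_frac=self.min_frac, jaccard_threshold=self.jaccard_threshold,
            n_reps=self.n_reps, majority=self.majority,
        ).fit(primary_matrix.T)
        selected = select_clusters(
            network.clusters_, datasets, positive=positive,
            n_clusters=self.n_clusters,
        )
        signature = train_signature(
            selected, datasets, positive=positive,
            auc_up=self.auc_up, auc_down=self.auc_down, k_cap=self.k_cap,
            rank_dataset_index=self.rank_cohort,
        )
        self.network_ = network
        self.selected_clusters_ = selected
        self.signature_ = signature
        self.up_genes_ = list(signature.up_genes)
        self.down_genes_ = list(signature.down_genes)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "signature_")
        X = self._as_frame(X)
        matrix = X.T
        normalized = _dataset_normalized(matrix)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = scoring.composite(normalized, self.signature_.gene_sets())
        return scores.to_numpy()

    def predict(self, X):
        scores = self.decision_function(X)
        negative = self.classes_[self.classes_ != self.positive_][0]
        return np.where(scores > 0, self.positive_, negative)
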