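"""Boolean implication relationships between discretized gene pairs.

After ternary discretization, every sample where both genes of a pair are
outside the intermediate zone falls into one of four Boolean quadrants
(low,low), (low,high), (high,low), (high,high) with counts a00, a01, a10,
a11.  A quadrant is *sparse* when its observed count sits far below the
count expected under independence:

    S_ij = (n_hat - n) / sqrt(n_hat),   n_hat = row_i * col_j / total

and the error probability

    p_ij = 1/2 * (a_ij / row_i + a_ij / col_j)

is small.  A quadrant with ``S > sThr`` and ``p < pThr`` (defaults 3 and
0.1) is sparse.  The identity of the sparse quadrant(s) determines one of
six Boolean implication relationships: two symmetric (equivalent, opposite)
and four asymmetric (low=>low, low=>high, high=>high, high=>low).  Any
other sparsity pattern yields no relationship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stepminer import HIGH, LOW, discretize, threshold_matrix

__all__ = [
    "QuadrantCounts",
    "Relationship",
    "count_quadrants",
    "quadrant_statistics",
    "classify",
    "dynamic_range_filter",
    "all_pairs",
    "permutation_fdr",
    "DEFAULT_S_THR",
    "DEFAULT_P_THR",
    "DEFAULT_MIN_FRAC",
]

DEFAULT_S_THR = 3.0
DEFAULT_P_THR = 0.1
DEFAULT_MIN_FRAC = 0.05

QUADRANTS = ("00", "01", "10", "11")


class Relationship:
    """The six Boolean implication relationship names plus NONE."""

    NONE = "none"
    EQUIVALENT = "equivalent"
    OPPOSITE = "opposite"
    LOLO = "lolo"  # A low  => B low
    LOHI = "lohi"  # A low  => B high
    HIHI = "hihi"  # A high => B high
    HILO = "hilo"  # A high => B low

    ALL = (EQUIVALENT, OPPOSITE, LOLO, LOHI, HIHI, HILO)


# integer codes used by the vectorized classifier
_CODE_TO_NAME = {
    0: Relationship.NONE,
    1: Relationship.EQUIVALENT,
    2: Relationship.OPPOSITE,
    3: Relationship.LOLO,
    4: Relationship.LOHI,
    5: Relationship.HIHI,
    6: Relationship.HILO,
}
# sparse-set bitmask (bit order 00,01,10,11) -> relationship code
_MASK_TO_CODE = np.zeros(16, dtype=np.int8)
_MASK_TO_CODE[0b0001] = 4  # {00} sparse: A low => B high
_MASK_TO_CODE[0b0010] = 3  # {01} sparse: A low => B low
_MASK_TO_CODE[0b0100] = 5  # {10} sparse: A high => B high
_MASK_TO_CODE[0b1000] = 6  # {11} sparse: A high => B low
_MASK_TO_CODE[0b0110] = 1  # {01,10} sparse: equivalent
_MASK_TO_CODE[0b1001] = 2  # {00,11} sparse: opposite


@dataclass(frozen=True)
class QuadrantCounts:
    """Joint low/high sample counts of an ordered gene pair (A, B)."""

    a00: int
    a01: int
    a10: int
    a11: int

    @property
    def total(self) -> int:
        return self.a00 + self.a01 + self.a10 + self.a11

    def as_array(self) -> np.ndarray:
        return np.array([self.a00, self.a01, self.a10, self.a11], dtype=float)


def count_quadrants(state_a, state_b) -> QuadrantCounts:
    """Count the four Boolean quadrants over samples where both genes
    are in a definite (LOW or HIGH) state."""
    a = np.asarray(state_a)
    b = np.asarray(state_b)
    if a.shape != b.shape:
        raise ValueError(f"state vectors differ in length: {a.shape} vs {b.shape}")
    keep = (a != 0) & (b != 0)
    a, b = a[keep], b[keep]
    return QuadrantCounts(
        a00=int(((a == LOW) & (b == LOW)).sum()),
        a01=int(((a == LOW) & (b == HIGH)).sum()),
        a10=int(((a == HIGH) & (b == LOW)).sum()),
        a11=int(((a == HIGH) & (b == HIGH)).sum()),
    )


def _stats_arrays(a00, a01, a10, a11):
    """Vectorized sparsity statistics for stacked count tables.

    Returns (S, p, defined) where S and p have a leading axis of length 4
    in quadrant order 00,01,10,11, and ``defined`` marks tables whose four
    margins are all positive.  Undefined entries hold NaN.
    """
    a00, a01, a10, a11 = (np.asarray(x, dtype=float) for x in (a00, a01, a10, a11))
    row0 = a00 + a01  # A low
    row1 = a10 + a11  # A high
    col0 = a00 + a10  # B low
    col1 = a01 + a11  # B high
    total = row0 + row1
    defined = (row0 > 0) & (row1 > 0) & (col0 > 0) & (col1 > 0)
    obs = np.stack([a00, a01, a10, a11])
    rows = np.stack([row0, row0, row1, row1])
    cols = np.stack([col0, col1, col0, col1])
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = rows * cols / total
        s = (expected - obs) / np.sqrt(expected)
        p = 0.5 * (obs / rows + obs / cols)
    s = np.where(defined, s, np.nan)
    p = np.where(defined, p, np.nan)
    return s, p, defined


def quadrant_statistics(counts: QuadrantCounts) -> pd.DataFrame:
    """Observed/expected counts, S and p for each quadrant of one pair.

    Raises ``ValueError`` when the statistics are undefined (empty table
    or a zero margin: a gene with only one observed state).
    """
    s, p, defined = _stats_arrays(counts.a00, counts.a01, counts.a10, counts.a11)
    if not bool(defined):
        raise ValueError(
            "quadrant statistics undefined: zero margin or empty table "
            f"({counts})"
        )
    obs = counts.as_array()
    row = np.array([obs[0] + obs[1]] * 2 + [obs[2] + obs[3]] * 2)
    col = np.array([obs[0] + obs[2], obs[1] + obs[3]] * 2)
    return pd.DataFrame(
        {
            "observed": obs.astype(int),
            "expected": row * col / counts.total,
            "S": s.ravel(),
            "p": p.ravel(),
        },
        index=pd.Index(QUADRANTS, name="quadrant"),
    )


def _classify_codes(a00, a01, a10, a11, s_thr, p_thr):
    """Vectorized relationship codes (see _CODE_TO_NAME) for count tables."""
    s, p, defined = _stats_arrays(a00, a01, a10, a11)
    sparse = (s > s_thr) & (p < p_thr)
    mask = (
        sparse[0].astype(np.int8)
        | (sparse[1].astype(np.int8) << 1)
        | (sparse[2].astype(np.int8) << 2)
        | (sparse[3].astype(np.int8) << 3)
    )
    codes = _MASK_TO_CODE[mask]
    return np.where(defined, codes, 0).astype(np.int8)


def classify(
    counts: QuadrantCounts,
    s_thr: float = DEFAULT_S_THR,
    p_thr: float = DEFAULT_P_THR,
) -> str:
    """Boolean implication relationship of an ordered pair from its counts.

    Sparse sets other than the six recognized patterns (singletons, the
    two diagonals) give ``Relationship.NONE``, as do tables with a zero
    margin, where the statistics are undefined.
    """
    code = _classify_codes(
        counts.a00, counts.a01, counts.a10, counts.a11, s_thr, p_thr
    )
    return _CODE_TO_NAME[int(code)]


def dynamic_range_filter(
    states: pd.DataFrame, min_frac: float = DEFAULT_MIN_FRAC
) -> pd.Index:
    """Genes with enough samples in both definite states to support
    Boolean inference.

    Keeps genes whose LOW fraction and HIGH fraction of samples are both
    >= ``min_frac`` (genes with *fewer* than that in either state are
    removed; the boundary is kept).
    """
    values = states.to_numpy()
    frac_low = (values == LOW).mean(axis=1)
    frac_high = (values == HIGH).mean(axis=1)
    keep = (frac_low >= min_frac) & (frac_high >= min_frac)
    return states.index[keep]


def all_pairs(
    states: pd.DataFrame,
    s_thr: float = DEFAULT_S_THR,
    p_thr: float = DEFAULT_P_THR,
) -> pd.DataFrame:
    """Classify every unordered gene pair of a ternary state matrix.

    Returns one row per pair with a non-NONE relationship, oriented
    gene_a -> gene_b in the matrix's gene order, with the quadrant counts,
    total, and the S / p statistics of each quadrant.  Genes should have
    been pre-filtered with :func:`dynamic_range_filter`.
    """
    genes = states.index
    x = states.to_numpy()
    low = (x == LOW).astype(np.float64)
    high = (x == HIGH).astype(np.float64)
    a00 = low @ low.T
    a01 = low @ high.T
    a10 = high @ low.T
    a11 = high @ high.T
    codes = _classify_codes(a00, a01, a10, a11, s_thr, p_thr)
    iu, ju = np.triu_indices(len(genes), k=1)
    hit = codes[iu, ju] != 0
    i, j = iu[hit], ju[hit]
    s, p, _ = _stats_arrays(a00[i, j], a01[i, j], a10[i, j], a11[i, j])
    edges = pd.DataFrame(
        {
            "gene_a": genes[i],
            "gene_b": genes[j],
            "relationship": [_CODE_TO_NAME[c] for c in codes[i, j]],
            "a00": a00[i, j].astype(int),
            "a01": a01[i, j].astype(int),
            "a10": a10[i, j].astype(int),
            "a11": a11[i, j].astype(int),
            "total": (a00 + a01 + a10 + a11)[i, j].astype(int),
        }
    )
    for q_idx, q in enumerate(QUADRANTS):
        edges[f"s{q}"] = s[q_idx]
        edges[f"p{q}"] = p[q_idx]
    return edges


def permutation_fdr(
    matrix: pd.DataFrame,
    n_perm: int = 3,
    seed: int | np.random.Generator = 0,
    s_thr: float = DEFAULT_S_THR,
    p_thr: float = DEFAULT_P_THR,
    margin: float = 0.5,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> float:
    """Permutation estimate of the false discovery rate of the pair scan.

    Each gene's expression values are shuffled independently across
    samples, destroying all pairwise structure while preserving per-gene
    marginals (and hence thresholds and the dynamic-range filter); the
    FDR estimate is the mean number of significant pairs across permuted
    datasets divided by the observed number.  Returns ``inf`` when no
    pair is significant in the observed data.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    rng = np.random.default_rng(seed)
    thresholds = threshold_matrix(matrix)
    states = discretize(matrix, thresholds, margin=margin)
    states = states.loc[dynamic_range_filter(states, min_frac=min_frac)]
    observed = len(all_pairs(states, s_thr, p_thr))
    null_counts = []
    values = states.to_numpy()
    for _ in range(n_perm):
        # shuffling states per gene == shuffling expression then rethresholding,
        # because thresholds depend only on each gene's sorted values
        permuted = np.array([rng.permutation(row) for row in values])
        null = pd.DataFrame(permuted, index=states.index, columns=states.columns)
        null_counts.append(len(all_pairs(null, s_thr, p_thr)))
    if observed == 0:
        return float("inf")
    return float(np.mean(null_counts) / observed)
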