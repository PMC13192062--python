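"""Threshold-centered normalization and composite gene-set scores.

Expression is normalized with a modified Z-score centered on the
StepMiner threshold ``t`` of each gene:

    normalized = (expr - t - 0.5) / (3 * SD)

where SD is the gene's sample standard deviation (n-1 denominator, all
samples of the dataset pooled).  A sample's composite score for a
weighted collection of gene sets is the weighted sum of the per-set means
of normalized values; for a trained signature this is
mean(up genes) - mean(down genes).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["normalize", "composite", "sample_ordering"]


def normalize(matrix: pd.DataFrame, thresholds: pd.Series) -> pd.DataFrame:
    """Modified Z-score around each gene's StepMiner threshold.

    Genes with zero standard deviation carry no information relative to
    their threshold; they are dropped with a warning.  The result carries
    per-gene ``threshold`` and ``sd`` in ``attrs``.
    """
    missing = matrix.index.difference(thresholds.index)
    if len(missing) > 0:
        raise ValueError(f"no threshold for gene(s): {list(missing)}")
    x = matrix.to_numpy(dtype=float)
    t = thresholds.loc[matrix.index].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"dropping {int(degenerate.sum())} gene(s) with zero variance: "
            f"{list(matrix.index[degenerate][:5])}...",
            stacklevel=2,
        )
    keep = ~degenerate
    normalized = (x[keep] - t[keep, None] - 0.5) / (3.0 * sd[keep, None])
    out = pd.DataFrame(normalized, index=matrix.index[keep], columns=matrix.columns)
    out.attrs["threshold"] = pd.Series(t[keep], index=matrix.index[keep])
    out.attrs["sd"] = pd.Series(sd[keep], index=matrix.index[keep])
    return out


def composite(
    normalized: pd.DataFrame, gene_sets: list[tuple[list, float]]
) -> pd.Series:
    """Weighted linear combination of per-set mean normalized expression.

    ``gene_sets`` is a list of ``(genes, weight)`` pairs.  Genes absent
    from the normalized matrix are dropped with a warning and the set
    mean renormalizes over the remaining genes; a set losing all its
    genes is an error.

    The returned Series carries in ``attrs`` a ``noise_band``: the
    two-fold-change margin propagated through the normalization
    (0.5 / (3 SD), averaged over the genes used, weighted like the
    score), and the ids of samples whose |score| falls inside it —
    reported as metadata only, never altering the scores.
    """
    scores = pd.Series(0.0, index=normalized.columns, name="score")
    sd = normalized.attrs.get("sd")
    band = 0.0
    for genes, weight in gene_sets:
        genes = list(genes)
        present = [g for g in genes if g in normalized.index]
        absent = [g for g in genes if g not in normalized.index]
        if absent:
            warnings.warn(
                f"{len(absent)} signature gene(s) absent from matrix, "
                f"dropped: {absent[:5]}...",
                stacklevel=2,
            )
        if not present:
            raise ValueError(
                f"gene set with weight {weight} has no genes in the matrix"
            )
        scores = scores + weight * normalized.loc[present].mean(axis=0)
        if sd is not None:
            band += abs(weight) * float((0.5 / (3.0 * sd.loc[present])).mean())
    scores.attrs["noise_band"] = band
    scores.attrs["indeterminate_samples"] = list(scores.index[scores.abs() < band])
    return scores


def sample_ordering(scores: pd.Series) -> list:
    """Sample ids in ascending score order; ties broken by sample id."""
    order = sorted(scores.index, key=lambda s: (scores[s], str(s)))
    return list(order)
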