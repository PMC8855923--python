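"""Per-peptide two-group statistics and the top-N differential selection.

Peptide-level evidence uses Welch's unequal-variance t with Benjamini–
Hochberg FDR across all QC-passing peptides.  "Differentially regulated" is
ranked by |t| (a config switch allows |delta|), and the heatmap matrix is
the per-peptide z-score across samples with average-linkage Euclidean
clustering of rows and columns — the common default of online heatmap tools.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from phoskin.io import SampleDesign
from phoskin.kinetics import PeptideSignalMatrix

logger = logging.getLogger("phoskin.differential")

DEFAULT_N_TOP = 75


def peptide_stats(
    matrix: PeptideSignalMatrix,
    design: SampleDesign,
    comparison: tuple[str, str],
) -> pd.DataFrame:
    """Welch t per QC-passing peptide for one (group1, group2) comparison.

    Returns a DataFrame with columns peptide_id, mean_g1, mean_g2, delta,
    t_stat, p_value, q_value.  Degenerate peptides follow explicit rules:
    zero variance in both groups with equal means → t 0, p 1; zero variance
    with unequal means → t = ±inf with p at the machine minimum (logged).
    """
    g1, g2 = comparison
    s1 = design.group_samples(g1)
    s2 = design.group_samples(g2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("both comparison groups need >=2 samples")
    peptides = matrix.passing_peptides()
    x1 = matrix.signal.loc[s1, peptides].to_numpy(dtype=float)
    x2 = matrix.signal.loc[s2, peptides].to_numpy(dtype=float)

    m1 = x1.mean(axis=0)
    m2 = x2.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v2 = x2.var(axis=0, ddof=1)
    delta = m1 - m2

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(x1, x2, axis=0, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)

    both_flat = (v1 == 0) & (v2 == 0)
    null_flat = both_flat & (delta == 0)
    t[null_flat] = 0.0
    p[null_flat] = 1.0
    sep_flat = both_flat & (delta != 0)
    if sep_flat.any():
        logger.warning(
            "%d peptide(s) with zero variance and unequal means: t set to ±inf",
            int(sep_flat.sum()),
        )
        t[sep_flat] = np.sign(delta[sep_flat]) * np.inf
        p[sep_flat] = np.finfo(float).tiny

    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "peptide_id": peptides,
            "mean_g1": m1,
            "mean_g2": m2,
            "delta": delta,
            "t_stat": t,
            "p_value": p,
            "q_value": q,
        }
    )


def select_top_peptides(
    results: pd.DataFrame, n: int = DEFAULT_N_TOP, by: str = "t_stat"
) -> list[str]:
    """The top-n differentially regulated peptides (up- and downregulated).

    Ranked by the absolute value of ``by`` (default the Welch t statistic,
    alternatively ``delta``) descending; ties break on smaller p, then
    lexicographic peptide_id.  Returns min(n, available) peptides.
    """
    if results.empty:
        raise ValueError("empty peptide results")
    if by not in ("t_stat", "delta"):
        raise ValueError(f"unknown ranking statistic {by!r}")
    ranked = results.assign(_abs=results[by].abs()).sort_values(
        ["_abs", "p_value", "peptide_id"], ascending=[False, True, True]
    )
    return ranked["peptide_id"].head(n).tolist()


def _ordered_linkage(z: np.ndarray) -> np.ndarray:
    """Average-linkage Euclidean leaf order, deterministic for a fixed row order."""
    if z.shape[0] < 2:
        return np.arange(z.shape[0])
    link = hierarchy.linkage(pdist(z, metric="euclidean"), method="average")
    return hierarchy.leaves_list(link)


def heatmap_matrix(
    matrix: PeptideSignalMatrix,
    selection: list[str],
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Row-standardized (peptides × samples) matrix with clustered orders.

    Each selected peptide's signals are z-scored across samples
    (zero-variance rows become all-zero, logged), then rows and columns are
    ordered by hierarchical clustering (Euclidean distance, average
    linkage).  Input rows/columns are pre-sorted lexicographically so the
    leaf order is a pure function of the data, not of input order; identical
    rows pair at distance zero and come out adjacent.
    """
    if not selection:
        raise ValueError("empty peptide selection")
    selection = sorted(selection)
    samples = sorted(matrix.samples)
    sub = matrix.signal.loc[samples, selection].T  # peptides × samples
    vals = sub.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        logger.warning("%d zero-variance row(s) z-scored to all zeros", int(flat.sum()))
    z = np.where(sd == 0, 0.0, (vals - mu) / np.where(sd == 0, 1.0, sd))
    zf = pd.DataFrame(z, index=sub.index, columns=sub.columns)

    row_order = [selection[i] for i in _ordered_linkage(z)]
    col_order = [samples[i] for i in _ordered_linkage(z.T)]
    zf = zf.loc[row_order, col_order]
    return zf, row_order, col_order
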