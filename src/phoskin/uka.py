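"""Upstream kinase analysis: the normalized kinase statistic and its scores.

For a kinase with n mapped, QC-passing, on-chip peptides the normalized
kinase statistic is

    tau = (1/n) * sum_i (m_i1 - m_i2) / sqrt(v_i1 + v_i2)

where m_ij, v_ij are the sample mean and variance of peptide i's signal in
comparison group j.  Two permutation tests judge it:

* the **significance score** permutes sample group labels and measures how
  much tau depends on the experimental grouping;
* the **specificity score** draws random peptide sets of the same size and
  measures how much tau depends on the kinase's specific substrate mapping
  rather than chip-wide drift.

Both use the pseudo-counted two-sided estimator p = (1 + b) / (B + 1) on
|tau| and are reported as -log10(p).  The **final score** is their sum;
kinases with final score above the reporting threshold (default 1.5) are
flagged for the ranked report.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from phoskin.io import SampleDesign
from phoskin.kinetics import PeptideSignalMatrix
from phoskin.mapping import KinaseMap

logger = logging.getLogger("phoskin.uka")

DEFAULT_B = 1000
DEFAULT_MIN_PEPTIDES = 3
DEFAULT_REPORT_THRESHOLD = 1.5
VAR_EPS = 1e-8

RESULT_COLUMNS = [
    "kinase",
    "tau",
    "significance",
    "specificity",
    "final_score",
    "n_peptides",
    "direction",
    "sig_p",
    "spec_p",
    "report",
]


class SkippedKinase(RuntimeError):
    """A kinase cannot be scored (too few usable mapped peptides)."""


@dataclass
class ComparisonContext:
    """Signal matrix restricted to one comparison, with per-peptide moments.

    ``signal`` holds only the comparison's samples and QC-passing peptides;
    ``d`` is the per-peptide standardized group-mean difference
    (m1 - m2)/sqrt(v1 + v2) that tau averages over a kinase's mapped set.
    """

    signal: pd.DataFrame  # samples × qc-passing peptides
    group1: list[str]
    group2: list[str]
    means1: pd.Series
    means2: pd.Series
    var1: pd.Series
    var2: pd.Series
    d: pd.Series

    @property
    def peptides(self) -> list[str]:
        return list(self.signal.columns)


def _standardized_diff(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """(mean1 - mean2)/sqrt(var1 + var2) along axis 0, eps-guarded."""
    m1 = x1.mean(axis=0)
    m2 = x2.mean(axis=0)
    v = x1.var(axis=0, ddof=1) + x2.var(axis=0, ddof=1)
    return (m1 - m2) / np.sqrt(np.maximum(v, VAR_EPS))


def make_context(
    matrix: PeptideSignalMatrix,
    design: SampleDesign,
    comparison: tuple[str, str],
) -> ComparisonContext:
    """Restrict the signal matrix to one comparison and precompute moments."""
    g1, g2 = comparison
    s1 = design.group_samples(g1)
    s2 = design.group_samples(g2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("each comparison group needs >=2 samples")
    peptides = matrix.passing_peptides()
    signal = matrix.signal.loc[s1 + s2, peptides]
    x1 = signal.loc[s1].to_numpy(dtype=float)
    x2 = signal.loc[s2].to_numpy(dtype=float)
    v1 = x1.var(axis=0, ddof=1)
    v2 = x2.var(axis=0, ddof=1)
    n_guard = int(((v1 + v2) < VAR_EPS).sum())
    if n_guard:
        logger.warning(
            "%d peptide(s) with pooled variance < %g use the epsilon guard",
            n_guard,
            VAR_EPS,
        )
    return ComparisonContext(
        signal=signal,
        group1=list(s1),
        group2=list(s2),
        means1=pd.Series(x1.mean(axis=0), index=peptides),
        means2=pd.Series(x2.mean(axis=0), index=peptides),
        var1=pd.Series(v1, index=peptides),
        var2=pd.Series(v2, index=peptides),
        d=pd.Series(_standardized_diff(x1, x2), index=peptides),
    )


def _usable_peptides(ctx: ComparisonContext, mapped_peptides) -> list[str]:
    chip = set(ctx.peptides)
    return sorted(p for p in set(mapped_peptides) if p in chip)


def kinase_tau(
    ctx: ComparisonContext,
    mapped_peptides,
    min_peptides: int = DEFAULT_MIN_PEPTIDES,
) -> tuple[float, int]:
    """The normalized kinase statistic over the usable mapped peptide set.

    n is the number of mapped peptides that are on-chip and QC-passing for
    this comparison; below ``min_peptides`` the kinase is skipped
    (:class:`SkippedKinase`).
    """
    use = _usable_peptides(ctx, mapped_peptides)
    n = len(use)
    if n < min_peptides:
        raise SkippedKinase(
            f"{n} usable mapped peptide(s) < min_peptides={min_peptides}"
        )
    tau = float(ctx.d.loc[use].mean())
    return tau, n


def _kinase_rng(seed: int, kinase: str, stream: int) -> np.random.Generator:
    """Per-kinase substream: stable under adding/removing other kinases."""
    return np.random.default_rng([seed, zlib.crc32(kinase.encode("utf-8")), stream])


def significance_score(
    ctx: ComparisonContext,
    mapped_peptides,
    B: int = DEFAULT_B,
    rng: np.random.Generator | None = None,
    min_peptides: int = DEFAULT_MIN_PEPTIDES,
) -> tuple[float, float]:
    """Sample-label permutation evidence that tau tracks the grouping.

    Group-1 membership is re-drawn among the comparison's samples.  Because
    the comparison is two-sided on |tau|, a labeling and its complement are
    the same test outcome, so the permutation space is the set of distinct
    group *partitions* (for equal group sizes each unordered split counts
    once) excluding the observed one — exhaustive when that space has at
    most B elements, otherwise B uniform draws.  Returns (score, sig_p)
    with score = -log10(sig_p) and
    sig_p = (1 + #{|tau_perm| >= |tau_obs|}) / (B_eff + 1).
    """
    if rng is None:
        rng = np.random.default_rng()
    use = _usable_peptides(ctx, mapped_peptides)
    if len(use) < min_peptides:
        raise SkippedKinase(f"{len(use)} usable mapped peptide(s)")
    tau_obs = float(ctx.d.loc[use].mean())

    X = ctx.signal[use].to_numpy(dtype=float)
    n1 = len(ctx.group1)
    N = X.shape[0]
    equal_split = 2 * n1 == N
    obs = frozenset(range(n1))

    def canon(c) -> frozenset:
        # canonical partition representative: the side containing sample 0
        s = frozenset(c)
        if equal_split and 0 not in s:
            s = frozenset(range(N)) - s
        return s

    n_relabel = (comb(N - 1, n1 - 1) if equal_split else comb(N, n1)) - 1
    if n_relabel < 10:
        logger.warning(
            "only %d distinct relabelings: permutation p-resolution is coarse",
            n_relabel,
        )
    if n_relabel <= B:
        if equal_split:
            pool = (frozenset({0}) | frozenset(c) for c in combinations(range(1, N), n1 - 1))
        else:
            pool = (frozenset(c) for c in combinations(range(N), n1))
        draws = [sorted(c) for c in pool if c != obs]
    else:
        draws = []
        while len(draws) < B:
            c = canon(rng.choice(N, size=n1, replace=False))
            if c != obs:
                draws.append(sorted(c))
    idx1 = np.array(draws)  # (B_eff, n1)
    mask = np.zeros((len(draws), N), dtype=bool)
    mask[np.arange(len(draws))[:, None], idx1] = True

    taus = np.empty(len(draws))
    for b in range(len(draws)):
        taus[b] = _standardized_diff(X[mask[b]], X[~mask[b]]).mean()

    b_exceed = int(np.sum(np.abs(taus) >= abs(tau_obs) - 1e-12))
    sig_p = (1 + b_exceed) / (len(draws) + 1)
    return float(-np.log10(sig_p)), float(sig_p)


def specificity_score(
    ctx: ComparisonContext,
    mapped_peptides,
    B: int = DEFAULT_B,
    rng: np.random.Generator | None = None,
    min_peptides: int = DEFAULT_MIN_PEPTIDES,
) -> tuple[float, float]:
    """Peptide-permutation evidence that tau tracks the substrate mapping.

    Draws B random peptide sets of the kinase's size n from all QC-passing
    peptides (without replacement within a draw) and compares |tau|.
    When no alternative set exists (chip size equals n) spec_p is forced
    to 1 with a warning.
    """
    if rng is None:
        rng = np.random.default_rng()
    use = _usable_peptides(ctx, mapped_peptides)
    n = len(use)
    if n < min_peptides:
        raise SkippedKinase(f"{n} usable mapped peptide(s)")
    tau_obs = float(ctx.d.loc[use].mean())

    d = ctx.d.to_numpy(dtype=float)
    P = len(d)
    if P <= n:
        logger.warning("specificity: no alternative peptide sets (chip size %d = n)", P)
        return 0.0, 1.0
    # B draws of n distinct peptide indices each: argpartition of random keys
    keys = rng.random((B, P))
    idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
    taus = d[idx].mean(axis=1)
    b_exceed = int(np.sum(np.abs(taus) >= abs(tau_obs) - 1e-12))
    spec_p = (1 + b_exceed) / (B + 1)
    return float(-np.log10(spec_p)), float(spec_p)


def final_scores(
    results: pd.DataFrame,
    report_threshold: float = DEFAULT_REPORT_THRESHOLD,
) -> pd.DataFrame:
    """Combine scores and rank the kinase table.

    final_score = significance + specificity, exactly.  Sorted by
    final_score descending (ties: |tau| descending, then kinase name);
    ``report`` flags kinases whose final score exceeds the threshold.
    """
    out = results.copy()
    out["final_score"] = out["significance"] + out["specificity"]
    out["report"] = out["final_score"] > report_threshold
    out = out.assign(_abs_tau=out["tau"].abs()).sort_values(
        ["final_score", "_abs_tau", "kinase"], ascending=[False, False, True]
    )
    return out.drop(columns="_abs_tau").reset_index(drop=True)


def _subsampled_tau(
    ctx: ComparisonContext,
    use: list[str],
    iters: int,
    rng: np.random.Generator,
    fraction: float = 0.8,
    min_peptides: int = DEFAULT_MIN_PEPTIDES,
) -> float:
    """Mean tau over random sub-samplings of the mapped set (vendor-style)."""
    n = len(use)
    m = max(int(np.ceil(fraction * n)), min(min_peptides, n))
    d = ctx.d.loc[use].to_numpy(dtype=float)
    taus = np.empty(iters)
    for i in range(iters):
        taus[i] = d[rng.choice(n, size=m, replace=False)].mean()
    return float(taus.mean())


def run_uka(
    matrix: PeptideSignalMatrix,
    design: SampleDesign,
    kinase_map: KinaseMap,
    B: int = DEFAULT_B,
    seed: int = 0,
    min_peptides: int = DEFAULT_MIN_PEPTIDES,
    report_threshold: float = DEFAULT_REPORT_THRESHOLD,
    subsample_iters: int = 0,
    comparisons: list[tuple[str, str]] | None = None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Score every mapped kinase for every comparison.

    Randomness uses per-kinase substreams derived from the run seed and a
    stable hash of the kinase name, so adding or removing one kinase never
    perturbs the others' permutation draws.  With ``subsample_iters`` > 0
    the reported tau is additionally averaged over random 80% sub-samplings
    of the mapped set (the permutation scores always use the full set).
    """
    if comparisons is None:
        comparisons = design.comparisons
    if not comparisons:
        raise ValueError("no comparisons to run")
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for comparison in comparisons:
        ctx = make_context(matrix, design, comparison)
        rows = []
        skipped = 0
        for kinase in kinase_map.kinases():
            mapped = kinase_map.peptides_for(kinase)
            try:
                tau, n = kinase_tau(ctx, mapped, min_peptides=min_peptides)
                sig, sig_p = significance_score(
                    ctx, mapped, B=B, rng=_kinase_rng(seed, kinase, 0),
                    min_peptides=min_peptides,
                )
                spec, spec_p = specificity_score(
                    ctx, mapped, B=B, rng=_kinase_rng(seed, kinase, 1),
                    min_peptides=min_peptides,
                )
            except SkippedKinase as err:
                logger.info("skipping kinase %s for %s: %s", kinase, comparison, err)
                skipped += 1
                continue
            tau_report = tau
            if subsample_iters > 0:
                use = _usable_peptides(ctx, mapped)
                tau_report = _subsampled_tau(
                    ctx, use, subsample_iters, _kinase_rng(seed, kinase, 2),
                    min_peptides=min_peptides,
                )
            direction = (
                "none" if tau_report == 0
                else ("up_in_g1" if tau_report > 0 else "up_in_g2")
            )
            rows.append(
                {
                    "kinase": kinase,
                    "tau": tau_report,
                    "significance": sig,
                    "specificity": spec,
                    "n_peptides": n,
                    "direction": direction,
                    "sig_p": sig_p,
                    "spec_p": spec_p,
                }
            )
        logger.info(
            "comparison %s: %d kinase(s) scored, %d skipped (B=%d)",
            comparison, len(rows), skipped, B,
        )
        table = pd.DataFrame(
            rows,
            columns=[c for c in RESULT_COLUMNS if c not in ("final_score", "report")],
        )
        out[tuple(comparison)] = final_scores(table, report_threshold)[RESULT_COLUMNS]
    return out
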