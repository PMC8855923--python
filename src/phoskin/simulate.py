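"""Synthetic kinome-chip experiments with planted ground truth.

The generator emulates a two-group serine/threonine chip study: each kinase
has a set of true substrate peptides (scored 301–600 so they survive the
mapping threshold) plus decoys (50–299, exercising the threshold from
below), a couple of in-vitro confirmed substrates, and a group-wise activity
level.  A peptide's true log2 signal is its basal level plus the
affinity-weighted sum of its kinases' activities plus Gaussian noise; the
kinetic series is the exact inverse of the extraction transform —
intensity(t) = (2^s − 1)/slope_scale · t plus read noise — so in the
noiseless limit the pipeline recovers the planted signals exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phoskin.io import (
    InVitroTargets,
    KineticSeriesSet,
    SampleDesign,
    ScoreTable,
)

logger = logging.getLogger("phoskin.simulate")

DEFAULT_EXPOSURES = (10.0, 20.0, 50.0, 100.0, 200.0)
DEFAULT_SLOPE_SCALE = 100.0
INVITRO_AFFINITY = 0.5


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated experiment."""

    kinases: list[str]
    peptides: list[str]
    activities: pd.DataFrame  # kinases × groups, baseline 1.0 + planted deltas
    affinity: pd.DataFrame  # kinases × peptides, nonzero exactly on map support
    basal: pd.Series  # per-peptide basal log2 signal
    true_signal: pd.DataFrame  # samples × peptides (noise included)
    planted: list[tuple[str, float]]
    noise_sigma: float
    kinetic_noise_sigma: float
    failing_peptides: list[str] = field(default_factory=list)
    exposures: tuple = DEFAULT_EXPOSURES
    seed: int = 0

    def to_tsv(self, path, sep: str = "\t") -> None:
        long = self.affinity.stack().rename("affinity").reset_index()
        long.columns = ["kinase", "peptide_id", "affinity"]
        long = long[long["affinity"] > 0]
        long.to_csv(path, sep=sep, index=False, float_format="%.6f", encoding="utf-8")


def _derive_seed(seed: int, *parts: int) -> int:
    """A stable child seed below 2**31."""
    return int(np.random.SeedSequence([seed, *parts]).generate_state(1)[0] % (2**31))


def simulate_experiment(
    n_kinases: int = 20,
    n_peptides: int = 140,
    samples_per_group: int = 6,
    groups: tuple[str, str] = ("control", "ko"),
    planted: list[tuple[str, float]] | None = None,
    targets_per_kinase: int = 9,
    decoys_per_kinase: int = 6,
    invitro_per_kinase: int = 2,
    noise_sigma: float = 0.25,
    kinetic_noise_sigma: float = 0.25,
    basal_range: tuple[float, float] = (2.0, 4.0),
    n_failing_peptides: int = 0,
    exposures: tuple = DEFAULT_EXPOSURES,
    slope_scale: float = DEFAULT_SLOPE_SCALE,
    seed: int = 0,
) -> tuple[KineticSeriesSet, SampleDesign, ScoreTable, InVitroTargets, SyntheticTruth]:
    """Generate one two-group kinome-chip experiment.

    ``planted`` lists (kinase, delta) activity differences: the kinase's
    activity in group 1 is 1 + delta versus 1 in group 2, so positive deltas
    raise its substrates' phosphorylation in group 1 (tau > 0).  The default
    plants delta 1.0 on the first kinase.  ``n_failing_peptides`` peptides
    (taken from the end of the chip and never mapped) get flat pure-noise
    curves that the QC gate should reject.
    """
    if planted is None:
        planted = [("K01", 1.0)]
    kinases = [f"K{i + 1:02d}" for i in range(n_kinases)]
    peptides = [f"P{i + 1:03d}" for i in range(n_peptides)]
    for kinase, _ in planted:
        if kinase not in kinases:
            raise ValueError(f"planted kinase {kinase!r} not among the {n_kinases} kinases")
    if n_failing_peptides >= n_peptides:
        raise ValueError("n_failing_peptides must leave measurable peptides")

    rng = np.random.default_rng(seed)
    failing = peptides[n_peptides - n_failing_peptides :] if n_failing_peptides else []
    mappable = peptides[: n_peptides - n_failing_peptides]

    # --- kinase→peptide truth, score table, in-vitro list ----------------
    score_rows = []
    iv_rows = []
    affinity = pd.DataFrame(0.0, index=kinases, columns=peptides)
    for kinase in kinases:
        chosen = rng.choice(
            mappable,
            size=min(targets_per_kinase + invitro_per_kinase, len(mappable)),
            replace=False,
        )
        targets = chosen[:targets_per_kinase]
        invitro = chosen[targets_per_kinase:]
        t_scores = rng.uniform(301.0, 600.0, size=len(targets))
        for pep, sc in zip(targets, t_scores):
            score_rows.append({"kinase": kinase, "peptide_id": pep, "score": sc})
            affinity.loc[kinase, pep] = sc / 1000.0
        for pep in invitro:
            iv_rows.append({"kinase": kinase, "peptide_id": pep})
            affinity.loc[kinase, pep] = INVITRO_AFFINITY
        decoys = rng.choice(
            [p for p in mappable if p not in set(chosen)],
            size=min(decoys_per_kinase, len(mappable) - len(chosen)),
            replace=False,
        )
        for pep, sc in zip(decoys, rng.uniform(50.0, 299.0, size=len(decoys))):
            score_rows.append({"kinase": kinase, "peptide_id": pep, "score": sc})

    scores = ScoreTable(pd.DataFrame(score_rows))
    invitro_targets = InVitroTargets(pd.DataFrame(iv_rows, columns=["kinase", "peptide_id"]))

    # --- activities and true signals -------------------------------------
    g1, g2 = groups
    activities = pd.DataFrame(1.0, index=kinases, columns=list(groups))
    for kinase, delta in planted:
        activities.loc[kinase, g1] = 1.0 + delta

    sample_ids = [f"{g}{i + 1}" for g in groups for i in range(samples_per_group)]
    sample_groups = [g for g in groups for _ in range(samples_per_group)]
    design = SampleDesign(
        pd.DataFrame({"sample_id": sample_ids, "group": sample_groups}),
        comparisons=[(g1, g2)],
    )

    basal = pd.Series(
        rng.uniform(basal_range[0], basal_range[1], size=n_peptides), index=peptides
    )
    aff = affinity.to_numpy()  # kinases × peptides
    true_signal = np.empty((len(sample_ids), n_peptides))
    for j, grp in enumerate(sample_groups):
        act = activities[grp].to_numpy()
        mean = basal.to_numpy() + act @ aff
        true_signal[j] = mean + rng.normal(0.0, noise_sigma, size=n_peptides)
    truth_signal = pd.DataFrame(true_signal, index=sample_ids, columns=peptides)

    # --- kinetic series: inverse of the extraction transform -------------
    exp_arr = np.asarray(exposures, dtype=float)
    n_exp = len(exp_arr)
    slopes = (np.power(2.0, true_signal) - 1.0) / slope_scale  # samples × peptides
    intensity = slopes[:, :, None] * exp_arr[None, None, :]
    if kinetic_noise_sigma > 0:
        intensity = intensity + rng.normal(
            0.0, kinetic_noise_sigma, size=intensity.shape
        )
    if failing:
        fail_idx = [peptides.index(p) for p in failing]
        intensity[:, fail_idx, :] = rng.normal(
            1.0, 0.5, size=(len(sample_ids), len(fail_idx), n_exp)
        )

    frame = pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, n_peptides * n_exp),
            "peptide_id": np.tile(np.repeat(peptides, n_exp), len(sample_ids)),
            "cycle": np.tile(np.arange(1, n_exp + 1), len(sample_ids) * n_peptides),
            "exposure_ms": np.tile(exp_arr, len(sample_ids) * n_peptides),
            "intensity": intensity.reshape(-1),
        }
    )
    kinetic = KineticSeriesSet(frame)

    truth = SyntheticTruth(
        kinases=kinases,
        peptides=peptides,
        activities=activities,
        affinity=affinity,
        basal=basal,
        true_signal=truth_signal,
        planted=list(planted),
        noise_sigma=noise_sigma,
        kinetic_noise_sigma=kinetic_noise_sigma,
        failing_peptides=failing,
        exposures=tuple(exposures),
        seed=seed,
    )
    return kinetic, design, scores, invitro_targets, truth


def simulate_null(replicates: int, seed: int = 0, **kwargs):
    """Experiments with no planted activity difference, one per replicate.

    Each replicate uses a seed substream derived from (seed, replicate), so
    replicates differ from each other but the list is reproducible.
    Returns a list of simulate_experiment tuples.
    """
    kwargs = dict(kwargs, planted=[])
    return [
        simulate_experiment(seed=_derive_seed(seed, 1, rep), **kwargs)
        for rep in range(replicates)
    ]


def _run_cell(delta, samples_per_group, rep_seed, B, **sim_kwargs):
    """One end-to-end pipeline run; returns planted-kinase rank and scores."""
    from phoskin.kinetics import build_signal_matrix, qc_filter
    from phoskin.mapping import build_map
    from phoskin.uka import run_uka

    planted = [("K01", delta)] if delta != 0 else []
    kinetic, design, scores, invitro, truth = simulate_experiment(
        samples_per_group=samples_per_group, planted=planted,
        seed=rep_seed, **sim_kwargs,
    )
    matrix = build_signal_matrix(kinetic)
    comparison = design.comparisons[0]
    samples = design.group_samples(comparison[0]) + design.group_samples(comparison[1])
    matrix = qc_filter(matrix, samples=samples)
    kmap = build_map(scores, invitro, chip_peptides=matrix.passing_peptides())
    table = run_uka(matrix, design, kmap, B=B, seed=rep_seed)[comparison]
    ranked = table.reset_index(drop=True)
    hit = ranked.index[ranked["kinase"] == "K01"]
    rank = int(hit[0]) + 1 if len(hit) else np.nan
    k01 = ranked[ranked["kinase"] == "K01"]
    return {
        "rank_planted": rank,
        "final_planted": float(k01["final_score"].iloc[0]) if len(k01) else np.nan,
        "n_flagged": int(ranked["report"].sum()),
        "top_kinase": ranked["kinase"].iloc[0] if len(ranked) else "",
    }


def recovery_experiment(
    deltas=(0.0, 0.5, 1.0, 2.0),
    samples_per_group_grid=(3, 6),
    replicates: int = 20,
    B: int = 199,
    seed: int = 0,
    **sim_kwargs,
) -> pd.DataFrame:
    """Power/recovery metrics over a (delta × group size) grid.

    Runs the full pipeline per grid cell and replicate; the metrics table
    has one row per run with the planted kinase's rank and final score,
    from which rank-1 frequency (power) and the null flag rate follow.
    """
    rows = []
    for delta in deltas:
        for spg in samples_per_group_grid:
            for rep in range(replicates):
                rep_seed = _derive_seed(seed, 2, int(round(delta * 1000)), spg, rep)
                metrics = _run_cell(delta, spg, rep_seed, B, **sim_kwargs)
                rows.append(
                    {"delta": delta, "samples_per_group": spg, "replicate": rep, **metrics}
                )
    table = pd.DataFrame(rows)
    logger.info(
        "recovery grid: %d runs, overall rank-1 rate %.3f",
        len(table),
        float((table.loc[table["delta"] > 0, "rank_planted"] == 1).mean())
        if (table["delta"] > 0).any()
        else np.nan,
    )
    return table
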