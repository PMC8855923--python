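import numpy as np
import pandas as pd
import pytest

import phoskin as pk


@pytest.fixture(scope="session")
def small_experiment():
    """A small planted-effect chip experiment shared by read-only tests."""
    return pk.simulate_experiment(
        n_kinases=6,
        n_peptides=40,
        samples_per_group=4,
        planted=[("K01", 1.0)],
        seed=42,
    )


@pytest.fixture(scope="session")
def small_matrix(small_experiment):
    kinetic, design, scores, invitro, truth = small_experiment
    matrix = pk.qc_filter(pk.build_signal_matrix(kinetic))
    return matrix, design, scores, invitro, truth


def toy_signal_matrix(values: dict[str, list[float]], samples: list[str]):
    """Build a PeptideSignalMatrix directly from per-peptide signal vectors.

    QC diagnostics are synthesized as passing (linear curves with high R²
    and intensity above the floor) so tests can focus on the statistics.
    """
    signal = pd.DataFrame(values, index=samples, dtype=float)
    rows = []
    for s in samples:
        for p in signal.columns:
            rows.append(
                {
                    "sample_id": s,
                    "peptide_id": p,
                    "max_intensity": 100.0,
                    "slope": 0.5,
                    "r_squared": 0.99,
                    "n_points": 5,
                    "measurable": True,
                    "signal": signal.loc[s, p],
                }
            )
    stats = pd.DataFrame(rows)
    qc = pd.Series(True, index=list(signal.columns), name="qc_pass")
    return pk.PeptideSignalMatrix(signal=signal, qc_stats=stats, qc_pass=qc)


def two_group_design(n1: int, n2: int, g1="a", g2="b"):
    samples = [f"{g1}{i}" for i in range(n1)] + [f"{g2}{i}" for i in range(n2)]
    groups = [g1] * n1 + [g2] * n2
    return (
        pk.SampleDesign(
            pd.DataFrame({"sample_id": samples, "group": groups}),
            comparisons=[(g1, g2)],
        ),
        samples,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
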