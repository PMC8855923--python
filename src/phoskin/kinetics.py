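"""Kinetic curve → signal extraction and the curve-quality QC gate.

Each (sample, peptide) series of fluorescence intensity versus exposure time
is reduced to one number: the least-squares slope of intensity on exposure,
scaled by ``slope_scale`` (default 100, matching typical millisecond exposure
grids), clamped at zero and variance-stabilized as ``log2(1 + scaled_slope)``.
Phosphorylation signal is physically non-negative, so negative slopes
(photobleaching and wash artifacts) clamp to zero rather than propagate.

QC ("acceptable kinetic curves and signals") is per comparison: a peptide
passes only if its curve fit is acceptable in *every* sample of the
comparison and it clears the intensity floor in at least one sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from phoskin.io import KineticSeriesSet

logger = logging.getLogger("phoskin.kinetics")

DEFAULT_SLOPE_SCALE = 100.0
DEFAULT_MIN_R2 = 0.8
DEFAULT_MIN_MAX_INTENSITY = 5.0


class QCError(RuntimeError):
    """Raised when QC leaves nothing to analyze."""


@dataclass
class PeptideSignalMatrix:
    """QC-annotated samples × peptides signal matrix on the log2 scale.

    ``signal``   — DataFrame, index = sample_ids, columns = peptide_ids; NaN
                   marks pairs that were unmeasurable (<3 exposure points).
    ``qc_stats`` — per-(sample, peptide) fit diagnostics: slope, r_squared,
                   max_intensity, n_points.
    ``qc_pass``  — boolean Series per peptide; populated by :func:`qc_filter`
                   for a specific set of comparison samples.
    """

    signal: pd.DataFrame
    qc_stats: pd.DataFrame
    qc_pass: pd.Series | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.signal.index)

    @property
    def peptides(self) -> list[str]:
        return list(self.signal.columns)

    def passing_peptides(self) -> list[str]:
        if self.qc_pass is None:
            raise QCError("qc_filter has not been applied")
        return list(self.qc_pass.index[self.qc_pass])


def _fit_line(exposure: np.ndarray, intensity: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R² of intensity on exposure.

    All-identical intensities give slope 0 with R² defined as 0 (a flat
    curve carries no kinetic evidence).
    """
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(intensity, dtype=float)
    sxx = np.sum((x - x.mean()) ** 2)
    syy = np.sum((y - y.mean()) ** 2)
    if syy == 0.0 or sxx == 0.0:
        return 0.0, 0.0
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    r2 = (sxy * sxy) / (sxx * syy)
    return float(slope), float(r2)


def extract_signal(
    exposure_ms,
    intensity,
    slope_scale: float = DEFAULT_SLOPE_SCALE,
) -> tuple[float, dict]:
    """Reduce one kinetic series to its log2 signal value.

    Returns ``(signal, diagnostics)`` where diagnostics carries the raw
    slope, R² and maximum observed intensity.  Requires >=3 distinct
    exposure points; the result is invariant to the ordering of the input
    points.
    """
    x = np.asarray(exposure_ms, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("extract_signal requires >=3 distinct exposure points")
    slope, r2 = _fit_line(x, y)
    signal = float(np.log2(1.0 + max(slope * slope_scale, 0.0)))
    diagnostics = {
        "slope": slope,
        "r_squared": r2,
        "max_intensity": float(y.max()),
        "n_points": int(len(x)),
    }
    return signal, diagnostics


def build_signal_matrix(
    data: KineticSeriesSet,
    slope_scale: float = DEFAULT_SLOPE_SCALE,
    min_points: int = 3,
) -> PeptideSignalMatrix:
    """Fit every (sample, peptide) series and assemble the signal matrix.

    Uses closed-form grouped least squares (sums of squares per group) so
    the whole chip is fitted in vectorized passes.  Pairs with fewer than
    ``min_points`` distinct exposures are flagged unmeasurable (NaN signal)
    rather than dropped.
    """
    df = data.frame
    x = df["exposure_ms"].to_numpy(dtype=float)
    y = df["intensity"].to_numpy(dtype=float)
    work = pd.DataFrame(
        {
            "sample_id": df["sample_id"].to_numpy(),
            "peptide_id": df["peptide_id"].to_numpy(),
            "x": x,
            "y": y,
            "xx": x * x,
            "yy": y * y,
            "xy": x * y,
        }
    )
    g = work.groupby(["sample_id", "peptide_id"], sort=True)
    agg = g.agg(
        n=("x", "size"),
        sx=("x", "sum"),
        sy=("y", "sum"),
        sxx=("xx", "sum"),
        syy=("yy", "sum"),
        sxy=("xy", "sum"),
        n_distinct=("x", "nunique"),
        max_intensity=("y", "max"),
    )
    n = agg["n"].to_numpy(dtype=float)
    cxx = agg["sxx"].to_numpy() - agg["sx"].to_numpy() ** 2 / n
    cyy = agg["syy"].to_numpy() - agg["sy"].to_numpy() ** 2 / n
    cxy = agg["sxy"].to_numpy() - agg["sx"].to_numpy() * agg["sy"].to_numpy() / n
    # guard tiny negative centered sums from cancellation
    cxx = np.maximum(cxx, 0.0)
    cyy = np.maximum(cyy, 0.0)
    flat = (cyy <= 1e-12 * np.maximum(agg["syy"].to_numpy(), 1.0)) | (cxx == 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(flat, 0.0, cxy / np.where(cxx == 0, 1.0, cxx))
        r2 = np.where(flat, 0.0, (cxy * cxy) / np.where((cxx * cyy) == 0, 1.0, cxx * cyy))
    measurable = agg["n_distinct"].to_numpy() >= min_points
    n_unmeasurable = int((~measurable).sum())
    if n_unmeasurable:
        logger.warning(
            "%d (sample, peptide) pair(s) have <%d distinct exposures; flagged unmeasurable",
            n_unmeasurable,
            min_points,
        )
    signal = np.where(
        measurable, np.log2(1.0 + np.maximum(slope * slope_scale, 0.0)), np.nan
    )

    stats = agg.reset_index()[["sample_id", "peptide_id", "max_intensity"]].copy()
    stats["slope"] = slope
    stats["r_squared"] = r2
    stats["n_points"] = agg["n"].to_numpy(dtype=int)
    stats["measurable"] = measurable
    stats["signal"] = signal

    mat = stats.pivot(index="sample_id", columns="peptide_id", values="signal")
    mat = mat.loc[sorted(mat.index), sorted(mat.columns)]
    mat.index.name = None
    mat.columns.name = None
    return PeptideSignalMatrix(signal=mat, qc_stats=stats)


def qc_filter(
    matrix: PeptideSignalMatrix,
    samples: list[str] | None = None,
    min_r2: float = DEFAULT_MIN_R2,
    min_max_intensity: float = DEFAULT_MIN_MAX_INTENSITY,
) -> PeptideSignalMatrix:
    """Apply the acceptable-curve QC gate over the given comparison samples.

    A peptide passes iff, in every sample of the comparison, its curve is
    measurable and either fits well (R² >= ``min_r2``) or was clamped flat
    (slope <= 0, carrying a legitimate zero signal), AND its maximum
    intensity clears ``min_max_intensity`` in at least one sample.
    Failing peptides stay in the object but are excluded from statistics.
    QC is monotone: relaxing either threshold never removes a passer.
    """
    if samples is None:
        samples = matrix.samples
    stats = matrix.qc_stats
    sub = stats[stats["sample_id"].isin(samples)]
    if sub.empty:
        raise QCError("no QC statistics for the requested samples")

    curve_ok = sub["measurable"] & ((sub["r_squared"] >= min_r2) | (sub["slope"] <= 0.0))
    per_pep = pd.DataFrame(
        {
            "curve_all": curve_ok.groupby(sub["peptide_id"]).all(),
            "n_samples": sub.groupby("peptide_id")["sample_id"].nunique(),
            "floor_any": (sub["max_intensity"] >= min_max_intensity)
            .groupby(sub["peptide_id"])
            .any(),
        }
    )
    qc = (
        per_pep["curve_all"]
        & per_pep["floor_any"]
        & (per_pep["n_samples"] == len(samples))
    )
    qc = qc.reindex(matrix.peptides, fill_value=False)
    qc.name = "qc_pass"
    n_pass = int(qc.sum())
    logger.info("QC: %d/%d peptides pass over %d samples", n_pass, len(qc), len(samples))
    if n_pass == 0:
        raise QCError(
            "zero peptides pass QC "
            f"(min_r2={min_r2}, min_max_intensity={min_max_intensity}; "
            f"{int(per_pep['curve_all'].sum())} with acceptable curves, "
            f"{int(per_pep['floor_any'].sum())} above the intensity floor)"
        )
    return replace(matrix, qc_pass=qc)
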