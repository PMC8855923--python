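"""Readers, writers and validated containers for every table the pipeline touches.

All interchange is long ("tidy") tab-separated text; wide matrices are an
export convenience only.  Readers are strict: a missing column or a duplicate
key is a :class:`FormatError`, never a silent repair.  Rows that fail numeric
coercion are dropped and counted in the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("phoskin.io")

KINETIC_COLUMNS = ["sample_id", "peptide_id", "cycle", "exposure_ms", "intensity"]
KINETIC_KEY = ["sample_id", "peptide_id", "cycle", "exposure_ms"]
RESULT_COLUMNS = [
    "kinase",
    "tau",
    "significance",
    "specificity",
    "final_score",
    "n_peptides",
    "direction",
]
FLOAT_FORMAT = "%.6f"


class FormatError(ValueError):
    """A file violates the declared schema (missing column, duplicate key...)."""


def _require_columns(frame: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _read(path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, dtype=str, comment="#", encoding="utf-8")


def _coerce_numeric(frame: pd.DataFrame, cols: list[str], path) -> pd.DataFrame:
    """Coerce columns to float, dropping (and logging) rows that fail."""
    out = frame.copy()
    for c in cols:
        out[c] = pd.to_numeric(out[c], errors="coerce")
    bad = out[cols].isna().any(axis=1)
    if bad.any():
        logger.warning("%s: dropped %d row(s) failing numeric coercion", path, int(bad.sum()))
        out = out.loc[~bad]
    return out


# ---------------------------------------------------------------------------
# Kinetic reads


@dataclass
class KineticSeriesSet:
    """Raw per-(sample, peptide) intensity readings across exposure times.

    ``frame`` has columns ``sample_id, peptide_id, cycle, exposure_ms,
    intensity`` with a unique (sample, peptide, cycle, exposure) key.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.frame, KINETIC_COLUMNS, "KineticSeriesSet")
        dup = self.frame.duplicated(KINETIC_KEY)
        if dup.any():
            first = self.frame.loc[dup, KINETIC_KEY].iloc[0].to_dict()
            raise FormatError(f"duplicate kinetic key tuple: {first}")
        if (self.frame["exposure_ms"] <= 0).any():
            raise FormatError("exposure_ms must be positive")
        if (self.frame["cycle"] < 0).any():
            raise FormatError("cycle must be non-negative")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return sorted(self.frame["sample_id"].unique())

    @property
    def peptides(self) -> list[str]:
        return sorted(self.frame["peptide_id"].unique())

    def missing_pairs(self) -> pd.DataFrame:
        """(sample, peptide) pairs absent from the rectangular design."""
        have = self.frame.groupby(["sample_id", "peptide_id"], sort=False).size()
        full = pd.MultiIndex.from_product(
            [self.samples, self.peptides], names=["sample_id", "peptide_id"]
        )
        missing = full.difference(have.index)
        return missing.to_frame(index=False)


def read_kinetic_table(path, sep: str = "\t") -> KineticSeriesSet:
    frame = _read(path, sep)
    _require_columns(frame, KINETIC_COLUMNS, path)
    frame = _coerce_numeric(frame, ["cycle", "exposure_ms", "intensity"], path)
    frame["cycle"] = frame["cycle"].astype(int)
    ks = KineticSeriesSet(frame[KINETIC_COLUMNS])
    n_missing = len(ks.missing_pairs())
    if n_missing:
        logger.warning("%s: %d (sample, peptide) pair(s) missing from design", path, n_missing)
    return ks


def write_kinetic_table(data: KineticSeriesSet, path, sep: str = "\t") -> None:
    data.frame.to_csv(path, sep=sep, index=False, float_format="%.12g", encoding="utf-8")


# ---------------------------------------------------------------------------
# Sample design


@dataclass
class SampleDesign:
    """Sample→group assignment plus the ordered group comparisons to run."""

    samples: pd.DataFrame  # columns: sample_id, group
    comparisons: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        _require_columns(self.samples, ["sample_id", "group"], "SampleDesign")
        if self.samples["sample_id"].duplicated().any():
            raise FormatError("a sample may belong to exactly one group (duplicate sample_id)")
        groups = set(self.samples["group"])
        counts = self.samples["group"].value_counts()
        self.comparisons = [tuple(c) for c in self.comparisons]
        for g1, g2 in self.comparisons:
            if g1 == g2:
                raise FormatError(f"comparison ({g1}, {g2}): groups must be distinct")
            for g in (g1, g2):
                if g not in groups:
                    raise FormatError(f"comparison references unknown group {g!r}")
                if counts[g] < 2:
                    raise FormatError(f"group {g!r} has <2 samples")
        self.samples = self.samples.reset_index(drop=True)

    def group_samples(self, group: str) -> list[str]:
        return self.samples.loc[self.samples["group"] == group, "sample_id"].tolist()


def read_design(path, comparisons: list[tuple[str, str]] | None = None, sep: str = "\t") -> SampleDesign:
    frame = _read(path, sep)
    _require_columns(frame, ["sample_id", "group"], path)
    return SampleDesign(frame[["sample_id", "group"]], comparisons or [])


def write_design(design: SampleDesign, path, sep: str = "\t") -> None:
    design.samples.to_csv(path, sep=sep, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Kinase→phosphosite score table


@dataclass
class ScoreTable:
    """Kinase→peptide phosphosite scores (PhosphoNET/Kinexus style).

    Duplicate (kinase, peptide) rows resolve to the maximum score — the
    conservative retention rule — and are logged.
    """

    frame: pd.DataFrame  # columns: kinase, peptide_id, score, source

    def __post_init__(self) -> None:
        frame = self.frame.copy()
        if "source" not in frame.columns:
            frame["source"] = "predicted"
        _require_columns(frame, ["kinase", "peptide_id", "score"], "ScoreTable")
        frame["score"] = pd.to_numeric(frame["score"])
        if not np.isfinite(frame["score"].to_numpy(dtype=float)).all():
            raise FormatError("scores must be finite")
        if (frame["score"] < 0).any():
            raise FormatError("scores must be >= 0")
        dup = frame.duplicated(["kinase", "peptide_id"])
        if dup.any():
            logger.warning(
                "ScoreTable: %d duplicate (kinase, peptide) row(s) resolved to max score",
                int(dup.sum()),
            )
            frame = (
                frame.sort_values(["kinase", "peptide_id", "score"])
                .drop_duplicates(["kinase", "peptide_id"], keep="last")
            )
        self.frame = frame[["kinase", "peptide_id", "score", "source"]].reset_index(drop=True)


def read_score_table(path, sep: str = "\t") -> ScoreTable:
    frame = _read(path, sep)
    _require_columns(frame, ["kinase", "peptide_id", "score"], path)
    frame = _coerce_numeric(frame, ["score"], path)
    if frame.empty:
        raise FormatError(f"{path}: empty score table after validation")
    return ScoreTable(frame)


def write_score_table(scores: ScoreTable, path, sep: str = "\t") -> None:
    scores.frame.to_csv(path, sep=sep, index=False, float_format="%.12g", encoding="utf-8")


# ---------------------------------------------------------------------------
# In-vitro kinase targets


@dataclass
class InVitroTargets:
    """Experimentally confirmed kinase→peptide substrate pairs (rank-0 tier)."""

    frame: pd.DataFrame  # columns: kinase, peptide_id

    def __post_init__(self) -> None:
        _require_columns(self.frame, ["kinase", "peptide_id"], "InVitroTargets")
        self.frame = (
            self.frame[["kinase", "peptide_id"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def restrict_to_chip(self, chip_peptides) -> "InVitroTargets":
        chip = set(chip_peptides)
        keep = self.frame["peptide_id"].isin(chip)
        if (~keep).any():
            logger.warning(
                "InVitroTargets: dropped %d pair(s) whose peptide is not on the chip",
                int((~keep).sum()),
            )
        return InVitroTargets(self.frame.loc[keep])


def read_invitro_targets(path, sep: str = "\t") -> InVitroTargets:
    frame = _read(path, sep)
    _require_columns(frame, ["kinase", "peptide_id"], path)
    return InVitroTargets(frame)


def write_invitro_targets(targets: InVitroTargets, path, sep: str = "\t") -> None:
    targets.frame.to_csv(path, sep=sep, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Kinase results


def write_results(results: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a ranked kinase result table with fixed column order.

    Extra columns (permutation p-values, report flag) follow the fixed
    prefix; floats print with 6 decimals.
    """
    _require_columns(results, RESULT_COLUMNS, "results")
    extra = [c for c in results.columns if c not in RESULT_COLUMNS]
    results[RESULT_COLUMNS + extra].to_csv(
        path, sep=sep, index=False, float_format=FLOAT_FORMAT, encoding="utf-8"
    )


def read_results(path, sep: str = "\t") -> pd.DataFrame:
    frame = pd.read_csv(path, sep=sep, encoding="utf-8")
    _require_columns(frame, RESULT_COLUMNS, path)
    return frame
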