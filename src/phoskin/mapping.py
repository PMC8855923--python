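"""Kinase → peptide target maps from phosphosite score tables.

The mapping rule mirrors the PhosphoNET/Kinexus convention used by upstream
kinase analysis on serine/threonine chips: per kinase, candidate phosphosites
with a prediction score strictly greater than ``score_threshold`` (default
300) are rank-ordered by descending score and the top ``top_k`` (default 12)
retained at ranks 1..k.  Experimentally confirmed in-vitro substrates form a
separate tier at rank 0 — they carry no score and never count against the
top-k budget.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from phoskin.io import InVitroTargets, ScoreTable

logger = logging.getLogger("phoskin.mapping")

DEFAULT_SCORE_THRESHOLD = 300.0
DEFAULT_TOP_K = 12


@dataclass
class KinaseMap:
    """Ordered kinase → peptide target lists.

    ``frame`` columns: kinase, peptide_id, rank (0 = in-vitro tier,
    1..k = score-ranked), score (NaN for rank 0), source.
    """

    frame: pd.DataFrame

    def kinases(self) -> list[str]:
        return sorted(self.frame["kinase"].unique())

    def peptides_for(self, kinase: str) -> list[str]:
        sub = self.frame[self.frame["kinase"] == kinase]
        return sub.sort_values("rank")["peptide_id"].tolist()

    def to_tsv(self, path, sep: str = "\t") -> None:
        self.frame.to_csv(path, sep=sep, index=False, float_format="%.12g", encoding="utf-8")


def build_map(
    scores: ScoreTable,
    invitro: InVitroTargets | None,
    chip_peptides,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    top_k: int = DEFAULT_TOP_K,
) -> KinaseMap:
    """Assemble the kinase→peptide map from scores plus in-vitro targets.

    Per kinase: restrict to on-chip peptides, keep scores strictly above
    ``score_threshold``, sort by descending score (ties broken
    lexicographically by peptide_id for reproducibility), keep the first
    ``top_k`` and assign ranks 1..k; prepend in-vitro targets at rank 0.
    A peptide never appears twice within one kinase's list — the in-vitro
    tier takes precedence.  Kinases left with no entries are omitted (and
    counted in the log).
    """
    chip = set(chip_peptides)
    if not chip:
        raise ValueError("chip_peptides must be nonempty")

    sf = scores.frame
    kinases_seen = set(sf["kinase"].unique())

    ranked = sf[(sf["peptide_id"].isin(chip)) & (sf["score"] > score_threshold)].copy()
    ranked = ranked.sort_values(
        ["kinase", "score", "peptide_id"], ascending=[True, False, True]
    )
    ranked = ranked.groupby("kinase", sort=True).head(top_k).copy()
    ranked["rank"] = ranked.groupby("kinase").cumcount() + 1

    parts = []
    if invitro is not None and not invitro.frame.empty:
        iv = invitro.restrict_to_chip(chip).frame.copy()
        kinases_seen |= set(invitro.frame["kinase"].unique())
        iv["rank"] = 0
        iv["score"] = np.nan
        iv["source"] = "in_vitro"
        parts.append(iv[["kinase", "peptide_id", "rank", "score", "source"]])
        # in-vitro precedence: drop score-ranked duplicates, then re-rank
        iv_pairs = pd.MultiIndex.from_frame(iv[["kinase", "peptide_id"]])
        rk_pairs = pd.MultiIndex.from_frame(ranked[["kinase", "peptide_id"]])
        ranked = ranked[~rk_pairs.isin(iv_pairs)]
        ranked = ranked.copy()
        ranked["rank"] = ranked.groupby("kinase").cumcount() + 1
    parts.append(ranked[["kinase", "peptide_id", "rank", "score", "source"]])

    frame = pd.concat(parts, ignore_index=True).sort_values(
        ["kinase", "rank", "peptide_id"]
    )
    omitted = kinases_seen - set(frame["kinase"].unique())
    if omitted:
        logger.info(
            "build_map: %d kinase(s) omitted with zero surviving entries", len(omitted)
        )
    return KinaseMap(frame.reset_index(drop=True))


def _window_identity(a: str, b: str) -> float:
    """Ungapped fractional identity of two phospho-centered windows.

    The phospho-acceptor residue sits at the center of each window; windows
    are compared center-aligned over their overlap, with the denominator the
    longer window's length so trailing truncation counts as mismatch.
    """
    if not a or not b:
        return 0.0
    ca, cb = len(a) // 2, len(b) // 2
    left = min(ca, cb)
    right = min(len(a) - ca, len(b) - cb)
    wa = a[ca - left : ca + right]
    wb = b[cb - left : cb + right]
    matches = sum(x == y for x, y in zip(wa, wb))
    return matches / max(len(a), len(b))


def homology_expand(
    scores: ScoreTable,
    peptide_sequences: dict[str, str],
    identity_threshold: float = 0.90,
    chip_peptides=None,
) -> ScoreTable:
    """Extend scores to chip peptides homologous to scored phosphosites.

    For each scored site whose ±7-residue window matches a chip peptide at
    ungapped identity >= ``identity_threshold`` (phospho position
    center-fixed), an extra row (kinase, chip_peptide, same score,
    source=homology_expanded) is emitted.  Sites lacking a sequence are
    skipped with a warning.  An empty sequence dictionary is a no-op.
    """
    if not peptide_sequences:
        return scores

    chip = set(chip_peptides) if chip_peptides is not None else set(peptide_sequences)
    chip_seqs = {p: peptide_sequences[p] for p in chip if p in peptide_sequences}

    new_rows = []
    n_missing = 0
    for row in scores.frame.itertuples(index=False):
        seq = peptide_sequences.get(row.peptide_id)
        if seq is None:
            n_missing += 1
            continue
        for chip_pep, chip_seq in chip_seqs.items():
            if chip_pep == row.peptide_id:
                continue
            if _window_identity(seq, chip_seq) >= identity_threshold:
                new_rows.append(
                    {
                        "kinase": row.kinase,
                        "peptide_id": chip_pep,
                        "score": row.score,
                        "source": "homology_expanded",
                    }
                )
    if n_missing:
        logger.warning("homology_expand: %d scored row(s) lack a sequence; skipped", n_missing)
    if not new_rows:
        return scores
    combined = pd.concat([scores.frame, pd.DataFrame(new_rows)], ignore_index=True)
    return ScoreTable(combined)  # dedup to max score happens in the container
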