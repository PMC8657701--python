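"""Partitioning Amps into WT and CRISPR classes per genetic background.

A WT Amp is any Amp present above the frequency threshold in at least one
wild-type replicate of a background; a CRISPR Amp is an Amp present in an
edited line but absent from every WT replicate.  WT Amps still seen in an
edited line are "non-targeted"; WT Amps it has lost are "putative
targeted" (presumed edited or deleted).  Per-line rows therefore satisfy
total = crispr + non_targeted and non_targeted + putative_targeted =
|WT set|.  When a line shows no CRISPR Amps at all, WT presence is
re-evaluated at a stricter (lower) secondary threshold before any WT Amp
is declared targeted, so that sub-threshold noise alone does not create
phantom targeting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

log = logging.getLogger(__name__)

__all__ = ["LineMeta", "ClassificationRow", "wt_amp_set", "classify_line",
           "offspring_table", "assign_subgenome"]

GENERATIONS = ("WT", "T0", "T1", "T2")


@dataclass(frozen=True)
class LineMeta:
    """Per-line metadata: background, generation, pedigree, Cas9 status."""

    line_id: str
    background: str
    generation: str              # WT | T0 | T1 | T2
    parent_id: str | None = None
    cas9: str = "unknown"        # present | absent | unknown

    def __post_init__(self):
        if self.generation not in GENERATIONS:
            raise ValueError(f"unknown generation {self.generation!r}")
        if self.generation == "WT" and self.parent_id is not None:
            raise ValueError("WT lines have no parent")


@dataclass
class ClassificationRow:
    line_id: str
    total_amps: int
    crispr_amps: int
    non_targeted_wt: int
    putative_targeted_wt: int
    crispr_set: frozenset = frozenset()
    non_targeted_set: frozenset = frozenset()
    non_segregating: bool | None = None

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.total_amps, self.crispr_amps, self.non_targeted_wt,
                self.putative_targeted_wt)


def _wt_lines(meta: list[LineMeta], background: str) -> list[LineMeta]:
    return [m for m in meta if m.background == background and m.generation == "WT"]


def wt_amp_set(presence: pd.DataFrame, meta: list[LineMeta], background: str
               ) -> tuple[frozenset, int]:
    """The background's WT Amp set and its reported count.

    Membership is the union over WT replicates (present above threshold in
    at least one); the reported count is the mean of the per-replicate
    totals, rounded to the nearest integer, which is what the per-line
    tables print for the WT row.
    """
    wt = _wt_lines(meta, background)
    if not wt:
        raise ValueError(f"background {background!r} has no WT lines")
    members: set[str] = set()
    totals = []
    for m in wt:
        col = presence[m.line_id]
        ids = set(col.index[col])
        members |= ids
        totals.append(len(ids))
    reported = int(round(sum(totals) / len(totals)))
    return frozenset(members), reported


def classify_line(presence: pd.DataFrame, wt_set: frozenset, line_id: str,
                  secondary_presence: pd.DataFrame | None = None
                  ) -> ClassificationRow:
    """Classify one edited line against its background's WT Amp set.

    secondary_presence, if given, is the presence matrix at the stricter
    (lower) threshold used to re-check WT Amps when the line has no CRISPR
    Amps.
    """
    if line_id not in presence.columns:
        raise KeyError(f"line {line_id!r} not in presence matrix")
    col = presence[line_id]
    present = set(col.index[col])
    crispr = present - wt_set
    non_targeted = present & wt_set
    if not crispr and secondary_presence is not None:
        col2 = secondary_presence[line_id]
        non_targeted = set(col2.index[col2]) & wt_set
    putative = wt_set - non_targeted
    return ClassificationRow(
        line_id=line_id,
        total_amps=len(crispr) + len(non_targeted),
        crispr_amps=len(crispr),
        non_targeted_wt=len(non_targeted),
        putative_targeted_wt=len(putative),
        crispr_set=frozenset(crispr),
        non_targeted_set=frozenset(non_targeted),
    )


def offspring_table(presence: pd.DataFrame, meta: list[LineMeta],
                    background: str,
                    secondary_presence: pd.DataFrame | None = None
                    ) -> list[ClassificationRow]:
    """Classification rows for every edited line of a background, ordered
    by pedigree: each T0 line first, then its T1 descendants, each followed
    by their T2 descendants.

    A line whose non-targeted and putative-targeted WT sets equal its
    parent's is flagged non-segregating (the edits passed on unchanged).
    Raises on pedigree cycles.
    """
    wt_set, _ = wt_amp_set(presence, meta, background)
    lines = {m.line_id: m for m in meta
             if m.background == background and m.generation != "WT"}
    children: dict[str | None, list[str]] = {}
    for m in lines.values():
        parent = m.parent_id if m.parent_id in lines else None
        children.setdefault(parent, []).append(m.line_id)
    for v in children.values():
        v.sort()

    rows: list[ClassificationRow] = []
    by_id: dict[str, ClassificationRow] = {}
    seen: set[str] = set()

    def visit(line_id: str, stack: tuple):
        if line_id in stack:
            raise ValueError(f"pedigree cycle involving {line_id!r}")
        if line_id in seen:
            return
        seen.add(line_id)
        row = classify_line(presence, wt_set, line_id, secondary_presence)
        parent = lines[line_id].parent_id
        if parent in by_id:
            prow = by_id[parent]
            row.non_segregating = (
                row.non_targeted_set == prow.non_targeted_set
                and row.crispr_set == prow.crispr_set)
        rows.append(row)
        by_id[line_id] = row
        for child in children.get(line_id, []):
            visit(child, stack + (line_id,))

    roots = sorted(children.get(None, []),
                   key=lambda lid: (GENERATIONS.index(lines[lid].generation), lid))
    for lid in roots:
        visit(lid, ())
    missing = set(lines) - seen
    if missing:
        raise ValueError(f"pedigree cycle: unreachable lines {sorted(missing)}")
    return rows


def rows_to_frame(rows: list[ClassificationRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.line_id, r.total_amps, r.crispr_amps, r.non_targeted_wt,
          r.putative_targeted_wt, r.non_segregating) for r in rows],
        columns=["line_id", "total_amps", "crispr_amps", "non_targeted_wt",
                 "putative_targeted_wt", "non_segregating"])


def assign_subgenome(sequence: str, motif_table: dict[str, object],
                     frame_offset: int = 0) -> str:
    """Assign an Amp to a subgenome by diagnostic peptide motifs.

    The amplicon is translated in the design frame (frame_offset from the
    amplicon start) and each subgenome's motif(s) are searched in the
    peptide.  Exactly one matching subgenome gives the call; zero or
    several give "NA".  Stop codons translate to '*' and simply fail to
    match any motif; a peptide that is all stops draws a warning.
    """
    seq = sequence.upper()[frame_offset:]
    seq = seq[: len(seq) - len(seq) % 3]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # partial codons already trimmed
        pep = str(Seq(seq).translate())
    if pep and set(pep) == {"*"}:
        log.warning("amplicon translates to stops only; no motif can match")
        return "NA"
    hits = []
    for sg, motifs in motif_table.items():
        if isinstance(motifs, str):
            motifs = [motifs]
        if any(m.upper() in pep for m in motifs):
            hits.append(sg)
    return hits[0] if len(hits) == 1 else "NA"
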