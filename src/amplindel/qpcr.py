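"""qPCR relative copy-number estimation (Pfaffl-style efficiency model).

Used to corroborate large deletions in a tandem gene family: if edited
lines lost whole amplicon copies, the target/reference copy-number ratio
drops relative to wild type.  The instrument reports a percent efficiency
E_CFX; the amplification base is E = E_CFX/100 + 1 (E = 2 is perfect
doubling), and the target copy number per haploid genome is

    ratio = N * E_ref^MCq_ref / E_target^MCq_target

with N the reference gene's copies per haploid genome and MCq the mean
quantification cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QpcrAssay", "efficiency", "copy_ratio", "crispr_vs_wt_ratio"]


@dataclass(frozen=True)
class QpcrAssay:
    """One amplification target on one sample.

    Give either e_cfx (instrument percent efficiency) or e (transformed
    base) directly.  n_copies is meaningful for reference genes only.
    """

    target_name: str
    mcq: float
    e_cfx: float | None = None
    e: float | None = None
    n_copies: int = 2

    def __post_init__(self):
        if (self.e_cfx is None) == (self.e is None):
            raise ValueError("give exactly one of e_cfx or e")
        if self.mcq <= 0:
            raise ValueError("mcq must be > 0")
        e = self.base
        if not 1.5 < e < 2.5:       # E_CFX sanity range (50, 150)
            raise ValueError(f"efficiency {e} outside the (50%, 150%) sanity range")

    @property
    def base(self) -> float:
        return efficiency(self.e_cfx) if self.e is None else self.e


def efficiency(e_cfx: float) -> float:
    """Amplification base from the instrument's percent efficiency:
    E = E_CFX/100 + 1 (100% -> 2.0, perfect doubling)."""
    if e_cfx <= 0:
        raise ValueError("e_cfx must be > 0")
    return e_cfx / 100.0 + 1.0


def copy_ratio(ref: QpcrAssay, target: QpcrAssay) -> float:
    """Target copies per haploid genome relative to the reference gene:
    N * E_ref^MCq_ref / E_target^MCq_target."""
    return ref.n_copies * ref.base ** ref.mcq / target.base ** target.mcq


def crispr_vs_wt_ratio(crispr: dict[str, list[float]],
                       wt: dict[str, list[float]]) -> dict[str, float]:
    """Fold change of amplicon copy number in edited vs wild-type lines.

    crispr / wt map reference-gene name -> per-line copy ratios computed
    with that reference.  Returns the per-gene fold (mean CRISPR ratio /
    mean WT ratio) plus a "pooled" entry, the geometric mean across
    reference genes.
    """
    if set(crispr) != set(wt):
        raise ValueError(
            f"reference gene sets differ: {sorted(crispr)} vs {sorted(wt)}")
    if not crispr:
        raise ValueError("no reference genes")
    folds = {}
    for gene in sorted(crispr):
        folds[gene] = float(np.mean(crispr[gene]) / np.mean(wt[gene]))
    folds["pooled"] = float(np.exp(np.mean(np.log(
        [folds[g] for g in sorted(crispr)]))))
    return folds
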