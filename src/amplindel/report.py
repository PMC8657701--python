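"""Summary artifacts: stage-statistics table, heatmap matrix, MDS.

Everything here is a pure function of upstream pipeline outputs; the
tested contract is the tabular data, with graphics left to the caller.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["stage_table", "minmax_heatmap_matrix", "mds_coordinates"]

_STAGE_ROWS = ["Pairs (raw reads)", "Merged", "Filtered", "Denoised",
               "Matched to the amplicon database", "Assigned to Amps"]


def stage_table(stats: dict) -> pd.DataFrame:
    """Per-stage read-survival percentages in the conventional layout.

    Merged/Filtered/Denoised are relative to the previous stage; Matched
    is the share of denoised-contained reads whose Amp matched the
    external database; Assigned is relative to the raw pairs.  Percentages
    are printed with two decimals; the Pairs row carries the raw count.
    """
    pairs = stats["pairs"]
    merged = stats.get("merged", 0)
    filtered = stats.get("filtered", 0)
    denoised = stats.get("denoised_reads", 0)
    matched = stats.get("matched_reads")
    assigned = stats.get("assigned_reads")

    def pct(num, den):
        return 100.0 * num / den if den else 0.0

    values = [100.0, pct(merged, pairs), pct(filtered, merged),
              pct(denoised, filtered),
              pct(matched, denoised) if matched is not None else np.nan,
              pct(assigned, pairs) if assigned is not None else np.nan]
    shown = [f"100 ({pairs:,} reads)"] + [
        "NA" if np.isnan(v) else f"{v:.2f}" for v in values[1:]]
    return pd.DataFrame({"stage": _STAGE_ROWS, "percent": values,
                         "formatted": shown})


def minmax_heatmap_matrix(tmm: pd.DataFrame, row_order: list[str] | None = None,
                          annotations: pd.DataFrame | None = None
                          ) -> pd.DataFrame:
    """Row-wise min-max scaling to [0, 1] for heatmap display.

    Rows are reordered to row_order (e.g. dendrogram leaf order) when
    given; constant rows map to 0 by convention.  annotations (per-Amp
    side columns such as WT/CRISPR status) are passed through reindexed.
    """
    if row_order is not None:
        tmm = tmm.loc[row_order]
    x = tmm.to_numpy(dtype=float)
    lo = x.min(axis=1, keepdims=True)
    span = x.max(axis=1, keepdims=True) - lo
    scaled = np.where(span > 0, (x - lo) / np.where(span > 0, span, 1.0), 0.0)
    out = pd.DataFrame(scaled, index=tmm.index, columns=tmm.columns)
    if annotations is not None:
        out = out.join(annotations.reindex(out.index))
    return out


def mds_coordinates(tmm: pd.DataFrame, n_axes: int = 2
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (metric) multidimensional scaling of the lines.

    Lines are tmm's columns; distances are Euclidean between their
    normalized abundance profiles.  Returns (coordinates, eigenvalues);
    coordinates are defined up to rotation/reflection, with the sign fixed
    so each axis's largest-magnitude loading is positive.
    """
    if tmm.shape[1] < 3:
        raise ValueError("MDS needs at least 3 lines")
    x = tmm.to_numpy(dtype=float).T
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    n = sq.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ sq @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = evecs[:, :n_axes] * np.sqrt(np.maximum(evals[:n_axes], 0.0))
    for k in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    frame = pd.DataFrame(coords, index=tmm.columns,
                         columns=[f"axis{k + 1}" for k in range(n_axes)])
    return frame, evals
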