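"""TMM normalization, per-line frequencies, and the presence threshold.

Between-line count normalization follows the trimmed mean of M-values
method (Robinson & Oshlack 2010) with the standard defaults: reference
column chosen by the upper quartile of library-size-scaled counts closest
to the mean, 30% two-sided trim on M-values, 5% on A-values, inverse
asymptotic-variance (precision) weighting, and scale factors renormalized
to geometric mean 1.  Normalized values are reported in counts-per-million
units: count / (library size * factor) * 1e6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["AbundanceMatrix", "tmm_factors", "tmm_normalize", "frequencies",
           "presence"]

_CPM = 1e6  # units constant for normalized values


def _quartile_ref(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> int:
    f = np.quantile(counts, p, axis=0) / lib
    return int(np.argmin(np.abs(f - f.mean())))


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float = 0.3, sum_trim: float = 0.05,
              weighted: bool = True) -> float:
    """TMM factor of one column against the reference column."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)
    rank_e = rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    if weighted:
        f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(log_r[keep])
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame, weighted: bool = True) -> pd.Series:
    """TMM scale factors per column, renormalized to geometric mean 1.

    weighted=True applies the standard precision (inverse asymptotic
    variance) weighting of M-values.  Note the weights depend on absolute
    counts, so factors are exactly invariant to rescaling a single column
    only with weighted=False; with weighting the invariance is approximate
    (the trimmed gene set is unchanged, the weights shift slightly).
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two lines")
    x = counts.to_numpy(dtype=float)
    x = x[x.sum(axis=1) > 0]       # all-zero rows carry no information
    lib = x.sum(axis=0)
    zero = np.nonzero(lib <= 0)[0]
    if zero.size:
        raise ValueError(f"line(s) with zero total counts: "
                         f"{list(counts.columns[zero])}")
    ref_idx = _quartile_ref(x, lib)
    f = np.array([_tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx],
                            weighted=weighted)
                  for j in range(x.shape[1])])
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="tmm_factor")


def tmm_normalize(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Scale factors plus the normalized (CPM-style) matrix."""
    factors = tmm_factors(counts)
    lib = counts.sum(axis=0)
    tmm = counts / (lib * factors) * _CPM
    return factors, tmm


def frequencies(tmm: pd.DataFrame) -> pd.DataFrame:
    """Per-line frequencies in percent: 100 * value / column sum."""
    colsum = tmm.sum(axis=0)
    zero = colsum[colsum <= 0]
    if len(zero):
        raise ValueError(f"all-zero column(s): {list(zero.index)}")
    return 100.0 * tmm / colsum


def presence(freq: pd.DataFrame, threshold_pct: float = 0.3) -> pd.DataFrame:
    """Presence calls at a strict frequency threshold (freq > threshold)."""
    if threshold_pct < 0:
        raise ValueError("threshold must be >= 0")
    return freq > threshold_pct


@dataclass
class AbundanceMatrix:
    """Raw counts with their TMM-normalized values and frequencies."""

    counts: pd.DataFrame
    scale_factors: pd.Series = None
    tmm: pd.DataFrame = None
    freq: pd.DataFrame = None

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "AbundanceMatrix":
        factors, tmm = tmm_normalize(counts)
        return cls(counts=counts, scale_factors=factors, tmm=tmm,
                   freq=frequencies(tmm))

    def presence(self, threshold_pct: float = 0.3) -> pd.DataFrame:
        return presence(self.freq, threshold_pct)
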