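"""Amplicon read processing: merge, filter, dereplicate, denoise, assign.

The chain mirrors the classic UNOISE-style amplicon workflow: paired reads
are merged on their best ungapped overlap with posterior quality
recalculation, merged reads are filtered on expected errors
(EE = sum 10^(-Q/10)), exact duplicates are collapsed, unique sequences are
denoised into centroid amplicons (Amps) with the beta(d) = 2^-(alpha*d+1)
abundance-skew rule, and each sample's reads are assigned back to the
pooled Amp set by global-identity search.

Defaults for the tunable parameters are the optimized values published for
the alpha-gliadin assay (maxdiffs 58.94, maxdiffpct 24.66, maxee 1.13,
minampsize 22.47, identity 0.99); real-valued settings for integer knobs
are floored at the point of use.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from ._seq import phred_to_probs, probs_to_phred, revcomp

__all__ = [
    "MergeParams", "FilterParams", "DenoiseParams", "SearchParams", "Amp",
    "ChainResult", "merge_pairs", "filter_maxee", "dereplicate", "denoise",
    "search_assign", "run_chain", "beta_skew", "posterior_error_probs",
]


@dataclass(frozen=True)
class MergeParams:
    maxdiffs: float = 58.94        # mismatch cap in the overlap (floored)
    maxdiffpct: float = 24.66      # mismatch percentage cap
    min_overlap: int = 16
    qmax: int = 41                 # cap for posterior qualities

    def __post_init__(self):
        if not 0 < self.maxdiffpct < 100:
            raise ValueError("maxdiffpct must be in (0, 100)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass(frozen=True)
class FilterParams:
    maxee: float = 1.13

    def __post_init__(self):
        if self.maxee <= 0:
            raise ValueError("maxee must be > 0")


@dataclass(frozen=True)
class DenoiseParams:
    minampsize: float = 22.47      # minimum abundance to seed a centroid (floored)
    alpha: float = 2.0             # skew-curve steepness
    chimera: bool = True           # de novo two-parent concatenation filter
    chimera_abskew: float = 2.0    # parents must be this many times more abundant

    def __post_init__(self):
        if math.floor(self.minampsize) < 1:
            raise ValueError("minampsize must floor to >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass(frozen=True)
class SearchParams:
    identity: float = 0.99
    mode: str = "global"           # "global" or "exact"

    def __post_init__(self):
        if not 0 < self.identity <= 1:
            raise ValueError("identity must be in (0, 1]")
        if self.mode not in ("global", "exact"):
            raise ValueError("mode must be 'global' or 'exact'")
        if self.mode == "exact" and self.identity != 1:
            raise ValueError("exact mode implies identity 1")


@dataclass
class Amp:
    """A unique denoised amplicon with per-line read counts."""

    id: str
    sequence: str
    size: int = 0
    sample_counts: dict = field(default_factory=dict)


def beta_skew(d: int, alpha: float) -> float:
    """Maximum abundance skew for a variant at edit distance d to join a
    centroid: beta(d) = 2^-(alpha*d + 1)."""
    return 2.0 ** (-(alpha * d + 1.0))


def posterior_error_probs(p1: np.ndarray, p2: np.ndarray, agree: np.ndarray
                          ) -> np.ndarray:
    """Posterior per-base error probabilities in a merged overlap.

    Agreeing columns combine both observations (p1*p2/3 normalized over the
    agreeing outcomes); disagreeing columns keep the higher-quality base
    with an inflated error probability.
    """
    pmin = np.minimum(p1, p2)
    pmax = np.maximum(p1, p2)
    match = (p1 * p2 / 3.0) / (1.0 - p1 - p2 + 4.0 * p1 * p2 / 3.0)
    mismatch = pmin * (1.0 - pmax / 3.0) / (pmin + pmax - 4.0 * pmin * pmax / 3.0)
    return np.where(agree, match, mismatch)


def _to_matrix(items: list[str]) -> np.ndarray:
    return np.frombuffer("".join(items).encode(), dtype="S1").reshape(len(items), -1)


def merge_pairs(r1, r2, params: MergeParams = MergeParams()
                ) -> tuple[list[tuple[str, str, str]], dict]:
    """Merge read pairs on their best ungapped overlap.

    r1/r2 are aligned lists of (id, sequence, quality) records; R2 is
    reverse-complemented before overlapping.  The best overlap maximizes
    matches - 2*mismatches (ties to the longer overlap); the pair is
    rejected when mismatches exceed floor(maxdiffs), the mismatch
    percentage exceeds maxdiffpct, or no overlap >= min_overlap exists.
    Returns (merged records, stats).
    """
    r1, r2 = list(r1), list(r2)
    if len(r1) != len(r2):
        raise ValueError(f"unpaired inputs: {len(r1)} forward vs {len(r2)} reverse")
    n = len(r1)
    merged: list = [None] * n
    maxdiffs = math.floor(params.maxdiffs)

    groups: dict[tuple[int, int], list[int]] = {}
    for i, ((_, s1, _), (_, s2, _)) in enumerate(zip(r1, r2)):
        groups.setdefault((len(s1), len(s2)), []).append(i)

    n_merged = 0
    for (L1, L2), idx in groups.items():
        A = _to_matrix([r1[i][1] for i in idx])
        B = _to_matrix([revcomp(r2[i][1]) for i in idx])
        Q1 = np.vstack([phred_to_probs(r1[i][2]) for i in idx])
        Q2 = np.vstack([phred_to_probs(r2[i][2])[::-1] for i in idx])
        m = len(idx)
        ov_hi = min(L1, L2)
        best_score = np.full(m, np.iinfo(np.int32).min, dtype=np.int64)
        best_ov = np.zeros(m, dtype=np.int32)
        best_mm = np.zeros(m, dtype=np.int32)
        for ov in range(params.min_overlap, ov_hi + 1):
            eq = A[:, L1 - ov:] == B[:, :ov]
            mism = ov - eq.sum(axis=1)
            score = ov - 3 * mism          # matches - 2*mismatches
            upd = score >= best_score      # >= : ties go to the longer overlap
            best_score[upd] = score[upd]
            best_ov[upd] = ov
            best_mm[upd] = mism[upd]
        ok = (best_ov >= params.min_overlap) & (best_mm <= maxdiffs) \
            & (100.0 * best_mm / np.maximum(best_ov, 1) <= params.maxdiffpct) \
            & (best_score > np.iinfo(np.int32).min)

        for ov in np.unique(best_ov[ok]):
            rows = np.nonzero(ok & (best_ov == ov))[0]
            a, b = A[rows, L1 - ov:], B[rows, :ov]
            p1, p2 = Q1[rows, L1 - ov:], Q2[rows, :ov]
            agree = a == b
            keep_first = p1 <= p2          # lower error prob = higher quality
            cons = np.where(agree | keep_first, a, b)
            post = posterior_error_probs(p1, p2, agree)
            for k, row in enumerate(rows):
                i = idx[row]
                rid, s1, q1 = r1[i]
                _, s2, q2 = r2[i]
                seq = s1[:L1 - ov] + cons[k].tobytes().decode() + revcomp(s2)[ov:]
                qual = (q1[:L1 - ov] + probs_to_phred(post[k], qmax=params.qmax)
                        + q2[::-1][ov:])
                merged[i] = (rid, seq, qual)
                n_merged += 1

    out = [rec for rec in merged if rec is not None]
    stats = {"pairs": n, "merged": n_merged,
             "fraction": n_merged / n if n else 0.0}
    return out, stats


def filter_maxee(records, params: FilterParams = FilterParams()
                 ) -> tuple[list[tuple[str, str]], dict]:
    """Keep reads whose expected error count sum(10^(-Q/10)) <= maxee.

    Returns (sequence-only records, stats).  A malformed quality string
    raises ValueError naming the record.
    """
    kept = []
    n = 0
    for rid, seq, qual in records:
        n += 1
        if len(qual) != len(seq):
            raise ValueError(f"record {rid}: quality length != sequence length")
        try:
            ee = float(phred_to_probs(qual).sum())
        except ValueError as exc:
            raise ValueError(f"record {rid}: {exc}") from exc
        if ee <= params.maxee:
            kept.append((rid, seq))
    return kept, {"input": n, "kept": len(kept),
                  "fraction": len(kept) / n if n else 0.0}


def dereplicate(seqs) -> list[tuple[str, int]]:
    """Collapse exact duplicate sequences.

    Accepts raw strings or (id, seq[, ...]) records.  Returns (sequence,
    abundance) sorted by abundance descending, ties broken lexicographically
    by sequence.
    """
    counts: dict[str, int] = {}
    for item in seqs:
        seq = item if isinstance(item, str) else item[1]
        counts[seq] = counts.get(seq, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def _is_chimera(x: str, parents: list[str]) -> bool:
    """True if x is a perfect left/right concatenation of two distinct,
    more abundant sequences."""
    if len(parents) < 2:
        return False
    L = len(x)
    pref = []
    suf = []
    for pseq in parents:
        k = 0
        for a, b in zip(x, pseq):
            if a != b:
                break
            k += 1
        pref.append(k)
        k = 0
        for a, b in zip(reversed(x), reversed(pseq)):
            if a != b:
                break
            k += 1
        suf.append(k)
    for i in range(len(parents)):
        for j in range(len(parents)):
            if i != j and pref[i] + suf[j] >= L and pref[i] < L and suf[j] < L:
                return True
    return False


def denoise(uniques: list[tuple[str, int]], params: DenoiseParams = DenoiseParams()
            ) -> list[tuple[str, int]]:
    """UNOISE-style greedy centroid pass over abundance-sorted uniques.

    A unique U joins an existing centroid C at edit distance d > 0 iff
    size(U)/size(C) <= beta(d) = 2^-(alpha*d+1), where size(C) is the
    centroid's founding abundance; among eligible centroids the closest one
    wins (ties: larger centroid, then earlier centroid).  Otherwise U founds
    a new centroid if its abundance >= floor(minampsize).  Joined
    abundances accumulate into the centroid size.  The optional de novo
    chimera pass removes centroids that are perfect two-parent
    concatenations of more abundant centroids.

    Returns (sequence, accumulated size) sorted by size descending.
    """
    minsize = math.floor(params.minampsize)
    cent_seq: list[str] = []
    cent_founder: list[int] = []   # founding abundance, used by the skew rule
    cent_size: list[int] = []
    for seq, a in uniques:
        best = None  # (d, -founder, index)
        for ci in range(len(cent_seq)):
            skew = a / cent_founder[ci]
            # largest d with beta(d) >= skew
            dmax = math.floor((-math.log2(skew) - 1.0) / params.alpha)
            if dmax < 1:
                continue
            res = edlib.align(seq, cent_seq[ci], mode="NW", task="distance",
                              k=dmax)
            d = res["editDistance"]
            if d == -1 or d == 0:
                continue
            cand = (d, -cent_founder[ci], ci)
            if best is None or cand < best:
                best = cand
        if best is not None:
            cent_size[best[2]] += a
        elif a >= minsize:
            cent_seq.append(seq)
            cent_founder.append(a)
            cent_size.append(a)
    out = sorted(zip(cent_seq, cent_size), key=lambda kv: (-kv[1], kv[0]))
    if params.chimera and len(out) > 2:
        keep = []
        for i, (seq, size) in enumerate(out):
            # candidate parents: sufficiently more abundant centroids
            # (chimeras arise late in PCR and stay rare) of the candidate's
            # own length — a crossover between homologous templates yields a
            # same-length product, whereas InDel variants of a parent change
            # length and must not be explained away as chimeras
            parents = [s for s, sz in out[:i]
                       if sz >= params.chimera_abskew * size
                       and len(s) == len(seq)]
            if not _is_chimera(seq, parents):
                keep.append((seq, size))
        out = keep
    return out


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def global_identity(query: str, target: str, k: int = -1) -> float:
    """End-to-end alignment identity = matches / alignment columns, with
    terminal gaps excluded.

    Implemented as a semi-global alignment of the shorter sequence against
    the longer (edlib infix mode), so an overhang of either sequence —
    e.g. untrimmed primers against a primer-trimmed database record —
    counts as free terminal gaps rather than differences.  Returns -1.0
    when k >= 0 and the (terminal-gap-free) edit distance exceeds k.
    """
    a, b = (query, target) if len(query) <= len(target) else (target, query)
    res = edlib.align(a, b, mode="HW", task="path", k=k)
    if res["editDistance"] == -1:
        return -1.0
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(res["cigar"])]
    # any residual end gaps of the shorter sequence are trimmed too
    while ops and ops[0][1] in "ID":
        ops.pop(0)
    while ops and ops[-1][1] in "ID":
        ops.pop()
    cols = sum(n for n, _ in ops)
    eq = sum(n for n, op in ops if op == "=")
    return eq / cols if cols else 1.0


def search_assign(queries, db: list[tuple[str, str]],
                  params: SearchParams = SearchParams()
                  ) -> tuple[dict, dict]:
    """Assign each query to its best database hit at or above the identity
    threshold.

    queries: (id, seq) or (id, seq, weight) records; db: (id, seq) records.
    Ties break on higher identity, then longer hit, then lexicographic id.
    Returns (assignments: qid -> (hit id or None, identity),
    counts: db id -> accumulated weight of assigned queries).
    """
    if not db:
        raise ValueError("empty search database")
    assignments: dict = {}
    counts: dict = {rid: 0.0 for rid, _ in db}
    exact = {seq: rid for rid, seq in reversed(db)} if params.mode == "exact" else None
    for item in queries:
        qid, seq = item[0], item[1]
        w = item[2] if len(item) > 2 else 1
        if exact is not None:
            hit = exact.get(seq)
            assignments[qid] = (hit, 1.0 if hit else 0.0)
            if hit:
                counts[hit] += w
            continue
        best = None  # (identity, hit id, hit seq)
        for rid, tseq in db:
            kmax = math.ceil((1.0 - params.identity)
                             * max(len(seq), len(tseq))) + 1
            ident = global_identity(seq, tseq, k=kmax)
            if ident < params.identity:
                continue
            if best is None:
                best = (ident, rid, tseq)
                continue
            tied = abs(ident - best[0]) <= 1e-12
            if (ident > best[0] + 1e-12
                    or (tied and len(tseq) > len(best[2]))
                    or (tied and len(tseq) == len(best[2]) and rid < best[1])):
                best = (ident, rid, tseq)
        if best is None:
            assignments[qid] = (None, 0.0)
        else:
            assignments[qid] = (best[1], best[0])
            counts[best[1]] += w
    return assignments, counts


@dataclass
class ChainResult:
    counts: pd.DataFrame           # Amps x lines, integer read counts
    amps: list[Amp]
    stats: dict                    # pooled stage statistics

    @property
    def amp_sequences(self) -> list[tuple[str, str]]:
        return [(a.id, a.sequence) for a in self.amps]


def run_chain(samples, merge_params: MergeParams = MergeParams(),
              filter_params: FilterParams = FilterParams(),
              denoise_params: DenoiseParams = DenoiseParams(),
              search_params: SearchParams = SearchParams(),
              match_db=None, match_params: SearchParams | None = None
              ) -> ChainResult:
    """Run the full read-processing chain over a set of samples.

    samples: list of (line_id, r1_records, r2_records).  Amps are denoised
    from the pooled filtered reads of all samples; per-line counts come
    from assigning each line's merged reads to the pooled Amp set.  If
    match_db (a list of (id, seq) or an AmpliconDB) is given, Amps are also
    matched against it and the matched-read total is reported in stats.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("need at least one sample")
    merged_per_line: dict[str, list] = {}
    stats = {"pairs": 0, "merged": 0, "filtered": 0}
    pooled_filtered: list[str] = []
    for line_id, r1, r2 in samples:
        try:
            merged, mstats = merge_pairs(r1, r2, merge_params)
            filtered, fstats = filter_maxee(merged, filter_params)
        except ValueError as exc:
            raise ValueError(f"sample {line_id}: {exc}") from exc
        merged_per_line[line_id] = merged
        stats["pairs"] += mstats["pairs"]
        stats["merged"] += mstats["merged"]
        stats["filtered"] += fstats["kept"]
        pooled_filtered.extend(seq for _, seq in filtered)

    uniques = dereplicate(pooled_filtered)
    centroids = denoise(uniques, denoise_params)
    amps = [Amp(id=f"Amp{i + 1}", sequence=seq, size=size)
            for i, (seq, size) in enumerate(centroids)]
    stats["denoised_reads"] = sum(a.size for a in amps)
    stats["n_amps"] = len(amps)

    amp_db = [(a.id, a.sequence) for a in amps]
    line_ids = [line_id for line_id, _, _ in samples]
    counts = pd.DataFrame(0, index=[a.id for a in amps], columns=line_ids,
                          dtype=np.int64)
    assigned_total = 0
    if amps:
        for line_id in line_ids:
            weighted = [(f"u{j}", seq, ab) for j, (seq, ab) in
                        enumerate(dereplicate(merged_per_line[line_id]))]
            _, line_counts = search_assign(weighted, amp_db, search_params)
            for a in amps:
                c = int(round(line_counts[a.id]))
                counts.loc[a.id, line_id] = c
                a.sample_counts[line_id] = c
            assigned_total += int(counts[line_id].sum())
    stats["assigned_reads"] = assigned_total

    if match_db is not None:
        db_records = match_db.records if hasattr(match_db, "records") else list(match_db)
        mp = match_params or search_params
        hits, _ = search_assign(amp_db, db_records, mp)
        matched = [aid for aid, (hit, _) in hits.items() if hit is not None]
        stats["matched_amps"] = len(matched)
        stats["matched_reads"] = sum(a.size for a in amps if a.id in set(matched))
    return ChainResult(counts=counts, amps=amps, stats=stats)
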