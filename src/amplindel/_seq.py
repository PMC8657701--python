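"""Low-level DNA helpers shared across the pipeline.

Only plain strings are passed around; Biopython objects are created at the
I/O boundary.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

#: IUPAC nucleotide codes mapped to the set of unambiguous bases they cover.
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_mismatches(pattern: str, window: str) -> int:
    """Number of positions where `window` is incompatible with `pattern`.

    `pattern` may carry IUPAC ambiguity codes; `window` is expected to be
    unambiguous (an N in the window matches nothing but N in the pattern).
    """
    mm = 0
    for p, b in zip(pattern, window):
        if b not in IUPAC.get(p, ()):
            mm += 1
    return mm


def scan_primer(seq: str, primer: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All start positions where `primer` matches `seq` with <= max_mismatch.

    Returns (position, mismatches) pairs sorted by position.  The scan is
    done on a numpy view so multi-kilobase inputs stay cheap.
    """
    n, k = len(seq), len(primer)
    if k == 0 or n < k:
        return []
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    hits = []
    # accumulate mismatch counts for every offset in one vectorized pass per
    # primer position (k is ~20, n can be kilobases)
    counts = np.zeros(n - k + 1, dtype=np.int32)
    for j, p in enumerate(primer.upper()):
        allowed = np.frombuffer("".join(sorted(IUPAC.get(p, {p}))).encode(), dtype="S1")
        col = arr[j:j + counts.size]
        counts += ~np.isin(col, allowed)
    for i in np.nonzero(counts <= max_mismatch)[0]:
        hits.append((int(i), int(counts[i])))
    return hits


def phred_to_probs(qual: str) -> np.ndarray:
    """Per-base error probabilities from a Phred+33 quality string."""
    q = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.float64) - 33.0
    if q.size and (q.min() < 0 or q.max() > 93):
        raise ValueError("quality string is not Phred+33")
    return 10.0 ** (-q / 10.0)


def probs_to_phred(p: np.ndarray, qmax: int = 41, qmin: int = 2) -> str:
    """Quality string from error probabilities, rounded and clamped."""
    with np.errstate(divide="ignore"):
        q = -10.0 * np.log10(np.maximum(p, 1e-12))
    q = np.clip(np.rint(q), qmin, qmax).astype(np.uint8) + 33
    return q.tobytes().decode()
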