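"""Non-redundant amplicon database construction.

Full-length family sequences (e.g. genomic alpha-gliadin accessions) are
reduced to the in-silico PCR amplicon: the region between the best forward
primer match and the best downstream reverse primer match, with both primers
trimmed.  Exact duplicate amplicons are collapsed, keeping provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO

from ._seq import revcomp, scan_primer

log = logging.getLogger(__name__)

__all__ = ["PrimerPair", "AmpliconDB", "extract_amplicon", "build_db"]


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse PCR primers, both written 5'->3' on their own
    strand; the reverse primer therefore matches the minus strand and is
    searched as its reverse complement.  IUPAC ambiguity codes are honored
    (R in the reverse primer matches A or G)."""

    forward: str
    reverse: str

    def __post_init__(self):
        from ._seq import IUPAC
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p:
                raise ValueError(f"{name} primer is empty")
            bad = set(p.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"{name} primer has non-IUPAC codes: {bad}")


@dataclass
class AmpliconDB:
    """Deduplicated amplicon records plus provenance of collapsed inputs."""

    records: list[tuple[str, str]] = field(default_factory=list)
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def sequences(self) -> list[str]:
        return [s for _, s in self.records]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.records:
                fh.write(f">{rid}\n{seq}\n")


def extract_amplicon(seq: str, primers: PrimerPair, max_mismatch: int = 1,
                     keep_primers: bool = False,
                     length_window: tuple[int, int] | None = None) -> str | None:
    """In-silico PCR: the region delimited by the primer pair, or None.

    Both primers must match within max_mismatch; among multiple valid
    pairings the longest amplicon wins (optionally restricted to a
    length_window in primer-included coordinates).  Primers are trimmed
    unless keep_primers is set.  A forward match only downstream of every
    reverse match yields None with a logged warning.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    s = seq.upper()
    fhits = scan_primer(s, primers.forward.upper(), max_mismatch)
    rhits = scan_primer(s, revcomp(primers.reverse).upper(), max_mismatch)
    if not fhits or not rhits:
        return None
    flen, rlen = len(primers.forward), len(primers.reverse)
    best = None
    for fpos, _ in fhits:
        for rpos, _ in rhits:
            end = rpos + rlen
            if rpos < fpos + flen:
                continue
            span = end - fpos
            if length_window and not (length_window[0] <= span <= length_window[1]):
                continue
            if best is None or span > best[2]:
                best = (fpos, end, span)
    if best is None:
        log.warning("forward primer match lies downstream of the reverse "
                    "primer match; no amplicon extracted")
        return None
    fpos, end, _ = best
    return s[fpos:end] if keep_primers else s[fpos + flen:end - rlen]


def build_db(fastas, primers: PrimerPair, max_mismatch: int = 1,
             length_window: tuple[int, int] | None = None) -> AmpliconDB:
    """Build a non-redundant amplicon database from multi-FASTA inputs.

    fastas: paths/handles to FASTA files, or iterables of (id, sequence)
    pairs.  Duplicate amplicons (exact string after uppercasing) collapse
    into one record whose provenance lists every source id.
    """
    order: list[str] = []
    prov: dict[str, list[str]] = {}
    n_inputs = 0
    for fasta in fastas:
        if isinstance(fasta, (str, bytes)) or hasattr(fasta, "read"):
            entries = ((r.id, str(r.seq)) for r in SeqIO.parse(fasta, "fasta"))
        else:
            entries = iter(fasta)
        for sid, seq in entries:
            n_inputs += 1
            amp = extract_amplicon(seq, primers, max_mismatch=max_mismatch,
                                   length_window=length_window)
            if amp is None:
                continue
            if amp not in prov:
                prov[amp] = []
                order.append(amp)
            prov[amp].append(sid)
    if not order:
        raise ValueError(
            f"no amplicon could be extracted from {n_inputs} input sequences")
    db = AmpliconDB()
    for i, amp in enumerate(order, start=1):
        rid = f"amp{i:04d}"
        db.records.append((rid, amp))
        db.provenance[rid] = prov[amp]
    return db
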