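"""Synthetic multi-copy gene families, CRISPR edits, and paired-end reads.

The simulator emulates the structure of a tandemly duplicated prolamin-like
gene family spread over the A/B/D subgenomes of polyploid wheat: dozens of
paralogous copies that share conserved primer landing sites and two sgRNA
target sites, diverge from each other by point substitutions, and carry a
short subgenome-diagnostic peptide motif in frame.  Edited descendants get
small NHEJ-style InDels at the Cas9 cut site (3 bp upstream of the PAM) and,
optionally, whole-copy losses that mimic large rearrangements of a tandem
locus.  Reads are 2x280 paired-end with a linearly decaying quality profile
and substitution errors whose per-base probability follows the emitted
quality scores.

All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawning, so every artifact is reproducible
byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from ._seq import revcomp, scan_primer
from .phylo import find_cut_sites

__all__ = [
    "FamilySpec", "EditSpec", "ReadSimSpec", "FamilySimulationError",
    "simulate_family", "apply_edits", "simulate_reads", "pcr_amplify",
    "find_cut_sites",
    "FORWARD_PRIMER", "REVERSE_PRIMER", "SGALPHA1", "SGALPHA2",
    "DEFAULT_MOTIFS",
]

# amplicon design shipped as defaults: the published alpha-gliadin assay
FORWARD_PRIMER = "GTTAGAGTTCCAGTGCCACAA"   # aGli900F1
REVERSE_PRIMER = "GGTTGTTGTGGTTGCGRATA"    # 33mer1R2, 5'->3' on the minus strand
SGALPHA1 = "GCCACAAGAGCAAGTTCCAT"
SGALPHA2 = "GGTTGTGATGGAAATGGTTG"

# subgenome-diagnostic peptide motifs; synthetic placeholders, editable by
# the caller (real diagnostic motifs are a curation input, not code)
DEFAULT_MOTIFS = {"A": "FRPQ", "B": "YEVW", "D": "HNIC"}

# one canonical codon per amino acid, used to embed peptide motifs in frame
_CODON = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC", "G": "GGT",
    "H": "CAT", "I": "ATC", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCA", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAC",
}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class FamilySimulationError(ValueError):
    """Raised when a spec cannot produce a usable family."""


@dataclass(frozen=True)
class FamilySpec:
    """Layout of a synthetic multi-copy gene family.

    divergence_within is the expected pairwise substitution divergence
    between paralogs; each copy is mutated independently at half that rate.
    Primer sites, sgRNA target sites and the motif codons are conserved by
    default (they are conserved in the real family, which is what makes the
    assay possible); set conserve_primers=False to let divergence destroy
    primer sites, which raises FamilySimulationError when it happens.
    """

    n_copies_per_subgenome: dict[str, int] = field(
        default_factory=lambda: {"A": 4, "B": 4, "D": 4})
    ancestral_length: int = 800
    divergence_within: float = 0.02
    subgenome_motifs: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MOTIFS))
    seed: int = 0
    forward_primer: str = FORWARD_PRIMER
    reverse_primer: str = REVERSE_PRIMER
    sgrna1: str = SGALPHA1
    sgrna2: str = SGALPHA2
    conserve_primers: bool = True

    def __post_init__(self):
        if not 0 <= self.divergence_within <= 0.1:
            raise ValueError("divergence_within must be in [0, 0.1]")
        for sg, n in self.n_copies_per_subgenome.items():
            if n < 1:
                raise ValueError(f"subgenome {sg}: need >= 1 copy")
            if sg not in self.subgenome_motifs:
                raise ValueError(f"no motif configured for subgenome {sg}")


@dataclass(frozen=True)
class EditSpec:
    """CRISPR edits to apply to a family.

    edits: (copy_id, signed indel length, offset from the cut site); negative
    lengths are deletions, positive insertions.  zygosity_fraction gives the
    molecular fraction carrying the edit (1.0 = homozygous); it can be a
    scalar or a per-copy-id mapping.  large_deletion lists copies removed
    entirely, emulating a rearrangement of the tandem locus.
    """

    target_site: str = SGALPHA2
    site_name: str = "sgAlpha2"
    edits: tuple = ()
    large_deletion: frozenset = frozenset()
    zygosity_fraction: float | dict = 1.0
    seed: int = 0


@dataclass(frozen=True)
class ReadSimSpec:
    """Paired-end read simulation settings (2 x read_length, Phred+33).

    substitution_error_rate is the mean per-base substitution probability;
    the quality profile (truncated normal, mean decaying linearly by
    quality_decay Q units across the read) is shifted so that the mean error
    probability implied by the emitted qualities equals this rate, and
    errors are then injected per base with probability 10^(-Q/10).
    """

    depth: float = 200.0
    read_length: int = 280
    substitution_error_rate: float = 0.002
    quality_decay: float = 8.0
    quality_sd: float = 3.0
    q_min: int = 2
    q_max: int = 41
    seed: int = 0


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _encode_peptide(pep: str) -> str:
    return "".join(_CODON[a] for a in pep.upper())


def _instantiate(seq: str, rng: np.random.Generator) -> str:
    """Replace IUPAC ambiguity codes with a concrete compatible base."""
    from ._seq import IUPAC
    out = []
    for ch in seq.upper():
        allowed = sorted(IUPAC[ch])
        out.append(allowed[0] if len(allowed) == 1
                   else allowed[int(rng.integers(len(allowed)))])
    return "".join(out)


def _ancestral_layout(spec: FamilySpec, rng: np.random.Generator):
    """Build the ancestral amplicon and remember the conserved intervals."""
    fwd = _instantiate(spec.forward_primer, rng)
    rev_rc = _instantiate(revcomp(spec.reverse_primer), rng)
    motif_len = 3 * max(len(m) for m in spec.subgenome_motifs.values())
    pads = [12, 60, 84, 66]
    parts, conserved = [], []
    pos = 0

    def emit(s: str, keep: bool):
        nonlocal pos
        parts.append(s)
        if keep:
            conserved.append((pos, pos + len(s)))
        pos += len(s)

    emit(fwd, True)
    emit(_random_dna(rng, pads[0]), False)
    motif_at = pos
    emit("N" * motif_len, True)            # placeholder, replaced per subgenome
    emit(_random_dna(rng, pads[1]), False)
    emit(spec.sgrna1 + "TGG", True)        # protospacer + PAM
    emit(_random_dna(rng, pads[2]), False)
    emit(spec.sgrna2 + "TGG", True)
    emit(_random_dna(rng, pads[3]), False)
    emit(rev_rc, True)
    amplicon = "".join(parts)
    if spec.ancestral_length < len(amplicon):
        raise FamilySimulationError(
            f"ancestral_length {spec.ancestral_length} shorter than the "
            f"amplicon span {len(amplicon)}")
    return amplicon, motif_at, motif_len, conserved


def simulate_family(spec: FamilySpec) -> pd.DataFrame:
    """Generate the family truth table: copy_id, subgenome, sequence.

    Identical seeds give identical output.  Raises FamilySimulationError if
    divergence destroys a primer site (possible only with
    conserve_primers=False).
    """
    rng = _rng(spec.seed, 1)
    amplicon, motif_at, motif_len, conserved = _ancestral_layout(spec, rng)
    flank5 = _random_dna(rng, 80)
    flank3_len = spec.ancestral_length - len(amplicon) - len(flank5)
    flank3 = _random_dna(rng, max(flank3_len, 0))
    shift = len(flank5)
    conserved = [(a + shift, b + shift) for (a, b) in conserved]
    mutable = np.ones(len(flank5) + len(amplicon) + len(flank3), dtype=bool)
    if spec.conserve_primers:
        for a, b in conserved:
            mutable[a:b] = False
    else:
        # motif codons stay conserved either way: they are the subgenome tag
        mutable[shift + motif_at:shift + motif_at + motif_len] = False

    per_copy_rate = spec.divergence_within / 2.0
    rows = []
    for sg in sorted(spec.n_copies_per_subgenome):
        motif = _encode_peptide(spec.subgenome_motifs[sg]).ljust(motif_len, "A")
        anc = (flank5 + amplicon[:motif_at] + motif
               + amplicon[motif_at + motif_len:] + flank3)
        base = np.frombuffer(anc.encode(), dtype="S1").copy()
        for i in range(spec.n_copies_per_subgenome[sg]):
            copy_rng = _rng(spec.seed, 2, ord(sg), i)
            seq = base.copy()
            hit = copy_rng.random(seq.size) < per_copy_rate
            hit &= mutable
            idx = np.nonzero(hit)[0]
            if idx.size:
                # substitute with one of the three other bases
                cur = seq[idx]
                offs = copy_rng.integers(1, 4, size=idx.size)
                code = np.searchsorted(_BASES, cur)
                seq[idx] = _BASES[(code + offs) % 4]
            s = seq.tobytes().decode()
            if not spec.conserve_primers:
                if (not scan_primer(s, spec.forward_primer, 1)
                        or not scan_primer(s, revcomp(spec.reverse_primer), 1)):
                    raise FamilySimulationError(
                        f"divergence destroyed a primer site in copy {sg}{i + 1:02d}")
            rows.append((f"{sg}{i + 1:02d}", sg, s))
    return pd.DataFrame(rows, columns=["copy_id", "subgenome", "sequence"])


def apply_edits(family: pd.DataFrame, spec: EditSpec
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply CRISPR edits; return (molecules, truth InDel table).

    molecules has one row per distinct molecule species with a relative
    weight: a heterozygous edit yields both the edited and the wild-type
    molecule of that copy.  Copies in large_deletion are dropped entirely.
    The truth table records, per edited molecule, the exact InDel with its
    0-based position on the unedited copy and the offset from the cut site.
    """
    rng = _rng(spec.seed, 3)
    seqs = dict(zip(family["copy_id"], family["sequence"]))
    unknown = [c for c, _, _ in spec.edits if c not in seqs]
    unknown += [c for c in spec.large_deletion if c not in seqs]
    if unknown:
        raise KeyError(f"edited copies not in family: {sorted(set(unknown))}")

    def zygosity(copy_id: str) -> float:
        z = spec.zygosity_fraction
        f = z.get(copy_id, 1.0) if isinstance(z, dict) else float(z)
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"zygosity fraction for {copy_id} outside [0,1]")
        return f

    edited: dict[str, list] = {}
    truth_rows = []
    for copy_id, length, offset in spec.edits:
        if length == 0:
            raise ValueError("indel length must be nonzero")
        if copy_id in spec.large_deletion:
            continue
        seq = seqs[copy_id]
        cuts = find_cut_sites(seq, spec.target_site)
        if not cuts:
            raise ValueError(
                f"copy {copy_id} has no {spec.site_name} protospacer+PAM site")
        cut = cuts[0][0]
        pos = cut + offset
        if not 0 <= pos <= len(seq):
            raise ValueError(f"edit offset {offset} outside copy {copy_id}")
        if length < 0:
            if pos - length > len(seq):
                raise ValueError(f"deletion runs off the end of {copy_id}")
            new = seq[:pos] + seq[pos - length:]
            kind = "deletion"
        else:
            new = seq[:pos] + _random_dna(rng, length) + seq[pos:]
            kind = "insertion"
        mol_id = f"{copy_id}.e{len(edited.get(copy_id, [])) + 1}"
        edited.setdefault(copy_id, []).append((mol_id, new))
        truth_rows.append((mol_id, copy_id, spec.site_name, kind,
                           abs(length), length, pos, offset))

    mol_rows = []
    for copy_id, sg, seq in family.itertuples(index=False):
        if copy_id in spec.large_deletion:
            continue
        variants = edited.get(copy_id, [])
        if not variants:
            mol_rows.append((copy_id, copy_id, sg, seq, 1.0, False))
            continue
        f = zygosity(copy_id)
        share = f / len(variants)
        for mol_id, new in variants:
            mol_rows.append((mol_id, copy_id, sg, new, share, True))
        if f < 1.0:
            mol_rows.append((copy_id, copy_id, sg, seq, 1.0 - f, False))
    molecules = pd.DataFrame(
        mol_rows, columns=["molecule_id", "copy_id", "subgenome",
                           "sequence", "weight", "edited"])
    truth = pd.DataFrame(
        truth_rows, columns=["molecule_id", "copy_id", "site", "type",
                             "length", "signed_length", "position", "offset"])
    return molecules, truth


def pcr_amplify(molecules: pd.DataFrame, forward: str = FORWARD_PRIMER,
                reverse: str = REVERSE_PRIMER, max_mismatch: int = 1
                ) -> pd.DataFrame:
    """Extract the primer-to-primer amplicon (primers included) per molecule."""
    from .db import extract_amplicon, PrimerPair
    primers = PrimerPair(forward=forward, reverse=reverse)
    out = []
    for row in molecules.itertuples(index=False):
        amp = extract_amplicon(row.sequence, primers, max_mismatch=max_mismatch,
                               keep_primers=True)
        if amp is None:
            raise FamilySimulationError(
                f"molecule {row.molecule_id} lost a primer site")
        out.append((row.molecule_id, amp, row.weight))
    return pd.DataFrame(out, columns=["molecule_id", "amplicon", "weight"])


def _calibrated_profile(sim: ReadSimSpec) -> np.ndarray:
    """Positional quality means whose implied mean error matches the
    requested substitution rate."""
    L = sim.read_length
    rel = np.linspace(0.0, 1.0, L)
    if sim.substitution_error_rate <= 0:
        return np.full(L, float(sim.q_max))

    grid = np.linspace(sim.q_min, sim.q_max, 400)[:, None]
    loss = 10.0 ** (-grid / 10.0)

    def mean_error(q0: float) -> float:
        mu = q0 - sim.quality_decay * rel
        a = (sim.q_min - mu) / sim.quality_sd
        b = (sim.q_max - mu) / sim.quality_sd
        # E[10^(-Q/10)] under the truncated normal, by quadrature per position
        pdf = truncnorm.pdf(grid, a, b, loc=mu, scale=sim.quality_sd)
        w = pdf / pdf.sum(axis=0)
        return float((w * loss).sum(axis=0).mean())

    lo, hi = float(sim.q_min), float(sim.q_max) + sim.quality_decay
    target = sim.substitution_error_rate
    if mean_error(lo) < target:
        return np.full(L, lo) - sim.quality_decay * rel + sim.quality_decay
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if mean_error(mid) > target:
            lo = mid
        else:
            hi = mid
    q0 = 0.5 * (lo + hi)
    return q0 - sim.quality_decay * rel


def simulate_reads(amplicons: pd.DataFrame, sim: ReadSimSpec
                   ) -> tuple[list, list]:
    """Simulate paired reads from amplicon molecules.

    amplicons needs columns molecule_id, amplicon, weight.  Per molecule the
    pair count is Poisson(depth * weight).  R1 reads the plus strand from
    the 5' end, R2 the minus strand; both are truncated to read_length (or
    the amplicon length if shorter).  Returns (r1, r2) lists of
    (id, sequence, quality) records.
    """
    if len(amplicons) == 0:
        raise ValueError("no molecules to sequence")
    mu = _calibrated_profile(sim)
    a = (sim.q_min - mu) / sim.quality_sd
    b = (sim.q_max - mu) / sim.quality_sd
    r1_out, r2_out = [], []
    for m, row in enumerate(amplicons.itertuples(index=False)):
        rng = _rng(sim.seed, 4, m)
        n = int(rng.poisson(sim.depth * row.weight))
        if n == 0:
            continue
        L = min(sim.read_length, len(row.amplicon))
        fwd = np.frombuffer(row.amplicon[:L].encode(), dtype="S1")
        rev = np.frombuffer(revcomp(row.amplicon)[:L].encode(), dtype="S1")
        for template, sink in ((fwd, r1_out), (rev, r2_out)):
            q = truncnorm.rvs(a[:L], b[:L], loc=mu[:L], scale=sim.quality_sd,
                              size=(n, L), random_state=rng)
            q = np.rint(q).astype(np.int16)
            perr = 10.0 ** (-q / 10.0)
            hits = rng.random((n, L)) < (perr if sim.substitution_error_rate > 0
                                         else 0.0)
            reads = np.broadcast_to(template, (n, L)).copy()
            if hits.any():
                ii, jj = np.nonzero(hits)
                code = np.searchsorted(_BASES, reads[ii, jj])
                offs = rng.integers(1, 4, size=ii.size)
                reads[ii, jj] = _BASES[(code + offs) % 4]
            quals = (q + 33).astype(np.uint8)
            for k in range(n):
                sink.append((f"{row.molecule_id}_r{k}",
                             reads[k].tobytes().decode(),
                             quals[k].tobytes().decode()))
    return r1_out, r2_out
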