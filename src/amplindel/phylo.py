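"""Closest wild-type reference selection and InDel calling.

Each putatively edited amplicon (CRISPR Amp) is compared to the wild-type
amplicon it most plausibly derives from.  In a multi-copy family with
near-identical paralogs that choice matters: the reference is picked from
the CRISPR Amp's cluster in a neighbor-joining dendrogram of all Amps of
the background, falling back to the globally nearest WT Amp when its
cluster holds none.  InDels are then read off a global pairwise alignment,
left-normalized, and attributed to the nearest Cas9 cut site (3 bp 5' of
the NGG PAM) within a window.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align
from skbio import TreeNode

from ._seq import revcomp, scan_primer

log = logging.getLogger(__name__)

__all__ = [
    "TargetSite", "IndelCall", "DEFAULT_SITES", "make_aligner",
    "pairwise_distances", "neighbor_joining", "tree_clusters",
    "pick_reference", "find_cut_sites", "call_indels", "indel_table",
]


@dataclass(frozen=True)
class TargetSite:
    """A Cas9 target: 20-mer protospacer followed by an NGG PAM; the blunt
    cut falls cut_offset bp 5' of the PAM."""

    name: str
    protospacer: str
    pam: str = "NGG"
    cut_offset: int = 3

    def __post_init__(self):
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be a 20-mer")


DEFAULT_SITES = (
    TargetSite("sgAlpha1", "GCCACAAGAGCAAGTTCCAT"),
    TargetSite("sgAlpha2", "GGTTGTGATGGAAATGGTTG"),
)


@dataclass
class IndelCall:
    crispr_amp_id: str
    reference_wt_amp_id: str
    type: str                    # insertion | deletion
    length: int
    position: int                # 1-based on the reference
    attributed_site: str | None
    distance_to_cut: int


def make_aligner() -> Align.PairwiseAligner:
    """The module's one documented scoring scheme: match +1, mismatch -1,
    gap open -2, gap extend -0.5, global."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def _align_pair(aligner, a: str, b: str) -> tuple[str, str]:
    aln = aligner.align(a, b)[0]
    return aln[0], aln[1]


def _gap_runs(row: str) -> int:
    runs = 0
    in_gap = False
    for ch in row:
        if ch == "-":
            if not in_gap:
                runs += 1
            in_gap = True
        else:
            in_gap = False
    return runs


def pairwise_distances(amps: list[tuple[str, str]]
                       ) -> tuple[list[str], np.ndarray]:
    """p-distance matrix over global pairwise alignments.

    d = (mismatched columns + gap runs) / alignment columns, so a single
    contiguous InDel costs one difference regardless of its length —
    appropriate when small NHEJ InDels should not dominate the distance.
    """
    if len(amps) < 2:
        raise ValueError("need at least two amplicons")
    aligner = make_aligner()
    labels = [aid for aid, _ in amps]
    n = len(amps)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ra, rb = _align_pair(aligner, amps[i][1], amps[j][1])
            cols = len(ra)
            mism = sum(1 for x, y in zip(ra, rb)
                       if x != "-" and y != "-" and x != y)
            gaps = _gap_runs(ra) + _gap_runs(rb)
            d[i, j] = d[j, i] = (mism + gaps) / cols
    return labels, d


def neighbor_joining(d: np.ndarray, labels: list[str]) -> str:
    """Classic neighbor joining; returns an unrooted newick string.

    Q-matrix joins with Saitou-Nei branch lengths; negative branch lengths
    are clamped to 0 with a warning; ties in Q break deterministically on
    the joined nodes' smallest contained label.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if d.shape != (n, n):
        raise ValueError("distance matrix does not match labels")
    dm = d.astype(float).copy()
    news = [f"{lab}" for lab in labels]
    tags = list(labels)            # smallest contained label, for tie-breaks
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            log.warning("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dm[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dm[i, j] - r[i] - r[j]
                key = (q, min(tags[i], tags[j]), max(tags[i], tags[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        bi = 0.5 * dm[i, j] + (r[i] - r[j]) / (2 * (len(active) - 2))
        bj = dm[i, j] - bi
        bi, bj = clamp(bi), clamp(bj)
        new = f"({news[i]}:{bi:.17g},{news[j]}:{bj:.17g})"
        u = len(news)
        news.append(new)
        tags.append(min(tags[i], tags[j]))
        dm = np.pad(dm, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dm[u, k] = dm[k, u] = 0.5 * (dm[i, k] + dm[j, k] - dm[i, j])
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    ba = clamp(0.5 * (dm[a, b] + dm[a, c] - dm[b, c]))
    bb = clamp(0.5 * (dm[a, b] + dm[b, c] - dm[a, c]))
    bc = clamp(0.5 * (dm[a, c] + dm[b, c] - dm[a, b]))
    return (f"({news[a]}:{ba:.17g},{news[b]}:{bb:.17g},"
            f"{news[c]}:{bc:.17g});")


def tree_clusters(newick: str, height_cut: float | None = None
                  ) -> list[set[str]]:
    """Maximal subtrees under a height cut of the midpoint-rooted tree.

    height_cut defaults to the median depth of internal nodes.  Returns the
    leaf-name sets of the clusters.
    """
    tree = TreeNode.read(io.StringIO(newick))
    if tree.count(tips=True) > 2:
        try:
            tree = tree.root_at_midpoint()
        except Exception:      # zero-length or degenerate trees
            pass
    depths = {}
    for node in tree.preorder():
        parent_depth = depths.get(id(node.parent), 0.0)
        depths[id(node)] = parent_depth + (node.length or 0.0)
    internal = [depths[id(n)] for n in tree.non_tips() if n.parent is not None]
    if height_cut is None:
        height_cut = float(np.median(internal)) if internal else 0.0

    clusters: list[set[str]] = []

    def walk(node):
        if node.is_tip():
            clusters.append({node.name})
            return
        if node.parent is not None and depths[id(node)] >= height_cut:
            clusters.append({tip.name for tip in node.tips()})
            return
        for child in node.children:
            walk(child)

    walk(tree)
    return clusters


def pick_reference(crispr_amp: str, wt_ids, labels: list[str],
                   d: np.ndarray, newick: str | None = None,
                   height_cut: float | None = None) -> str:
    """The WT Amp a CRISPR Amp is compared against.

    Preference order: the minimum-distance WT Amp inside the CRISPR Amp's
    dendrogram cluster, else (cluster holds no WT Amp, or no tree) the
    nearest WT Amp overall.  Distance ties break on the lexicographically
    smallest WT id.  Never returns a non-WT Amp.
    """
    wt_ids = set(wt_ids)
    if not wt_ids:
        raise ValueError("empty WT set")
    idx = {lab: i for i, lab in enumerate(labels)}
    qi = idx[crispr_amp]
    candidates: set[str] = set()
    if newick is not None:
        for cluster in tree_clusters(newick, height_cut):
            if crispr_amp in cluster:
                candidates = (cluster & wt_ids) - {crispr_amp}
                break
    if not candidates:
        candidates = wt_ids & set(labels)
    return min(candidates, key=lambda w: (d[qi, idx[w]], w))


def find_cut_sites(seq: str, protospacer: str, max_mismatch: int = 0
                   ) -> list[tuple[int, str]]:
    """All Cas9 cut positions for protospacer+NGG on either strand.

    A cut position c means the blunt cut falls between c-1 and c (0-based),
    3 bp 5' of the PAM on the protospacer strand.  The protospacer may
    match with up to max_mismatch substitutions; the PAM NGG is exact.
    """
    sites = []
    n, k = len(seq), len(protospacer)
    s = seq.upper()
    for pos, _ in scan_primer(s, protospacer.upper(), max_mismatch):
        if pos + k + 3 <= n and s[pos + k + 1:pos + k + 3] == "GG":
            sites.append((pos + k - 3, "+"))
    for pos, _ in scan_primer(s, revcomp(protospacer).upper(), max_mismatch):
        if pos >= 3 and s[pos - 3:pos - 1] == "CC":
            sites.append((pos + 3, "-"))
    return sorted(set(sites))


def _left_normalize(ref: str, events: list[dict]) -> list[dict]:
    """Shift gaps maximally left in repeat context (standard variant
    normalization)."""
    out = []
    for ev in events:
        p, L = ev["pos"], ev["length"]
        if ev["type"] == "deletion":
            while p > 0 and ref[p - 1] == ref[p + L - 1]:
                p -= 1
        else:
            s = ev["seq"]
            while p > 0 and ref[p - 1] == s[-1]:
                s = ref[p - 1] + s[:-1]
                p -= 1
            ev = {**ev, "seq": s}
        out.append({**ev, "pos": p})
    return out


def call_indels(crispr_seq: str, ref_seq: str,
                sites=DEFAULT_SITES, window: int = 10,
                site_max_mismatch: int = 2,
                crispr_id: str = "query", ref_id: str = "reference"
                ) -> list[IndelCall]:
    """InDels of a CRISPR Amp relative to its WT reference.

    Each maximal gap run in the global alignment is one InDel, reported at
    its left-normalized 1-based reference position.  Cut sites are indexed
    for every protospacer+NGG occurrence on both strands (allowing
    site_max_mismatch substitutions in the protospacer) and an InDel is
    attributed to the nearest cut when |distance| <= window.
    """
    if not crispr_seq or not ref_seq:
        raise ValueError("sequences must be non-empty")
    aligner = make_aligner()
    qa, ra = _align_pair(aligner, crispr_seq, ref_seq)
    # qa = aligned query, ra = aligned reference
    events = []
    ref_pos = 0
    col = 0
    ncol = len(ra)
    while col < ncol:
        if ra[col] == "-":                      # insertion relative to ref
            start = col
            while col < ncol and ra[col] == "-":
                col += 1
            events.append({"type": "insertion", "pos": ref_pos,
                           "length": col - start, "seq": qa[start:col]})
        elif qa[col] == "-":                    # deletion of ref bases
            start_ref = ref_pos
            while col < ncol and qa[col] == "-" and ra[col] != "-":
                ref_pos += 1
                col += 1
            events.append({"type": "deletion", "pos": start_ref,
                           "length": ref_pos - start_ref, "seq": ""})
        else:
            ref_pos += 1
            col += 1
    events = _left_normalize(ref_seq, events)

    cuts = []
    for site in sites:
        for c, _strand in find_cut_sites(ref_seq, site.protospacer,
                                         site_max_mismatch):
            cuts.append((site.name, c))

    calls = []
    for ev in events:
        attributed, dist = None, 0
        if cuts:
            name, c = min(cuts, key=lambda sc: (abs(ev["pos"] - sc[1]),
                                                cuts.index(sc)))
            dist = ev["pos"] - c
            if abs(dist) <= window:
                attributed = name
        calls.append(IndelCall(
            crispr_amp_id=crispr_id, reference_wt_amp_id=ref_id,
            type=ev["type"], length=ev["length"], position=ev["pos"] + 1,
            attributed_site=attributed, distance_to_cut=dist))
    return calls


def indel_table(amps: list[tuple[str, str]], wt_ids, crispr_ids,
                sites=DEFAULT_SITES, window: int = 10,
                height_cut: float | None = None,
                site_max_mismatch: int = 2) -> list[IndelCall]:
    """End-to-end InDel characterization for a background.

    amps: all (id, sequence) Amps of the background; wt_ids / crispr_ids:
    the classification of those ids.  Builds the dendrogram, picks each
    CRISPR Amp's reference, and calls InDels against it.
    """
    labels, d = pairwise_distances(amps)
    newick = neighbor_joining(d, labels) if len(labels) >= 3 else None
    seqs = dict(amps)
    calls: list[IndelCall] = []
    for cid in sorted(crispr_ids):
        ref = pick_reference(cid, wt_ids, labels, d, newick, height_cut)
        calls.extend(call_indels(seqs[cid], seqs[ref], sites, window,
                                 site_max_mismatch, crispr_id=cid, ref_id=ref))
    return calls
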