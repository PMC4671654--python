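"""LCR (segmental-duplication) detection and characterization.

Paralogous blocks are found by exact k-mer self-matching (both orientations,
trivial diagonal excluded), collinear chaining on the (anti-)diagonal, and
block-level verification by alignment.  Pairwise identities are computed
from a global alignment path; identity profiles summarize local identity in
100 bp windows; and the degenerate 13-mer PRDM9 recombination-hotspot motif
(5'-CCNCCNTNNCCNC-3') is scanned on both strands.

The chainer assumes substitution-dominated divergence between copies (the
diagonal of a copy pair stays within a small band); small indels are
absorbed by the band parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .locus import GenomeInterval

__all__ = [
    "ParalogPair",
    "ParalogFamily",
    "MotifHit",
    "PRDM9_MOTIF",
    "detect_paralogs",
    "group_paralog_families",
    "pairwise_identity",
    "alignment_columns",
    "identity_profile",
    "scan_prdm9",
    "revcomp",
]

PRDM9_MOTIF = "CCNCCNTNNCCNC"

_COMP_TABLE = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


@dataclass(frozen=True)
class ParalogPair:
    """A pair of paralogous blocks with orientation and identities."""

    block_a: GenomeInterval
    block_b: GenomeInterval
    relative_orientation: str  # "+" / "-"
    identity: float            # matches / ungapped aligned columns
    identity_gapped: float     # matches / all alignment columns (internal gaps count)
    n_anchors: int = 0


@dataclass(frozen=True)
class ParalogFamily:
    members: tuple  # of GenomeInterval, the distinct copies
    pairs: tuple    # of ParalogPair within the family

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def median_length(self) -> float:
        return float(np.median([m.length for m in self.members]))


@dataclass(frozen=True)
class MotifHit:
    position: int     # forward-strand start of the 13-mer window
    strand: str       # "+" / "-"
    score_fraction: float  # matched informative positions / 8


# --------------------------------------------------------------------------
# k-mer anchors
# --------------------------------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _CODE[_c] = _i
    _CODE[_c + 32] = _i


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed k-mer integers (k <= 31) at each start position."""
    n = len(codes) - k + 1
    out = np.zeros(n, dtype=np.uint64)
    for off in range(k):
        out = (out << np.uint64(2)) | codes[off : off + n].astype(np.uint64)
    return out


def _anchor_pairs(seq: str, k: int, max_occ: int = 10):
    """Exact self-match anchors: arrays (i, j, strand) with i < j, strand +1
    for direct and -1 for inverted matches; the trivial diagonal excluded."""
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence must contain only ACGT")
    rc = 3 - codes[::-1]
    kf = _kmer_codes(codes, k)
    kr = _kmer_codes(rc, k)
    n = len(codes)
    nf = len(kf)
    # reverse entry at rc-index jr corresponds to forward window start n-k-jr
    vals = np.concatenate([kf, kr])
    pos = np.concatenate([np.arange(nf, dtype=np.int64),
                          (n - k) - np.arange(nf, dtype=np.int64)])
    tag = np.concatenate([np.zeros(nf, dtype=np.int8), np.ones(nf, dtype=np.int8)])
    order = np.argsort(vals, kind="stable")
    vals, pos, tag = vals[order], pos[order], tag[order]
    starts = np.flatnonzero(np.concatenate([[True], vals[1:] != vals[:-1]]))
    ends = np.concatenate([starts[1:], [len(vals)]])

    ai, aj, ast = [], [], []
    for s, e in zip(starts, ends):
        if e - s < 2 or e - s > max_occ:
            continue
        p, t = pos[s:e], tag[s:e]
        fpos = p[t == 0]
        rpos = p[t == 1]
        for x in range(len(fpos)):
            for y in range(x + 1, len(fpos)):
                a, b = fpos[x], fpos[y]
                if a != b:
                    ai.append(min(a, b)); aj.append(max(a, b)); ast.append(1)
        for x in range(len(fpos)):
            for y in range(len(rpos)):
                a, b = fpos[x], rpos[y]
                if a < b:
                    ai.append(a); aj.append(b); ast.append(-1)
    if not ai:
        return (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.int8))
    arr = np.unique(np.stack([np.array(ai), np.array(aj),
                              np.array(ast, dtype=np.int64)]), axis=1)
    return arr[0], arr[1], arr[2].astype(np.int8)


def _chain(i: np.ndarray, j: np.ndarray, key: np.ndarray, k: int,
           band: int, max_gap: int, min_anchors: int):
    """Cluster anchors collinear on ``key`` (diagonal or anti-diagonal)."""
    if len(i) == 0:
        return []
    # pass 1: cluster on the (anti-)diagonal alone, so anchors from slightly
    # offset sub-diagonals (e.g. an embedded copy a few bp off) stay together
    order = np.argsort(key, kind="stable")
    i, j, key = i[order], j[order], key[order]
    kbrk = np.diff(key) > band
    kid = np.concatenate([[0], np.cumsum(kbrk)])
    blocks = []
    for c in np.unique(kid):
        sel = kid == c
        ii, jj = i[sel], j[sel]
        # pass 2: split each diagonal cluster at positional gaps
        o2 = np.argsort(ii, kind="stable")
        ii, jj = ii[o2], jj[o2]
        gbrk = np.diff(ii) > max_gap
        gid = np.concatenate([[0], np.cumsum(gbrk)])
        for g in np.unique(gid):
            s2 = gid == g
            if s2.sum() < min_anchors:
                continue
            blocks.append((int(ii[s2].min()), int(ii[s2].max()) + k,
                           int(jj[s2].min()), int(jj[s2].max()) + k,
                           int(s2.sum())))
    return blocks


def detect_paralogs(seq: str, k: int = 31, min_block: int = 10_000,
                    min_identity: float = 0.9, max_gap: int = 2_000,
                    band: int = 100, min_anchors: int = 10,
                    chrom: str = "seq") -> list:
    """Detect paralogous block pairs in a sequence by self-alignment.

    Returns :class:`ParalogPair` objects with blocks at least ``min_block``
    bp on both sides and alignment identity at least ``min_identity``.
    Coordinates are 0-based offsets into ``seq`` (labelled ``chrom``).
    """
    if len(seq) < 2 * min_block:
        raise ValueError("sequence shorter than two minimum blocks")
    i, j, strand = _anchor_pairs(seq, k)
    pairs = []
    for st in (+1, -1):
        sel = strand == st
        key = (j[sel] - i[sel]) if st > 0 else (i[sel] + j[sel])
        for a0, a1, b0, b1, nanch in _chain(i[sel], j[sel], key, k,
                                            band, max_gap, min_anchors):
            if (a1 - a0) < min_block or (b1 - b0) < min_block:
                continue
            sa = seq[a0:a1]
            sb = seq[b0:b1] if st > 0 else revcomp(seq[b0:b1])
            ident, ident_gapped = pairwise_identity(sa, sb)
            if ident < min_identity:
                continue
            pairs.append(ParalogPair(
                GenomeInterval(chrom, a0, a1),
                GenomeInterval(chrom, b0, b1),
                "+" if st > 0 else "-",
                ident, ident_gapped, nanch,
            ))
    pairs.sort(key=lambda pr: (pr.block_a.start, pr.block_b.start))
    return pairs


def group_paralog_families(pairs, min_reciprocal: float = 0.5) -> list:
    """Group block pairs into LCR families.

    Blocks referring to the same genomic copy (reciprocal overlap at least
    ``min_reciprocal``) are unified; families are the connected components of
    the copy graph induced by the pairs.  Reciprocal (rather than plain)
    overlap keeps a 45 kb copy embedded inside a 358 kb copy from collapsing
    the two families into one.
    """
    blocks: list = []

    def copy_index(iv: GenomeInterval) -> int:
        for idx, known in enumerate(blocks):
            ov = min(iv.end, known.end) - max(iv.start, known.start)
            if ov > 0 and ov >= min_reciprocal * max(iv.length, known.length):
                # widen the representative to the union
                blocks[idx] = GenomeInterval(known.chrom,
                                             min(known.start, iv.start),
                                             max(known.end, iv.end))
                return idx
        blocks.append(iv)
        return len(blocks) - 1

    edges = []
    for pr in pairs:
        edges.append((copy_index(pr.block_a), copy_index(pr.block_b), pr))
    parent = list(range(len(blocks)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _ in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    groups: dict = {}
    for idx in range(len(blocks)):
        groups.setdefault(find(idx), []).append(idx)
    fams = []
    for members in groups.values():
        mem = tuple(sorted((blocks[m] for m in members), key=lambda b: b.start))
        fam_pairs = tuple(pr for a, b, pr in edges
                          if find(a) == find(members[0]))
        fams.append(ParalogFamily(mem, fam_pairs))
    fams.sort(key=lambda f: -f.median_length)
    return fams


# --------------------------------------------------------------------------
# Identity
# --------------------------------------------------------------------------

def alignment_columns(a: str, b: str) -> str:
    """Column classes of a minimum-edit global alignment of a vs b:
    '=' match, 'X' mismatch, 'I'/'D' gap columns."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    res = edlib.align(a, b, mode="NW", task="path")
    cols = []
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            cols.append(ch * int(num))
            num = ""
    return "".join(cols)


def pairwise_identity(a: str, b: str, orientation: str = "+") -> tuple:
    """(identity, identity_gapped) of a global alignment.

    ``identity`` is matches over ungapped aligned columns (the fraction of
    aligned positions that match); ``identity_gapped`` additionally charges
    internal gap columns, so it is always <= identity.  With
    ``orientation='-'`` the second sequence is reverse-complemented first.
    The pair is aligned in a canonical order, so the measure is exactly
    symmetric even when co-optimal alignment paths differ.
    """
    if orientation == "-":
        b = revcomp(b)
    if b < a:
        a, b = b, a
    cols = alignment_columns(a, b)
    matches = cols.count("=")
    mismatches = cols.count("X")
    ungapped = matches + mismatches
    if ungapped == 0:
        return 0.0, 0.0
    return matches / ungapped, matches / len(cols)


def identity_profile(a: str, b: str, window: int = 100,
                     orientation: str = "+") -> np.ndarray:
    """Per-window identity along the alignment of a vs b: non-overlapping
    windows of ``window`` alignment columns, each scored matches/window
    (mismatch and gap columns count against)."""
    if orientation == "-":
        b = revcomp(b)
    cols = alignment_columns(a, b)
    if len(cols) < window:
        raise ValueError("alignment shorter than one window")
    nwin = len(cols) // window
    arr = np.frombuffer(cols[: nwin * window].encode(), dtype=np.uint8)
    arr = arr.reshape(nwin, window)
    return (arr == ord("=")).mean(axis=1)


# --------------------------------------------------------------------------
# PRDM9 motif scanning
# --------------------------------------------------------------------------

def _informative(motif: str):
    return [(off, c) for off, c in enumerate(motif) if c != "N"]


def scan_prdm9(seq: str, threshold: float = 0.85) -> list:
    """Scan both strands for the degenerate PRDM9 hotspot 13-mer.

    The motif's 8 informative (non-N) positions define the per-site score as
    matched informative positions / 8; a hit requires score strictly above
    ``threshold`` (0.85 by default, i.e. at most one informative mismatch).
    Overlapping hits on opposite strands are counted separately.  Hit
    positions are forward-strand starts of the 13-mer window.
    """
    m = len(PRDM9_MOTIF)
    if len(seq) < m:
        raise ValueError(f"sequence shorter than the {m}-mer motif")
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    n = len(arr) - m + 1
    hits = []
    for strand, motif in (("+", PRDM9_MOTIF), ("-", revcomp(PRDM9_MOTIF))):
        info = _informative(motif)
        score = np.zeros(n, dtype=np.int16)
        for off, c in info:
            score += arr[off : off + n] == ord(c)
        frac = score / len(info)
        for p in np.flatnonzero(frac > threshold):
            hits.append(MotifHit(int(p), strand, float(frac[p])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits
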