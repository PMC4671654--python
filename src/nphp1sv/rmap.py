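"""Restriction-map (Rmap) evidence: in-silico digestion, alignment, SV calling.

Optical mapping produces ordered restriction-fragment-length maps of single
DNA molecules; consensus maps are compared against in-silico digests of
candidate haplotypes to call structural variants.  Fragment sizing error,
missed cuts (partial digestion / unresolved small gaps) and false cuts
(random breakage) are the dominant noise sources; the aligner scores block
pairings of fragment runs under a Gaussian sizing-error model with a fixed
penalty per unmatched cut.

Fragment lengths are in kb throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .locus import Haplotype, LocusArchitecture, make_haplotype

__all__ = [
    "Rmap",
    "RmapAlignment",
    "RmapCall",
    "RmapCallSet",
    "SWAI_SITE",
    "digest_insilico",
    "rmap_from_sites",
    "haplotype_site_positions",
    "candidate_rmaps",
    "merge_small_fragments",
    "align_rmap",
    "consensus_rmap",
    "call_haplotype_rmap",
]

SWAI_SITE = "ATTTAAAT"


@dataclass(frozen=True)
class Rmap:
    """Ordered restriction-fragment lengths (kb) for one molecule/contig."""

    map_id: str
    enzyme: str
    fragments: tuple  # of float, kb, chromosomal order

    @property
    def total_kb(self) -> float:
        return float(sum(self.fragments))

    def __len__(self) -> int:
        return len(self.fragments)


def digest_insilico(seq: str, enzyme: str = SWAI_SITE, map_id: str = "insilico") -> Rmap:
    """Exact in-silico digest: fragments between successive recognition-site
    starts, plus the two flanks.  A sequence without any site yields a single
    fragment spanning the whole molecule."""
    if not enzyme or "N" in enzyme.upper():
        raise ValueError("enzyme recognition sequence must be non-degenerate")
    seq = seq.upper()
    sites = []
    i = seq.find(enzyme)
    while i != -1:
        sites.append(i)
        i = seq.find(enzyme, i + 1)
    return rmap_from_sites(sites, len(seq), enzyme=enzyme, map_id=map_id)


def rmap_from_sites(sites, length_bp: int, enzyme: str = SWAI_SITE,
                    map_id: str = "insilico") -> Rmap:
    """Build an Rmap from cut-site positions (bp) on a molecule of given length."""
    cuts = sorted(set(int(s) for s in sites if 0 < s < length_bp))
    bounds = [0] + cuts + [length_bp]
    frags = tuple((b - a) / 1000.0 for a, b in zip(bounds[:-1], bounds[1:]))
    return Rmap(map_id, enzyme, frags)


def haplotype_site_positions(hap: Haplotype, ref_sites) -> list:
    """Project reference-frame cut sites through a haplotype's segment path
    into haplotype-frame positions (sites in deleted material vanish; sites
    in an inverted segment come out reordered)."""
    ref_sites = np.sort(np.asarray(ref_sites, dtype=np.int64))
    out: list = []
    off = 0
    for seg in hap.segments:
        if not seg.stuffer:
            lo = np.searchsorted(ref_sites, seg.ref_start, side="left")
            hi = np.searchsorted(ref_sites, seg.ref_end, side="left")
            inside = ref_sites[lo:hi]
            if seg.strand > 0:
                out.extend(off + (inside - seg.ref_start))
            else:
                out.extend(off + (seg.ref_end - inside[::-1]))
        off += seg.length
    return [int(x) for x in out]


def candidate_rmaps(arch: LocusArchitecture, ref_sites, labels=None,
                    enzyme: str = SWAI_SITE) -> dict:
    """In-silico digests of the candidate haplotypes (H1..H7 by default),
    given the reference-frame cut-site layout."""
    if labels is None:
        labels = ("H1", "H2", "H3", "H4", "H5", "H6", "H7")
    out = {}
    for label in labels:
        hap = make_haplotype(label, arch)
        sites = haplotype_site_positions(hap, ref_sites)
        out[label] = rmap_from_sites(sites, hap.length, enzyme=enzyme, map_id=label)
    return out


def merge_small_fragments(fragments, min_kb: float):
    """Merge fragments below the resolution limit into the preceding
    fragment (or the following one at the left end), mirroring the loss of
    small restriction fragments from optical-map surfaces."""
    frags = list(fragments)
    i = 0
    while i < len(frags) and len(frags) > 1:
        if frags[i] < min_kb:
            if i > 0:
                frags[i - 1] = frags[i - 1] + frags[i]
                del frags[i]
                i -= 1  # the grown neighbor is re-checked
            else:
                frags[1] = frags[0] + frags[1]
                del frags[0]
        else:
            i += 1
    return tuple(frags)


# --------------------------------------------------------------------------
# Alignment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RmapAlignment:
    """A global block alignment of two Rmaps.

    ``blocks`` are ((q_lo, q_hi), (r_lo, r_hi)) half-open fragment-index runs
    pairing query fragments q_lo..q_hi with reference fragments r_lo..r_hi.
    ``cuts_missed`` counts cuts present in the query but absent from the
    reference run (query run length a > 1); ``cuts_false`` the converse.
    """

    blocks: tuple
    cost: float
    cuts_missed: int
    cuts_false: int


def _block_cost(sq: float, sr, sigma_rel: float, c_cut: float, a: int, b: int):
    return (sq - sr) ** 2 / (2.0 * (sigma_rel * sr) ** 2) + c_cut * (a - 1 + b - 1)


def align_rmap(query: Rmap, ref: Rmap, sigma_rel: float = 0.05,
               c_cut: float = 3.0, delta: int = 3) -> RmapAlignment:
    """Minimum-cost global alignment by dynamic programming over block
    pairings of up to ``delta`` fragments per side.  A block pairing query
    fragments summing to Sq against reference fragments summing to Sr costs
    (Sq-Sr)^2 / (2 (sigma_rel Sr)^2) plus ``c_cut`` per merged cut."""
    q = np.asarray(query.fragments, dtype=float)
    r = np.asarray(ref.fragments, dtype=float)
    if len(q) == 0 or len(r) == 0:
        raise ValueError("both maps must be non-empty")
    n, m = len(q), len(r)
    qs = np.concatenate([[0.0], np.cumsum(q)])
    rs = np.concatenate([[0.0], np.cumsum(r)])

    INF = np.inf
    dp = np.full((n + 1, m + 1), INF)
    dp[0, 0] = 0.0
    a_ch = np.zeros((n + 1, m + 1), dtype=np.int32)
    b_ch = np.zeros((n + 1, m + 1), dtype=np.int32)

    for i in range(1, n + 1):
        for a in range(1, min(delta, i) + 1):
            sq = qs[i] - qs[i - a]
            prev_row = dp[i - a]
            for b in range(1, min(delta, m) + 1):
                sr = rs[b:] - rs[:-b]  # ref run sums ending at j = b..m
                cost = (sq - sr) ** 2 / (2.0 * (sigma_rel * sr) ** 2) \
                    + c_cut * (a - 1 + b - 1)
                cand = prev_row[: m - b + 1] + cost
                row = dp[i]
                better = cand < row[b:]
                if better.any():
                    row[b:][better] = cand[better]
                    a_ch[i, b:][better] = a
                    b_ch[i, b:][better] = b

    if not np.isfinite(dp[n, m]):
        raise ValueError("no feasible alignment (check delta)")

    blocks = []
    i, j = n, m
    while i > 0 or j > 0:
        a, b = int(a_ch[i, j]), int(b_ch[i, j])
        blocks.append(((i - a, i), (j - b, j)))
        i, j = i - a, j - b
    blocks.reverse()
    cuts_missed = sum((qhi - qlo) - 1 for (qlo, qhi), _ in blocks)
    cuts_false = sum((rhi - rlo) - 1 for _, (rlo, rhi) in blocks)
    return RmapAlignment(tuple(blocks), float(dp[n, m]), cuts_missed, cuts_false)


# --------------------------------------------------------------------------
# Consensus and calling
# --------------------------------------------------------------------------

def consensus_rmap(molecules, sigma_rel: float = 0.05, c_cut: float = 3.0,
                   delta: int = 3, map_id: str = "consensus") -> Rmap:
    """Average single-molecule Rmaps from one origin into a consensus map.

    The molecule with the modal fragment count serves as the backbone; every
    other molecule is aligned to it and each aligned block's query mass is
    distributed over the backbone fragments of the block in proportion to
    their sizes, so missed/false cuts in individual molecules average out.
    """
    if not molecules:
        raise ValueError("need at least one molecule")
    counts = [len(m) for m in molecules]
    vals, freq = np.unique(counts, return_counts=True)
    modal = int(vals[np.argmax(freq)])
    backbone = next(m for m in molecules if len(m) == modal)
    back = np.asarray(backbone.fragments, dtype=float)

    acc = np.zeros(len(back))
    nobs = np.zeros(len(back))
    for mol in molecules:
        aln = align_rmap(mol, backbone, sigma_rel=sigma_rel, c_cut=c_cut, delta=delta)
        frags = np.asarray(mol.fragments, dtype=float)
        for (qlo, qhi), (rlo, rhi) in aln.blocks:
            qsum = frags[qlo:qhi].sum()
            weights = back[rlo:rhi] / back[rlo:rhi].sum()
            acc[rlo:rhi] += qsum * weights
            nobs[rlo:rhi] += 1
    est = np.where(nobs > 0, acc / np.maximum(nobs, 1), back)
    return Rmap(map_id, backbone.enzyme, tuple(float(x) for x in est))


@dataclass(frozen=True)
class RmapCall:
    map_id: str
    best: str
    cost: float
    runner_up: str
    margin: float
    ambiguous: bool


@dataclass(frozen=True)
class RmapCallSet:
    calls: tuple  # of RmapCall
    allele_types: tuple  # distinct best labels across consensus maps
    unresolved: bool  # True when every consensus map is ambiguous


def call_haplotype_rmap(consensus_maps, candidates: dict, margin: float = 5.0,
                        sigma_rel: float = 0.05, c_cut: float = 3.0,
                        delta: int = 3, min_fragment_kb: float = 0.8) -> RmapCallSet:
    """Assign each consensus map the minimum-cost candidate haplotype.

    A call is flagged ambiguous when the runner-up candidate's cost lies
    within ``margin`` of the best.  The distinct best labels across consensus
    maps form the allele-type set (more than two types indicates mosaicism).
    """
    cand = {
        lab: Rmap(r.map_id, r.enzyme, merge_small_fragments(r.fragments, min_fragment_kb))
        for lab, r in candidates.items()
    }
    calls = []
    for cons in consensus_maps:
        q = Rmap(cons.map_id, cons.enzyme,
                 merge_small_fragments(cons.fragments, min_fragment_kb))
        costs = {}
        for lab, ref in cand.items():
            try:
                costs[lab] = align_rmap(q, ref, sigma_rel=sigma_rel,
                                        c_cut=c_cut, delta=delta).cost
            except ValueError:
                costs[lab] = np.inf
        ranked = sorted(costs.items(), key=lambda kv: kv[1])
        best, best_cost = ranked[0]
        runner, runner_cost = ranked[1] if len(ranked) > 1 else (best, np.inf)
        gap = runner_cost - best_cost
        calls.append(RmapCall(cons.map_id, best, best_cost, runner,
                              float(gap), bool(gap < margin)))
    allele_types = tuple(dict.fromkeys(c.best for c in calls))
    unresolved = all(c.ambiguous for c in calls) if calls else True
    return RmapCallSet(tuple(calls), allele_types, unresolved)
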