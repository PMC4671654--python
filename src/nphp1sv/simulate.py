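"""Synthetic evidence generation for every assay the pipeline consumes.

Generators emulate, with configurable error models: haplotype sequences with
planted LCR families, fosmid end-sequence-pair (ESP) libraries, SwaI
single-molecule Rmaps, aCGH probe log2 ratios against a four-copy reference
genome, windowed read-depth copy-number tracks, and diploid population
samples drawn from haplotype frequencies.

Every generator is a pure function of its inputs and ``SimParams.seed``; the
seed is combined with a per-generator salt so the streams are independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosage import RegionDosage
from .locus import (
    Genotype,
    GenomeInterval,
    Haplotype,
    LocusArchitecture,
    make_haplotype,
)
from .rmap import (
    Rmap,
    SWAI_SITE,
    haplotype_site_positions,
    merge_small_fragments,
    rmap_from_sites,
)

__all__ = [
    "SimParams",
    "FosmidESP",
    "PopulationSample",
    "default_swai_sites",
    "default_probe_table",
    "synth_haplotype_sequence",
    "simulate_fosmid_library",
    "simulate_rmaps",
    "simulate_acgh",
    "simulate_readdepth",
    "sample_population",
]

# fixed constant for the default SwaI site layout: the layout is part of the
# simulated locus design (like the real genome's site positions), not of the
# per-run randomness, so it does not move with SimParams.seed.
_SITE_LAYOUT_SEED = 20151207

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Error-model and design knobs for all generators.

    Units: lengths in bp, rates per bp or per event, aCGH noise in log2 units,
    read-depth noise in copies.
    """

    seed: int = 0
    paralog_divergence: float = 0.0025  # per-bp substitution rate per LCR copy
    insert_mean: float = 40_000.0       # fosmid insert length
    insert_sd: float = 2_500.0
    rmap_cv: float = 0.05               # multiplicative fragment sizing CV
    rmap_p_miss: float = 0.10           # per true cut
    rmap_false_per_bp: float = 1.0 / 500_000.0
    rmap_min_fragment_bp: float = 800.0
    acgh_sigma: float = 0.10            # per-probe log2 noise
    acgh_identity_factor: float = 1.0   # cross-species hybridization attenuation
    readdepth_window: int = 500
    readdepth_sigma: float = 0.2        # per-window copy-number noise
    swai_sites: tuple | None = None     # override the default site layout
    prdm9_sites: tuple = ()             # positions at which to plant motif copies
    mapq: int = 60

    def __post_init__(self) -> None:
        for name in ("paralog_divergence", "rmap_cv", "rmap_p_miss",
                     "acgh_identity_factor"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.readdepth_window < 100:
            raise ValueError("read-depth window must be >= 100 bp")

    def rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng((int(self.seed), int(salt)))


@dataclass(frozen=True)
class FosmidESP:
    """A fosmid clone's two mapped ends in the reference frame."""

    clone_id: str
    chrom: str
    pos1: int
    strand1: str
    pos2: int
    strand2: str
    mapq: int


@dataclass(frozen=True)
class PopulationSample:
    individual_id: str
    population: str
    genotype: Genotype


def default_swai_sites(arch: LocusArchitecture) -> tuple:
    """Irregular ~15 kb SwaI site grid across the locus (reference frame).

    The layout is deterministic (fixed layout constant) so candidate digests
    and simulated molecules share the same site model across seeds.
    """
    rng = np.random.default_rng(_SITE_LAYOUT_SEED)
    pos = arch.region.start + 4_000
    sites = []
    while True:
        pos += int(rng.uniform(9_000, 21_000))
        if pos >= arch.region.end - 4_000:
            break
        sites.append(pos)
    return tuple(sites)


# --------------------------------------------------------------------------
# Sequence synthesis
# --------------------------------------------------------------------------

_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTacgt", b"TGCATGCA"):
    _COMP[_a] = _b
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _a in enumerate(b"ACGT"):
    _CODE[_a] = _i


def _revcomp_bytes(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = arr.copy()
    if rate <= 0:
        return out
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    if len(hits):
        # substitute with one of the three other bases, uniformly
        shifted = (_CODE[out[hits]] + rng.integers(1, 4, size=len(hits))) % 4
        out[hits] = _BASES[shifted]
    return out


def _reference_bytes(arch: LocusArchitecture, p: SimParams) -> np.ndarray:
    """The H1 reference sequence as bytes, with planted LCR families, SwaI
    sites and optional PRDM9 motif instances."""
    rng = p.rng(1)
    n = arch.region.length
    seq = _BASES[rng.integers(0, 4, size=n)]
    shift = arch.region.start

    masters = {}
    for fam in ("358K", "45K"):
        copies = arch.family(fam)
        if copies:
            mlen = max(c.interval.length for c in copies)
            masters[fam] = _BASES[rng.integers(0, 4, size=mlen)]
    # mirror the real containment 45PROX < 358PROX: the 358 consensus carries
    # the 45 consensus at the embedding offset, so 358-paralog homology runs
    # continuously through the embedded 45 kb copies
    if "45K" in masters and "358K" in masters:
        try:
            p45 = arch.copy("45PROX").interval
            p358 = arch.copy("358PROX").interval
            off = p45.start - p358.start
            if 0 <= off and off + p45.length <= len(masters["358K"]):
                masters["358K"][off : off + p45.length] = \
                    masters["45K"][: p45.length]
        except KeyError:
            pass
    for fam in ("358K", "45K"):  # 45 copies overwrite their host 358 regions
        for c in arch.family(fam):
            body = _mutate(masters[fam][: c.interval.length],
                           p.paralog_divergence, rng)
            if c.orientation < 0:
                body = _revcomp_bytes(body)
            seq[c.interval.start - shift : c.interval.end - shift] = body

    sites = default_swai_sites(arch) if p.swai_sites is None else p.swai_sites
    swai = np.frombuffer(SWAI_SITE.encode(), dtype=np.uint8)
    for s in sites:
        seq[s - shift : s - shift + len(swai)] = swai
    motif = np.frombuffer(b"CCACCATAACCAC", dtype=np.uint8)  # consensus instance
    for s in p.prdm9_sites:
        seq[s - shift : s - shift + len(motif)] = motif
    return seq


def _stuffer_bytes(arch: LocusArchitecture, p: SimParams) -> np.ndarray:
    rng = p.rng(2)
    return _BASES[rng.integers(0, 4, size=arch.stuffer_length)]


def synth_haplotype_sequence(arch: LocusArchitecture, hap: Haplotype,
                             p: SimParams) -> str:
    """Synthesize the DNA sequence of a haplotype.

    One master sequence per LCR family is mutated independently per copy at
    the paralog-divergence rate and planted into a random background; the
    haplotype sequence is then assembled from its reference segment path
    (reverse-complementing inverted segments and filling stuffers with the
    shared 5936 bp stuffer sequence), so all haplotypes of one seed share a
    consistent base sequence.
    """
    base = _reference_bytes(arch, p)
    stuffer = _stuffer_bytes(arch, p)
    shift = arch.region.start
    parts = []
    for seg in hap.segments:
        if seg.stuffer:
            parts.append(stuffer[: seg.stuffer_length])
        else:
            piece = base[seg.ref_start - shift : seg.ref_end - shift]
            parts.append(piece if seg.strand > 0 else _revcomp_bytes(piece))
    return np.concatenate(parts).tobytes().decode("ascii")


# --------------------------------------------------------------------------
# Fosmid ESP libraries
# --------------------------------------------------------------------------

def simulate_fosmid_library(g: Genotype, n_clones: int, p: SimParams) -> list:
    """Sample fosmid clones from a genotype and map their ends onto the H1
    reference frame.

    Clones are drawn from genotype components weighted by fraction; insert
    length is Normal(mean, sd) truncated to positive.  Ends are projected
    through the source haplotype's segment path, so clones spanning a lost
    45 kb copy show an enlarged reference span and clones spanning an
    inversion breakpoint show equal-strand ends.  Clones falling off the
    locus or with an end inside a stuffer (no unique reference position) are
    resampled.
    """
    if n_clones <= 0:
        raise ValueError("n_clones must be positive")
    rng = p.rng(3)
    haps = [h for h, _ in g.components]
    fracs = np.array([f for _, f in g.components], dtype=float)
    chrom = haps[0].arch.region.chrom
    clones: list = []
    attempts = 0
    while len(clones) < n_clones:
        attempts += 1
        if attempts > 200 * n_clones:
            raise RuntimeError("fosmid resampling did not converge")
        hap = haps[rng.choice(len(haps), p=fracs)]
        insert = rng.normal(p.insert_mean, p.insert_sd)
        if insert <= 0 or insert >= hap.length:
            continue
        insert = int(round(insert))
        start = int(rng.integers(0, hap.length - insert))
        r1, s1 = hap.hap_to_ref(start)
        r2, s2 = hap.hap_to_ref(start + insert - 1)
        if r1 is None or r2 is None:
            continue  # end in stuffer: unmappable, resample
        # clone-start read points rightward (+), clone-end read leftward (-)
        strand1 = "+" if s1 > 0 else "-"
        strand2 = "-" if s2 > 0 else "+"
        clones.append(FosmidESP(f"clone{len(clones):05d}", chrom,
                                int(r1), strand1, int(r2), strand2, p.mapq))
    return clones


# --------------------------------------------------------------------------
# Rmaps
# --------------------------------------------------------------------------

def _true_rmap(truth, p: SimParams, enzyme: str) -> Rmap:
    from .rmap import digest_insilico  # local to avoid confusion in callers

    if isinstance(truth, Rmap):
        return truth
    if isinstance(truth, str):
        return digest_insilico(truth, enzyme=enzyme)
    if isinstance(truth, Haplotype):
        sites = default_swai_sites(truth.arch) if p.swai_sites is None else p.swai_sites
        hap_sites = haplotype_site_positions(truth, sites)
        return rmap_from_sites(hap_sites, truth.length, enzyme=enzyme)
    sites, length = truth  # (site positions, molecule length)
    return rmap_from_sites(sites, length, enzyme=enzyme)


def simulate_rmaps(truth, p: SimParams, n_molecules: int,
                   enzyme: str = SWAI_SITE) -> list:
    """Simulate noisy single-molecule Rmaps of one haplotype/sequence.

    ``truth`` may be a sequence, an exact :class:`Rmap`, a
    :class:`~nphp1sv.locus.Haplotype` (digested via the configured site
    layout) or a ``(site_positions, length_bp)`` pair.  Per molecule: each
    true cut is missed with ``rmap_p_miss`` (adjacent fragments merge), false
    cuts arrive as Poisson(rate x length), fragment sizes are scaled by
    Normal(1, CV), and fragments below the resolution limit are merged into a
    neighbor.
    """
    base = _true_rmap(truth, p, enzyme)
    length_kb = base.total_kb
    cuts = np.cumsum(base.fragments)[:-1]  # interior cut positions, kb
    rng = p.rng(4)
    min_kb = p.rmap_min_fragment_bp / 1000.0
    out = []
    for i in range(n_molecules):
        kept = cuts[rng.random(len(cuts)) >= p.rmap_p_miss]
        n_false = rng.poisson(p.rmap_false_per_bp * length_kb * 1000.0)
        false = rng.uniform(0.0, length_kb, size=n_false)
        allcuts = np.sort(np.concatenate([kept, false]))
        bounds = np.concatenate([[0.0], allcuts, [length_kb]])
        frags = np.diff(bounds)
        if p.rmap_cv > 0:
            frags = frags * rng.normal(1.0, p.rmap_cv, size=len(frags))
            frags = np.maximum(frags, 1e-6)
        frags = merge_small_fragments(tuple(float(f) for f in frags), min_kb)
        out.append(Rmap(f"{base.map_id}_mol{i:04d}", enzyme, frags))
    return out


# --------------------------------------------------------------------------
# aCGH and read depth
# --------------------------------------------------------------------------

def _probe_family(arch: LocusArchitecture, pos: int) -> str:
    for c in arch.family("45K"):
        if c.interval.start <= pos < c.interval.end:
            return "45K"
    for c in arch.family("358K"):
        if c.interval.start <= pos < c.interval.end:
            return "358K"
    return "unique"


def _dosage_at(g: Genotype, family: str) -> float:
    """Hybridizable copies of a family's sequence in a genotype: signal sums
    over paralogs because the array tiles only one copy per family."""
    per_hap = {"45K": lambda h: h.count45,
               "358K": lambda h: sum(1 for e in h.elements if e.kind == "lcr358"),
               "unique": lambda h: 1}[family]
    return g.ploidy * sum(f * per_hap(h) for h, f in g.components)


def default_probe_table(arch: LocusArchitecture, spacing_lcr: int = 250,
                        spacing_unique: int = 2_000) -> pd.DataFrame:
    """A probe design tiling one copy of each LCR family at high density
    (45MID; 358PROX outside its embedded 45PROX) plus the unique backbone."""
    rows = []
    c45 = arch.copy("45MID").interval
    for s in range(c45.start, c45.end - 59, spacing_lcr):
        rows.append((s, s + 60))
    c358 = arch.copy("358PROX").interval
    p45 = arch.copy("45PROX").interval
    for s in range(c358.start, c358.end - 59, spacing_lcr * 4):
        if not (p45.start - 60 < s < p45.end):
            rows.append((s, s + 60))
    lcr_spans = [c.interval for c in arch.lcr_copies]
    for s in range(arch.region.start, arch.region.end - 59, spacing_unique):
        if not any(iv.start - 60 < s < iv.end for iv in lcr_spans):
            rows.append((s, s + 60))
    rows.sort()
    return pd.DataFrame(
        {
            "probe_id": [f"p{i:05d}" for i in range(len(rows))],
            "chrom": arch.region.chrom,
            "start": [r[0] for r in rows],
            "end": [r[1] for r in rows],
        }
    )


def simulate_acgh(test: Genotype, ref: Genotype, probes: pd.DataFrame,
                  p: SimParams, arch: LocusArchitecture | None = None) -> RegionDosage:
    """Per-probe log2 ratios of test vs reference hybridizable dosage.

    LR = log2(test dosage x identity factor / ref dosage) + Normal(0, sigma).
    The identity factor models cross-species hybridization attenuation.
    Probes with zero reference dosage are masked (dropped).
    """
    if arch is None:
        arch = (test.components[0][0]).arch
    rng = p.rng(5)
    pos = ((probes["start"] + probes["end"]) // 2).to_numpy()
    fams = [_probe_family(arch, int(x)) for x in pos]
    test_d = np.array([_dosage_at(test, f) for f in fams], dtype=float)
    ref_d = np.array([_dosage_at(ref, f) for f in fams], dtype=float)
    keep = ref_d > 0
    pos, test_d, ref_d = pos[keep], test_d[keep], ref_d[keep]
    signal = test_d * p.acgh_identity_factor
    with np.errstate(divide="ignore"):
        lr = np.log2(signal / ref_d)
    noise = rng.normal(0.0, p.acgh_sigma, size=len(lr)) if p.acgh_sigma > 0 else 0.0
    lr = lr + noise
    order = np.argsort(pos)
    return RegionDosage(
        interval=GenomeInterval(arch.region.chrom, int(pos.min()), int(pos.max()) + 1),
        positions=tuple(int(x) for x in pos[order]),
        values=tuple(float(x) for x in np.asarray(lr)[order]),
        kind="log2ratio",
    )


def simulate_readdepth(g: Genotype, p: SimParams,
                       arch: LocusArchitecture | None = None) -> RegionDosage:
    """Windowed copy-number track: per 500 bp (default) window, the true
    family dosage plus Normal(0, sigma_cn) noise."""
    if arch is None:
        arch = (g.components[0][0]).arch
    rng = p.rng(6)
    w = p.readdepth_window
    starts = np.arange(arch.region.start, arch.region.end - w + 1, w)
    mid = starts + w // 2
    cn = np.array([_dosage_at(g, _probe_family(arch, int(x))) for x in mid],
                  dtype=float)
    if p.readdepth_sigma > 0:
        cn = cn + rng.normal(0.0, p.readdepth_sigma, size=len(cn))
    return RegionDosage(
        interval=GenomeInterval(arch.region.chrom, int(starts[0]), int(starts[-1]) + w),
        positions=tuple(int(x) for x in starts),
        values=tuple(float(x) for x in cn),
        kind="copynumber",
    )


# --------------------------------------------------------------------------
# Population sampling
# --------------------------------------------------------------------------

def sample_population(freqs: dict, n: int, p: SimParams,
                      arch: LocusArchitecture | None = None) -> list:
    """Draw ``n`` diploid individuals per population by random union of
    haplotypes at the given per-population frequencies.

    ``freqs`` maps population label -> {haplotype label: frequency}; each
    population's frequencies must sum to 1 (tolerance 1e-9).
    """
    rng = p.rng(7)
    cache: dict = {}

    def hap(label):
        if label not in cache:
            cache[label] = make_haplotype(label, arch)
        return cache[label]

    out: list = []
    for pop, table in freqs.items():
        labels = sorted(table)
        q = np.array([table[l] for l in labels], dtype=float)
        if abs(q.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies for {pop} sum to {q.sum()}, not 1")
        for i in range(n):
            a, b = rng.choice(len(labels), size=2, p=q)
            g = Genotype.diploid(hap(labels[a]), hap(labels[b]))
            out.append(PopulationSample(f"{pop}_{i:04d}", pop, g))
    return out
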