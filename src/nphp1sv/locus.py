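"""Coordinate-level model of the *NPHP1* locus and its structural-variant haplotypes.

The human 2q13 *NPHP1* region carries two ~358 kb low-copy repeats (LCRs),
358PROX and 358DIST, flanking the gene in inverted orientation, and three
~45 kb LCRs: 45PROX (embedded in 358PROX), 45MID (between the gene and
358DIST) and 45DIST (embedded in 358DIST).  Seven structural haplotypes
H1..H7 are defined by (a) which 45 kb copies are lost -- each loss leaves a
5,936 bp stuffer sequence at the junction -- and (b) whether the segment
between the two 358 kb LCRs (containing the gene and 45MID) is inverted.

A haplotype that retains a pair of 45 kb copies flanking the gene in direct
orientation is a substrate for intra-chromosomal NAHR deletion of *NPHP1*
("susceptible"); haplotypes lacking such a pair are "protected".

Coordinates are 0-based half-open throughout (hg19 chr2 for the reference
architecture).  Haplotype-frame coordinates start at the reference locus
start and shift as transforms are applied; every haplotype also carries a
segment path mapping its frame back onto the reference, which is what lets
simulated fosmid ends acquire discordance signatures naturally.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

__all__ = [
    "GenomeInterval",
    "LCRCopy",
    "LocusArchitecture",
    "Element",
    "Segment",
    "Haplotype",
    "Genotype",
    "DEFAULT_COORDINATES",
    "HAPLOTYPE_TABLE",
    "build_reference_architecture",
    "make_haplotype",
    "infer_label",
    "apply_inversion",
    "delete_45_with_stuffer",
    "classify_nahr_susceptibility",
    "genotype_protection_report",
]

STUFFER_LENGTH = 5936  # the "5936Ins" stuffer left at a 45 kb LCR loss junction


@dataclass(frozen=True)
class GenomeInterval:
    """Half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class LCRCopy:
    """One copy of an LCR family; orientation is a sign (+1/-1) relative to
    the family consensus, so the relative orientation of a pair is the
    product of the two signs."""

    name: str
    family: str  # "45K" or "358K"
    interval: GenomeInterval
    orientation: int  # +1 or -1

    def __post_init__(self) -> None:
        if self.family not in ("45K", "358K"):
            raise ValueError(f"unknown LCR family {self.family!r}")
        if self.orientation not in (+1, -1):
            raise ValueError("orientation must be +1 or -1")


# Reference coordinates of the locus architecture (hg19 chr2, 0-based
# half-open).  Orientation signs are chosen so that the pairwise relative
# orientations are (45PROX,45MID)=+, (45MID,45DIST)=-, (45DIST,45PROX)=-,
# (358PROX,358DIST)=-.
DEFAULT_COORDINATES: dict = {
    "region": ("2", 110080914, 111762639),
    "gene": ("2", 110880913, 110962639),
    "lcrs": {
        "45PROX": ("2", 110688765, 110733137, "45K", +1),
        "45MID": ("2", 110983704, 111031088, "45K", +1),
        "45DIST": ("2", 111153516, 111197896, "45K", -1),
        "358PROX": ("2", 110494431, 110852754, "358K", +1),
        "358DIST": ("2", 111033787, 111392192, "358K", -1),
    },
    "stuffer_length": STUFFER_LENGTH,
}


@dataclass(frozen=True)
class LocusArchitecture:
    """The reference (H1) architecture: LCR copies, the gene, locus span."""

    lcr_copies: tuple
    gene: GenomeInterval
    region: GenomeInterval
    stuffer_length: int = STUFFER_LENGTH

    def copy(self, name: str) -> LCRCopy:
        for c in self.lcr_copies:
            if c.name == name:
                return c
        raise KeyError(name)

    def family(self, family: str) -> list:
        return [c for c in self.lcr_copies if c.family == family]

    def relative_orientation(self, a: str, b: str) -> str:
        """'+' if the two named copies run in the same orientation."""
        sign = self.copy(a).orientation * self.copy(b).orientation
        return "+" if sign > 0 else "-"

    def validate(self) -> None:
        by_name = {c.name: c for c in self.lcr_copies}
        for inner, outer in (("45PROX", "358PROX"), ("45DIST", "358DIST")):
            if inner in by_name and outer in by_name:
                if not by_name[outer].interval.contains(by_name[inner].interval):
                    raise ValueError(f"{inner} not contained in {outer}")
        if "358PROX" in by_name and "45MID" in by_name:
            if not (
                by_name["358PROX"].interval.end
                <= self.gene.start
                < self.gene.end
                <= by_name["45MID"].interval.start
            ):
                raise ValueError("gene must lie between 358PROX.end and 45MID.start")
        # no overlaps beyond the stated containments
        for a, b in itertools.combinations(self.lcr_copies, 2):
            pair = {a.name, b.name}
            if pair in ({"45PROX", "358PROX"}, {"45DIST", "358DIST"}):
                continue
            if a.interval.overlaps(b.interval):
                raise ValueError(f"unexpected overlap between {a.name} and {b.name}")
        for c in self.lcr_copies:
            if not self.region.contains(c.interval):
                raise ValueError(f"{c.name} outside the locus region")
        for fam in ("45K", "358K"):
            lens = [c.interval.length for c in self.family(fam)]
            if lens and (max(lens) - min(lens)) > 0.1 * max(lens):
                raise ValueError(f"{fam} copy lengths differ by more than 10%")


def build_reference_architecture(config: dict | None = None) -> LocusArchitecture:
    """Construct the H1 reference architecture from a coordinate table.

    ``config`` defaults to :data:`DEFAULT_COORDINATES`; the same mapping shape
    may be loaded from a structured config file.  Raises ``ValueError`` if the
    containment/overlap invariants are violated.
    """
    cfg = DEFAULT_COORDINATES if config is None else config
    copies = tuple(
        LCRCopy(name, fam, GenomeInterval(chrom, s, e), ori)
        for name, (chrom, s, e, fam, ori) in cfg["lcrs"].items()
    )
    arch = LocusArchitecture(
        lcr_copies=tuple(sorted(copies, key=lambda c: c.interval.start)),
        gene=GenomeInterval(*cfg["gene"]),
        region=GenomeInterval(*cfg["region"]),
        stuffer_length=cfg.get("stuffer_length", STUFFER_LENGTH),
    )
    arch.validate()
    return arch


# --------------------------------------------------------------------------
# Haplotypes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Element:
    """An annotated element in haplotype-frame coordinates."""

    name: str
    kind: str  # lcr45 | lcr358 | gene | stuffer
    start: int
    end: int
    orientation: int  # +1 / -1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Segment:
    """One piece of the haplotype->reference mapping.  A stuffer segment has
    no unique reference position (ref_start/ref_end describe the junction)."""

    ref_start: int
    ref_end: int
    strand: int  # +1 / -1
    stuffer: bool = False
    stuffer_length: int = 0

    @property
    def length(self) -> int:
        return self.stuffer_length if self.stuffer else self.ref_end - self.ref_start


# label -> (lost copies, inversion flag); Fig 1B / Table 2 compositions.
HAPLOTYPE_TABLE: dict = {
    "H1": (frozenset(), False),
    "H2": (frozenset({"45PROX"}), True),
    "H3": (frozenset(), True),
    "H4": (frozenset({"45PROX", "45DIST"}), True),
    "H5": (frozenset({"45PROX"}), False),
    "H6": (frozenset({"45DIST"}), True),
    "H7": (frozenset({"45PROX", "45DIST"}), False),
}

_COMPOSITION_TO_LABEL = {v: k for k, v in HAPLOTYPE_TABLE.items()}


def infer_label(lost_copies, inversion: bool) -> str:
    """Label for a (lost copies, inversion) composition; 'custom' if none of
    H1..H7 matches (e.g. 45DIST loss without inversion)."""
    return _COMPOSITION_TO_LABEL.get((frozenset(lost_copies), bool(inversion)), "custom")


@dataclass(frozen=True)
class Haplotype:
    label: str
    arch: LocusArchitecture
    elements: tuple  # of Element, sorted by start, haplotype frame
    segments: tuple  # of Segment, mapping haplotype frame -> reference frame
    inversion: bool = False
    lost_copies: frozenset = frozenset()

    @property
    def count45(self) -> int:
        return sum(1 for e in self.elements if e.kind == "lcr45")

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)

    def element(self, name: str) -> Element:
        for e in self.elements:
            if e.name == name:
                return e
        raise KeyError(name)

    def has_element(self, name: str) -> bool:
        return any(e.name == name for e in self.elements)

    def hap_to_ref(self, pos: int):
        """Map a haplotype-frame position to (reference position, strand).

        Returns ``(None, None)`` inside a stuffer segment (the stuffer has no
        unique reference position).  ``strand`` is +1 when local haplotype
        orientation matches the reference.
        """
        off = 0
        for seg in self.segments:
            if off <= pos < off + seg.length:
                if seg.stuffer:
                    return None, None
                d = pos - off
                if seg.strand > 0:
                    return seg.ref_start + d, +1
                return seg.ref_end - 1 - d, -1
            off += seg.length
        raise ValueError(f"position {pos} outside haplotype of length {self.length}")


def _segments_split_at(segments, pos: int):
    """Split the segment path so that a boundary falls at haplotype offset pos."""
    out = []
    off = 0
    for seg in segments:
        if off < pos < off + seg.length:
            d = pos - off
            if seg.stuffer:
                raise ValueError("cannot split inside a stuffer segment")
            if seg.strand > 0:
                out.append(replace(seg, ref_end=seg.ref_start + d))
                out.append(replace(seg, ref_start=seg.ref_start + d))
            else:
                out.append(replace(seg, ref_start=seg.ref_end - d))
                out.append(replace(seg, ref_end=seg.ref_end - d))
        else:
            out.append(seg)
        off += seg.length
    return out


def _merge_segments(segments):
    """Coalesce adjacent contiguous same-strand segments (canonical form, so
    that e.g. inverting twice restores the original path exactly)."""
    out: list = []
    for seg in segments:
        if out and not seg.stuffer and not out[-1].stuffer and seg.strand == out[-1].strand:
            prev = out[-1]
            if seg.strand > 0 and prev.ref_end == seg.ref_start:
                out[-1] = replace(prev, ref_end=seg.ref_end)
                continue
            if seg.strand < 0 and prev.ref_start == seg.ref_end:
                out[-1] = replace(prev, ref_start=seg.ref_start)
                continue
        out.append(seg)
    return tuple(out)


def _segments_slice(segments, a: int, b: int):
    """Return (before, middle, after) sub-paths for haplotype interval [a, b)."""
    segs = _segments_split_at(_segments_split_at(list(segments), a), b)
    before, middle, after = [], [], []
    off = 0
    for seg in segs:
        if off + seg.length <= a:
            before.append(seg)
        elif off >= b:
            after.append(seg)
        else:
            middle.append(seg)
        off += seg.length
    return before, middle, after


def _h1_haplotype(arch: LocusArchitecture) -> Haplotype:
    elements = [
        Element(c.name, "lcr45" if c.family == "45K" else "lcr358",
                c.interval.start, c.interval.end, c.orientation)
        for c in arch.lcr_copies
    ]
    elements.append(Element("NPHP1", "gene", arch.gene.start, arch.gene.end, +1))
    elements.sort(key=lambda e: (e.start, e.end))
    # haplotype frame: 0-based from region start
    shift = arch.region.start
    elements = [replace(e, start=e.start - shift, end=e.end - shift) for e in elements]
    segments = (Segment(arch.region.start, arch.region.end, +1),)
    return Haplotype("H1", arch, tuple(elements), segments)


def make_haplotype(label: str, arch: LocusArchitecture | None = None) -> Haplotype:
    """Build one of the H1..H7 haplotypes by lookup: lost 45 kb copies are
    replaced by the stuffer, then the inversion (if any) is applied."""
    if label not in HAPLOTYPE_TABLE:
        raise KeyError(f"unknown haplotype label {label!r}")
    if arch is None:
        arch = build_reference_architecture()
    lost, inv = HAPLOTYPE_TABLE[label]
    hap = _h1_haplotype(arch)
    for which in sorted(lost):
        hap = delete_45_with_stuffer(hap, which)
    if inv:
        hap = apply_inversion(hap)
    return hap


def delete_45_with_stuffer(hap: Haplotype, which: str) -> Haplotype:
    """Remove a full 45 kb copy, inserting a stuffer of ``stuffer_length`` bp
    at the junction.  Net length change is -(copy length - stuffer length)."""
    if which not in ("45PROX", "45DIST"):
        raise ValueError(f"only 45PROX/45DIST can be deleted, not {which!r}")
    if not hap.has_element(which):
        raise ValueError(f"{which} already lost from {hap.label}")
    target = hap.element(which)
    s, e = target.start, target.end
    stuffer_len = hap.arch.stuffer_length
    delta = target.length - stuffer_len

    new_elements = []
    for el in hap.elements:
        if el.name == which:
            continue
        if el.end <= s:
            new_elements.append(el)
        elif el.start >= e:
            new_elements.append(replace(el, start=el.start - delta, end=el.end - delta))
        elif el.start <= s and el.end >= e:
            # the containing 358 copy shrinks by the net loss
            new_elements.append(replace(el, end=el.end - delta))
        else:
            raise ValueError(f"element {el.name} partially overlaps deleted {which}")
    new_elements.append(Element(f"stuffer@{which}", "stuffer", s, s + stuffer_len, +1))
    new_elements.sort(key=lambda el: (el.start, el.end))

    before, middle, after = _segments_slice(hap.segments, s, e)
    junction = middle[0].ref_start if middle else None
    stuffer_seg = Segment(
        ref_start=junction if junction is not None else 0,
        ref_end=junction if junction is not None else 0,
        strand=+1, stuffer=True, stuffer_length=stuffer_len,
    )
    segments = _merge_segments(tuple(before) + (stuffer_seg,) + tuple(after))

    lost = hap.lost_copies | {which}
    return Haplotype(
        infer_label(lost, hap.inversion), hap.arch, tuple(new_elements), segments,
        inversion=hap.inversion, lost_copies=lost,
    )


def apply_inversion(hap: Haplotype) -> Haplotype:
    """Invert the segment strictly between 358PROX.end and 358DIST.start
    (the segment carrying the gene and 45MID): element order and coordinates
    are reflected, orientations negated, and the reference mapping reversed.
    Applying it twice restores the original haplotype."""
    for name in ("358PROX", "358DIST"):
        if not hap.has_element(name):
            raise ValueError(f"inversion unsupported: {name} missing")
    a = hap.element("358PROX").end
    b = hap.element("358DIST").start
    if a >= b:
        raise ValueError("358 copies out of order; cannot invert")

    new_elements = []
    for el in hap.elements:
        if el.end <= a or el.start >= b:
            new_elements.append(el)
        elif a <= el.start and el.end <= b:
            new_elements.append(
                replace(el, start=a + b - el.end, end=a + b - el.start,
                        orientation=-el.orientation)
            )
        else:
            raise ValueError(f"element {el.name} straddles an inversion breakpoint")
    new_elements.sort(key=lambda el: (el.start, el.end))

    before, middle, after = _segments_slice(hap.segments, a, b)
    flipped = tuple(
        replace(seg, strand=-seg.strand) for seg in reversed(middle)
    )
    segments = _merge_segments(tuple(before) + flipped + tuple(after))

    inv = not hap.inversion
    return Haplotype(
        infer_label(hap.lost_copies, inv), hap.arch, tuple(new_elements), segments,
        inversion=inv, lost_copies=hap.lost_copies,
    )


# --------------------------------------------------------------------------
# NAHR susceptibility
# --------------------------------------------------------------------------

def classify_nahr_susceptibility(hap: Haplotype) -> str:
    """'susceptible' iff some pair of 45 kb copies flanks the gene (one
    proximal, one distal) in direct orientation -- the geometry required for
    an intra-chromosomal NAHR deletion of the gene."""
    gene = hap.element("NPHP1")
    proximal = [e for e in hap.elements if e.kind == "lcr45" and e.end <= gene.start]
    distal = [e for e in hap.elements if e.kind == "lcr45" and e.start >= gene.end]
    for p in proximal:
        for d in distal:
            if p.orientation == d.orientation:
                return "susceptible"
    return "protected"


# --------------------------------------------------------------------------
# Genotypes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Genotype:
    """A diploid pair, haploid genome, or mosaic mixture of haplotypes.

    ``components`` are (haplotype, fraction) pairs with fractions summing to
    one; a non-mosaic diploid has exactly two components of 0.5 each.
    """

    components: tuple  # of (Haplotype, float)
    ploidy: int = 2

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component fractions sum to {total}, not 1")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")

    @classmethod
    def diploid(cls, h1: Haplotype, h2: Haplotype) -> "Genotype":
        return cls(((h1, 0.5), (h2, 0.5)), ploidy=2)

    @classmethod
    def haploid(cls, h: Haplotype) -> "Genotype":
        return cls(((h, 1.0),), ploidy=1)

    @classmethod
    def mosaic(cls, pairs, weights) -> "Genotype":
        """Mixture of diploid cell populations, e.g. H5/H7 and H6/H7 cells."""
        if len(pairs) != len(weights):
            raise ValueError("one weight per pair required")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("pair weights must sum to 1")
        acc: dict = {}
        for (h1, h2), w in zip(pairs, weights):
            for h in (h1, h2):
                acc[h] = acc.get(h, 0.0) + w / 2.0
        return cls(tuple(acc.items()), ploidy=2)

    @property
    def total45(self) -> float:
        """Fraction-weighted diploid (or haploid) count of 45 kb copies."""
        return self.ploidy * sum(f * h.count45 for h, f in self.components)

    @property
    def labels(self) -> tuple:
        return tuple(h.label for h, _ in self.components)


def genotype_protection_report(g: Genotype) -> str:
    """Classify a diploid genotype's overall NAHR-deletion exposure.

    Both haplotypes susceptible -> 'fully_susceptible'; exactly one protected
    -> 'heterozygous_protective'; both protected -> 'fully_protected'.  For a
    haploid genotype the per-haplotype class is returned directly.
    """
    classes = []
    for h, f in g.components:
        n = round(f * 2) if g.ploidy == 2 else 1
        classes.extend([classify_nahr_susceptibility(h)] * max(n, 1))
    if g.ploidy == 1:
        return classes[0]
    if len(classes) != 2:
        # mosaic: report on the union of haplotypes present
        n_prot = sum(1 for h, _ in g.components
                     if classify_nahr_susceptibility(h) == "protected")
        if n_prot == len(g.components):
            return "fully_protected"
        return "heterozygous_protective" if n_prot else "fully_susceptible"
    n_prot = classes.count("protected")
    return ("fully_susceptible", "heterozygous_protective", "fully_protected")[n_prot]
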