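"""Fosmid end-sequence-pair (ESP) discordance calling.

A fosmid clone's two mapped ends should sit ~40 kb apart on opposite,
convergent strands.  Against a reference that carries sequence the donor
chromosome lacks, a clone spanning the lost material maps with an enlarged
span (deletion signature); extra donor sequence compresses the span
(insertion); and a clone spanning an inversion breakpoint maps with
equal-strand ends.
"""

from __future__ import annotations

from dataclasses import dataclass

from .locus import LocusArchitecture, build_reference_architecture
from .simulate import FosmidESP

__all__ = ["ESPCall", "IndividualEvidence", "classify_esp", "aggregate_individual"]

CLASSES = ("concordant", "deletion", "insertion", "inversion", "unusable")


@dataclass(frozen=True)
class ESPCall:
    clone_id: str
    call_class: str  # one of CLASSES
    ref_span: int
    side: str  # proximal | distal | spanning | NA


_DEFAULT_ARCH: list = []


def _arch_default() -> LocusArchitecture:
    if not _DEFAULT_ARCH:
        _DEFAULT_ARCH.append(build_reference_architecture())
    return _DEFAULT_ARCH[0]


def classify_esp(esp: FosmidESP, insert_min: int = 32_000, insert_max: int = 48_000,
                 min_mapq: int = 20, arch: LocusArchitecture | None = None) -> ESPCall:
    """Classify one ESP by the distance and orientation between its ends.

    Low mapping quality -> unusable.  Opposite-strand convergent ends with a
    span inside [insert_min, insert_max] are concordant; opposite-strand
    spans beyond insert_max signal a deletion in the donor, below insert_min
    an insertion; equal-strand ends signal an inversion breakpoint.  The
    side (proximal/distal/spanning) is assigned from the span midpoint
    relative to the gene.
    """
    if arch is None:
        arch = _arch_default()
    if esp.mapq < min_mapq:
        return ESPCall(esp.clone_id, "unusable", 0, "NA")
    (lp, ls), (rp, rs) = sorted(
        [(esp.pos1, esp.strand1), (esp.pos2, esp.strand2)]
    )
    span = rp - lp
    if ls == rs:
        cls = "inversion"
    elif span > insert_max:
        cls = "deletion"
    elif span < insert_min:
        cls = "insertion"
    elif ls == "+" and rs == "-":
        cls = "concordant"
    else:  # divergent opposite-strand pair within the insert range
        cls = "unusable"
    if cls in ("concordant", "unusable"):
        side = "NA"
    else:
        mid = (lp + rp) / 2.0
        gene = arch.gene
        if lp < gene.start and rp >= gene.end:
            side = "spanning"
        elif mid < gene.start:
            side = "proximal"
        elif mid >= gene.end:
            side = "distal"
        else:
            side = "spanning"
    return ESPCall(esp.clone_id, cls, span, side)


@dataclass(frozen=True)
class IndividualEvidence:
    counts: tuple  # of (class, count)
    deletion: bool
    deletion_sides: tuple  # sides with supported deletion evidence
    inversion: bool

    def count(self, cls: str) -> int:
        return dict(self.counts).get(cls, 0)


def aggregate_individual(calls, min_support: int = 1) -> IndividualEvidence:
    """Aggregate one individual's ESP calls: a class is asserted as evidence
    when at least ``min_support`` clones agree."""
    counts = {c: 0 for c in CLASSES}
    side_counts: dict = {}
    for call in calls:
        counts[call.call_class] += 1
        if call.call_class == "deletion":
            side_counts[call.side] = side_counts.get(call.side, 0) + 1
    return IndividualEvidence(
        counts=tuple(sorted((c, n) for c, n in counts.items() if n)),
        deletion=counts["deletion"] >= min_support,
        deletion_sides=tuple(sorted(s for s, n in side_counts.items()
                                    if n >= min_support)),
        inversion=counts["inversion"] >= min_support,
    )
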