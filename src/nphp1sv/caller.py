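"""Integration of fosmid, Rmap and dosage evidence into SV-haplotype
genotypes.

Rmap consensus maps identify allele compositions (which 45 kb copies are
lost, whether the gene segment is inverted); fosmid discordance corroborates
them; aCGH/read-depth dosage fixes the diploid total of 45 kb copies.  The
consistent genotypes are the haplotype pairs drawn from the observed allele
types whose copy counts sum to the dosage total; three or more observed
allele types are interpreted as cell-population mosaicism, with each
candidate cell genotype still constrained by the dosage total.
"""

from __future__ import annotations

from dataclasses import dataclass

from .locus import (
    Genotype,
    HAPLOTYPE_TABLE,
    genotype_protection_report,
    infer_label,
    make_haplotype,
)

__all__ = [
    "AlleleEvidence",
    "GenotypeReport",
    "allele_to_haplotype",
    "label_count45",
    "enumerate_diploid",
    "integrate_evidence",
]


@dataclass(frozen=True)
class AlleleEvidence:
    lost_copies: frozenset
    inversion: bool
    source: str = "rmap"  # rmap | fosmid | combined


def allele_to_haplotype(e: AlleleEvidence) -> str:
    """Inverse of the haplotype lookup: the label whose composition matches
    the evidence, or a descriptive custom label when none of H1..H7 does."""
    label = infer_label(e.lost_copies, e.inversion)
    if label != "custom":
        return label
    losses = "+".join(sorted(e.lost_copies)) or "none"
    inv = ",inv" if e.inversion else ""
    return f"custom[{losses}{inv}]"


def label_count45(label: str) -> int:
    lost, _ = HAPLOTYPE_TABLE[label]
    return 3 - len(lost)


def enumerate_diploid(total45: int, observed) -> list:
    """All unordered haplotype pairs (with repetition) drawn from the
    observed labels whose 45 kb copy counts sum to ``total45``."""
    if total45 < 0:
        raise ValueError("total45 must be non-negative")
    labels = sorted(set(observed))
    out = []
    for i, a in enumerate(labels):
        for b in labels[i:]:
            if label_count45(a) + label_count45(b) == total45:
                out.append((a, b))
    return out


@dataclass(frozen=True)
class GenotypeReport:
    sample_id: str
    allele_types: tuple
    consistent_genotypes: tuple  # of (label, label) pairs, or (label,) haploid
    total45: int | None
    protection: tuple  # classification per consistent genotype
    mosaic: bool
    flags: tuple

    @property
    def resolved(self) -> bool:
        return len(self.consistent_genotypes) > 0


def _protection_of(genotype_labels) -> str:
    if len(genotype_labels) == 1:
        return genotype_protection_report(
            Genotype.haploid(make_haplotype(genotype_labels[0]))
        )
    h1, h2 = (make_haplotype(l) for l in genotype_labels)
    return genotype_protection_report(Genotype.diploid(h1, h2))


def integrate_evidence(fosmid_evidence, rmap_calls, dosage_call,
                       sample_id: str) -> GenotypeReport:
    """Combine per-sample evidence into a genotype report.

    ``rmap_calls`` is an :class:`~nphp1sv.rmap.RmapCallSet` (or an iterable
    of allele labels) and is the primary source of allele compositions;
    ``fosmid_evidence`` (an :class:`~nphp1sv.fosmid.IndividualEvidence` or
    None) is cross-checked against it and discordances are flagged, never
    dropped; ``dosage_call`` (a :class:`~nphp1sv.dosage.CNCall` or None)
    fixes the diploid 45 kb copy total.  Without dosage, a single allele
    type yields a haploid-style report of that allele alone.
    """
    flags: list = []
    if hasattr(rmap_calls, "allele_types"):
        allele_types = tuple(rmap_calls.allele_types)
        if getattr(rmap_calls, "unresolved", False):
            flags.append("rmap_unresolved")
    else:
        allele_types = tuple(dict.fromkeys(rmap_calls)) if rmap_calls else ()
    if not allele_types and fosmid_evidence is None and dosage_call is None:
        raise ValueError("at least one evidence source required")

    # cross-check fosmid discordance classes against rmap compositions
    if fosmid_evidence is not None and allele_types:
        known = [l for l in allele_types if l in HAPLOTYPE_TABLE]
        rmap_del = any(HAPLOTYPE_TABLE[l][0] for l in known)
        rmap_inv = any(HAPLOTYPE_TABLE[l][1] for l in known)
        if fosmid_evidence.deletion != rmap_del:
            flags.append("fosmid_rmap_deletion_discordant")
        if fosmid_evidence.inversion != rmap_inv:
            flags.append("fosmid_rmap_inversion_discordant")

    mosaic = len(allele_types) > 2
    total45 = None if dosage_call is None else int(dosage_call.cn)

    known_types = [l for l in allele_types if l in HAPLOTYPE_TABLE]
    if len(known_types) < len(allele_types):
        flags.append("custom_allele_type")

    if total45 is None:
        if len(known_types) == 1:
            genos = ((known_types[0],),)
        else:
            genos = ()
            if known_types:
                flags.append("dosage_required_for_multiple_alleles")
    else:
        pairs = enumerate_diploid(total45, known_types) if known_types else []
        if len(known_types) == 2 and not mosaic:
            # both alleles were observed: a non-mosaic diploid must carry both
            both = [p for p in pairs if set(p) == set(known_types)]
            pairs = both if both else pairs
        genos = tuple(pairs)
        if not genos:
            flags.append("no_consistent_genotype")

    protection = tuple(_protection_of(g) for g in genos)
    if mosaic:
        flags.append("mosaic")
    return GenotypeReport(
        sample_id=sample_id,
        allele_types=allele_types,
        consistent_genotypes=genos,
        total45=total45,
        protection=protection,
        mosaic=mosaic,
        flags=tuple(dict.fromkeys(flags)),
    )
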