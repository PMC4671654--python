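"""Copy-number estimation from aCGH log2 ratios and read-depth windows.

The array design tiles a single copy of each LCR family, so a probe's log2
ratio reflects the summed dosage of all paralogous copies in the test genome
relative to the reference genome (which carries four 45 kb copies).  Two
decision rules are provided:

* intra-species: the integer copy number whose theoretical ratio
  log2(c / cn_ref) is nearest the observed mean LR (ties toward smaller c);
* inter-species: a three-way classification -- mean LR <= -1 means the
  orthologous sequence is essentially absent, between -1 and -0.25 means a
  reduced (half-reference) copy number, above -0.25 a copy number equal to
  the reference.  Cross-species ratios also absorb hybridization loss from
  sequence divergence, which is why the rule is coarser than the
  intra-species one.

DLRS (derivative log ratio spread) summarizes probe-to-probe noise: the
standard deviation of successive differences divided by sqrt(2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .locus import GenomeInterval

__all__ = [
    "RegionDosage",
    "CNCall",
    "summarize_region",
    "theoretical_lr",
    "estimate_cn_intra",
    "classify_cn_interspecies",
    "tabulate_content_classes",
    "window_species_average",
]

NEG_INF_LR = float("-inf")  # sentinel for a zero-copy theoretical ratio


@dataclass(frozen=True)
class RegionDosage:
    """Ordered per-probe or per-window measurements over an interval."""

    interval: GenomeInterval
    positions: tuple  # probe/window start positions, ascending
    values: tuple     # log2 ratios or copy numbers, same order
    kind: str         # "log2ratio" | "copynumber"

    def __post_init__(self) -> None:
        if self.kind not in ("log2ratio", "copynumber"):
            raise ValueError(f"unknown dosage kind {self.kind!r}")
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values must have equal length")
        if len(self.values) < 1:
            raise ValueError("at least one value required")
        if any(b < a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be ascending")

    def subset(self, start: int, end: int) -> "RegionDosage":
        """Measurements whose position falls in [start, end)."""
        keep = [(p, v) for p, v in zip(self.positions, self.values)
                if start <= p < end]
        if not keep:
            raise ValueError("no measurements in requested interval")
        return RegionDosage(
            GenomeInterval(self.interval.chrom, start, end),
            tuple(p for p, _ in keep), tuple(v for _, v in keep), self.kind,
        )


@dataclass(frozen=True)
class CNCall:
    mean_lr: float
    dlrs: float | None
    cn: int
    rule: str  # "intra" | "interspecies"


def summarize_region(d: RegionDosage) -> tuple:
    """(mean LR, DLRS).  DLRS is the sample standard deviation of successive
    differences divided by sqrt(2); it is undefined (None) with fewer than
    three values, since a single difference has no sample deviation."""
    vals = np.asarray(d.values, dtype=float)
    mean_lr = float(vals.mean())
    if len(vals) < 3:
        return mean_lr, None
    diffs = np.diff(vals)
    dlrs = float(np.std(diffs, ddof=1) / math.sqrt(2.0))
    return mean_lr, dlrs


def theoretical_lr(cn_test: int, cn_ref: int) -> float:
    """log2(cn_test / cn_ref); -inf sentinel at zero test copies."""
    if cn_test < 0 or cn_ref <= 0:
        raise ValueError("copy numbers must be non-negative (reference positive)")
    if cn_test == 0:
        return NEG_INF_LR
    return math.log2(cn_test / cn_ref)


def estimate_cn_intra(mean_lr: float, cn_ref: int = 4, cn_max: int = 8) -> CNCall:
    """Nearest-theoretical-ratio integer copy number within the same species.

    cn = argmin over c in 1..cn_max of |mean_lr - log2(c/cn_ref)|, ties
    broken toward the smaller c; ratios below log2(0.5/cn_ref) -- less than
    half a copy's expected signal -- are called copy number zero.
    """
    if not math.isfinite(mean_lr):
        raise ValueError("mean_lr must be finite")
    if mean_lr < math.log2(0.5 / cn_ref):
        return CNCall(mean_lr, None, 0, "intra")
    best = min(range(1, cn_max + 1),
               key=lambda c: (abs(mean_lr - math.log2(c / cn_ref)), c))
    return CNCall(mean_lr, None, best, "intra")


def classify_cn_interspecies(mean_lr: float, cn_ref: int = 4,
                             t_absent: float = -1.0,
                             t_equal: float = -0.25) -> CNCall:
    """Three-way cross-species call: absent (0), reduced (cn_ref/2), or
    equal to reference (cn_ref)."""
    if not math.isfinite(mean_lr):
        raise ValueError("mean_lr must be finite")
    if mean_lr <= t_absent:
        cn = 0
    elif mean_lr <= t_equal:
        cn = cn_ref // 2
    else:
        cn = cn_ref
    return CNCall(mean_lr, None, cn, "interspecies")


def tabulate_content_classes(d: RegionDosage, region_length: int) -> dict:
    """Per-class genomic content (kb and fraction of the region) from probe
    log2 ratios: absent (-inf, -1], reduced (-1, 0], comparable (0, inf).

    Contiguous probes of one class are merged into segments whose span is
    taken from midpoints between adjacent probes (flank probes extend half a
    median probe spacing outward).
    """
    if d.kind != "log2ratio":
        raise ValueError("content classes are defined on log2 ratios")
    pos = np.asarray(d.positions, dtype=float)
    vals = np.asarray(d.values, dtype=float)
    if len(pos) == 0:
        raise ValueError("empty region")

    def klass(v: float) -> str:
        if v <= -1.0:
            return "absent"
        if v <= 0.0:
            return "reduced"
        return "comparable"

    classes = [klass(v) for v in vals]
    if len(pos) > 1:
        half = float(np.median(np.diff(pos))) / 2.0
        mids = (pos[:-1] + pos[1:]) / 2.0
        lefts = np.concatenate([[pos[0] - half], mids])
        rights = np.concatenate([mids, [pos[-1] + half]])
    else:
        lefts, rights = pos - 0.5, pos + 0.5
    out = {c: 0.0 for c in ("absent", "reduced", "comparable")}
    for c, l, r in zip(classes, lefts, rights):
        out[c] += (r - l)
    return {
        c: {"kb": bp / 1000.0, "fraction": bp / region_length}
        for c, bp in out.items()
    }


def window_species_average(tables: dict) -> dict:
    """Per-window mean copy number across the individuals of each species.

    ``tables`` maps species -> list of :class:`RegionDosage` (copy-number
    kind) with aligned windows; windows missing from any individual of a
    species are masked (dropped) for that species.
    """
    out: dict = {}
    for species, dosages in tables.items():
        if not dosages:
            continue
        common = set(dosages[0].positions)
        for d in dosages[1:]:
            common &= set(d.positions)
        common = sorted(common)
        stack = []
        for d in dosages:
            lut = dict(zip(d.positions, d.values))
            stack.append([lut[p] for p in common])
        means = np.asarray(stack, dtype=float).mean(axis=0)
        out[species] = RegionDosage(
            dosages[0].interval, tuple(common),
            tuple(float(x) for x in means), "copynumber",
        )
    return out
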