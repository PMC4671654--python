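"""The seven SV haplotypes of the NPHP1 locus and their NAHR exposure.

Builds the reference locus architecture, derives haplotypes H1..H7 by
deletion/inversion transforms, and classifies each as NAHR-deletion
susceptible (a directly oriented 45 kb LCR pair still flanks the gene) or
protected.
"""

from nphp1sv.locus import (
    Genotype,
    build_reference_architecture,
    classify_nahr_susceptibility,
    genotype_protection_report,
    make_haplotype,
)

arch = build_reference_architecture()
print(f"locus: chr{arch.region.chrom}:{arch.region.start}-{arch.region.end} "
      f"({arch.region.length:,} bp)")
print(f"45 kb LCR copies: {[c.name for c in arch.family('45K')]}")
print(f"358 kb LCR copies: {[c.name for c in arch.family('358K')]} "
      f"(relative orientation {arch.relative_orientation('358PROX', '358DIST')})")
print()
print("label  n45  inverted  lost              NAHR class")
for label in ("H1", "H2", "H3", "H4", "H5", "H6", "H7"):
    h = make_haplotype(label, arch)
    print(f"{label:5s}  {h.count45}    {str(h.inversion):8s} "
          f"{','.join(sorted(h.lost_copies)) or '-':17s} "
          f"{classify_nahr_susceptibility(h)}")

g = Genotype.diploid(make_haplotype("H5"), make_haplotype("H2"))
print()
print(f"H5/H2 diploid: {genotype_protection_report(g)} "
      "(one chromosome still carries a direct 45 kb pair)")
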