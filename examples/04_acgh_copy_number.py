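"""Copy-number estimation of the 45 kb LCR region from aCGH log2 ratios.

Simulates probe ratios of test genomes against a four-copy human reference
(NA10851-like), summarizes the 45 kb LCR probes (mean LR, DLRS) and applies
the intra-species nearest-ratio rule; then mimics a chimpanzee-like
hybridization (reduced dosage and sequence-divergence attenuation) and
applies the inter-species three-way rule.
"""

from nphp1sv.dosage import (
    classify_cn_interspecies,
    estimate_cn_intra,
    summarize_region,
)
from nphp1sv.locus import Genotype, build_reference_architecture, make_haplotype
from nphp1sv.simulate import SimParams, default_probe_table, simulate_acgh

arch = build_reference_architecture()
probes = default_probe_table(arch)
ref = Genotype.diploid(make_haplotype("H2"), make_haplotype("H2"))  # CN4
c45 = arch.copy("45MID").interval

for label, pair in (("H2/H2 (CN4)", ("H2", "H2")),
                    ("H2/H5 (CN4)", ("H2", "H5")),
                    ("H7/H7 (CN2)", ("H7", "H7")),
                    ("H1/H2 (CN5)", ("H1", "H2"))):
    test = Genotype.diploid(make_haplotype(pair[0]), make_haplotype(pair[1]))
    d = simulate_acgh(test, ref, probes, SimParams(seed=31))
    mean_lr, dlrs = summarize_region(d.subset(c45.start, c45.end))
    call = estimate_cn_intra(mean_lr, cn_ref=4)
    print(f"{label}: mean LR {mean_lr:+.3f}, DLRS {dlrs:.3f} "
          f"-> estimated CN {call.cn}")

# chimpanzee-like: sequence divergence attenuates hybridization of the
# single diverged ortholog, placing the ratio between 0 and -1
chimp = Genotype.diploid(make_haplotype("H2"), make_haplotype("H2"))
d = simulate_acgh(chimp, ref, probes,
                  SimParams(seed=32, acgh_identity_factor=0.63))
mean_lr, _ = summarize_region(d.subset(c45.start, c45.end))
call = classify_cn_interspecies(mean_lr, cn_ref=4)
print(f"\nchimp-like test: mean LR {mean_lr:+.3f} -> inter-species class "
      f"CN {call.cn} (a ratio between -1 and -0.25 reads as reduced, "
      f"half-reference copy number)")
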