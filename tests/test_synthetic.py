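"""Statistical and determinism properties of the synthetic-data generators."""

import numpy as np
import pytest
from scipy import stats as sps

from nphp1sv.dosage import summarize_region
from nphp1sv.lcr import pairwise_identity
from nphp1sv.locus import Genotype, make_haplotype
from nphp1sv.rmap import digest_insilico
from nphp1sv.simulate import (
    SimParams,
    sample_population,
    simulate_acgh,
    simulate_fosmid_library,
    simulate_readdepth,
    simulate_rmaps,
    synth_haplotype_sequence,
    default_probe_table,
)


class TestSequenceSynthesis:
    def test_seed_determinism(self, arch, haps):
        p = SimParams(seed=5)
        s1 = synth_haplotype_sequence(arch, haps["H2"], p)
        s2 = synth_haplotype_sequence(arch, haps["H2"], p)
        assert s1 == s2
        s3 = synth_haplotype_sequence(arch, haps["H2"], SimParams(seed=6))
        assert s1 != s3

    def test_zero_divergence_gives_identical_paralogs(self, arch, haps):
        p = SimParams(seed=5, paralog_divergence=0.0, swai_sites=())
        seq = synth_haplotype_sequence(arch, haps["H1"], p)
        shift = arch.region.start
        a = arch.copy("45PROX").interval
        b = arch.copy("45MID").interval
        sa = seq[a.start - shift : a.end - shift]
        sb = seq[b.start - shift : b.start - shift + a.length]
        assert sa == sb  # identity 1.0

    def test_default_divergence_identity_range(self, arch, haps):
        p = SimParams(seed=5)
        seq = synth_haplotype_sequence(arch, haps["H1"], p)
        shift = arch.region.start
        a = arch.copy("45PROX").interval
        b = arch.copy("45MID").interval
        ident, _ = pairwise_identity(seq[a.start - shift : a.end - shift],
                                     seq[b.start - shift : b.start - shift + a.length])
        assert 0.994 <= ident <= 0.999

    def test_haplotype_sequence_length_matches_model(self, arch, haps):
        p = SimParams(seed=5)
        for lab in ("H2", "H7"):
            assert len(synth_haplotype_sequence(arch, haps[lab], p)) == \
                haps[lab].length


class TestFosmids:
    def test_concordant_span_distribution(self, haps):
        g = Genotype.diploid(haps["H1"], haps["H1"])
        p = SimParams(seed=9)
        esps = simulate_fosmid_library(g, 5000, p)
        spans = np.array([abs(e.pos2 - e.pos1) for e in esps], dtype=float)
        # H1 donor against H1 reference: spans follow the insert distribution
        stat = sps.kstest(spans, "norm",
                          args=(p.insert_mean - 1, p.insert_sd))
        assert stat.pvalue > 0.01

    def test_deleted_copy_enlarges_span(self, haps):
        g = Genotype.diploid(haps["H2"], haps["H2"])
        p = SimParams(seed=9)
        esps = simulate_fosmid_library(g, 3000, p)
        spans = np.array([abs(e.pos2 - e.pos1) for e in esps
                          if e.strand1 != e.strand2])
        big = spans[spans > 60_000]
        assert len(big) > 10
        assert abs(big.mean() - (p.insert_mean + 38_436)) < 1_500

    def test_inversion_breakpoint_gives_equal_strands(self, haps):
        g = Genotype.diploid(haps["H2"], haps["H2"])
        esps = simulate_fosmid_library(g, 1000, SimParams(seed=9))
        assert any(e.strand1 == e.strand2 for e in esps)

    def test_h1_donor_has_no_equal_strand_pairs(self, haps):
        g = Genotype.diploid(haps["H1"], haps["H1"])
        esps = simulate_fosmid_library(g, 1000, SimParams(seed=9))
        assert all(e.strand1 != e.strand2 for e in esps)

    def test_rejects_empty_library(self, haps):
        with pytest.raises(ValueError):
            simulate_fosmid_library(Genotype.haploid(haps["H1"]), 0,
                                    SimParams(seed=1))


class TestRmapSimulation:
    def test_noiseless_equals_exact_digest(self, haps):
        p = SimParams(seed=2, rmap_cv=0.0, rmap_p_miss=0.0,
                      rmap_false_per_bp=0.0, rmap_min_fragment_bp=0.0)
        mols = simulate_rmaps(haps["H1"], p, 3)
        truth = simulate_rmaps(haps["H1"], SimParams(
            seed=2, rmap_cv=0.0, rmap_p_miss=0.0, rmap_false_per_bp=0.0,
            rmap_min_fragment_bp=0.0), 1)[0]
        for m in mols:
            assert np.allclose(m.fragments, truth.fragments)

    def test_all_cuts_missed_gives_single_fragment(self, haps):
        p = SimParams(seed=2, rmap_p_miss=1.0, rmap_false_per_bp=0.0,
                      rmap_cv=0.0)
        m = simulate_rmaps(haps["H1"], p, 1)[0]
        assert len(m.fragments) == 1
        assert m.fragments[0] == pytest.approx(haps["H1"].length / 1000.0)

    def test_expected_fragment_count(self, haps, swai_sites):
        p = SimParams(seed=2, rmap_cv=0.0, rmap_min_fragment_bp=0.0)
        mols = simulate_rmaps(haps["H1"], p, 1000)
        n_cuts = len(swai_sites)
        length_bp = haps["H1"].length
        expected = n_cuts * (1 - p.rmap_p_miss) \
            + p.rmap_false_per_bp * length_bp + 1
        observed = np.mean([len(m) for m in mols])
        assert abs(observed - expected) < 0.5

    def test_sequence_and_site_routes_agree(self, arch, haps):
        p = SimParams(seed=2)
        seq = synth_haplotype_sequence(arch, haps["H1"], p)
        from_seq = digest_insilico(seq)
        # the sequence route includes chance ATTTAAAT occurrences on top of
        # the planted layout, so compare total length only
        assert from_seq.total_kb == pytest.approx(haps["H1"].length / 1000.0)


class TestAcgh:
    def test_halved_dosage_gives_minus_one(self, arch, haps, cn4_reference):
        test = Genotype.diploid(haps["H7"], haps["H7"])  # CN2
        p = SimParams(seed=3, acgh_sigma=0.0)
        d = simulate_acgh(test, cn4_reference, default_probe_table(arch), p, arch)
        c45 = arch.copy("45MID").interval
        sub = d.subset(c45.start, c45.end)
        assert np.allclose(sub.values, -1.0)

    def test_identity_factor_attenuates(self, arch, cn4_reference):
        p = SimParams(seed=3, acgh_sigma=0.0, acgh_identity_factor=0.63)
        d = simulate_acgh(cn4_reference, cn4_reference,
                          default_probe_table(arch), p, arch)
        assert np.allclose(d.values, np.log2(0.63))

    def test_equal_genotypes_give_zero(self, arch, cn4_reference):
        p = SimParams(seed=3, acgh_sigma=0.0)
        d = simulate_acgh(cn4_reference, cn4_reference,
                          default_probe_table(arch), p, arch)
        assert np.allclose(d.values, 0.0)

    def test_dlrs_reflects_noise(self, arch, cn4_reference):
        p = SimParams(seed=3)
        d = simulate_acgh(cn4_reference, cn4_reference,
                          default_probe_table(arch), p, arch)
        _, dlrs = summarize_region(d)
        assert 0.05 < dlrs < 0.2  # sigma = 0.10


class TestReadDepth:
    def test_noiseless_equals_dosage(self, haps):
        g = Genotype.diploid(haps["H2"], haps["H2"])
        p = SimParams(seed=4, readdepth_sigma=0.0)
        d = simulate_readdepth(g, p)
        assert set(d.values) <= {2.0, 4.0}

    def test_cn4_region_mean(self, arch, haps):
        g = Genotype.diploid(haps["H2"], haps["H2"])
        d = simulate_readdepth(g, SimParams(seed=4))
        c45 = arch.copy("45MID").interval
        sub = d.subset(c45.start, c45.end)
        assert abs(np.mean(sub.values) - 4.0) < 0.1


class TestPopulation:
    def test_fixed_haplotype(self, arch):
        out = sample_population({"POP": {"H2": 1.0}}, 5, SimParams(seed=1), arch)
        assert all(s.genotype.total45 == 4 for s in out)
        assert all(s.genotype.labels == ("H2", "H2") for s in out)

    def test_empty_sample(self, arch):
        assert sample_population({"POP": {"H1": 1.0}}, 0,
                                 SimParams(seed=1), arch) == []

    def test_expected_copy_number(self, arch):
        freqs = {"POP": {"H1": 0.5, "H7": 0.5}}
        out = sample_population(freqs, 400, SimParams(seed=1), arch)
        totals = [s.genotype.total45 for s in out]
        # E[total45] = 2 * (0.5*3 + 0.5*1) = 4; sd of mean ~ 0.07
        assert abs(np.mean(totals) - 4.0) < 0.25

    def test_bad_frequencies_rejected(self, arch):
        with pytest.raises(ValueError):
            sample_population({"POP": {"H1": 0.7}}, 3, SimParams(seed=1), arch)
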