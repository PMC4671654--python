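"""Dosage summaries and copy-number decision rules, including the published
aCGH worked examples they must reproduce."""

import math

import numpy as np
import pytest

from nphp1sv.dosage import (
    RegionDosage,
    classify_cn_interspecies,
    estimate_cn_intra,
    summarize_region,
    tabulate_content_classes,
    theoretical_lr,
    window_species_average,
)
from nphp1sv.locus import GenomeInterval, Genotype
from nphp1sv.simulate import SimParams, simulate_readdepth

# published per-sample mean log2 ratios and copy-number calls for the 45 kb
# LCR region (aCGH against a four-copy human reference)
HUMAN_ROWS = {
    "NA18517": (0.33, 5), "NA18555": (-0.32, 3), "NA15510": (0.06, 4),
    "NA12878": (-0.78, 2), "NA07535": (0.04, 4), "NA18994": (0.04, 4),
    "NA10860": (0.00, 4), "MCF7": (-0.30, 3), "H1-P208": (-0.22, 3),
    "PT1": (-0.76, 2), "PT2": (-0.74, 2), "PT3": (-0.79, 2), "PT4": (0.02, 4),
    "PT5": (-0.73, 2), "PT6": (-0.78, 2), "PT8": (-0.77, 2),
}
# the two rows the plain ratio rule cannot reproduce (calls informed by
# orthogonal evidence in the source data)
KNOWN_DISCORDANT = {"H1-P22": (-0.18, 3), "PT7": (-0.65, 2)}
GORILLA_ROWS = {"Gorilla1": (-0.07, 4), "Gorilla2": (-0.18, 4),
                "Gorilla3": (-0.14, 4)}
NONHUMAN_ROWS = {
    "Baboon1": (-1.97, 0), "Rhesus1": (-1.67, 0), "Rhesus2": (-1.79, 0),
    "Orangutan1": (-0.54, 2), "Chimp1": (-0.66, 2), "Chimp2": (-0.60, 2),
    "Chimp3": (-0.51, 2), "Chimp4": (-0.67, 2), "Chimp5": (-0.66, 2),
    "Chimp6": (-0.67, 2), "Chimp7": (-0.67, 2),
    "Gorilla1": (-0.07, 4), "Gorilla2": (-0.18, 4), "Gorilla3": (-0.14, 4),
}


def dosage(values, kind="log2ratio", spacing=100):
    positions = tuple(range(0, spacing * len(values), spacing))
    return RegionDosage(GenomeInterval("2", 1, spacing * len(values) + 1),
                        positions, tuple(values), kind)


class TestSummaries:
    def test_constant_values_zero_dlrs(self):
        mean, dlrs = summarize_region(dosage([0.5] * 5))
        assert mean == 0.5 and dlrs == 0.0

    def test_alternating_closed_form(self):
        _, dlrs = summarize_region(dosage([0.0, 1.0, 0.0]))
        assert dlrs == pytest.approx(1.0)  # sd(1, -1)/sqrt(2)

    def test_mean(self):
        mean, _ = summarize_region(dosage([-1.0, -0.5]))
        assert mean == -0.75

    def test_single_value_dlrs_undefined(self):
        mean, dlrs = summarize_region(dosage([0.3]))
        assert mean == 0.3 and dlrs is None

    def test_dlrs_shift_invariance(self):
        vals = [0.1, -0.4, 0.7, 0.2, -0.1]
        _, d1 = summarize_region(dosage(vals))
        _, d2 = summarize_region(dosage([v + 3.7 for v in vals]))
        assert d1 == pytest.approx(d2)


class TestTheoreticalLR:
    @pytest.mark.parametrize("test,ref,expected",
                             [(4, 4, 0.0), (2, 4, -1.0), (6, 4, math.log2(1.5))])
    def test_values(self, test, ref, expected):
        assert theoretical_lr(test, ref) == pytest.approx(expected)

    def test_zero_copies_sentinel(self):
        assert theoretical_lr(0, 4) == float("-inf")

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            theoretical_lr(-1, 4)


class TestIntraSpeciesRule:
    @pytest.mark.parametrize("sample", sorted(HUMAN_ROWS))
    def test_reproduces_published_human_calls(self, sample):
        lr, cn = HUMAN_ROWS[sample]
        assert estimate_cn_intra(lr).cn == cn

    @pytest.mark.parametrize("sample", sorted(GORILLA_ROWS))
    def test_reproduces_published_gorilla_calls(self, sample):
        lr, cn = GORILLA_ROWS[sample]
        assert estimate_cn_intra(lr).cn == cn

    def test_known_discordant_rows(self):
        # the ratio rule alone lands one copy above the published calls
        assert estimate_cn_intra(KNOWN_DISCORDANT["H1-P22"][0]).cn == 4
        assert estimate_cn_intra(KNOWN_DISCORDANT["PT7"][0]).cn == 3

    def test_round_trip_identity(self):
        for ref in (2, 4):
            for c in range(1, 2 * ref + 1):
                assert estimate_cn_intra(theoretical_lr(c, ref), cn_ref=ref,
                                         cn_max=2 * ref).cn == c

    def test_deep_loss_called_zero(self):
        assert estimate_cn_intra(-3.5).cn == 0


class TestInterSpeciesRule:
    @pytest.mark.parametrize("sample", sorted(NONHUMAN_ROWS))
    def test_reproduces_published_nonhuman_calls(self, sample):
        lr, cn = NONHUMAN_ROWS[sample]
        assert classify_cn_interspecies(lr).cn == cn

    def test_boundaries(self):
        assert classify_cn_interspecies(-1.0).cn == 0
        assert classify_cn_interspecies(-0.25).cn == 2
        assert classify_cn_interspecies(-0.2499).cn == 4


class TestContentClasses:
    def test_all_absent(self):
        out = tabulate_content_classes(dosage([-2.0] * 10, spacing=1000), 10_000)
        assert out["absent"]["fraction"] == pytest.approx(1.0)
        assert out["absent"]["kb"] == pytest.approx(10.0)

    def test_half_reduced_half_comparable(self):
        out = tabulate_content_classes(
            dosage([-0.5] * 5 + [0.1] * 5, spacing=1000), 10_000)
        assert out["reduced"]["fraction"] == pytest.approx(0.5)
        assert out["comparable"]["fraction"] == pytest.approx(0.5)

    def test_boundary_minus_one_is_absent(self):
        out = tabulate_content_classes(dosage([-1.0] * 4, spacing=500), 2_000)
        assert out["absent"]["fraction"] == pytest.approx(1.0)

    def test_copynumber_kind_rejected(self):
        with pytest.raises(ValueError):
            tabulate_content_classes(dosage([2.0], kind="copynumber"), 100)


class TestWindowAverages:
    def test_single_individual_identity(self):
        d = dosage([2.0, 4.0, 4.0], kind="copynumber")
        out = window_species_average({"human": [d]})
        assert out["human"].values == d.values

    def test_two_individuals_mean(self):
        d1 = dosage([2.0, 2.0], kind="copynumber")
        d2 = dosage([4.0, 4.0], kind="copynumber")
        out = window_species_average({"sp": [d1, d2]})
        assert out["sp"].values == (3.0, 3.0)

    def test_simulated_species_average_tight(self, arch, haps):
        g = Genotype.diploid(haps["H2"], haps["H2"])
        tables = {"human": [simulate_readdepth(g, SimParams(seed=s), arch)
                            for s in range(30)]}
        avg = window_species_average(tables)["human"]
        c45 = arch.copy("45MID").interval
        # keep only windows fully inside the copy (its dosage is CN4)
        sub = avg.subset(c45.start, c45.end - 500)
        # n=30 at sigma 0.2: per-window SE ~ 0.037
        assert max(abs(v - 4.0) for v in sub.values) < 0.15
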