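"""Locus architecture, haplotype transforms and NAHR-susceptibility logic."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nphp1sv.locus import (
    DEFAULT_COORDINATES,
    Genotype,
    apply_inversion,
    build_reference_architecture,
    classify_nahr_susceptibility,
    delete_45_with_stuffer,
    genotype_protection_report,
    make_haplotype,
)


class TestArchitecture:
    def test_family_counts_and_orientations(self, arch):
        assert len(arch.family("45K")) == 3
        assert len(arch.family("358K")) == 2
        assert arch.relative_orientation("358PROX", "358DIST") == "-"
        assert arch.relative_orientation("45PROX", "45MID") == "+"
        assert arch.relative_orientation("45MID", "45DIST") == "-"
        assert arch.relative_orientation("45DIST", "45PROX") == "-"

    def test_45prox_length(self, arch):
        assert arch.copy("45PROX").interval.length == 44_372

    def test_containment_violation_rejected(self):
        cfg = {k: (dict(v) if isinstance(v, dict) else v)
               for k, v in DEFAULT_COORDINATES.items()}
        # move 45PROX outside its host 358PROX
        cfg["lcrs"] = dict(cfg["lcrs"])
        cfg["lcrs"]["45PROX"] = ("2", 110860000, 110870000, "45K", +1)
        with pytest.raises(ValueError):
            build_reference_architecture(cfg)


LOOKUP = [
    ("H1", 3, False, set()),
    ("H2", 2, True, {"45PROX"}),
    ("H3", 3, True, set()),
    ("H4", 1, True, {"45PROX", "45DIST"}),
    ("H5", 2, False, {"45PROX"}),
    ("H6", 2, True, {"45DIST"}),
    ("H7", 1, False, {"45PROX", "45DIST"}),
]


class TestHaplotypes:
    @pytest.mark.parametrize("label,count45,inversion,lost", LOOKUP)
    def test_lookup_composition(self, haps, label, count45, inversion, lost):
        h = haps[label]
        assert h.count45 == count45
        assert h.inversion is inversion
        assert set(h.lost_copies) == lost
        assert h.count45 + len(h.lost_copies) == 3

    def test_unknown_label(self, arch):
        with pytest.raises(KeyError):
            make_haplotype("H9", arch)

    def test_h1_matches_reference(self, arch, haps):
        h1 = haps["H1"]
        shift = arch.region.start
        by_name = {e.name: e for e in h1.elements}
        for c in arch.lcr_copies:
            el = by_name[c.name]
            assert (el.start + shift, el.end + shift) == \
                (c.interval.start, c.interval.end)
            assert el.orientation == c.orientation

    def test_inversion_is_involution(self, haps):
        h1 = haps["H1"]
        assert apply_inversion(apply_inversion(h1)) == h1

    def test_inversion_reorders_and_flips(self, arch, haps):
        inv = apply_inversion(haps["H1"])
        names = [e.name for e in inv.elements]
        # the in-between segment (gene, 45MID) is reversed: 45MID now proximal
        assert names.index("45MID") < names.index("NPHP1")
        # 45MID vs 45DIST relative orientation flips '-' -> '+'
        ori = {e.name: e.orientation for e in inv.elements}
        assert ori["45MID"] * ori["45DIST"] > 0
        assert inv.count45 == 3 and inv.length == haps["H1"].length

    def test_deletion_net_length(self, arch, haps):
        h5 = delete_45_with_stuffer(haps["H1"], "45PROX")
        assert haps["H1"].length - h5.length == 44_372 - 5_936
        assert h5.label == "H5"

    def test_two_deletions_compose_h7(self, haps):
        h = delete_45_with_stuffer(
            delete_45_with_stuffer(haps["H1"], "45PROX"), "45DIST")
        assert h.label == "H7" and h.count45 == 1

    def test_deleting_lost_copy_rejected(self, haps):
        with pytest.raises(ValueError):
            delete_45_with_stuffer(haps["H5"], "45PROX")

    def test_degenerate_stuffer_equals_copy_length(self):
        cfg = dict(DEFAULT_COORDINATES, stuffer_length=44_372)
        arch = build_reference_architecture(cfg)
        h1 = make_haplotype("H1", arch)
        assert delete_45_with_stuffer(h1, "45PROX").length == h1.length

    def test_inversion_requires_both_358(self):
        cfg = dict(DEFAULT_COORDINATES)
        cfg["lcrs"] = {k: v for k, v in DEFAULT_COORDINATES["lcrs"].items()
                       if k != "358DIST"}
        arch = build_reference_architecture(cfg)
        with pytest.raises(ValueError):
            apply_inversion(make_haplotype("H1", arch))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(lost=st.sets(st.sampled_from(["45PROX", "45DIST"])),
           invert=st.booleans())
    def test_count45_and_length_conservation(self, haps, lost, invert):
        h = haps["H1"]
        for which in sorted(lost):
            h = delete_45_with_stuffer(h, which)
        if invert:
            before = h.length
            h = apply_inversion(h)
            assert h.length == before
        assert h.count45 + len(h.lost_copies) == 3


class TestSusceptibility:
    def test_exhaustive_table(self, haps):
        classes = {l: classify_nahr_susceptibility(h) for l, h in haps.items()}
        assert {l for l, c in classes.items() if c == "susceptible"} == \
            {"H1", "H2", "H3"}
        assert {l for l, c in classes.items() if c == "protected"} == \
            {"H4", "H5", "H6", "H7"}

    @pytest.mark.parametrize("a,b,expected", [
        ("H2", "H2", "fully_susceptible"),
        ("H5", "H5", "fully_protected"),
        ("H5", "H2", "heterozygous_protective"),
    ])
    def test_protection_report(self, haps, a, b, expected):
        g = Genotype.diploid(haps[a], haps[b])
        assert genotype_protection_report(g) == expected

    def test_haploid_report(self, haps):
        assert genotype_protection_report(Genotype.haploid(haps["H5"])) == \
            "protected"


class TestGenotype:
    def test_diploid_total45(self, haps):
        assert Genotype.diploid(haps["H2"], haps["H2"]).total45 == 4

    def test_fractions_must_sum_to_one(self, haps):
        with pytest.raises(ValueError):
            Genotype(((haps["H1"], 0.6),), ploidy=2)

    def test_mosaic_total45(self, haps):
        g = Genotype.mosaic([(haps["H5"], haps["H7"]), (haps["H6"], haps["H7"])],
                            [0.5, 0.5])
        assert g.total45 == pytest.approx(3.0)
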