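"""In-silico digestion and Rmap alignment/calling, checked against an
exhaustive brute-force alignment oracle on small maps."""

import itertools

import numpy as np
import pytest

from nphp1sv.locus import make_haplotype
from nphp1sv.rmap import (
    Rmap,
    align_rmap,
    call_haplotype_rmap,
    candidate_rmaps,
    consensus_rmap,
    digest_insilico,
    merge_small_fragments,
    rmap_from_sites,
)
from nphp1sv.simulate import SimParams, default_swai_sites, simulate_rmaps

SIGMA, CCUT, DELTA = 0.05, 3.0, 3


def brute_force_cost(q, r, sigma=SIGMA, c_cut=CCUT, delta=DELTA):
    """Minimum alignment cost by exhaustive enumeration of all block
    decompositions (independent of the dynamic program)."""
    q, r = list(q), list(r)

    def rec(i, j):
        if i == len(q) and j == len(r):
            return 0.0
        best = np.inf
        for a in range(1, min(delta, len(q) - i) + 1):
            for b in range(1, min(delta, len(r) - j) + 1):
                sq, sr = sum(q[i:i + a]), sum(r[j:j + b])
                cost = (sq - sr) ** 2 / (2 * (sigma * sr) ** 2) \
                    + c_cut * (a - 1 + b - 1)
                best = min(best, cost + rec(i + a, j + b))
        return best

    return rec(0, 0)


class TestDigest:
    def test_two_sites(self):
        seq = "A" * 10_000 + "ATTTAAAT" + "C" * 14_992 + "ATTTAAAT" + "G" * 74_992
        assert digest_insilico(seq).fragments == (10.0, 15.0, 75.0)

    def test_single_site_two_fragments(self):
        assert len(digest_insilico("AC" * 500 + "ATTTAAAT" + "GT" * 500)) == 2

    def test_no_site_single_fragment(self):
        assert digest_insilico("ACGT" * 1000).fragments == (4.0,)

    def test_degenerate_enzyme_rejected(self):
        with pytest.raises(ValueError):
            digest_insilico("ACGT", enzyme="ATTNAAAT")

    def test_h1_vs_h2_digest_difference(self, arch, swai_sites):
        h1 = rmap_from_sites(default_swai_sites(arch), make_haplotype("H1", arch).length)
        h2 = candidate_rmaps(arch, swai_sites, labels=("H2",))["H2"]
        assert h1.total_kb - h2.total_kb == pytest.approx(38.436)


class TestAlignment:
    def test_self_alignment_zero_cost(self):
        r = Rmap("r", "SwaI", (12.0, 30.0, 7.5, 22.0))
        aln = align_rmap(r, r)
        assert aln.cost == 0.0
        assert all(qhi - qlo == 1 and rhi - rlo == 1
                   for (qlo, qhi), (rlo, rhi) in aln.blocks)

    def test_merged_fragment_block(self):
        aln = align_rmap(Rmap("q", "SwaI", (8.0, 12.0)), Rmap("r", "SwaI", (20.0,)))
        assert aln.blocks == (((0, 2), (0, 1)),)
        assert aln.cost == pytest.approx(CCUT)
        assert aln.cuts_missed == 1 and aln.cuts_false == 0

    @pytest.mark.parametrize("seed", range(15))
    def test_dp_matches_bruteforce_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        nq, nr = rng.integers(1, 7, size=2)
        q = Rmap("q", "SwaI", tuple(rng.uniform(2.0, 40.0, size=nq)))
        r = Rmap("r", "SwaI", tuple(rng.uniform(2.0, 40.0, size=nr)))
        oracle = brute_force_cost(q.fragments, r.fragments)
        if np.isinf(oracle):  # infeasible under the block-size cap
            with pytest.raises(ValueError):
                align_rmap(q, r, SIGMA, CCUT, DELTA)
        else:
            aln = align_rmap(q, r, SIGMA, CCUT, DELTA)
            assert aln.cost == pytest.approx(oracle)

    def test_dp_matches_bruteforce_on_perturbed_maps(self):
        rng = np.random.default_rng(99)
        base = rng.uniform(5.0, 30.0, size=6)
        q = tuple(base * rng.normal(1.0, 0.05, size=6))
        r = tuple(base)
        aln = align_rmap(Rmap("q", "SwaI", q), Rmap("r", "SwaI", r))
        assert aln.cost == pytest.approx(brute_force_cost(q, r))

    def test_permuted_reference_costs_more(self):
        rng = np.random.default_rng(3)
        frags = tuple(rng.uniform(5.0, 40.0, size=6))
        q = Rmap("q", "SwaI", frags)
        best_other = min(
            align_rmap(q, Rmap("p", "SwaI", perm)).cost
            for perm in itertools.permutations(frags)
            if perm != frags
        )
        assert align_rmap(q, q).cost < best_other

    @pytest.mark.parametrize("seed", range(5))
    def test_cost_invariant_under_simultaneous_reversal(self, seed):
        rng = np.random.default_rng(100 + seed)
        q = tuple(rng.uniform(2.0, 40.0, size=rng.integers(2, 7)))
        r = tuple(rng.uniform(2.0, 40.0, size=rng.integers(2, 7)))
        fwd = align_rmap(Rmap("q", "S", q), Rmap("r", "S", r))
        rev = align_rmap(Rmap("q", "S", q[::-1]), Rmap("r", "S", r[::-1]))
        assert fwd.cost == pytest.approx(rev.cost)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            align_rmap(Rmap("q", "S", ()), Rmap("r", "S", (5.0,)))


class TestMergeSmall:
    def test_small_fragments_absorbed(self):
        assert merge_small_fragments((5.0, 0.3, 7.0), 0.8) == (5.3, 7.0)
        assert merge_small_fragments((0.3, 5.0, 7.0), 0.8) == (5.3, 7.0)

    def test_total_conserved(self):
        frags = (0.2, 4.0, 0.5, 0.1, 9.0)
        assert sum(merge_small_fragments(frags, 0.8)) == pytest.approx(sum(frags))


class TestCalling:
    def test_simulated_haplotypes_recovered(self, arch, swai_sites):
        candidates = candidate_rmaps(arch, swai_sites)
        p = SimParams(seed=11)
        for truth in ("H2", "H5"):
            mols = simulate_rmaps(make_haplotype(truth, arch), p, 12)
            cons = consensus_rmap(mols, map_id=truth)
            callset = call_haplotype_rmap([cons], candidates)
            assert callset.calls[0].best == truth
            assert not callset.calls[0].ambiguous

    def test_three_allele_types_detected(self, arch, swai_sites):
        candidates = candidate_rmaps(arch, swai_sites)
        p = SimParams(seed=12)
        consensi = [
            consensus_rmap(simulate_rmaps(make_haplotype(lab, arch), p, 12),
                           map_id=lab)
            for lab in ("H5", "H6", "H7")
        ]
        callset = call_haplotype_rmap(consensi, candidates)
        assert set(callset.allele_types) == {"H5", "H6", "H7"}
        assert not callset.unresolved

    def test_exact_candidate_is_unambiguous_zero_cost(self, arch, swai_sites):
        candidates = candidate_rmaps(arch, swai_sites)
        callset = call_haplotype_rmap([candidates["H6"]], candidates)
        call = callset.calls[0]
        assert call.best == "H6" and call.cost == 0.0 and not call.ambiguous
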