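"""Duplication mapping, clade extraction, NG86 Ks, and mixture fitting."""

import math

import numpy as np
import pytest

from phylodiscord._trees import parse_newick
from phylodiscord.duplications import (
    UnsupportedTreeError,
    duplication_percentages,
    extract_rooted_clades,
    map_duplications,
)
from phylodiscord.ks import fit_ks_mixture, ks_distribution, ks_pairwise
from phylodiscord.simulate import (
    simulate_duplication_family,
    simulate_ks_sample,
    simulate_species_tree,
)

from conftest import mutate_codon_seq, oracle_ng86, random_codon_seq


SP4 = "(((A:1,B:1):1,C:2):1,O:3);"


def supported_homolog(nwk):
    return parse_newick(nwk, rooted=False)


class TestExtractRootedClades:
    def test_low_mean_support_rejected(self):
        tree = supported_homolog(
            "(((A@1:1,B@1:1)49:1,(C@1:1,D@1:1)49:1)49:1,O@1:1);"
        )
        assert extract_rooted_clades(tree, ["O"], 50, 3) == []

    def test_supported_clade_extracted(self):
        tree = supported_homolog(
            "(((A@1:1,B@1:1)90:1,(C@1:1,D@1:1)80:1)85:1,O@1:1);"
        )
        clades = extract_rooted_clades(tree, ["O"], 50, 3)
        assert len(clades) == 1
        taxa = {l.taxon.label.split("@")[0]
                for l in clades[0].leaf_node_iter()}
        assert taxa == {"A", "B", "C", "D"}

    def test_unsupported_tree_raises(self):
        tree = supported_homolog("((A@1:1,B@1:1):1,(C@1:1,O@1:1):1);")
        with pytest.raises(UnsupportedTreeError, match="bootstrap"):
            extract_rooted_clades(tree, ["O"], 50, 2)

    def test_hand_enumeration_on_ten_tips(self):
        """Two maximal ingroup clades split by an interior outgroup tip."""
        nwk = ("(((a1@1:1,a2@1:1)90:1,(a3@1:1,a4@1:1)90:1)90:1,"
               "(O1@1:1,((b1@1:1,b2@1:1)90:1,((b3@1:1,b4@1:1)90:1,O2@1:1)90:1)90:1)90:1);")
        tree = supported_homolog(nwk)
        clades = extract_rooted_clades(tree, ["O1", "O2"], 50, 2)
        got = sorted(
            tuple(sorted({l.taxon.label.split("@")[0]
                          for l in c.leaf_node_iter()}))
            for c in clades
        )
        assert got == [("a1", "a2", "a3", "a4"), ("b1", "b2"), ("b3", "b4")]

    def test_deterministic(self):
        tree = supported_homolog(
            "(((A@1:1,B@1:1)90:1,(C@1:1,D@1:1)80:1)85:1,O@1:1);"
        )
        a = extract_rooted_clades(tree, ["O"], 50, 2)
        b = extract_rooted_clades(tree, ["O"], 50, 2)
        assert len(a) == len(b)


class TestMapDuplications:
    def test_single_taxon_overlap_is_not_an_event(self):
        sp = parse_newick(SP4, rooted=True)
        clade = parse_newick("((A@1:1,B@1:1):1,(A@2:1,C@1:1):1);", rooted=True)
        assert map_duplications(clade, sp) == []

    def test_two_taxon_overlap_maps_to_mrca(self):
        sp = parse_newick(SP4, rooted=True)
        clade = parse_newick(
            "(((A@1:1,B@1:1):1,C@1:2):1,(A@2:1,B@2:1):1);", rooted=True
        )
        events = map_duplications(clade, sp)
        assert len(events) == 1
        assert events[0].species_branch == frozenset({"A", "B", "C"})
        assert events[0].n_overlap == 2

    def test_unknown_taxon_raises(self):
        sp = parse_newick(SP4, rooted=True)
        clade = parse_newick("((A@1:1,Z@1:1):1,(A@2:1,Z@2:1):1);", rooted=True)
        with pytest.raises(ValueError, match="Z"):
            map_duplications(clade, sp)

    def test_lossless_simulation_maps_exactly(self):
        """Full-overlap duplications map to their true species branch.

        Duplications on terminal species branches are invisible to the
        two-taxon-overlap rule by construction (both daughters carry the
        same single taxon), so truth is restricted to internal branches.
        """
        sp = simulate_species_tree(8, 1.0, seed=17)
        n_events = 0
        for seed in range(100):
            fam = simulate_duplication_family(sp, 0.3, 0.0, seed=seed)
            events = map_duplications(fam.tree, sp)
            truth = [t for t in fam.surviving_duplications
                     if len(t.species_branch) >= 2]
            assert len(events) == len(truth)
            for ev, tr in zip(
                sorted(events, key=lambda e: sorted(e.species_branch)),
                sorted(truth, key=lambda t: sorted(t.species_branch)),
            ):
                assert ev.species_branch == tr.species_branch
                n_events += 1
        assert n_events > 50


class TestDuplicationPercentages:
    def test_no_events_gives_zero_everywhere(self):
        sp = parse_newick(SP4, rooted=True)
        clades = [parse_newick("((A@1:1,B@1:1):1,C@1:2);", rooted=True)]
        pct = duplication_percentages([], clades, sp)
        for branch, (count, p) in pct.items():
            assert count == 0
            assert p in (0.0, None)

    def test_direct_arithmetic(self):
        """10 informative clades, 2 events at the branch: 20%."""
        sp = parse_newick(SP4, rooted=True)
        clades = [
            parse_newick("((A@1:1,B@1:1):1,C@1:2);", rooted=True)
            for _ in range(10)
        ]
        dup = parse_newick(
            "(((A@1:1,B@1:1):1,C@1:2):1,(A@2:1,B@2:1):1);", rooted=True
        )
        events = map_duplications(dup, sp) * 2
        pct = duplication_percentages(events, clades, sp)
        count, p = pct[frozenset({"A", "B", "C"})]
        assert count == 2
        assert abs(p - 20.0) < 1e-9

    def test_percentages_bounded(self):
        sp = simulate_species_tree(8, 1.0, seed=23)
        clades, events = [], []
        for seed in range(50):
            fam = simulate_duplication_family(sp, 0.4, 0.1, seed=seed)
            if fam.tree is None:
                continue
            clades.append(fam.tree)
            events.extend(map_duplications(fam.tree, sp))
        for branch, (count, p) in duplication_percentages(
            events, clades, sp
        ).items():
            if p is not None:
                assert 0.0 <= p


class TestKsPairwise:
    def test_identical_sequences_zero(self):
        est = ks_pairwise("ATGGCTAAA", "ATGGCTAAA")
        assert est.ks == 0.0
        assert est.Sd == 0.0

    def test_jc_correction_closed_form(self):
        """pS = 0.3 corrects to 0.383119."""
        p = 0.3
        expect = -0.75 * math.log(1 - 4 * p / 3)
        assert abs(expect - 0.383119) < 1e-6

    def test_length_validation(self):
        with pytest.raises(ValueError):
            ks_pairwise("ATGG", "ATGG")
        with pytest.raises(ValueError):
            ks_pairwise("ATGGCT", "ATG")

    def test_symmetry(self, pyrng):
        a = random_codon_seq(pyrng, 50)
        b = mutate_codon_seq(pyrng, a, 20)
        e1 = ks_pairwise(a, b)
        e2 = ks_pairwise(b, a)
        assert abs(e1.S - e2.S) < 1e-9
        assert abs(e1.Sd - e2.Sd) < 1e-9

    def test_matches_brute_force_oracle(self, pyrng):
        """S, N, Sd, Nd equal path-enumeration recounts on 50 random pairs."""
        for _ in range(50):
            a = random_codon_seq(pyrng, 40)
            b = mutate_codon_seq(pyrng, a, pyrng.randrange(0, 30))
            est = ks_pairwise(a, b)
            S, N, Sd, Nd = oracle_ng86(a, b)
            assert abs(est.S - S) < 1e-9
            assert abs(est.N - N) < 1e-9
            assert abs(est.Sd - Sd) < 1e-9
            assert abs(est.Nd - Nd) < 1e-9

    def test_site_counts_complement_to_three_per_codon(self, pyrng):
        a = random_codon_seq(pyrng, 30)
        b = mutate_codon_seq(pyrng, a, 10)
        est = ks_pairwise(a, b)
        assert abs(est.S + est.N - 3 * est.n_codons) < 1e-9

    def test_ambiguous_codons_skipped(self):
        est = ks_pairwise("ATGNNNGCT", "ATGAAAGCT")
        assert est.n_codons == 2


class TestKsDistribution:
    def test_single_sequence_taxa_give_empty_list(self):
        clusters = {"c1": [("A@1", "ATGGCT"), ("B@1", "ATGGCT")]}
        assert ks_distribution(clusters, "A") == []

    def test_three_sequences_give_three_pairs(self):
        # variants differ by one synonymous change each, in distinct codons
        base = "ATGGCTAAAGGGCCCTTTGAACATAGACTG"
        variants = [
            base,
            base[:5] + "C" + base[6:],    # GCT -> GCC
            base[:8] + "G" + base[9:],    # AAA -> AAG
        ]
        clusters = {"c1": [(f"A@{i}", s) for i, s in enumerate(variants)]}
        vals = ks_distribution(clusters, "A")
        assert len(vals) == 3
        assert all(v > 0 for v in vals)

    def test_near_zero_and_saturated_pairs_excluded(self):
        clusters = {"c1": [("A@1", "ATGGCT"), ("A@2", "ATGGCT")]}
        assert ks_distribution(clusters, "A") == []  # Ks = 0 excluded


class TestKsMixture:
    def test_single_tight_component_selects_k1(self):
        vals = simulate_ks_sample([(1.0, math.log(0.5), 0.05)], 500, seed=1)
        fit = fit_ks_mixture(vals, k_max=3, seed=2)
        assert fit.k == 1
        assert abs(fit.ks_peaks[0] - 0.5) / 0.5 < 0.05

    def test_two_component_recovery(self):
        """BIC selects k=2; exp(means) within 15% of 0.2 and 1.9."""
        spec = [(0.5, math.log(0.2), 0.3), (0.5, math.log(1.9), 0.3)]
        vals = simulate_ks_sample(spec, 4000, seed=3)
        fit = fit_ks_mixture(vals, k_max=3, seed=4)
        assert fit.k == 2
        assert abs(fit.ks_peaks[0] - 0.2) / 0.2 < 0.15
        assert abs(fit.ks_peaks[1] - 1.9) / 1.9 < 0.15

    def test_loglik_trajectory_monotone(self):
        spec = [(0.5, math.log(0.2), 0.3), (0.5, math.log(1.9), 0.3)]
        vals = simulate_ks_sample(spec, 1000, seed=5)
        fit = fit_ks_mixture(vals, k_max=3, seed=6)
        diffs = np.diff(fit.ll_trajectory)
        assert (diffs >= -1e-6).all()

    def test_refuses_small_samples(self):
        with pytest.raises(ValueError, match="at least 50"):
            fit_ks_mixture([0.5] * 20, k_max=2, seed=0)

    def test_component_recovery_median_error(self):
        """Median |exp(mean) - truth| <= 10% per component over 20 fits."""
        spec = [(0.5, math.log(0.2), 0.3), (0.5, math.log(1.9), 0.3)]
        errs_low, errs_high = [], []
        for seed in range(20):
            vals = simulate_ks_sample(spec, 2000, seed=100 + seed)
            fit = fit_ks_mixture(vals, k_max=2, seed=seed)
            errs_low.append(abs(fit.ks_peaks[0] - 0.2) / 0.2)
            errs_high.append(abs(fit.ks_peaks[-1] - 1.9) / 1.9)
        assert np.median(errs_low) <= 0.10
        assert np.median(errs_high) <= 0.10

    def test_agrees_with_sklearn_reference(self):
        """Independent cross-check against sklearn's GaussianMixture."""
        sklearn = pytest.importorskip("sklearn.mixture")
        spec = [(0.5, math.log(0.2), 0.3), (0.5, math.log(1.9), 0.3)]
        vals = simulate_ks_sample(spec, 3000, seed=7)
        fit = fit_ks_mixture(vals, k_max=2, seed=8)
        gm = sklearn.GaussianMixture(n_components=2, n_init=5, random_state=0)
        gm.fit(np.log(np.asarray(vals))[:, None])
        ref = np.sort(gm.means_.ravel())
        assert np.allclose(np.sort(fit.means), ref, atol=0.05)
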