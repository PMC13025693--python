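"""Nei-Gojobori site counting, pathway averaging, and Ka/Ks estimation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import ref_kaks, ref_pathway_differences, ref_site_counts
from mitochar.codon_usage import ALL_CODONS, genetic_code
from mitochar.evolrates import (
    SaturationError,
    cds_site_counts,
    classify_regime,
    gene_selection_screen,
    kaks_pair,
    pathway_differences,
    site_counts,
)

SENSE_CODONS = sorted(set(ALL_CODONS) - set(genetic_code(5).stop_codons))


class TestSiteCounts:
    def test_phenylalanine_third_position(self):
        s, n = site_counts("TTT")
        assert s == pytest.approx(1 / 3) and n == pytest.approx(8 / 3)

    def test_fourfold_glycine_site(self):
        s, _ = site_counts("GGA")
        assert s == pytest.approx(1.0)  # all three third-position changes synonymous

    @pytest.mark.parametrize("codon", SENSE_CODONS)
    def test_conservation_and_oracle_agreement(self, codon):
        s, n = site_counts(codon)
        assert s + n == pytest.approx(3.0)
        rs, rn = ref_site_counts(codon)
        assert s == pytest.approx(rs) and n == pytest.approx(rn)

    def test_cds_sum_matches_enumeration(self):
        rng = np.random.default_rng(1)
        cds = list(rng.choice(SENSE_CODONS, 40))
        s, n = cds_site_counts(cds)
        rs = sum(ref_site_counts(c)[0] for c in cds)
        assert s == pytest.approx(rs) and s + n == pytest.approx(120.0)


class TestPathwayDifferences:
    def test_identical_codons(self):
        assert pathway_differences("ATG", "ATG") == (0.0, 0.0)

    def test_single_synonymous_change(self):
        assert pathway_differences("TTT", "TTC") == (1.0, 0.0)

    def test_two_difference_hand_oracle(self):
        # AAA(K)->ACG(T): both orders give one syn + one nonsyn step
        assert pathway_differences("AAA", "ACG") == (1.0, 1.0)

    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.choice(SENSE_CODONS, 2)
        sd, nd = pathway_differences(a, b)
        rsd, rnd = ref_pathway_differences(a, b)
        assert sd == pytest.approx(rsd) and nd == pytest.approx(rnd)


class TestKaksPair:
    def test_identical_sequences(self):
        cds = ["ATG", "TTT", "GGA"]
        r = kaks_pair(cds, cds)
        assert r.Ka == 0.0 and r.Ks == 0.0 and math.isnan(r.ratio)

    def test_synonymous_only_changes(self):
        a = ["ATG", "TTT", "GGA", "CCA"] + ["GCA"] * 8
        b = ["ATG", "TTC", "GGT", "CCA"] + ["GCA"] * 8  # two synonymous changes
        r = kaks_pair(a, b)
        assert r.Ka == 0.0 and r.Ks > 0 and r.ratio == 0.0

    def test_nonsynonymous_only_changes(self):
        a = ["ATG", "AAA", "TTT"]
        b = ["ATG", "GAA", "TAT"]  # K->E and F->Y, no synonymous change
        r = kaks_pair(a, b)
        assert r.Ks == 0.0 and math.isnan(r.ratio)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a = list(rng.choice(SENSE_CODONS, 30))
        b = list(rng.choice(SENSE_CODONS, 30))
        r1, r2 = kaks_pair(a, b), kaks_pair(b, a)
        assert r1.Ka == pytest.approx(r2.Ka) and r1.Ks == pytest.approx(r2.Ks)

    def test_gapped_codons_dropped_pairwise(self):
        a = ["ATG", "T-T", "GGA"]
        b = ["ATG", "TTT", "GGA"]
        assert kaks_pair(a, b).n_codons == 2

    def test_saturation_error(self):
        a = ["AAA"] * 40
        b = ["GGG"] * 40
        with pytest.raises(SaturationError):
            kaks_pair(a, b)

    def test_site_conservation(self):
        rng = np.random.default_rng(3)
        a = list(rng.choice(SENSE_CODONS, 25))
        b = list(rng.choice(SENSE_CODONS, 25))
        try:
            r = kaks_pair(a, b)
        except SaturationError:
            return
        assert r.S + r.N == pytest.approx(3 * r.n_codons)

    def test_oracle_equivalence_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            a = list(rng.choice(SENSE_CODONS, 30))
            # derive b from a by a few mutations so distances stay estimable
            b = list(a)
            for _m in range(rng.integers(1, 12)):
                i = int(rng.integers(0, 30))
                b[i] = str(rng.choice(SENSE_CODONS))
            r = kaks_pair(a, b)
            ka, ks, _ = ref_kaks(a, b)
            assert abs(r.Ka - ka) < 1e-12 and abs(r.Ks - ks) < 1e-12


class TestSelectionScreen:
    def test_identical_taxa_undefined(self):
        aln = {"COI": {"t1": "ATGTTTGGA", "t2": "ATGTTTGGA"}}
        df = gene_selection_screen(aln)
        assert df.iloc[0]["regime"] == "undefined"
        assert math.isnan(df.iloc[0]["mean_kaks"])

    def test_regime_labels(self):
        assert classify_regime(0.2) == "purifying"
        assert classify_regime(1.005) == "neutral"
        assert classify_regime(1.17) == "positive"
        assert classify_regime(float("nan")) == "undefined"

    def test_purifying_simulation_recovery_small(self):
        from mitochar.synthetic_data import EvolutionSpec, evolve_on_tree, random_cds

        rng = np.random.default_rng(0)
        means = []
        for rep in range(10):
            root = random_cds(200, rng)
            seqs, _ = evolve_on_tree(
                EvolutionSpec(tree="(A:0.2,B:0.2);", n_sites=600, mode="cds",
                              omega=0.1, root_seq=root, seed=500 + rep)
            )
            df = gene_selection_screen({"g": seqs})
            means.append(df.iloc[0]["mean_kaks"])
        assert 0.05 <= float(np.mean(means)) <= 0.2

    def test_neutral_recovery_under_unbiased_mutation(self):
        """With all three substitutions equally likely (the condition matching
        NG86's equal-weight pathway counting) a neutral gene recovers ~1."""
        from mitochar.synthetic_data import EvolutionSpec, evolve_on_tree, random_cds

        rng = np.random.default_rng(1)
        means = []
        for rep in range(15):
            root = random_cds(250, rng)
            seqs, _ = evolve_on_tree(
                EvolutionSpec(tree="(A:0.2,B:0.2);", n_sites=750, mode="cds",
                              omega=1.0, ts_tv_ratio=0.5, root_seq=root,
                              seed=700 + rep)
            )
            means.append(gene_selection_screen({"g": seqs}).iloc[0]["mean_kaks"])
        assert 0.8 <= float(np.mean(means)) <= 1.2
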