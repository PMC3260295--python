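import numpy as np
import pandas as pd
import pytest

from isodiv import motif_enrichment as me
from isodiv.io_formats import PWM, GenomicInterval, TranscriptModel, revcomp
from conftest import sharp_pwm, random_sequences


def make_transcript(exons, strand="+", contig="c"):
    return TranscriptModel(
        "t", "g", contig, strand,
        tuple(GenomicInterval(contig, s, e, strand) for s, e in exons),
    )


class TestPromoterExtraction:
    def test_plus_strand_window(self, rng):
        genome = {"c": "".join(random_sequences(rng, 1, 10000)["s0"])}
        t = make_transcript([(5000, 5400)])
        prom = me.extract_promoter(t, genome)
        assert prom == genome["c"][4000:5300]
        assert len(prom) == 1300
        assert prom[1000] == genome["c"][5000]  # TSS at offset 1000

    def test_minus_strand_window_is_mirror(self, rng):
        genome = {"c": random_sequences(rng, 1, 10000)["s0"]}
        t = make_transcript([(4600, 5001)], strand="-")  # TSS at 5000
        prom = me.extract_promoter(t, genome)
        assert prom == revcomp(genome["c"][4701:6001])
        assert len(prom) == 1300
        assert prom[1000] == revcomp(genome["c"][5000])

    def test_contig_edge_clipped_with_warning(self, rng):
        genome = {"c": random_sequences(rng, 1, 2000)["s0"]}
        t = make_transcript([(500, 900)])
        with pytest.warns(UserWarning, match="clipped"):
            prom = me.extract_promoter(t, genome)
        assert prom == genome["c"][0:800]
        assert len(prom) == 800


class TestUTRExtraction:
    def test_plus_strand_last_exon(self, rng):
        genome = {"c": random_sequences(rng, 1, 1000)["s0"]}
        t = make_transcript([(100, 200), (300, 400)])
        assert me.extract_utr3(t, genome) == genome["c"][300:400]

    def test_minus_strand_last_exon_revcomp(self, rng):
        genome = {"c": random_sequences(rng, 1, 1000)["s0"]}
        t = make_transcript([(100, 200), (300, 400)], strand="-")
        assert me.extract_utr3(t, genome) == revcomp(genome["c"][100:200])

    def test_single_exon_transcript_is_its_own_utr(self, rng):
        genome = {"c": random_sequences(rng, 1, 1000)["s0"]}
        t = make_transcript([(100, 250)])
        assert me.extract_utr3(t, genome) == genome["c"][100:250]


class TestScanPWM:
    def test_cg_motif_palindrome_counts_both_strands(self):
        pwm = PWM("M", "m", np.array([[0, 0], [10, 0], [0, 10], [0, 0]], float))
        res = me.scan_pwm("ACGT", pwm, rel_threshold=1.0)
        assert res.count == 2
        assert set(res.positions) == {(1, "+"), (1, "-")}

    def test_uniform_pwm_hits_every_window(self):
        pwm = PWM("M", "m", np.full((4, 3), 2.5))
        res = me.scan_pwm("ACGTACGT", pwm, rel_threshold=0.9)
        assert res.count == res.n_windows == 2 * (8 - 3 + 1)

    def test_sequence_shorter_than_motif_rejected(self):
        pwm = PWM("M", "m", np.full((4, 5), 1.0))
        with pytest.raises(ValueError):
            me.scan_pwm("ACG", pwm)

    def test_equal_length_scans_one_window_per_strand(self):
        pwm = sharp_pwm("M", "ACGTA")
        res = me.scan_pwm("ACGTA", pwm, rel_threshold=1.0)
        assert res.n_windows == 2
        assert res.count == 1

    def test_n_windows_skipped(self):
        pwm = sharp_pwm("M", "ACG")
        res = me.scan_pwm("ANGACG", pwm, rel_threshold=1.0)
        # windows containing N are not scanned on either strand
        assert res.n_windows == 2 * 2
        assert res.count == 1

    def test_bad_threshold_rejected(self):
        pwm = sharp_pwm("M", "ACG")
        with pytest.raises(ValueError):
            me.scan_pwm("ACGT", pwm, rel_threshold=1.5)

    def test_strand_consistency_under_revcomp(self, rng):
        pwm = sharp_pwm("M", "ACGGAAGT")
        for seq in random_sequences(rng, 20, 300).values():
            fwd = me.scan_pwm(seq, pwm, rel_threshold=0.85)
            rev = me.scan_pwm(revcomp(seq), pwm, rel_threshold=0.85)
            assert fwd.count == rev.count


def brute_force_seed_sites(utr, mirna):
    """Independent classifier: examine every substring position."""
    mirna = mirna.upper().replace("U", "T")
    utr = utr.upper().replace("U", "T")
    s7 = revcomp(mirna[1:8])
    s6 = revcomp(mirna[1:7])
    m8c = revcomp(mirna[7])
    counts = {"8mer": 0, "7mer-m8": 0, "7mer-1A": 0}
    for p in range(len(utr)):
        if utr[p:p + 7] == s7:
            if utr[p + 7:p + 8] == "A":
                counts["8mer"] += 1
            else:
                counts["7mer-m8"] += 1
        if (
            utr[p:p + 6] == s6
            and utr[p + 6:p + 7] == "A"
            and not (p > 0 and utr[p - 1] == m8c)
        ):
            counts["7mer-1A"] += 1
    return counts


class TestSeedSites:
    def test_worked_8mer_example(self):
        assert me.count_seed_sites("AATGCTGCTAAA", "TAGCAGCAT") == {
            "8mer": 1, "7mer-m8": 0, "7mer-1A": 0,
        }

    def test_worked_7mer_m8_example(self):
        assert me.count_seed_sites("TGCTGCTG", "TAGCAGCAT") == {
            "8mer": 0, "7mer-m8": 1, "7mer-1A": 0,
        }

    def test_no_complementarity_counts_zero(self):
        counts = me.count_seed_sites("AAAAAAAA", "TAGCAGCAT")
        assert sum(counts.values()) == 0

    def test_7mer_1a_without_m8_pairing(self):
        # S6 = GCTGCT followed by A, preceded by a base that does not
        # pair miRNA position 8 (T would)
        assert me.count_seed_sites("AGCTGCTA", "TAGCAGCAT")["7mer-1A"] == 1

    def test_u_mapped_to_t(self):
        assert me.count_seed_sites("AAUGCUGCUAAA", "UAGCAGCAU")["8mer"] == 1

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            me.count_seed_sites("ACGTACGT", "ACGTACG")

    def test_matches_brute_force_on_random_sequences(self, rng):
        # AT-rich alphabet raises the chance of seed-like substrings
        bases = np.array(list("AATGCTG"))
        for _ in range(300):
            utr = "".join(bases[rng.integers(0, len(bases), size=80)])
            mirna = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=21)])
            assert me.count_seed_sites(utr, mirna) == brute_force_seed_sites(utr, mirna)


class TestBackground:
    def test_same_seed_reproducible(self):
        pool = [f"seq{i}" for i in range(100)]
        assert me.sample_background(pool, 10, seed=3) == me.sample_background(
            pool, 10, seed=3
        )

    def test_full_pool_returned(self):
        pool = ["a", "b", "c"]
        assert sorted(me.sample_background(pool, 3, seed=0)) == pool

    def test_undersized_pool_rejected(self):
        with pytest.raises(ValueError):
            me.sample_background(["a"] * 4999, 5000, seed=0)


class TestEnrichmentZ:
    def test_zero_at_expectation(self):
        z = me.enrichment_z(10, 10000, 100, 100000)
        assert z.z == pytest.approx(0.0, abs=1e-12)
        assert z.expected == pytest.approx(10.0)

    def test_worked_binomial_example(self):
        z = me.enrichment_z(16, 10000, 100, 100000)
        assert z.z == pytest.approx(1.898, abs=1e-3)

    def test_antisymmetry_about_expectation(self):
        over = me.enrichment_z(16, 10000, 100, 100000)
        under = me.enrichment_z(4, 10000, 100, 100000)
        assert under.z == pytest.approx(-over.z, abs=1e-12)

    def test_background_against_itself_is_zero(self):
        z = me.enrichment_z(100, 100000, 100, 100000)
        assert z.z == 0.0

    def test_zero_background_hits_degenerate(self):
        z = me.enrichment_z(5, 1000, 0, 100000)
        assert z.degenerate and np.isnan(z.z)

    def test_saturated_background_rate_rejected(self):
        with pytest.raises(ValueError):
            me.enrichment_z(5, 1000, 100000, 100000)


class TestSelectInformative:
    def test_all_equal_matrix_selects_nothing(self):
        zm = me.ZMatrix(pd.DataFrame({"A": [1.0, 1.0, 1.0], "B": [2.0, 2.0, 2.0]}))
        with pytest.warns(UserWarning):
            assert me.select_informative(zm).values.empty

    def test_outlier_row_selected(self):
        zm = me.ZMatrix(
            pd.DataFrame({"A": [0.0, 0.1, -0.1, 5.0], "B": [0.0] * 4},
                         index=list("wxyz"))
        )
        with pytest.warns(UserWarning):  # zero-SD column B flagged
            sel = me.select_informative(zm)
        assert "z" in sel.values.index

    def test_invariant_to_column_shift(self):
        df = pd.DataFrame({"A": [0.0, 1.0, 4.0], "B": [1.0, 2.0, 0.5]},
                          index=list("xyz"))
        sel1 = me.select_informative(me.ZMatrix(df))
        sel2 = me.select_informative(me.ZMatrix(df + 100.0))
        assert list(sel1.values.index) == list(sel2.values.index)


class TestClustering:
    def df(self):
        return pd.DataFrame(
            {
                "A": [1.0, 1.0, 5.0, -3.0],
                "B": [2.0, 2.0, 1.0, -1.0],
                "C": [0.5, 0.5, 9.0, -6.0],
            },
            index=["m1", "m2", "m3", "m4"],
        )

    def test_identical_rows_merge_first(self):
        zm = me.hierarchical_cluster(me.ZMatrix(self.df()), k=2)
        first_merge = zm.linkage[0]
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}  # m1, m2
        assert first_merge[2] == 0.0

    def test_k_equal_rows_gives_singletons(self):
        zm = me.hierarchical_cluster(me.ZMatrix(self.df().iloc[[0, 2, 3]]), k=3)
        assert len(set(zm.cluster_labels.values())) == 3

    def test_k_above_rows_rejected(self):
        with pytest.raises(ValueError):
            me.hierarchical_cluster(me.ZMatrix(self.df()), k=5)

    def test_duplicated_rows_pair_before_cross_merges(self, rng):
        base = pd.DataFrame(
            rng.normal(size=(5, 3)), index=[f"a{i}" for i in range(5)],
            columns=list("ABC"),
        )
        dup = base.copy()
        dup.index = [f"b{i}" for i in range(5)]
        zm = me.hierarchical_cluster(me.ZMatrix(pd.concat([base, dup])), k=5)
        # first five merges are all zero-distance twin pairs
        assert np.allclose(zm.linkage[:5, 2], 0.0)

    def test_newick_export_contains_all_leaves(self):
        zm = me.hierarchical_cluster(me.ZMatrix(self.df()), k=2)
        nwk = me.dendrogram_newick(zm)
        assert nwk.endswith(";")
        for m in self.df().index:
            assert m in nwk


class TestNetwork:
    def edges(self):
        return pd.DataFrame(
            {
                "source": ["miR-499", "miR-125b", "SRF", "FOXF2"],
                "target": ["SRF", "SRF", "EGR1", "TUBB3"],
                "sign": ["inhibition", "inhibition", "activation", "activation"],
            }
        )

    def test_one_step_inhibition_edge_found(self):
        out = me.direct_interactions({"SRF"}, {"miR-499"}, self.edges())
        assert len(out) == 1
        assert out.iloc[0].sign == "inhibition"

    def test_empty_sets_empty_result(self):
        assert me.direct_interactions(set(), set(), self.edges()).empty

    def test_edge_with_outside_endpoint_excluded(self):
        out = me.direct_interactions({"SRF", "EGR1"}, {"miR-499"}, self.edges())
        assert set(out.target) == {"SRF", "EGR1"}
        assert "TUBB3" not in set(out.target)

    def test_unknown_sign_rejected(self):
        bad = self.edges()
        bad.loc[0, "sign"] = "represses"
        with pytest.raises(ValueError):
            me.direct_interactions({"SRF"}, {"miR-499"}, bad)
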