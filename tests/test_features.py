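"""Centromere localization, centromeric repeat families, spans, composition,
and telomeric tract detection."""

import itertools

import numpy as np
import pandas as pd
import pytest

import kelpfold as kf


def toy_trans_map(cen_bins=(3, 7, 4), boost=6.0, n_per_chrom=10):
    """Three 10-bin chromosomes with mutually enriched planted cells."""
    names = ["c1", "c2", "c3"]
    g = kf.GenomeSpec([(n, n_per_chrom * 10_000) for n in names], 10_000)
    n = g.n_bins
    oe = np.ones((n, n))
    cen_global = [g.chrom_offset(nm) + b for nm, b in zip(names, cen_bins)]
    for a, b in itertools.combinations(cen_global, 2):
        oe[a, b] = oe[b, a] = boost
    counts = np.ones((n, n))
    m = kf.ContactMatrix(g, counts, weights=np.ones(n))
    return m, oe, cen_global, g


def bruteforce_centromeres(oe, g):
    """Exhaustive search over all bin tuples maximizing total pairwise trans O/E."""
    slices = [range(g.chrom_slice(n).start, g.chrom_slice(n).stop) for n in g.names]
    best, best_score = None, -np.inf
    for tup in itertools.product(*slices):
        score = sum(oe[a, b] for a, b in itertools.combinations(tup, 2))
        if score > best_score:
            best, best_score = tup, score
    return list(best)


class TestLocateCentromeresHic:
    def test_matches_bruteforce_on_toy(self):
        m, oe, cen_global, g = toy_trans_map()
        res = kf.locate_centromeres_hic(
            m, oe=oe, smooth_bins=1, refine=False, exclude_terminal=0
        )
        assert list(res["bin"]) == bruteforce_centromeres(oe, g) == cen_global

    def test_planted_recovery_within_one_bin(self):
        t = kf.SyntheticTruth(seed=4)
        m = kf.ice_balance(kf.mask_low_coverage(kf.simulate_contact_map(t, 1_000_000)))
        res = kf.locate_centromeres_hic(m)
        g = t.genome()
        for _, r in res.iterrows():
            truth_bin = g.bin_index(r["chrom"], t.centromeres()[r["chrom"]])
            assert abs(r["bin"] - truth_bin) <= 1
        assert not res["no_enrichment"].any()

    def test_uniform_map_flags_no_enrichment(self):
        g = kf.GenomeSpec([("c1", 100_000), ("c2", 100_000)], 10_000)
        n = g.n_bins
        m = kf.ContactMatrix(g, np.ones((n, n)), weights=np.ones(n))
        res = kf.locate_centromeres_hic(m, smooth_bins=1, refine=False, exclude_terminal=0)
        assert res["no_enrichment"].all()

    def test_single_chromosome_raises(self):
        g = kf.GenomeSpec([("c1", 100_000)], 10_000)
        m = kf.ContactMatrix(g, np.ones((10, 10)), weights=np.ones(10))
        with pytest.raises(ValueError, match="2 chromosomes"):
            kf.locate_centromeres_hic(m)


@pytest.fixture
def planted_repeats():
    rows = [
        # family CEN-A: all copies inside windows, on every chromosome
        ("c1", 30_000, 36_000, "CEN-A", "interspersed"),
        ("c1", 40_000, 46_000, "CEN-A", "interspersed"),
        ("c2", 70_000, 76_000, "CEN-A", "interspersed"),
        ("c3", 40_000, 44_000, "CEN-A", "interspersed"),
        ("c4", 50_000, 56_000, "CEN-A", "interspersed"),
        # family ONE-CHROM: windowed copies on only one chromosome
        ("c1", 32_000, 34_000, "ONE-CHROM", "interspersed"),
        ("c2", 5_000, 7_000, "ONE-CHROM", "interspersed"),
        # scattered background
        ("c1", 90_000, 95_000, "BG", "interspersed"),
        ("c2", 10_000, 15_000, "BG", "interspersed"),
        ("c3", 90_000, 95_000, "BG", "tandem"),
    ]
    return kf.RepeatAnnotation(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "family", "class"])
    )


WINDOWS = {"c1": (20_000, 50_000), "c2": (60_000, 90_000), "c3": (30_000, 50_000), "c4": (40_000, 60_000)}


class TestScanCentromericFamilies:
    def test_planted_family_selected_with_full_specificity(self, planted_repeats):
        res = kf.scan_centromeric_families(planted_repeats, WINDOWS)
        assert list(res["family"]) == ["CEN-A"]
        assert res.loc[0, "specificity"] == 1.0
        assert res.loc[0, "ubiquity"] == 1.0

    def test_single_chromosome_family_rejected_on_ubiquity(self, planted_repeats):
        res = kf.scan_centromeric_families(planted_repeats, WINDOWS, min_chrom_fraction=1.0)
        assert "ONE-CHROM" not in set(res["family"])

    def test_two_passing_families_both_returned(self, planted_repeats):
        df = planted_repeats.intervals.copy()
        extra = pd.DataFrame(
            [
                ("c1", 35_000, 36_000, "CEN-B", "interspersed"),
                ("c2", 65_000, 66_000, "CEN-B", "interspersed"),
                ("c3", 45_000, 46_000, "CEN-B", "interspersed"),
                ("c4", 41_000, 42_000, "CEN-B", "interspersed"),
            ],
            columns=df.columns,
        )
        r = kf.RepeatAnnotation(pd.concat([df, extra], ignore_index=True))
        res = kf.scan_centromeric_families(r, WINDOWS)
        assert set(res["family"]) == {"CEN-A", "CEN-B"}
        assert res.loc[0, "family"] == "CEN-A"  # more copies ranks first


class TestDefineCentromereSpans:
    def test_min_to_max_span(self):
        r = kf.RepeatAnnotation(
            pd.DataFrame(
                [("c1", 10_000, 16_000, "F", "interspersed"), ("c1", 80_000, 86_000, "F", "interspersed")],
                columns=["chrom", "start", "end", "family", "class"],
            )
        )
        calls = kf.define_centromere_spans(r, ["F"])
        assert (calls[0].start, calls[0].end) == (10_000, 86_000)

    def test_single_copy_span_is_that_copy(self):
        r = kf.RepeatAnnotation(
            pd.DataFrame(
                [("c1", 50_000, 56_800, "F", "interspersed")],
                columns=["chrom", "start", "end", "family", "class"],
            )
        )
        calls = kf.define_centromere_spans(r, ["F"])
        assert (calls[0].start, calls[0].end) == (50_000, 56_800)

    def test_empty_family_list_raises(self, planted_repeats):
        with pytest.raises(ValueError):
            kf.define_centromere_spans(planted_repeats, [])

    def test_idempotent_under_interior_copy(self):
        rows = [
            ("c1", 10_000, 16_000, "F", "interspersed"),
            ("c1", 80_000, 86_000, "F", "interspersed"),
        ]
        cols = ["chrom", "start", "end", "family", "class"]
        base = kf.define_centromere_spans(kf.RepeatAnnotation(pd.DataFrame(rows, columns=cols)), ["F"])
        rows.append(("c1", 40_000, 46_000, "F", "interspersed"))
        more = kf.define_centromere_spans(kf.RepeatAnnotation(pd.DataFrame(rows, columns=cols)), ["F"])
        assert (base[0].start, base[0].end) == (more[0].start, more[0].end)


class TestCentromereComposition:
    def _call(self, start=10_000, end=30_000):
        return kf.CentromereCall("c1", start, end, "repeat-span", families=["FAM-A"])

    def test_hand_built_fractions(self):
        r = kf.RepeatAnnotation(
            pd.DataFrame(
                [
                    ("c1", 12_000, 18_000, "FAM-A", "interspersed"),  # 6 kb in a 20 kb span
                    ("c1", 20_000, 22_000, "SAT", "tandem"),  # 2 kb
                ],
                columns=["chrom", "start", "end", "family", "class"],
            )
        )
        table = kf.centromere_composition([self._call()], r)
        row = table.iloc[0]
        assert row["frac_FAM-A"] == pytest.approx(0.30)
        assert row["frac_tandem"] == pytest.approx(0.10)
        assert row["frac_other_interspersed"] == 0.0

    def test_full_family_coverage(self):
        r = kf.RepeatAnnotation(
            pd.DataFrame(
                [("c1", 10_000, 30_000, "FAM-A", "interspersed")],
                columns=["chrom", "start", "end", "family", "class"],
            )
        )
        table = kf.centromere_composition([self._call()], r)
        assert table.iloc[0]["frac_FAM-A"] == 1.0
        assert table.iloc[0]["frac_tandem"] == 0.0

    def test_fractions_sum_below_one_with_overlaps(self):
        r = kf.RepeatAnnotation(
            pd.DataFrame(
                [
                    ("c1", 12_000, 18_000, "FAM-A", "interspersed"),
                    ("c1", 16_000, 22_000, "SAT", "tandem"),  # overlaps FAM-A
                    ("c1", 21_000, 26_000, "BG", "interspersed"),  # overlaps SAT
                ],
                columns=["chrom", "start", "end", "family", "class"],
            )
        )
        row = kf.centromere_composition([self._call()], r).iloc[0]
        # precedence family > tandem > other removes double counting
        assert row["frac_FAM-A"] == pytest.approx(0.30)
        assert row["frac_tandem"] == pytest.approx(0.20)
        assert row["frac_other_interspersed"] == pytest.approx(0.20)
        total = row["frac_FAM-A"] + row["frac_tandem"] + row["frac_other_interspersed"]
        assert total <= 1.0

    def test_gc_and_genes_reported(self):
        seq = {"c1": "AT" * 5_000 + "GC" * 10_000 + "AT" * 5_000}  # span 10-30 kb all GC
        genes = pd.DataFrame({"chrom": ["c1", "c1"], "start": [15_000, 90_000], "end": [16_000, 91_000]})
        r = kf.RepeatAnnotation(pd.DataFrame(columns=["chrom", "start", "end", "family", "class"]))
        row = kf.centromere_composition([self._call()], r, sequences=seq, genes=genes).iloc[0]
        assert row["gc_span"] == pytest.approx(1.0)
        assert row["gc_rest"] == pytest.approx(0.0)
        assert row["n_genes"] == 1


class TestTelomericTracts:
    def test_three_prime_tract_detected(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 5_000)) + "TTAGGG" * 30
        res = kf.detect_telomeric_tracts(seq)
        tract = res["three_prime"]
        assert tract is not None
        assert tract["end"] - tract["start"] == 180
        assert tract["n_copies"] == 30
        assert res["five_prime"] is None and not res["t2t"]

    def test_five_prime_uses_reverse_complement(self):
        rng = np.random.default_rng(1)
        seq = "CCCTAA" * 10 + "".join(rng.choice(list("ACGT"), 5_000))
        res = kf.detect_telomeric_tracts(seq)
        assert res["five_prime"] is not None
        assert res["five_prime"]["n_copies"] == 10

    def test_no_motif_means_absent(self):
        seq = "ACAC" * 2_000
        res = kf.detect_telomeric_tracts(seq)
        assert res["five_prime"] is None and res["three_prime"] is None and not res["t2t"]

    def test_t2t_requires_both_ends(self):
        rng = np.random.default_rng(2)
        mid = "".join(rng.choice(list("ACGT"), 10_000))
        seq = "CCCTAA" * 8 + mid + "TTAGGG" * 8
        assert kf.detect_telomeric_tracts(seq)["t2t"]

    def test_invariant_under_appending_beyond_max_offset(self):
        rng = np.random.default_rng(3)
        core = "".join(rng.choice(list("ACGT"), 3_000)) + "TTAGGG" * 10
        res1 = kf.detect_telomeric_tracts(core)
        res2 = kf.detect_telomeric_tracts(core + "".join(rng.choice(list("ACGT"), 5_000)))
        assert res1["three_prime"] is not None
        assert res2["three_prime"] is None  # tract now farther than max_offset from the end

    def test_min_copies_threshold(self):
        seq = "A" * 3_000 + "TTAGGG" * 4
        assert kf.detect_telomeric_tracts(seq, min_copies=5)["three_prime"] is None
        assert kf.detect_telomeric_tracts(seq, min_copies=4)["three_prime"] is not None

    def test_genome_summary_counts(self, default_tracks):
        res = kf.telomere_summary(default_tracks.sequences)
        # generator default plan: chr1/chr2 both ends, chr3 5' only, chr4 none
        assert res["n_resolved_ends"] == 5
        assert res["n_t2t"] == 2
        assert res["n_ends"] == 8
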