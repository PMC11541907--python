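import numpy as np
import pytest

from mrnadecay import ConfigurationError, SchemaError, ValidationError
from mrnadecay import features as ft
from mrnadecay import synthetic_data as sd


class TestMotifs:
    def test_overlapping_agga_count(self):
        # sliding-window oracle: AGGA occurs at offsets 0 and 3 in AGGAGGA
        assert ft.count_motifs("AGGAGGA", {"m": "AGGA"}) == {"m": 2}

    def test_empty_motif_set(self):
        assert ft.count_motifs("ACGU", {}) == {}

    def test_absent_motif_zero(self):
        assert ft.count_motifs("CCCC", {"m": "AGGA"}) == {"m": 0}

    def test_iupac_expansion(self):
        assert ft.count_motifs("AGGAAUUA", {"m": "RWW"})["m"] > 0
        with pytest.raises(ConfigurationError):
            ft.count_motifs("ACGU", {"m": "AXGU"})


class TestQuadruplexDetection:
    def test_canonical_g4_span(self):
        seq = "GGG" + "AUCAUC" + "GGG" + "AUCAUC" + "GGG" + "AUCAUC" + "GGG"
        spans = ft.detect_quadruplex(seq)
        assert spans == [(0, 30)]

    def test_c_runs_are_imotif_not_g4(self):
        seq = "CCC" + "AUGAUG" + "CCC" + "AUGAUG" + "CCC" + "AUGAUG" + "CCC"
        assert ft.detect_quadruplex(seq) == []
        assert ft.detect_quadruplex(seq, base="C") == [(0, 30)]

    def test_six_gs_alone_no_match(self):
        assert ft.detect_quadruplex("GGGGGG") == []

    def test_brute_force_regex_oracle_on_random_sequences(self):
        # oracle: exhaustive scan of every placement of four G3 runs
        rng = np.random.default_rng(0)
        for _ in range(50):
            seq = "".join("ACGU"[i] for i in rng.integers(0, 4, 200))
            spans = ft.detect_quadruplex(seq)
            naive = []
            i = 0
            while i <= len(seq) - 30:
                window = seq[i : i + 30]
                ok = all(
                    window[9 * r : 9 * r + 3] == "GGG" for r in range(4)
                )
                if ok and (not naive or i >= naive[-1][1]):
                    naive.append((i, i + 30))
                    i += 30
                else:
                    i += 1
            assert spans == naive


class TestFolding:
    def test_hairpin_folds_to_expected_structure(self):
        stem = "GCGGCAUC"
        rc = stem[::-1].translate(str.maketrans("ACGU", "UGCA"))
        pt = ft.NussinovFolder().fold(stem + "GAAA" + rc)
        assert ft.to_dot_bracket(pt) == "((((((((....))))))))"

    def test_blocked_positions_stay_unpaired(self):
        stem = "GCGGCAUC"
        rc = stem[::-1].translate(str.maketrans("ACGU", "UGCA"))
        pt = ft.NussinovFolder().fold(stem + "GAAA" + rc, blocked=range(0, 8))
        assert all(pt[i] == -1 for i in range(8))

    def test_no_lone_pairs(self):
        rng = np.random.default_rng(1)
        folder = ft.NussinovFolder()
        for _ in range(30):
            seq = "".join("ACGU"[i] for i in rng.integers(0, 4, 60))
            pt = folder.fold(seq)
            ft.validate_pair_table(pt)
            for i, j in enumerate(pt):
                if j > i:
                    stacked = (i + 1 < len(pt) and pt[i + 1] == j - 1) or (
                        i > 0 and j + 1 < len(pt) and pt[i - 1] == j + 1
                    )
                    assert stacked, (i, j)

    def test_min_hairpin_loop(self):
        folder = ft.NussinovFolder()
        for seq in ("GCGC", "GGCC", "GCAGC"):
            pt = folder.fold(seq)
            for i, j in enumerate(pt):
                if j > i:
                    assert j - i - 1 >= 3

    def test_dot_bracket_round_trip(self):
        s = "((..((...))..))"
        assert ft.to_dot_bracket(ft.parse_dot_bracket(s)) == s

    def test_bad_pair_table_rejected(self):
        with pytest.raises(ValidationError):
            ft.validate_pair_table([1, -1, -1])  # partner does not point back


class TestAnatomy:
    def test_fully_unpaired_utr(self):
        a = ft.annotate("A" * 20, [-1] * 20)
        assert a.ssrna_total_nt == 20
        assert a.hairpin_count == 0
        assert a.ssrna_segment_lengths == [20]
        assert a.ssrna_composition["A"] == 1.0

    def test_perfect_hairpin_anatomy(self):
        # hand-traversal oracle for "((((((((....))))))))"
        pt = ft.parse_dot_bracket("((((((((....))))))))")
        a = ft.annotate("GCGGCAUCGAAAGAUGCCGC", pt)
        assert a.duplex_lengths == [8]
        assert a.loop_lengths == [4]
        assert a.bulge_count == 0
        assert a.internal_loop_count == 0
        assert a.hairpin_count == 1
        assert a.ssrna_total_nt == 4

    def test_bulge_and_internal_loop(self):
        #  5' ((..((...))))  -> one bulge (left side 2, right side 0)
        pt = ft.parse_dot_bracket("((..((...))))")
        a = ft.annotate("GCAAGCAAAGCGC", pt)
        assert a.bulge_count == 1
        assert a.internal_loop_count == 0
        # ((..((...))..)) -> internal loop (2 and 2)
        pt2 = ft.parse_dot_bracket("((..((...))..))")
        a2 = ft.annotate("GCAAGCAAAGCAAGC", pt2)
        assert a2.internal_loop_count == 1
        assert a2.bulge_count == 0

    def test_g4_aware_vs_secondary_only(self):
        rng = np.random.default_rng(5)
        block = sd.quadruplex_block(rng)
        utr = "AACG" + "AAAAA" + block + "CAACA"
        folder = ft.NussinovFolder()
        aware = ft.fold_and_annotate(utr, folder, "g4_aware")
        sec = ft.fold_and_annotate(utr, folder, "secondary_only")
        assert aware.tertiary_nt == 30
        assert aware.g4_present
        assert sec.tertiary_nt == 0
        assert sec.ssrna_total_nt > aware.ssrna_total_nt

    def test_partition_invariant_fuzz(self):
        # unpaired + paired + tertiary == length, over random sequences
        rng = np.random.default_rng(7)
        folder = ft.NussinovFolder()
        for _ in range(60):
            n = int(rng.integers(10, 70))
            seq = "".join("ACGU"[i] for i in rng.integers(0, 4, n))
            mode = "g4_aware" if rng.random() < 0.5 else "secondary_only"
            a = ft.fold_and_annotate(seq, folder, mode)
            assert a.ssrna_total_nt + a.paired_nt + a.tertiary_nt == n

    def test_empty_sequence_rejected(self):
        with pytest.raises(ConfigurationError):
            ft.fold_and_annotate("", ft.NussinovFolder())


class TestProviders:
    def test_surrogate_tx_deterministic(self):
        p = ft.SurrogateTxProvider()
        seq = sd.PROMOTER + "AACG" + "A" * 20
        assert p(seq) == p(seq)

    def test_surrogate_tx_sensitive_to_itr_change(self):
        p = ft.SurrogateTxProvider()
        base = sd.PROMOTER + "AACGAAAAAAAAAAAAAAAA" + "CAACA"
        # single-nt change within the first 20 transcribed nt
        changed = sd.PROMOTER + "AACGAAAAAAGAAAAAAAAA" + "CAACA"
        r1 = dict(p(base))
        r2 = dict(p(changed))
        assert any(r1[o] != r2.get(o, None) for o in r1)

    def test_surrogate_tx_always_returns_sites(self):
        rng = np.random.default_rng(0)
        p = ft.SurrogateTxProvider()
        for _ in range(10):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
            assert len(p(seq)) >= 1

    def test_surrogate_tir_sd_strength_ordering(self):
        p = ft.SurrogateTirProvider()
        leader = "CAACAACAACAA"
        strong = leader + "AGGAGG" + "UCAACAA" + "AUGGCU"
        weak = leader + "CACCAC" + "UCAACAA" + "AUGGCU"
        cds = len(leader) + 6 + 7
        assert p(strong, cds) > p(weak, cds)

    def test_surrogate_tir_occlusion_lowers_rate(self):
        p = ft.SurrogateTirProvider()
        sd_seq = "AGGAGG"
        # hairpin arm complementary to the SD region sequesters it
        anti = sd_seq[::-1].translate(str.maketrans("ACGU", "UGCA"))
        open_leader = "AACAACAAAC" + sd_seq + "UCAACAA"
        closed_leader = anti + "GAAA" + sd_seq + "UCAACAA"
        tir_open = p(open_leader + "AUGGCU", len(open_leader))
        tir_closed = p(closed_leader + "AUGGCU", len(closed_leader))
        assert tir_closed < tir_open

    def test_tie_break_by_offset(self):
        provider = lambda construct: [(10, 5.0), (4, 5.0), (7, 9.0)]
        isoforms = ft.enumerate_isoforms("A" * 40, provider, n=3)
        assert [i.tss_offset for i in isoforms] == [7, 4, 10]
        assert [i.rank for i in isoforms] == [1, 2, 3]

    def test_no_sites_is_error(self):
        with pytest.raises(ValidationError):
            ft.enumerate_isoforms("ACGU" * 10, lambda c: [], n=5)


class TestSchema:
    def test_default_dimension_is_496(self):
        assert ft.build_schema().dimension == 496

    def test_excluded_schema_is_smaller_and_lacks_columns(self):
        excl = ("duplex_max_len", "internal_loop_count", "bulge_count")
        schema = ft.build_schema(exclude=excl)
        assert schema.dimension < 496
        for name in excl:
            assert not any(n.endswith(name) for n in schema.names)

    def test_unknown_exclusion_rejected(self):
        with pytest.raises(SchemaError):
            ft.build_schema(exclude=("not_a_feature",))

    def test_schema_hash_stable_and_sensitive(self):
        s1, s2 = ft.build_schema(), ft.build_schema()
        assert s1.version_hash == s2.version_hash
        assert s1.version_hash != ft.build_schema(exclude=("bulge_count",)).version_hash


@pytest.fixture(scope="module")
def small_setup():
    lib = sd.generate_design_library({"full_factorial_polyA": {"n_rbs": 2}}, seed=0)[:30]
    return lib, ft.providers_for_library(lib), ft.build_schema()


class TestFeaturize:

    def test_deterministic_featurization(self, small_setup):
        lib, provs, schema = small_setup
        x1 = ft.featurize_library(lib, provs, schema)
        x2 = ft.featurize_library(lib, provs, schema)
        assert x1.equals(x2)

    def test_rpph_onehot_matches_site(self, small_setup):
        lib, provs, schema = small_setup
        X = ft.featurize_library(lib, provs, schema)
        for v in lib[:8]:
            for p, base in enumerate(v.rpph_site):
                assert X.loc[v.variant_id, f"iso1_rpph_p{p}_{base}"] == 1.0

    def test_absent_isoforms_padded_with_sentinel(self, small_setup):
        lib, provs, schema = small_setup
        X = ft.featurize_library(lib[:3], provs, schema)
        # designed provider yields a single dominant isoform
        assert (X["iso2_log_tir"] == ft.SENTINEL).all()
        assert (X["iso5_utr_len"] == ft.SENTINEL).all()

    def test_single_site_n1_vs_n5_differ_only_in_padding(self, small_setup):
        lib, provs, _ = small_setup
        s1 = ft.build_schema(n_isoforms=1, pad_to=None)
        s5 = ft.build_schema(n_isoforms=5, pad_to=None)
        v = lib[0]
        import mrnadecay.synthetic_data as sdm

        construct = v.construct()
        cds = len(sdm.PROMOTER) + len(v.utr_seq)
        x1 = ft.featurize_construct(construct, cds, provs, s1)
        x5 = ft.featurize_construct(construct, cds, provs, s5)
        iso1_names = [n for n in s5.names if n.startswith("iso1_")]
        for name in iso1_names:
            assert x5[s5.index(name)] == x1[s1.index(name)]
        other = [n for n in s5.names if n.startswith(("iso2_", "iso3_", "iso4_", "iso5_"))]
        assert all(x5[s5.index(n)] == ft.SENTINEL for n in other)

    def test_too_many_blocks_rejected(self):
        schema = ft.build_schema(n_isoforms=1, pad_to=None)
        with pytest.raises(SchemaError):
            ft.assemble_features(schema, [{}, {}], {})
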