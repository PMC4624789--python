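"""Haplotype parsing, filtering and classification."""

import hypothesis.strategies as st
import pytest
from hypothesis import given, settings

from mitofounder import (
    BUNDLED_MOTIF_TABLE,
    HVS1_RANGE,
    FilterPolicy,
    Haplotype,
    VariantCall,
    VariantKind,
    assign_haplogroup_motif,
    classify_diagnostic_snp,
    filter_positions,
    format_variant_string,
    haplotype_from_sequence,
    parse_variant_string,
    read_freq_table,
    read_haplotype_table,
    synthetic_reference,
    write_haplotype_table,
)
from mitofounder.haplotype_io import (
    CoverageError,
    FULL_RANGE,
    HaplotypeError,
    MotifTableError,
    RangeError,
    VariantParseError,
)


class TestParseVariantString:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("16172C", {(16172, "C", VariantKind.SUBSTITUTION)}),
            ("", set()),
            (
                "16183.1C 16189d 16093Y 16126C",
                {
                    (16183, "C", VariantKind.INSERTION),
                    (16189, "-", VariantKind.DELETION),
                    (16093, "Y", VariantKind.HETEROPLASMY),
                    (16126, "C", VariantKind.SUBSTITUTION),
                },
            ),
            ("16189del", {(16189, "-", VariantKind.DELETION)}),
        ],
    )
    def test_grammar(self, text, expected):
        h = parse_variant_string(text)
        assert {(v.position, v.derived_allele, v.kind) for v in h.variants} == expected

    def test_empty_string_is_reference_identity(self):
        assert parse_variant_string("").variants == frozenset()

    def test_malformed_token_named_in_error(self):
        with pytest.raises(VariantParseError, match="16172X"):
            parse_variant_string("16126C 16172X")

    def test_out_of_range_token_named_in_error(self):
        with pytest.raises(RangeError, match="73G"):
            parse_variant_string("16126C 73G")

    def test_insertion_needs_subindex(self):
        with pytest.raises(VariantParseError):
            VariantCall(16183, "C", VariantKind.INSERTION, 0)

    def test_substitution_identical_to_reference_rejected(self):
        ref = synthetic_reference()
        base = ref[16172 - 1]
        with pytest.raises(VariantParseError, match="identical"):
            parse_variant_string(f"16172{base}", reference=ref)

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_parse_format_round_trip(self, data):
        positions = data.draw(
            st.lists(
                st.integers(16051, 16400), min_size=0, max_size=8, unique=True
            )
        )
        tokens = []
        for p in positions:
            kind = data.draw(st.sampled_from(["sub", "ins", "del", "het"]))
            if kind == "sub":
                tokens.append(f"{p}{data.draw(st.sampled_from('ACGT'))}")
            elif kind == "ins":
                tokens.append(f"{p}.1{data.draw(st.sampled_from('ACGT'))}")
            elif kind == "del":
                tokens.append(f"{p}d")
            else:
                tokens.append(f"{p}Y")
        text = " ".join(tokens)
        h = parse_variant_string(text)
        assert parse_variant_string(format_variant_string(h)).variants == h.variants


class TestFilterPositions:
    def test_default_exclusions(self):
        # range widened to the control-region end so the 16519 call (beyond
        # HVS-I proper) can be scored and then dropped by the policy
        h = parse_variant_string("16182C 16183C 16519C 16172C", range=(16051, 16569))
        assert format_variant_string(filter_positions(h)) == "16172C"

    def test_indels_and_heteroplasmy_dropped(self, hap):
        h = hap("16093Y 16189.1C")
        assert filter_positions(h).variants == frozenset()

    def test_16519_dropped_for_any_allele_16183_only_c(self):
        h = parse_variant_string("16519A 16183A", range=(16051, 16569))
        kept = filter_positions(h)
        assert format_variant_string(kept) == "16183A"

    def test_original_untouched(self, hap):
        h = hap("16182C 16172C")
        filter_positions(h)
        assert len(h.variants) == 2

    @given(st.lists(st.tuples(st.integers(16051, 16400), st.sampled_from("ACGT")),
                    max_size=8, unique_by=lambda t: t[0]))
    @settings(max_examples=100, deadline=None)
    def test_idempotence(self, calls):
        h = Haplotype(
            variants=frozenset(
                VariantCall(p, a, VariantKind.SUBSTITUTION) for p, a in calls
            )
        )
        once = filter_positions(h)
        assert filter_positions(once).variants == once.variants


class TestDiagnosticSnp:
    def test_u6_marker(self):
        h = parse_variant_string("3348G", range=FULL_RANGE)
        assert classify_diagnostic_snp(h) == "U6"

    def test_lm_marker(self):
        h = parse_variant_string("10873C", range=FULL_RANGE)
        assert classify_diagnostic_snp(h) == "L/M"

    def test_no_marker(self):
        h = parse_variant_string("16172C", range=FULL_RANGE)
        assert classify_diagnostic_snp(h) == "none"

    def test_multiple_markers_all_reported(self):
        h = parse_variant_string("3348G 10873C", range=FULL_RANGE)
        assert set(classify_diagnostic_snp(h)) == {"U6", "L/M"}

    def test_uncovered_assay_position_raises(self, hap):
        with pytest.raises(CoverageError):
            classify_diagnostic_snp(hap("16172C"))

    def test_labels_only_from_assay_table(self, hap):
        table = {16189: {"C": "lab1"}}
        assert classify_diagnostic_snp(hap("16189C"), table) == "lab1"
        assert classify_diagnostic_snp(hap("16189T"), table) == "none"


class TestMotifAssignment:
    def test_deepest_match(self, hap):
        h = hap("16172C 16219G 16278T")
        assert assign_haplogroup_motif(h) == "U6a"

    def test_parent_when_child_motif_incomplete(self, hap):
        assert assign_haplogroup_motif(hap("16172C 16219G")) == "U6"

    def test_empty_variants_root(self, hap):
        assert assign_haplogroup_motif(hap("")) == "mt-root"

    def test_sibling_tie_reported(self, hap):
        table = {
            "root": (None, frozenset()),
            "A": ("root", frozenset({"16172C"})),
            "B": ("root", frozenset({"16219G"})),
        }
        assert assign_haplogroup_motif(hap("16172C 16219G"), table) == ["A", "B"]

    def test_cyclic_hierarchy_rejected(self, hap):
        table = {"A": ("B", frozenset({"16172C"})), "B": ("A", frozenset({"16219G"}))}
        with pytest.raises(MotifTableError, match="cyclic"):
            assign_haplogroup_motif(hap("16172C"), table)


class TestSequenceInput:
    def test_scores_against_reference_slice(self):
        ref = synthetic_reference()
        lo, hi = HVS1_RANGE
        seq = list(ref[lo - 1 : hi])
        idx = 16172 - lo
        seq[idx] = "A" if ref[16172 - 1] != "A" else "G"
        h = haplotype_from_sequence("".join(seq), ref)
        assert [v.position for v in h.variants] == [16172]

    def test_wrong_length_rejected(self):
        with pytest.raises(RangeError, match="length"):
            haplotype_from_sequence("ACGT", synthetic_reference())


class TestTables:
    def test_haplotype_tsv_round_trip(self, tmp_path, hap):
        hs = [
            hap("16172C 16219G", sample_id="a", population="P1", region_role="source"),
            hap("", sample_id="b", population="P2", region_role="sink"),
        ]
        path = tmp_path / "h.tsv"
        write_haplotype_table(hs, path)
        back = read_haplotype_table(path)
        assert [(h.sample_id, h.population, h.region_role, h.variants) for h in back] \
            == [(h.sample_id, h.population, h.region_role, h.variants) for h in hs]

    def test_count_table_dash_means_zero(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("haplogroup\tP1\tP2\nn\t10\t20\nU6\t2\t-\n")
        table = read_freq_table(path)
        assert table.count("U6", "P1") == 2
        assert table.count("U6", "P2") == 0

    def test_count_exceeding_n_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("haplogroup\tP1\nn\t10\nU6\t11\n")
        with pytest.raises(HaplotypeError, match="exceeds"):
            read_freq_table(path)

    def test_variants_must_lie_in_range(self):
        with pytest.raises(RangeError):
            Haplotype(
                range=(16051, 16400),
                variants=frozenset({VariantCall(73, "G", VariantKind.SUBSTITUTION)}),
            )
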