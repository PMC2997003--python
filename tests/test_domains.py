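from itertools import product

import numpy as np
import pytest

from aarspred.domains import (
    BUILTIN_PATTERNS,
    CLASS1_PREFERRED_DOMAINS,
    CLASS2_PREFERRED_DOMAINS,
    DomainAnnotation,
    STAGE1_DOMAINS,
    STAGE2_DOMAINS,
    encode_domains,
    load_domain_hits,
    match_pattern,
    parse_prosite_pattern,
    scan_sequences,
)
from aarspred.errors import FormatError, ValidationError
from aarspred.sequence_io import ProteinSequence


class TestParsePattern:
    def test_literal_elements(self):
        p = parse_prosite_pattern("H-I-G-H.", "PS00178")
        assert [e.kind for e in p.elements] == ["literal"] * 4
        assert [next(iter(e.residues)) for e in p.elements] == list("HIGH")

    def test_set_wildcard_repeat(self):
        p = parse_prosite_pattern("[AC]-x(2)-D.")
        kinds = [(e.kind, e.min_repeat, e.max_repeat) for e in p.elements]
        assert kinds == [("set", 1, 1), ("any", 2, 2), ("literal", 1, 1)]
        assert p.elements[0].residues == frozenset("AC")

    def test_exclusion_and_range(self):
        p = parse_prosite_pattern("{PG}-x(1,3)-K.")
        assert p.elements[0].kind == "excluded"
        assert (p.elements[1].min_repeat, p.elements[1].max_repeat) == (1, 3)

    def test_anchors(self):
        p = parse_prosite_pattern("<M-x-K>.")
        assert p.n_anchor and p.c_anchor

    @pytest.mark.parametrize(
        "bad", ["[A-C]-x(", "[AC-D.", "x(3,1).", "A-?-C.", "", "x()-A."]
    )
    def test_malformed_patterns_rejected(self, bad):
        with pytest.raises(FormatError):
            parse_prosite_pattern(bad)


def brute_force_match(pattern_elements, residues):
    """Enumerate all substrings; only for patterns without ranges."""
    starts = []
    n = len(pattern_elements)
    for i in range(len(residues)):
        if i + n > len(residues):
            break
        ok = True
        for el, ch in zip(pattern_elements, residues[i : i + n]):
            if el.kind == "literal" and ch not in el.residues:
                ok = False
            elif el.kind == "set" and ch not in el.residues:
                ok = False
            elif el.kind == "excluded" and ch in el.residues:
                ok = False
        if ok:
            starts.append(i + 1)
    return starts


class TestMatchPattern:
    def test_high_in_context(self):
        p = parse_prosite_pattern("H-I-G-H.", "PS00178")
        assert match_pattern(p, ProteinSequence("s", "MAHIGHK")) == [3]

    def test_exclusion_blocks_match(self):
        p = parse_prosite_pattern("{P}-G.")
        assert match_pattern(p, "PG") == []
        assert match_pattern(p, "AG") == [1]

    def test_wildcard_matches_everywhere(self):
        p = parse_prosite_pattern("x.")
        assert match_pattern(p, "A") == [1]

    def test_overlapping_matches_all_reported(self):
        p = parse_prosite_pattern("A-x-A.")
        assert match_pattern(p, "ACADA") == [1, 3]

    def test_anchored_pattern_respects_termini(self):
        assert match_pattern(parse_prosite_pattern("<M-A."), "MAMA") == [1]
        assert match_pattern(parse_prosite_pattern("M-A>."), "MAMA") == [3]

    def test_variable_range_with_c_anchor_backtracks(self):
        p = parse_prosite_pattern("A-x(1,3)-K>.")
        assert match_pattern(p, "ACK") == [1]
        assert match_pattern(p, "ACCCK") == [1]

    def test_agrees_with_substring_enumerator(self):
        # fixed-length patterns on every sequence of length <= 6 over {A,C,G}
        pats = ["A-C.", "[AC]-G.", "{A}-x-C.", "A-x-x-C."]
        parsed = [parse_prosite_pattern(t) for t in pats]
        for L in range(1, 7):
            for tup in product("ACG", repeat=L):
                s = "".join(tup)
                for p in parsed:
                    assert match_pattern(p, s) == brute_force_match(p.elements, s)


class TestDomainTables:
    def test_load_aggregates_per_id(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("s1\tPS00178\ns1\tPS50889\ns2\tPS50862\n")
        ann = load_domain_hits(path)
        assert ann.domains_of("s1") == {"PS00178", "PS50889"}
        assert ann.domains_of("s2") == {"PS50862"}

    def test_empty_file_and_duplicates(self, tmp_path):
        empty = tmp_path / "e.tsv"
        empty.write_text("")
        assert load_domain_hits(empty).hits == {}
        dup = tmp_path / "d.tsv"
        dup.write_text("s1\tPS00178\ns1\tPS00178\n")
        assert load_domain_hits(dup).domains_of("s1") == {"PS00178"}

    def test_header_tolerated_and_bad_rows_located(self, tmp_path):
        ok = tmp_path / "h.tsv"
        ok.write_text("seq_id\taccession\ns1\tPS00178\n")
        assert load_domain_hits(ok).domains_of("s1") == {"PS00178"}
        bad = tmp_path / "b.tsv"
        bad.write_text("s1\tPS00178\ns2\tnot-an-accession\n")
        with pytest.raises(FormatError, match=":2"):
            load_domain_hits(bad)

    def test_unknown_id_gives_zero_vector(self):
        ann = DomainAnnotation({"s1": frozenset({"PS00178"})})
        v = encode_domains(ann, "missing", STAGE2_DOMAINS)
        assert list(v.values) == [0.0] * 5


class TestEncodeDomains:
    def test_single_hit_bit_position(self):
        ann = DomainAnnotation({"s1": frozenset({"PS00178"})})
        v = encode_domains(ann, "s1", STAGE1_DOMAINS)
        assert list(v.values) == [0.0, 1.0, 0.0, 0.0]

    def test_saturation(self):
        ann = DomainAnnotation({"s1": frozenset(STAGE2_DOMAINS)})
        v = encode_domains(ann, "s1", STAGE2_DOMAINS)
        assert list(v.values) == [1.0] * 5

    def test_multiplicity_and_order_irrelevant(self):
        a = DomainAnnotation({"s": frozenset({"PS50860", "PS00178"})})
        b = DomainAnnotation({"s": frozenset({"PS00178", "PS50860"})})
        va = encode_domains(a, "s", STAGE1_DOMAINS)
        vb = encode_domains(b, "s", STAGE1_DOMAINS)
        assert np.array_equal(va.values, vb.values)

    def test_accession_format_enforced(self):
        with pytest.raises(ValidationError):
            DomainAnnotation({"s": frozenset({"PF00001"})})


class TestStageConstants:
    def test_stage_lists_and_class_preferences_partition(self):
        assert set(STAGE1_DOMAINS) == {"PS50862", "PS00178", "PS50860", "PS50861"}
        assert set(STAGE2_DOMAINS) == set(STAGE1_DOMAINS) | {"PS50889"}
        assert CLASS1_PREFERRED_DOMAINS == {"PS00178", "PS50889"}
        assert CLASS2_PREFERRED_DOMAINS == {"PS50862", "PS50860", "PS50861"}
        assert CLASS1_PREFERRED_DOMAINS | CLASS2_PREFERRED_DOMAINS == set(
            STAGE2_DOMAINS
        )
        assert not CLASS1_PREFERRED_DOMAINS & CLASS2_PREFERRED_DOMAINS

    def test_builtin_scanner_finds_high_signature(self):
        seqs = [
            ProteinSequence("has", "MAHIGHKMSKS"),
            ProteinSequence("lacks", "MACDEFKLMNP"),
        ]
        ann = scan_sequences(seqs, BUILTIN_PATTERNS)
        assert ann.domains_of("has") == {"PS00178"}
        assert ann.domains_of("lacks") == frozenset()
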