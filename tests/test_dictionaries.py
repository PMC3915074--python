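"""Dictionary loading, lookup, search, links and method classification."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from simmeta import (
    build_term_index,
    classify_method,
    load_dictionary,
    lookup_term,
    resolve_link,
    search_terms,
    validate_dictionary_set,
)
from simmeta.dictionaries import PACKAGED_DICTIONARIES, matches_query
from simmeta.errors import (
    DictionaryLoadError,
    ReferentialIntegrityError,
    SchemaError,
    UsageError,
)

SIMPLE_CSV = "ID,TERM,DESCRIPTION\nA1,alpha,first letter\nB2,beta,second letter\n"


class TestLoadDictionary:
    def test_three_column_source_maps_rows_to_entries(self):
        d = load_dictionary(io.StringIO(SIMPLE_CSV), name="letters")
        assert len(d) == 2
        assert d.get("A1").term == "alpha"
        assert d.get("B2").description == "second letter"

    def test_force_field_row_carries_link_and_boolean_extra(self, dictionaries):
        entry = dictionaries["force_field"].get("MARTINI")
        assert entry.links["TYPE_ID"].target_dictionary == "force_field_type"
        assert entry.extras["IS_COARSE_GRAIN"] is True
        assert dictionaries["force_field"].get("FF99SB").extras[
            "IS_COARSE_GRAIN"] is False

    def test_duplicate_id_is_a_load_error(self):
        csv = "ID,TERM,DESCRIPTION\nA1,alpha,x\nA1,alef,y\n"
        with pytest.raises(DictionaryLoadError, match="A1"):
            load_dictionary(io.StringIO(csv), name="dup")

    def test_missing_mandatory_column_is_a_schema_error(self):
        with pytest.raises(SchemaError, match="DESCRIPTION"):
            load_dictionary(io.StringIO("ID,TERM\nA,alpha\n"), name="bad")

    def test_empty_term_is_a_load_error(self):
        csv = "ID,TERM,DESCRIPTION\nA1,,oops\n"
        with pytest.raises(DictionaryLoadError):
            load_dictionary(io.StringIO(csv), name="empty")


class TestLookup:
    def test_qmmm_term_resolves_to_hybrid_method_description(self, dictionaries):
        entry = lookup_term(dictionaries["computational_method"], "QM/MM")
        assert entry.description == ("Hybrid computational method mixing "
                                     "quantum chemistry and molecular "
                                     "mechanics")

    def test_lookup_is_case_insensitive(self, dictionaries):
        upper = lookup_term(dictionaries["computational_method"], "QM/MM")
        lower = lookup_term(dictionaries["computational_method"], "qm/mm")
        assert upper is lower

    def test_absent_term_returns_none(self, dictionaries):
        assert lookup_term(dictionaries["force_field"], "NOSUCHTERM") is None

    def test_empty_term_is_a_usage_error(self, dictionaries):
        with pytest.raises(UsageError):
            lookup_term(dictionaries["force_field"], "  ")


class TestSearch:
    def test_prefix_search_honours_max_n(self, term_index):
        results = search_terms(term_index, "AMBER FF", max_n=2)
        assert len(results) == 2
        assert all(r.term.startswith("AMBER FF") for r in results)

    def test_exact_full_term_match_ranks_first(self, term_index, dictionaries):
        for name in ("force_field", "qm_method", "thermostat"):
            for entry in dictionaries[name]:
                top = search_terms(term_index, entry.term, max_n=1)[0]
                assert top.term == entry.term

    def test_unmatched_query_returns_empty_list(self, term_index):
        assert search_terms(term_index, "zzzznope") == []

    def test_empty_query_is_a_usage_error(self, term_index):
        with pytest.raises(UsageError):
            search_terms(term_index, "   ")

    def test_rebuilding_index_gives_identical_results(self, dictionaries):
        a = build_term_index(dictionaries)
        b = build_term_index(dictionaries)
        for query in ("AMBER", "Nose", "MP2", "water", "REMD"):
            left = [(e.id, e.term) for e in search_terms(a, query, 10)]
            right = [(e.id, e.term) for e in search_terms(b, query, 10)]
            assert left == right

    @settings(deadline=None, max_examples=50)
    @given(st.text(alphabet="ambers f9QM/", min_size=1, max_size=8),
           st.integers(min_value=1, max_value=5))
    def test_results_subset_of_linear_scan(self, dictionaries, term_index,
                                           query, max_n):
        """Index search never returns anything a brute-force scan with the
        same match predicate would not."""
        if not query.strip():
            return
        scan = {(d.name, e.id) for d in dictionaries.values() for e in d
                if matches_query(e.term, query)[1]}
        results = search_terms(term_index, query, max_n)
        assert len(results) <= max_n
        got = set()
        for entry in results:
            owner = next(d.name for d in dictionaries.values()
                         if d.get(entry.id) is entry)
            got.add((owner, entry.id))
        assert got <= scan


class TestLinks:
    def test_method_class_links_to_family(self, dictionaries):
        mp = dictionaries["qm_method_class"].get("MP")
        family = resolve_link(mp, "FAMILY_ID", dictionaries)
        assert family.term == "ab initio"

    def test_dangling_link_is_an_integrity_error(self, dictionaries):
        import io
        d = load_dictionary(io.StringIO(
            "ID,TERM,DESCRIPTION,FAMILY_ID\nX,mystery,desc,NOFAM\n"),
            name="qm_method_class")
        entry = d.get("X")
        with pytest.raises(ReferentialIntegrityError, match="NOFAM"):
            resolve_link(entry, "FAMILY_ID", dictionaries)

    def test_undeclared_link_name_is_a_usage_error(self, dictionaries):
        entry = dictionaries["force_field"].get("FF99SB")
        with pytest.raises(UsageError):
            resolve_link(entry, "NOT_A_LINK", dictionaries)

    def test_packaged_set_has_full_referential_integrity(self, dictionaries):
        assert validate_dictionary_set(dictionaries) == []
        assert set(PACKAGED_DICTIONARIES) == set(dictionaries)


class TestClassifyMethod:
    @pytest.mark.parametrize("name,klass,family", [
        ("MP2", "Møller-Plesset", "ab initio"),
        ("B3LYP", "DFT", "ab initio"),
        ("AM1", "all valence electron restricted", "semi-empirical"),
        ("CCSD(T)", "Coupled-Cluster", "ab initio"),
    ])
    def test_known_methods_gain_class_and_family(self, dictionaries, name,
                                                 klass, family):
        c = classify_method(name, dictionaries)
        assert c.specific_name == name
        assert c.method_class.term == klass
        assert c.method_family.term == family

    def test_unknown_method_keeps_specific_name_only(self, dictionaries):
        c = classify_method("XYZ999", dictionaries)
        assert c.specific_name == "XYZ999"
        assert c.method is None and c.method_class is None
        assert c.method_family is None

    def test_family_present_whenever_class_is(self, dictionaries):
        for entry in dictionaries["qm_method"]:
            c = classify_method(entry.term, dictionaries)
            if c.method_class is not None:
                assert c.method_family is not None
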