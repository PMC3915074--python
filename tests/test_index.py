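"""AVU-triplet flattening, tagging, and query/linear-scan equivalence."""

import random

import pytest

from simmeta import flatten_to_triplets, query_index, tag_subject
from simmeta.errors import UsageError
from simmeta.index import AVUTriplet, TripletStore


class TestFlatten:
    def test_force_field_name_yields_derived_type_triplet(
            self, md_experiment, dictionaries):
        triplets = flatten_to_triplets(md_experiment, dictionaries)
        names = {t.value for t in triplets
                 if t.attribute == "Force field/name"}
        assert "AMBER FF99SB" in names
        derived = [t for t in triplets
                   if t.attribute == "Force field/force field type"]
        assert derived and all(t.value == "classical" and t.derived
                               for t in derived)

    def test_qm_method_yields_class_and_family_triplets(self, tmp_path,
                                                        dictionaries):
        from simmeta import assemble_directory, generate_qm_study
        manifest = generate_qm_study(tmp_path / "q", seed=2)
        triplets = flatten_to_triplets(
            assemble_directory(manifest.directory), dictionaries)
        by_attr = {t.attribute: t.value for t in triplets}
        assert by_attr["QM method/method class"] == "Møller-Plesset"
        assert by_attr["QM method/method family"] == "ab initio"

    def test_empty_experiment_yields_identity_triplets_only(self,
                                                            dictionaries):
        from simmeta.model import Experiment
        triplets = flatten_to_triplets(
            Experiment(id="e0", name="empty"), dictionaries)
        assert {(t.attribute, t.value) for t in triplets} == {
            ("Experiment/id", "e0"), ("Experiment/name", "empty")}

    def test_flattening_is_deterministic_and_idempotent(self, md_experiment,
                                                        dictionaries):
        first = flatten_to_triplets(md_experiment, dictionaries)
        second = flatten_to_triplets(md_experiment, dictionaries)
        assert first == second

    def test_units_are_copied_verbatim(self, md_experiment, dictionaries):
        triplets = flatten_to_triplets(md_experiment, dictionaries)
        units = {t.attribute: t.unit for t in triplets if t.unit}
        assert units["Simulated conditions/reference temperature"] == "K"
        assert units["MD parameter set/step length"] == "ps"


def _linear_scan(store, predicates):
    """Independent oracle: per-predicate subject sets intersected."""
    surviving = None
    for attribute, comparator, value in predicates:
        subjects = set()
        for t in store.triplets:
            if t.attribute != attribute:
                continue
            if comparator == "=" and t.value == value:
                subjects.add(t.subject)
            elif (comparator == "contains"
                  and value.lower() in t.value.lower()):
                subjects.add(t.subject)
        surviving = subjects if surviving is None else surviving & subjects
    return surviving or set()


class TestQuery:
    def test_file_format_predicate_returns_exactly_tagged_files(
            self, md_experiment, dictionaries):
        store = TripletStore(
            triplets=flatten_to_triplets(md_experiment, dictionaries))
        subjects = query_index(store, [("File/format", "=", "TRAJ")])
        expected = {t.subject for t in store.triplets
                    if t.attribute == "File/format" and t.value == "TRAJ"}
        assert set(subjects) == expected
        assert all(s.startswith("file:") for s in subjects)

    def test_conjunction_equals_intersection(self, md_experiment,
                                             dictionaries):
        store = TripletStore(
            triplets=flatten_to_triplets(md_experiment, dictionaries))
        both = query_index(store, [
            ("Force field/name", "=", "TIP3P"),
            ("Thermostat/implementation name", "contains", "e")])
        left = set(query_index(store, [("Force field/name", "=", "TIP3P")]))
        right = set(query_index(
            store, [("Thermostat/implementation name", "contains", "e")]))
        assert set(both) == left & right

    def test_unmatched_value_gives_empty_list(self, md_experiment,
                                              dictionaries):
        store = TripletStore(
            triplets=flatten_to_triplets(md_experiment, dictionaries))
        assert query_index(store, [("Force field/name", "=", "nope")]) == []

    def test_unknown_comparator_is_a_usage_error(self):
        store = TripletStore(triplets=[])
        with pytest.raises(UsageError):
            query_index(store, [("a", ">", "1")])

    def test_oracle_equivalence_on_random_stores(self):
        rng = random.Random(42)
        attributes = ["Force field/name", "File/format", "Software/name",
                      "color", "Molecule/count"]
        values = ["PDB", "TRAJ", "AMBER", "red", "blue", "3", "TIP3P"]
        for _ in range(200):
            store = TripletStore(triplets=[
                AVUTriplet(attribute=rng.choice(attributes),
                           value=rng.choice(values),
                           subject=f"s{rng.randrange(6)}")
                for _ in range(rng.randrange(1, 40))])
            predicates = [(rng.choice(attributes),
                           rng.choice(["=", "contains"]),
                           rng.choice(values))
                          for _ in range(rng.randrange(1, 4))]
            assert set(query_index(store, predicates)) == _linear_scan(
                store, predicates)


class TestTagging:
    def test_tag_then_query_returns_subject(self):
        store = TripletStore(triplets=[])
        tag_subject(store, "file:a.traj", "frames", "500")
        assert query_index(store, [("frames", "=", "500")]) == ["file:a.traj"]

    def test_lab_specific_attribute_is_accepted_and_flagged(self, catalog):
        store = TripletStore(triplets=[], catalog=catalog)
        tag_subject(store, "dir:study", "our lab protocol id", "LP-9")
        tag_subject(store, "dir:study", "Force field/name", "AMBER FF99SB")
        flags = {t.attribute: t.standard for t in store.triplets}
        assert flags["our lab protocol id"] is False
        assert flags["Force field/name"] is True

    def test_empty_attribute_is_a_usage_error(self):
        with pytest.raises(UsageError):
            tag_subject(TripletStore(triplets=[]), "s", "  ", "v")
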