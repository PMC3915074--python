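"""Natural file ordering, experiment assembly and replica grouping."""

import functools
import itertools
import random
import re

import pytest
from hypothesis import given, settings, strategies as st

from simmeta import (
    assemble_directory,
    assemble_experiment,
    generate_md_study,
    generate_remd_study,
    group_replicas,
    load_study_directory,
    order_task_files,
    validate_experiment,
)
from simmeta.errors import AssemblyError, UsageError
from simmeta.fixtures import MDStudyConfig
from simmeta.model import MDTask


# -- independent brute-force comparator (the ordering oracle) ---------------

def _tokens(name):
    return [t for t in re.split(r"(\d+)", name) if t]


def _compare_names(a, b):
    """Pairwise natural comparison written independently of the sort key:
    digit runs compare as integers (shorter spelling first on ties, digits
    before text), other segments lexicographically."""
    for ta, tb in itertools.zip_longest(_tokens(a), _tokens(b)):
        if ta is None:
            return -1
        if tb is None:
            return 1
        da, db = ta.isdigit(), tb.isdigit()
        if da and db:
            if int(ta) != int(tb):
                return -1 if int(ta) < int(tb) else 1
            if len(ta) != len(tb):
                return -1 if len(ta) < len(tb) else 1
        elif da != db:
            return -1 if da else 1
        elif ta != tb:
            return -1 if ta < tb else 1
    return 0


def brute_force_order(names):
    return sorted(names, key=functools.cmp_to_key(_compare_names))


class TestOrderTaskFiles:
    def test_two_ranks_before_ten(self):
        assert order_task_files(["10.traj", "2.traj"]) == ["2.traj", "10.traj"]

    def test_already_ordered_sequence_is_unchanged(self):
        names = ["1.traj", "2.traj", "3.traj"]
        assert order_task_files(names) == names

    def test_mixed_prefixes_and_leading_zeros(self):
        assert order_task_files(["md10.traj", "md02.traj", "md1.traj"]) == [
            "md1.traj", "md02.traj", "md10.traj"]

    def test_empty_input_is_a_usage_error(self):
        with pytest.raises(UsageError):
            order_task_files([])

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.text(alphabet="abm.traj0123456789", min_size=1,
                            max_size=12), min_size=1, max_size=8))
    def test_agrees_with_brute_force_comparator(self, names):
        assert order_task_files(names) == brute_force_order(names)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.text(alphabet="xy0123456789.", min_size=1, max_size=10),
                    min_size=1, max_size=8),
           st.randoms(use_true_random=False))
    def test_total_order_properties(self, names, rng):
        """Idempotent and permutation-invariant: any shuffle of the same
        multiset sorts to the same sequence."""
        once = order_task_files(names)
        assert order_task_files(once) == once
        shuffled = list(names)
        rng.shuffle(shuffled)
        assert order_task_files(shuffled) == once


class TestAssembleExperiment:
    def test_min_heat_prod_is_one_group_with_three_processes(
            self, md_experiment):
        assert len(md_experiment.process_groups) == 1
        group = md_experiment.process_groups[0]
        assert len(group.processes) == 3
        kinds = [p.tasks[0].task_kind for p in group.processes]
        assert kinds == ["minimization", "md", "md"]

    def test_two_copies_of_one_system_give_two_groups(self, tmp_path):
        generate_md_study(tmp_path / "s", seed=4,
                          config=MDStudyConfig(copies=2))
        experiment = assemble_directory(tmp_path / "s")
        assert len(experiment.process_groups) == 2
        assert all(len(g.processes) == 3 for g in experiment.process_groups)
        assert (experiment.process_groups[0].system
                is experiment.process_groups[1].system)

    def test_separate_subsystems_get_separate_groups(self, tmp_path):
        ligand = generate_md_study(
            tmp_path / "both", seed=5,
            config=MDStudyConfig(system_name="ligand", solute_name="LIG",
                                 stages=("minimization",), n_traj=0))
        receptor = generate_md_study(
            tmp_path / "rec", seed=6,
            config=MDStudyConfig(system_name="receptor", solute_name="REC",
                                 stages=("minimization",), n_traj=0))
        experiment = assemble_experiment(
            [ligand.system, receptor.system],
            ligand.records + receptor.records)
        assert len(experiment.process_groups) == 2
        systems = {g.system.name for g in experiment.process_groups}
        assert systems == {"ligand", "receptor"}

    def test_unresolvable_system_is_an_assembly_error(self, tmp_path):
        manifest = generate_md_study(tmp_path / "s", seed=7)
        other = generate_md_study(
            tmp_path / "o", seed=8,
            config=MDStudyConfig(system_name="unrelated"))
        with pytest.raises(AssemblyError, match="unrelated"):
            assemble_experiment([manifest.system], other.records)

    def test_assembled_experiment_always_validates(self, tmp_path):
        for seed in (11, 12):
            manifest = generate_md_study(tmp_path / f"s{seed}", seed=seed)
            experiment = assemble_directory(manifest.directory)
            assert validate_experiment(experiment).valid

    def test_no_task_lost_or_duplicated(self, tmp_path):
        manifest = generate_md_study(tmp_path / "s", seed=13,
                                     config=MDStudyConfig(copies=3))
        experiment = assemble_directory(manifest.directory)
        task_ids = [t.id for t in experiment.all_tasks()]
        assert len(task_ids) == len(manifest.records)
        assert len(set(task_ids)) == len(task_ids)

    def test_trajectory_segments_attach_in_natural_order(self, md_manifest,
                                                         md_experiment):
        md_tasks = [t for t in md_experiment.all_tasks()
                    if isinstance(t, MDTask)]
        traj = [f.uid for f in md_tasks[-1].files if f.format == "TRAJ"]
        assert traj == md_manifest.traj_order
        assert traj.index("2.traj") < traj.index("10.traj")


class TestGroupReplicas:
    def test_four_replicas_single_process(self, tmp_path):
        manifest = generate_remd_study(tmp_path / "r", seed=1, n_replicas=4)
        experiment = assemble_directory(manifest.directory)
        processes = [p for g in experiment.process_groups
                     for p in g.processes]
        assert len(processes) == 1 and len(processes[0].tasks) == 4

    def test_four_replicas_per_replica(self, tmp_path):
        manifest = generate_remd_study(tmp_path / "r", seed=1, n_replicas=4)
        experiment = assemble_directory(manifest.directory,
                                        replica_mode="per_replica")
        processes = [p for g in experiment.process_groups
                     for p in g.processes]
        assert [len(p.tasks) for p in processes] == [1, 1, 1, 1]
        assert validate_experiment(experiment).valid

    def test_single_replica_modes_coincide(self, tmp_path):
        manifest = generate_remd_study(tmp_path / "r1", seed=2, n_replicas=1)
        single = group_replicas(
            [t for t in assemble_directory(manifest.directory).all_tasks()],
            "single_process")
        per = group_replicas(
            [t for t in assemble_directory(manifest.directory).all_tasks()],
            "per_replica")
        assert len(single) == len(per) == 1
        assert [t.id for t in single[0].tasks] == [t.id for t in per[0].tasks]

    def test_empty_task_list_is_a_usage_error(self):
        with pytest.raises(UsageError):
            group_replicas([], "single_process")


def test_generator_parser_recovery_matrix(tmp_path):
    """Random seeds and configs: parse + assemble reproduces the manifest."""
    rng = random.Random(0)
    for case in range(6):
        seed = rng.randrange(1, 10_000)
        config = MDStudyConfig(
            stages=rng.choice([("minimization",),
                               ("minimization", "production"),
                               ("minimization", "heating", "production")]),
            explicit_water=rng.choice([True, False]),
            copies=rng.choice([1, 2]),
            chain_length=rng.randrange(4, 20),
        )
        manifest = generate_md_study(tmp_path / f"case{case}", seed=seed,
                                     config=config)
        systems, records, _ = load_study_directory(manifest.directory)
        assert systems == [manifest.system]
        assert records == manifest.records
        experiment = assemble_directory(manifest.directory)
        assert len(experiment.process_groups) == manifest.n_process_groups
        assert sum(len(g.processes) for g in experiment.process_groups) \
            == manifest.n_processes
        assert validate_experiment(experiment).valid
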