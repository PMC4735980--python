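import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ardrakit import (
    BandPattern,
    NucleotideSequence,
    RestrictionEnzyme,
    RestrictionMap,
    TaxonEntry,
    ValidationError,
    create_scheme,
    export_dot,
    identify,
    load_scheme,
    partition_group,
    save_scheme,
    select_enzyme,
)
from conftest import random_restriction_map


def bp(*lengths):
    return BandPattern(tuple(lengths))


def make_map(cells, merge_delta=10):
    """cells: {entry: {enzyme: BandPattern}} -> RestrictionMap."""
    entry_ids = sorted(cells)
    enzyme_names = sorted(next(iter(cells.values())))
    entries = tuple(
        TaxonEntry(e, (e,), (NucleotideSequence(f"{e}/c", "ACGTACGT"),))
        for e in entry_ids)
    pool = tuple(RestrictionEnzyme(z, "AACGTT", 2) for z in enzyme_names)
    patterns = {(e, z): cells[e][z] for e in entry_ids for z in enzyme_names}
    return RestrictionMap(entries, pool, patterns, merge_delta=merge_delta)


@pytest.fixture()
def worked_map():
    """Five strains; the greedy picks Z1 (3 classes), then Z2, then Z3.

    Strain s3's traversal observes 3 fragments under the root enzyme, 2
    under the next, then a unique class — the classic three-digest walk.
    """
    return make_map({
        "s3": {"Z1": bp(300, 200, 100), "Z2": bp(600, 100), "Z3": bp(900, 700, 500, 300, 100)},
        "s2": {"Z1": bp(310, 210, 110), "Z2": bp(610, 110), "Z3": bp(910, 710, 510, 310, 110, 50)},
        "s4": {"Z1": bp(320, 220, 120), "Z2": bp(620, 420, 120), "Z3": bp(920, 720, 520, 320, 120)},
        "s1": {"Z1": bp(400, 300, 200, 100), "Z2": bp(630, 130), "Z3": bp(930, 730, 530, 330, 130)},
        "s5": {"Z1": bp(700, 600, 500, 400, 300, 200, 90), "Z2": bp(640, 140), "Z3": bp(940, 740, 540, 340, 140)},
    })


class TestPartitionGroup:
    def test_count_classes(self, worked_map):
        parts = partition_group(["s1", "s2", "s3", "s4", "s5"], "Z1",
                                worked_map, "count_only")
        by_count = {k.count: set(v) for k, v in parts.items()}
        assert by_count == {3: {"s2", "s3", "s4"}, 4: {"s1"}, 7: {"s5"}}

    def test_no_discrimination_single_class(self, worked_map):
        parts = partition_group(["s1", "s2", "s3"], "Z2", worked_map,
                                "count_only")
        assert len(parts) == 1

    def test_two_factor_splits_equal_counts_by_length(self):
        rmap = make_map({
            "a": {"Z": bp(500, 300)},
            "b": {"Z": bp(500, 260)},
        })
        assert len(partition_group(["a", "b"], "Z", rmap, "count_only")) == 1
        parts = partition_group(["a", "b"], "Z", rmap, "count_and_length")
        assert len(parts) == 2

    def test_two_factor_tolerates_comigrating_lengths(self):
        rmap = make_map({
            "a": {"Z": bp(500, 300)},
            "b": {"Z": bp(505, 296)},
        })
        parts = partition_group(["a", "b"], "Z", rmap, "count_and_length")
        assert len(parts) == 1

    def test_unknown_enzyme_raises(self, worked_map):
        with pytest.raises(KeyError):
            partition_group(["s1"], "nope", worked_map, "count_only")


class TestSelectEnzyme:
    def test_picks_most_discriminative(self, worked_map):
        name, n = select_enzyme(["s1", "s2", "s3", "s4", "s5"], worked_map,
                                "count_only")
        assert (name, n) == ("Z1", 3)

    def test_perfectly_discriminating_enzyme_wins(self):
        cells = {f"e{i}": {"E1": bp(500), "E2": bp(*range(900, 900 - 100 * (i + 1), -100))}
                 for i in range(4)}
        rmap = make_map(cells)
        name, n = select_enzyme(sorted(cells), rmap, "count_only")
        assert (name, n) == ("E2", 4)

    def test_used_enzymes_excluded(self, worked_map):
        name, _ = select_enzyme(["s2", "s3", "s4"], worked_map, "count_only",
                                used_on_path={"Z1", "Z2"})
        assert name == "Z3"

    def test_returns_none_when_nothing_splits(self):
        rmap = make_map({"a": {"Z": bp(500, 300)}, "b": {"Z": bp(500, 300)}})
        assert select_enzyme(["a", "b"], rmap, "count_only") == (None, 1)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10**6))
    def test_greedy_equals_exhaustive_argmax(self, seed):
        rng = random.Random(seed)
        rmap = random_restriction_map(rng, n_entries=8, n_enzymes=5)
        group = rmap.entry_ids
        for mode in ("count_only", "count_and_length"):
            # independent exhaustive search over the pool
            scored = []
            for z in rmap.enzyme_names:
                n = len(partition_group(group, z, rmap, mode))
                scored.append((-n, z))
            best_n, best_name = -min(scored)[0], min(scored)[1]
            got_name, got_n = select_enzyme(group, rmap, mode)
            if best_n == 1:
                assert (got_name, got_n) == (None, 1)
            else:
                assert (got_name, got_n) == (best_name, best_n)


def walk_nodes(node):
    yield node
    for child in node.children.values():
        yield from walk_nodes(child)


class TestCreateScheme:
    def test_perfect_enzyme_gives_depth_one_tree(self):
        cells = {f"e{i}": {"E1": bp(500),
                           "E2": bp(*range(900, 900 - 100 * (i + 1), -100))}
                 for i in range(4)}
        scheme = create_scheme(make_map(cells))
        assert scheme.enzymes_used == ("E2",)
        assert scheme.max_path == scheme.min_path == 1
        assert all(c.leaf_status == "identified"
                   for c in scheme.root.children.values())

    def test_identical_entries_become_indistinguishable_leaf(self):
        rmap = make_map({
            "twinA": {"Z": bp(500, 300)}, "twinB": {"Z": bp(500, 300)},
            "other": {"Z": bp(800)},
        })
        scheme = create_scheme(rmap)
        leaves = [n for n in walk_nodes(scheme.root) if n.is_leaf]
        indist = next(n for n in leaves if n.leaf_status == "indistinguishable")
        assert set(indist.group) == {"twinA", "twinB"}

    def test_children_partition_parent_everywhere(self):
        rng = random.Random(1234)
        for _ in range(10):
            rmap = random_restriction_map(rng)
            for mode in ("count_only", "count_and_length"):
                scheme = create_scheme(rmap, mode=mode)
                for node in walk_nodes(scheme.root):
                    if node.is_leaf:
                        continue
                    child_union = sorted(
                        e for c in node.children.values() for e in c.group)
                    assert child_union == sorted(node.group)

    def test_no_enzyme_repeats_on_any_path(self):
        rng = random.Random(99)
        for _ in range(10):
            rmap = random_restriction_map(rng)
            scheme = create_scheme(rmap)

            def check(node, seen):
                if node.is_leaf:
                    return
                assert node.enzyme not in seen
                for child in node.children.values():
                    check(child, seen | {node.enzyme})

            check(scheme.root, frozenset())
            assert scheme.max_path <= len(scheme.enzyme_pool)

    def test_deterministic_serialization(self, tmp_path):
        rng = random.Random(7)
        rmap = random_restriction_map(rng)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_scheme(create_scheme(rmap), p1)
        save_scheme(create_scheme(rmap), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_invalid_mode_rejected(self, worked_map):
        with pytest.raises(ValidationError):
            create_scheme(worked_map, mode="bands_only")


class TestIdentify:
    def test_three_step_walk_identifies_strain(self, worked_map):
        scheme = create_scheme(worked_map)
        provider = {z: worked_map.pattern("s3", z)
                    for z in worked_map.enzyme_names}
        result = identify(scheme, provider)
        assert result.status == "identified"
        assert result.members == ("s3",)
        assert [step[0] for step in result.path] == ["Z1", "Z2", "Z3"]
        assert [step[1] for step in result.path][:2] == ["3", "2"]

    def test_out_of_family_query_fails(self, worked_map):
        scheme = create_scheme(worked_map)
        provider = {z: bp(990, 880, 770, 660, 550, 440, 330, 220, 110)
                    for z in worked_map.enzyme_names}
        result = identify(scheme, provider)
        assert result.status == "failed"
        assert result.members == ()

    def test_missing_enzyme_named_in_error(self, worked_map):
        scheme = create_scheme(worked_map)
        with pytest.raises(KeyError, match="Z1"):
            identify(scheme, {})

    def test_indistinguishable_set_reported(self):
        rmap = make_map({
            "twinA": {"Z": bp(500, 300)}, "twinB": {"Z": bp(500, 300)},
            "other": {"Z": bp(800)},
        })
        scheme = create_scheme(rmap)
        result = identify(scheme, {"Z": bp(500, 300)})
        assert result.status == "indistinguishable_set"
        assert set(result.members) == {"twinA", "twinB"}

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10**6))
    def test_every_entry_identifies_as_itself(self, seed):
        rng = random.Random(seed)
        rmap = random_restriction_map(rng, n_entries=rng.randint(2, 10),
                                      n_enzymes=rng.randint(2, 5))
        for mode in ("count_only", "count_and_length"):
            scheme = create_scheme(rmap, mode=mode)
            for entry in rmap.entries:
                provider = {z: rmap.pattern(entry.entry_id, z)
                            for z in rmap.enzyme_names}
                result = identify(scheme, provider)
                if result.status == "identified":
                    assert result.members == entry.member_names
                else:
                    assert result.status == "indistinguishable_set"
                    assert set(entry.member_names) <= set(result.members)


class TestSerialization:
    def test_save_load_identity_on_three_level_scheme(self, tmp_path,
                                                      worked_map):
        scheme = create_scheme(worked_map)
        assert scheme.max_path == 3
        path = tmp_path / "scheme.json"
        save_scheme(scheme, path)
        assert load_scheme(path) == scheme

    def test_schema_invalid_json_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(ValidationError):
            load_scheme(p)
        p.write_text('{"format": "something-else", "version": 1}')
        with pytest.raises(ValidationError):
            load_scheme(p)
        p.write_text('{"format": "ardrakit-scheme", "version": 1, '
                     '"mode": "count_only"}')
        with pytest.raises(ValidationError):
            load_scheme(p)

    def test_dot_node_count_matches_tree(self, tmp_path, worked_map):
        scheme = create_scheme(worked_map)
        path = tmp_path / "scheme.dot"
        export_dot(scheme, path)
        text = path.read_text()
        n_nodes = sum(1 for _ in walk_nodes(scheme.root))
        node_lines = [ln for ln in text.splitlines()
                      if "label=" in ln and "->" not in ln and "shape=box" not in ln]
        assert len(node_lines) == n_nodes

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10**6))
    def test_random_schemes_survive_round_trip(self, tmp_path_factory, seed):
        rng = random.Random(seed)
        rmap = random_restriction_map(rng, n_entries=rng.randint(2, 8),
                                      n_enzymes=rng.randint(1, 4))
        for mode in ("count_only", "count_and_length"):
            scheme = create_scheme(rmap, mode=mode)
            path = tmp_path_factory.mktemp("schemes") / "s.json"
            save_scheme(scheme, path)
            assert load_scheme(path) == scheme
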