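"""Bond perception, species census, ring census, tracking, IDT."""

import itertools

import networkx as nx
import numpy as np
import pytest

from nanoreax.builders import miller_system
from nanoreax.fixtures import diamond_lattice, hexagonal_sheet, reaction_toy_trajectory
from nanoreax.molfind import (
    BondRules,
    CanonicalKeyer,
    count_unique_species,
    detect_bonds,
    extract_molecules,
    ignition_delay_time,
    molecular_formula,
    parse_formula,
    ring_census,
    track_species,
)
from nanoreax.system import Cell, Configuration, Trajectory


def carbon_pair(r):
    return Configuration(
        ("C", "C"), np.array([[5.0, 5, 5], [5.0 + r, 5, 5]]), Cell.cubic(20)
    )


class TestBondRules:
    def test_carbon_cutoff_is_1_72(self):
        assert BondRules().cutoff("C", "C") == pytest.approx(1.72)

    def test_boundary_behavior(self):
        bonded = detect_bonds(carbon_pair(1.71))
        assert bonded.number_of_edges() == 1
        unbonded = detect_bonds(carbon_pair(1.73))
        assert unbonded.number_of_edges() == 0

    def test_single_atom_has_no_edges(self):
        config = Configuration(("O",), np.array([[1.0, 1, 1]]), Cell.cubic(8))
        assert detect_bonds(config).number_of_edges() == 0

    def test_missing_radius_names_the_element(self):
        rules = BondRules(covalent_radii={"C": 0.85})
        config = Configuration(
            ("C", "O"), np.array([[5.0, 5, 5], [6.0, 5, 5]]), Cell.cubic(10)
        )
        with pytest.raises(KeyError, match="O"):
            detect_bonds(config, rules)

    def test_diamond_coordination_four(self):
        graph = detect_bonds(diamond_lattice(3.567, (2, 2, 2)))
        assert set(dict(graph.degree()).values()) == {4}


def union_find_components(n, edges):
    """Independent disjoint-set oracle."""
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(map(frozenset, groups.values()), key=min)


class TestExtractMolecules:
    def test_edgeless_graph_gives_singletons(self):
        g = nx.Graph()
        for i in range(7):
            g.add_node(i, element="C")
        assert sorted(map(min, extract_molecules(g))) == list(range(7))

    def test_packed_miller_box_has_72_molecules(self, miller_box):
        comps = extract_molecules(detect_bonds(miller_box))
        assert len(comps) == 72
        oracle = union_find_components(
            miller_box.n_atoms, detect_bonds(miller_box).edges()
        )
        assert sorted(map(frozenset, comps), key=min) == oracle

    def test_random_graphs_match_union_find(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            n = int(rng.integers(2, 50))
            g = nx.gnp_random_graph(n, 0.08, seed=int(rng.integers(1 << 30)))
            for i in g.nodes:
                g.nodes[i]["element"] = "C"
            assert sorted(map(frozenset, extract_molecules(g)), key=min) == (
                union_find_components(n, g.edges())
            )


def brute_force_isomorphic(g1, g2):
    """Exhaustive permutation matcher (independent of the implementation)."""
    n = g1.number_of_nodes()
    if n != g2.number_of_nodes() or g1.number_of_edges() != g2.number_of_edges():
        return False
    nodes1 = list(g1.nodes)
    nodes2 = list(g2.nodes)
    lab1 = [g1.nodes[v]["element"] for v in nodes1]
    lab2 = [g2.nodes[v]["element"] for v in nodes2]
    if sorted(lab1) != sorted(lab2):
        return False
    e1 = {frozenset((nodes1.index(a), nodes1.index(b))) for a, b in g1.edges}
    for perm in itertools.permutations(range(n)):
        if any(lab1[i] != lab2[perm[i]] for i in range(n)):
            continue
        mapped = {
            frozenset((perm[i], perm[j])) for i, j in e1
        }
        target = {
            frozenset((nodes2.index(a), nodes2.index(b))) for a, b in g2.edges
        }
        if mapped == target:
            return True
    return False


def random_labeled_graph(rng, max_nodes=9):
    n = int(rng.integers(2, max_nodes + 1))
    g = nx.gnp_random_graph(n, float(rng.uniform(0.15, 0.5)),
                            seed=int(rng.integers(1 << 30)))
    for i in g.nodes:
        g.nodes[i]["element"] = ("C", "H")[int(rng.integers(2))]
    return g


class TestCanonicalKeys:
    def test_relabeling_preserves_key(self):
        keyer = CanonicalKeyer()
        g = nx.path_graph(5)
        labels = ["C", "H", "O", "H", "C"]
        for i, lab in enumerate(labels):
            g.nodes[i]["element"] = lab
        perm = [3, 0, 4, 1, 2]
        h = nx.relabel_nodes(g, dict(zip(g.nodes, perm)))
        assert keyer.key(g) == keyer.key(h)

    def test_constitutional_isomers_get_distinct_keys(self):
        """Ethanol-like vs dimethyl-ether-like C2H6O topologies differ."""

        def molecule(edges, labels):
            g = nx.Graph()
            for i, lab in enumerate(labels):
                g.add_node(i, element=lab)
            g.add_edges_from(edges)
            return g

        labels = ["C", "C", "O"] + ["H"] * 6
        ethanol = molecule(
            [(0, 1), (1, 2), (0, 3), (0, 4), (0, 5), (1, 6), (1, 7), (2, 8)], labels
        )
        ether = molecule(
            [(0, 2), (1, 2), (0, 3), (0, 4), (0, 5), (1, 6), (1, 7), (1, 8)], labels
        )
        keyer = CanonicalKeyer()
        assert keyer.key(ethanol) != keyer.key(ether)
        assert brute_force_isomorphic(ethanol, ether) is False

    def test_exhaustive_small_graphs_vs_brute_force(self):
        """All connected atlas graphs up to 6 nodes (sampled 2-element
        labelings): key equality must coincide exactly with brute-force
        isomorphism."""
        from networkx.generators.atlas import graph_atlas_g

        rng = np.random.default_rng(5)
        labeled = []
        for g in graph_atlas_g()[1:]:
            n = g.number_of_nodes()
            if n == 0 or n > 6 or not nx.is_connected(g):
                continue
            if n <= 4:
                labelings = list(itertools.product("CH", repeat=n))
            else:
                labelings = [
                    tuple("CH"[int(b)] for b in rng.integers(0, 2, n))
                    for _ in range(4)
                ]
            for labels in labelings:
                h = g.copy()
                for i, lab in zip(h.nodes, labels):
                    h.nodes[i]["element"] = lab
                labeled.append(h)
        keyer = CanonicalKeyer()
        keys = [keyer.key(g) for g in labeled]
        # compare within buckets of equal (n, m, label multiset): outside a
        # bucket graphs are trivially non-isomorphic and keys embed formula
        buckets = {}
        for g, key in zip(labeled, keys):
            sig = (
                g.number_of_nodes(),
                g.number_of_edges(),
                tuple(sorted(d["element"] for _, d in g.nodes(data=True))),
                tuple(sorted(dict(g.degree()).values())),
            )
            buckets.setdefault(sig, []).append((g, key))
        checked = 0
        for members in buckets.values():
            for (g1, k1), (g2, k2) in itertools.combinations(members, 2):
                assert (k1 == k2) == brute_force_isomorphic(g1, g2)
                checked += 1
        assert checked > 500

    def test_random_graphs_vs_brute_force(self):
        rng = np.random.default_rng(9)
        graphs = [random_labeled_graph(rng) for _ in range(500)]
        keyer = CanonicalKeyer()
        keyed = [(g, keyer.key(g)) for g in graphs]
        buckets = {}
        for g, key in keyed:
            sig = (
                g.number_of_nodes(),
                g.number_of_edges(),
                tuple(sorted(d["element"] for _, d in g.nodes(data=True))),
                tuple(sorted(dict(g.degree()).values())),
            )
            buckets.setdefault(sig, []).append((g, key))
        for members in buckets.values():
            if len(members) > 12:
                members = members[:12]  # bound the quadratic comparison
            for (g1, k1), (g2, k2) in itertools.combinations(members, 2):
                assert (k1 == k2) == brute_force_isomorphic(g1, g2)


class TestSpeciesCensus:
    def test_miller_box_has_five_species(self, miller_box):
        census = count_unique_species(Trajectory([miller_box], [0.0]))
        assert sorted(r.formula for r in census) == [
            "CH4", "CO", "H2", "H2O", "H3N",
        ]
        assert sum(r.counts[0] for r in census) == 72

    def test_census_totals_partition_all_atoms(self, miller_box):
        census = count_unique_species(Trajectory([miller_box], [0.0]))
        atoms = 0
        for rec in census:
            atoms += rec.counts[0] * sum(parse_formula(rec.formula).values())
        assert atoms == miller_box.n_atoms

    def test_new_species_first_frame(self):
        traj = reaction_toy_trajectory("2H2+O2->2H2O@frame2", n_frames=5)
        census = {r.formula: r for r in count_unique_species(traj)}
        assert census["H2O"].first_frame == 2
        assert census["H2"].counts[:2] == [2, 2]
        assert census["H2"].counts[2:] == [0, 0, 0]

    def test_empty_trajectory_gives_empty_census(self):
        assert count_unique_species(Trajectory()) == []

    def test_lookup_table_annotates_names(self, miller_box):
        census = count_unique_species(
            Trajectory([miller_box], [0.0]), lookup={"H2O": "water"}
        )
        water = next(r for r in census if r.formula == "H2O")
        assert water.name == "water"


class TestRingCensus:
    def test_acyclic_graph_has_no_rings(self):
        g = nx.path_graph(10)
        for i in g.nodes:
            g.nodes[i]["element"] = "C"
        assert ring_census(g) == {3: 0, 4: 0, 5: 0, 6: 0, 7: 0}

    def test_single_hexagon(self):
        sheet = hexagonal_sheet(1)
        assert ring_census(detect_bonds(sheet))[6] == 1

    @pytest.mark.parametrize("k", [2, 4, 7])
    def test_fused_sheet_counts_every_hexagon(self, k):
        counts = ring_census(detect_bonds(hexagonal_sheet(k)))
        assert counts == {3: 0, 4: 0, 5: 0, 6: k, 7: 0}

    def test_element_filter_excludes_heteroatom_rings(self):
        g = nx.cycle_graph(6)
        for i in g.nodes:
            g.nodes[i]["element"] = "C"
        g.nodes[3]["element"] = "O"
        assert ring_census(g)[6] == 1
        assert ring_census(g, elements=("C",))[6] == 0


class TestTracking:
    def test_initial_methane_frame_counts(self):
        from nanoreax.builders import methane_combustion_system

        config = methane_combustion_system(np.random.default_rng(6))
        traj = Trajectory([config], [0.0])
        series = track_species(traj, ["CH4", "CO", "CO2", "H2O"])
        assert series["CH4"] == [20]
        assert series["CO"] == [0]
        assert series["CO2"] == [0]
        assert series["H2O"] == [0]

    def test_scripted_conversion_event(self):
        traj = reaction_toy_trajectory("CO2->CO2@frame0", n_frames=3)
        # a richer scripted event: CO + ... handled by the census test; here
        # assert the trivially-scripted species is present from frame 0
        series = track_species(traj, ["CO2"])
        assert series["CO2"] == [1, 1, 1]

    def test_unknown_target_format_rejected(self, miller_box):
        traj = Trajectory([miller_box], [0.0])
        with pytest.raises(ValueError):
            track_species(traj, ["not-a-formula!"])


class TestIgnitionDelay:
    def test_all_above_threshold_from_start(self):
        times = [0.0, 1.0, 2.0]
        s = [5, 5, 5]
        assert ignition_delay_time(times, s, s, s) == 0.0

    def test_mean_of_constructed_crossings(self):
        times = list(np.arange(0.0, 40_000.0, 1000.0))
        co = [5 if t >= 10_000 else 0 for t in times]
        co2 = [6 if t >= 20_000 else 1 for t in times]
        h2o = [9 if t >= 30_000 else 4 for t in times]
        assert ignition_delay_time(times, co, co2, h2o) == pytest.approx(20_000.0)

    def test_undefined_when_a_product_never_crosses(self):
        times = [0.0, 1.0]
        assert np.isnan(ignition_delay_time(times, [5, 5], [5, 5], [0, 1]))

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            ignition_delay_time([0.0, 1.0], [5], [5, 5], [5, 5])


class TestFormulas:
    def test_hill_ordering(self):
        assert molecular_formula(["H", "O", "H"]) == "H2O"
        assert molecular_formula(["C", "H", "H", "H", "H"]) == "CH4"
        assert molecular_formula(["N", "H", "H", "H"]) == "H3N"

    def test_parse_round_trip(self):
        assert parse_formula("C2H5NO2") == {"C": 2, "H": 5, "N": 1, "O": 2}
        assert parse_formula("CO") == {"C": 1, "O": 1}
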