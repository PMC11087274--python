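"""MolFind: reactive-trajectory analysis on molecular bond graphs.

Per frame, atoms become nodes and covalent-cutoff contacts become edges
(bonded iff the minimum-image distance is strictly below the sum of the two
covalent radii plus a small buffer — for carbon pairs the default rules
give the 1.72 Å cutoff).  On top of the bond graph this module provides

* connected-component extraction (molecules),
* canonical topology keys via label-refinement (Weisfeiler–Lehman) hashing
  backed by an exact isomorphism check to separate hash collisions,
* a species census over a trajectory,
* a ring census (minimum cycle basis, sizes 3–7 by default), and
* species time series plus the ignition-delay-time statistic.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .system import Configuration, Trajectory, neighbor_pairs

#: bump when the canonical-key construction changes: keys from different
#: versions must never be compared silently
KEY_VERSION = "wl1"

#: Default covalent radii (Å).  Carbon is 0.85 Å so that with the 0.02 Å
#: buffer the C–C bond cutoff is exactly 1.72 Å; the others follow a
#: standard covalent-radius table (hydrogen uses the classic 0.37 Å value —
#: the smaller modern 0.31 Å radius would leave the 0.74 Å H–H bond
#: unbonded) and are configurable.
DEFAULT_COVALENT_RADII = {"H": 0.37, "C": 0.85, "N": 0.71, "O": 0.66}


@dataclass(frozen=True)
class BondRules:
    """Distance rules for bond perception: cutoff(A,B) = r_A + r_B + buffer."""

    covalent_radii: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVALENT_RADII)
    )
    buffer: float = 0.02

    def __post_init__(self) -> None:
        if self.buffer < 0:
            raise ValueError("buffer must be non-negative")
        if any(r <= 0 for r in self.covalent_radii.values()):
            raise ValueError("covalent radii must be positive")

    def cutoff(self, elem_a: str, elem_b: str) -> float:
        try:
            return (
                self.covalent_radii[elem_a] + self.covalent_radii[elem_b] + self.buffer
            )
        except KeyError as exc:
            raise KeyError(f"no covalent radius for element {exc.args[0]!r}") from None

    def max_cutoff(self, elements) -> float:
        radii = []
        for e in set(elements):
            if e not in self.covalent_radii:
                raise KeyError(f"no covalent radius for element {e!r}")
            radii.append(self.covalent_radii[e])
        return 2 * max(radii) + self.buffer if radii else 0.0


def detect_bonds(
    config: Configuration, rules: BondRules | None = None
) -> nx.Graph:
    """Bond graph of a configuration: nodes carry ``element``, edges carry
    ``distance`` (Å).  Bonded iff minimum-image distance < cutoff(A, B),
    strictly."""
    rules = rules or BondRules()
    graph = nx.Graph()
    for i, elem in enumerate(config.species):
        graph.add_node(i, element=elem)
    if config.n_atoms < 2:
        return graph
    rmax = rules.max_cutoff(config.species)
    pairs = neighbor_pairs(config, rmax, allow_multi_image=True)
    for i, j, dist in pairs:
        if dist < rules.cutoff(config.species[i], config.species[j]):
            graph.add_edge(i, j, distance=dist)
    return graph


def extract_molecules(graph: nx.Graph) -> list[set[int]]:
    """Maximal connected components (each a set of atom indices)."""
    return [set(c) for c in nx.connected_components(graph)]


def molecular_formula(elements) -> str:
    """Hill-convention formula string: C, then H, then other elements
    alphabetically."""
    counts = Counter(elements)
    parts = []
    for elem in ("C", "H"):
        if counts.get(elem):
            n = counts.pop(elem)
            parts.append(elem + (str(n) if n > 1 else ""))
    for elem in sorted(counts):
        n = counts[elem]
        parts.append(elem + (str(n) if n > 1 else ""))
    return "".join(parts)


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """'C2H5NO2' → {'C': 2, 'H': 5, 'N': 1, 'O': 2}."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        if not m.group(1):
            break
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def _wl_hash(graph: nx.Graph) -> str:
    return nx.weisfeiler_lehman_graph_hash(
        graph, node_attr="element", iterations=3, digest_size=8
    )


def _isomorphic(g1: nx.Graph, g2: nx.Graph) -> bool:
    return nx.is_isomorphic(
        g1, g2, node_match=lambda a, b: a["element"] == b["element"]
    )


class CanonicalKeyer:
    """Canonical topology keys: equal keys ⇔ isomorphic element-labeled graphs.

    Keys are ``<version>:<formula>:<WL-hash>`` from label-refinement
    (Weisfeiler–Lehman) hashing; graphs that collide in the hash but are
    not isomorphic (checked exactly) get a ``#k`` disambiguation suffix.
    The keyer carries the collision registry, so key comparisons are valid
    within one keyer (one census run).
    """

    def __init__(self) -> None:
        self._registry: dict[str, list[nx.Graph]] = defaultdict(list)

    def key(self, component: nx.Graph) -> str:
        if component.number_of_nodes() == 0:
            raise ValueError("empty component has no key")
        formula = molecular_formula(
            data["element"] for _, data in component.nodes(data=True)
        )
        base = f"{KEY_VERSION}:{formula}:{_wl_hash(component)}"
        bucket = self._registry[base]
        for idx, rep in enumerate(bucket):
            if _isomorphic(component, rep):
                return base if idx == 0 else f"{base}#{idx}"
        bucket.append(component.copy())
        idx = len(bucket) - 1
        return base if idx == 0 else f"{base}#{idx}"


def canonical_key(component: nx.Graph, keyer: CanonicalKeyer | None = None) -> str:
    """Key of one molecular graph (uses a throwaway keyer when none given)."""
    keyer = keyer or CanonicalKeyer()
    return keyer.key(component)


@dataclass
class SpeciesRecord:
    """Census entry for one topologically distinct species."""

    formula: str
    key: str
    counts: list[int]  # per frame
    first_frame: int
    last_frame: int
    name: str | None = None

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def max_count(self) -> int:
        return max(self.counts) if self.counts else 0


def _frame_components(
    config: Configuration, rules: BondRules
) -> list[nx.Graph]:
    graph = detect_bonds(config, rules)
    return [graph.subgraph(c).copy() for c in nx.connected_components(graph)]


def count_unique_species(
    trajectory: Trajectory,
    rules: BondRules | None = None,
    lookup: dict[str, str] | None = None,
) -> list[SpeciesRecord]:
    """Census of topologically distinct species across all frames.

    ``lookup`` optionally maps canonical keys (or formulas, as a fallback)
    to human-readable names — the local stand-in for a molecule-name
    database.  Records are ordered by first appearance, then formula.
    """
    rules = rules or BondRules()
    keyer = CanonicalKeyer()
    records: dict[str, SpeciesRecord] = {}
    n_frames = len(trajectory)
    for f, frame in enumerate(trajectory.frames):
        frame_counts: Counter[str] = Counter()
        formulas: dict[str, str] = {}
        for comp in _frame_components(frame, rules):
            key = keyer.key(comp)
            frame_counts[key] += 1
            formulas[key] = molecular_formula(
                d["element"] for _, d in comp.nodes(data=True)
            )
        for key, count in frame_counts.items():
            if key not in records:
                records[key] = SpeciesRecord(
                    formula=formulas[key],
                    key=key,
                    counts=[0] * n_frames,
                    first_frame=f,
                    last_frame=f,
                )
            rec = records[key]
            rec.counts[f] = count
            rec.last_frame = f
    out = sorted(records.values(), key=lambda r: (r.first_frame, r.formula))
    if lookup:
        for rec in out:
            rec.name = lookup.get(rec.key) or lookup.get(rec.formula)
    return out


def ring_census(
    graph: nx.Graph,
    sizes: tuple[int, ...] = (3, 4, 5, 6, 7),
    elements: tuple[str, ...] | None = None,
) -> dict[int, int]:
    """Ring counts by size from a minimum cycle basis.

    Rings are independent cycles of the (optionally element-filtered)
    subgraph, perceived per connected component via a minimum cycle basis;
    only the requested sizes are tallied.  ``elements=("C",)`` restricts
    the census to carbon rings (graphene-style analyses).
    """
    if elements is not None:
        keep = [n for n, d in graph.nodes(data=True) if d["element"] in elements]
        graph = graph.subgraph(keep)
    counts = {s: 0 for s in sizes}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if sub.number_of_edges() < sub.number_of_nodes():
            continue  # acyclic component
        for cycle in nx.minimum_cycle_basis(sub):
            if len(cycle) in counts:
                counts[len(cycle)] += 1
    return counts


def track_species(
    trajectory: Trajectory,
    targets: list[str],
    rules: BondRules | None = None,
) -> dict[str, list[int]]:
    """Per-frame molecule counts for each target.

    A target starting with the key version prefix (e.g. ``wl1:``) matches
    on topology; anything else is parsed as a molecular formula and matches
    on composition.
    """
    rules = rules or BondRules()
    formula_targets: dict[str, dict[str, int]] = {}
    key_targets: list[str] = []
    for t in targets:
        if t.startswith(f"{KEY_VERSION}:"):
            key_targets.append(t)
        else:
            formula_targets[t] = parse_formula(t)  # raises on bad targets
    series: dict[str, list[int]] = {t: [] for t in targets}
    keyer = CanonicalKeyer()
    for frame in trajectory.frames:
        frame_formula: Counter[str] = Counter()
        frame_keys: Counter[str] = Counter()
        for comp in _frame_components(frame, rules):
            elems = [d["element"] for _, d in comp.nodes(data=True)]
            frame_formula[molecular_formula(elems)] += 1
            if key_targets:
                frame_keys[keyer.key(comp)] += 1
        for t, want in formula_targets.items():
            canonical = molecular_formula(
                e for e, n in want.items() for _ in range(n)
            )
            series[t].append(frame_formula.get(canonical, 0))
        for t in key_targets:
            series[t].append(frame_keys.get(t, 0))
    return series


#: Sentinel for "never ignited".
IDT_UNDEFINED = float("nan")


def ignition_delay_time(
    times: list[float],
    co_series: list[int],
    co2_series: list[int],
    h2o_series: list[int],
    threshold: int = 5,
) -> float:
    """Ignition delay time: mean first time each of CO, CO2, H2O reaches
    ``threshold`` molecules.

    All three series must share the trajectory's time grid.  Returns NaN if
    any species never reaches the threshold (no ignition within the
    trajectory).
    """
    series = (co_series, co2_series, h2o_series)
    if any(len(s) != len(times) for s in series):
        raise ValueError("series and time grid lengths differ")
    crossings = []
    for s in series:
        hit = next((times[i] for i, v in enumerate(s) if v >= threshold), None)
        if hit is None:
            return IDT_UNDEFINED
        crossings.append(hit)
    return float(np.mean(crossings))


def ignition_delay_from_trajectory(
    trajectory: Trajectory,
    rules: BondRules | None = None,
    threshold: int = 5,
) -> float:
    """Convenience wrapper: track CO/CO2/H2O and compute the IDT."""
    series = track_species(trajectory, ["CO", "CO2", "H2O"], rules)
    return ignition_delay_time(
        trajectory.times, series["CO"], series["CO2"], series["H2O"], threshold
    )


def mean_ignition_delay(idts: list[float]) -> float:
    """Replicate-mean IDT helper: averages defined IDTs over trajectories;
    NaN if none are defined."""
    vals = [t for t in idts if not np.isnan(t)]
    return float(np.mean(vals)) if vals else IDT_UNDEFINED
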