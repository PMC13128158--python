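"""Signed causal-loop diagrams and feedback-loop classification.

A causal loop diagram (CLD) is a directed graph whose links carry a
polarity: ``+1`` when the target moves in the same direction as the source,
``-1`` when it moves opposite. A feedback loop is a simple directed cycle;
its character is the product of its link polarities — positive products are
*reinforcing* loops (amplifying change), negative products are *balancing*
loops (goal-seeking).

The module ships the canonical workshop diagram for readmission-score
adoption (:func:`workshop_cld`): a CMS-penalty-driven institutional response
feeding training and individual interest, with internal reinforcement
through perceived evidence of avoided readmissions and team use on rounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import networkx as nx

__all__ = [
    "CausalLink",
    "CLDGraph",
    "LoopRecord",
    "build_cld",
    "workshop_cld",
    "enumerate_loops",
    "name_loops",
    "export_dot",
]

BALANCING = "balancing"
REINFORCING = "reinforcing"


@dataclass(frozen=True)
class CausalLink:
    """One signed arrow of a causal loop diagram."""

    source: str
    target: str
    polarity: int

    def __post_init__(self) -> None:
        if self.polarity not in (+1, -1):
            raise ValueError(
                f"link {self.source!r}->{self.target!r}: polarity must be +1 or -1, "
                f"got {self.polarity!r}"
            )
        if self.source == self.target:
            raise ValueError(f"self-loop on {self.source!r} is not allowed")


@dataclass(frozen=True)
class CLDGraph:
    """A causal loop diagram: ordered variables plus signed links.

    Variables are kept in first-appearance order so that serialization and
    DOT export are deterministic. At most one link may connect any ordered
    (source, target) pair.
    """

    variables: tuple[str, ...]
    links: tuple[CausalLink, ...]

    def __post_init__(self) -> None:
        declared = set(self.variables)
        seen: set[tuple[str, str]] = set()
        for link in self.links:
            if link.source not in declared or link.target not in declared:
                raise ValueError(
                    f"link {link.source!r}->{link.target!r} references an undeclared variable"
                )
            pair = (link.source, link.target)
            if pair in seen:
                raise ValueError(f"duplicate link {pair[0]!r}->{pair[1]!r}")
            seen.add(pair)

    def to_networkx(self) -> nx.DiGraph:
        """Return the diagram as a :class:`networkx.DiGraph` with a ``polarity`` edge attribute."""
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        for link in self.links:
            g.add_edge(link.source, link.target, polarity=link.polarity)
        return g

    def to_json(self) -> str:
        """Serialize to a JSON object with ``variables`` and ``links`` arrays."""
        return json.dumps(
            {
                "variables": list(self.variables),
                "links": [
                    {"source": l.source, "target": l.target, "polarity": l.polarity}
                    for l in self.links
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CLDGraph":
        data = json.loads(text)
        graph = build_cld(
            [(l["source"], l["target"], int(l["polarity"])) for l in data["links"]]
        )
        declared = tuple(data.get("variables", graph.variables))
        if set(declared) < set(graph.variables):
            raise ValueError("JSON variables array omits a link endpoint")
        return cls(variables=declared, links=graph.links)


@dataclass(frozen=True)
class LoopRecord:
    """A classified feedback loop.

    ``cycle`` is the simple directed cycle, rotated to start at the
    lexicographically smallest member (the first element is implicitly
    repeated at the end). ``classification`` is *reinforcing* iff the
    product of link polarities is +1, *balancing* iff it is -1.
    """

    cycle: tuple[str, ...]
    polarity_product: int
    classification: str
    name: str | None = field(default=None)

    def __post_init__(self) -> None:
        expected = REINFORCING if self.polarity_product == +1 else BALANCING
        if self.classification != expected:
            raise ValueError(
                f"classification {self.classification!r} inconsistent with "
                f"polarity product {self.polarity_product}"
            )

    def __len__(self) -> int:
        return len(self.cycle)


def build_cld(links: list[tuple[str, str, int]]) -> CLDGraph:
    """Build a :class:`CLDGraph` from ``(source, target, sign)`` triples.

    Declared variables are the union of endpoints in first-appearance
    order. Duplicate ordered pairs and signs outside {+1, -1} are rejected.
    """
    variables: list[str] = []
    seen_vars: set[str] = set()
    link_objs: list[CausalLink] = []
    for source, target, sign in links:
        link_objs.append(CausalLink(source, target, sign))
        for v in (source, target):
            if v not in seen_vars:
                seen_vars.add(v)
                variables.append(v)
    return CLDGraph(variables=tuple(variables), links=tuple(link_objs))


#: signed links of the workshop diagram; the single negative arrow is the
#: effect of avoided readmissions on the readmission rate.
_WORKSHOP_LINKS: list[tuple[str, str, int]] = [
    ("ReadmissionRate", "CMSPenalty", +1),
    ("CMSPenalty", "InstitutionalInterest", +1),
    ("InstitutionalInterest", "IndividualInterest", +1),
    ("IndividualInterest", "ScoreUse", +1),
    ("ScoreUse", "AvoidedReadmissions", +1),
    ("AvoidedReadmissions", "ReadmissionRate", -1),
    ("InstitutionalInterest", "Training", +1),
    ("Training", "TrainedIndividuals", +1),
    ("TrainedIndividuals", "ScoreUse", +1),
    ("AvoidedReadmissions", "PerceivedEvidence", +1),
    ("PerceivedEvidence", "IndividualInterest", +1),
    ("ScoreUse", "UseOnRounds", +1),
    ("UseOnRounds", "InternalPressure", +1),
    ("InternalPressure", "Training", +1),
]


def workshop_cld() -> CLDGraph:
    """The canonical workshop causal loop diagram for readmission-score adoption.

    Eleven variables and fourteen signed links encoding the two balancing
    loops (institutional incentives, training) and the two reinforcing
    loops (individual motivation through perceived evidence, team use on
    rounds). This encoding is a reconstruction: it is the minimal link set
    consistent with the four named loops.
    """
    return build_cld(_WORKSHOP_LINKS)


def _canonicalize(cycle: list[str]) -> tuple[str, ...]:
    # rotate so the lexicographically smallest variable comes first
    i = cycle.index(min(cycle))
    return tuple(cycle[i:] + cycle[:i])


def enumerate_loops(graph: CLDGraph) -> list[LoopRecord]:
    """Enumerate all simple directed cycles of ``graph`` as classified loops.

    Cycles are canonicalized (rotation starting at the smallest variable)
    and returned sorted by the canonical cycle tuple, so the order is
    deterministic. An acyclic graph yields an empty list.
    """
    g = graph.to_networkx()
    sign = {(l.source, l.target): l.polarity for l in graph.links}
    records = []
    for cycle in nx.simple_cycles(g):
        canon = _canonicalize(list(cycle))
        product = 1
        for a, b in zip(canon, canon[1:] + canon[:1]):
            product *= sign[(a, b)]
        records.append(
            LoopRecord(
                cycle=canon,
                polarity_product=product,
                classification=REINFORCING if product == +1 else BALANCING,
            )
        )
    records.sort(key=lambda r: r.cycle)
    return records


# membership rules mapping loops of the workshop diagram to their names;
# checked in order, first match wins
_NAME_RULES: list[tuple[str, frozenset[str], frozenset[str]]] = [
    ("Training", frozenset({"Training", "CMSPenalty"}), frozenset()),
    ("Institutional Incentives", frozenset({"CMSPenalty"}), frozenset({"Training"})),
    ("Individual Motivation", frozenset({"PerceivedEvidence"}), frozenset()),
    ("Team Use", frozenset({"InternalPressure"}), frozenset()),
]


def name_loops(loops: list[LoopRecord]) -> list[LoopRecord]:
    """Attach the workshop loop names by membership tests.

    A loop through both ``Training`` and ``CMSPenalty`` is the "Training"
    loop; through ``CMSPenalty`` without ``Training``, "Institutional
    Incentives"; through ``PerceivedEvidence``, "Individual Motivation";
    through ``InternalPressure``, "Team Use". Loops matching no rule are
    labeled ``"unnamed"``.
    """
    named = []
    for loop in loops:
        members = set(loop.cycle)
        label = "unnamed"
        for name, required, forbidden in _NAME_RULES:
            if required <= members and not (forbidden & members):
                label = name
                break
        named.append(replace(loop, name=label))
    return named


def export_dot(graph: CLDGraph, loops: list[LoopRecord] | None = None) -> str:
    """Render the diagram as Graphviz DOT source.

    Positive links are solid, negative links dashed with a ``-`` edge
    label. When ``loops`` is given, their names are added as a graph
    label. Output is deterministic for a fixed graph.
    """
    lines = ["digraph CLD {", "  rankdir=LR;"]
    if loops:
        names = ", ".join(
            f"{l.name or 'unnamed'} ({l.classification})" for l in loops
        )
        lines.append(f'  label="{names}";')
    for v in graph.variables:
        lines.append(f'  "{v}";')
    for link in graph.links:
        attrs = 'style=dashed, label="-"' if link.polarity < 0 else "style=solid"
        lines.append(f'  "{link.source}" -> "{link.target}" [{attrs}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
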