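"""Referral networks for difficult implant removals.

Facilities that cannot manage a removal case refer the client to another
facility. Each surveyed facility names at most one destination, so the
referral graph is a functional digraph; in practice it decomposes into star
networks around a few receiving facilities. This module builds those
networks, assigns each facility a role, and audits whether the facilities
that must absorb referred cases — the receiving facilities and the
standalone ones that can send cases nowhere — are actually ready for them.

Roles
-----
* ``RECEIVING`` — at least one other facility refers to it (takes precedence
  for a facility that both refers and receives; its outgoing link still
  counts toward network membership).
* ``REFERRING`` — has an outgoing referral and receives none.
* ``STANDALONE`` — neither refers nor receives.

Chains (a→b, b→c) are structurally permitted but reported as warnings,
since surveyed networks are star-shaped; cycles are errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .readiness import Level, ReadinessResult
from .survey_data import FacilityRecord, check_dataset


class ReferralCycleError(ValueError):
    """The referral links contain a cycle."""

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__("referral cycle: " + " -> ".join(cycle + cycle[:1]))


class CoverageError(ValueError):
    """A readiness result is missing for an assessed facility."""


@dataclass(frozen=True)
class ReferralNetwork:
    """One receiving facility and everyone who refers to it (itself included)."""

    receiving_id: str
    member_ids: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class NetworkBuild:
    networks: list[ReferralNetwork]
    roles: dict[str, str]  # facility_id -> REFERRING | RECEIVING | STANDALONE
    warnings: list[str] = field(default_factory=list)

    def role_counts(self) -> dict[str, int]:
        counts = {"REFERRING": 0, "RECEIVING": 0, "STANDALONE": 0}
        for role in self.roles.values():
            counts[role] += 1
        return counts


def build_networks(facilities: Sequence[FacilityRecord]) -> NetworkBuild:
    """Group facilities into referral networks and assign roles.

    Networks and roles are independent of input ordering. Raises
    :class:`ReferralCycleError` on cyclic links and the dataset-level errors
    of :func:`~implant_access.survey_data.check_dataset` on invalid links.
    """
    check_dataset(facilities)
    graph = nx.DiGraph()
    graph.add_nodes_from(f.facility_id for f in facilities)
    graph.add_edges_from(
        (f.facility_id, f.refers_to) for f in facilities if f.refers_to is not None
    )
    try:
        cycle = nx.find_cycle(graph)
    except nx.NetworkXNoCycle:
        pass
    else:
        raise ReferralCycleError([edge[0] for edge in cycle])

    roles: dict[str, str] = {}
    for node in graph.nodes:
        if graph.in_degree(node) > 0:
            roles[node] = "RECEIVING"
        elif graph.out_degree(node) > 0:
            roles[node] = "REFERRING"
        else:
            roles[node] = "STANDALONE"

    warnings = [
        f"chain: {node} both receives referrals and refers onward to "
        f"{next(iter(graph.successors(node)))}"
        for node in graph.nodes
        if graph.in_degree(node) > 0 and graph.out_degree(node) > 0
    ]

    networks = [
        ReferralNetwork(
            receiving_id=node,
            member_ids=frozenset(graph.predecessors(node)) | {node},
        )
        for node in sorted(graph.nodes)
        if graph.in_degree(node) > 0
    ]
    return NetworkBuild(networks=networks, roles=roles, warnings=warnings)


@dataclass
class RationalityReport:
    """Does the system route difficult cases toward facilities ready for them?

    Receiving and standalone facilities are where cases terminate: receiving
    ones absorb referred clients, standalone ones must manage their own. The
    report tabulates readiness among those terminal facilities; unassessed
    ones are ``UNKNOWN`` and excluded from ready-count denominators.
    """

    receiving_levels: dict[str, str]  # receiving_id -> level name or UNKNOWN
    n_referring: int
    n_receiving: int
    n_standalone: int
    n_terminal_assessed: int  # assessed receiving-or-standalone facilities
    n_terminal_regular_ready: int
    n_terminal_difficult_ready: int

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "Referring facilities": self.n_referring,
                "Receiving facilities": self.n_receiving,
                "Standalone facilities": self.n_standalone,
                "Assessed receiving-or-standalone": self.n_terminal_assessed,
                "...ready for regular removals": self.n_terminal_regular_ready,
                "...ready for difficult removals": self.n_terminal_difficult_ready,
            }
        )


def assess_rationality(
    build: NetworkBuild,
    facilities: Sequence[FacilityRecord],
    readiness: Mapping[str, ReadinessResult],
) -> RationalityReport:
    """Join roles with readiness levels.

    ``readiness`` must cover every assessed facility (``CoverageError``
    otherwise). Unassessed facilities appear as ``UNKNOWN``.
    """
    by_id = {f.facility_id: f for f in facilities}
    missing = [
        f.facility_id
        for f in facilities
        if f.assessed and f.facility_id not in readiness
    ]
    if missing:
        raise CoverageError(f"no readiness result for assessed facility(ies): {missing}")

    counts = build.role_counts()
    receiving_levels = {
        net.receiving_id: (
            readiness[net.receiving_id].level.name
            if by_id[net.receiving_id].assessed
            else "UNKNOWN"
        )
        for net in build.networks
    }
    terminal = [
        fid
        for fid, role in build.roles.items()
        if role in ("RECEIVING", "STANDALONE") and by_id[fid].assessed
    ]
    regular_ready = sum(1 for fid in terminal if readiness[fid].level >= Level.REGULAR)
    difficult_ready = sum(
        1 for fid in terminal if readiness[fid].level >= Level.DIFFICULT
    )
    return RationalityReport(
        receiving_levels=receiving_levels,
        n_referring=counts["REFERRING"],
        n_receiving=counts["RECEIVING"],
        n_standalone=counts["STANDALONE"],
        n_terminal_assessed=len(terminal),
        n_terminal_regular_ready=regular_ready,
        n_terminal_difficult_ready=difficult_ready,
    )


def networks_to_frame(build: NetworkBuild) -> pd.DataFrame:
    """Network listing: one row per network, largest first."""
    rows = [
        {
            "receiving_id": net.receiving_id,
            "size": net.size,
            "member_ids": ";".join(sorted(net.member_ids)),
        }
        for net in sorted(build.networks, key=lambda n: (-n.size, n.receiving_id))
    ]
    return pd.DataFrame(rows, columns=["receiving_id", "size", "member_ids"])


def referral_graph(facilities: Sequence[FacilityRecord]) -> nx.DiGraph:
    """The raw referral digraph (for DOT/GraphML export or plotting)."""
    g = nx.DiGraph()
    for f in facilities:
        g.add_node(f.facility_id, district=f.district.value, type=f.facility_type.value)
    g.add_edges_from(
        (f.facility_id, f.refers_to) for f in facilities if f.refers_to is not None
    )
    return g
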