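"""Optimal assignment of independent hubs to existing networks.

Each currently unaffiliated hub *a* must join exactly one network *n*; the
cost of that choice is the average distance from *a* to the network's
current members, and the objective is the sum of these costs:

    min  Σ_n Σ_a Σ_{b∈Bⁿ} x_{a,n} · d(a,b) / h_n
    s.t. Σ_n x_{a,n} = 1  for every a,   x binary.

Because the objective is separable in the hubs, the exact optimum is simply
the per-hub argmin of the assignment cost; the greedy engine exploits this
and a 0/1 integer program (scipy.optimize.milp) is kept as a fidelity
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import logging

import numpy as np
from scipy.optimize import LinearConstraint, milp

from .core import UNASSIGNED, DistanceMatrix, NetworkDesign

logger = logging.getLogger("strokenet")

__all__ = [
    "AssignmentProblem",
    "assignment_cost",
    "assign_independent_hubs",
    "apply_assignment",
]


@dataclass
class AssignmentProblem:
    """Independent hubs A, per-network member sets Bⁿ, and distances d."""

    independent_hubs: list[str]
    networks: dict[str, list[str]]
    distances: DistanceMatrix

    def __post_init__(self) -> None:
        members = {m for mem in self.networks.values() for m in mem}
        overlap = members & set(self.independent_hubs)
        if overlap:
            raise ValueError(f"hubs cannot be both independent and members: {sorted(overlap)}")
        for n, mem in self.networks.items():
            if not mem:
                raise ValueError(f"network {n} has no current members")

    @classmethod
    def from_design(cls, design: NetworkDesign, distances: DistanceMatrix) -> "AssignmentProblem":
        return cls(
            independent_hubs=design.unassigned,
            networks={n: design.members(n) for n in design.network_ids},
            distances=distances,
        )


def assignment_cost(a: str, n: str, problem: AssignmentProblem) -> float:
    """Average distance from hub ``a`` to the current members of network ``n``."""
    members = problem.networks[n]
    return float(sum(problem.distances(a, b) for b in members) / len(members))


def _cost_table(problem: AssignmentProblem) -> tuple[list[str], list[str], np.ndarray]:
    hubs = sorted(problem.independent_hubs)
    nets = sorted(problem.networks)
    cost = np.array([[assignment_cost(a, n, problem) for n in nets] for a in hubs])
    return hubs, nets, cost


def _solve_greedy(hubs, nets, cost) -> dict[str, str]:
    mapping = {}
    for i, a in enumerate(hubs):
        j = int(np.argmin(cost[i]))  # first index on ties ⇒ network-id order
        ties = np.flatnonzero(cost[i] == cost[i, j])
        if len(ties) > 1:
            logger.info("hub %s: tie between networks %s; keeping %s",
                        a, [nets[t] for t in ties], nets[j])
        mapping[a] = nets[j]
    return mapping


def _solve_milp(hubs, nets, cost) -> dict[str, str]:
    """Explicit 0/1 program over x_{a,n}; one choice constraint per hub."""
    n_a, n_n = cost.shape
    c = cost.ravel()
    rows = np.repeat(np.arange(n_a), n_n)
    A = np.zeros((n_a, n_a * n_n))
    A[rows, np.arange(n_a * n_n)] = 1.0
    res = milp(
        c=c,
        constraints=LinearConstraint(A, lb=1, ub=1),
        integrality=np.ones_like(c),
        bounds=(0, 1),
    )
    if not res.success:
        raise RuntimeError(f"assignment MILP failed: {res.message}")
    x = res.x.reshape(n_a, n_n)
    return {hubs[i]: nets[int(np.argmax(x[i]))] for i in range(n_a)}


def assign_independent_hubs(
    problem: AssignmentProblem, engine: str = "greedy"
) -> tuple[dict[str, str], float]:
    """Assign every independent hub to exactly one network, minimizing the
    summed average member distance.

    Returns the mapping and the achieved objective value.  ``engine`` is
    ``"greedy"`` (exact, via separability) or ``"milp"`` (the explicit 0/1
    program, used as a cross-check).  Ties go to the lexicographically
    first network id.
    """
    if not problem.networks:
        raise ValueError("no networks to assign to")
    hubs, nets, cost = _cost_table(problem)
    if not hubs:
        return {}, 0.0
    if engine == "greedy":
        mapping = _solve_greedy(hubs, nets, cost)
    elif engine == "milp":
        mapping = _solve_milp(hubs, nets, cost)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    objective = float(sum(cost[i, nets.index(mapping[a])] for i, a in enumerate(hubs)))
    return mapping, objective


def apply_assignment(design: NetworkDesign, mapping: Mapping[str, str]) -> NetworkDesign:
    """Fold an assignment back into a design, leaving the original untouched.

    ``mapping`` must cover exactly the design's unassigned hubs.
    """
    unassigned = set(design.unassigned)
    if set(mapping) != unassigned:
        raise ValueError(
            "mapping must cover exactly the unassigned hubs; "
            f"missing={sorted(unassigned - set(mapping))}, "
            f"extra={sorted(set(mapping) - unassigned)}"
        )
    assignment = dict(design.assignment)
    known = set(design.network_ids)
    for hid, net in mapping.items():
        if net not in known:
            raise ValueError(f"unknown target network {net!r} for hub {hid}")
        assignment[hid] = net
    return NetworkDesign(assignment)
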