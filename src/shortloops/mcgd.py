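"""Markov Chain Graph Dynamics: degree-constrained edge-swap randomisation.

Null models for loop statistics are built by rewiring the observed network
with repeated edge swaps (a,b),(c,d) -> (a,d),(c,b), which conserve every
node's degree.  Two constraint modes are supported:

* ``DEGREE`` — conserve the degree sequence only (Maslov-Sneppen rewiring
  restricted to the simple-graph space).
* ``DEGREE_DEGREE`` — additionally conserve the joint edge-end degree
  matrix W(k,k') exactly, by rejecting any swap that would change the
  multiset of edge degree pairs.  A swap leaves W unchanged iff the two
  exchanged partners have equal degree (deg(b)=deg(d), or deg(a)=deg(c)
  for the other pairing).

Moves are counted as *proposed* swaps, accepted or not, so a budget of
100 x NI moves means the same wall-clock of the chain under both modes.
The hard DEGREE_DEGREE constraint samples the fixed-W graph space
approximately uniformly (proposals carry no mobility correction); this is
a documented bias, not an error.

Randomness is a single seeded ``random.Random`` per chain; identical seeds
reproduce trajectories bit for bit.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from random import Random
from typing import Callable, Optional, Sequence

from .loops import count_loops
from .network import InteractionNetwork, edge_key
from .topology import degree_correlation_matrix

__all__ = [
    "ConstraintMode",
    "SwapProposal",
    "TrajectorySample",
    "MCGDTrajectory",
    "RandomisedEnsemble",
    "propose_swap",
    "swap_is_admissible",
    "hamming_distance",
    "run_mcgd",
    "run_ensemble",
    "DEFAULT_MOVES_PER_EDGE",
    "DEFAULT_N_REPLICAS",
]

DEFAULT_MOVES_PER_EDGE = 100
DEFAULT_N_REPLICAS = 5


class ConstraintMode(enum.Enum):
    """Topological constraints conserved by the randomisation."""

    DEGREE = "k"
    DEGREE_DEGREE = "kk"

    @classmethod
    def parse(cls, value: "ConstraintMode | str") -> "ConstraintMode":
        if isinstance(value, cls):
            return value
        for mode in cls:
            if value in (mode.value, mode.name, mode.name.lower()):
                return mode
        raise ValueError(f"unknown constraint mode {value!r}")


@dataclass(frozen=True)
class SwapProposal:
    """Edge swap acting on a quadruplet of nodes: old edges out, new edges in."""

    edge1: tuple[str, str]
    edge2: tuple[str, str]
    new1: tuple[str, str]
    new2: tuple[str, str]

    @property
    def nodes(self) -> tuple[str, ...]:
        return (*self.edge1, *self.edge2)


def _propose(edges: list[tuple[str, str]], rng: Random) -> SwapProposal:
    m = len(edges)
    i = rng.randrange(m)
    j = rng.randrange(m - 1)
    if j >= i:
        j += 1
    a, b = edges[i]
    c, d = edges[j]
    # the two possible rewirings of the quadruplet, chosen uniformly
    if rng.random() < 0.5:
        new1, new2 = edge_key(a, d), edge_key(c, b)
    else:
        new1, new2 = edge_key(a, c), edge_key(b, d)
    return SwapProposal(edge1=(a, b), edge2=(c, d), new1=new1, new2=new2)


def propose_swap(net: InteractionNetwork, rng: Random) -> SwapProposal:
    """Draw two distinct edges uniformly and one of the two rewirings.

    Validity is *not* checked here; see :func:`swap_is_admissible`.
    """
    if net.n_interactions < 2:
        raise ValueError("need at least 2 edges to propose a swap")
    return _propose(sorted(net.edges()), rng)


def _admissible(
    proposal: SwapProposal,
    edge_set: set[tuple[str, str]],
    degs: dict[str, int],
    mode: ConstraintMode,
) -> bool:
    a, b = proposal.edge1
    c, d = proposal.edge2
    if len({a, b, c, d}) != 4:
        return False
    for e in (proposal.new1, proposal.new2):
        if e[0] == e[1] or e in edge_set:
            return False
    if mode is ConstraintMode.DEGREE_DEGREE:
        before = sorted(
            (
                tuple(sorted((degs[a], degs[b]))),
                tuple(sorted((degs[c], degs[d]))),
            )
        )
        after = sorted(
            (
                tuple(sorted((degs[proposal.new1[0]], degs[proposal.new1[1]]))),
                tuple(sorted((degs[proposal.new2[0]], degs[proposal.new2[1]]))),
            )
        )
        if before != after:
            return False
    return True


def swap_is_admissible(
    net: InteractionNetwork,
    proposal: SwapProposal,
    mode: ConstraintMode | str = ConstraintMode.DEGREE,
) -> bool:
    """Whether applying ``proposal`` keeps the chain inside the constraint set.

    DEGREE: all four nodes distinct and neither rewired edge already exists
    (the chain stays in simple-graph space).  DEGREE_DEGREE: additionally the
    edge degree-pair multiset is unchanged.
    """
    mode = ConstraintMode.parse(mode)
    for e in (proposal.edge1, proposal.edge2):
        if not net.has_edge(*e):
            raise ValueError(f"proposal references absent edge {e!r}")
    return _admissible(proposal, net.edge_set(), net.degrees(), mode)


def hamming_distance(net_a: InteractionNetwork, net_b: InteractionNetwork) -> float:
    """Fraction of node pairs whose adjacency differs between two networks.

    Normalised by C(NP, 2), i.e. all node pairs; requires identical node sets.
    """
    if net_a.nodes != net_b.nodes:
        raise ValueError("hamming distance requires identical node sets")
    n = net_a.n_proteins
    pairs = n * (n - 1) // 2
    return len(net_a.edge_set() ^ net_b.edge_set()) / pairs


@dataclass
class TrajectorySample:
    step: int
    loop_counts: Optional[dict[int, int]]
    hamming: float


@dataclass
class MCGDTrajectory:
    mode: ConstraintMode
    seed: int
    samples: list[TrajectorySample] = field(default_factory=list)
    accepted: int = 0
    proposed: int = 0

    def final_counts(self) -> Optional[dict[int, int]]:
        return self.samples[-1].loop_counts if self.samples else None

    def hamming_series(self) -> list[tuple[int, float]]:
        return [(s.step, s.hamming) for s in self.samples]


def run_mcgd(
    net: InteractionNetwork,
    mode: ConstraintMode | str = ConstraintMode.DEGREE,
    total_moves: Optional[int] = None,
    measure_every: Optional[int] = None,
    seed: int = 0,
    *,
    lengths: Sequence[int] = (3, 4, 5, 6),
    census_cap: int = 10_000_000,
    probe_budget: int = 1000,
    on_sample: Optional[Callable[[InteractionNetwork, int], None]] = None,
) -> tuple[InteractionNetwork, MCGDTrajectory]:
    """Run one randomisation chain and monitor loops and Hamming distance.

    Parameters
    ----------
    total_moves:
        Proposed swaps to perform; defaults to 100 * NI.
    measure_every:
        Sampling interval in moves; defaults to NI.  Step 0 and the final
        step are always sampled.
    lengths:
        Loop lengths counted at each sample; pass ``()`` to monitor the
        Hamming distance only.
    probe_budget:
        Consecutive rejections after which the chain is declared frozen
        (warning + early stop with diagnostics).
    on_sample:
        Optional callback ``(current_network, step)`` invoked at each sample,
        e.g. to assert invariants during testing.

    Returns the final randomised network and the trajectory.
    """
    mode = ConstraintMode.parse(mode)
    ni = net.n_interactions
    if ni < 2:
        raise ValueError("MCGD requires at least 2 edges")
    if total_moves is None:
        total_moves = DEFAULT_MOVES_PER_EDGE * ni
    if measure_every is None:
        measure_every = ni

    rng = Random(seed)
    work = net.copy()
    edges = sorted(work.edges())
    pos = {e: i for i, e in enumerate(edges)}
    edge_set = set(edges)
    degs = work.degrees()  # degrees are invariant under swaps
    orig_edges = frozenset(edges)
    n = work.n_proteins
    pairs = n * (n - 1) // 2
    sym_diff = 0  # |E_t symmetric-difference E_0|

    traj = MCGDTrajectory(mode=mode, seed=seed)

    def census() -> Optional[dict[int, int]]:
        if not lengths:
            return None
        lmin, lmax = min(lengths), max(lengths)
        c = count_loops(work, lmin, lmax, cap=census_cap)
        return {length: c.counts[length] for length in lengths}

    def sample(step: int) -> None:
        traj.samples.append(
            TrajectorySample(
                step=step, loop_counts=census(), hamming=sym_diff / pairs
            )
        )
        if on_sample is not None:
            on_sample(work, step)

    sample(0)
    consecutive_rejections = 0
    step = 0
    while step < total_moves:
        proposal = _propose(edges, rng)
        step += 1
        traj.proposed += 1
        if _admissible(proposal, edge_set, degs, mode):
            for old, new in (
                (proposal.edge1, proposal.new1),
                (proposal.edge2, proposal.new2),
            ):
                old = edge_key(*old)
                i = pos.pop(old)
                edge_set.discard(old)
                work.remove_edge(*old)
                sym_diff += 1 if old in orig_edges else -1
                edges[i] = new
                pos[new] = i
                edge_set.add(new)
                work.add_edge(*new)
                sym_diff += -1 if new in orig_edges else 1
            traj.accepted += 1
            consecutive_rejections = 0
        else:
            consecutive_rejections += 1
            if consecutive_rejections >= probe_budget:
                warnings.warn(
                    f"MCGD chain appears frozen: {consecutive_rejections} "
                    f"consecutive rejections at step {step} "
                    f"(mode={mode.name}, NI={ni}); stopping early"
                )
                break
        if step % measure_every == 0:
            sample(step)
    if traj.samples[-1].step != step:
        sample(step)
    return work, traj


@dataclass
class Replica:
    final: InteractionNetwork
    trajectory: MCGDTrajectory


@dataclass
class RandomisedEnsemble:
    """Independent MCGD replicas of one network under one constraint mode."""

    mode: ConstraintMode
    replicas: list[Replica]
    total_moves: int

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    def final_counts(self, length: int) -> list[int]:
        out = []
        for rep in self.replicas:
            counts = rep.trajectory.final_counts()
            if counts is None or length not in counts:
                raise ValueError(
                    f"ensemble was not run with loop length {length} monitored"
                )
            out.append(counts[length])
        return out

    def mean_final(self, length: int) -> float:
        counts = self.final_counts(length)
        return sum(counts) / len(counts)

    def sd_final(self, length: int) -> float:
        counts = self.final_counts(length)
        mean = sum(counts) / len(counts)
        if len(counts) < 2:
            return 0.0
        return math.sqrt(
            sum((c - mean) ** 2 for c in counts) / (len(counts) - 1)
        )


def run_ensemble(
    net: InteractionNetwork,
    mode: ConstraintMode | str = ConstraintMode.DEGREE,
    n_replicas: int = DEFAULT_N_REPLICAS,
    total_moves: Optional[int] = None,
    base_seed: int = 0,
    **kwargs,
) -> RandomisedEnsemble:
    """Run ``n_replicas`` independent chains seeded ``base_seed + index``."""
    mode = ConstraintMode.parse(mode)
    if total_moves is None:
        total_moves = DEFAULT_MOVES_PER_EDGE * net.n_interactions
    replicas = []
    for i in range(n_replicas):
        final, traj = run_mcgd(
            net,
            mode,
            total_moves=total_moves,
            seed=base_seed + i,
            **kwargs,
        )
        replicas.append(Replica(final=final, trajectory=traj))
    return RandomisedEnsemble(mode=mode, replicas=replicas, total_moves=total_moves)


def check_degree_degree_invariant(
    net_before: InteractionNetwork, net_after: InteractionNetwork
) -> bool:
    """True iff the two networks have identical W(k,k') matrices."""
    return (
        degree_correlation_matrix(net_before).W
        == degree_correlation_matrix(net_after).W
    )
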