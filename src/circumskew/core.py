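"""Asynchronous reproductive-skew dynamics of inequality on polity networks.

The model simulates a landscape of polities (groups), each containing a
dominant who extracts a share ``z`` of the subordinates' surplus, with
``z = 0`` fully egalitarian and ``z = 1`` full extraction.  Subordinates can
credibly threaten to migrate to a neighbouring polity, paying a proportional
migration cost ``c_m``; the dominant therefore concedes exactly enough to
keep them indifferent between staying and leaving.  When a random polity
``i`` updates, its dominant sets

    z_i  <-  1 - (1 - c_m) * max_{j in P_i} (1 - z_j)

where ``P_i`` is the set of network neighbours of ``i``.  With probability
``mu_r`` per update, the freshly set inequality is additionally perturbed by
a shock drawn uniformly from ``[-epsilon, +epsilon]`` (clamped to [0, 1]),
representing dominants' errors or fluctuations in their power.  One *time
step* is defined as ``P`` single-polity updates, so each polity updates once
on average per time step.

The network is the model's representation of geographic circumscription:
a complete graph is an open plain, a lattice with a maximum travelling
distance varies connectivity, and clique-based "islands"/"valleys" graphs
capture fragmented landscapes.  The module is organised in the order the
method runs: network generators, the update dynamics, replicate/sweep
experiments, then configuration and file I/O.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

__version__ = "0.1.0"

log = logging.getLogger("circumskew")

#: All seeds handed to numpy generators are reduced modulo 2**31.
SEED_MOD = 2**31

# ---------------------------------------------------------------------------
# Defaults: an open landscape of ~50 polities with a 5% migration cost,
# shocks of half-width 0.25 firing on 1% of updates, and a near-egalitarian
# initial inequality drawn from U[0.05, 0.10].
# ---------------------------------------------------------------------------
DEFAULT_C_M = 0.05
DEFAULT_MU_R = 0.01
DEFAULT_EPSILON = 0.25
DEFAULT_Z0_LOW = 0.05
DEFAULT_Z0_HIGH = 0.10
DEFAULT_N_TIME_STEPS = 3000
DEFAULT_LAST_K = 500
DEFAULT_N_REPLICATES = 100

NETWORK_FAMILIES = ("complete", "grid", "islands", "valleys", "custom")
WITHIN_TOPOLOGIES = ("complete", "stepping_stone")
BETWEEN_TOPOLOGIES = ("chain", "ring", "complete")
SCENARIOS = ("plain", "islands", "valleys")

DEFAULT_ISLANDS_CLIQUES = 10
DEFAULT_VALLEYS_CLIQUES = 3


class CircumskewError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CircumskewError, ValueError):
    """A parameter violates its documented precondition."""


class NoNeighbourError(CircumskewError):
    """A polity without neighbours was asked for an outside option."""


class InvalidRequestError(CircumskewError):
    """A valid object was asked for something it cannot provide."""


class ConfigError(CircumskewError):
    """Base class for configuration errors."""


class ConfigParseError(ConfigError):
    """The configuration file is not valid YAML / not a mapping."""


class ConfigValidationError(ConfigError):
    """A configuration key is unknown or holds an invalid value."""


# ===========================================================================
# Polity networks
# ===========================================================================


@dataclass(frozen=True, eq=False)
class PolityNetwork:
    """Undirected migration network over ``n_polities`` polities.

    ``edges`` is a canonical tuple of ``(i, j)`` pairs with ``i < j``,
    sorted lexicographically and free of duplicates and self-loops.
    ``coordinates`` holds per-polity lattice positions for grid networks;
    ``clique_labels`` holds per-polity clique ids for clique networks.
    """

    n_polities: int
    edges: tuple[tuple[int, int], ...]
    coordinates: np.ndarray | None = None
    clique_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.n_polities
        if not isinstance(n, (int, np.integer)) or n < 1:
            raise InvalidParameterError(f"n_polities must be a positive integer, got {n!r}")
        prev = None
        for e in self.edges:
            i, j = e
            if not (0 <= i < j < n):
                raise InvalidParameterError(
                    f"edge {e!r} is not a canonical pair of distinct indices in [0, {n})"
                )
            if prev is not None and e <= prev:
                raise InvalidParameterError("edges must be sorted and unique")
            prev = e

    @classmethod
    def from_edges(
        cls,
        n_polities: int,
        edges: Iterable[tuple[int, int]],
        coordinates: np.ndarray | None = None,
        clique_labels: np.ndarray | None = None,
    ) -> "PolityNetwork":
        """Build a network, canonicalizing edge order and rejecting self-loops."""
        canonical = set()
        for i, j in edges:
            i, j = int(i), int(j)
            if i == j:
                raise InvalidParameterError(f"self-loop on polity {i}")
            canonical.add((min(i, j), max(i, j)))
        return cls(
            n_polities=int(n_polities),
            edges=tuple(sorted(canonical)),
            coordinates=coordinates,
            clique_labels=clique_labels,
        )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbor_arrays(self) -> list[np.ndarray]:
        """Per-polity arrays of neighbour indices (cached)."""
        cached = self.__dict__.get("_nbrs")
        if cached is None:
            adj: list[list[int]] = [[] for _ in range(self.n_polities)]
            for i, j in self.edges:
                adj[i].append(j)
                adj[j].append(i)
            cached = [np.asarray(sorted(a), dtype=np.intp) for a in adj]
            object.__setattr__(self, "_nbrs", cached)
        return cached

    def degrees(self) -> np.ndarray:
        return np.asarray([nb.size for nb in self.neighbor_arrays()], dtype=int)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_polities))
        g.add_edges_from(self.edges)
        return g


def make_complete(n_polities: int) -> PolityNetwork:
    """Complete graph: the open-plain landscape where every polity is a neighbour."""
    if n_polities < 2:
        raise InvalidParameterError(f"a complete network needs >= 2 polities, got {n_polities}")
    edges = itertools.combinations(range(int(n_polities)), 2)
    return PolityNetwork.from_edges(n_polities, edges)


@dataclass(frozen=True)
class GridSpec:
    """Square-lattice landscape with a maximum travelling distance.

    Polities sit on integer lattice points with unit spacing; two polities
    are connected iff their Euclidean distance is <= ``d_max`` (or < when
    ``inclusive_distance`` is False).  ``periodic`` wraps distances on the
    torus.  The default comparator is inclusive so that ``d_max = 1``
    connects adjacent squares.
    """

    rows: int
    cols: int
    d_max: float = 100.0
    periodic: bool = False
    inclusive_distance: bool = True

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise InvalidParameterError(
                f"grid must be non-empty, got rows={self.rows}, cols={self.cols}"
            )
        if not self.d_max > 0:
            raise InvalidParameterError(f"d_max must be > 0, got {self.d_max}")

    @property
    def n_polities(self) -> int:
        return self.rows * self.cols


def make_grid(spec: GridSpec) -> PolityNetwork:
    """Lattice network: edge iff Euclidean distance within ``spec.d_max``.

    Distances are compared on squared values, so exact thresholds such as
    ``d_max = 1`` (rook moves) or ``d_max = sqrt(2)`` (adding diagonals)
    behave without floating-point surprises.
    """
    rows, cols = spec.rows, spec.cols
    pos = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=np.int64)
    dr = np.abs(pos[:, 0][:, None] - pos[:, 0][None, :])
    dc = np.abs(pos[:, 1][:, None] - pos[:, 1][None, :])
    if spec.periodic:
        dr = np.minimum(dr, rows - dr)
        dc = np.minimum(dc, cols - dc)
    d2 = dr.astype(np.float64) ** 2 + dc.astype(np.float64) ** 2
    lim = float(spec.d_max) ** 2
    mask = (d2 <= lim) if spec.inclusive_distance else (d2 < lim)
    iu, ju = np.triu_indices(spec.n_polities, k=1)
    keep = mask[iu, ju]
    edges = zip(iu[keep].tolist(), ju[keep].tolist())
    return PolityNetwork.from_edges(spec.n_polities, edges, coordinates=pos)


@dataclass(frozen=True)
class CliqueSpec:
    """Clique-structured landscape (islands / valleys generative model).

    Polities are assigned to ``n_cliques`` cliques uniformly at random
    (rejecting assignments that leave a clique empty).  Within a clique the
    polities are either fully connected (``complete``, islands) or
    path-connected in index order (``stepping_stone``, valleys).  Linked
    clique pairs — a chain by default — are bridged by one edge between a
    uniformly chosen polity of each clique.
    """

    n_polities: int
    n_cliques: int
    within_topology: str = "complete"
    between_topology: str = "chain"

    def __post_init__(self) -> None:
        if self.n_cliques < 1:
            raise InvalidParameterError(f"n_cliques must be >= 1, got {self.n_cliques}")
        if self.n_cliques > self.n_polities:
            raise InvalidParameterError(
                f"n_cliques ({self.n_cliques}) cannot exceed n_polities ({self.n_polities})"
            )
        if self.within_topology not in WITHIN_TOPOLOGIES:
            raise InvalidParameterError(f"unknown within_topology {self.within_topology!r}")
        if self.between_topology not in BETWEEN_TOPOLOGIES:
            raise InvalidParameterError(f"unknown between_topology {self.between_topology!r}")


def _clique_pairs(n_cliques: int, between_topology: str) -> list[tuple[int, int]]:
    if n_cliques < 2:
        return []
    chain = [(c, c + 1) for c in range(n_cliques - 1)]
    if between_topology == "chain":
        return chain
    if between_topology == "ring":
        # a 2-clique ring degenerates to the chain (no doubled bridge)
        return chain + ([(n_cliques - 1, 0)] if n_cliques > 2 else [])
    return list(itertools.combinations(range(n_cliques), 2))


def make_cliques(spec: CliqueSpec, rng: np.random.Generator) -> PolityNetwork:
    """Random clique network; consumes the label draws then one bridge draw per end."""
    n, k = spec.n_polities, spec.n_cliques
    labels = None
    if k == n:
        # uniform assignment conditioned on no empty clique is exactly a
        # uniform permutation in this degenerate (all-singleton) case
        labels = rng.permutation(n)
    else:
        for _ in range(100_000):
            candidate = rng.integers(0, k, size=n)
            if np.unique(candidate).size == k:
                labels = candidate
                break
    if labels is None:
        raise InvalidParameterError(
            "could not draw a clique assignment with no empty clique; "
            f"n_cliques={k} is too close to n_polities={n} for rejection sampling"
        )
    members = [np.flatnonzero(labels == c) for c in range(k)]
    edges: set[tuple[int, int]] = set()
    for mem in members:
        ids = mem.tolist()
        if spec.within_topology == "complete":
            edges.update(itertools.combinations(ids, 2))
        else:  # stepping_stone: path in ascending polity-index order
            edges.update(zip(ids[:-1], ids[1:]))
    for a, b in _clique_pairs(k, spec.between_topology):
        u = int(rng.choice(members[a]))
        v = int(rng.choice(members[b]))
        edges.add((min(u, v), max(u, v)))
    return PolityNetwork.from_edges(n, edges, clique_labels=labels)


def validate_network(net: PolityNetwork) -> dict[str, Any]:
    """Diagnostics record: connectivity, degree distribution, isolated polities."""
    g = net.to_networkx()
    degrees = net.degrees()
    return {
        "n_polities": net.n_polities,
        "n_edges": net.n_edges,
        "connected": bool(nx.is_connected(g)) if net.n_polities > 0 else True,
        "n_components": int(nx.number_connected_components(g)),
        "degrees": degrees.tolist(),
        "degree_min": int(degrees.min()),
        "degree_max": int(degrees.max()),
        "degree_mean": float(degrees.mean()),
        "isolated": np.flatnonzero(degrees == 0).tolist(),
    }


def write_edgelist(net: PolityNetwork, path: str | Path) -> Path:
    """Write the canonical edge-list text format (round-trips bit-exactly)."""
    path = Path(path)
    lines = [f"# n_polities={net.n_polities}"]
    lines += [f"{i} {j}" for i, j in net.edges]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_edgelist(path: str | Path) -> PolityNetwork:
    """Read the edge-list format written by :func:`write_edgelist`."""
    path = Path(path)
    text = path.read_text()
    n_polities = None
    edges = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("n_polities="):
                n_polities = int(body.split("=", 1)[1])
            continue
        parts = line.split()
        if len(parts) != 2:
            raise InvalidParameterError(f"{path}:{lineno}: expected two indices, got {line!r}")
        edges.append((int(parts[0]), int(parts[1])))
    if n_polities is None:
        raise InvalidParameterError(f"{path}: missing '# n_polities=<N>' header")
    return PolityNetwork.from_edges(n_polities, edges)


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative network description used by configs, sweeps and replicates.

    ``family`` selects the generator: ``complete`` (open plain), ``grid``
    (lattice with travelling radius ``d_max``), ``islands`` (complete
    cliques, sparse bridges), ``valleys`` (stepping-stone cliques, sparse
    bridges) or ``custom`` (edge-list file).  Random families (islands,
    valleys) are re-drawn per replicate by default.
    """

    family: str = "complete"
    n_polities: int | None = None
    rows: int | None = None
    cols: int | None = None
    d_max: float = 100.0
    periodic: bool = False
    inclusive_distance: bool = True
    n_cliques: int | None = None
    between_topology: str = "chain"
    edgelist_path: str | None = None

    def __post_init__(self) -> None:
        if self.family not in NETWORK_FAMILIES:
            raise ConfigValidationError(
                f"network.family must be one of {NETWORK_FAMILIES}, got {self.family!r}"
            )

    @property
    def is_random(self) -> bool:
        """True when building the network consumes random draws."""
        return self.family in ("islands", "valleys")

    def validate(self) -> None:
        """Check family-specific preconditions before any simulation starts."""
        fam = self.family
        if fam == "custom":
            if not self.edgelist_path:
                raise ConfigValidationError("network.edgelist_path is required for family=custom")
            return
        if fam == "grid":
            if self.rows is None or self.cols is None:
                n = self.n_polities
                if n is None:
                    raise ConfigValidationError(
                        "network.n_polities (a perfect square) or rows+cols required for family=grid"
                    )
                side = math.isqrt(n)
                if side * side != n:
                    raise ConfigValidationError(
                        f"network.n_polities={n} is not a perfect square; give rows and cols"
                    )
            GridSpec(*self._grid_shape(), d_max=self.d_max, periodic=self.periodic,
                     inclusive_distance=self.inclusive_distance)
            return
        if self.n_polities is None:
            raise ConfigValidationError(f"network.n_polities is required for family={fam}")
        if fam == "complete":
            if self.n_polities < 2:
                raise ConfigValidationError("network.n_polities must be >= 2 for family=complete")
        else:  # islands / valleys
            CliqueSpec(
                n_polities=self.n_polities,
                n_cliques=self._n_cliques(),
                within_topology="complete" if fam == "islands" else "stepping_stone",
                between_topology=self.between_topology,
            )

    def _grid_shape(self) -> tuple[int, int]:
        if self.rows is not None and self.cols is not None:
            return self.rows, self.cols
        side = math.isqrt(int(self.n_polities))
        return side, side

    def _n_cliques(self) -> int:
        if self.n_cliques is not None:
            return self.n_cliques
        return DEFAULT_ISLANDS_CLIQUES if self.family == "islands" else DEFAULT_VALLEYS_CLIQUES


def build_network(spec: NetworkSpec, rng: np.random.Generator | None = None) -> PolityNetwork:
    """Materialize a :class:`NetworkSpec`; random families require ``rng``."""
    spec.validate()
    fam = spec.family
    if fam == "complete":
        return make_complete(spec.n_polities)
    if fam == "grid":
        rows, cols = spec._grid_shape()
        return make_grid(GridSpec(rows, cols, d_max=spec.d_max, periodic=spec.periodic,
                                  inclusive_distance=spec.inclusive_distance))
    if fam == "custom":
        return read_edgelist(spec.edgelist_path)
    if rng is None:
        raise InvalidParameterError(f"family={fam!r} needs a random generator")
    cspec = CliqueSpec(
        n_polities=spec.n_polities,
        n_cliques=spec._n_cliques(),
        within_topology="complete" if fam == "islands" else "stepping_stone",
        between_topology=spec.between_topology,
    )
    return make_cliques(cspec, rng)


# ===========================================================================
# Skew dynamics
# ===========================================================================


@dataclass(frozen=True)
class SimParams:
    """Scalar model parameters.

    c_m
        Proportional migration cost in [0, 1] paid by a subordinate moving
        to a neighbouring polity.
    mu_r
        Probability per update that the freshly set inequality receives a
        shock.
    epsilon
        Shock half-width: shocks are uniform on [-epsilon, +epsilon].
    z0_low, z0_high
        Range of the uniform initial inequality draw.
    n_time_steps
        Horizon in time steps; one time step = n_polities single updates.
    seed
        Base seed; the whole run is a pure function of (network, params).
    record_full
        Keep the full (T+1, P) matrix of z, not just the population mean.
    autarky
        If True, an isolated polity sets z = 1 (no outside option means
        full extraction) instead of raising :class:`NoNeighbourError`.
    """

    c_m: float = DEFAULT_C_M
    mu_r: float = DEFAULT_MU_R
    epsilon: float = DEFAULT_EPSILON
    z0_low: float = DEFAULT_Z0_LOW
    z0_high: float = DEFAULT_Z0_HIGH
    n_time_steps: int = DEFAULT_N_TIME_STEPS
    seed: int = 0
    record_full: bool = False
    autarky: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.c_m <= 1.0:
            raise InvalidParameterError(f"c_m must be in [0, 1], got {self.c_m}")
        if not 0.0 <= self.mu_r <= 1.0:
            raise InvalidParameterError(f"mu_r must be in [0, 1], got {self.mu_r}")
        if not self.epsilon >= 0.0:
            raise InvalidParameterError(f"epsilon must be >= 0, got {self.epsilon}")
        if not 0.0 <= self.z0_low <= self.z0_high <= 1.0:
            raise InvalidParameterError(
                f"initial range needs 0 <= z0_low <= z0_high <= 1, "
                f"got z0_low={self.z0_low}, z0_high={self.z0_high}"
            )
        if self.n_time_steps < 0:
            raise InvalidParameterError(f"n_time_steps must be >= 0, got {self.n_time_steps}")


@dataclass
class SimState:
    """Mutable simulation state: per-polity inequality plus counters."""

    z: np.ndarray
    time_step: int = 0
    updates_done: int = 0


@dataclass
class Trajectory:
    """Recorded run: population-mean inequality per time step (index 0 = initial).

    ``z_full`` holds the (T+1, P) matrix when the run recorded fully.
    """

    mean_z: np.ndarray
    z_full: np.ndarray | None
    params: SimParams
    network_info: dict[str, Any]

    @property
    def n_time_steps(self) -> int:
        return len(self.mean_z) - 1


def draw_initial_inequality(
    n_polities: int, params: SimParams, rng: np.random.Generator
) -> np.ndarray:
    """Independent uniform draws on [z0_low, z0_high], one per polity."""
    if n_polities < 1:
        raise InvalidParameterError(f"n_polities must be positive, got {n_polities}")
    return rng.uniform(params.z0_low, params.z0_high, size=n_polities)


def outside_option(z: np.ndarray, net: PolityNetwork, i: int) -> float:
    """Best payoff share available to polity ``i``'s subordinates elsewhere:
    ``max_{j in P_i} (1 - z_j)``."""
    nb = net.neighbor_arrays()[i]
    if nb.size == 0:
        raise NoNeighbourError(f"polity {i} has no neighbours")
    return float((1.0 - z[nb]).max())


def would_migrate(z_i: float, best_outside: float, c_m: float) -> bool:
    """Migration condition: stay payoff strictly below discounted outside option.

    Indifference keeps the subordinate at home, so the dominant can set
    exactly the indifference value.
    """
    return (1.0 - z_i) < (1.0 - c_m) * best_outside


def optimal_inequality(
    z: np.ndarray, net: PolityNetwork, i: int, c_m: float, autarky: bool = False
) -> float:
    """The dominant's optimum: highest z at which subordinates still stay."""
    nb = net.neighbor_arrays()[i]
    if nb.size == 0:
        if autarky:
            return 1.0
        raise NoNeighbourError(f"polity {i} has no neighbours")
    return 1.0 - (1.0 - c_m) * float((1.0 - z[nb]).max())


def apply_shock(z_i: float, params: SimParams, rng: np.random.Generator) -> float:
    """With probability ``mu_r``, perturb by U[-epsilon, +epsilon] and clamp to [0, 1].

    Consumes exactly one Bernoulli draw, plus one uniform draw only when the
    shock fires — the same stream contract the run loop uses.
    """
    if rng.random() < params.mu_r:
        z_i = z_i + rng.uniform(-params.epsilon, params.epsilon)
        if z_i > 1.0:
            z_i = 1.0
        elif z_i < 0.0:
            z_i = 0.0
    return z_i


def update_one(
    state: SimState, net: PolityNetwork, params: SimParams, rng: np.random.Generator
) -> SimState:
    """One asynchronous event: a uniformly chosen dominant re-optimizes, then
    the shock process may strike.  Mutates ``state`` in place and returns it.

    Draw order per event: polity choice, shock Bernoulli, shock magnitude
    (only when the Bernoulli fires).
    """
    i = int(rng.integers(0, net.n_polities))
    zi = optimal_inequality(state.z, net, i, params.c_m, params.autarky)
    state.z[i] = apply_shock(zi, params, rng)
    state.updates_done += 1
    return state


def run(
    net: PolityNetwork, params: SimParams, rng: np.random.Generator | None = None
) -> Trajectory:
    """Simulate ``params.n_time_steps`` time steps of ``net.n_polities`` updates each.

    The initial inequality is drawn inside the run, so the trajectory is a
    pure function of ``(net, params)``.  Passing ``rng`` lets callers chain
    the stream (e.g. after drawing a random network from the same seed); the
    draw order is identical to calling :func:`draw_initial_inequality` once
    and :func:`update_one` ``T * P`` times.
    """
    n = net.n_polities
    if n < 2:
        raise InvalidParameterError(f"a run requires >= 2 polities, got {n}")
    nbrs = net.neighbor_arrays()
    if not params.autarky:
        isolated = [i for i, nb in enumerate(nbrs) if nb.size == 0]
        if isolated:
            raise NoNeighbourError(
                f"polities {isolated} have no neighbours (set autarky=True to allow)"
            )
    if rng is None:
        rng = np.random.default_rng(params.seed % SEED_MOD)
    T = params.n_time_steps
    z = draw_initial_inequality(n, params, rng)
    means = np.empty(T + 1)
    means[0] = z.mean()
    full = None
    if params.record_full:
        full = np.empty((T + 1, n))
        full[0] = z
    one_minus_cm = 1.0 - params.c_m
    mu_r = params.mu_r
    eps = params.epsilon
    # hot loop: local bindings, arithmetic identical to the single-step ops
    integers = rng.integers
    random = rng.random
    uniform = rng.uniform
    for t in range(1, T + 1):
        for _ in range(n):
            i = integers(0, n)
            nb = nbrs[i]
            if nb.size:
                zi = 1.0 - one_minus_cm * (1.0 - z[nb]).max()
            else:
                zi = 1.0
            if random() < mu_r:
                zi = zi + uniform(-eps, eps)
                if zi > 1.0:
                    zi = 1.0
                elif zi < 0.0:
                    zi = 0.0
            z[i] = zi
        means[t] = z.mean()
        if full is not None:
            full[t] = z
    return Trajectory(
        mean_z=means,
        z_full=full,
        params=params,
        network_info={"n_polities": n, "n_edges": net.n_edges},
    )


# ===========================================================================
# Experiments: replicate ensembles, summaries, sweeps, scenarios
# ===========================================================================


@dataclass
class EnsembleSummary:
    """Replicate-averaged statistics of one experimental condition."""

    n_replicates: int
    replicate_seeds: tuple[int, ...]
    mean_trajectory: np.ndarray            # (T+1,), mean over replicates
    rep_mean_trajectories: np.ndarray      # (R, T+1), per-replicate mean z
    last_k: int
    equilibrium_by_replicate: np.ndarray   # (R,)
    equilibrium_mean: float
    equilibrium_sd: float
    time_to_threshold: np.ndarray | None   # (R,), NaN when never crossed
    threshold: float | None
    params: SimParams
    net_spec: NetworkSpec | dict[str, Any]

    @property
    def equilibrium_se(self) -> float:
        return self.equilibrium_sd / math.sqrt(self.n_replicates)


@dataclass
class SweepResult:
    """Cartesian-product parameter sweep output.

    ``cells`` holds one row per parameter combination with the equilibrium
    mean and its replicate dispersion; ``replicates`` is the tidy
    per-(cell, replicate) table.
    """

    param_names: tuple[str, ...]
    cells: pd.DataFrame
    replicates: pd.DataFrame
    summaries: list[EnsembleSummary]


def _replicate_seeds(base_seed: int, n_replicates: int) -> tuple[int, ...]:
    return tuple((base_seed + r) % SEED_MOD for r in range(n_replicates))


def _resolve_last_k(last_k: int | None, series_len: int) -> int:
    if last_k is None:
        last_k = DEFAULT_LAST_K if series_len > DEFAULT_LAST_K else max(1, series_len // 2)
    if last_k < 1 or last_k >= series_len:
        raise InvalidParameterError(
            f"last_k must be in [1, trajectory length), got {last_k} for length {series_len}"
        )
    return last_k


def run_replicates(
    net_spec: PolityNetwork | NetworkSpec,
    params: SimParams,
    n_replicates: int,
    *,
    last_k: int | None = None,
    threshold: float | None = None,
    threshold_mode: str = "mean",
    replicate_seeds: Sequence[int] | None = None,
    fresh_network_per_replicate: bool = True,
) -> EnsembleSummary:
    """Run an ensemble of independent replicates and aggregate.

    Replicate ``r`` uses seed ``params.seed + r``.  For random network
    families (islands, valleys) a fresh network is drawn per replicate from
    the replicate's own stream (disable with
    ``fresh_network_per_replicate=False`` to reuse one draw).
    """
    if n_replicates < 1:
        raise InvalidParameterError(f"n_replicates must be >= 1, got {n_replicates}")
    if replicate_seeds is not None:
        seeds = tuple(int(s) % SEED_MOD for s in replicate_seeds)
        if len(seeds) != n_replicates:
            raise InvalidParameterError("replicate_seeds length must equal n_replicates")
    else:
        seeds = _replicate_seeds(params.seed, n_replicates)

    fixed_net: PolityNetwork | None = None
    if isinstance(net_spec, PolityNetwork):
        fixed_net = net_spec
        provenance: NetworkSpec | dict[str, Any] = {
            "family": "explicit",
            "n_polities": net_spec.n_polities,
            "n_edges": net_spec.n_edges,
        }
    elif isinstance(net_spec, NetworkSpec):
        net_spec.validate()
        provenance = net_spec
        if not (net_spec.is_random and fresh_network_per_replicate):
            fixed_net = build_network(net_spec, np.random.default_rng(params.seed % SEED_MOD))
    else:
        raise InvalidParameterError(f"net_spec must be PolityNetwork or NetworkSpec, got {type(net_spec)}")

    trajectories: list[Trajectory] = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        net = fixed_net if fixed_net is not None else build_network(net_spec, rng)
        trajectories.append(run(net, replace(params, seed=seed), rng=rng))

    rep = np.vstack([t.mean_z for t in trajectories])
    lk = _resolve_last_k(last_k, rep.shape[1])
    eq_by_rep = rep[:, -lk:].mean(axis=1)
    times = None
    if threshold is not None:
        times = np.array(
            [
                float(t) if (t := time_to_threshold(traj, threshold, threshold_mode)) is not None
                else np.nan
                for traj in trajectories
            ]
        )
    return EnsembleSummary(
        n_replicates=n_replicates,
        replicate_seeds=seeds,
        mean_trajectory=rep.mean(axis=0),
        rep_mean_trajectories=rep,
        last_k=lk,
        equilibrium_by_replicate=eq_by_rep,
        equilibrium_mean=float(eq_by_rep.mean()),
        equilibrium_sd=float(eq_by_rep.std(ddof=1)) if n_replicates > 1 else 0.0,
        time_to_threshold=times,
        threshold=threshold,
        params=params,
        net_spec=provenance,
    )


def equilibrium_mean(obj: Trajectory | EnsembleSummary, last_k: int) -> float:
    """Mean population-mean inequality over the final ``last_k`` time steps
    (and over replicates for an ensemble)."""
    series = obj.mean_trajectory if isinstance(obj, EnsembleSummary) else obj.mean_z
    if last_k < 1 or last_k >= len(series):
        raise InvalidParameterError(
            f"last_k must be in [1, trajectory length), got {last_k} for length {len(series)}"
        )
    return float(series[-last_k:].mean())


def time_to_threshold(traj: Trajectory, theta: float, mode: str = "mean") -> int | None:
    """First time step at which inequality crosses ``theta``; None if never.

    ``mode='mean'`` uses the population mean; ``mode='all_polities'``
    requires full recording and uses the per-step minimum over polities
    (every dominant has reached the threshold).
    """
    if not 0.0 <= theta <= 1.0:
        raise InvalidParameterError(f"theta must be in [0, 1], got {theta}")
    if mode == "mean":
        series = traj.mean_z
    elif mode == "all_polities":
        if traj.z_full is None:
            raise InvalidRequestError(
                "mode='all_polities' requires a trajectory recorded with record_full=True"
            )
        series = traj.z_full.min(axis=1)
    else:
        raise InvalidParameterError(f"mode must be 'mean' or 'all_polities', got {mode!r}")
    hits = np.flatnonzero(series >= theta)
    return int(hits[0]) if hits.size else None


_SWEEP_SEED_STRIDE = 100_003  # prime stride separating per-cell seed blocks


def sweep(
    param_grid: Mapping[str, Sequence[Any]],
    base_params: SimParams,
    net_spec: NetworkSpec,
    n_replicates: int,
    *,
    last_k: int | None = None,
    fresh_network_per_replicate: bool = True,
) -> SweepResult:
    """Cartesian-product sweep over dynamics and/or network parameters.

    Grid keys may name any :class:`SimParams` field (except ``seed``) or any
    :class:`NetworkSpec` field.  Cells are visited in the deterministic
    row-major order of the given grids; cell ``c`` runs with base seed
    ``base_seed + 100003 * c`` so replicate streams never collide across
    cells of desk-scale sweeps.
    """
    if not param_grid:
        raise InvalidParameterError("param_grid must name at least one parameter")
    names = list(param_grid.keys())
    grids = []
    for name, values in param_grid.items():
        values = list(values)
        if not values:
            raise InvalidParameterError(f"grid for {name!r} is empty")
        grids.append(values)
    sim_fields = {f.name for f in dataclasses.fields(SimParams)} - {"seed"}
    net_fields = {f.name for f in dataclasses.fields(NetworkSpec)}
    for name in names:
        if name not in sim_fields and name not in net_fields:
            raise InvalidParameterError(f"unknown sweep parameter {name!r}")

    cell_rows = []
    rep_rows = []
    summaries = []
    for idx, combo in enumerate(itertools.product(*grids)):
        cell = dict(zip(names, combo))
        cell_seed = (base_params.seed + _SWEEP_SEED_STRIDE * idx) % SEED_MOD
        p = replace(
            base_params,
            seed=cell_seed,
            **{k: v for k, v in cell.items() if k in sim_fields},
        )
        ns = replace(net_spec, **{k: v for k, v in cell.items() if k in net_fields})
        log.info("sweep cell %d/%d: %s", idx + 1, math.prod(len(g) for g in grids), cell)
        summary = run_replicates(
            ns, p, n_replicates,
            last_k=last_k, fresh_network_per_replicate=fresh_network_per_replicate,
        )
        summaries.append(summary)
        cell_rows.append(
            {
                "cell_index": idx,
                **cell,
                "seed": cell_seed,
                "n_replicates": n_replicates,
                "equilibrium_mean": summary.equilibrium_mean,
                "equilibrium_sd": summary.equilibrium_sd,
            }
        )
        for r, (rep_seed, eq) in enumerate(
            zip(summary.replicate_seeds, summary.equilibrium_by_replicate)
        ):
            rep_rows.append(
                {"cell_index": idx, **cell, "replicate": r, "seed": rep_seed,
                 "equilibrium": float(eq)}
            )
    return SweepResult(
        param_names=tuple(names),
        cells=pd.DataFrame(cell_rows),
        replicates=pd.DataFrame(rep_rows),
        summaries=summaries,
    )


def scenario_spec(
    name: str,
    n_polities: int = 50,
    *,
    islands_n_cliques: int = DEFAULT_ISLANDS_CLIQUES,
    valleys_n_cliques: int = DEFAULT_VALLEYS_CLIQUES,
    between_topology: str = "chain",
) -> NetworkSpec:
    """NetworkSpec for one of the named geographic scenarios."""
    if name == "plain":
        return NetworkSpec(family="complete", n_polities=n_polities)
    if name == "islands":
        return NetworkSpec(family="islands", n_polities=n_polities,
                           n_cliques=islands_n_cliques, between_topology=between_topology)
    if name == "valleys":
        return NetworkSpec(family="valleys", n_polities=n_polities,
                           n_cliques=valleys_n_cliques, between_topology=between_topology)
    raise InvalidParameterError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")


def scenario_compare(
    scenarios: Sequence[str],
    params: SimParams,
    n_replicates: int,
    *,
    n_polities: int = 50,
    islands_n_cliques: int = DEFAULT_ISLANDS_CLIQUES,
    valleys_n_cliques: int = DEFAULT_VALLEYS_CLIQUES,
    last_k: int | None = None,
    fresh_network_per_replicate: bool = True,
) -> dict[str, EnsembleSummary]:
    """Run the plain / islands / valleys scenarios with matched parameters
    and replicate seeds, returning per-scenario summaries."""
    out: dict[str, EnsembleSummary] = {}
    for name in scenarios:
        spec = scenario_spec(
            name, n_polities,
            islands_n_cliques=islands_n_cliques, valleys_n_cliques=valleys_n_cliques,
        )
        log.info("scenario %s: %s", name, spec)
        out[name] = run_replicates(
            spec, params, n_replicates,
            last_k=last_k, fresh_network_per_replicate=fresh_network_per_replicate,
        )
    return out


# ===========================================================================
# Configuration and file I/O
# ===========================================================================


@dataclass(frozen=True)
class ExperimentConfig:
    """Ensemble-level settings: replicate count, equilibrium window, sweeps."""

    n_replicates: int = DEFAULT_N_REPLICATES
    last_k: int = DEFAULT_LAST_K
    scenarios: tuple[str, ...] = SCENARIOS
    sweep: dict[str, list[Any]] | None = None
    threshold: float | None = None
    threshold_mode: str = "mean"
    fresh_network_per_replicate: bool = True

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigValidationError(f"n_replicates must be >= 1, got {self.n_replicates}")
        if self.last_k < 1:
            raise ConfigValidationError(f"last_k must be >= 1, got {self.last_k}")
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ConfigValidationError(f"unknown scenario {s!r}; expected subset of {SCENARIOS}")


@dataclass(frozen=True)
class OutputConfig:
    directory: str = "results"


@dataclass(frozen=True)
class RunConfig:
    """Fully validated configuration: seed + one section per module."""

    seed: int = 0
    network: NetworkSpec = NetworkSpec(n_polities=49)
    dynamics: SimParams = SimParams()
    experiment: ExperimentConfig = ExperimentConfig()
    output: OutputConfig = OutputConfig()


_TOP_KEYS = {"seed", "network", "dynamics", "experiment", "output"}


def _check_section(section: str, raw: Mapping[str, Any], allowed: set[str]) -> None:
    for key in raw:
        if key not in allowed:
            raise ConfigValidationError(f"unknown key {key!r} in section {section!r}")


def config_from_dict(raw: Mapping[str, Any]) -> RunConfig:
    """Validate a parsed mapping into a :class:`RunConfig` with defaults filled."""
    if not isinstance(raw, Mapping):
        raise ConfigParseError(f"configuration must be a mapping, got {type(raw).__name__}")
    for key in raw:
        if key not in _TOP_KEYS:
            raise ConfigValidationError(f"unknown top-level key {key!r}")
    seed = int(raw.get("seed", 0))

    net_raw = dict(raw.get("network") or {})
    dyn_raw = dict(raw.get("dynamics") or {})
    # the network owns n_polities; accept it under dynamics as an alias
    if "n_polities" in dyn_raw:
        net_raw.setdefault("n_polities", dyn_raw.pop("n_polities"))
    net_fields = {f.name for f in dataclasses.fields(NetworkSpec)}
    _check_section("network", net_raw, net_fields)
    dyn_fields = {f.name for f in dataclasses.fields(SimParams)} - {"seed"}
    _check_section("dynamics", dyn_raw, dyn_fields)
    exp_raw = dict(raw.get("experiment") or {})
    exp_fields = {f.name for f in dataclasses.fields(ExperimentConfig)}
    _check_section("experiment", exp_raw, exp_fields)
    out_raw = dict(raw.get("output") or {})
    _check_section("output", out_raw, {f.name for f in dataclasses.fields(OutputConfig)})

    try:
        network = NetworkSpec(**net_raw)
        network.validate()
        dynamics = SimParams(seed=seed, **dyn_raw)
        if "scenarios" in exp_raw:
            exp_raw["scenarios"] = tuple(exp_raw["scenarios"])
        experiment = ExperimentConfig(**exp_raw)
        output = OutputConfig(**out_raw)
    except InvalidParameterError as exc:
        raise ConfigValidationError(str(exc)) from exc
    if experiment.last_k >= dynamics.n_time_steps + 1:
        raise ConfigValidationError(
            f"last_k ({experiment.last_k}) must be smaller than the trajectory length "
            f"({dynamics.n_time_steps + 1})"
        )
    return RunConfig(seed=seed, network=network, dynamics=dynamics,
                     experiment=experiment, output=output)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigParseError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    return config_from_dict(raw)


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    """Normalized plain-dict form of a config (inverse of :func:`config_from_dict`)."""
    return {
        "seed": cfg.seed,
        "network": _jsonable(dataclasses.asdict(cfg.network)),
        "dynamics": {k: v for k, v in _jsonable(dataclasses.asdict(cfg.dynamics)).items()
                     if k != "seed"},
        "experiment": _jsonable(dataclasses.asdict(cfg.experiment)),
        "output": dataclasses.asdict(cfg.output),
    }


def dump_config(cfg: RunConfig) -> str:
    """Canonical YAML text for a config; load(dump(cfg)) == cfg."""
    return yaml.safe_dump(config_to_dict(cfg), sort_keys=False)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Tabular view: time_step, mean_z and, when recorded, z_0 ... z_{P-1}."""
    data: dict[str, Any] = {
        "time_step": np.arange(len(traj.mean_z)),
        "mean_z": traj.mean_z,
    }
    if traj.z_full is not None:
        for p in range(traj.z_full.shape[1]):
            data[f"z_{p}"] = traj.z_full[:, p]
    return pd.DataFrame(data)


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> list[Path]:
    """Write a trajectory CSV plus a JSON metadata sidecar; returns both paths."""
    path = Path(path)
    trajectory_frame(traj).to_csv(path, index=False, lineterminator="\n")
    sidecar = path.with_suffix(".json")
    meta = {
        "version": __version__,
        "seed": traj.params.seed,
        "params": _jsonable(dataclasses.asdict(traj.params)),
        "network": _jsonable(traj.network_info),
    }
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return [path, sidecar]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _ensemble_frames(summary: EnsembleSummary) -> tuple[pd.DataFrame, pd.DataFrame]:
    T1 = summary.mean_trajectory.shape[0]
    traj = {"time_step": np.arange(T1), "mean_z": summary.mean_trajectory}
    for r in range(summary.n_replicates):
        traj[f"rep_{r}"] = summary.rep_mean_trajectories[r]
    eq = pd.DataFrame(
        {
            "replicate": np.arange(summary.n_replicates),
            "seed": list(summary.replicate_seeds),
            "equilibrium": summary.equilibrium_by_replicate,
        }
    )
    if summary.time_to_threshold is not None:
        eq["time_to_threshold"] = summary.time_to_threshold
    return pd.DataFrame(traj), eq


def _summary_stats(summary: EnsembleSummary) -> dict[str, Any]:
    return {
        "n_replicates": summary.n_replicates,
        "last_k": summary.last_k,
        "equilibrium_mean": summary.equilibrium_mean,
        "equilibrium_sd": summary.equilibrium_sd,
        "equilibrium_se": summary.equilibrium_se,
        "final_mean": float(summary.mean_trajectory[-1]),
    }


def write_summary(
    summary: EnsembleSummary | SweepResult | Mapping[str, EnsembleSummary],
    out_dir: str | Path,
    extra_metadata: Mapping[str, Any] | None = None,
) -> dict[str, Any]:
    """Write an experiment's outputs to ``out_dir`` with deterministic names.

    CSVs hold the tables, ``metadata.json`` the provenance (parameters, seed,
    version, plus any ``extra_metadata`` such as a config echo), and
    ``manifest.json`` lists every file written with its SHA-256 checksum.
    Returns the manifest mapping.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    meta: dict[str, Any] = {"version": __version__}
    if extra_metadata:
        meta.update(_jsonable(dict(extra_metadata)))

    if isinstance(summary, EnsembleSummary):
        traj_df, eq_df = _ensemble_frames(summary)
        p = out_dir / "trajectory.csv"
        traj_df.to_csv(p, index=False, lineterminator="\n")
        written.append(p)
        p = out_dir / "equilibrium.csv"
        eq_df.to_csv(p, index=False, lineterminator="\n")
        written.append(p)
        meta.update(
            {
                "kind": "ensemble",
                "seed": summary.params.seed,
                "params": _jsonable(dataclasses.asdict(summary.params)),
                "network": _jsonable(summary.net_spec),
                "summary": _jsonable(_summary_stats(summary)),
            }
        )
    elif isinstance(summary, SweepResult):
        p = out_dir / "sweep_cells.csv"
        summary.cells.to_csv(p, index=False, lineterminator="\n")
        written.append(p)
        p = out_dir / "sweep_replicates.csv"
        summary.replicates.to_csv(p, index=False, lineterminator="\n")
        written.append(p)
        first = summary.summaries[0]
        meta.update(
            {
                "kind": "sweep",
                "param_names": list(summary.param_names),
                "seed": first.params.seed,
                "base_params": _jsonable(dataclasses.asdict(first.params)),
            }
        )
    elif isinstance(summary, Mapping):
        stats = {}
        for name in sorted(summary):
            ens = summary[name]
            traj_df, eq_df = _ensemble_frames(ens)
            p = out_dir / f"{name}_trajectory.csv"
            traj_df.to_csv(p, index=False, lineterminator="\n")
            written.append(p)
            p = out_dir / f"{name}_equilibrium.csv"
            eq_df.to_csv(p, index=False, lineterminator="\n")
            written.append(p)
            stats[name] = _jsonable(_summary_stats(ens))
        p = out_dir / "scenario_summary.json"
        p.write_text(json.dumps(stats, indent=2, sort_keys=True) + "\n")
        written.append(p)
        any_summary = next(iter(summary.values()))
        meta.update(
            {
                "kind": "scenario",
                "seed": any_summary.params.seed,
                "params": _jsonable(dataclasses.asdict(any_summary.params)),
                "scenarios": sorted(summary),
                "summary": stats,
            }
        )
    else:
        raise InvalidParameterError(f"cannot write a summary of type {type(summary)}")

    p = out_dir / "metadata.json"
    p.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    written.append(p)
    manifest = {
        "files": [
            {"path": f.name, "sha256": _sha256(f)} for f in sorted(written, key=lambda f: f.name)
        ]
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ===========================================================================
# Plot helpers (thin conveniences; experiments return the underlying tables)
# ===========================================================================


def plot_mean_trajectories(summaries: Mapping[str, EnsembleSummary], ax=None):
    """Replicate-averaged inequality vs time, one line per labelled condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, summary in summaries.items():
        ax.plot(summary.mean_trajectory, label=label)
    ax.set_xlabel("time step")
    ax.set_ylabel("average inequality $z$")
    ax.set_ylim(0, 1.05)
    ax.legend()
    return ax


def plot_sweep_heatmap(result: SweepResult, x: str, y: str, ax=None):
    """Equilibrium-mean heatmap over a two-parameter sweep."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pivot = result.cells.pivot_table(index=y, columns=x, values="equilibrium_mean")
    im = ax.imshow(pivot.to_numpy(), origin="lower", aspect="auto", vmin=0, vmax=1)
    ax.set_xticks(range(pivot.shape[1]), [str(v) for v in pivot.columns])
    ax.set_yticks(range(pivot.shape[0]), [str(v) for v in pivot.index])
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.figure.colorbar(im, ax=ax, label="equilibrium mean inequality")
    return ax
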