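"""Independent oracles and small graph builders shared across tests.

The replay oracle re-implements the update process naively (python lists,
direct formula, same documented draw order) so simulator trajectories can be
checked bit-for-bit against code that shares nothing with the hot loop.
"""

from __future__ import annotations

import numpy as np

import circumskew as cs


def path_net(n: int) -> cs.PolityNetwork:
    return cs.PolityNetwork.from_edges(n, [(i, i + 1) for i in range(n - 1)])


def ring_net(n: int) -> cs.PolityNetwork:
    return cs.PolityNetwork.from_edges(n, [(i, (i + 1) % n) for i in range(n)])


def star_net(n: int) -> cs.PolityNetwork:
    return cs.PolityNetwork.from_edges(n, [(0, i) for i in range(1, n)])


def random_connected_net(n: int, n_edges: int, seed: int) -> cs.PolityNetwork:
    """Connected Erdos-Renyi-style graph via rejection on connectivity."""
    import networkx as nx

    for attempt in range(1000):
        g = nx.gnm_random_graph(n, n_edges, seed=seed + attempt)
        if nx.is_connected(g):
            return cs.PolityNetwork.from_edges(n, g.edges())
    raise AssertionError("could not draw a connected graph")


def naive_replay(net: cs.PolityNetwork, params: cs.SimParams) -> list[float]:
    """Brute-force re-simulation: same seed and draw order, independent code.

    Returns the final per-polity inequality as plain python floats.
    """
    rng = np.random.default_rng(params.seed % cs.SEED_MOD)
    n = net.n_polities
    z = [float(v) for v in rng.uniform(params.z0_low, params.z0_high, size=n)]
    nbrs: list[list[int]] = [[] for _ in range(n)]
    for i, j in net.edges:
        nbrs[i].append(j)
        nbrs[j].append(i)
    for _ in range(params.n_time_steps):
        for _ in range(n):
            i = int(rng.integers(0, n))
            zi = 1.0 - (1.0 - params.c_m) * max(1.0 - z[j] for j in nbrs[i])
            if rng.random() < params.mu_r:
                zi = zi + rng.uniform(-params.epsilon, params.epsilon)
                zi = min(1.0, max(0.0, zi))
            z[i] = zi
    return z


def min_survives_schedule(net: cs.PolityNetwork, params: cs.SimParams) -> bool:
    """Whether the update schedule lets the initial minimum inequality persist.

    Valid for epsilon = 0 (shocks never move z).  Tracks the set of polities
    currently holding the running minimum: an updating polity joins the set
    iff one of its neighbours holds the minimum; the minimum is lost iff the
    holder set empties.  Pure function of the seed and the network — it never
    looks at simulator output.
    """
    assert params.epsilon == 0.0
    rng = np.random.default_rng(params.seed % cs.SEED_MOD)
    n = net.n_polities
    z0 = rng.uniform(params.z0_low, params.z0_high, size=n)
    holders = {int(np.argmin(z0))}
    nbrs = [set(map(int, a)) for a in net.neighbor_arrays()]
    for _ in range(params.n_time_steps * n):
        i = int(rng.integers(0, n))
        if rng.random() < params.mu_r:
            rng.uniform(-params.epsilon, params.epsilon)
        if nbrs[i] & holders:
            holders.add(i)
        else:
            holders.discard(i)
            if not holders:
                return False
    return True
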