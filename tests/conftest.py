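import numpy as np
import pytest

import epimap as em


@pytest.fixture(scope="session")
def layout16():
    return em.grid_layout(16, 16, 3.5)


@pytest.fixture(scope="session")
def graph16(layout16):
    return em.build_adjacency(layout16, "grid8")


@pytest.fixture(scope="session")
def sinus_fixture(layout16):
    """Noise-free plane-wave fixture at the default rate/CV, with truth."""
    scenario = em.sinus_scenario(layout16)
    rec, truth = em.render_recording(layout16, scenario, duration_s=2.0, seed=11)
    return rec, truth, scenario


@pytest.fixture
def layout3():
    return em.grid_layout(3, 3, 1.0)


@pytest.fixture
def graph3(layout3):
    return em.build_adjacency(layout3, "grid8")


def brute_force_arrivals(n_nodes, edges, sources):
    """Independent oracle: branch-and-bound enumeration of simple paths.

    ``edges``: iterable of (i, j, weight); ``sources``: list of
    (node, onset).  Returns the earliest arrival per node (inf if cut off).
    """
    adj = {i: [] for i in range(n_nodes)}
    for i, j, w in edges:
        adj[i].append((j, w))
        adj[j].append((i, w))
    best = np.full(n_nodes, np.inf)

    def dfs(node, t, visited):
        if t >= best[node]:
            return
        best[node] = t
        for nxt, w in adj[node]:
            if nxt not in visited:
                dfs(nxt, t + w, visited | {nxt})

    for src, onset in sources:
        dfs(src, onset, {src})
    return best
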