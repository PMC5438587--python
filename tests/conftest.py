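import pytest

import mutualcore as mc


@pytest.fixture(scope="session")
def fig3():
    """The worked 5-plant / 4-disperser seed-dispersal network."""
    return mc.fixture_fig3()


@pytest.fixture(scope="session")
def fig3_table(fig3):
    return mc.compute_all(fig3)


def brute_force_shells(nodes, edges):
    """Independent shell oracle: for each k, delete degree-<k nodes to fixpoint.

    A node's shell is the largest k at which it survives.  Deliberately
    naive; recomputes degrees from scratch at every sweep.
    """
    shell = {n: 0 for n in nodes}
    k = 1
    while True:
        alive = set(nodes)
        es = set(edges)
        while True:
            deg = {n: 0 for n in alive}
            for u, v in es:
                deg[u] += 1
                deg[v] += 1
            drop = {n for n in alive if deg[n] < k}
            if not drop:
                break
            alive -= drop
            es = {(u, v) for u, v in es if u in alive and v in alive}
        if not alive:
            return shell
        for n in alive:
            shell[n] = k
        k += 1
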