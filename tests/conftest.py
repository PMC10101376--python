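import numpy as np
import pytest

from cognimage import apps, make_abdominal_phantom, make_tube_phantom
from cognimage.blackboard import (NOT_FOUND, PENDING, RECOGNIZED, UNRELIABLE,
                                  build_blackboard)
from cognimage.kb import parse_network


@pytest.fixture(scope="session")
def kidney_net(tmp_path_factory):
    return apps.kidney_kb(tmp_path_factory.mktemp("kidney_kb"))


@pytest.fixture(scope="session")
def ett_net(tmp_path_factory):
    return apps.ett_kb(tmp_path_factory.mktemp("ett_kb"))


@pytest.fixture(scope="session")
def abdominal():
    return make_abdominal_phantom(seed=7)


@pytest.fixture(scope="session")
def tube():
    return make_tube_phantom(seed=7)


def make_carina_hook(phantom, offset=(0, 0)):
    """Point-predictor hook returning the truth carina (optionally displaced)."""
    def hook(_image, _spacing):
        mask = np.zeros(phantom.image.shape, dtype=bool)
        y, x = phantom.points["carina"]
        mask[y + offset[0], x + offset[1]] = True
        return mask
    return hook


def random_dag_network(rng, tmp_path, n_nodes=8, p_edge=0.4):
    """A random acyclic network: each node depends (PartOf) on a random
    subset of earlier nodes."""
    files = {}
    names = [f"n{i}" for i in range(n_nodes)]
    for i, name in enumerate(names):
        deps = [names[j] for j in range(i) if rng.random() < p_edge]
        files[name] = "".join(f"PartOf {d}\n" for d in deps)
    apps.write_kb(files, tmp_path)
    return parse_network(tmp_path)


def random_dag_blackboard(rng, tmp_path, n_nodes=8):
    """Blackboard over a random DAG with a random subset of elements already
    in a random terminal status."""
    net = random_dag_network(rng, tmp_path, n_nodes=n_nodes)
    bb = build_blackboard(net, np.zeros((4, 4)), (1.0, 1.0))
    statuses = [RECOGNIZED, NOT_FOUND, UNRELIABLE]
    for el in bb.elements.values():
        if rng.random() < 0.5:
            el.status = statuses[int(rng.integers(len(statuses)))]
    return net, bb


def brute_force_next(net, bb):
    """Independent scheduler oracle: exhaustive max-fraction search straight
    from the node attribute files, ties by Node List order."""
    best, best_frac = None, -1.0
    for node in net.nodes:
        el = bb.elements[node.name]
        if el.status != PENDING:
            continue
        refs = [ref for attr in node.attributes for ref in attr.node_refs()]
        if refs:
            resolved = sum(1 for r in refs if bb.elements[r].status != PENDING)
            frac = resolved / len(refs)
        else:
            frac = 1.0
        if frac > best_frac:
            best, best_frac = node.name, frac
    return best
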