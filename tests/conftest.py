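import numpy as np
import pytest

from galliphylo import trees as T
from galliphylo.simulate import GeneratorConfig, RadiationSpec, generate_dataset

SMALL_LOCI = (
    ("L1", "nuclear", 300),
    ("L2", "nuclear", 450),
    ("L3", "nuclear", 350),
    ("L4", "nuclear", 500),
    ("M1", "mitochondrial", 250),
    ("M2", "mitochondrial", 200),
)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(
        n_taxa=10,
        loci=SMALL_LOCI,
        radiation=RadiationSpec(count=2, length=0.05),
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture
def caterpillar8():
    """Binary 8-leaf caterpillar with supports on every internal edge."""
    return T.parse_newick(
        "(A,B,(C,(D,(E,(F,(G,H)99)98)97)96)95);"
    )


def patristic_matrix(tree):
    """Branch-length path distances between leaves (test oracle helper)."""
    nodes = list(tree.root.postorder())
    adj = {id(nd): [] for nd in nodes}
    for nd in nodes:
        for c in nd.children:
            adj[id(nd)].append((c, c.length or 0.0))
            adj[id(c)].append((nd, c.length or 0.0))
    leaves = sorted((nd for nd in nodes if nd.is_leaf()), key=lambda nd: nd.label)
    taxa = [nd.label for nd in leaves]
    n = len(taxa)
    d = np.zeros((n, n))
    for i, src in enumerate(leaves):
        dist = {id(src): 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[id(u)]:
                if id(v) not in dist:
                    dist[id(v)] = dist[id(u)] + w
                    stack.append(v)
        for j, dst in enumerate(leaves):
            d[i, j] = dist[id(dst)]
    return taxa, d
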