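import random

import pytest
from hypothesis import settings

from rcrnet import (
    ActivityTag,
    CausalEdge,
    CausalGraph,
    Evidence,
    NodeRef,
    Species,
    Subnetwork,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def build_graph(
    name: str,
    edges: list[tuple[str, int, str]],
    evidences: dict[tuple[str, str], list[Evidence]] | None = None,
) -> CausalGraph:
    """Build a graph from (source_label, sign, target_label) triples."""
    from rcrnet import parse_node_label

    g = CausalGraph(name)
    evidences = evidences or {}
    for src, sign, tgt in edges:
        g.add_edge(
            CausalEdge(
                parse_node_label(src),
                sign,
                parse_node_label(tgt),
                tuple(evidences.get((src, tgt), ())),
            )
        )
    return g


def random_graph(seed: int, n_controllers: int = 8, n_genes: int = 30) -> CausalGraph:
    """Small random bipartite causal graph with evidence annotations."""
    rng = random.Random(seed)
    g = CausalGraph(f"rand{seed}")
    tags = [ActivityTag.KINASE_ACTIVITY, ActivityTag.TRANSCRIPTIONAL_ACTIVITY,
            ActivityTag.CATALYTIC_ACTIVITY, ActivityTag.ABUNDANCE]
    for i in range(n_controllers):
        src = NodeRef(f"U{i}", rng.choice(tags))
        for j in rng.sample(range(n_genes), rng.randint(1, 6)):
            evs = tuple(
                Evidence(
                    citation_id=str(rng.randint(10_000_000, 99_999_999)),
                    species=rng.choice(list(Species)[:3]),
                    context_keywords=frozenset(
                        rng.sample(["endothelial cells", "aorta", "HeLa", "platelet"],
                                   rng.randint(0, 2))
                    ),
                )
                for _ in range(rng.randint(0, 2))
            )
            g.add_edge(
                CausalEdge(
                    src,
                    rng.choice([-1, 1, 1]),
                    NodeRef(f"G{j}", ActivityTag.RNA_EXPRESSION),
                    evs,
                )
            )
    return g


@pytest.fixture
def toy_subnetwork() -> Subnetwork:
    g = build_graph(
        "toy",
        [
            ("taof(NFKB1)", 1, "exp(CXCL1)"),
            ("taof(NFKB1)", 1, "exp(IL6)"),
            ("taof(NFKB1)", -1, "exp(KLF2)"),
            ("kaof(Chuk)", 1, "exp(CXCL1)"),
            ("kaof(Chuk)", 0, "exp(VCAM1)"),
        ],
    )
    return Subnetwork("toy", g)
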