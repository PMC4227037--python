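"""Synthetic causal knowledgebases and planted-perturbation experiments.

The generator emulates the statistical shape of a curated causal
knowledgebase paired with a transcriptomics experiment, so the whole
pipeline — possible-HYP enumeration, richness/concordance scoring, and the
coverage / odds-ratio subnetwork evaluation — is testable end to end with
known ground truth:

* a bipartite controller -> RNA-expression graph (depth 1, matching the
  hypothesis model) with a knowledgebase-scale number of controllers,
  Poisson out-degrees and signed edges;
* a planted perturbation: a small set of active controllers with chosen
  directions whose downstream transcripts change accordingly, corrupted by
  sign-flip noise, silencing, and a genome-wide background change rate;
* subnetwork assignments in which active controllers enter with an odds
  multiplier rho, planting the enrichment that the evaluation statistics
  are supposed to detect (rho = 1 is the null).

All randomness flows from a single integer seed through spawned NumPy
generators, so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kbase import CausalEdge, CausalGraph, NodeRef, ActivityTag
from .state_changes import StateChange

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_kb",
    "simulate_experiment",
    "assign_subnetworks",
]


@dataclass
class SynthConfig:
    """Study-condition parameters of the synthetic generator.

    Defaults emulate the scale of a knowledgebase-backed evaluation: ~2,400
    scorable controllers over a ~10,000-gene measured universe, a few
    hundred truly active controllers, and six subnetworks of a few dozen
    possible HYPs each.
    """

    n_controllers: int = 2400
    n_rna: int = 10000
    downstream_mean: float = 25.0
    negative_sign_prob: float = 0.3
    n_active: int = 300
    flip_noise: float = 0.05
    silence_prob: float = 0.10
    background_rate: float = 0.01
    n_subnets: int = 6
    subnet_size: int = 60
    enrichment: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "negative_sign_prob": self.negative_sign_prob,
            "flip_noise": self.flip_noise,
            "silence_prob": self.silence_prob,
            "background_rate": self.background_rate,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]; got {p}")
        if self.flip_noise + self.silence_prob >= 1.0:
            raise ValueError("flip_noise + silence_prob must be < 1")
        if not (0 <= self.n_active <= self.n_controllers):
            raise ValueError("n_active must be in [0, n_controllers]")
        if not (0 < self.subnet_size <= self.n_controllers):
            raise ValueError("subnet_size must be in (0, n_controllers]")
        if self.downstream_mean < 1 or self.enrichment <= 0:
            raise ValueError("downstream_mean must be >= 1 and enrichment > 0")
        # leave Poisson headroom so sampled out-degrees fit in the universe
        if self.downstream_mean + 8 * self.downstream_mean**0.5 > self.n_rna:
            raise ValueError(
                f"n_rna={self.n_rna} too small for downstream_mean="
                f"{self.downstream_mean}"
            )


@dataclass
class GroundTruth:
    """Planted perturbation: active controllers and subnetwork memberships."""

    active: dict[str, int]
    memberships: dict[str, set[str]] = field(default_factory=dict)


def _rng(config: SynthConfig, stream: int, seed: int | None) -> np.random.Generator:
    base = config.seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence([int(base), stream]))


def controller_label(i: int) -> str:
    return f"kaof(C{i:05d})"


def gene_symbol(j: int) -> str:
    return f"G{j:05d}"


def generate_kb(config: SynthConfig, seed: int | None = None) -> tuple[CausalGraph, GroundTruth]:
    """Generate a bipartite signed controller -> exp(gene) graph.

    Out-degrees are Poisson(``downstream_mean``) truncated at >= 1; edge
    signs are -1 with probability ``negative_sign_prob`` and +1 otherwise.
    The planted active set (``n_active`` controllers, direction +-1 uniform)
    is returned as ground truth.  Deterministic per seed.
    """
    rng = _rng(config, 0, seed)
    graph = CausalGraph("synthetic_kb")
    genes = [NodeRef(gene_symbol(j), ActivityTag.RNA_EXPRESSION)
             for j in range(config.n_rna)]
    degrees = rng.poisson(config.downstream_mean, size=config.n_controllers)
    degrees = np.clip(degrees, 1, config.n_rna)
    for i in range(config.n_controllers):
        upstream = NodeRef(f"C{i:05d}", ActivityTag.KINASE_ACTIVITY)
        targets = rng.choice(config.n_rna, size=int(degrees[i]), replace=False)
        signs = np.where(rng.random(len(targets)) < config.negative_sign_prob, -1, 1)
        for j, s in zip(targets, signs):
            graph.add_edge(CausalEdge(upstream, int(s), genes[j]))
    active_idx = rng.choice(config.n_controllers, size=config.n_active, replace=False)
    directions = np.where(rng.random(config.n_active) < 0.5, -1, 1)
    active = {
        controller_label(int(i)): int(d)
        for i, d in sorted(zip(active_idx, directions))
    }
    return graph, GroundTruth(active=active)


def simulate_experiment(
    kb: CausalGraph,
    truth: GroundTruth,
    config: SynthConfig,
    seed: int | None = None,
) -> list[StateChange]:
    """Simulate State Changes from the planted perturbation.

    A transcript downstream of an active controller (edge sign s, controller
    direction delta) has implied direction s * delta; transcripts with
    several active parents resolve by majority of implied signs (tie -> no
    implied direction).  An implied transcript changes to its implied
    direction with probability 1 - flip_noise - silence_prob, to the
    opposite with probability flip_noise, and stays 0 otherwise.
    Transcripts with no implied direction change at ``background_rate`` with
    a uniform random direction.  Every gene of the universe is reported
    (direction 0 included).  Deterministic per seed.
    """
    unknown = sorted(set(truth.active) - kb.node_labels())
    if unknown:
        raise ValueError("active controllers absent from graph: " + ", ".join(unknown))
    rng = _rng(config, 1, seed)
    implied_votes: dict[str, int] = {}
    for edge in kb.edges:
        delta = truth.active.get(edge.source.label)
        if delta is None or edge.sign == 0:
            continue
        gene = edge.target.entity_symbol
        implied_votes[gene] = implied_votes.get(gene, 0) + edge.sign * delta
    out = []
    for j in range(config.n_rna):
        gene = gene_symbol(j)
        vote = implied_votes.get(gene, 0)
        u = rng.random()
        if vote != 0:
            implied = 1 if vote > 0 else -1
            if u < 1.0 - config.flip_noise - config.silence_prob:
                d = implied
            elif u < 1.0 - config.silence_prob:
                d = -implied
            else:
                d = 0
        else:
            d = 0
            if u < config.background_rate:
                d = 1 if rng.random() < 0.5 else -1
        out.append(StateChange(gene, d))
    return out


def assign_subnetworks(
    kb: CausalGraph,
    truth: GroundTruth,
    config: SynthConfig,
    seed: int | None = None,
) -> dict[str, set[str]]:
    """Sample subnetwork possible-HYP sets with planted enrichment.

    Each of ``n_subnets`` subnetworks draws ``subnet_size`` controllers
    without replacement, with active controllers entering at the odds
    multiplier ``enrichment`` (rho); rho = 1 is the unenriched null.  The
    number of active members is drawn from Fisher's noncentral
    hypergeometric distribution with odds rho — the sampling law whose
    enrichment odds ratio is exactly rho — and the members themselves are
    then uniform within each stratum.  Memberships are recorded on
    ``truth`` and returned.  Deterministic per seed.
    """
    from scipy import stats

    rng = _rng(config, 2, seed)
    labels = [controller_label(i) for i in range(config.n_controllers)]
    active = np.array([lab in truth.active for lab in labels])
    act_idx = np.flatnonzero(active)
    inact_idx = np.flatnonzero(~active)
    labels = np.array(labels)
    memberships: dict[str, set[str]] = {}
    for s in range(config.n_subnets):
        lo = max(0, config.subnet_size - len(inact_idx))
        hi = min(len(act_idx), config.subnet_size)
        if config.enrichment == 1.0:
            n_act = int(
                rng.hypergeometric(len(act_idx), len(inact_idx), config.subnet_size)
            )
        else:
            n_act = int(
                stats.nchypergeom_fisher.rvs(
                    config.n_controllers,
                    len(act_idx),
                    config.subnet_size,
                    config.enrichment,
                    random_state=rng,
                )
            )
        n_act = min(max(n_act, lo), hi)
        chosen = np.concatenate(
            [
                rng.choice(act_idx, size=n_act, replace=False),
                rng.choice(inact_idx, size=config.subnet_size - n_act, replace=False),
            ]
        )
        memberships[f"SN{s}"] = set(labels[chosen])
    truth.memberships = memberships
    return memberships
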