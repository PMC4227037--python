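"""Reverse causal reasoning: upstream-controller enumeration and scoring.

A hypothesis (HYP) is a candidate upstream controller together with the
signed causal edges linking it to measured RNA-expression nodes at depth 1.
Each HYP is scored against the dataset's State Changes with two one-sided
exact tail probabilities:

* **richness** — hypergeometric P(X >= x) that x of the HYP's k measured
  downstream transcripts changed, when n of the N measured transcripts
  changed overall.  Low richness means the HYP's neighbourhood is unusually
  loaded with changed genes.
* **concordance** — binomial P(X >= c | m, p0) that c of the m changed,
  sign-informative downstream transcripts moved in the direction the HYP
  orientation implies (p0 = 0.5 by default).  Low concordance means the
  changes consistently agree with one orientation of the controller.

Both orientations (controller increased / decreased) are scored; the
direction call is the orientation with the smaller concordance tail, with
ties reported as ambiguous.  A HYP is significant when both p-values fall
below the cutoff (0.05 by default, uncorrected — an optional
Benjamini-Hochberg adjustment is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .kbase import ActivityTag, CausalGraph, NodeRef

__all__ = [
    "Hyp",
    "HypScore",
    "enumerate_possible_hyps",
    "richness_p",
    "concordance_p",
    "score_hyp",
    "run_rcr",
]

DIRECTION_INCREASED = "increased"
DIRECTION_DECREASED = "decreased"
DIRECTION_AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class Hyp:
    """An upstream controller with its measured signed downstream transcripts.

    ``downstream`` holds ``(gene_id, expected_sign)`` pairs, where the
    expected sign is the causal-edge sign for the controller-increased
    orientation (+1 increases, -1 decreases, 0 ambiguous).
    """

    upstream: NodeRef
    downstream: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.downstream]
        if len(genes) != len(set(genes)):
            raise ValueError(
                f"duplicate downstream gene_ids in HYP {self.upstream.label}"
            )
        if any(s not in (-1, 0, 1) for _, s in self.downstream):
            raise ValueError("expected signs must be -1, 0 or +1")

    @property
    def k(self) -> int:
        return len(self.downstream)


@dataclass(frozen=True)
class HypScore:
    """Scoring result for one HYP against one dataset.

    ``n_correct``/``n_contra`` are counted in the called orientation (for an
    ambiguous call, in the controller-increased orientation), so that
    ``n_correct + n_contra + n_ambiguous == n_changed`` always holds;
    ``n_ambiguous`` counts changed downstreams whose edge sign is ambiguous.
    """

    hyp: Hyp
    n_downstream_measured: int
    n_changed: int
    n_correct: int
    n_contra: int
    n_ambiguous: int
    richness_p: float
    concordance_p: float
    direction: str
    significant: bool

    def __post_init__(self) -> None:
        if self.n_correct + self.n_contra + self.n_ambiguous != self.n_changed:
            raise ValueError("support counts do not sum to n_changed")


def richness_p(x: int, k: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= x).

    Probability of seeing at least ``x`` changed genes among ``k`` measured
    downstream transcripts when ``n`` of the ``N`` measured transcripts
    changed.  Exact tail summation (no normal approximation).
    """
    if not (0 <= x <= k <= N):
        raise ValueError(f"require 0 <= x <= k <= N; got x={x}, k={k}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"require 0 <= n <= N; got n={n}, N={N}")
    if x > n:
        raise ValueError(f"require x <= n; got x={x}, n={n}")
    if x == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(x - 1, N, n, k)))


def concordance_p(n_correct: int, n_informative: int, p0: float = 0.5) -> float:
    """Upper-tail binomial probability P(X >= n_correct | n_informative, p0).

    ``n_informative`` counts changed downstream transcripts with an
    unambiguous expected sign; exact tail summation.
    """
    if not (0 <= n_correct <= n_informative):
        raise ValueError(
            f"require 0 <= n_correct <= n_informative; got {n_correct}, {n_informative}"
        )
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"p0 must be in (0, 1); got {p0}")
    if n_correct == 0:
        return 1.0
    return float(min(1.0, stats.binom.sf(n_correct - 1, n_informative, p0)))


def enumerate_possible_hyps(
    graph: CausalGraph,
    measured_genes: Iterable[str],
    min_downstream: int = 4,
) -> list[Hyp]:
    """Enumerate the "possible HYPs" of a graph for a measured-gene universe.

    A node is a possible HYP when it has at least ``min_downstream`` depth-1
    RNA-expression downstream nodes whose gene symbol was measured.  The
    length of the returned list is the "total number of possible HYPs" for
    this graph/dataset pairing — the universe of the evaluation statistics.
    """
    measured = set(measured_genes)
    if not measured:
        raise ValueError("measured_genes must be non-empty")
    if min_downstream < 1:
        raise ValueError("min_downstream must be >= 1")
    downstream: dict[str, list[tuple[str, int]]] = {}
    for edge in graph.edges:
        if edge.target.activity_tag is not ActivityTag.RNA_EXPRESSION:
            continue
        gene = edge.target.entity_symbol
        if gene not in measured:
            continue
        downstream.setdefault(edge.source.label, []).append((gene, edge.sign))
    hyps = []
    for label in sorted(downstream):
        pairs = downstream[label]
        if len(pairs) >= min_downstream:
            hyps.append(Hyp(graph.nodes[label], tuple(sorted(pairs))))
    return hyps


def score_hyp(
    hyp: Hyp,
    scs: Mapping[str, int],
    p_cut: float = 0.05,
    p0: float = 0.5,
) -> HypScore:
    """Score one HYP against a State-Change mapping.

    ``scs`` must cover the full measured universe (gene -> direction, with 0
    for measured-but-unchanged genes); its size is the richness population N
    and its nonzero count the number of changed genes n.
    """
    missing = [g for g, _ in hyp.downstream if g not in scs]
    if missing:
        raise KeyError(
            f"downstream gene(s) of {hyp.upstream.label} absent from the "
            "State-Change mapping: " + ", ".join(sorted(missing))
        )
    N = len(scs)
    n = sum(1 for d in scs.values() if d != 0)
    changed = correct_up = contra_up = ambiguous = 0
    for gene, expected in hyp.downstream:
        d = scs[gene]
        if d == 0:
            continue
        changed += 1
        if expected == 0:
            ambiguous += 1
        elif d == expected:
            correct_up += 1
        else:
            contra_up += 1
    informative = correct_up + contra_up
    p_up = concordance_p(correct_up, informative, p0)
    p_down = concordance_p(contra_up, informative, p0)
    if p_up < p_down:
        direction, conc, correct, contra = DIRECTION_INCREASED, p_up, correct_up, contra_up
    elif p_down < p_up:
        direction, conc, correct, contra = DIRECTION_DECREASED, p_down, contra_up, correct_up
    else:
        direction, conc, correct, contra = DIRECTION_AMBIGUOUS, p_up, correct_up, contra_up
    rich = richness_p(changed, hyp.k, n, N)
    return HypScore(
        hyp=hyp,
        n_downstream_measured=hyp.k,
        n_changed=changed,
        n_correct=correct,
        n_contra=contra,
        n_ambiguous=ambiguous,
        richness_p=rich,
        concordance_p=conc,
        direction=direction,
        significant=bool(rich < p_cut and conc < p_cut),
    )


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    m = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def run_rcr(
    graph: CausalGraph,
    scs: Mapping[str, int],
    measured_genes: Iterable[str] | None = None,
    p_cut: float = 0.05,
    min_downstream: int = 4,
    p0: float = 0.5,
    bh_adjust: bool = False,
) -> list[HypScore]:
    """Score every possible HYP of ``graph`` against a dataset.

    Returns scores sorted by (richness_p, concordance_p, upstream label),
    deterministically.  With ``bh_adjust`` the significance call (but not
    the reported p-values) uses Benjamini-Hochberg adjusted richness and
    concordance p-values.
    """
    if measured_genes is None:
        measured_genes = scs.keys()
    measured = set(measured_genes)
    if not measured:
        raise ValueError("the measured universe is empty")
    hyps = enumerate_possible_hyps(graph, measured, min_downstream)
    scores = [score_hyp(h, scs, p_cut=p_cut, p0=p0) for h in hyps]
    if bh_adjust and scores:
        rich = _bh_adjust(np.array([s.richness_p for s in scores]))
        conc = _bh_adjust(np.array([s.concordance_p for s in scores]))
        scores = [
            HypScore(
                hyp=s.hyp,
                n_downstream_measured=s.n_downstream_measured,
                n_changed=s.n_changed,
                n_correct=s.n_correct,
                n_contra=s.n_contra,
                n_ambiguous=s.n_ambiguous,
                richness_p=s.richness_p,
                concordance_p=s.concordance_p,
                direction=s.direction,
                significant=bool(r < p_cut and c < p_cut),
            )
            for s, r, c in zip(scores, rich, conc)
        ]
    scores.sort(key=lambda s: (s.richness_p, s.concordance_p, s.hyp.upstream.label))
    return scores
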