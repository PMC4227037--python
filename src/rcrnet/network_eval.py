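"""Dataset-vs-subnetwork evaluation statistics.

Given the set of HYPs called significant in a dataset and the set of
possible HYPs belonging to a subnetwork, both inside a common possible-HYP
universe, the 2x2 contingency table is::

                      in subnetwork   not in subnetwork
    significant            a                 b
    not significant        c                 d

* **coverage** (sensitivity) = a / (a + c): the fraction of the
  subnetwork's possible HYPs that the dataset lit up.
* **odds ratio** = (a * d) / (b * c): enrichment of significant HYPs inside
  the subnetwork relative to outside; OR > 1 means the subnetwork
  preferentially captures the dataset's biology.
* **chi-square p** — Pearson chi-square on the 2x2 table (1 df, upper
  tail), starred at p < 0.05 / 0.01 / 0.001.

Report formatting follows the conventions of the source material: coverage
as an integer percent, whole-model odds ratios to two decimals, subnetwork
odds ratios to one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "EvalResult",
    "make_contingency",
    "coverage",
    "odds_ratio",
    "chi_square_p",
    "stars",
    "evaluate",
    "evaluate_all",
    "dataset_overlap_patterns",
    "write_report",
]

WHOLE_MODEL = "whole_model"


@dataclass(frozen=True)
class ContingencyTable:
    """Cells of the significant-HYP x subnetwork 2x2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_significant(self) -> int:
        return self.a + self.b

    @property
    def n_subnet_possible(self) -> int:
        return self.a + self.c


@dataclass(frozen=True)
class EvalResult:
    coverage: float
    odds_ratio: float
    chi2_p: float
    stars: str


def make_contingency(
    significant: Iterable[str], subnet_possible: Iterable[str], universe: Iterable[str]
) -> ContingencyTable:
    """Build the 2x2 table from the three HYP sets.

    ``subnet_possible`` must be a subset of the universe; the significant
    set is intersected with the universe before cell assignment.
    """
    uni = set(universe)
    sub = set(subnet_possible)
    offenders = sorted(sub - uni)
    if offenders:
        raise ValueError(
            "subnetwork possible-HYPs outside the universe: "
            + ", ".join(offenders[:10])
            + ("..." if len(offenders) > 10 else "")
        )
    sig = set(significant) & uni
    a = len(sig & sub)
    b = len(sig - sub)
    c = len(sub - sig)
    return ContingencyTable(a, b, c, len(uni) - a - b - c)


def coverage(ct: ContingencyTable) -> float:
    """Subnetwork coverage a / (a + c)."""
    if ct.n_subnet_possible == 0:
        raise ValueError("coverage undefined: subnetwork has no possible HYPs")
    return ct.a / ct.n_subnet_possible


def odds_ratio(ct: ContingencyTable, haldane: bool = False) -> float:
    """Cross-product ratio (a*d)/(b*c).

    With ``haldane`` the Haldane-Anscombe +0.5 correction is applied to all
    cells.  Without it, a zero ``b*c`` with nonzero ``a*d`` is reported as
    ``inf``; the 0/0 case is undefined and raises.
    """
    if haldane:
        return ((ct.a + 0.5) * (ct.d + 0.5)) / ((ct.b + 0.5) * (ct.c + 0.5))
    ad, bc = ct.a * ct.d, ct.b * ct.c
    if bc == 0:
        if ad == 0:
            raise ValueError("odds ratio undefined: both diagonal products are zero")
        return math.inf
    return ad / bc


def chi_square_p(ct: ContingencyTable, continuity_correction: bool = False) -> float:
    """Pearson chi-square upper-tail p on the 2x2 table (1 df)."""
    if ct.universe_size == 0:
        raise ValueError("chi-square undefined on an empty table")
    marginals = (ct.a + ct.b, ct.c + ct.d, ct.a + ct.c, ct.b + ct.d)
    if 0 in marginals:
        raise ValueError("chi-square undefined: a marginal total is zero")
    _, p, _, _ = stats.chi2_contingency(
        [[ct.a, ct.b], [ct.c, ct.d]], correction=continuity_correction
    )
    return float(p)


def stars(p: float) -> str:
    if math.isnan(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def evaluate(ct: ContingencyTable, continuity_correction: bool = False) -> EvalResult:
    """Coverage, odds ratio and chi-square p for one table.

    Degenerate tables (no significant HYPs, or a zero marginal) yield
    OR 0 / inf per :func:`odds_ratio` rules and a NaN chi-square p rather
    than raising, so that full evaluation matrices stay rectangular.
    """
    try:
        cov = coverage(ct)
    except ValueError:
        cov = math.nan
    try:
        orr = odds_ratio(ct)
    except ValueError:
        orr = math.nan
    try:
        p = chi_square_p(ct, continuity_correction)
    except ValueError:
        p = math.nan
    return EvalResult(cov, orr, p, stars(p))


def _resolve_universe(universe, dataset: str) -> set:
    if isinstance(universe, Mapping):
        return set(universe[dataset])
    return set(universe)


def evaluate_all(
    hyp_sets: Mapping[str, Iterable[str]],
    subnets: Mapping[str, Iterable[str]],
    universe,
    continuity_correction: bool = False,
    whole_model_name: str = WHOLE_MODEL,
) -> pd.DataFrame:
    """Evaluate every dataset against every subnetwork plus the whole model.

    ``universe`` is either one possible-HYP set shared by all datasets or a
    mapping dataset -> universe (e.g. species-matched universes).  The
    whole-model row of each dataset uses the union of the subnetwork
    possible sets.  Returns a tidy DataFrame with one row per
    (dataset, subnetwork) including the raw cells, coverage (fraction and
    integer percent), OR, chi-square p and significance stars; datasets with
    an empty significant set are flagged in the ``degenerate`` column.
    """
    rows = []
    union_possible: dict[str, set] = {}
    for ds in hyp_sets:
        uni = _resolve_universe(universe, ds)
        union_possible[ds] = set().union(
            *(set(s) & uni for s in subnets.values())
        ) if subnets else set()
    for ds, sig in hyp_sets.items():
        uni = _resolve_universe(universe, ds)
        sig = set(sig)
        targets = [(name, set(s) & uni) for name, s in subnets.items()]
        targets.append((whole_model_name, union_possible[ds]))
        for name, possible in targets:
            ct = make_contingency(sig, possible, uni)
            res = evaluate(ct, continuity_correction)
            rows.append(
                {
                    "dataset": ds,
                    "subnetwork": name,
                    "a": ct.a,
                    "b": ct.b,
                    "c": ct.c,
                    "d": ct.d,
                    "coverage": res.coverage,
                    "coverage_pct": (
                        round(100 * res.coverage) if math.isfinite(res.coverage) else -1
                    ),
                    "odds_ratio": res.odds_ratio,
                    "chi2_p": res.chi2_p,
                    "stars": res.stars,
                    "degenerate": ct.n_significant == 0 or math.isnan(res.chi2_p),
                }
            )
    return pd.DataFrame(rows)


def dataset_overlap_patterns(
    hyp_sets: Mapping[str, Iterable[str]],
    subnets: Mapping[str, Iterable[str]],
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Presence/absence patterns of HYPs across datasets.

    For every pattern of membership across the datasets (rows like
    ``X/X/-``), counts the HYPs showing that pattern overall and within each
    subnetwork (with percentages of the subnetwork-possible counts).
    Patterns partition the universe (default: union of subnetwork possible
    sets), so per-subnetwork counts sum to the subnetwork size.
    """
    datasets = list(hyp_sets)
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to form overlap patterns")
    sets = {d: set(hyp_sets[d]) for d in datasets}
    sub_sets = {name: set(s) for name, s in subnets.items()}
    uni = set(universe) if universe is not None else set().union(*sub_sets.values())
    sub_sets = {name: s & uni for name, s in sub_sets.items()}
    members: dict[tuple[bool, ...], set] = {}
    for h in uni:
        pattern = tuple(h in sets[d] for d in datasets)
        members.setdefault(pattern, set()).add(h)
    rows = []
    for pattern in sorted(members, reverse=True):
        grp = members[pattern]
        row = {d: ("X" if present else "-") for d, present in zip(datasets, pattern)}
        row["n_hyps"] = len(grp)
        for name, sub in sub_sets.items():
            n = len(grp & sub)
            row[name] = n
            row[f"{name}_pct"] = round(100 * n / len(sub)) if sub else 0
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(df: pd.DataFrame, path, whole_model_name: str = WHOLE_MODEL) -> None:
    """Write an evaluation matrix as delimited text with printed rounding."""
    out = df.copy()
    out["coverage_pct"] = out["coverage_pct"].map(lambda v: f"{v:d}%")
    out["odds_ratio"] = [
        (f"{orr:.2f}" if name == whole_model_name else f"{orr:.1f}")
        if math.isfinite(orr)
        else str(orr)
        for orr, name in zip(df["odds_ratio"], df["subnetwork"])
    ]
    out["chi2_p"] = out["chi2_p"].map(lambda p: f"{p:.3g}")
    out.drop(columns=["coverage"]).to_csv(path, sep="\t", index=False)
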