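"""Discretization of differential-expression tables into State Changes.

A State Change (SC) is the per-gene discrete call — increase (+1), decrease
(-1) or no change (0) — derived from a treated-vs-control differential
expression comparison.  SCs are the dataset-side input to reverse causal
reasoning.  Genes that were measured but not significant are retained with
direction 0: the scoring universe downstream is the *measured* gene
population, not just the changed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DifferentialRecord",
    "StateChange",
    "call_state_changes",
    "count_state_changes",
    "read_de_table",
    "write_sc_table",
    "read_sc_table",
]

DE_COLUMNS = ("gene_id", "log2fc", "pvalue", "adj_pvalue")


@dataclass(frozen=True)
class DifferentialRecord:
    """One gene's differential-expression summary."""

    gene_id: str
    log2_fold_change: float
    p_value: float
    adj_p_value: float

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        for name in ("p_value", "adj_p_value"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or math.isnan(v):
                raise ValueError(f"{name} out of [0, 1] for {self.gene_id}: {v}")
        if math.isnan(self.log2_fold_change):
            raise ValueError(f"log2_fold_change is NaN for {self.gene_id}")


@dataclass(frozen=True)
class StateChange:
    gene_id: str
    direction: int

    def __post_init__(self) -> None:
        if self.direction not in (-1, 0, 1):
            raise ValueError(f"direction must be -1, 0 or +1; got {self.direction}")


def call_state_changes(
    records: Sequence[DifferentialRecord],
    adj_p_cut: float = 0.05,
    min_abs_lfc: float = 0.0,
) -> list[StateChange]:
    """Call one State Change per measured gene.

    ``direction = sign(log2fc)`` when ``adj_p < adj_p_cut`` and
    ``|log2fc| >= min_abs_lfc``, else 0.  Every input gene appears exactly
    once; the number of nonzero calls is the dataset's "number of state
    changes".
    """
    if not (0.0 <= adj_p_cut <= 1.0):
        raise ValueError("adj_p_cut must be in [0, 1]")
    if min_abs_lfc < 0:
        raise ValueError("min_abs_lfc must be >= 0")
    seen: dict[str, int] = {}
    for r in records:
        seen[r.gene_id] = seen.get(r.gene_id, 0) + 1
    dups = sorted(g for g, n in seen.items() if n > 1)
    if dups:
        raise ValueError("duplicate gene_id(s): " + ", ".join(dups))
    out = []
    for r in records:
        significant = r.adj_p_value < adj_p_cut and abs(r.log2_fold_change) >= min_abs_lfc
        direction = 0
        if significant and r.log2_fold_change != 0.0:
            direction = 1 if r.log2_fold_change > 0 else -1
        out.append(StateChange(r.gene_id, direction))
    return out


def count_state_changes(scs: Iterable[StateChange]) -> int:
    return sum(1 for sc in scs if sc.direction != 0)


def read_de_table(path) -> list[DifferentialRecord]:
    """Read a tab-separated differential-expression table.

    Required header columns: gene_id, log2fc, pvalue, adj_pvalue.  Rows with
    missing or non-numeric values are rejected with their row numbers.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise IOError(f"{path}: missing required column(s): {', '.join(missing)}")
    records = []
    bad_rows = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based, after the header line
        try:
            records.append(
                DifferentialRecord(
                    str(row["gene_id"]),
                    float(row["log2fc"]),
                    float(row["pvalue"]),
                    float(row["adj_pvalue"]),
                )
            )
        except (TypeError, ValueError):
            bad_rows.append(rowno)
    if bad_rows:
        raise IOError(
            f"{path}: unparseable or out-of-range row(s): "
            + ", ".join(str(r) for r in bad_rows)
        )
    return records


def write_sc_table(scs: Sequence[StateChange], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tdirection\n")
        for sc in scs:
            fh.write(f"{sc.gene_id}\t{sc.direction:+d}\n".replace("+0", "0"))


def read_sc_table(path) -> list[StateChange]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene_id", "direction"} <= set(df.columns):
        raise IOError(f"{path}: expected columns gene_id and direction")
    return [StateChange(str(g), int(d)) for g, d in zip(df["gene_id"], df["direction"])]


def sc_mapping(scs: Sequence[StateChange]) -> Mapping[str, int]:
    """Gene -> direction mapping over the full measured universe."""
    return {sc.gene_id: sc.direction for sc in scs}
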