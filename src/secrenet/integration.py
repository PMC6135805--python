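"""Intersection of PPI expansion with differential expression, and
candidate ranking.

The step that surfaces the top survival-factor candidates: each secretome
seed protein is scored by how many of its potential interaction partners
are differentially expressed between blood ASC and BM LLPC, and seeds are
ranked by that count (ties broken by total partner count, then symbol).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .network import ExpansionResult


def overlap_targets(expansion: ExpansionResult, degs: set[str]) -> set[str]:
    """Partners of any seed that are differentially expressed."""
    return expansion.union_partners & set(degs)


@dataclass
class CandidateTable:
    """Ranked secretome candidates.

    ``table`` columns: seed, n_partners_total, n_partners_deg, rank,
    above_threshold; ``partner_deg_symbols`` maps each seed to its
    DEG-overlapping partners.
    """

    table: pd.DataFrame
    partner_deg_symbols: dict[str, list[str]]
    report_threshold: int

    def top(self, n: int = 10) -> list[str]:
        return self.table["seed"].head(n).tolist()

    def summary(self) -> str:
        flagged = self.table[self.table["above_threshold"]]
        lines = [
            "Candidate ranking summary",
            "=========================",
            f"seed proteins ranked        : {len(self.table)}",
            f"seeds with > {self.report_threshold} DEG partners : {len(flagged)}",
        ]
        for _, row in self.table.head(10).iterrows():
            lines.append(
                f"  #{int(row['rank']):>2} {row['seed']}: "
                f"{int(row['n_partners_deg'])} DEG-overlapping of "
                f"{int(row['n_partners_total'])} partners"
            )
        return "\n".join(lines)


def rank_candidates(
    expansion: ExpansionResult,
    degs: set[str],
    report_threshold: int = 45,
) -> CandidateTable:
    """Rank seeds by DEG-overlapping partner count.

    Sort key: descending n_partners_deg, then descending n_partners_total,
    then ascending symbol. ``report_threshold`` only flags seeds (the
    source study highlighted those with more than 45 DEG-overlapping
    partners); it filters nothing.
    """
    if not expansion.per_seed:
        raise ValueError("empty expansion: no seeds matched the network")
    degs = set(degs)
    rows = []
    partner_syms: dict[str, list[str]] = {}
    for seed, partners in expansion.per_seed.items():
        hits = partners & degs
        partner_syms[seed] = sorted(hits)
        rows.append(
            {
                "seed": seed,
                "n_partners_total": len(partners),
                "n_partners_deg": len(hits),
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["n_partners_deg", "n_partners_total", "seed"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    table["rank"] = range(1, len(table) + 1)
    table["above_threshold"] = table["n_partners_deg"] > report_threshold
    return CandidateTable(
        table=table,
        partner_deg_symbols=partner_syms,
        report_threshold=report_threshold,
    )


def pairwise_shared(
    expansion: ExpansionResult,
    seed_a: str,
    seed_b: str,
    degs: set[str],
) -> tuple[set[str], set[str]]:
    """Partners shared by two seeds, and the DEG subset of those."""
    for s in (seed_a, seed_b):
        if s not in expansion.per_seed:
            raise KeyError(f"seed {s!r} not in expansion")
    shared = expansion.per_seed[seed_a] & expansion.per_seed[seed_b]
    return shared, shared & set(degs)
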