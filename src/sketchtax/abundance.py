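"""Abundance estimation at a requested taxonomic rank.

Per-read assignments land on sequence-level taxa (unambiguous reads) and
on inner LCA nodes (ambiguous ones). To report composition at one rank,
counts below the rank are pruned upward onto their at-rank ancestor, and
counts above the rank are pushed down level by level, split among children
in proportion to the read weight of the subtree rooted at each child.
Counts with no at-rank node to land on go to an "unassigned" row, so the
total is conserved exactly (the redistribution is done in exact rational
arithmetic).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from fractions import Fraction
from typing import Mapping, Sequence

import pandas as pd

from .classify import CLASSIFIED, ReadAssignment
from .taxonomy import Taxonomy

UNASSIGNED_TAXID = -1


def tally(assignments: Sequence[ReadAssignment]) -> tuple[Counter, int]:
    """Read counts per assigned taxon; unclassified reads counted apart."""
    counts: Counter = Counter()
    unclassified = 0
    for a in assignments:
        if a.status == CLASSIFIED:
            counts[a.taxid] += 1
        else:
            unclassified += 1
    return counts, unclassified


def redistribute(
    counts: Mapping[int, int], taxonomy: Taxonomy, rank: str
) -> tuple[dict[int, Fraction], Fraction]:
    """Exact prune-up / distribute-down of read counts onto one rank.

    Returns ``(estimates, unassigned)`` where estimates maps at-rank taxids
    to exact rational read counts and ``unassigned`` absorbs counts whose
    lineage has no at-rank node carrying weight. The sum of all returned
    quantities equals ``sum(counts.values())`` exactly.
    """
    base: dict[int, int] = defaultdict(int)
    pending: list[tuple[int, int]] = []
    for taxid, c in counts.items():
        at = taxonomy.ancestor_at_rank(taxid, rank)
        if at is None:
            pending.append((taxid, c))
        else:
            base[at] += c
    weight: dict[int, int] = defaultdict(int)
    for taxid, w in base.items():
        for anc in taxonomy.ancestors(taxid):
            weight[anc] += w
    children = taxonomy.children_map()
    est: dict[int, Fraction] = {t: Fraction(c) for t, c in base.items()}
    unassigned = Fraction(0)
    for taxid, c in pending:
        stack: list[tuple[int, Fraction]] = [(taxid, Fraction(c))]
        while stack:
            node, amount = stack.pop()
            if weight.get(node, 0) == 0:
                unassigned += amount
            elif taxonomy.rank(node) == rank:
                est[node] = est.get(node, Fraction(0)) + amount
            else:
                kids = [(ch, weight.get(ch, 0)) for ch in children.get(node, ())]
                total = sum(w for _, w in kids)
                for ch, w in kids:
                    if w > 0:
                        stack.append((ch, amount * w / total))
    return dict(est), unassigned


def estimate_abundance(
    counts: Mapping[int, int], taxonomy: Taxonomy, rank: str
) -> pd.DataFrame:
    """Abundance table at ``rank``: taxid, rank, name, reads_est, percent.

    Percentages are relative to all classified reads; together with the
    trailing "unassigned" row the estimated reads sum to the classified
    total and percentages to 100. Rows are ordered by estimated reads
    descending (ties by taxid), unassigned last.
    """
    est, unassigned = redistribute(counts, taxonomy, rank)
    total = sum(counts.values())
    rows = [
        (t, rank, taxonomy.name(t), float(v), float(v) / total * 100 if total else 0.0)
        for t, v in est.items()
    ]
    rows.sort(key=lambda r: (-r[3], r[0]))
    rows.append(
        (
            UNASSIGNED_TAXID,
            "",
            "unassigned",
            float(unassigned),
            float(unassigned) / total * 100 if total else 0.0,
        )
    )
    df = pd.DataFrame(rows, columns=["taxid", "rank", "name", "reads_est", "percent"])
    df.attrs["rank"] = rank
    df.attrs["total_classified"] = total
    return df
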