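"""End-to-end query orchestration: classify, coverage-filter, quantify."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .abundance import estimate_abundance, tally
from .classify import (
    ClassifyParams,
    ReadAssignment,
    classify_reads,
    reassign,
    seq_taxon_map,
)
from .coverage import (
    DEFAULT_MIN_CANDIDATES,
    CoverageProfile,
    collect_coverage,
    filter_targets,
)
from .database import SketchDatabase
from .taxonomy import Taxonomy


@dataclass
class QueryResult:
    assignments: list[ReadAssignment]
    profiles: dict[int, CoverageProfile] = field(default_factory=dict)
    excluded: set[int] = field(default_factory=set)
    abundance: pd.DataFrame | None = None
    stats: dict = field(default_factory=dict)


def run_query(
    databases: Sequence[SketchDatabase],
    taxonomy: Taxonomy,
    reads: Sequence[tuple],
    params: ClassifyParams | None = None,
    coverage_quantile: float = 0.0,
    rank: str | None = None,
    min_candidates: int = DEFAULT_MIN_CANDIDATES,
) -> QueryResult:
    """Classify reads, optionally filter low-coverage targets, quantify.

    With ``coverage_quantile`` > 0 a second assignment pass is run after
    excluding the lowest-coverage quantile of candidate targets; excluded
    targets receive zero reads in the final output. With ``rank`` set, an
    abundance table at that rank is produced from the final assignments.
    """
    params = params or ClassifyParams()
    assignments = classify_reads(databases, reads, taxonomy, params)
    window_counts = {
        t.target_id: t.window_count for db in databases for t in db.targets
    }
    profiles: dict[int, CoverageProfile] = {}
    excluded: set[int] = set()
    if coverage_quantile > 0:
        profiles = collect_coverage(assignments, window_counts)
        excluded = filter_targets(profiles, coverage_quantile, min_candidates)
        if excluded:
            bparams = databases[0].params
            paired = bool(reads) and len(reads[0]) == 3
            min_hits = params.resolved_min_hits(
                bparams.sketch_size, 2 if paired else 1
            )
            assignments = reassign(
                assignments,
                excluded,
                taxonomy,
                seq_taxon_map(databases),
                min_hits,
                params,
            )
    counts, unclassified = tally(assignments)
    abundance = estimate_abundance(counts, taxonomy, rank) if rank else None
    stats = {
        "reads": len(reads),
        "classified": sum(counts.values()),
        "unclassified": unclassified,
        "excluded_targets": len(excluded),
    }
    return QueryResult(assignments, profiles, excluded, abundance, stats)
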