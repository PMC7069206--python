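"""Read assignment from window count statistics.

A read (or read pair) is sketched like a reference window and each sketch
value is looked up in every partition's table. Returned locations are
accumulated into a sparse per-query table of hit counts per
(target, window) — the *window count statistic*. Because a sequenced
fragment can straddle window borders, counts are summed over contiguous
window ranges wide enough to span the fragment, and the best range per
target becomes that target's candidate. A read is assigned to the single
best target if it clearly outscores the runner-up, to the lowest common
ancestor of all near-tied candidates otherwise, and left unclassified when
the best count is too small to be trustworthy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .kmers import BuildParams
from .sketch import sketch_batch
from .taxonomy import Taxonomy

CLASSIFIED = "classified"
UNCLASSIFIED = "unclassified"


class ClassificationError(Exception):
    pass


@dataclass(frozen=True)
class ClassifyParams:
    """Knobs of the read-assignment stage.

    ``tophits`` caps how many candidate targets are retained per query and
    per partition. ``min_hits`` is the minimum best-range count needed to
    classify at all (default: ceil(s/2) per sketch queried, i.e. doubled
    for pairs). ``band`` controls which runner-ups count as near-ties and
    go into the LCA (default max(2, ceil(0.1 * best))). ``max_fragment`` is
    the assumed maximum genomic span of a query in bp (default 3x read
    length for pairs, read length for singles) and sets the scored range
    width. ``min_partition_hits`` (the pruning threshold H) drops weak
    candidates inside each partition before merging; 0 disables it, and
    nonzero values can change results relative to an unpartitioned run.
    """

    tophits: int = 8
    min_hits: int | None = None
    band: int | None = None
    max_fragment: int | None = None
    min_partition_hits: int = 0

    def __post_init__(self) -> None:
        if self.tophits < 2:
            raise ValueError("tophits must be >= 2")
        if self.min_partition_hits < 0:
            raise ValueError("min_partition_hits (H) must be >= 0")

    def resolved_min_hits(self, sketch_size: int, n_sketches: int) -> int:
        if self.min_hits is not None:
            return self.min_hits
        return math.ceil(sketch_size / 2) * n_sketches

    def resolved_band(self, best: int) -> int:
        if self.band is not None:
            return self.band
        return max(2, math.ceil(0.1 * best))


@dataclass(frozen=True)
class CandidateRange:
    """Best contiguous window range of one target for one query."""

    target_id: int
    first_window: int
    last_window: int
    hits: int


@dataclass
class ReadAssignment:
    read_id: str
    status: str
    taxid: int | None
    hits: int
    candidates: list[CandidateRange]


def range_width(max_fragment: int, stride: int) -> int:
    """Number of consecutive windows a fragment of max_fragment bp can span."""
    return math.ceil(max_fragment / stride) + 1


def query_statistic(
    databases: Sequence, sketches: Iterable[np.ndarray]
) -> dict[int, int]:
    """Accumulate hits per packed (target, window) over one query's sketches.

    Every location returned for a sketch value found in a table increments
    that cell by one; all sketches of a query (both mates of a pair) share
    the statistic. ``databases`` may be one partition or several.
    """
    stat: dict[int, int] = {}
    for db in databases:
        table = db.table
        for values in sketches:
            for v in values.tolist():
                locs = table.get(v)
                if locs is None:
                    continue
                for p in locs.tolist():
                    stat[p] = stat.get(p, 0) + 1
    return stat


def best_ranges(
    stat: Mapping[int, int],
    r: int,
    tophits: int,
    min_partition_hits: int = 0,
) -> list[CandidateRange]:
    """Per-target maximum-sum contiguous window range of width <= r.

    Output is sorted by hits descending, ties by ascending target id, and
    truncated to ``tophits`` entries; candidates below the pruning
    threshold H are dropped first.
    """
    per_target: dict[int, list[tuple[int, int]]] = {}
    for packed, count in stat.items():
        per_target.setdefault(packed >> 32, []).append((packed & 0xFFFFFFFF, count))
    candidates = []
    for tid in sorted(per_target):
        cells = sorted(per_target[tid])
        best = -1
        bf = bl = 0
        acc = 0
        i = 0
        for j, (wj, cj) in enumerate(cells):
            acc += cj
            while wj - cells[i][0] + 1 > r:
                acc -= cells[i][1]
                i += 1
            if acc > best:
                best = acc
                bf, bl = cells[i][0], wj
        if best >= max(min_partition_hits, 1):
            candidates.append(CandidateRange(tid, bf, bl, best))
    candidates.sort(key=lambda c: (-c.hits, c.target_id))
    return candidates[:tophits]


def merge_partitions(
    per_partition: Sequence[Sequence[CandidateRange]], tophits: int
) -> list[CandidateRange]:
    """Merge per-partition candidate lists into one global ranked list.

    Targets are partition-exclusive, so each may appear at most once; a
    duplicate indicates a broken partition plan and raises.
    """
    merged: list[CandidateRange] = []
    seen: set[int] = set()
    for ranked in per_partition:
        for c in ranked:
            if c.target_id in seen:
                raise ClassificationError(
                    f"target {c.target_id} returned by multiple partitions"
                )
            seen.add(c.target_id)
            merged.append(c)
    merged.sort(key=lambda c: (-c.hits, c.target_id))
    return merged[:tophits]


def assign(
    read_id: str,
    candidates: Sequence[CandidateRange],
    taxonomy: Taxonomy,
    seq_taxon_of: Mapping[int, int],
    min_hits: int,
    params: ClassifyParams,
) -> ReadAssignment:
    """Turn a ranked candidate list into a read assignment.

    Below ``min_hits`` (or with no candidates) the read is unclassified.
    A single candidate within ``band`` of the best maps the read to that
    target's sequence-level taxon; several near-tied candidates map it to
    their lowest common ancestor.
    """
    if not candidates or candidates[0].hits < min_hits:
        return ReadAssignment(read_id, UNCLASSIFIED, None, 0, list(candidates))
    best = candidates[0].hits
    band = params.resolved_band(best)
    co = [c for c in candidates if c.hits >= best - band]
    if len(co) == 1:
        taxid = seq_taxon_of[co[0].target_id]
    else:
        taxid = taxonomy.lca_of_set([seq_taxon_of[c.target_id] for c in co])
    return ReadAssignment(read_id, CLASSIFIED, taxid, best, list(candidates))


def _check_params(databases: Sequence) -> BuildParams:
    params = databases[0].params
    for db in databases[1:]:
        if db.params != params:
            raise ClassificationError(
                f"partition parameter mismatch: {db.params} != {params}"
            )
    return params


def seq_taxon_map(databases: Sequence) -> dict[int, int]:
    return {t.target_id: t.seq_taxid for db in databases for t in db.targets}


def classify_reads(
    databases: Sequence,
    reads: Sequence[tuple],
    taxonomy: Taxonomy,
    params: ClassifyParams | None = None,
) -> list[ReadAssignment]:
    """Classify a read set against one or more database partitions.

    ``reads`` holds ``(read_id, seq)`` singles or ``(read_id, seq1, seq2)``
    pairs (uniform per run). Partitions are queried separately; their
    ranked candidate lists are merged before assignment, reproducing the
    unpartitioned result whenever pruning is off and tophits is not
    limiting.
    """
    params = params or ClassifyParams()
    bparams = _check_params(databases)
    if not reads:
        return []
    paired = len(reads[0]) == 3
    n_sk = 2 if paired else 1
    mate1 = sketch_batch([r[1] for r in reads], bparams)
    mate2 = sketch_batch([r[2] for r in reads], bparams) if paired else None
    min_hits = params.resolved_min_hits(bparams.sketch_size, n_sk)
    taxa = seq_taxon_map(databases)
    out = []
    for i, read in enumerate(reads):
        sketches = [mate1[i], mate2[i]] if paired else [mate1[i]]
        max_len = max(len(read[j + 1]) for j in range(n_sk))
        mf = params.max_fragment or (3 * max_len if paired else max_len)
        r = range_width(mf, bparams.stride)
        ranked = [
            best_ranges(
                query_statistic([db], sketches),
                r,
                params.tophits,
                params.min_partition_hits,
            )
            for db in databases
        ]
        merged = merge_partitions(ranked, params.tophits)
        out.append(assign(read[0], merged, taxonomy, taxa, min_hits, params))
    return out


def reassign(
    assignments: Sequence[ReadAssignment],
    excluded: set[int],
    taxonomy: Taxonomy,
    seq_taxon_of: Mapping[int, int],
    min_hits: int,
    params: ClassifyParams,
) -> list[ReadAssignment]:
    """Re-run assignment with some targets' candidates removed."""
    out = []
    for a in assignments:
        kept = [c for c in a.candidates if c.target_id not in excluded]
        out.append(assign(a.read_id, kept, taxonomy, seq_taxon_of, min_hits, params))
    return out
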