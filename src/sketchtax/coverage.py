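"""Coverage-based false-positive target filtering.

Shared DNA between reference genomes can hand reads to a genome that is
not actually in the sample. Such false-positive targets typically collect
all their hits in the few shared windows, while genuinely present genomes
are covered more evenly. After a first classification pass, the fraction
of read-covered windows is computed per candidate genome, the lowest
quantile of targets is excluded, and reads are reassigned against the
remaining candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .classify import ReadAssignment

#: below this many candidate targets the quantile filter is a no-op
DEFAULT_MIN_CANDIDATES = 5


@dataclass
class CoverageProfile:
    """Which windows of one target are covered by any retained candidate."""

    target_id: int
    covered: np.ndarray  # bool flag per window

    @property
    def windows_total(self) -> int:
        return len(self.covered)

    @property
    def windows_covered(self) -> int:
        return int(self.covered.sum())

    @property
    def fraction(self) -> float:
        return self.windows_covered / self.windows_total if len(self.covered) else 0.0


def collect_coverage(
    assignments: Sequence[ReadAssignment], window_counts: Mapping[int, int]
) -> dict[int, CoverageProfile]:
    """Mark best-range windows of every retained candidate of every read.

    Coverage is collected from all tophits candidates (not only winners):
    the filter acts on the candidate list identified during read
    assignment, before the final per-read decision. Only targets receiving
    at least one candidacy get a profile.
    """
    profiles: dict[int, CoverageProfile] = {}
    for a in assignments:
        for c in a.candidates:
            prof = profiles.get(c.target_id)
            if prof is None:
                prof = CoverageProfile(
                    c.target_id,
                    np.zeros(window_counts[c.target_id], dtype=bool),
                )
                profiles[c.target_id] = prof
            prof.covered[c.first_window : c.last_window + 1] = True
    return profiles


def filter_targets(
    profiles: Mapping[int, CoverageProfile],
    quantile: float,
    min_candidates: int = DEFAULT_MIN_CANDIDATES,
) -> set[int]:
    """Exclude the floor(q * T) candidate targets with the lowest coverage.

    No exclusion with q = 0 or when fewer than ``min_candidates`` targets
    received candidacies (deleting a fixed share of a tiny candidate set
    would be meaningless). Ties in covered fraction break by target id.
    """
    if not 0 <= quantile < 1:
        raise ValueError("quantile must be in [0, 1)")
    n = len(profiles)
    if quantile == 0 or n < min_candidates:
        return set()
    n_excl = math.floor(quantile * n)
    order = sorted(profiles.values(), key=lambda p: (p.fraction, p.target_id))
    return {p.target_id for p in order[:n_excl]}
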