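"""Taxonomic tree: loading, lowest common ancestors and rank lookups.

Supports the NCBI dump dialect (``nodes.dmp``/``names.dmp`` with ``\\t|\\t``
field separators) as well as plain 3-column TSV (taxid, parent, rank) with a
2-column names TSV, plus a 2-column sequence-name -> taxid mapping.

Each reference target additionally receives a private "sequence"-rank leaf
beneath its mapped taxon, so two reference genomes of the same species stay
distinguishable during read assignment while merging at species rank for
quantification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import reduce
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

NO_RANK = "no rank"

#: fixed rank order, most specific first
DEFAULT_RANKS: tuple[str, ...] = (
    "sequence",
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "kingdom",
    "root",
)


class TaxonomyError(Exception):
    """Fatal taxonomy problem: cycles, missing parents, unknown taxids."""


@dataclass
class TaxonNode:
    taxid: int
    parent: int
    rank: str
    name: str


class Taxonomy:
    """A rooted tree of taxa with parent links and named ranks."""

    def __init__(self, ranks: tuple[str, ...] = DEFAULT_RANKS) -> None:
        self.ranks = tuple(ranks)
        self._nodes: dict[int, TaxonNode] = {}
        self._root: int | None = None

    # -- construction -----------------------------------------------------

    def add_node(self, taxid: int, parent: int, rank: str, name: str = "") -> None:
        if rank not in self.ranks:
            rank = NO_RANK
        self._nodes[taxid] = TaxonNode(taxid, parent, rank, name or str(taxid))
        if parent == taxid:
            self._root = taxid

    def validate(self) -> None:
        """Check single-rootedness, parent presence and absence of cycles."""
        roots = [t for t, n in self._nodes.items() if n.parent == t]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {roots}")
        self._root = roots[0]
        for taxid, node in self._nodes.items():
            if node.parent not in self._nodes:
                raise TaxonomyError(
                    f"taxid {taxid} references missing parent {node.parent}"
                )
        for taxid in self._nodes:
            seen = set()
            cur = taxid
            while cur != self._root:
                if cur in seen:
                    raise TaxonomyError(f"cycle detected at taxid {cur}")
                seen.add(cur)
                cur = self._nodes[cur].parent

    def add_sequence_taxon(self, name: str, parent_taxid: int) -> int:
        """Create a private sequence-level leaf below ``parent_taxid``."""
        if parent_taxid not in self._nodes:
            raise TaxonomyError(f"unknown parent taxid {parent_taxid}")
        taxid = max(self._nodes) + 1
        self.add_node(taxid, parent_taxid, "sequence", name)
        return taxid

    def register_sequence_taxa(self, entries: Iterable[tuple[int, int, str]]) -> None:
        """Re-insert persisted sequence-level taxa: (seq_taxid, parent, name)."""
        for taxid, parent, name in entries:
            if taxid in self._nodes:
                continue
            if parent not in self._nodes:
                raise TaxonomyError(f"unknown parent taxid {parent}")
            self.add_node(taxid, parent, "sequence", name)

    # -- queries -----------------------------------------------------------

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    @property
    def root(self) -> int:
        if self._root is None:
            raise TaxonomyError("taxonomy has no root (validate first)")
        return self._root

    def node(self, taxid: int) -> TaxonNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise TaxonomyError(f"unknown taxid {taxid}") from None

    def parent(self, taxid: int) -> int:
        return self.node(taxid).parent

    def rank(self, taxid: int) -> str:
        return self.node(taxid).rank

    def name(self, taxid: int) -> str:
        return self.node(taxid).name

    def nodes(self) -> list[TaxonNode]:
        return [self._nodes[t] for t in sorted(self._nodes)]

    def ancestors(self, taxid: int, include_self: bool = True) -> list[int]:
        """Lineage from ``taxid`` up to (and including) the root."""
        node = self.node(taxid)
        path = [taxid] if include_self else []
        cur = taxid
        while cur != self.root:
            cur = self._nodes[cur].parent
            path.append(cur)
        return path

    def depth(self, taxid: int) -> int:
        return len(self.ancestors(taxid)) - 1

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for taxid in sorted(self._nodes):
            parent = self._nodes[taxid].parent
            if parent != taxid:
                out.setdefault(parent, []).append(taxid)
        return out

    def lca(self, a: int, b: int) -> int:
        """Deepest node that is an ancestor-or-self of both a and b."""
        anc_a = set(self.ancestors(a))
        cur = b
        self.node(b)
        while cur not in anc_a:
            cur = self._nodes[cur].parent
        return cur

    def lca_of_set(self, taxa: Iterable[int]) -> int:
        taxa = list(taxa)
        if not taxa:
            raise TaxonomyError("lca_of_set requires a non-empty set")
        return reduce(self.lca, taxa)

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """Nearest ancestor-or-self with the requested rank (None if absent).

        "no rank" nodes are transparent: they are skipped and never returned.
        """
        if rank not in self.ranks or rank == NO_RANK:
            raise ValueError(
                f"unknown rank {rank!r}; valid ranks: {', '.join(self.ranks)}"
            )
        cur = taxid
        self.node(taxid)
        while True:
            if self._nodes[cur].rank == rank:
                return cur
            if cur == self.root:
                return None
            cur = self._nodes[cur].parent


# -- file parsing ----------------------------------------------------------


def _split_dmp_or_tsv(line: str) -> list[str]:
    line = line.rstrip("\n")
    if "\t|" in line:
        line = line.rstrip("|").rstrip("\t")
        return [f.strip() for f in line.split("\t|\t")]
    return line.split("\t")


def load_taxonomy(
    nodes_path: str | Path,
    names_path: str | Path | None = None,
    mapping_path: str | Path | None = None,
    ranks: tuple[str, ...] = DEFAULT_RANKS,
) -> tuple[Taxonomy, dict[str, int]]:
    """Load a taxonomy plus an optional sequence-name -> taxid mapping.

    ``nodes_path`` may be an NCBI-style nodes.dmp or a 3-column TSV
    (taxid, parent, rank); names and mapping files are optional. Unknown
    rank names map to "no rank". A mapping entry referencing a taxid absent
    from the tree is a fatal error naming the taxid.
    """
    tax = Taxonomy(ranks)
    with open(nodes_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _split_dmp_or_tsv(line)
            taxid, parent = int(fields[0]), int(fields[1])
            rank = fields[2] if len(fields) > 2 else NO_RANK
            tax.add_node(taxid, parent, rank)
    if names_path is not None:
        with open(names_path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                fields = _split_dmp_or_tsv(line)
                taxid = int(fields[0])
                if len(fields) >= 4 and fields[3] != "scientific name":
                    continue
                if taxid in tax:
                    tax.node(taxid).name = fields[1]
    tax.validate()
    mapping: dict[str, int] = {}
    if mapping_path is not None:
        with open(mapping_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                name, taxid_s = line.split("\t")[:2]
                taxid = int(taxid_s)
                if taxid not in tax:
                    raise TaxonomyError(
                        f"mapping entry {name!r} references unknown taxid {taxid}"
                    )
                mapping[name.strip()] = taxid
    return tax, mapping
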