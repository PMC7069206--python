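"""Sketch databases: build, finalize, extend, partition, persist.

Each database maps a 64-bit sketch hash value (key) to the sorted list of
locations (target id, window id) whose window sketches contain it. Keys
whose location list would exceed ``max_locations`` carry almost no
discriminative information and are deleted entirely at finalization; a
database remembers such deleted keys so that later reference additions do
not resurrect them.

Large reference collections are split into disjoint partitions of whole
genomes with roughly equal total length; one database per partition is
built and queried in succession, bounding peak memory.
"""

from __future__ import annotations

import heapq
import json
import logging
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .kmers import BuildParams, extract_windows
from .sketch import sequence_hashes, sketch_from_hashes
from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)

MAGIC = b"SKTXDB"
FORMAT_VERSION = 1
MANIFEST_NAME = "manifest.json"

_WINDOW_MASK = np.uint64(0xFFFFFFFF)


class DatabaseError(Exception):
    pass


class DatabaseFormatError(DatabaseError):
    """Wrong magic bytes or unsupported format version."""


class DatabaseIntegrityError(DatabaseError):
    """Truncated or corrupted database file / inconsistent partitions."""


def pack_location(target_id: int, window_id: int) -> int:
    return (target_id << 32) | window_id


def unpack_location(packed: int) -> tuple[int, int]:
    return packed >> 32, packed & 0xFFFFFFFF


@dataclass
class TargetInfo:
    """Metadata of one reference genome registered in a database."""

    target_id: int
    name: str
    length: int
    window_count: int
    taxid: int
    seq_taxid: int


@dataclass
class PartitionPlan:
    """Greedy longest-first assignment of targets to disjoint partitions."""

    assignments: list[int]
    loads: list[int]
    n_partitions: int

    @property
    def total_bp(self) -> int:
        return sum(self.loads)


def plan_partitions(lengths: Sequence[int], n_partitions: int) -> PartitionPlan:
    """Assign whole genomes to ``n_partitions`` disjoint, balanced buckets.

    Targets are taken longest first (ties by ascending target id) and each
    is placed in the currently lightest partition (ties by ascending
    partition index), so the spread between partition loads never exceeds
    the largest single genome.
    """
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    if n_partitions > len(lengths):
        raise ValueError(
            f"n_partitions={n_partitions} exceeds target count {len(lengths)}"
        )
    order = sorted(range(len(lengths)), key=lambda t: (-lengths[t], t))
    heap = [(0, i) for i in range(n_partitions)]
    heapq.heapify(heap)
    assignments = [0] * len(lengths)
    for t in order:
        load, idx = heapq.heappop(heap)
        assignments[t] = idx
        heapq.heappush(heap, (load + lengths[t], idx))
    loads = [0] * n_partitions
    for t, idx in enumerate(assignments):
        loads[idx] += lengths[t]
    return PartitionPlan(assignments, loads, n_partitions)


class SketchDatabase:
    """One partition's key -> location-list table plus target metadata."""

    def __init__(self, params: BuildParams) -> None:
        self.params = params
        self.targets: list[TargetInfo] = []
        self.table: dict[int, np.ndarray] = {}
        self.deleted_keys: set[int] = set()
        self._staging: dict[int, list[int]] = {}
        self.total_inserted = 0  # distinct (key, location) pairs ever staged
        self.overflow_locations = 0  # locations lost to deleted keys

    # -- construction -----------------------------------------------------

    @property
    def target_ids(self) -> list[int]:
        return [t.target_id for t in self.targets]

    @property
    def n_keys(self) -> int:
        return len(self.table)

    @property
    def overflowed_keys(self) -> int:
        return len(self.deleted_keys)

    def target_by_id(self, target_id: int) -> TargetInfo:
        for t in self.targets:
            if t.target_id == target_id:
                return t
        raise DatabaseError(f"unknown target id {target_id}")

    def insert_reference(
        self,
        name: str,
        seq: str,
        taxid: int,
        seq_taxid: int,
        target_id: int | None = None,
    ) -> TargetInfo:
        """Sketch every window of a reference and stage its locations."""
        if any(t.name == name for t in self.targets):
            raise DatabaseError(f"duplicate target name {name!r}")
        if target_id is None:
            target_id = max(self.target_ids, default=-1) + 1
        windows = extract_windows(len(seq), self.params)
        hashes, valid = sequence_hashes(seq, self.params.k)
        s = self.params.sketch_size
        for wid, start, end in windows:
            vals = sketch_from_hashes(
                hashes[start : end - self.params.k + 1],
                valid[start : end - self.params.k + 1],
                s,
            )
            loc = pack_location(target_id, wid)
            for v in vals.tolist():
                self._staging.setdefault(v, []).append(loc)
                self.total_inserted += 1
        info = TargetInfo(target_id, name, len(seq), len(windows), taxid, seq_taxid)
        self.targets.append(info)
        return info

    def finalize(self) -> "SketchDatabase":
        """Merge staged insertions; drop keys exceeding ``max_locations``.

        Location lists are deduplicated and sorted by (target id, window id).
        Keys deleted here (or in an earlier finalize) stay deleted even if
        re-inserted later.
        """
        cap = self.params.max_locations
        for key, locs in self._staging.items():
            if key in self.deleted_keys:
                self.overflow_locations += len(locs)
                continue
            arr = np.asarray(locs, dtype=np.uint64)
            prev = self.table.get(key)
            if prev is not None:
                arr = np.concatenate([prev, arr])
            arr = np.unique(arr)  # dedupe + sort by packed (target, window)
            if len(arr) > cap:
                self.table.pop(key, None)
                self.deleted_keys.add(key)
                self.overflow_locations += len(arr)
            else:
                self.table[key] = arr
        self._staging = {}
        return self

    def add_references(
        self,
        refs: Iterable[tuple[str, str]],
        taxonomy: Taxonomy | None = None,
        target_map: dict[str, int] | None = None,
        target_ids: Sequence[int] | None = None,
    ) -> "SketchDatabase":
        """Add sequences to an already-finalized database.

        Equivalent to having built from the union of references, except that
        keys deleted by an earlier finalize remain deleted.
        """
        refs = list(refs)
        for i, (name, seq) in enumerate(refs):
            taxid, seq_taxid = _resolve_taxa(name, taxonomy, target_map)
            tid = target_ids[i] if target_ids is not None else None
            self.insert_reference(name, seq, taxid, seq_taxid, target_id=tid)
        return self.finalize()

    def lookup(self, key: int) -> np.ndarray | None:
        return self.table.get(key)

    def total_locations(self) -> int:
        return sum(len(v) for v in self.table.values())


def _resolve_taxa(
    name: str, taxonomy: Taxonomy | None, target_map: dict[str, int] | None
) -> tuple[int, int]:
    if taxonomy is None:
        return 0, -1
    taxid = (target_map or {}).get(name)
    if taxid is None:
        logger.warning("target %r has no taxid mapping; assigned to root", name)
        taxid = taxonomy.root
    seq_taxid = taxonomy.add_sequence_taxon(name, taxid)
    return taxid, seq_taxid


def build_database(
    refs: Iterable[tuple[str, str]],
    params: BuildParams,
    taxonomy: Taxonomy | None = None,
    target_map: dict[str, int] | None = None,
    target_ids: Sequence[int] | None = None,
) -> SketchDatabase:
    """Build and finalize a single-partition database from (name, seq) pairs."""
    refs = list(refs)
    if not refs:
        raise DatabaseError("cannot build a database from zero references")
    db = SketchDatabase(params)
    for i, (name, seq) in enumerate(refs):
        taxid, seq_taxid = _resolve_taxa(name, taxonomy, target_map)
        tid = target_ids[i] if target_ids is not None else None
        db.insert_reference(name, seq, taxid, seq_taxid, target_id=tid)
    return db.finalize()


def build_partitioned(
    refs: Sequence[tuple[str, str]],
    params: BuildParams,
    taxonomy: Taxonomy | None = None,
    target_map: dict[str, int] | None = None,
    n_partitions: int = 1,
) -> list[SketchDatabase]:
    """Split references into balanced partitions and build one DB per part.

    Target ids are global across partitions (position in the input list), so
    per-read results from different partitions can be merged directly.
    """
    plan = plan_partitions([len(seq) for _, seq in refs], n_partitions)
    dbs = []
    for p in range(n_partitions):
        part_refs = [r for t, r in enumerate(refs) if plan.assignments[t] == p]
        part_ids = [t for t in range(len(refs)) if plan.assignments[t] == p]
        dbs.append(
            build_database(part_refs, params, taxonomy, target_map, target_ids=part_ids)
        )
    return dbs


# -- persistence -----------------------------------------------------------


def _db_header(db: SketchDatabase, keys: np.ndarray, counts: np.ndarray) -> bytes:
    header = {
        "format": "sketchtax-db",
        "version": FORMAT_VERSION,
        "params": {
            "k": db.params.k,
            "window_len": db.params.window_len,
            "sketch_size": db.params.sketch_size,
            "max_locations": db.params.max_locations,
        },
        "targets": [
            [t.target_id, t.name, t.length, t.window_count, t.taxid, t.seq_taxid]
            for t in db.targets
        ],
        "n_keys": int(len(keys)),
        "n_locations": int(counts.sum()),
        "n_deleted": len(db.deleted_keys),
        "total_inserted": db.total_inserted,
        "overflow_locations": db.overflow_locations,
    }
    return json.dumps(header, sort_keys=True).encode()


def save_database(db: SketchDatabase, path: str | Path) -> None:
    """Write one partition to a single little-endian binary file.

    Layout: magic, u16 version, u32 header length, JSON header (params +
    target table), sorted keys (u64), per-key location counts (u32), packed
    locations (u64), deleted keys (u64), trailing CRC32 of everything after
    the magic.
    """
    if db._staging:
        raise DatabaseError("finalize() before saving")
    keys = np.array(sorted(db.table), dtype=np.uint64)
    counts = np.array([len(db.table[int(k)]) for k in keys], dtype=np.uint32)
    if len(keys):
        flat = np.concatenate([db.table[int(k)] for k in keys])
    else:
        flat = np.empty(0, dtype=np.uint64)
    deleted = np.array(sorted(db.deleted_keys), dtype=np.uint64)
    header = _db_header(db, keys, counts)
    body = b"".join(
        [
            struct.pack("<H", FORMAT_VERSION),
            struct.pack("<I", len(header)),
            header,
            keys.astype("<u8").tobytes(),
            counts.astype("<u4").tobytes(),
            flat.astype("<u8").tobytes(),
            deleted.astype("<u8").tobytes(),
        ]
    )
    crc = zlib.crc32(body)
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(body)
        fh.write(struct.pack("<I", crc))


def load_database(path: str | Path) -> SketchDatabase:
    """Load a partition file, verifying magic, version and checksum."""
    raw = Path(path).read_bytes()
    if raw[: len(MAGIC)] != MAGIC:
        raise DatabaseFormatError(f"{path}: not a sketchtax database file")
    if len(raw) < len(MAGIC) + 10:
        raise DatabaseIntegrityError(f"{path}: truncated file")
    body, (crc,) = raw[len(MAGIC) : -4], struct.unpack("<I", raw[-4:])
    if zlib.crc32(body) != crc:
        raise DatabaseIntegrityError(f"{path}: checksum mismatch (corrupt file)")
    (version,) = struct.unpack_from("<H", body, 0)
    if version != FORMAT_VERSION:
        raise DatabaseFormatError(
            f"{path}: unsupported format version {version} "
            f"(expected {FORMAT_VERSION})"
        )
    (hlen,) = struct.unpack_from("<I", body, 2)
    off = 6
    header = json.loads(body[off : off + hlen])
    off += hlen
    n_keys = header["n_keys"]
    n_loc = header["n_locations"]
    n_del = header["n_deleted"]
    expected = off + 8 * n_keys + 4 * n_keys + 8 * n_loc + 8 * n_del
    if len(body) != expected:
        raise DatabaseIntegrityError(f"{path}: unexpected payload length")
    keys = np.frombuffer(body, dtype="<u8", count=n_keys, offset=off)
    off += 8 * n_keys
    counts = np.frombuffer(body, dtype="<u4", count=n_keys, offset=off)
    off += 4 * n_keys
    flat = np.frombuffer(body, dtype="<u8", count=n_loc, offset=off)
    off += 8 * n_loc
    deleted = np.frombuffer(body, dtype="<u8", count=n_del, offset=off)
    p = header["params"]
    db = SketchDatabase(BuildParams(**p))
    db.targets = [TargetInfo(*row) for row in header["targets"]]
    db.deleted_keys = set(int(x) for x in deleted)
    db.total_inserted = header.get("total_inserted", 0)
    db.overflow_locations = header.get("overflow_locations", 0)
    bounds = np.concatenate(([0], np.cumsum(counts.astype(np.int64))))
    for i, k in enumerate(keys):
        db.table[int(k)] = flat[bounds[i] : bounds[i + 1]].astype(np.uint64)
    return db


def save_partitioned(
    dbs: Sequence[SketchDatabase], taxonomy: Taxonomy | None, out_dir: str | Path
) -> Path:
    """Write partition files plus a manifest (with embedded taxonomy)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for i, db in enumerate(dbs):
        fname = f"part_{i:04d}.skdb"
        save_database(db, out / fname)
        files.append(fname)
    manifest = {
        "format": "sketchtax-manifest",
        "version": FORMAT_VERSION,
        "partitions": files,
        "taxonomy": (
            [[n.taxid, n.parent, n.rank, n.name] for n in taxonomy.nodes()]
            if taxonomy is not None
            else None
        ),
    }
    (out / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out / MANIFEST_NAME


def load_partitioned(path: str | Path) -> tuple[list[SketchDatabase], Taxonomy | None]:
    """Load a manifest directory (or manifest path) into memory."""
    p = Path(path)
    if p.is_dir():
        p = p / MANIFEST_NAME
    manifest = json.loads(p.read_text())
    if manifest.get("format") != "sketchtax-manifest":
        raise DatabaseFormatError(f"{p}: not a sketchtax manifest")
    dbs = [load_database(p.parent / f) for f in manifest["partitions"]]
    taxonomy = None
    if manifest.get("taxonomy") is not None:
        taxonomy = Taxonomy()
        for taxid, parent, rank, name in manifest["taxonomy"]:
            taxonomy.add_node(taxid, parent, rank, name)
        taxonomy.validate()
    seen: set[int] = set()
    for db in dbs:
        for t in db.targets:
            if t.target_id in seen:
                raise DatabaseIntegrityError(
                    f"target id {t.target_id} appears in multiple partitions"
                )
            seen.add(t.target_id)
    return dbs, taxonomy
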