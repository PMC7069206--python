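"""Synthetic references, read sets and evaluation metrics.

Emulates calibrator-style mixtures of known composition: an ancestor
genome is drawn uniformly at random, each taxon's genome is derived from
it (or from another taxon, for close relatives) by i.i.d. substitutions at
a stated divergence, and shotgun reads are drawn from the mixture with
i.i.d. substitution errors. Substitution-only models keep the k-mer
survival probability of a read analytically simple ((1 - e)^k per k-mer)
while still exercising every classification branch: close taxon pairs
force LCA decisions, a zero-fraction in-database taxon provides a
false-positive surface, and a planted shared segment in an otherwise
unrelated genome provides the coverage-filter surface.

Everything is deterministic under a fixed seed.

Evaluation reports the two composition metrics used for mixture studies:
the summed estimated percentage over truly absent taxa (sum_fp) and the
summed absolute deviation from the true composition (sum_dev).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .taxonomy import Taxonomy

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class TaxonSpec:
    """One synthetic taxon.

    ``divergence`` is the substitution rate per site relative to the
    parent sequence (the shared ancestor, or the taxon named in
    ``derived_from`` for close relatives); ``None`` means an independent
    random genome, unrelated to the ancestor. ``genus`` groups taxa under
    a shared genus node; taxa without one sit directly below the root.
    """

    name: str
    divergence: float | None = 0.05
    genus: str | None = None
    derived_from: str | None = None

    def __post_init__(self) -> None:
        if self.divergence is not None and not 0 <= self.divergence <= 0.5:
            raise DesignError("divergence must lie in [0, 0.5]")


@dataclass(frozen=True)
class SharedSegment:
    """Copy ``length`` bp starting at ``start`` from donor into recipient."""

    donor: str
    recipient: str
    start: int
    length: int


@dataclass(frozen=True)
class SyntheticDesign:
    seed: int = 1
    genome_length: int = 100_000
    taxa: tuple[TaxonSpec, ...] = ()
    composition: dict[str, float] = field(default_factory=dict)
    n_reads: int = 10_000
    read_length: int = 101
    error_rate: float = 0.01
    paired: bool = True
    insert_range: tuple[int, int] = (250, 400)
    shared_segments: tuple[SharedSegment, ...] = ()

    def __post_init__(self) -> None:
        fracs = list(self.composition.values())
        if fracs and (min(fracs) < 0 or abs(sum(fracs) - 1.0) > 1e-9):
            raise DesignError("composition fractions must be >= 0 and sum to 1")
        names = {t.name for t in self.taxa}
        for name in self.composition:
            if name not in names:
                raise DesignError(f"composition taxon {name!r} not in references")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticDesign":
        taxa = tuple(TaxonSpec(**t) for t in d.get("taxa", ()))
        segs = tuple(SharedSegment(**s) for s in d.get("shared_segments", ()))
        kwargs = {
            k: v for k, v in d.items() if k not in ("taxa", "shared_segments")
        }
        if "insert_range" in kwargs:
            kwargs["insert_range"] = tuple(kwargs["insert_range"])
        return cls(taxa=taxa, shared_segments=segs, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ReferenceSet:
    refs: list[tuple[str, str]]
    taxonomy: Taxonomy
    target_map: dict[str, int]

    def seq(self, name: str) -> str:
        for n, s in self.refs:
            if n == name:
                return s
        raise KeyError(name)


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position independently with probability ``rate``."""
    out = codes.copy()
    hit = rng.random(len(codes)) < rate
    shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    out[hit] = (out[hit] + shift) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return _LETTERS[codes].tobytes().decode("ascii")


def generate_references(design: SyntheticDesign) -> ReferenceSet:
    """Generate divergent genomes plus a taxonomy grouping close pairs.

    Taxids are assigned deterministically: root = 1, genera from 10,
    species from 100 in taxon order.
    """
    rng = np.random.default_rng(design.seed)
    ancestor = rng.integers(0, 4, size=design.genome_length, dtype=np.uint8)
    genomes: dict[str, np.ndarray] = {}
    for spec in design.taxa:
        if spec.derived_from is not None:
            if spec.derived_from not in genomes:
                raise DesignError(
                    f"{spec.name!r} derived from unknown taxon {spec.derived_from!r}"
                )
            parent = genomes[spec.derived_from]
        else:
            parent = ancestor
        if spec.divergence is None:
            genomes[spec.name] = rng.integers(
                0, 4, size=design.genome_length, dtype=np.uint8
            )
        else:
            genomes[spec.name] = _mutate(parent, spec.divergence, rng)
    for seg in design.shared_segments:
        if seg.donor not in genomes or seg.recipient not in genomes:
            raise DesignError("shared segment references unknown taxon")
        sl = slice(seg.start, seg.start + seg.length)
        genomes[seg.recipient][sl] = genomes[seg.donor][sl]

    taxonomy = Taxonomy()
    taxonomy.add_node(1, 1, "root", "root")
    genus_ids: dict[str, int] = {}
    next_genus = 10
    for spec in design.taxa:
        if spec.genus and spec.genus not in genus_ids:
            genus_ids[spec.genus] = next_genus
            taxonomy.add_node(next_genus, 1, "genus", spec.genus)
            next_genus += 1
    target_map: dict[str, int] = {}
    for i, spec in enumerate(design.taxa):
        taxid = 100 + i
        parent = genus_ids[spec.genus] if spec.genus else 1
        taxonomy.add_node(taxid, parent, "species", spec.name)
        target_map[spec.name] = taxid
    taxonomy.validate()
    refs = [(spec.name, _decode(genomes[spec.name])) for spec in design.taxa]
    return ReferenceSet(refs, taxonomy, target_map)


def simulate_reads(
    design: SyntheticDesign, refset: ReferenceSet
) -> tuple[list[tuple], list[tuple[str, int]]]:
    """Draw reads from the composition; returns (reads, truth).

    ``reads`` holds ``(id, seq)`` or ``(id, seq1, seq2)`` tuples in read
    order; ``truth`` maps each read id to its source species taxid. Mate 2
    of a pair is the reverse complement of the far end of the fragment.
    """
    comp = {n: f for n, f in design.composition.items() if f > 0}
    if not comp:
        raise DesignError("composition has no positive fractions")
    rng = np.random.default_rng(design.seed + 1)
    names = sorted(comp)
    probs = np.array([comp[n] for n in names])
    probs = probs / probs.sum()
    src = rng.choice(len(names), size=design.n_reads, p=probs)
    rl = design.read_length
    lo, hi = design.insert_range
    if design.paired:
        flens = rng.integers(max(lo, rl), max(hi, rl) + 1, size=design.n_reads)
    else:
        flens = np.full(design.n_reads, rl)
    genome_codes = {
        n: np.frombuffer(refset.seq(n).encode(), dtype=np.uint8) for n in names
    }
    code_lut = np.full(256, 0, dtype=np.uint8)
    for i, c in enumerate(b"ACGT"):
        code_lut[c] = i
    reads: list[tuple] = [None] * design.n_reads  # type: ignore[list-item]
    truth: list[tuple[str, int]] = [None] * design.n_reads  # type: ignore[list-item]
    for t, name in enumerate(names):
        idx = np.nonzero(src == t)[0]
        if len(idx) == 0:
            continue
        codes = code_lut[genome_codes[name]]
        fl = flens[idx]
        pos = rng.integers(0, len(codes) - fl + 1)
        m1 = codes[pos[:, None] + np.arange(rl)]
        m1 = _mutate_matrix(m1, design.error_rate, rng)
        if design.paired:
            end = pos + fl - rl
            m2 = codes[end[:, None] + np.arange(rl)]
            m2 = (3 - m2)[:, ::-1]  # reverse complement of the far end
            m2 = _mutate_matrix(m2, design.error_rate, rng)
        taxid = refset.target_map[name]
        for row, i in enumerate(idx):
            rid = f"r{i:06d}"
            if design.paired:
                reads[i] = (rid, _decode(m1[row]), _decode(m2[row]))
            else:
                reads[i] = (rid, _decode(m1[row]))
            truth[i] = (rid, taxid)
    return reads, truth


def _mutate_matrix(
    codes: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    if rate <= 0:
        return codes
    out = codes.copy()
    hit = rng.random(codes.shape) < rate
    shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    out[hit] = (out[hit] + shift) % 4
    return out


# -- file emission ---------------------------------------------------------


def write_fasta(refs: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in refs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(reads: Sequence[tuple], path1: str | Path, path2=None) -> None:
    paired = bool(reads) and len(reads[0]) == 3
    f2 = open(path2, "w") if (paired and path2 is not None) else None
    with open(path1, "w") as f1:
        for read in reads:
            f1.write(f"@{read[0]}\n{read[1]}\n+\n{'I' * len(read[1])}\n")
            if f2 is not None:
                f2.write(f"@{read[0]}\n{read[2]}\n+\n{'I' * len(read[2])}\n")
    if f2 is not None:
        f2.close()


def write_taxonomy_files(refset: ReferenceSet, out_dir: str | Path) -> dict[str, Path]:
    """Emit nodes/names/mapping TSVs consumed by the build pipeline."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nodes = out / "nodes.tsv"
    names = out / "names.tsv"
    mapping = out / "mapping.tsv"
    with open(nodes, "w") as fh:
        for n in refset.taxonomy.nodes():
            if n.rank == "sequence":
                continue
            fh.write(f"{n.taxid}\t{n.parent}\t{n.rank}\n")
    with open(names, "w") as fh:
        for n in refset.taxonomy.nodes():
            if n.rank == "sequence":
                continue
            fh.write(f"{n.taxid}\t{n.name}\n")
    with open(mapping, "w") as fh:
        for name, taxid in sorted(refset.target_map.items()):
            fh.write(f"{name}\t{taxid}\n")
    return {"nodes": nodes, "names": names, "mapping": mapping}


def write_truth(truth: Sequence[tuple[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttaxid\n")
        for rid, taxid in truth:
            fh.write(f"{rid}\t{taxid}\n")


# -- evaluation ------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Composition recovery metrics at one rank."""

    table: pd.DataFrame
    sum_fp: float
    sum_dev: float


def evaluate(
    abundance: pd.DataFrame, truth_percent: dict[int, float], rank: str
) -> EvaluationReport:
    """Compare an abundance table to the true composition at the same rank.

    Estimated percentages are renormalized over the at-rank taxa (the
    unassigned row is excluded) before comparison. ``sum_fp`` is the summed
    estimate over taxa with a true share of zero; ``sum_dev`` sums absolute
    deviations over all taxa.
    """
    if abundance.attrs.get("rank") != rank:
        raise ValueError(
            f"abundance table is at rank {abundance.attrs.get('rank')!r}, "
            f"truth at {rank!r}"
        )
    at_rank = abundance[abundance["taxid"] != -1]
    total = at_rank["reads_est"].sum()
    est = {
        int(r.taxid): (r.reads_est / total * 100 if total else 0.0)
        for r in at_rank.itertuples(index=False)
    }
    taxa = sorted(set(est) | set(truth_percent))
    rows = []
    for t in taxa:
        e = est.get(t, 0.0)
        tr = truth_percent.get(t, 0.0)
        rows.append((t, tr, e, abs(e - tr), tr == 0))
    table = pd.DataFrame(
        rows, columns=["taxid", "true_percent", "est_percent", "abs_dev", "absent"]
    )
    sum_fp = float(table.loc[table["absent"], "est_percent"].sum())
    sum_dev = float(table["abs_dev"].sum())
    return EvaluationReport(table, sum_fp, sum_dev)


# -- canned study designs --------------------------------------------------


def partition_invariance_design(seed: int = 1, n_reads: int = 10_000) -> SyntheticDesign:
    """Four well-separated taxa in equal proportions (partition studies)."""
    taxa = (
        TaxonSpec("taxonA", 0.03),
        TaxonSpec("taxonB", 0.05),
        TaxonSpec("taxonC", 0.06),
        TaxonSpec("taxonD", 0.08),
    )
    comp = {"taxonA": 0.25, "taxonB": 0.25, "taxonC": 0.25, "taxonD": 0.25}
    return SyntheticDesign(
        seed=seed, taxa=taxa, composition=comp, n_reads=n_reads
    )


def mixture_recovery_design(seed: int = 1, n_reads: int = 100_000) -> SyntheticDesign:
    """Calibrator-style 80/14/5.5/0.5% mixture plus an absent close relative.

    The absent taxon diverges by 2% from the dominant component and shares
    its genus, emulating the cattle/water-buffalo confusion surface.
    """
    taxa = (
        TaxonSpec("pigoid", 0.10, genus="genusP"),
        TaxonSpec("bovoid", 0.10, genus="genusB"),
        TaxonSpec("galloid", 0.12, genus="genusG"),
        TaxonSpec("meleagroid", 0.12, genus="genusM"),
        TaxonSpec("pigoid_sister", 0.02, genus="genusP", derived_from="pigoid"),
    )
    comp = {
        "pigoid": 0.80,
        "bovoid": 0.14,
        "galloid": 0.055,
        "meleagroid": 0.005,
        "pigoid_sister": 0.0,
    }
    return SyntheticDesign(
        seed=seed, taxa=taxa, composition=comp, n_reads=n_reads
    )


def coverage_filter_design(seed: int = 1, n_reads: int = 20_000) -> SyntheticDesign:
    """Nine present taxa plus an absent decoy sharing one 5 kb segment.

    The decoy genome is unrelated random sequence except for a 5 kb region
    copied from the dominant source, so its read hits concentrate in a few
    windows (patchy coverage) while genuine sources are covered evenly.
    """
    taxa = tuple(
        TaxonSpec(f"taxon{i}", 0.03 + 0.01 * i) for i in range(9)
    ) + (TaxonSpec("decoy", None),)
    fracs = [0.20, 0.15, 0.12, 0.11, 0.10, 0.09, 0.08, 0.08, 0.07]
    comp = {f"taxon{i}": fracs[i] for i in range(9)}
    comp["decoy"] = 0.0
    return SyntheticDesign(
        seed=seed,
        taxa=taxa,
        composition=comp,
        n_reads=n_reads,
        shared_segments=(SharedSegment("taxon0", "decoy", 10_000, 5_000),),
    )
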