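"""Sequence input and tabular output.

FASTA and FASTQ (optionally gzip-compressed) are read through Biopython's
streaming parsers; the classifier is quality-agnostic, so FASTQ quality
strings are ignored. All output tables are TSV with '#' header lines that
record the tool version and the full parameterization, and rows in a
deterministic order so identical runs produce byte-identical files.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import __version__
from .abundance import UNASSIGNED_TAXID
from .classify import CLASSIFIED, ReadAssignment
from .coverage import CoverageProfile
from .taxonomy import Taxonomy


class SequenceInputError(Exception):
    pass


class MateMismatchError(SequenceInputError):
    """Paired files with different record counts."""


def open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream (id, sequence) records from a FASTA or FASTQ file.

    The format is detected from the first character ('>' FASTA, '@' FASTQ);
    record ids are the first whitespace-separated token of the title line.
    """
    with open_text(path) as fh:
        first = fh.read(1)
        fh.seek(0)
        if first == ">":
            for title, seq in SimpleFastaParser(fh):
                yield title.split()[0], seq
        elif first == "@":
            for title, seq, _qual in FastqGeneralIterator(fh):
                yield title.split()[0], seq
        elif first == "":
            return
        else:
            raise SequenceInputError(f"{path}: neither FASTA nor FASTQ")


def read_pairs(
    path1: str | Path, path2: str | Path
) -> Iterator[tuple[str, str, str]]:
    """Stream (id, mate1, mate2); mates are matched by record order."""
    it1 = read_sequences(path1)
    it2 = read_sequences(path2)
    sentinel = object()
    while True:
        r1 = next(it1, sentinel)
        r2 = next(it2, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        if r1 is sentinel or r2 is sentinel:
            raise MateMismatchError(
                f"{path1} and {path2} hold different numbers of reads"
            )
        yield r1[0], r1[1], r2[1]


def load_reads(
    path1: str | Path, path2: str | Path | None = None
) -> list[tuple]:
    if path2 is None:
        return list(read_sequences(path1))
    return list(read_pairs(path1, path2))


def _header_lines(meta: dict) -> list[str]:
    lines = [f"# sketchtax {__version__}"]
    for key in sorted(meta):
        lines.append(f"# {key}: {meta[key]}")
    return lines


def write_assignments_tsv(
    path: str | Path,
    assignments: Sequence[ReadAssignment],
    taxonomy: Taxonomy,
    meta: dict | None = None,
) -> None:
    """Per-read TSV: read_id, status, taxid, rank, taxon_name, hits, candidates."""
    with open(path, "w") as fh:
        for line in _header_lines(meta or {}):
            fh.write(line + "\n")
        fh.write("read_id\tstatus\ttaxid\trank\ttaxon_name\thits\tcandidates\n")
        for a in assignments:
            if a.status == CLASSIFIED:
                taxid, rank, name = a.taxid, taxonomy.rank(a.taxid), taxonomy.name(a.taxid)
            else:
                taxid, rank, name = "-", "-", "-"
            cand = ";".join(f"{c.target_id}:{c.hits}" for c in a.candidates)
            fh.write(
                f"{a.read_id}\t{a.status}\t{taxid}\t{rank}\t{name}\t{a.hits}\t{cand}\n"
            )


def write_abundance_tsv(path: str | Path, table, meta: dict | None = None) -> None:
    """Abundance TSV sorted by estimated reads descending, unassigned last."""
    with open(path, "w") as fh:
        for line in _header_lines(meta or {}):
            fh.write(line + "\n")
        fh.write("taxid\trank\tname\treads_est\tpercent\n")
        for row in table.itertuples(index=False):
            fh.write(
                f"{row.taxid}\t{row.rank}\t{row.name}\t"
                f"{row.reads_est:.4f}\t{row.percent:.2f}\n"
            )


def write_coverage_tsv(
    path: str | Path,
    profiles: dict[int, CoverageProfile],
    excluded: set[int],
    target_names: dict[int, str],
    meta: dict | None = None,
) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(meta or {}):
            fh.write(line + "\n")
        fh.write("target_id\tname\twindows_total\twindows_covered\tfraction\texcluded\n")
        for tid in sorted(profiles):
            p = profiles[tid]
            fh.write(
                f"{tid}\t{target_names.get(tid, tid)}\t{p.windows_total}\t"
                f"{p.windows_covered}\t{p.fraction:.4f}\t"
                f"{str(tid in excluded).lower()}\n"
            )


def preflight_writable(paths: Iterable[str | Path]) -> None:
    """Fail before any computation if an output path cannot be written."""
    for p in paths:
        if p is None:
            continue
        p = Path(p)
        try:
            p.parent.mkdir(parents=True, exist_ok=True)
            with open(p, "a"):
                pass
        except OSError as exc:
            raise SequenceInputError(f"cannot write output {p}: {exc}") from exc
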