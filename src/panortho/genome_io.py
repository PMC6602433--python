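"""Genome intake and FASTA plumbing.

Genomes arrive one FASTA file per genome (an assembled isolate, strain or
species — fully assembled or as contigs), either loose in a directory or
bundled in a ``.zip`` / ``.tar.gz`` archive.  The genome id is the file
basename with the FASTA extension stripped; genomes are sorted
lexicographically by id so every downstream table and phyletic string is
order-deterministic.
"""

from __future__ import annotations

import io
import logging
import tarfile
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

FASTA_EXTENSIONS = (".fa", ".fasta", ".fna")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC one-letter ambiguity codes accepted (beyond ACGTN) when
#: ``ambiguous="map"``; each is replaced by N.
IUPAC_AMBIGUITY = set("RYSWKMBDHV")


class GenomeInputError(ValueError):
    """Fatal problem with the user's genome archive."""


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRecord:
    """One genome: an id plus an ordered map of contig id -> nucleotide sequence."""

    genome_id: str
    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not seq:
                raise GenomeInputError(
                    f"genome {self.genome_id!r}: contig {cid!r} is empty"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass
class GenomeSet:
    """Ordered collection of genomes (lexicographic by genome id)."""

    genomes: list[GenomeRecord]

    def __post_init__(self) -> None:
        ids = [g.genome_id for g in self.genomes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise GenomeInputError(f"duplicate genome id(s): {', '.join(dup)}")
        self.genomes.sort(key=lambda g: g.genome_id)

    def __iter__(self) -> Iterator[GenomeRecord]:
        return iter(self.genomes)

    def __len__(self) -> int:
        return len(self.genomes)

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]

    def __getitem__(self, genome_id: str) -> GenomeRecord:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)


def _normalize_sequence(seq: str, *, source: str, ambiguous: str) -> str:
    """Uppercase, U->T, and resolve IUPAC ambiguity codes.

    ``ambiguous="map"`` replaces non-N ambiguity codes by N (with a warning);
    ``ambiguous="strict"`` rejects them.  Anything that is not a nucleotide
    code at all is always rejected.
    """
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if not bad:
        return seq
    if not bad <= IUPAC_AMBIGUITY:
        raise GenomeInputError(
            f"{source}: non-nucleotide characters {sorted(bad - IUPAC_AMBIGUITY)}"
        )
    if ambiguous == "strict":
        raise GenomeInputError(
            f"{source}: IUPAC ambiguity codes {sorted(bad)} (strict mode)"
        )
    logger.warning(
        "%s: mapping IUPAC ambiguity codes %s to N", source, sorted(bad)
    )
    table = str.maketrans({c: "N" for c in bad})
    return seq.translate(table)


def _genome_id_from_name(name: str) -> str:
    base = Path(name).name
    for ext in FASTA_EXTENSIONS:
        if base.lower().endswith(ext):
            return base[: -len(ext)]
    return Path(base).stem


def _parse_genome_fasta(
    handle: io.TextIOBase, *, genome_id: str, source: str, ambiguous: str
) -> GenomeRecord:
    contigs: dict[str, str] = {}
    raw_len = 0
    non_acgtn = 0
    for rec in SeqIO.parse(handle, "fasta"):
        seq = str(rec.seq)
        raw_len += len(seq)
        up = seq.upper().replace("U", "T")
        non_acgtn += sum(1 for c in up if c not in "ACGTN")
        if rec.id in contigs:
            raise GenomeInputError(f"{source}: duplicate contig id {rec.id!r}")
        contigs[rec.id] = up
    if not contigs:
        raise GenomeInputError(f"{source}: no FASTA records")
    if raw_len and non_acgtn / raw_len > 0.20:
        raise GenomeInputError(
            f"{source}: {100 * non_acgtn / raw_len:.1f}% non-ACGTN characters; "
            "not a nucleotide FASTA"
        )
    contigs = {
        cid: _normalize_sequence(s, source=f"{source}:{cid}", ambiguous=ambiguous)
        for cid, s in contigs.items()
    }
    return GenomeRecord(genome_id=genome_id, contigs=contigs)


def _iter_fasta_members(path: Path) -> Iterable[tuple[str, str]]:
    """Yield (member name, text content) for every FASTA member of *path*.

    *path* may be a directory, a .zip archive, or a .tar.gz archive.
    """
    def is_fasta(name: str) -> bool:
        base = Path(name).name
        return not base.startswith(".") and base.lower().endswith(FASTA_EXTENSIONS)

    if path.is_dir():
        for p in sorted(path.rglob("*")):
            if p.is_file() and is_fasta(p.name):
                yield p.name, p.read_text()
    elif zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            for info in zf.infolist():
                if not info.is_dir() and is_fasta(info.filename):
                    yield info.filename, zf.read(info).decode()
    elif tarfile.is_tarfile(path):
        with tarfile.open(path, "r:*") as tf:
            for member in tf.getmembers():
                if member.isfile() and is_fasta(member.name):
                    data = tf.extractfile(member)
                    assert data is not None
                    yield member.name, data.read().decode()
    else:
        raise GenomeInputError(
            f"{path}: not a directory, .zip, or .tar(.gz) archive"
        )


def read_genome_archive(path: str | Path, *, ambiguous: str = "map") -> GenomeSet:
    """Read every FASTA file in a directory or zip/tar.gz archive into a GenomeSet.

    One :class:`GenomeRecord` per file; genome id = basename minus extension.
    Sequences are uppercased, U is mapped to T, and IUPAC ambiguity codes are
    mapped to N (``ambiguous="map"``, default, with a warning) or rejected
    (``ambiguous="strict"``).  Fails fast with the offending file named.
    """
    path = Path(path)
    if not path.exists():
        raise GenomeInputError(f"{path}: no such file or directory")
    genomes: list[GenomeRecord] = []
    seen: set[str] = set()
    for name, text in _iter_fasta_members(path):
        gid = _genome_id_from_name(name)
        if gid in seen:
            raise GenomeInputError(f"duplicate genome id {gid!r} (file {name})")
        seen.add(gid)
        genomes.append(
            _parse_genome_fasta(
                io.StringIO(text), genome_id=gid, source=name, ambiguous=ambiguous
            )
        )
    if not genomes:
        raise GenomeInputError(f"{path}: no genomes (no .fa/.fasta/.fna files found)")
    return GenomeSet(genomes)


def write_fasta(records: Mapping[str, str], path: str | Path, *, width: int = 60) -> None:
    """Write an id -> sequence map as FASTA with 60-column wrapping.

    Ids are written verbatim; the output round-trips through any standard
    FASTA reader.
    """
    path = Path(path)
    with path.open("w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence map (verbatim case)."""
    with Path(path).open() as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
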