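"""Per-orthogroup protein MSAs and codon-level back-translation.

The built-in aligner is center-star progressive: the center sequence is
the one maximising its summed pairwise global-alignment score against the
others (Needleman–Wunsch, BLOSUM62, affine gaps 11/1), and the remaining
sequences are merged against it under "once a gap, always a gap".  The
production-quality external alternative is MAFFT ``--auto`` through
:func:`external_aligner`; both satisfy the same MSA contract.

Because ORF sequences exclude their stop codon, back-translation is a pure
1 amino acid : 1 codon substitution — every aligned residue is replaced by
its source codon and every gap by ``---``.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from .genome_io import read_fasta, write_fasta
from .orf import translate
from .search import make_aligner

logger = logging.getLogger(__name__)


@dataclass
class ProteinMSA:
    """Aligned amino-acid rows (orf id -> gapped string), all equal length."""

    og_id: str
    rows: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.og_id}: ragged alignment rows {lengths}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def degapped(self, row_id: str) -> str:
        return self.rows[row_id].replace("-", "")


@dataclass
class CodonMSA:
    """Nucleotide alignment whose columns come in triplets mirroring a ProteinMSA."""

    og_id: str
    rows: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, s in self.rows.items():
            if len(s) % 3 != 0:
                raise ValueError(f"{self.og_id}/{rid}: codon row length not divisible by 3")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.og_id}: ragged codon rows")


def _merge_into_star(
    rows: list[list[str]], center_aligned: str, new_aligned: str
) -> list[str]:
    """Merge one pairwise alignment against the center into the growing MSA.

    ``rows[0]`` is the center's current gapped row; gaps already present in
    the master stay ("once a gap, always a gap"), and gaps the new pairwise
    alignment opens in the center are inserted into every existing row.
    """
    master = rows[0]
    out: list[list[str]] = [[] for _ in rows]
    new_row: list[str] = []
    i = j = 0
    while i < len(master) or j < len(center_aligned):
        if i < len(master) and master[i] == "-":
            for dst, src in zip(out, rows):
                dst.append(src[i])
            new_row.append("-")
            i += 1
        elif j < len(center_aligned) and center_aligned[j] == "-":
            for dst in out:
                dst.append("-")
            new_row.append(new_aligned[j])
            j += 1
        else:
            for dst, src in zip(out, rows):
                dst.append(src[i])
            new_row.append(new_aligned[j])
            i += 1
            j += 1
    merged = ["".join(r) for r in out]
    merged.append("".join(new_row))
    return merged


def align_proteins(seqs: dict[str, str], *, og_id: str = "OG") -> ProteinMSA:
    """Center-star progressive multiple alignment of protein sequences.

    Input order is fixed by sorting on orf id, making the output
    deterministic.  A single sequence passes through unaligned.
    """
    if not seqs:
        raise ValueError("cannot align an empty sequence set")
    ids = sorted(seqs)
    if len(ids) == 1:
        return ProteinMSA(og_id=og_id, rows={ids[0]: seqs[ids[0]]})
    aligner = make_aligner(mode="global")
    # center = sequence maximising summed pairwise global scores; ties -> smallest id
    totals = {i: 0.0 for i in ids}
    for a_idx in range(len(ids)):
        for b_idx in range(a_idx + 1, len(ids)):
            a, b = ids[a_idx], ids[b_idx]
            s = float(aligner.score(seqs[a], seqs[b]))
            totals[a] += s
            totals[b] += s
    center = min(ids, key=lambda i: (-totals[i], i))
    rows = [seqs[center]]
    order = [center]
    for other in ids:
        if other == center:
            continue
        aln = aligner.align(seqs[center], seqs[other])[0]
        rows = _merge_into_star(rows, str(aln[0]), str(aln[1]))
        order.append(other)
    by_id = dict(zip(order, rows))
    msa = ProteinMSA(og_id=og_id, rows={i: by_id[i] for i in ids})
    for i in ids:
        assert msa.degapped(i) == seqs[i]
    return msa


@dataclass
class AlignerConfig:
    binary: str = "mafft"
    flags: tuple[str, ...] = ("--auto",)


def external_aligner(
    seqs: dict[str, str], config: AlignerConfig | None = None, *, og_id: str = "OG"
) -> ProteinMSA:
    """Align with MAFFT (``--auto``); falls back to the built-in aligner.

    Row order follows the same orf-id sort as the built-in aligner so the
    two engines are drop-in interchangeable downstream.
    """
    config = config or AlignerConfig()
    ids = sorted(seqs)
    if len(ids) == 1:
        return ProteinMSA(og_id=og_id, rows={ids[0]: seqs[ids[0]]})
    if shutil.which(config.binary) is None:
        logger.warning(
            "aligner %r not found; falling back to built-in center-star aligner",
            config.binary,
        )
        return align_proteins(seqs, og_id=og_id)
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.faa"
        write_fasta({i: seqs[i] for i in ids}, inp)
        proc = subprocess.run(
            [config.binary, *config.flags, str(inp)],
            check=True, capture_output=True, text=True,
        )
        aligned = {}
        out = Path(tmp) / "out.faa"
        out.write_text(proc.stdout)
        aligned = {rid: s.upper() for rid, s in read_fasta(out).items()}
    return ProteinMSA(og_id=og_id, rows={i: aligned[i] for i in ids})


def back_translate(pmsa: ProteinMSA, nt_seqs: dict[str, str]) -> CodonMSA:
    """Replace each aligned residue by its source codon; '-' becomes '---'."""
    rows = {}
    for rid, aa_row in pmsa.rows.items():
        nt = nt_seqs.get(rid)
        if nt is None:
            raise ValueError(f"{pmsa.og_id}: no nucleotide sequence for {rid}")
        degapped = aa_row.replace("-", "")
        if len(nt) != 3 * len(degapped):
            raise ValueError(
                f"{pmsa.og_id}/{rid}: nucleotide length {len(nt)} != 3 x "
                f"{len(degapped)} aligned residues"
            )
        if translate(nt, as_start=True) != degapped:
            raise ValueError(f"{pmsa.og_id}/{rid}: nucleotide sequence does not translate to aligned row")
        codons = []
        k = 0
        for aa in aa_row:
            if aa == "-":
                codons.append("---")
            else:
                codons.append(nt[3 * k : 3 * k + 3])
                k += 1
        rows[rid] = "".join(codons)
    return CodonMSA(og_id=pmsa.og_id, rows=rows)


def concatenate_core(
    msas: list[ProteinMSA],
    genome_order: list[str],
    genome_of: dict[str, str],
) -> tuple[ProteinMSA, list[tuple[str, int, int]]]:
    """Concatenate single-copy core orthogroup MSAs into a supermatrix.

    Orthogroups missing a genome or carrying paralogs are excluded (counted
    and logged).  Returns the genome-keyed supermatrix and a partition
    table of per-orthogroup column intervals (1-based inclusive).
    """
    parts: dict[str, list[str]] = {g: [] for g in genome_order}
    partition: list[tuple[str, int, int]] = []
    skipped = 0
    col = 0
    for msa in sorted(msas, key=lambda m: m.og_id):
        by_genome: dict[str, str] = {}
        usable = True
        for rid, row in msa.rows.items():
            g = genome_of.get(rid)
            if g is None or g in by_genome:
                usable = False
                break
            by_genome[g] = row
        if not usable or set(by_genome) != set(genome_order):
            skipped += 1
            continue
        width = msa.n_columns
        for g in genome_order:
            parts[g].append(by_genome[g])
        partition.append((msa.og_id, col + 1, col + width))
        col += width
    if skipped:
        logger.warning(
            "%d orthogroup(s) excluded from core concatenation (missing genome or paralogs)",
            skipped,
        )
    if not partition:
        raise ValueError("no single-copy core orthogroups to concatenate")
    super_rows = {g: "".join(parts[g]) for g in genome_order}
    return ProteinMSA(og_id="core_concatenation", rows=super_rows), partition
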