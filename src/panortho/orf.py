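"""ORF extraction, translation (bacterial code, table 11) and GC content.

The built-in finder is a deterministic six-frame scanner: for every stop
codon in every frame it reports at most one ORF — the one beginning at the
most upstream in-frame start codon since the previous in-frame stop.  ORFs
shorter than ``min_len_nt`` (stop excluded) and ORFs truncated by contig
ends are discarded.  It deliberately trades the statistical modelling of a
trained gene finder for determinism and zero dependencies; for production
use the Prodigal adapter (:func:`external_orf_caller`) plugs in a trained
caller behind the same record contract.

Coordinate convention, used everywhere in this package: 0-based, half-open,
on the forward strand of the contig; the interval spans start codon through
stop codon inclusive, while ``nt_seq``/``aa_seq`` exclude the stop.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Data import CodonTable

from .genome_io import GenomeRecord, GenomeSet, revcomp, write_fasta

logger = logging.getLogger(__name__)

TRANSLATION_TABLE = 11
DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})
DEFAULT_MIN_LEN_NT = 90

_TABLE11 = CodonTable.unambiguous_dna_by_id[TRANSLATION_TABLE]
STOP_CODONS = frozenset(_TABLE11.stop_codons)  # TAA, TAG, TGA
_CODON_TO_AA = dict(_TABLE11.forward_table)


class TranslationError(ValueError):
    pass


@dataclass
class ORFRecord:
    """A predicted protein-coding region.

    ``start``/``end`` are 0-based half-open forward-strand coordinates
    covering start codon through stop codon; ``nt_seq`` is the coding-strand
    sequence without the stop codon, so ``len(aa_seq) == len(nt_seq) // 3``.
    """

    orf_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    nt_seq: str
    aa_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.orf_id}: bad strand {self.strand!r}")
        if (self.end - self.start) % 3 != 0 or self.end - self.start != len(self.nt_seq) + 3:
            raise ValueError(
                f"{self.orf_id}: span {self.end - self.start} inconsistent with "
                f"coding length {len(self.nt_seq)} + stop codon"
            )
        if len(self.aa_seq) * 3 != len(self.nt_seq):
            raise ValueError(f"{self.orf_id}: aa/nt length mismatch")
        if "*" in self.aa_seq:
            raise ValueError(f"{self.orf_id}: internal stop in translation")


@dataclass
class ProteomeTable:
    """Per-genome ORF lists with globally unique orf ids."""

    orfs_by_genome: dict[str, list[ORFRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [o.orf_id for orfs in self.orfs_by_genome.values() for o in orfs]
        if len(ids) != len(set(ids)):
            raise ValueError("orf ids are not globally unique")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.orfs_by_genome)

    def orf_counts(self) -> dict[str, int]:
        return {g: len(orfs) for g, orfs in self.orfs_by_genome.items()}

    def all_orfs(self) -> list[ORFRecord]:
        return [o for orfs in self.orfs_by_genome.values() for o in orfs]

    def by_id(self) -> dict[str, ORFRecord]:
        return {o.orf_id: o for o in self.all_orfs()}


def translate(nt_seq: str, *, table: int = TRANSLATION_TABLE, as_start: bool = False) -> str:
    """Translate an in-frame coding sequence under the bacterial genetic code.

    With ``as_start`` the first codon, if it is a recognised start
    (ATG/GTG/TTG), is rendered as M regardless of its table-11 amino acid —
    the initiator tRNA carries formyl-methionine.  A stop codon anywhere is
    an error: ORF sequences in this package never include their stop.
    """
    if table != TRANSLATION_TABLE:
        raise ValueError("only translation table 11 is supported")
    if len(nt_seq) % 3 != 0:
        raise TranslationError(f"sequence length {len(nt_seq)} not divisible by 3")
    aas = []
    for i in range(0, len(nt_seq), 3):
        codon = nt_seq[i : i + 3]
        if codon in STOP_CODONS:
            raise TranslationError(f"stop codon {codon} at nt position {i}")
        aa = _CODON_TO_AA.get(codon, "X")  # codons containing N -> X
        aas.append(aa)
    if as_start and aas and nt_seq[:3] in DEFAULT_START_CODONS:
        aas[0] = "M"
    return "".join(aas)


def _scan_strand(
    seq: str, *, min_len_nt: int, start_codons: frozenset[str]
) -> list[tuple[int, int]]:
    """ORF intervals (0-based half-open, incl. stop) on the given strand of *seq*.

    One ORF per stop codon at most: from the most upstream start codon after
    the previous in-frame stop.  ORFs with no terminating stop before the
    sequence end are truncated and discarded.
    """
    n = len(seq)
    orfs: list[tuple[int, int]] = []
    for frame in range(3):
        pending_start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if pending_start is not None and i - pending_start >= min_len_nt:
                    orfs.append((pending_start, i + 3))
                pending_start = None
            elif pending_start is None and codon in start_codons:
                pending_start = i
    return orfs


def find_orfs(
    genome: GenomeRecord,
    *,
    min_len_nt: int = DEFAULT_MIN_LEN_NT,
    start_codons: frozenset[str] = DEFAULT_START_CODONS,
) -> list[ORFRecord]:
    """Six-frame longest-ORF-per-stop extraction for one genome.

    Coordinates are reported on the forward strand; minus-strand intervals
    are mirrored accordingly.  ORFs containing N (untranslatable codons)
    are kept with X residues.  Results are sorted by (contig, start, strand)
    and numbered ``<genome>_<serial>``.
    """
    if min_len_nt < 3 or min_len_nt % 3 != 0:
        raise ValueError("min_len_nt must be >= 3 and divisible by 3")
    found: list[tuple[str, int, int, str, str]] = []
    for contig_id, seq in genome.contigs.items():
        for start, end in _scan_strand(seq, min_len_nt=min_len_nt, start_codons=start_codons):
            found.append((contig_id, start, end, "+", seq[start : end - 3]))
        rc = revcomp(seq)
        for start, end in _scan_strand(rc, min_len_nt=min_len_nt, start_codons=start_codons):
            # mirror onto forward strand: rc position p <-> forward len-1-p
            f_start, f_end = len(seq) - end, len(seq) - start
            found.append((contig_id, f_start, f_end, "-", rc[start : end - 3]))
    found.sort(key=lambda t: (t[0], t[1], t[3]))
    records = []
    for serial, (contig_id, start, end, strand, nt) in enumerate(found, 1):
        records.append(
            ORFRecord(
                orf_id=f"{genome.genome_id}_{serial:05d}",
                genome_id=genome.genome_id,
                contig_id=contig_id,
                start=start,
                end=end,
                strand=strand,
                nt_seq=nt,
                aa_seq=translate(nt, as_start=True),
            )
        )
    return records


def resolve_overlaps(
    orfs: list[ORFRecord], *, max_overlap_frac: float = 0.5
) -> list[ORFRecord]:
    """Longest-ORF-wins resolution of overlapping six-frame calls.

    A raw six-frame scan reports "shadow" ORFs — stop-free stretches on the
    other frames and strand of a real gene — alongside the gene itself.
    Trained gene finders suppress these with a coding model; here the
    standard length heuristic is used instead: ORFs are kept longest-first,
    and a candidate is dropped when more than ``max_overlap_frac`` of its
    genomic span overlaps an already-kept ORF on the same contig.  Genuine
    genes are the longest ORFs at their locus, so they always survive;
    modest real overlaps (operon boundaries) below the threshold are kept.
    """
    kept: list[ORFRecord] = []
    by_contig: dict[str, list[ORFRecord]] = {}
    for o in sorted(orfs, key=lambda o: (-(o.end - o.start), o.orf_id)):
        span = o.end - o.start
        clashes = False
        for k in by_contig.get(o.contig_id, ()):
            ov = min(o.end, k.end) - max(o.start, k.start)
            if ov > max_overlap_frac * span:
                clashes = True
                break
        if not clashes:
            kept.append(o)
            by_contig.setdefault(o.contig_id, []).append(o)
    kept.sort(key=lambda o: (o.contig_id, o.start, o.strand))
    return kept


def build_proteomes(
    genomes: GenomeSet,
    *,
    min_len_nt: int = DEFAULT_MIN_LEN_NT,
    caller: str = "builtin",
    adapter_config: "ProdigalConfig | None" = None,
    overlap_resolution: bool = True,
) -> ProteomeTable:
    """Run the configured ORF caller over every genome.

    With the built-in caller, overlapping six-frame calls are resolved
    longest-first (:func:`resolve_overlaps`) unless disabled; external
    callers apply their own overlap model and are taken verbatim.
    """
    table: dict[str, list[ORFRecord]] = {}
    for genome in genomes:
        if caller == "prodigal":
            table[genome.genome_id] = external_orf_caller(
                genome, adapter_config or ProdigalConfig()
            )
        else:
            orfs = find_orfs(genome, min_len_nt=min_len_nt)
            if overlap_resolution:
                orfs = resolve_overlaps(orfs)
            table[genome.genome_id] = orfs
    return ProteomeTable(table)


def gc_content(orfs: list[ORFRecord]) -> float:
    """G+C fraction over the concatenated coding sequences of a genome's ORFs.

    N bases count in neither numerator nor denominator.
    """
    if not orfs:
        raise ValueError("no ORFs for genome")
    gc = acgt = 0
    for o in orfs:
        for c in o.nt_seq:
            if c in "GC":
                gc += 1
                acgt += 1
            elif c in "AT":
                acgt += 1
    if acgt == 0:
        raise ValueError("no unambiguous bases in ORFs")
    return gc / acgt


@dataclass
class ProdigalConfig:
    """How to invoke the external gene caller."""

    binary: str = "prodigal"
    mode: str = "single"  # passed verbatim to -p ("single" == normal mode)
    extra_args: tuple[str, ...] = ()


def external_orf_caller(genome: GenomeRecord, config: ProdigalConfig | None = None) -> list[ORFRecord]:
    """Call ORFs with Prodigal, mapped onto the package's record conventions.

    Prodigal's GFF output is 1-based inclusive with the stop codon included;
    records are converted to 0-based half-open.  Genes flagged as partial
    (running off a contig edge) are dropped, matching the built-in finder's
    discard-truncated rule.  If the binary is missing the built-in finder is
    used instead, with a warning.
    """
    config = config or ProdigalConfig()
    if shutil.which(config.binary) is None:
        logger.warning(
            "external gene caller %r not found; falling back to built-in ORF finder",
            config.binary,
        )
        return find_orfs(genome)
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "genome.fa"
        gff = Path(tmp) / "genes.gff"
        write_fasta(genome.contigs, fasta)
        cmd = [
            config.binary, "-i", str(fasta), "-o", str(gff),
            "-f", "gff", "-p", config.mode, "-q", *config.extra_args,
        ]
        subprocess.run(cmd, check=True, capture_output=True)
        rows = _parse_prodigal_gff(gff.read_text())
    records: list[ORFRecord] = []
    serial = 0
    for contig_id, start1, end1, strand, partial in rows:
        if partial != "00":
            continue
        start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
        seq = genome.contigs[contig_id][start:end]
        nt = seq[:-3] if strand == "+" else revcomp(seq)[:-3]
        try:
            aa = translate(nt, as_start=True)
        except TranslationError:
            logger.warning("skipping caller gene with internal stop at %s:%d-%d", contig_id, start, end)
            continue
        serial += 1
        records.append(
            ORFRecord(
                orf_id=f"{genome.genome_id}_{serial:05d}",
                genome_id=genome.genome_id,
                contig_id=contig_id,
                start=start,
                end=end,
                strand=strand,
                nt_seq=nt,
                aa_seq=aa,
            )
        )
    return records


def _parse_prodigal_gff(text: str) -> list[tuple[str, int, int, str, str]]:
    """(contig, start 1-based, end inclusive, strand, partial flag) per CDS line."""
    rows = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9 or fields[2] != "CDS":
            continue
        contig, _, _, start, end, _, strand, _, attrs = fields
        partial = "00"
        for kv in attrs.split(";"):
            if kv.startswith("partial="):
                partial = kv.split("=", 1)[1]
        try:
            rows.append((contig, int(start), int(end), strand, partial))
        except ValueError as e:
            raise ValueError(f"malformed gene caller output at line {lineno}: {line!r}") from e
    return rows
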