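"""All-against-all translated homology search.

Every ORF is compared against every ORF of every *other* genome and, per
(query ORF, target genome), only the best-scoring target is recorded — the
raw material of reciprocal-best-hit orthology.  ORFs are extracted in
frame, so the built-in engine scores their translations directly with
Smith–Waterman local alignment under BLOSUM62 and BLAST-default affine gap
costs (11 to open a gap, +1 per residue); a six-frame nucleotide search
would be redundant here.  An adapter accepts the standard 12-column tabular
output of external engines under identical filter/tie-break semantics.

Recorded hit scores are bit scores: the raw Smith-Waterman score rescaled
by the standard Karlin-Altschul parameters for BLOSUM62 with 11/1 gaps
(lambda = 0.267, K = 0.041), the same scale the 12th column of tabular
search output uses.  The score floor (``min_score``, default 50 bits)
stands in for an engine's significance threshold: a 50-bit hit is a
genuinely significant match, while chance local alignments between
unrelated ~100-300 aa proteins stay in the 20-30 bit range.  Rescaling is
strictly monotonic, so top-hit choices and tie-breaks are identical to
those under raw scores.
"""

from __future__ import annotations

import itertools
import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .orf import ProteomeTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 50.0  # bits
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1

# Karlin-Altschul parameters for gapped BLOSUM62, gap costs 11 + k
BLOSUM62_GAPPED_LAMBDA = 0.267
BLOSUM62_GAPPED_K = 0.041


def bit_score(raw_score: float) -> float:
    """Raw BLOSUM62 11/1 local alignment score on the bit-score scale.

    An empty alignment (raw 0) is reported as 0 bits rather than the
    formula's positive offset.
    """
    if raw_score <= 0:
        return 0.0
    return (BLOSUM62_GAPPED_LAMBDA * raw_score - math.log(BLOSUM62_GAPPED_K)) / math.log(2)


@dataclass(frozen=True)
class PairScore:
    query_orf_id: str
    target_orf_id: str
    score: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("scores are non-negative")


@dataclass
class TopHitTable:
    """(query orf, target genome) -> best PairScore in that genome."""

    hits: dict[tuple[str, str], PairScore] = field(default_factory=dict)
    genome_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (q, tg), ps in self.hits.items():
            if self.genome_of and self.genome_of.get(ps.target_orf_id) != tg:
                raise ValueError(f"hit ({q},{tg}) targets an ORF outside genome {tg}")
            if self.genome_of and self.genome_of.get(q) == tg:
                raise ValueError(f"hit ({q},{tg}) targets the query's own genome")

    def top_hit(self, query_orf_id: str, target_genome: str) -> PairScore | None:
        return self.hits.get((query_orf_id, target_genome))


def make_aligner(
    matrix: str = "BLOSUM62",
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    mode: str = "local",
) -> Align.PairwiseAligner:
    """Affine-gap aligner; a length-k gap costs gap_open + k * gap_extend."""
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def score_pair(
    aa_a: str,
    aa_b: str,
    *,
    matrix: str = "BLOSUM62",
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    aligner: Align.PairwiseAligner | None = None,
) -> float:
    """Optimal Smith–Waterman local alignment score of two proteins.

    Symmetric in its arguments; 0 when no positive-scoring local alignment
    exists.  Pass a pre-built ``aligner`` to amortise setup in bulk scoring.
    """
    if not aa_a or not aa_b:
        raise ValueError("cannot score an empty sequence")
    if aligner is None:
        aligner = make_aligner(matrix, gap_open, gap_extend)
    return max(0.0, float(aligner.score(aa_a, aa_b)))


def min_score_filter(
    hits: list[PairScore], min_score: float = DEFAULT_MIN_SCORE
) -> list[PairScore]:
    """Drop hits scoring below the floor (applied before top-hit selection)."""
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    return [h for h in hits if h.score >= min_score]


def all_vs_all_top_hits(
    proteomes: ProteomeTable,
    *,
    min_score: float = DEFAULT_MIN_SCORE,
    matrix: str = "BLOSUM62",
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> TopHitTable:
    """For every ORF, its best hit in each other genome.

    The built-in scorer is symmetric, so each unordered cross-genome pair is
    scored once; scores are recorded in bits and floored at ``min_score``.
    Ties on score are broken by lexicographically smallest target orf id;
    the result is independent of genome input order.
    """
    genome_ids = sorted(proteomes.genome_ids)
    if len(genome_ids) < 2:
        raise ValueError("need at least 2 genomes for all-against-all search")
    logger.info(
        "all-vs-all search: %d genomes, %d ORFs, min_score=%g",
        len(genome_ids), len(proteomes.all_orfs()), min_score,
    )
    aligner = make_aligner(matrix, gap_open, gap_extend)
    genome_of = {o.orf_id: o.genome_id for o in proteomes.all_orfs()}
    # best[(query, target_genome)] = (score, target_id)
    best: dict[tuple[str, str], tuple[float, str]] = {}

    def consider(q: str, tg: str, t: str, s: float) -> None:
        cur = best.get((q, tg))
        if cur is None or (s, _NegStr(t)) > (cur[0], _NegStr(cur[1])):
            best[(q, tg)] = (s, t)

    for ga, gb in itertools.combinations(genome_ids, 2):
        for oa in proteomes.orfs_by_genome[ga]:
            for ob in proteomes.orfs_by_genome[gb]:
                s = bit_score(float(aligner.score(oa.aa_seq, ob.aa_seq)))
                if s < min_score:
                    continue
                consider(oa.orf_id, gb, ob.orf_id, s)
                consider(ob.orf_id, ga, oa.orf_id, s)
    hits = {
        key: PairScore(query_orf_id=key[0], target_orf_id=t, score=s)
        for key, (s, t) in best.items()
    }
    return TopHitTable(hits=hits, genome_of=genome_of)


class _NegStr(str):
    """Orders strings in reverse, so (score, _NegStr(id)) maxes score then min id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


@dataclass
class SearchEngineConfig:
    """External all-vs-all engine invocation (e.g. mmseqs easy-search)."""

    binary: str = "mmseqs"
    extra_args: tuple[str, ...] = ()


def external_search_adapter(
    proteomes: ProteomeTable,
    engine_config: SearchEngineConfig | None = None,
    *,
    min_score: float = DEFAULT_MIN_SCORE,
) -> TopHitTable:
    """Run an external search engine and parse its tabular output.

    The engine must emit standard 12-column tabular hits (query, target,
    identity, length, mismatches, gap opens, qstart, qend, tstart, tend,
    e-value, bitscore); filtering and tie-breaking then match the built-in
    engine exactly.  A missing binary falls back to the built-in search with
    a warning.
    """
    engine_config = engine_config or SearchEngineConfig()
    if shutil.which(engine_config.binary) is None:
        logger.warning(
            "search engine %r not found; falling back to built-in Smith-Waterman search",
            engine_config.binary,
        )
        return all_vs_all_top_hits(proteomes, min_score=min_score)
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        fasta = tmp / "proteome.faa"
        out = tmp / "hits.tsv"
        with fasta.open("w") as fh:
            for o in proteomes.all_orfs():
                fh.write(f">{o.orf_id}\n{o.aa_seq}\n")
        cmd = [
            engine_config.binary, "easy-search", str(fasta), str(fasta),
            str(out), str(tmp / "mmtmp"), *engine_config.extra_args,
        ]
        subprocess.run(cmd, check=True, capture_output=True)
        text = out.read_text()
    return parse_tabular_hits(text, proteomes, min_score=min_score)


def parse_tabular_hits(
    text: str, proteomes: ProteomeTable, *, min_score: float = DEFAULT_MIN_SCORE
) -> TopHitTable:
    """Build a TopHitTable from 12-column tabular search output."""
    genome_of = {o.orf_id: o.genome_id for o in proteomes.all_orfs()}
    best: dict[tuple[str, str], tuple[float, str]] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ValueError(f"malformed search output at line {lineno}: {line!r}")
        q, t = fields[0], fields[1]
        try:
            score = float(fields[11])
        except ValueError:
            raise ValueError(f"malformed search output at line {lineno}: {line!r}")
        if q not in genome_of or t not in genome_of:
            raise ValueError(f"unknown orf id in search output at line {lineno}")
        tg = genome_of[t]
        if tg == genome_of[q] or score < min_score:
            continue
        cur = best.get((q, tg))
        if cur is None or (score, _NegStr(t)) > (cur[0], _NegStr(cur[1])):
            best[(q, tg)] = (score, t)
    hits = {
        key: PairScore(query_orf_id=key[0], target_orf_id=t, score=s)
        for key, (s, t) in best.items()
    }
    return TopHitTable(hits=hits, genome_of=genome_of)


def write_hits_table(table: TopHitTable, path: str | Path) -> None:
    """Tab-separated (query, target, score) top-hit dump."""
    with Path(path).open("w") as fh:
        fh.write("query\ttarget\tscore\n")
        for (q, _tg), ps in sorted(table.hits.items()):
            fh.write(f"{q}\t{ps.target_orf_id}\t{ps.score:g}\n")
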