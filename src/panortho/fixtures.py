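"""Synthetic pan-genome generator with known orthology ground truth.

Evolution is emulated at the level the pipeline measures: a set of
ancestral gene families is drawn (random codon sequences between a start
codon and a stop), each genome independently loses each family with
probability ``gene_loss_prob``, retained copies accumulate per-site
substitutions at ``sub_rate`` (codons that would become stops, and start
codons that would stop being starts, are resampled so every planted gene
stays a structurally valid ORF), and genome-private "gained" genes are
added at ``gain_rate`` (expected private genes per genome = gain_rate x
n_ancestral_genes).  Genes are placed on a contig in shuffled order, on
random strands, separated by random intergenic spacers of 50-500 nt; an
in-frame stop codon is planted immediately upstream of every gene so the
deterministic ORF finder recovers exactly the planted start.

Not emulated: indels, rearrangements, gene duplication (paralogs), codon
usage bias, sequencing/assembly error.  Pipeline recovery on these genomes
therefore measures orthology inference under substitution divergence and
presence/absence variation only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .genome_io import GenomeRecord, GenomeSet, revcomp
from .orf import ORFRecord, ProteomeTable, STOP_CODONS
from .orthogroups import OrthogroupTable

BASES = "ACGT"
START_CODONS = ("ATG", "GTG", "TTG")
_ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
NONSTOP_CODONS = [c for c in _ALL_CODONS if c not in STOP_CODONS]


@dataclass(frozen=True)
class PangenomeParams:
    """Study conditions for the synthetic pan-genome."""

    n_genomes: int = 10
    n_ancestral_genes: int = 100
    gene_loss_prob: float = 0.1
    gain_rate: float = 0.1
    sub_rate: float = 0.02
    gene_len: tuple[int, int] = (300, 900)  # nt, start codon incl., stop excl.
    spacer_len: tuple[int, int] = (50, 500)

    def validate(self) -> None:
        if self.sub_rate >= 0.3:
            raise ValueError("sub_rate must be < 0.3 to keep homology detectable")
        if self.n_ancestral_genes < 1:
            raise ValueError("need at least one ancestral gene family")
        if not (0 <= self.gene_loss_prob < 1) or self.gain_rate < 0:
            raise ValueError("invalid loss/gain rates")
        lo, hi = self.gene_len
        if lo < 6 or lo > hi:
            raise ValueError("invalid gene length range")


@dataclass(frozen=True)
class PlantedGene:
    """One gene instance as placed in a genome."""

    gene_id: str
    family_id: str
    genome_id: str
    contig_id: str
    start: int  # 0-based half-open, forward strand, incl. stop codon
    end: int
    strand: str
    nt_seq: str  # coding strand, stop excluded


@dataclass
class SyntheticPangenome:
    genomes: GenomeSet
    truth: list[PlantedGene]
    params: PangenomeParams
    seed: int

    @property
    def families(self) -> dict[str, list[PlantedGene]]:
        fams: dict[str, list[PlantedGene]] = {}
        for g in self.truth:
            fams.setdefault(g.family_id, []).append(g)
        return fams

    def fully_retained_families(self) -> list[str]:
        """Ancestral families with a member in every genome."""
        n = len(self.genomes)
        return sorted(
            f for f, members in self.families.items()
            if f.startswith("F") and len({m.genome_id for m in members}) == n
        )


def _random_gene(rng: np.random.Generator, lo: int, hi: int) -> str:
    n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
    start = START_CODONS[int(rng.integers(len(START_CODONS)))]
    body = rng.choice(len(NONSTOP_CODONS), size=n_codons - 1)
    return start + "".join(NONSTOP_CODONS[i] for i in body)


def _mutate(rng: np.random.Generator, nt: str, sub_rate: float) -> str:
    """Per-site substitution avoiding stop codons and start-codon loss."""
    seq = list(nt)
    hit = np.flatnonzero(rng.random(len(seq)) < sub_rate)
    for pos in hit:
        old = seq[pos]
        choices = [b for b in BASES if b != old]
        seq[pos] = choices[int(rng.integers(3))]
        codon_start = (pos // 3) * 3
        codon = "".join(seq[codon_start : codon_start + 3])
        bad = codon in STOP_CODONS or (codon_start == 0 and codon not in START_CODONS)
        if bad:
            seq[pos] = old  # revert: the site's substitution was not viable
    return "".join(seq)


def _random_spacer(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _random_stop(rng: np.random.Generator) -> str:
    stops = sorted(STOP_CODONS)
    return stops[int(rng.integers(len(stops)))]


def generate_pangenome(
    params: PangenomeParams | None = None, seed: int = 0
) -> SyntheticPangenome:
    """Simulate a pan-genome; deterministic for a given (params, seed)."""
    params = params or PangenomeParams()
    params.validate()
    rng = np.random.default_rng(seed)
    lo, hi = params.gene_len
    families = {
        f"F{i:04d}": _random_gene(rng, lo, hi)
        for i in range(1, params.n_ancestral_genes + 1)
    }
    genomes: list[GenomeRecord] = []
    truth: list[PlantedGene] = []
    for gi in range(params.n_genomes):
        genome_id = f"g{gi:02d}"
        contig_id = "c1"
        genes: list[tuple[str, str, str]] = []  # (gene_id, family_id, nt)
        for fam_id, anc in sorted(families.items()):
            if rng.random() < params.gene_loss_prob:
                continue
            nt = _mutate(rng, anc, params.sub_rate)
            genes.append((f"{genome_id}.{fam_id}", fam_id, nt))
        n_private = rng.poisson(params.gain_rate * params.n_ancestral_genes)
        for k in range(n_private):
            fam_id = f"P_{genome_id}_{k:03d}"  # genome-private family
            genes.append((f"{genome_id}.{fam_id}", fam_id, _random_gene(rng, lo, hi)))
        order = rng.permutation(len(genes))
        pieces: list[str] = []
        pos = 0
        slo, shi = params.spacer_len
        for idx in order:
            gene_id, fam_id, nt = genes[idx]
            spacer = _random_spacer(rng, slo, shi)
            pieces.append(spacer)
            pos += len(spacer)
            strand = "+" if rng.random() < 0.5 else "-"
            # frame-anchoring stop upstream + gene + its stop, on the coding strand
            cassette = _random_stop(rng) + nt + _random_stop(rng)
            if strand == "-":
                # forward layout: revcomp(stop) + revcomp(gene) + revcomp(anchor)
                placed = revcomp(cassette)
                start, end = pos, pos + len(nt) + 3
            else:
                placed = cassette
                start, end = pos + 3, pos + 3 + len(nt) + 3
            pieces.append(placed)
            pos += len(placed)
            truth.append(
                PlantedGene(
                    gene_id=gene_id, family_id=fam_id, genome_id=genome_id,
                    contig_id=contig_id, start=start, end=end, strand=strand,
                    nt_seq=nt,
                )
            )
        pieces.append(_random_spacer(rng, slo, shi))
        genomes.append(GenomeRecord(genome_id=genome_id, contigs={contig_id: "".join(pieces)}))
    return SyntheticPangenome(
        genomes=GenomeSet(genomes), truth=truth, params=params, seed=seed
    )


def write_pangenome(pg: SyntheticPangenome, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the archive layout the pipeline consumes plus the truth table."""
    import zipfile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    archive = out_dir / "pangenome.zip"
    with zipfile.ZipFile(archive, "w") as zf:
        for genome in pg.genomes:
            lines = []
            for cid, seq in genome.contigs.items():
                lines.append(f">{cid}")
                lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
            zf.writestr(f"{genome.genome_id}.fasta", "\n".join(lines) + "\n")
    truth_path = out_dir / "truth.tsv"
    with truth_path.open("w") as fh:
        fh.write("gene_id\tfamily_id\tgenome\tcontig\tstart\tend\tstrand\n")
        for g in pg.truth:
            fh.write(
                f"{g.gene_id}\t{g.family_id}\t{g.genome_id}\t{g.contig_id}\t"
                f"{g.start}\t{g.end}\t{g.strand}\n"
            )
    return archive, truth_path


def match_orfs_to_truth(
    proteomes: ProteomeTable, truth: list[PlantedGene]
) -> dict[str, str]:
    """orf_id -> gene_id, matching by shared stop codon (contig, strand, 3' end).

    A gene finder may pick an upstream in-frame start, but the stop codon of
    a planted gene is unambiguous; matching on it is therefore robust to
    start-site disagreement.
    """
    by_stop: dict[tuple[str, str, str, int], str] = {}
    for g in truth:
        stop_coord = g.end if g.strand == "+" else g.start
        by_stop[(g.genome_id, g.contig_id, g.strand, stop_coord)] = g.gene_id
    mapping = {}
    for orf in proteomes.all_orfs():
        stop_coord = orf.end if orf.strand == "+" else orf.start
        gene = by_stop.get((orf.genome_id, orf.contig_id, orf.strand, stop_coord))
        if gene is not None:
            mapping[orf.orf_id] = gene
    return mapping


@dataclass
class RecoveryScore:
    precision: float
    recall: float
    f1: float
    n_truth_pairs: int
    n_inferred_pairs: int
    precision_defined: bool = True


def score_recovery(
    truth: list[PlantedGene],
    inferred: OrthogroupTable,
    orf_to_gene: dict[str, str],
) -> RecoveryScore:
    """Pairwise precision/recall/F1 of inferred co-clustering vs ground truth.

    The pair universe is the planted gene instances.  Truth pairs are genes
    sharing a family; inferred pairs are matched genes sharing an inferred
    orthogroup (unmatched ORFs — spurious predictions — cannot create
    pairs).  With zero inferred pairs precision is undefined and reported
    as 1.0 with ``precision_defined=False``.
    """
    families: dict[str, list[str]] = {}
    for g in truth:
        families.setdefault(g.family_id, []).append(g.gene_id)
    truth_pairs: set[frozenset[str]] = set()
    for members in families.values():
        for a, b in itertools.combinations(sorted(members), 2):
            truth_pairs.add(frozenset((a, b)))
    inferred_pairs: set[frozenset[str]] = set()
    for og in inferred.og_ids:
        genes = sorted(
            orf_to_gene[m] for m in inferred.all_members(og) if m in orf_to_gene
        )
        for a, b in itertools.combinations(genes, 2):
            inferred_pairs.add(frozenset((a, b)))
    tp = len(truth_pairs & inferred_pairs)
    precision_defined = bool(inferred_pairs)
    precision = tp / len(inferred_pairs) if inferred_pairs else 1.0
    recall = tp / len(truth_pairs) if truth_pairs else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return RecoveryScore(
        precision=precision, recall=recall, f1=f1,
        n_truth_pairs=len(truth_pairs), n_inferred_pairs=len(inferred_pairs),
        precision_defined=precision_defined,
    )
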