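"""End-to-end pipeline: genomes in, comparative-genomics output inventory out.

Stage order: intake -> ORF extraction -> all-vs-all search -> reciprocal
best hits -> Markov clustering -> orthogroup analytics -> per-orthogroup
protein and codon alignments -> x%-core extraction -> core concatenation
-> species tree -> GC content -> summary plots.

The results directory mirrors the six output groups a comparative
genomics study reports: (i) ORF counts, (ii) orthogroup list and size
distribution, (iii) per-orthogroup unaligned/aligned/codon FASTA,
(iv) orthogroup table, phyletic patterns, core list and concatenated core
alignment, (v) species tree in Newick, (vi) GC content per genome; plus a
machine-readable run manifest with parameters and stage checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .alignment import (AlignerConfig, align_proteins, back_translate,
                        concatenate_core, external_aligner)
from .genome_io import read_genome_archive, write_fasta
from .mcl import mcl_cluster, write_clusters
from .orf import build_proteomes, gc_content
from .orthogroups import (build_og_table, core_proteome, og_size_distribution,
                          phyletic_patterns, write_og_table,
                          write_phyletic_fasta)
from .phylogeny import (external_ml_adapter, nj_tree, p_distances,
                        write_newick, write_phylip_distances)
from .rbh import build_rbh_graph, write_edge_list
from .search import all_vs_all_top_hits, write_hits_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_path: str
    output_dir: str
    min_orf_len: int = 90
    min_score: float = 50.0
    inflation: float = 2.0
    core_x_percent: float = 100.0
    orf_caller: str = "builtin"  # builtin | prodigal
    aligner: str = "builtin"  # builtin | mafft
    tree_engine: str = "nj"  # nj | raxml
    seed: int = 0
    threads: int = 1
    plots: bool = True

    def validate(self) -> None:
        if self.min_orf_len < 3 or self.min_orf_len % 3:
            raise ValueError("min_orf_len must be >= 3 and divisible by 3")
        if self.min_score < 0:
            raise ValueError("min_score must be >= 0")
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if not (0 < self.core_x_percent <= 100):
            raise ValueError("core_x_percent must be in (0, 100]")
        if self.orf_caller not in ("builtin", "prodigal"):
            raise ValueError(f"unknown orf_caller {self.orf_caller!r}")
        if self.aligner not in ("builtin", "mafft"):
            raise ValueError(f"unknown aligner {self.aligner!r}")
        if self.tree_engine not in ("nj", "raxml"):
            raise ValueError(f"unknown tree_engine {self.tree_engine!r}")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the full output inventory; returns output dir."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage 1/9: genome intake from %s", config.input_path)
    genomes = read_genome_archive(config.input_path)
    if len(genomes) < 2:
        raise ValueError("orthology analysis requires at least 2 genomes")
    logger.info("  %d genomes", len(genomes))

    logger.info("stage 2/9: ORF extraction (%s caller)", config.orf_caller)
    proteomes = build_proteomes(
        genomes, min_len_nt=config.min_orf_len, caller=config.orf_caller
    )
    orf_dir = out / "i_orf_statistics"
    orf_dir.mkdir(exist_ok=True)
    counts = proteomes.orf_counts()
    with (orf_dir / "orf_counts.tsv").open("w") as fh:
        fh.write("genome\torf_count\n")
        for g in sorted(counts):
            fh.write(f"{g}\t{counts[g]}\n")
    seq_dir = orf_dir / "orfs"
    seq_dir.mkdir(exist_ok=True)
    with (seq_dir / "orf_coordinates.tsv").open("w") as fh:
        fh.write("# coordinates are 0-based half-open on the forward strand, stop codon included\n")
        fh.write("orf_id\tgenome\tcontig\tstart\tend\tstrand\n")
        for o in proteomes.all_orfs():
            fh.write(f"{o.orf_id}\t{o.genome_id}\t{o.contig_id}\t{o.start}\t{o.end}\t{o.strand}\n")
    for g, orfs in proteomes.orfs_by_genome.items():
        write_fasta({o.orf_id: o.nt_seq for o in orfs}, seq_dir / f"{g}.ffn")
        write_fasta({o.orf_id: o.aa_seq for o in orfs}, seq_dir / f"{g}.faa")
    logger.info("  %d ORFs total", sum(counts.values()))

    logger.info("stage 3/9: all-vs-all homology search (min_score=%g)", config.min_score)
    top_hits = all_vs_all_top_hits(proteomes, min_score=config.min_score)
    logger.info("  %d directed top hits", len(top_hits.hits))

    logger.info("stage 4/9: reciprocal best hits")
    graph = build_rbh_graph(top_hits)
    logger.info("  %d RBH edges over %d ORFs", graph.number_of_edges(), graph.number_of_nodes())

    logger.info("stage 5/9: Markov clustering (inflation=%g)", config.inflation)
    clusters = mcl_cluster(graph, inflation=config.inflation)
    logger.info("  %d orthogroups", len(clusters))

    logger.info("stage 6/9: orthogroup analytics")
    og_dir = out / "ii_orthogroups"
    og_dir.mkdir(exist_ok=True)
    write_hits_table(top_hits, og_dir / "top_hits.tsv")
    write_edge_list(graph, og_dir / "rbh_edges.abc")
    write_clusters(clusters, og_dir / "orthogroups.mcl")
    table = build_og_table(clusters, proteomes)
    sizes = og_size_distribution(table)
    with (og_dir / "og_size_distribution.tsv").open("w") as fh:
        fh.write("og_size\tn_orthogroups\n")
        for size, n in sizes.items():
            fh.write(f"{size}\t{n}\n")
    core_dir = out / "iv_orthogroup_tables"
    core_dir.mkdir(exist_ok=True)
    write_og_table(table, core_dir / "orthogroups_table.csv")
    write_phyletic_fasta(phyletic_patterns(table), core_dir / "phyletic_patterns.fasta")
    core_ogs = core_proteome(table, config.core_x_percent)
    (core_dir / "core_orthogroups.txt").write_text(
        "".join(f"{og}\n" for og in core_ogs)
    )
    logger.info("  %d core orthogroups at x=%g%%", len(core_ogs), config.core_x_percent)

    logger.info("stage 7/9: per-orthogroup alignments (%s)", config.aligner)
    aln_dir = out / "iii_alignments"
    aln_dir.mkdir(exist_ok=True)
    by_id = proteomes.by_id()
    align = (
        (lambda s, og: external_aligner(s, AlignerConfig(), og_id=og))
        if config.aligner == "mafft"
        else (lambda s, og: align_proteins(s, og_id=og))
    )
    msas = {}
    for og in table.og_ids:
        members = table.all_members(og)
        aa = {m: by_id[m].aa_seq for m in members}
        nt = {m: by_id[m].nt_seq for m in members}
        pmsa = align(aa, og)
        cmsa = back_translate(pmsa, nt)
        msas[og] = pmsa
        write_fasta(aa, aln_dir / f"{og}.faa")
        write_fasta(pmsa.rows, aln_dir / f"{og}.aln.faa")
        write_fasta(cmsa.rows, aln_dir / f"{og}.codon.fna")

    logger.info("stage 8/9: core concatenation and species tree (%s)", config.tree_engine)
    genome_of = {o.orf_id: o.genome_id for o in proteomes.all_orfs()}
    core_msas = [msas[og] for og in core_ogs if table.occupancy(og) == len(genomes)]
    tree_dir = out / "v_species_tree"
    tree_dir.mkdir(exist_ok=True)
    supermatrix = None
    if core_msas:
        try:
            supermatrix, partition = concatenate_core(
                core_msas, genomes.genome_ids, genome_of
            )
        except ValueError as e:
            logger.warning("no core supermatrix: %s", e)
    if supermatrix is not None:
        write_fasta(supermatrix.rows, core_dir / "core_concatenated.faa")
        with (core_dir / "core_partition.tsv").open("w") as fh:
            fh.write("# columns are 1-based inclusive\n")
            fh.write("orthogroup\tstart\tend\n")
            for og, a, b in partition:
                fh.write(f"{og}\t{a}\t{b}\n")
        dm = p_distances(supermatrix)
        write_phylip_distances(dm, tree_dir / "core_p_distances.phylip")
        if config.tree_engine == "raxml":
            tree = external_ml_adapter(supermatrix)
        else:
            tree = nj_tree(dm)
        write_newick(tree, tree_dir / "species_tree.nwk")
        logger.info("  supermatrix: %d aligned columns", supermatrix.n_columns)
    else:
        logger.warning("species tree skipped: no single-copy core orthogroups")

    logger.info("stage 9/9: GC content")
    gc_dir = out / "vi_gc_content"
    gc_dir.mkdir(exist_ok=True)
    gc = {g: gc_content(orfs) for g, orfs in proteomes.orfs_by_genome.items() if orfs}
    with (gc_dir / "gc_content.tsv").open("w") as fh:
        fh.write("genome\tgc_percent\n")
        for g in sorted(gc):
            fh.write(f"{g}\t{100 * gc[g]:.2f}\n")

    if config.plots:
        summary_plots(
            orf_counts=counts, gc=gc, og_sizes=sizes, out_dir=out
        )

    manifest = {
        "panortho_version": __version__,
        "config": asdict(config),
        "n_genomes": len(genomes),
        "n_orfs": sum(counts.values()),
        "n_orthogroups": len(clusters),
        "n_core_orthogroups": len(core_ogs),
        "supermatrix_columns": supermatrix.n_columns if supermatrix else 0,
        "output_checksums": {
            str(p.relative_to(out)): _checksum(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.suffix != ".png" and p.name != "run_manifest.json"
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline complete: %s", out)
    return out


def summary_plots(
    *, orf_counts: dict[str, int], gc: dict[str, float], og_sizes: dict[int, int],
    out_dir: Path,
) -> list[Path]:
    """Violin/histogram summaries of ORF counts, GC and orthogroup sizes.

    Purely presentational — all numbers come from the tab-separated tables.
    Plot failure never fails the pipeline.
    """
    written: list[Path] = []
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        specs = [
            ("i_orf_statistics/orf_counts_violin.png", list(orf_counts.values()),
             "ORFs per genome", "violin"),
            ("vi_gc_content/gc_violin.png", [100 * v for v in gc.values()],
             "%GC per genome", "violin"),
        ]
        for rel, values, title, kind in specs:
            if not values:
                logger.warning("plot %s skipped: no data", rel)
                continue
            fig, ax = plt.subplots(figsize=(3, 4))
            ax.violinplot(values, showmedians=True)
            ax.set_title(title)
            ax.set_xticks([])
            path = out_dir / rel
            path.parent.mkdir(parents=True, exist_ok=True)
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)
        if og_sizes:
            fig, ax = plt.subplots(figsize=(4, 3))
            sizes = sorted(og_sizes)
            ax.bar(sizes, [og_sizes[s] for s in sizes])
            ax.set_xlabel("orthogroup size (ORFs)")
            ax.set_ylabel("orthogroups")
            path = out_dir / "ii_orthogroups/og_size_histogram.png"
            path.parent.mkdir(parents=True, exist_ok=True)
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)
        else:
            logger.warning("orthogroup size histogram skipped: empty distribution")
    except Exception as e:  # plotting is best-effort
        logger.warning("summary plots failed: %s", e)
    return written
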