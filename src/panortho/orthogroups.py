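"""Orthogroup tables, phyletic patterns, size distributions and x%-core.

Clusters become rows of a genomes-wide table (OG0000001, ..., ordered by
decreasing size then smallest member); per-genome presence/absence across
orthogroups is serialised as binary "phyletic pattern" strings in FASTA
(the layout gain/loss inference servers consume); the core proteome at x%
is the set of orthogroups occupied in at least ceil(x/100 * n_genomes)
genomes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from math import ceil
from pathlib import Path

import pandas as pd

from .mcl import ClusterSet
from .orf import ProteomeTable


@dataclass
class OrthogroupTable:
    """Rows: orthogroups; columns: genomes; cells: ';'-joined member orf ids."""

    table: pd.DataFrame  # index og_id, columns genome ids, cells str ("" if absent)

    @property
    def og_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.table.columns)

    def members(self, og_id: str) -> dict[str, list[str]]:
        """genome -> member orf ids for one orthogroup (absent genomes omitted)."""
        row = self.table.loc[og_id]
        return {g: cell.split(";") for g, cell in row.items() if cell}

    def all_members(self, og_id: str) -> list[str]:
        return [m for ms in self.members(og_id).values() for m in ms]

    def occupancy(self, og_id: str) -> int:
        """Number of genomes with at least one member in the orthogroup."""
        return int((self.table.loc[og_id] != "").sum())

    def size(self, og_id: str) -> int:
        return len(self.all_members(og_id))

    def is_single_copy(self, og_id: str) -> bool:
        row = self.table.loc[og_id]
        return all(cell == "" or ";" not in cell for cell in row)


def build_og_table(clusters: ClusterSet, proteomes: ProteomeTable) -> OrthogroupTable:
    """Assemble the orthogroup x genome membership table from MCL clusters.

    Row order: decreasing total size, then smallest member orf id; cells
    with several members of one genome are ';'-joined in sorted order.
    """
    genome_of = {o.orf_id: o.genome_id for o in proteomes.all_orfs()}
    genome_ids = sorted(proteomes.genome_ids)
    rows = []
    for c in clusters:
        missing = [m for m in c if m not in genome_of]
        if missing:
            raise ValueError(
                f"cluster member(s) not in proteomes: {sorted(missing)[:5]}"
            )
        rows.append(sorted(c))
    rows.sort(key=lambda ms: (-len(ms), min(ms)))
    data = []
    for members in rows:
        cell: dict[str, list[str]] = {g: [] for g in genome_ids}
        for m in members:
            cell[genome_of[m]].append(m)
        data.append({g: ";".join(sorted(ms)) for g, ms in cell.items()})
    index = [f"OG{i:07d}" for i in range(1, len(rows) + 1)]
    df = pd.DataFrame(data, index=index, columns=genome_ids).fillna("")
    return OrthogroupTable(table=df)


def phyletic_patterns(table: OrthogroupTable) -> dict[str, str]:
    """Per-genome binary presence strings across orthogroups (fixed OG order)."""
    out = {}
    present = table.table != ""
    for g in table.genome_ids:
        out[g] = "".join("1" if v else "0" for v in present[g])
    return out


def core_proteome(table: OrthogroupTable, x_percent: float = 100.0) -> list[str]:
    """Orthogroups occupied in at least ceil(x/100 * n_genomes) genomes.

    x = 100 (default) is the strict core: present in every genome.
    """
    if not (0 < x_percent <= 100):
        raise ValueError("x_percent must be in (0, 100]")
    n = len(table.genome_ids)
    threshold = ceil(x_percent / 100.0 * n)
    occ = (table.table != "").sum(axis=1)
    return [og for og in table.og_ids if occ[og] >= threshold]


def og_size_distribution(table: OrthogroupTable) -> dict[int, int]:
    """Histogram: orthogroup size (total member ORFs) -> number of orthogroups."""
    sizes = Counter(table.size(og) for og in table.og_ids)
    return dict(sorted(sizes.items()))


def write_og_table(table: OrthogroupTable, path: str | Path) -> None:
    table.table.to_csv(path, index_label="orthogroup")


def write_phyletic_fasta(patterns: dict[str, str], path: str | Path) -> None:
    """Phyletic patterns as FASTA of 0/1 strings, one record per genome."""
    from .genome_io import write_fasta

    write_fasta(patterns, path)
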