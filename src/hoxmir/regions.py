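"""Hox-cluster gene sets, restricted-denominator FDR and target overlap.

The four Hox clusters (HOXA-D) are defined operationally: every gene
whose transcription start site lies between the start sites of a pair of
boundary genes (e.g. HOXA1-HOXA13) belongs to the cluster, boundary
genes included.  Differential-expression q-values over such a set are
recomputed with a fixed Benjamini-Hochberg denominator m — the size of
the restricted hypothesis family — rather than the genome-wide count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .de import bh_adjust


@dataclass(frozen=True)
class GeneInterval:
    """A gene with 1-based closed coordinates; TSS is strand-dependent."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.name}: start > end")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


def hox_gene_set(
    genes: Sequence[GeneInterval],
    boundary_pairs: Iterable[tuple[str, str]],
) -> set[str]:
    """Genes whose TSS falls between the TSSs of each boundary pair.

    The interval is closed and strand-agnostic on TSS coordinates, the
    boundary genes themselves included; the result is the union over
    pairs.  Genes on other chromosomes are excluded.
    """
    by_name = {g.name: g for g in genes}
    selected: set[str] = set()
    for left_name, right_name in boundary_pairs:
        for bname in (left_name, right_name):
            if bname not in by_name:
                raise KeyError(f"boundary gene {bname!r} not in gene table")
        left, right = by_name[left_name], by_name[right_name]
        if left.chrom != right.chrom:
            raise ValueError(
                f"boundary genes {left_name}/{right_name} lie on different chromosomes"
            )
        lo, hi = sorted((left.tss, right.tss))
        for g in genes:
            if g.chrom == left.chrom and lo <= g.tss <= hi:
                selected.add(g.name)
    return selected


def restricted_de(
    de_table: pd.DataFrame, gene_set: Iterable[str], m: int
) -> pd.DataFrame:
    """Recompute BH q-values over a restricted feature set.

    ``m`` is the correction denominator (the size of the hypothesis
    family, e.g. 55 for the Hox clusters) and must be at least the
    number of set members actually tested.  Other columns pass through
    unchanged.
    """
    members = [f for f in de_table.index if f in set(gene_set)]
    missing = set(gene_set) - set(de_table.index)
    if missing:
        raise KeyError(f"gene set members not among tested features: {sorted(missing)}")
    sub = de_table.loc[members].copy()
    sub["qvalue"] = bh_adjust(sub["pvalue"].to_numpy(), m=m)
    return sub


def target_overlap(target_map: Mapping[str, set[str]]) -> dict:
    """Pairwise and full-intersection shared-target counts.

    Returns a dict with ``pairwise`` ((miRNA a, miRNA b) -> sorted shared
    gene list), ``all_shared`` (genes common to every miRNA) and
    ``total_unique`` (number of distinct targets overall).
    """
    names = list(target_map)
    if len(names) < 2:
        raise ValueError("target overlap requires >= 2 miRNAs")
    sets = {n: set(target_map[n]) for n in names}
    pairwise = {
        (a, b): sorted(sets[a] & sets[b]) for a, b in combinations(names, 2)
    }
    all_shared = set.intersection(*sets.values())
    return {
        "pairwise": pairwise,
        "all_shared": sorted(all_shared),
        "total_unique": len(set.union(*sets.values())),
    }


# ---------------------------------------------------------------------------
# IO


def read_gene_table(path) -> list[GeneInterval]:
    """Gene intervals from TSV with columns name, chrom, start, end, strand[, biotype]."""
    df = pd.read_csv(path, sep="\t")
    return [
        GeneInterval(
            str(r["name"]), str(r["chrom"]), int(r["start"]), int(r["end"]),
            str(r.get("strand", "+")), str(r.get("biotype", "protein_coding")),
        )
        for _, r in df.iterrows()
    ]


def write_gene_table(genes: Iterable[GeneInterval], path) -> None:
    pd.DataFrame(
        [
            {"name": g.name, "chrom": g.chrom, "start": g.start, "end": g.end,
             "strand": g.strand, "biotype": g.biotype}
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_target_map(path) -> dict[str, set[str]]:
    """Two-column TSV (miRNA, gene) -> miRNA -> set of target genes."""
    df = pd.read_csv(path, sep="\t", header=None, names=["mirna", "gene"], comment="#")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["mirna"]), set()).add(str(row["gene"]))
    return out
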