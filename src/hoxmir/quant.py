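"""Exact-match alignment and 5'-anchored mature-miRNA counting.

Collapsed read species are aligned to the genome with no mismatches and
no limit on the number of mapping locations.  A species is credited to a
mature miRNA only when some hit lies on the annotated strand and its 5'
terminus coincides exactly with the annotated 5' terminus — the rule
that separates true mature reads and 3' isomiRs (counted) from 5'
isomiRs (rejected), since a shifted 5' end changes the seed register.
Species longer than 27 nt are removed as non-mature.

All coordinates are 0-based half-open internally.  BED6 input is native;
GFF3 (1-based closed) is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .reads import ReadSpecies

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatureRecord:
    """A named mature-miRNA genomic interval.

    Names may recur across loci: duplicated mature genes (the miR-196a
    situation, encoded in both the HOXB and HOXC clusters) appear as two
    records sharing one name.
    """

    name: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"{self.name}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.name}: strand must be + or -")

    @property
    def five_prime(self) -> int:
        """0-based coordinate of the 5' terminal base."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class AlignmentHit:
    species_seq: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


class ExactMatchIndex:
    """Seed-and-verify exact-match index over a genome.

    Fixed-length seeds (k-mers) are hashed to their positions; a query is
    located by looking up its first seed and verifying the full match by
    substring equality.  Queries shorter than the seed fall back to a
    direct scan.  N never matches, in seeds or in verification.
    """

    def __init__(self, genome: Mapping[str, str], seed_len: int = 12):
        if not genome or any(len(s) == 0 for s in genome.values()):
            raise ValueError("genome must contain nonempty sequences")
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.seed_len = seed_len
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - seed_len + 1):
                kmer = seq[i : i + seed_len]
                if "N" in kmer:
                    continue
                self._seeds.setdefault(kmer, []).append((chrom, i))

    def _locate_forward(self, query: str) -> list[tuple[str, int]]:
        """All exact occurrences of ``query`` on the forward text."""
        if "N" in query:
            return []
        n = len(query)
        if n < self.seed_len:
            hits = []
            for chrom, seq in self.genome.items():
                pos = seq.find(query)
                while pos != -1:
                    if "N" not in seq[pos : pos + n]:
                        hits.append((chrom, pos))
                    pos = seq.find(query, pos + 1)
            return hits
        seed = query[: self.seed_len]
        hits = []
        for chrom, pos in self._seeds.get(seed, ()):  # pre-sorted by construction
            window = self.genome[chrom][pos : pos + n]
            if len(window) == n and "N" not in window and window == query:
                hits.append((chrom, pos))
        return hits

    def locate(self, query: str) -> list[AlignmentHit]:
        """All exact occurrences of ``query`` on both strands."""
        query = query.upper()
        hits = [
            AlignmentHit(query, chrom, pos, pos + len(query), "+")
            for chrom, pos in self._locate_forward(query)
        ]
        rc = revcomp(query)
        hits += [
            AlignmentHit(query, chrom, pos, pos + len(query), "-")
            for chrom, pos in self._locate_forward(rc)
        ]
        return sorted(hits, key=lambda h: (h.chrom, h.start, h.strand))


def build_index(genome: Mapping[str, str], seed_len: int = 12) -> ExactMatchIndex:
    return ExactMatchIndex(genome, seed_len=seed_len)


def align_exact(
    species: Iterable[ReadSpecies], index: ExactMatchIndex
) -> dict[str, list[AlignmentHit]]:
    """Map each species sequence to all of its exact hits (both strands)."""
    return {sp.seq: index.locate(sp.seq) for sp in species}


def assign_mature(
    hits: Mapping[str, list[AlignmentHit]],
    annotation: Sequence[MatureRecord],
    max_len: int = 27,
    require_strand: bool = True,
) -> dict[str, set[str]]:
    """5'-anchored assignment of species to mature miRNA names.

    A species is assigned to mature name M iff its length is <= max_len
    and some hit overlaps a record of M by >= 1 bp on the annotated
    strand with the hit's 5' terminus equal to the record's 5' terminus.
    ``require_strand=False`` relaxes the same-strand requirement (the
    interval-intersection tool the rule descends from ignores strand by
    default); the 5' anchor is still taken per the hit's own strand.
    """
    assignments: dict[str, set[str]] = {}
    for seq, seq_hits in hits.items():
        names: set[str] = set()
        if len(seq) <= max_len:
            for hit in seq_hits:
                for rec in annotation:
                    if rec.chrom != hit.chrom:
                        continue
                    if require_strand and rec.strand != hit.strand:
                        continue
                    overlap = min(hit.end, rec.end) - max(hit.start, rec.start)
                    if overlap >= 1 and hit.five_prime == rec.five_prime:
                        names.add(rec.name)
        assignments[seq] = names
    return assignments


def count_features(
    assignments: Mapping[str, set[str]],
    species_per_sample: Mapping[str, Sequence[ReadSpecies]],
    annotation: Sequence[MatureRecord],
    unique_only: bool = False,
) -> pd.DataFrame:
    """Sum collapsed species counts per annotated mature miRNA and sample.

    A species mapping to several loci of one mature name contributes its
    count once to that name.  By default a species satisfying the rules
    for two *different* names contributes its full count to each;
    ``unique_only=True`` drops multi-name species instead.  Annotated
    miRNAs with no assigned species keep an all-zero row.
    """
    feature_names = list(dict.fromkeys(rec.name for rec in annotation))
    samples = list(species_per_sample)
    counts = pd.DataFrame(0, index=feature_names, columns=samples, dtype=int)
    for sample, species in species_per_sample.items():
        for sp in species:
            names = assignments.get(sp.seq, set())
            if not names:
                continue
            if unique_only and len(names) > 1:
                continue
            for name in names:
                counts.loc[name, sample] += sp.count
    return counts


def quantify(
    genome: Mapping[str, str],
    annotation: Sequence[MatureRecord],
    species_per_sample: Mapping[str, Sequence[ReadSpecies]],
    max_len: int = 27,
    unique_only: bool = False,
) -> pd.DataFrame:
    """Full quantification: index, align, assign, count."""
    index = build_index(genome)
    all_species: dict[str, ReadSpecies] = {}
    for species in species_per_sample.values():
        for sp in species:
            all_species.setdefault(sp.seq, sp)
    hits = align_exact(all_species.values(), index)
    assignments = assign_mature(hits, annotation, max_len=max_len)
    return count_features(assignments, species_per_sample, annotation,
                          unique_only=unique_only)


# ---------------------------------------------------------------------------
# Annotation IO

def read_bed(path) -> list[MatureRecord]:
    """Read BED6 mature annotation (0-based half-open, native)."""
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if len(fields) > 5 else "+"
            records.append(MatureRecord(name, chrom, start, end, strand))
    return records


def write_bed(records: Iterable[MatureRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}\t0\t{rec.strand}\n")


def read_gff3(path) -> list[MatureRecord]:
    """Read a miRBase-dialect GFF3 (1-based closed; converted on input).

    The feature name is taken from the ``Name=`` attribute, falling back
    to ``ID=``.
    """
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = fields[:9]
            attrd = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            name = attrd.get("Name", attrd.get("ID", ""))
            records.append(MatureRecord(name, chrom, int(start) - 1, int(end), strand))
    return records


def write_gff3(records: Iterable[MatureRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            fh.write(
                f"{rec.chrom}\t.\tmiRNA\t{rec.start + 1}\t{rec.end}\t.\t"
                f"{rec.strand}\t.\tID={rec.name};Name={rec.name}\n"
            )


def write_sam(hits: Mapping[str, list[AlignmentHit]], genome: Mapping[str, str], path) -> None:
    """Dump hits in SAM format for inspection."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, seq in genome.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(seq)}\n")
        for seq, seq_hits in hits.items():
            for i, h in enumerate(seq_hits):
                flag = 16 if h.strand == "-" else 0
                if i > 0:
                    flag |= 256
                read = revcomp(seq) if h.strand == "-" else seq
                fh.write(
                    f"species\t{flag}\t{h.chrom}\t{h.start + 1}\t255\t"
                    f"{len(seq)}M\t*\t0\t0\t{read}\t*\n"
                )
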