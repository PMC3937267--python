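"""Primary processing of single-end small-RNA sequencing reads.

The processing chain is fixed: per-read quality filtering, 3' adapter
clipping with a minimum insert length, and collapsing of surviving reads
into unique read species.  Mature miRNAs are short (~18-27 nt), so a
50 nt single-end read normally contains the full insert followed by the
3' sequencing adapter; the insert is everything before the adapter.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
PHRED_OFFSET = 33


class MalformedRecordError(ValueError):
    """A read whose sequence and quality strings disagree in length."""


@dataclass(frozen=True)
class Read:
    """A single sequencing read with Phred+33 qualities."""

    id: str
    seq: str
    qual: str

    def phred(self) -> list[int]:
        return [ord(c) - PHRED_OFFSET for c in self.qual]

    def validate(self) -> None:
        if len(self.seq) != len(self.qual):
            raise MalformedRecordError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )
        if len(self.seq) < 1:
            raise MalformedRecordError(f"read {self.id!r}: empty sequence")


@dataclass(frozen=True)
class ReadSpecies:
    """A unique read sequence with its collapsed multiplicity."""

    seq: str
    count: int


def quality_filter(
    reads: Iterable[Read], min_q: int = 20, min_fraction: float = 0.80
) -> list[Read]:
    """Retain reads with at least ``min_fraction`` of bases at Q >= ``min_q``.

    Both thresholds are inclusive (a 10 nt read with exactly 8 bases at
    Q20 passes), matching the ``-q 20 -p 80`` semantics of the classic
    FASTQ quality filter.  Input order is preserved.
    """
    kept = []
    for read in reads:
        read.validate()
        phred = read.phred()
        n_good = sum(1 for q in phred if q >= min_q)
        if n_good / len(phred) >= min_fraction:
            kept.append(read)
    return kept


def _clip_point(seq: str, adapter: str, min_overlap: int) -> int | None:
    """Position at which the adapter begins in ``seq``, or None.

    The leftmost full-adapter occurrence wins; otherwise the longest
    adapter *prefix* (>= min_overlap nt) that is a suffix of the read.
    N bases never match the adapter.
    """
    if "N" not in seq:
        pos = seq.find(adapter)
        if pos != -1:
            return pos
    else:
        # scan manually so that N never matches
        for pos in range(len(seq) - len(adapter) + 1):
            window = seq[pos : pos + len(adapter)]
            if "N" not in window and window == adapter:
                return pos
    max_k = min(len(adapter) - 1, len(seq))
    for k in range(max_k, min_overlap - 1, -1):
        tail = seq[len(seq) - k :]
        if "N" not in tail and tail == adapter[:k]:
            return len(seq) - k
    return None


def clip_adapter(
    reads: Iterable[Read],
    adapter: str = DEFAULT_ADAPTER,
    min_len: int = 15,
    min_overlap: int = 5,
) -> list[Read]:
    """Remove the 3' adapter and discard inserts shorter than ``min_len``.

    Reads with no adapter evidence (no full occurrence and no qualifying
    adapter-prefix suffix) are kept unmodified; they are still subject to
    the minimum length threshold.
    """
    if not adapter:
        raise ValueError("adapter must be nonempty")
    out = []
    for read in reads:
        read.validate()
        cut = _clip_point(read.seq, adapter, min_overlap)
        if cut is None:
            clipped = read
        else:
            clipped = Read(read.id, read.seq[:cut], read.qual[:cut])
        if len(clipped.seq) >= min_len:
            out.append(clipped)
    return out


def collapse(reads: Iterable[Read]) -> list[ReadSpecies]:
    """Collapse reads to unique species.

    Output order is deterministic: descending count, ties broken by
    lexicographic sequence.  The sum of species counts equals the number
    of input reads.
    """
    counts: dict[str, int] = {}
    for read in reads:
        counts[read.seq] = counts.get(read.seq, 0) + 1
    return [
        ReadSpecies(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def preprocess(
    reads: Iterable[Read],
    adapter: str = DEFAULT_ADAPTER,
    min_len: int = 15,
    min_q: int = 20,
    min_fraction: float = 0.80,
    min_overlap: int = 5,
    log=None,
) -> list[ReadSpecies]:
    """Run the full chain: quality filter, adapter clip, collapse.

    Per-stage survivor counts are written to ``log`` (a file-like object)
    when given, mirroring the read-statistics summary a sequencing run
    report would carry.
    """
    reads = list(reads)
    qpass = quality_filter(reads, min_q=min_q, min_fraction=min_fraction)
    clipped = clip_adapter(qpass, adapter=adapter, min_len=min_len, min_overlap=min_overlap)
    species = collapse(clipped)
    if log is not None:
        print(f"input reads\t{len(reads)}", file=log)
        print(f"passed quality filter\t{len(qpass)}", file=log)
        print(f"passed adapter clip / length\t{len(clipped)}", file=log)
        print(f"unique species\t{len(species)}", file=log)
    return species


# ---------------------------------------------------------------------------
# FASTQ / FASTA IO

def read_fastq(path) -> Iterator[Read]:
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + PHRED_OFFSET) for q in rec.letter_annotations["phred_quality"]
        )
        yield Read(rec.id, str(rec.seq).upper(), qual)


def write_fastq(reads: Iterable[Read], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - PHRED_OFFSET for c in r.qual]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_species_fasta(species: Iterable[ReadSpecies], path) -> None:
    """Write collapsed species as FASTA with ``>species_<rank>_x<count>`` headers."""
    with open(path, "w") as fh:
        for rank, sp in enumerate(species, start=1):
            fh.write(f">species_{rank}_x{sp.count}\n{sp.seq}\n")


def write_species_tsv(species: Iterable[ReadSpecies], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq\tcount\n")
        for sp in species:
            fh.write(f"{sp.seq}\t{sp.count}\n")


def read_species_tsv(path) -> list[ReadSpecies]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            seq, count = line.rstrip("\n").split("\t")
            out.append(ReadSpecies(seq, int(count)))
    return out
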