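"""Alignment ingest, read filtering and fragment start-site counting.

The per-position statistic downstream is built from *read start sites*: the
5' end of an aligned fragment marks the reverse-transcription stop and hence
the cleavage position.  This module ingests SAM/BAM (via pysam) or aligns
simulator FASTQ internally with an exact-substring aligner, applies the
pipeline's filters (pre-tRNA subtraction through genomic flanks, MAPQ >= 1,
pseudogene/mitochondrial exclusion, optional duplicate collapsing) and
tabulates per-contig, per-position start counts with a minimum read-support
threshold of 10 reads per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .reference import Flank, ReferenceSet


@dataclass(frozen=True)
class ReadAlignment:
    """One primary alignment; coordinates 0-based half-open."""

    read_id: str
    contig_id: str
    start: int
    end: int
    mapq: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self}")
        if self.mapq < 0:
            raise ValueError("mapq must be non-negative")


def read_alignments(
    path: str,
    known_contigs: Iterable[str] | None = None,
    on_unknown: str = "warn",
) -> list[ReadAlignment]:
    """Primary mapped alignments from a SAM/BAM file.

    Secondary, supplementary and unmapped records are skipped.  Records on
    contigs absent from ``known_contigs`` are skipped with a warning, or
    raise when ``on_unknown='error'``.
    """
    import warnings

    known = None if known_contigs is None else set(known_contigs)
    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            contig = rec.reference_name
            if known is not None and contig not in known:
                if on_unknown == "error":
                    raise ValueError(f"alignment to unknown contig {contig!r}")
                warnings.warn(f"skipping alignment to unknown contig {contig!r}")
                continue
            out.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    contig_id=contig,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    mapq=rec.mapping_quality,
                    sequence=rec.query_sequence,
                )
            )
    return out


def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def naive_align(
    reads: Iterable[tuple[str, str]],
    sequences: Mapping[str, str],
) -> list[ReadAlignment]:
    """Exact-substring alignment of sense-strand reads.

    A read with exactly one occurrence across all target sequences gets
    MAPQ 30; multiple equally good occurrences give MAPQ 0 (placed at the
    lexicographically first hit); no occurrence leaves the read unaligned.
    Intended for simulator output and small fixtures, not production data.
    """
    names = sorted(sequences)
    out: list[ReadAlignment] = []
    for read_id, seq in reads:
        if not seq:
            continue
        hits: list[tuple[str, int]] = []
        for name in names:
            for pos in _find_all(sequences[name], seq):
                hits.append((name, pos))
                if len(hits) > 1:
                    break
            if len(hits) > 1:
                break
        if not hits:
            continue
        contig, pos = hits[0]
        out.append(
            ReadAlignment(
                read_id=read_id,
                contig_id=contig,
                start=pos,
                end=pos + len(seq),
                mapq=30 if len(hits) == 1 else 0,
                sequence=seq,
            )
        )
    return out


def subtract_pretrna(
    trna_alignments: Sequence[ReadAlignment],
    genome_alignments: Sequence[ReadAlignment],
    flanks: Sequence[Flank],
) -> tuple[list[ReadAlignment], set[str]]:
    """Remove reads whose genomic alignment falls into a tRNA flank.

    A read aligning to the unmasked genome with >= 1 base of overlap with
    any flank interval is treated as pre-tRNA-derived; all its tRNA-contig
    alignments are dropped.  Returns the surviving alignments and the
    removed read-name set.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for fl in flanks:
        by_chrom.setdefault(fl.chrom, []).append((fl.start, fl.end))
    removed: set[str] = set()
    for aln in genome_alignments:
        for s, e in by_chrom.get(aln.contig_id, ()):
            if aln.start < e and aln.end > s:
                removed.add(aln.read_id)
                break
    survivors = [a for a in trna_alignments if a.read_id not in removed]
    return survivors, removed


def filter_alignments(
    alignments: Sequence[ReadAlignment],
    mapq_min: int = 1,
    exclude: Iterable[str] = (),
    dedup: bool = False,
) -> list[ReadAlignment]:
    """MAPQ and contig-exclusion filters, optional duplicate collapsing.

    Duplicate collapsing keeps one representative per identical
    (contig, start, end, sequence); it is off by default because the
    simulator has no PCR duplication model.
    """
    excluded = set(exclude)
    kept = [
        a
        for a in alignments
        if a.mapq >= mapq_min and a.contig_id not in excluded
    ]
    if dedup:
        seen: set[tuple] = set()
        unique = []
        for a in kept:
            key = (a.contig_id, a.start, a.end, a.sequence)
            if key not in seen:
                seen.add(key)
                unique.append(a)
        kept = unique
    return kept


@dataclass
class StartCountTable:
    """Per-contig, per-position fragment start counts for one condition.

    ``raw_starts`` holds the unthresholded counts; ``starts`` has cells with
    fewer than ``min_support`` reads zeroed.  ``totals`` counts every
    aligned read of the contig (zeroed cells still contribute): the
    cleavage-ratio denominator is total aligned reads, not the sum of
    retained starts.  Positions are 0-based internally.
    """

    condition: str
    starts: dict[tuple[str, int], int] = field(default_factory=dict)
    raw_starts: dict[tuple[str, int], int] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)
    filters_applied: dict = field(default_factory=dict)

    def count(self, contig: str, position_0based: int) -> int:
        return self.starts.get((contig, position_0based), 0)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tpos_1based\tcount\ttotal\tcondition\n")
            for (contig, pos), n in sorted(self.starts.items()):
                if n:
                    fh.write(
                        f"{contig}\t{pos + 1}\t{n}\t{self.totals[contig]}\t"
                        f"{self.condition}\n"
                    )
            for contig in sorted(set(self.totals) - {c for c, _ in self.starts}):
                fh.write(f"{contig}\t0\t0\t{self.totals[contig]}\t{self.condition}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "StartCountTable":
        df = pd.read_csv(path, sep="\t")
        conditions = df["condition"].unique()
        if len(conditions) != 1:
            raise ValueError("count TSV must hold exactly one condition")
        table = cls(condition=str(conditions[0]))
        for row in df.itertuples(index=False):
            table.totals[row.contig] = int(row.total)
            if row.pos_1based > 0 and row.count > 0:
                key = (row.contig, int(row.pos_1based) - 1)
                table.starts[key] = int(row.count)
                table.raw_starts[key] = int(row.count)
        return table


def count_start_sites(
    alignments: Sequence[ReadAlignment],
    condition: str = "treated",
    min_support: int = 10,
    filters_applied: dict | None = None,
) -> StartCountTable:
    """Tabulate fragment start sites; zero cells below ``min_support``.

    Each read contributes exactly one start, so per contig the raw counts
    sum exactly to the total; zeroed low-support cells still count in the
    denominator.
    """
    table = StartCountTable(
        condition=condition, filters_applied=dict(filters_applied or {})
    )
    table.filters_applied["min_support"] = min_support
    for aln in alignments:
        key = (aln.contig_id, aln.start)
        table.raw_starts[key] = table.raw_starts.get(key, 0) + 1
        table.totals[aln.contig_id] = table.totals.get(aln.contig_id, 0) + 1
    table.starts = {
        key: n for key, n in table.raw_starts.items() if n >= min_support
    }
    return table


def coverage_profile(
    alignments: Sequence[ReadAlignment],
    contig_lengths: Mapping[str, int] | None = None,
) -> dict[str, np.ndarray]:
    """Per-contig read depth: depth(p) = number of alignments covering p."""
    lengths: dict[str, int] = dict(contig_lengths or {})
    if contig_lengths is None:
        for a in alignments:
            lengths[a.contig_id] = max(lengths.get(a.contig_id, 0), a.end)
    depth = {c: np.zeros(n, dtype=np.int64) for c, n in lengths.items()}
    for a in alignments:
        if a.contig_id in depth:
            depth[a.contig_id][a.start : a.end] += 1
    return depth


def write_bedgraph(depth: Mapping[str, np.ndarray], path: str) -> None:
    """Run-length-encoded bedGraph of a depth profile."""
    with open(path, "w") as fh:
        for contig in sorted(depth):
            arr = depth[contig]
            if arr.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [arr.size]))
            for s, e in zip(starts, ends):
                if arr[s]:
                    fh.write(f"{contig}\t{s}\t{e}\t{arr[s]}\n")


def align_and_count(
    reads_by_condition: Mapping[str, Sequence[tuple[str, str]]],
    ref: ReferenceSet,
    mapq_min: int = 1,
    min_support: int = 10,
    dedup: bool = False,
) -> tuple[dict[str, StartCountTable], dict[str, list[ReadAlignment]], dict[str, set[str]]]:
    """Full counting stage on in-memory reads for both conditions.

    Aligns reads to the tRNA contigs and (when a genome is present) to the
    unmasked genome for pre-tRNA subtraction, then filters and counts.
    Returns the per-condition count tables, the filtered alignments and the
    removed pre-tRNA read-name sets.
    """
    tables: dict[str, StartCountTable] = {}
    filtered: dict[str, list[ReadAlignment]] = {}
    removed: dict[str, set[str]] = {}
    for condition, reads in reads_by_condition.items():
        trna_alns = naive_align(reads, ref.contigs)
        stats = {"input_reads": len(reads), "aligned_trna": len(trna_alns)}
        if ref.genome and ref.flanks:
            genome_alns = naive_align(reads, ref.genome)
            trna_alns, dropped = subtract_pretrna(trna_alns, genome_alns, ref.flanks)
            removed[condition] = dropped
            stats["pretrna_removed"] = len(dropped)
        else:
            removed[condition] = set()
        kept = filter_alignments(
            trna_alns, mapq_min=mapq_min, exclude=ref.excluded, dedup=dedup
        )
        stats.update({"after_filters": len(kept), "mapq_min": mapq_min})
        filtered[condition] = kept
        tables[condition] = count_start_sites(
            kept, condition=condition, min_support=min_support,
            filters_applied=stats,
        )
    return tables, filtered, removed
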