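"""Mapping-reference construction for tRNA cleavage sequencing.

Builds the combined mapping target used by the rest of the pipeline:

* mature tRNA contigs with a 3' CCA tail appended, collapsed at 100%
  sequence identity (one contig per distinct post-CCA sequence);
* a tRNA-masked genome (tRNA loci replaced by N) so genomic alignments
  cannot hit the gene bodies;
* genomic flank intervals around each tRNA locus, used downstream to
  identify and subtract pre-tRNA reads.

Coordinates are 0-based half-open internally; user-facing reports are
1-based inclusive. U is normalised to T at ingest and FASTA output uses T.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_ALPHABET = frozenset("ACGTN")


class Locus(NamedTuple):
    """Genomic location of a tRNA gene, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"


class Flank(NamedTuple):
    """A genomic flank interval (BED6-style), 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str = "+"


def normalize_sequence(sequence: str) -> str:
    """Uppercase, map U to T and validate the alphabet."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"illegal characters in sequence: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class TRNAGene:
    """A mature (intron-less) tRNA gene without the CCA tail.

    ``source`` is one of ``db`` (database-derived), ``chromosomal_prediction``
    or ``mito_prediction``; mitochondrial predictions are excluded from
    scoring downstream, together with contigs made up entirely of
    pseudogenes.
    """

    gene_id: str
    sequence: str
    isoacceptor: str
    source: str = "db"
    pseudogene: bool = False
    locus: Locus | None = None

    _SOURCES = ("db", "chromosomal_prediction", "mito_prediction")

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.source not in self._SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.locus is not None:
            loc = Locus(*self.locus)
            if loc.end <= loc.start:
                raise ValueError(f"locus end must exceed start: {loc}")
            if loc.strand not in "+-":
                raise ValueError(f"bad strand {loc.strand!r}")
            object.__setattr__(self, "locus", loc)

    @property
    def mitochondrial(self) -> bool:
        return self.source == "mito_prediction"


@dataclass
class ReferenceSet:
    """The constructed mapping reference.

    ``contigs`` maps contig id to its CCA-tailed sequence; ``members`` maps
    contig id to the gene ids collapsed into it.  ``excluded`` holds contigs
    whose members are all pseudogenes or mitochondrial.  ``genome`` is the
    unmasked genome (needed for pre-tRNA read placement), ``masked_genome``
    the copy with tRNA loci N-masked.
    """

    contigs: dict[str, str] = field(default_factory=dict)
    members: dict[str, list[str]] = field(default_factory=dict)
    isoacceptor_of: dict[str, str] = field(default_factory=dict)
    excluded: set[str] = field(default_factory=set)
    flanks: list[Flank] = field(default_factory=list)
    masked_genome: dict[str, str] | None = None
    genome: dict[str, str] | None = None
    gene_loci: dict[str, Locus] = field(default_factory=dict)

    def contig_loci(self, contig_id: str) -> list[tuple[str, Locus]]:
        """Genomic loci of a contig's member genes (those that have one)."""
        return [
            (g, self.gene_loci[g])
            for g in self.members.get(contig_id, [])
            if g in self.gene_loci
        ]

    @property
    def scored_contigs(self) -> list[str]:
        return sorted(set(self.contigs) - self.excluded)


def append_cca(sequence: str, only_if_absent: bool = False) -> str:
    """Append the mature-tRNA 3' CCA tail.

    Appending is unconditional by default: inputs are intron-less gene
    bodies without tails.  With ``only_if_absent`` a sequence already ending
    in CCA is returned unchanged.
    """
    seq = normalize_sequence(sequence)
    if only_if_absent and seq.endswith("CCA"):
        return seq
    return seq + "CCA"


def collapse_identical(
    genes: Sequence[TRNAGene], cca_applied: bool = True
) -> ReferenceSet:
    """Collapse genes with identical sequences into single contigs.

    One contig per distinct sequence; the contig id is the lexicographically
    smallest member gene id.  A contig is excluded only when *all* its
    members are pseudogenes or mitochondrial — a functional copy keeps a
    mixed group in play.  ``cca_applied=False`` appends CCA here first.
    """
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene_ids: {dupes}")
    by_seq: dict[str, list[TRNAGene]] = {}
    for gene in genes:
        seq = gene.sequence if cca_applied else append_cca(gene.sequence)
        by_seq.setdefault(seq, []).append(gene)

    ref = ReferenceSet()
    for seq, group in by_seq.items():
        group = sorted(group, key=lambda g: g.gene_id)
        cid = group[0].gene_id
        ref.contigs[cid] = seq
        ref.members[cid] = [g.gene_id for g in group]
        ref.isoacceptor_of[cid] = group[0].isoacceptor
        if all(g.pseudogene or g.mitochondrial for g in group):
            ref.excluded.add(cid)
        for g in group:
            if g.locus is not None:
                ref.gene_loci[g.gene_id] = g.locus
    return ref


def mask_genome(
    genome: Mapping[str, str], loci: Iterable[Locus]
) -> dict[str, str]:
    """Replace bases inside each locus with N, lengths preserved."""
    masked = {chrom: bytearray(seq.encode()) for chrom, seq in genome.items()}
    for loc in loci:
        loc = Locus(*loc)
        if loc.chrom not in masked:
            raise ValueError(f"unknown chromosome {loc.chrom!r}")
        size = len(masked[loc.chrom])
        if loc.start < 0 or loc.end > size:
            raise ValueError(
                f"interval {loc} out of bounds for {loc.chrom} (len {size})"
            )
        masked[loc.chrom][loc.start:loc.end] = b"N" * (loc.end - loc.start)
    return {chrom: buf.decode() for chrom, buf in masked.items()}


def extract_flanks(
    loci: Iterable[tuple[str, Locus]] | Iterable[Locus],
    flank_len: int = 50,
    up_shift: int = 3,
    down_shift: int = 6,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[Flank]:
    """Genomic flank intervals around each tRNA locus.

    On the + strand the upstream flank is
    ``[start - flank_len - up_shift, start - up_shift)`` and the downstream
    flank ``[end + down_shift, end + down_shift + flank_len)``; mirrored for
    the - strand (upstream in transcript sense lies genomically right).
    Intervals are clipped at chromosome bounds.
    """
    if flank_len <= 0:
        raise ValueError("flank_len must be positive")
    flanks: list[Flank] = []
    for item in loci:
        if isinstance(item, tuple) and len(item) == 2 and isinstance(item[1], Locus):
            name, loc = item
        else:
            loc = Locus(*item)  # type: ignore[arg-type]
            name = f"{loc.chrom}:{loc.start}-{loc.end}"
        if loc.strand == "+":
            up = (loc.start - flank_len - up_shift, loc.start - up_shift)
            down = (loc.end + down_shift, loc.end + down_shift + flank_len)
        else:
            up = (loc.end + up_shift, loc.end + up_shift + flank_len)
            down = (loc.start - down_shift - flank_len, loc.start - down_shift)
        size = None if chrom_sizes is None else chrom_sizes.get(loc.chrom)
        for tag, (s, e) in (("up", up), ("down", down)):
            s = max(0, s)
            if size is not None:
                e = min(e, size)
            if e > s:
                flanks.append(Flank(loc.chrom, s, e, f"{name}_{tag}", loc.strand))
    return flanks


def build_reference(
    genes: Sequence[TRNAGene],
    genome: Mapping[str, str] | None = None,
    flank_len: int = 50,
    up_shift: int = 3,
    down_shift: int = 6,
    cca_if_absent: bool = False,
) -> ReferenceSet:
    """Compose the full reference: CCA, collapse, mask, flanks."""
    if not genes:
        raise ValueError("no genes supplied")
    tailed = [
        dataclasses.replace(
            g, sequence=append_cca(g.sequence, only_if_absent=cca_if_absent)
        )
        for g in genes
    ]
    ref = collapse_identical(tailed, cca_applied=True)
    if genome is not None:
        genome = {c: normalize_sequence(s) for c, s in genome.items()}
        named_loci = [
            (g.gene_id, g.locus) for g in genes if g.locus is not None
        ]
        sizes = {c: len(s) for c, s in genome.items()}
        ref.genome = genome
        ref.masked_genome = mask_genome(genome, [loc for _, loc in named_loci])
        ref.flanks = extract_flanks(
            named_loci, flank_len, up_shift, down_shift, chrom_sizes=sizes
        )
    return ref


# ---------------------------------------------------------------------------
# I/O


def _write_fasta(path: str, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, path, "fasta")


def write_reference(ref: ReferenceSet, outdir: str) -> dict[str, str]:
    """Write reference FASTA, flanks BED6, members TSV (+ genomes if any)."""
    os.makedirs(outdir, exist_ok=True)
    paths = {"reference": os.path.join(outdir, "reference.fasta")}
    _write_fasta(paths["reference"], ref.contigs)

    paths["members"] = os.path.join(outdir, "members.tsv")
    with open(paths["members"], "w") as fh:
        fh.write("contig\tgene_id\tisoacceptor\texcluded\n")
        for cid in sorted(ref.members):
            for gid in ref.members[cid]:
                fh.write(
                    f"{cid}\t{gid}\t{ref.isoacceptor_of[cid]}\t"
                    f"{int(cid in ref.excluded)}\n"
                )

    paths["flanks"] = os.path.join(outdir, "flanks.bed")
    with open(paths["flanks"], "w") as fh:
        for fl in sorted(ref.flanks):
            fh.write(f"{fl.chrom}\t{fl.start}\t{fl.end}\t{fl.name}\t0\t{fl.strand}\n")

    paths["loci"] = os.path.join(outdir, "loci.tsv")
    with open(paths["loci"], "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for gid in sorted(ref.gene_loci):
            loc = ref.gene_loci[gid]
            fh.write(f"{gid}\t{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.strand}\n")

    if ref.genome is not None:
        paths["genome"] = os.path.join(outdir, "genome.fasta")
        _write_fasta(paths["genome"], ref.genome)
    if ref.masked_genome is not None:
        paths["masked_genome"] = os.path.join(outdir, "masked_genome.fasta")
        _write_fasta(paths["masked_genome"], ref.masked_genome)
    return paths


def _read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def load_reference(refdir: str) -> ReferenceSet:
    """Load a reference previously written by :func:`write_reference`."""
    ref = ReferenceSet(contigs=_read_fasta(os.path.join(refdir, "reference.fasta")))
    with open(os.path.join(refdir, "members.tsv")) as fh:
        next(fh)
        for line in fh:
            cid, gid, iso, exc = line.rstrip("\n").split("\t")
            ref.members.setdefault(cid, []).append(gid)
            ref.isoacceptor_of[cid] = iso
            if int(exc):
                ref.excluded.add(cid)
    bed = os.path.join(refdir, "flanks.bed")
    if os.path.exists(bed):
        with open(bed) as fh:
            for line in fh:
                chrom, s, e, name, _score, strand = line.rstrip("\n").split("\t")
                ref.flanks.append(Flank(chrom, int(s), int(e), name, strand))
    loci = os.path.join(refdir, "loci.tsv")
    if os.path.exists(loci):
        with open(loci) as fh:
            next(fh)
            for line in fh:
                gid, chrom, s, e, strand = line.rstrip("\n").split("\t")
                ref.gene_loci[gid] = Locus(chrom, int(s), int(e), strand)
    for tag, attr in (("genome", "genome"), ("masked_genome", "masked_genome")):
        path = os.path.join(refdir, f"{tag}.fasta")
        if os.path.exists(path):
            setattr(ref, attr, _read_fasta(path))
    return ref


def read_genes_tsv(fasta_path: str, meta_path: str) -> list[TRNAGene]:
    """Read genes from a FASTA plus a metadata TSV.

    The TSV columns are gene_id, isoacceptor, source, pseudogene (0/1) and
    optionally chrom, start, end, strand.
    """
    seqs = _read_fasta(fasta_path)
    genes = []
    with open(meta_path) as fh:
        header = next(fh).rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            row = line.rstrip("\n").split("\t")
            gid = row[idx["gene_id"]]
            if gid not in seqs:
                raise ValueError(f"gene {gid!r} missing from FASTA")
            locus = None
            if "chrom" in idx and row[idx["chrom"]]:
                locus = Locus(
                    row[idx["chrom"]],
                    int(row[idx["start"]]),
                    int(row[idx["end"]]),
                    row[idx["strand"]] if "strand" in idx else "+",
                )
            genes.append(
                TRNAGene(
                    gene_id=gid,
                    sequence=seqs[gid],
                    isoacceptor=row[idx["isoacceptor"]],
                    source=row[idx["source"]] if "source" in idx else "db",
                    pseudogene=bool(int(row[idx["pseudogene"]]))
                    if "pseudogene" in idx
                    else False,
                    locus=locus,
                )
            )
    return genes
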