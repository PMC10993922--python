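"""Ground-truthed read simulator for borohydride/aniline cleavage libraries.

The generative model mirrors the wet chemistry: a modified base at position
N (m7G at G, with m3C at C and dihydrouridine at T as off-target analogues)
is reduced to an abasic site and the chain is cleaved by beta-elimination
after N.  Reverse transcription of the 3' fragment stops at or just after
the lesion, so its observed read start falls in the window N..N+3.  The 5'
fragment carries a blocked 3' end and is recovered far less often than the
3' fragment.  Unmodified molecules yield full-length reads or random
background breaks; a configurable fraction of reads derive from unprocessed
pre-tRNA and extend into the genomic flanks.  Untreated libraries see no
modification-directed cleavage at all.

Everything is deterministic given the seed; the truth log records every
read's origin so downstream stages can be validated exactly.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .reference import Locus, ReferenceSet, normalize_sequence

MOD_BASE = {"m7G": "G", "m3C": "C", "D": "T"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ModSite(NamedTuple):
    """A planted modification: contig, 1-based position, type, efficiency."""

    contig_id: str
    position: int
    mod_type: str
    efficiency: float


@dataclass
class ModificationTruth:
    """Ground-truth table of planted modifications."""

    entries: list[ModSite] = field(default_factory=list)

    def by_contig(self) -> dict[str, list[ModSite]]:
        out: dict[str, list[ModSite]] = {}
        for e in self.entries:
            out.setdefault(e.contig_id, []).append(e)
        return out

    def positions(self, mod_types: Iterable[str] | None = None) -> set[tuple[str, int]]:
        types = None if mod_types is None else set(mod_types)
        return {
            (e.contig_id, e.position)
            for e in self.entries
            if types is None or e.mod_type in types
        }

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tposition\tmod_type\tefficiency\n")
            for e in sorted(self.entries):
                fh.write(f"{e.contig_id}\t{e.position}\t{e.mod_type}\t{e.efficiency}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "ModificationTruth":
        truth = cls()
        with open(path) as fh:
            next(fh)
            for line in fh:
                cid, pos, mt, eff = line.rstrip("\n").split("\t")
                truth.entries.append(ModSite(cid, int(pos), mt, float(eff)))
        return truth


@dataclass(frozen=True)
class ModRule:
    """Planting rule: modification type at a 1-based position.

    ``contigs`` limits the rule to the named contigs (default: every
    non-excluded contig).  Planting at a base incompatible with the
    modification type is an error, never a silent skip.
    """

    mod_type: str
    position: int
    efficiency: float = 1.0
    contigs: Sequence[str] | None = None

    @classmethod
    def parse(cls, text: str) -> "ModRule":
        """Parse ``"m7G@46"`` or ``"m7G@46:0.8"``."""
        head, _, eff = text.partition(":")
        mod, _, pos = head.partition("@")
        if mod not in MOD_BASE or not pos:
            raise ValueError(f"cannot parse modification rule {text!r}")
        return cls(mod, int(pos), float(eff) if eff else 1.0)


def plant_modifications(
    ref: ReferenceSet, rules: Sequence[ModRule | str], seed: int = 0
) -> ModificationTruth:
    """Resolve planting rules against the reference into a truth table."""
    rng = np.random.default_rng(seed)
    truth = ModificationTruth()
    for rule in rules:
        if isinstance(rule, str):
            rule = ModRule.parse(rule)
        if rule.mod_type not in MOD_BASE:
            raise ValueError(f"unknown modification type {rule.mod_type!r}")
        targets = (
            sorted(rule.contigs) if rule.contigs is not None else ref.scored_contigs
        )
        want = MOD_BASE[rule.mod_type]
        for cid in targets:
            if cid not in ref.contigs:
                raise ValueError(f"contig {cid!r} not in reference")
            seq = ref.contigs[cid]
            if not 1 <= rule.position <= len(seq):
                raise ValueError(
                    f"position {rule.position} outside contig {cid!r} "
                    f"(length {len(seq)})"
                )
            base = seq[rule.position - 1]
            if base != want:
                raise ValueError(
                    f"cannot plant {rule.mod_type} at {cid}:{rule.position}: "
                    f"reference base is {base}, needs {want}"
                )
            truth.entries.append(
                ModSite(cid, rule.position, rule.mod_type, rule.efficiency)
            )
    truth.entries.sort()
    # rng reserved for future stochastic rules; consuming one draw keeps the
    # signature honest about seed-dependence
    rng.random()
    return truth


@dataclass
class SimulationConfig:
    """Per-condition library parameters.

    The stop-offset distribution spreads observed read starts over N..N+3
    (peak at N+1, where beta-elimination severs the chain); 3' fragments are
    recovered far more often than 5' fragments, whose blocked 3' ends fail
    adapter ligation.
    """

    n_reads: int = 50_000
    read_length: int = 51
    stop_offset_distribution: dict[int, float] = field(
        default_factory=lambda: {0: 0.15, 1: 0.55, 2: 0.20, 3: 0.10}
    )
    p_three_prime_recovery: float = 0.9
    p_five_prime_recovery: float = 0.05
    background_break_rate: float = 0.001
    pretrna_fraction: float = 0.0
    error_rate: float = 0.0
    min_fragment_length: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length <= 0 or self.n_reads < 0:
            raise ValueError("read_length and n_reads must be positive")
        offs = self.stop_offset_distribution
        if set(offs) - {0, 1, 2, 3}:
            raise ValueError("stop offsets must lie in 0..3")
        if abs(sum(offs.values()) - 1.0) > 1e-9:
            raise ValueError("stop_offset_distribution must sum to 1")
        for name in (
            "p_three_prime_recovery",
            "p_five_prime_recovery",
            "background_break_rate",
            "pretrna_fraction",
            "error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        if self.p_three_prime_recovery + self.p_five_prime_recovery <= 0:
            raise ValueError("at least one fragment class must be recoverable")
        if self.min_fragment_length < 1:
            raise ValueError("min_fragment_length must be >= 1")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["stop_offset_distribution"] = {
            int(k): float(v) for k, v in self.stop_offset_distribution.items()
        }
        return d


class SimRead(NamedTuple):
    read_id: str
    sequence: str


TRUTH_COLUMNS = ["read_id", "contig", "fragtype", "cleavage_site", "start"]


def _condition_rng(config: SimulationConfig, condition: str) -> np.random.Generator:
    tag = {"treated": 1, "untreated": 2}[condition]
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


def _pretrna_read(
    ref: ReferenceSet,
    gene_id: str,
    loc: Locus,
    rng: np.random.Generator,
    read_length: int,
) -> str | None:
    """A read spanning a locus/flank junction on the unmasked genome.

    The junction offset ranges guarantee at least one base of overlap with
    the shifted flank intervals (3 bp upstream, 6 bp downstream) and at
    least a few bases inside the gene body.
    """
    chrom = ref.genome[loc.chrom]  # type: ignore[index]
    five_prime = rng.random() < 0.5
    if five_prime:
        k = int(rng.integers(4, max(5, read_length - 3)))
        if loc.strand == "+":
            gstart = loc.start - k
        else:
            gstart = loc.end + k - read_length
    else:
        m = int(rng.integers(7, max(8, read_length - 3)))
        if loc.strand == "+":
            gstart = loc.end + m - read_length
        else:
            gstart = loc.start - m
    gstart = max(0, min(gstart, len(chrom) - read_length))
    seq = chrom[gstart : gstart + read_length]
    if loc.strand == "-":
        seq = _revcomp(seq)
    return seq if seq else None


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = "ACGT"[int(rng.integers(4))]
    return "".join(chars)


def simulate_library(
    ref: ReferenceSet,
    truth: ModificationTruth,
    condition: str,
    config: SimulationConfig,
) -> tuple[list[SimRead], pd.DataFrame]:
    """Simulate one sequencing library.

    Returns the reads and a truth log with one row per read recording the
    originating contig, fragment type (``cleaved_3prime``, ``cleaved_5prime``,
    ``full_length``, ``background`` or ``pre_trna``), the true cleavage site
    (-1 if none) and the 1-based read start on the contig (-1 for pre-tRNA
    reads, which live on the genome).
    """
    if condition not in ("treated", "untreated"):
        raise ValueError("condition must be 'treated' or 'untreated'")
    if not ref.contigs:
        raise ValueError("empty reference")
    if config.pretrna_fraction > 0 and not (ref.genome and ref.gene_loci):
        raise ValueError("pre-tRNA simulation requires genome and gene loci")

    rng = _condition_rng(config, condition)
    contig_ids = sorted(ref.contigs)
    mods = truth.by_contig() if condition == "treated" else {}
    offsets = np.array(sorted(config.stop_offset_distribution), dtype=int)
    probs = np.array(
        [config.stop_offset_distribution[int(o)] for o in offsets], dtype=float
    )
    p3 = config.p_three_prime_recovery
    odds3 = p3 / (p3 + config.p_five_prime_recovery)
    loci = sorted(ref.gene_loci.items())

    reads: list[SimRead] = []
    log_rows: list[tuple] = []
    rl = config.read_length

    for serial in range(config.n_reads):
        if config.pretrna_fraction > 0 and rng.random() < config.pretrna_fraction:
            gid, loc = loci[int(rng.integers(len(loci)))]
            seq = _pretrna_read(ref, gid, loc, rng, rl)
            contig = next(c for c, ms in ref.members.items() if gid in ms)
            read_id = f"{contig}|pre_trna|-1|{serial}"
            reads.append(SimRead(read_id, _apply_errors(seq, config.error_rate, rng)))
            log_rows.append((read_id, contig, "pre_trna", -1, -1))
            continue

        contig = contig_ids[int(rng.integers(len(contig_ids)))]
        cseq = ref.contigs[contig]
        L = len(cseq)

        fired = [m for m in mods.get(contig, []) if rng.random() < m.efficiency]
        if fired:
            site = fired[int(rng.integers(len(fired)))] if len(fired) > 1 else fired[0]
            if rng.random() < odds3:
                off = int(offsets[int(rng.choice(len(offsets), p=probs))])
                start = min(site.position + off, L)  # 1-based observed start
                seq = cseq[start - 1 : start - 1 + rl]
                fragtype = "cleaved_3prime"
            else:
                # the reduced base at N is lost with the abasic site, so the
                # 5' fragment carries bases 1..N-1
                start = 1
                seq = cseq[: max(site.position - 1, 1)][:rl]
                fragtype = "cleaved_5prime"
            cleavage_site = site.position
        else:
            # size selection during library prep discards fragments shorter
            # than min_fragment_length, so background breaks only yield
            # recoverable 3' fragments of at least that length
            b_max = L - config.min_fragment_length
            p_break = 1.0 - (1.0 - config.background_break_rate) ** L
            if b_max >= 1 and p_break > 0 and rng.random() < p_break:
                b = int(rng.integers(1, b_max + 1))  # scission after base b
                start = b + 1
                seq = cseq[b : b + rl]
                fragtype = "background"
            else:
                start = 1
                seq = cseq[:rl]
                fragtype = "full_length"
            cleavage_site = -1

        read_id = f"{contig}|{fragtype}|{cleavage_site}|{serial}"
        reads.append(SimRead(read_id, _apply_errors(seq, config.error_rate, rng)))
        log_rows.append((read_id, contig, fragtype, cleavage_site, start))

    log = pd.DataFrame(log_rows, columns=TRUTH_COLUMNS)
    return reads, log


def simulate_pretrna_reads(
    ref: ReferenceSet, config: SimulationConfig, n_reads: int | None = None
) -> tuple[list[SimRead], pd.DataFrame]:
    """Generate only pre-tRNA reads (junction-spanning, flank-overlapping)."""
    if not (ref.genome and ref.gene_loci):
        raise ValueError("reference lacks genome or gene loci")
    cfg = replace(config, pretrna_fraction=1.0)
    if n_reads is not None:
        cfg = replace(cfg, n_reads=n_reads)
    return simulate_library(ref, ModificationTruth(), "untreated", cfg)


def write_fastq(reads: Iterable[SimRead], path: str) -> None:
    """Write reads as FASTQ; constant quality 'I'. Gzipped iff path ends .gz."""
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:  # type: ignore[operator]
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


def read_fastq(path: str) -> list[SimRead]:
    opener = gzip.open if path.endswith(".gz") else open
    reads = []
    with opener(path, "rt") as fh:  # type: ignore[operator]
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()
            fh.readline()
            reads.append(SimRead(header[1:].rstrip("\n"), seq))
    return reads


def offtarget_rules(
    ref: ReferenceSet,
    contigs: Sequence[str],
    efficiency: float = 0.8,
    c_range: tuple[int, int] = (20, 40),
    t_range: tuple[int, int] = (55, 72),
) -> list[ModRule]:
    """m3C and dihydrouridine planting rules for off-target realism.

    For each contig, plants m3C at the first C in ``c_range`` and D at the
    first T in ``t_range`` (1-based, inclusive); positions without a
    compatible base are skipped.  These sites cleave exactly like m7G sites
    so only the downstream guanosine restriction can remove them.
    """
    rules: list[ModRule] = []
    for cid in contigs:
        seq = ref.contigs[cid]
        for base, mod, (lo, hi) in (("C", "m3C", c_range), ("T", "D", t_range)):
            pos = next(
                (p for p in range(lo, min(hi, len(seq)) + 1) if seq[p - 1] == base),
                None,
            )
            if pos is not None:
                rules.append(ModRule(mod, pos, efficiency, contigs=[cid]))
    return rules


# ---------------------------------------------------------------------------
# Synthetic study system: tRNA-like genes with a G46 analogue, embedded in a
# toy genome with inter-locus spacers.

_ISOACCEPTORS = [
    "AlaTGC", "LysCTT", "MetCAT", "AsnGTT", "ProAGG",
    "ArgTCG", "AspGTC", "LeuTAG", "GluTTC", "GluCTC",
    "GlyGCC", "HisGTG", "IleAAT", "PheGAA", "SerAGA",
    "ThrAGT", "TrpCCA", "TyrGTA", "ValAAC", "CysGCA",
]


def synthetic_genes(
    n_genes: int = 20,
    body_length: int = 76,
    g_position: int = 46,
    seed: int = 0,
    duplicate_rate: float = 0.0,
    genes_per_isoacceptor: int = 1,
) -> list:
    """Random tRNA-like gene bodies with a guaranteed G at ``g_position``.

    The three positions immediately downstream of the planted-G analogue are
    forced to non-G so the upstream-G assignment of a candidate call is
    unambiguous for every stop offset in the N..N+3 window.  With
    ``duplicate_rate`` a gene reuses an earlier gene's sequence under a new
    id, exercising 100%-identity collapsing.
    """
    from .reference import TRNAGene

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    genes: list[TRNAGene] = []
    seqs: list[str] = []
    for i in range(n_genes):
        if seqs and rng.random() < duplicate_rate:
            seq = seqs[int(rng.integers(len(seqs)))]
        else:
            arr = bases[rng.integers(0, 4, size=body_length)]
            arr[g_position - 1] = "G"
            non_g = np.array(list("ACT"))
            for j in range(g_position, min(g_position + 3, body_length)):
                arr[j] = non_g[int(rng.integers(3))]
            seq = "".join(arr)
        seqs.append(seq)
        iso = _ISOACCEPTORS[(i // genes_per_isoacceptor) % len(_ISOACCEPTORS)]
        genes.append(
            TRNAGene(gene_id=f"tRNA-{iso}-{i + 1:03d}", sequence=seq, isoacceptor=iso)
        )
    return genes


def synthetic_genome(
    genes: Sequence,
    spacer: int = 200,
    chrom: str = "chrSim",
    seed: int = 0,
) -> tuple[dict[str, str], list]:
    """Embed gene bodies in a toy chromosome with random spacers.

    Returns the genome and a copy of the genes with loci attached (all on
    the + strand).  Spacers never start with C so a mature read running into
    the appended CCA tail can never exactly match genomic sequence at a
    flank-overlapping position.
    """
    import dataclasses as _dc

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    parts: list[str] = []
    placed = []
    pos = 0

    def make_spacer() -> str:
        sp = bases[rng.integers(0, 4, size=spacer)]
        sp[0] = "AGT"[int(rng.integers(3))]
        return "".join(sp)

    for gene in genes:
        sp = make_spacer()
        parts.append(sp)
        pos += len(sp)
        start = pos
        parts.append(gene.sequence)
        pos += len(gene.sequence)
        placed.append(
            _dc.replace(gene, locus=Locus(chrom, start, pos, "+"))
        )
    parts.append(make_spacer())
    return {chrom: normalize_sequence("".join(parts))}, placed
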