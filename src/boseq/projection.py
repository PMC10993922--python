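"""Projection of per-gene positions onto isoacceptor canonical coordinates.

Candidate sites are called in per-contig coordinates, but the biology is
stated per isoacceptor family ("position 46 in the variable loop").  Given
one multiple sequence alignment per isoacceptor (Stockholm format), a gene
position maps to its alignment column — a bijection between a row's
non-gap columns and its ungapped positions — and candidates from different
isodecoders that land in the same column merge into one family-level site.

Column labels come from the ``#=GC RF`` reference-annotation line when
present (non-gap RF columns are numbered 1..n), or from user-supplied
anchors (e.g. declaring that one gene's position 46 carries the label
"46"); otherwise raw column indices are reported.  Alignments cover the
tRNA body only: positions inside the appended CCA tail map to the synthetic
labels CCA1..CCA3.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from Bio import AlignIO

from .reference import ReferenceSet
from .scoring import CandidateSite

GAP_CHARS = set("-.~")


@dataclass
class AlignmentProfile:
    """One isoacceptor's multiple alignment with optional column labels."""

    isoacceptor: str
    aligned_sequences: dict[str, str]
    column_labels: dict[int, str] = field(default_factory=dict)
    anchors: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.aligned_sequences.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"ragged alignment for {self.isoacceptor}: row lengths {sorted(lengths)}"
            )
        for gene_id, position, label in self.anchors:
            col, _ = map_position(self, gene_id, position)
            if label and label.isdigit():
                # extend a numeric anchor along the anchor row's ungapped
                # coordinates so neighbouring columns get consecutive labels
                base = int(label)
                row = self.aligned_sequences[gene_id]
                ungapped = 0
                anchor_ungapped = position
                for c, ch in enumerate(row, start=1):
                    if ch not in GAP_CHARS:
                        ungapped += 1
                        self.column_labels.setdefault(
                            c, str(base + ungapped - anchor_ungapped)
                        )
            else:
                self.column_labels.setdefault(col, label)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.aligned_sequences.values()), ""))

    def ungapped(self, gene_id: str) -> str:
        row = self.aligned_sequences[gene_id]
        return "".join(ch for ch in row if ch not in GAP_CHARS).upper().replace("U", "T")


def parse_stockholm(path: str, isoacceptor: str | None = None) -> AlignmentProfile:
    """Read one Stockholm alignment (interleaved blocks supported).

    The ``#=GC RF`` line, when present, yields canonical column labels by
    numbering its non-gap columns sequentially.
    """
    with open(path) as fh:
        if not any(line.strip() == "//" for line in fh):
            raise ValueError(f"malformed Stockholm file {path!r}: missing '//'")
    try:
        aln = AlignIO.read(path, "stockholm")
    except ValueError as exc:
        raise ValueError(f"malformed Stockholm file {path!r}: {exc}") from exc
    name = isoacceptor or os.path.splitext(os.path.basename(path))[0]
    profile = AlignmentProfile(
        isoacceptor=name,
        aligned_sequences={rec.id: str(rec.seq) for rec in aln},
    )
    rf = aln.column_annotations.get("reference_annotation")
    if rf:
        counter = 0
        for col, ch in enumerate(rf, start=1):
            if ch not in GAP_CHARS:
                counter += 1
                profile.column_labels[col] = str(counter)
    return profile


def map_position(
    profile: AlignmentProfile, gene_id: str, position: int
) -> tuple[int | None, str | None]:
    """Alignment column (1-based) holding a gene's 1-based ungapped position.

    Positions beyond the aligned body (the CCA tail, up to 3 bases) map to
    column ``None`` with labels ``CCA1``..``CCA3``.
    """
    if gene_id not in profile.aligned_sequences:
        raise KeyError(f"gene {gene_id!r} not in profile {profile.isoacceptor!r}")
    if position < 1:
        raise ValueError("position must be >= 1")
    row = profile.aligned_sequences[gene_id]
    seen = 0
    for col, ch in enumerate(row, start=1):
        if ch not in GAP_CHARS:
            seen += 1
            if seen == position:
                return col, profile.column_labels.get(col)
    overhang = position - seen
    if 1 <= overhang <= 3:
        return None, f"CCA{overhang}"
    raise ValueError(
        f"position {position} beyond gene {gene_id!r} (ungapped length {seen})"
    )


def column_to_position(
    profile: AlignmentProfile, gene_id: str, column: int
) -> int:
    """Inverse of :func:`map_position` on non-gap columns."""
    row = profile.aligned_sequences[gene_id]
    if not 1 <= column <= len(row):
        raise ValueError(f"column {column} out of range")
    if row[column - 1] in GAP_CHARS:
        raise ValueError(f"column {column} is a gap in {gene_id!r}")
    return sum(1 for ch in row[:column] if ch not in GAP_CHARS)


def match_contig_row(
    profiles: Sequence[AlignmentProfile],
    ref: ReferenceSet | None,
    contig_id: str,
    contig_seq: str | None = None,
) -> tuple[AlignmentProfile, str] | None:
    """Find the profile row representing a contig.

    A row matches when its gene id is the contig id or one of the contig's
    collapsed members *and* its ungapped sequence equals the contig sequence
    minus the CCA tail (exact match; fuzzy matches are rejected).
    """
    member_ids = {contig_id}
    body = None
    if ref is not None:
        member_ids |= set(ref.members.get(contig_id, ()))
        seq = ref.contigs.get(contig_id)
        if seq is not None:
            body = seq[:-3] if seq.endswith("CCA") else seq
    if contig_seq is not None:
        body = contig_seq[:-3] if contig_seq.endswith("CCA") else contig_seq
    for profile in profiles:
        for gene_id in profile.aligned_sequences:
            if gene_id in member_ids:
                if body is not None and profile.ungapped(gene_id) != body:
                    continue
                return profile, gene_id
    return None


def aggregate_isoacceptor(
    candidates: Sequence[CandidateSite],
    profiles: Sequence[AlignmentProfile],
    ref: ReferenceSet | None = None,
) -> pd.DataFrame:
    """Merge per-contig candidates into isoacceptor-level sites.

    Candidates from member genes of one isoacceptor projecting to the same
    alignment column merge into one row (max score; member list retained).
    Contigs absent from every profile pass through unprojected with
    ``projected=False``.
    """
    import warnings

    merged: dict[tuple[str, object], dict] = {}
    for cand in candidates:
        hit = match_contig_row(profiles, ref, cand.contig_id)
        if hit is None:
            warnings.warn(f"contig {cand.contig_id!r} not found in any profile")
            key = (cand.isoacceptor or cand.contig_id, f"raw:{cand.g_position}")
            entry = merged.setdefault(
                key,
                {
                    "isoacceptor": key[0],
                    "column": pd.NA,
                    "label": str(cand.g_position),
                    "score": cand.score,
                    "members": [],
                    "projected": False,
                },
            )
        else:
            profile, gene_id = hit
            col, label = map_position(profile, gene_id, cand.g_position)
            key = (profile.isoacceptor, col if col is not None else label)
            entry = merged.setdefault(
                key,
                {
                    "isoacceptor": profile.isoacceptor,
                    "column": col if col is not None else pd.NA,
                    "label": label if label is not None else str(col),
                    "score": cand.score,
                    "members": [],
                    "projected": True,
                },
            )
        entry["score"] = max(entry["score"], cand.score)
        entry["members"].append(cand.contig_id)
    rows = [
        {
            "isoacceptor": e["isoacceptor"],
            "column": e["column"],
            "label": e["label"],
            "score": e["score"],
            "n_members": len(e["members"]),
            "members": ",".join(sorted(e["members"])),
            "projected": e["projected"],
        }
        for e in merged.values()
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "isoacceptor", "column", "label", "score",
            "n_members", "members", "projected",
        ],
    )
    return df.sort_values(["isoacceptor", "label"], ignore_index=True)


def profiles_from_reference(ref: ReferenceSet) -> list[AlignmentProfile]:
    """Gap-free profiles built from the reference contigs themselves.

    Valid when the isodecoders of each isoacceptor share one body length
    (as the synthetic study system does); columns then equal body
    positions, labelled 1..L.  Real data should supply curated Stockholm
    alignments instead.
    """
    by_iso: dict[str, dict[str, str]] = {}
    for contig, seq in ref.contigs.items():
        body = seq[:-3] if seq.endswith("CCA") else seq
        by_iso.setdefault(ref.isoacceptor_of.get(contig, contig), {})[contig] = body
    profiles = []
    for iso in sorted(by_iso):
        rows = by_iso[iso]
        if len({len(s) for s in rows.values()}) != 1:
            raise ValueError(
                f"isoacceptor {iso!r} has unequal body lengths; supply a real alignment"
            )
        n = len(next(iter(rows.values())))
        profiles.append(
            AlignmentProfile(
                isoacceptor=iso,
                aligned_sequences=dict(rows),
                column_labels={c: str(c) for c in range(1, n + 1)},
            )
        )
    return profiles


def write_stockholm(profile: AlignmentProfile, path: str) -> None:
    """Write a profile as a minimal single-block Stockholm file."""
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for gene_id, row in profile.aligned_sequences.items():
            fh.write(f"{gene_id}  {row}\n")
        fh.write("//\n")
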