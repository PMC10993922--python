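"""Cleavage ratios, log2 cleavage scores and m7G candidate calling.

For each position i of a contig the cleavage ratio is the fraction of that
contig's aligned reads whose fragment start site is i:

    r = (n_i + alpha) / N

with a symmetric pseudocount ``alpha`` (default 0.5) applied in both
conditions so the score stays finite and antisymmetric.  The cleavage score
is

    s_i = log2(r_treated / r_untreated)

Positions scoring above the threshold (default 6.5; 5 is the documented
relaxed operating point) are grouped into windows and assigned to the
nearest guanosine at most 3 positions upstream of the window peak — the
reverse-transcription stop lands anywhere in N..N+3 relative to the
modified G, and restricting calls to guanosines removes m3C/dihydrouridine
off-target cleavage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .counts import StartCountTable
from .reference import ReferenceSet

SCORE_COLUMNS = [
    "contig", "position", "ref_base",
    "n_treated", "N_treated", "n_untreated", "N_untreated",
    "ratio_treated", "ratio_untreated", "score",
]

#: Conservative threshold for candidate calling.
THRESHOLD_STRICT = 6.5
#: Relaxed operating point that broadens the candidate list.
THRESHOLD_RELAXED = 5.0


def cleavage_ratio(n: int, total: int, alpha: float = 0.5) -> float:
    """Fraction of a contig's reads starting at one site, pseudocounted."""
    if total < 1:
        raise ValueError("total aligned reads must be >= 1")
    if n < 0 or alpha < 0:
        raise ValueError("count and pseudocount must be non-negative")
    return (n + alpha) / total

def cleavage_score(ratio_treated: float, ratio_untreated: float) -> float:
    """log2 of the treated/untreated cleavage-ratio quotient."""
    if ratio_treated <= 0 or ratio_untreated <= 0:
        raise ValueError("cleavage ratios must be positive (use alpha > 0)")
    # difference-of-logs form keeps condition-swap antisymmetry bit-exact
    return math.log2(ratio_treated) - math.log2(ratio_untreated)


def score_table(
    treated: StartCountTable,
    untreated: StartCountTable,
    ref: ReferenceSet,
    alpha: float = 0.5,
) -> pd.DataFrame:
    """Per-position cleavage scores for every contig present in both tables.

    Contigs missing from either condition (no aligned reads) are skipped.
    Positions are 1-based in the output.  With ``alpha=0`` the literal
    ratio formula is reproduced and any zero ratio raises.
    """
    if treated.condition == untreated.condition:
        raise ValueError("treated and untreated tables share a condition label")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    frames = []
    shared = sorted(
        (set(treated.totals) & set(untreated.totals) & set(ref.contigs))
        - ref.excluded
    )
    for contig in shared:
        seq = ref.contigs[contig]
        n_pos = len(seq)
        n_t = np.zeros(n_pos, dtype=np.int64)
        n_u = np.zeros(n_pos, dtype=np.int64)
        for (c, p), n in treated.starts.items():
            if c == contig and p < n_pos:
                n_t[p] = n
        for (c, p), n in untreated.starts.items():
            if c == contig and p < n_pos:
                n_u[p] = n
        N_t = treated.totals[contig]
        N_u = untreated.totals[contig]
        r_t = (n_t + alpha) / N_t
        r_u = (n_u + alpha) / N_u
        if alpha == 0 and (np.any(r_t <= 0) or np.any(r_u <= 0)):
            raise ValueError(
                f"zero cleavage ratio on contig {contig!r} with alpha=0; "
                "use a positive pseudocount"
            )
        frames.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "position": np.arange(1, n_pos + 1),
                    "ref_base": list(seq),
                    "n_treated": n_t,
                    "N_treated": N_t,
                    "n_untreated": n_u,
                    "N_untreated": N_u,
                    "ratio_treated": r_t,
                    "ratio_untreated": r_u,
                    "score": np.log2(r_t) - np.log2(r_u),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    return pd.concat(frames, ignore_index=True)[SCORE_COLUMNS]


@dataclass(frozen=True)
class CandidateSite:
    """A called m7G site: the assigned G and the stop-window evidence."""

    contig_id: str
    g_position: int
    peak_position: int
    score: float
    window: tuple[int, int]
    n_treated: int
    isoacceptor: str = ""


def call_candidates(
    table: pd.DataFrame,
    threshold: float = THRESHOLD_STRICT,
    max_gap: int = 3,
    ref: ReferenceSet | None = None,
) -> list[CandidateSite]:
    """Guanosine-restricted candidate sites from a score table.

    Qualifying positions (score > threshold and observed treated starts)
    are grouped into maximal windows whose consecutive members lie at most
    ``max_gap`` apart; each window's peak (highest score, ties toward the
    smaller coordinate) is assigned to the closest G at offset 0..3 upstream.
    Windows with no such G — e.g. off-target cleavage at m3C or D — are
    discarded.
    """
    candidates: list[CandidateSite] = []
    if table.empty:
        return candidates
    for contig, sub in table.groupby("contig", sort=True):
        sub = sub.sort_values("position")
        bases = dict(zip(sub["position"], sub["ref_base"]))
        qual = sub[(sub["score"] > threshold) & (sub["n_treated"] > 0)]
        if qual.empty:
            continue
        positions = qual["position"].to_numpy()
        scores = dict(zip(qual["position"], qual["score"]))
        counts = dict(zip(qual["position"], qual["n_treated"]))
        windows: list[list[int]] = [[int(positions[0])]]
        for p in positions[1:]:
            if p - windows[-1][-1] <= max_gap:
                windows[-1].append(int(p))
            else:
                windows.append([int(p)])
        iso = ref.isoacceptor_of.get(str(contig), "") if ref else ""
        for window in windows:
            peak = max(window, key=lambda p: (scores[p], -p))
            g_pos = next(
                (g for g in range(peak, peak - 4, -1) if bases.get(g) == "G"),
                None,
            )
            if g_pos is None:
                continue
            candidates.append(
                CandidateSite(
                    contig_id=str(contig),
                    g_position=g_pos,
                    peak_position=peak,
                    score=float(scores[peak]),
                    window=(window[0], window[-1]),
                    n_treated=int(counts[peak]),
                    isoacceptor=iso,
                )
            )
    candidates.sort(key=lambda c: (c.contig_id, c.g_position))
    return candidates


def candidates_to_frame(candidates: Sequence[CandidateSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": c.contig_id,
                "g_position": c.g_position,
                "peak_position": c.peak_position,
                "score": c.score,
                "window_start": c.window[0],
                "window_end": c.window[1],
                "n_treated": c.n_treated,
                "isoacceptor": c.isoacceptor,
            }
            for c in candidates
        ],
        columns=[
            "contig", "g_position", "peak_position", "score",
            "window_start", "window_end", "n_treated", "isoacceptor",
        ],
    )


def compare_conditions(
    calls_a: Sequence[CandidateSite], calls_b: Sequence[CandidateSite]
) -> pd.DataFrame:
    """Set comparison of two call sets (e.g. wild type vs methyltransferase
    knockout), keyed by (isoacceptor-or-contig, G position)."""

    def keys(calls: Sequence[CandidateSite]) -> dict:
        return {
            (c.isoacceptor or c.contig_id, c.g_position): c for c in calls
        }

    a, b = keys(calls_a), keys(calls_b)
    rows = []
    for key in sorted(set(a) | set(b)):
        status = "both" if key in a and key in b else ("a_only" if key in a else "b_only")
        site = a.get(key) or b.get(key)
        rows.append(
            {
                "group": key[0],
                "g_position": key[1],
                "status": status,
                "score_a": a[key].score if key in a else np.nan,
                "score_b": b[key].score if key in b else np.nan,
                "contig": site.contig_id,
            }
        )
    return pd.DataFrame(
        rows, columns=["group", "g_position", "status", "score_a", "score_b", "contig"]
    )
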