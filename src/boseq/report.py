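"""Reporting and end-to-end pipeline orchestration.

Produces the analysis-facing artifacts: normalized coverage heatmap
matrices per isoacceptor (the pile-up of 3'-cleaved fragments downstream of
a methylated G is the visual signature of a site), long-format cleavage
score profiles with candidate flags, and a deterministic self-contained
pipeline run over the synthetic study system with a YAML manifest of
checksums.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import counts as _counts
from . import projection as _projection
from . import scoring as _scoring
from . import simulate as _simulate
from .reference import ReferenceSet, build_reference, write_reference


@dataclass
class HeatmapMatrix:
    """Isoacceptor x column matrix of normalized coverage."""

    values: pd.DataFrame  # rows: isoacceptors, columns: alignment columns
    normalization: str
    condition: str

    def to_tsv(self, path: str) -> None:
        self.values.to_csv(path, sep="\t", index_label="isoacceptor")


def heatmap_matrix(
    coverage: Mapping[str, np.ndarray],
    ref: ReferenceSet,
    profiles: Sequence[_projection.AlignmentProfile] | None = None,
    normalization: str = "row_max",
    condition: str = "treated",
    library_size: int | None = None,
) -> HeatmapMatrix:
    """Project per-contig coverage onto isoacceptor rows and normalize.

    Member coverages are summed per isoacceptor before normalization.
    ``row_max`` divides each row by its maximum (zero rows stay zero);
    ``cpm`` divides by library size in millions and needs ``library_size``.
    """
    if normalization not in ("row_max", "cpm"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if normalization == "cpm" and not library_size:
        raise ValueError("cpm normalization requires library_size")

    n_cols = 0
    rows: dict[str, np.ndarray] = {}

    def add(iso: str, idx: np.ndarray, depth: np.ndarray) -> None:
        nonlocal n_cols
        n_cols = max(n_cols, int(idx.max()) + 1 if idx.size else 0)
        arr = rows.get(iso)
        need = int(idx.max()) + 1 if idx.size else 0
        if arr is None or arr.size < need:
            new = np.zeros(max(need, n_cols), dtype=float)
            if arr is not None:
                new[: arr.size] = arr
            rows[iso] = arr = new
        np.add.at(arr, idx, depth)

    for contig in sorted(coverage):
        depth = np.asarray(coverage[contig], dtype=float)
        iso = ref.isoacceptor_of.get(contig, contig)
        if profiles:
            hit = _projection.match_contig_row(profiles, ref, contig)
            if hit is not None:
                profile, gene_id = hit
                row = profile.aligned_sequences[gene_id]
                cols = [
                    c for c, ch in enumerate(row)
                    if ch not in _projection.GAP_CHARS
                ]
                body_len = len(cols)
                idx = np.array(
                    cols + [profile.n_columns + k for k in range(len(depth) - body_len)],
                    dtype=int,
                )[: len(depth)]
                add(profile.isoacceptor, idx, depth[: len(idx)])
                continue
        add(iso, np.arange(len(depth)), depth)

    matrix = pd.DataFrame(
        {iso: np.pad(arr, (0, n_cols - arr.size)) for iso, arr in rows.items()}
    ).T
    matrix.columns = np.arange(1, n_cols + 1)
    matrix = matrix.sort_index()

    if normalization == "row_max":
        maxima = matrix.max(axis=1).replace(0, 1.0)
        matrix = matrix.div(maxima, axis=0)
    else:
        matrix = matrix / (library_size / 1e6)
    return HeatmapMatrix(values=matrix, normalization=normalization, condition=condition)


def score_profile_export(
    table: pd.DataFrame,
    candidates: Sequence[_scoring.CandidateSite],
    ref: ReferenceSet | None = None,
    profiles: Sequence[_projection.AlignmentProfile] | None = None,
) -> pd.DataFrame:
    """Long-format, plot-ready cleavage score profiles with candidate flags."""
    out = table.copy()
    if ref is not None:
        out["isoacceptor"] = out["contig"].map(
            lambda c: ref.isoacceptor_of.get(c, c)
        )
    else:
        out["isoacceptor"] = out["contig"]
    flagged = {(c.contig_id, p) for c in candidates for p in (c.g_position,)}
    out["is_candidate"] = [
        (c, p) in flagged for c, p in zip(out["contig"], out["position"])
    ]
    if profiles:
        labels = []
        for contig, pos in zip(out["contig"], out["position"]):
            hit = _projection.match_contig_row(profiles, ref, contig)
            if hit is None:
                labels.append("")
            else:
                profile, gene_id = hit
                try:
                    _, label = _projection.map_position(profile, gene_id, int(pos))
                except ValueError:
                    label = None
                labels.append(label or "")
        out["label"] = labels
    cols = ["isoacceptor", "contig", "position", "score",
            "n_treated", "n_untreated", "is_candidate"]
    if "label" in out:
        cols.insert(3, "label")
    return out[cols].sort_values(["isoacceptor", "contig", "position"],
                                 ignore_index=True)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_study(
    seed: int,
    n_contigs: int = 20,
    n_modified: int = 10,
    body_length: int = 76,
    g_position: int = 46,
    efficiency: float = 0.8,
    n_reads: int = 50_000,
    pretrna_fraction: float = 0.0,
    extra_rules: Sequence[_simulate.ModRule] | None = None,
    with_offtargets: bool = False,
    config: _simulate.SimulationConfig | None = None,
) -> dict:
    """Build the synthetic study system and simulate both conditions.

    Plants m7G at the G46 analogue in the first ``n_modified`` contigs (by
    sorted contig id); ``with_offtargets`` additionally plants m3C and
    dihydrouridine sites in the remaining contigs, and ``extra_rules`` can
    add arbitrary sites.  Returns a dict with the reference, truth, reads
    and truth logs.
    """
    genes = _simulate.synthetic_genes(
        n_genes=n_contigs, body_length=body_length, g_position=g_position, seed=seed
    )
    genome, placed = _simulate.synthetic_genome(genes, seed=seed + 1)
    ref = build_reference(placed, genome=genome)
    modified = ref.scored_contigs[:n_modified]
    rules: list[_simulate.ModRule] = []
    if modified:
        rules.append(
            _simulate.ModRule("m7G", g_position, efficiency, contigs=modified)
        )
    if with_offtargets:
        rules.extend(
            _simulate.offtarget_rules(
                ref, ref.scored_contigs[n_modified:], efficiency=efficiency
            )
        )
    rules.extend(extra_rules or [])
    truth = _simulate.plant_modifications(ref, rules, seed=seed)
    if config is None:
        config = _simulate.SimulationConfig(
            n_reads=n_reads, pretrna_fraction=pretrna_fraction, seed=seed
        )
    reads, logs = {}, {}
    for condition in ("treated", "untreated"):
        reads[condition], logs[condition] = _simulate.simulate_library(
            ref, truth, condition, config
        )
    return {
        "ref": ref,
        "truth": truth,
        "reads": reads,
        "logs": logs,
        "config": config,
        "modified_contigs": modified,
    }


def run_pipeline(
    outdir: str,
    seed: int = 0,
    simulate: bool = True,
    n_contigs: int = 20,
    n_modified: int = 10,
    n_reads: int = 50_000,
    efficiency: float = 0.8,
    pretrna_fraction: float = 0.05,
    alpha: float = 0.5,
    threshold: float = _scoring.THRESHOLD_STRICT,
    min_support: int = 10,
    mapq_min: int = 1,
) -> dict:
    """Self-contained end-to-end run; returns the YAML-serializable manifest.

    Stages: reference build -> simulation -> alignment/filtering/counting ->
    scoring -> candidate calling -> projection -> reports.  All outputs are
    deterministic functions of the parameters and seed; the manifest records
    resolved parameters and SHA-256 checksums of every artifact.
    """
    if not simulate:
        raise NotImplementedError(
            "file-based runs go through the individual subcommands; "
            "run_pipeline drives the simulated study"
        )
    os.makedirs(outdir, exist_ok=True)
    study = simulate_study(
        seed=seed,
        n_contigs=n_contigs,
        n_modified=n_modified,
        n_reads=n_reads,
        efficiency=efficiency,
        pretrna_fraction=pretrna_fraction,
    )
    ref: ReferenceSet = study["ref"]
    refdir = os.path.join(outdir, "ref")
    artifact_paths = dict(write_reference(ref, refdir))

    truth_path = os.path.join(outdir, "truth.tsv")
    study["truth"].to_tsv(truth_path)
    artifact_paths["truth"] = truth_path

    for condition in ("treated", "untreated"):
        fq = os.path.join(outdir, f"{condition}.fastq")
        _simulate.write_fastq(study["reads"][condition], fq)
        artifact_paths[f"fastq_{condition}"] = fq
        log_path = os.path.join(outdir, f"{condition}.truthlog.tsv")
        study["logs"][condition].to_csv(log_path, sep="\t", index=False)
        artifact_paths[f"truthlog_{condition}"] = log_path

    tables, filtered, removed = _counts.align_and_count(
        study["reads"], ref, mapq_min=mapq_min, min_support=min_support
    )
    for condition, table in tables.items():
        path = os.path.join(outdir, f"counts_{condition}.tsv")
        table.to_tsv(path)
        artifact_paths[f"counts_{condition}"] = path

    score_df = _scoring.score_table(
        tables["treated"], tables["untreated"], ref, alpha=alpha
    )
    score_path = os.path.join(outdir, "scores.tsv")
    score_df.to_csv(score_path, sep="\t", index=False, float_format="%.6g")
    artifact_paths["scores"] = score_path

    candidates = _scoring.call_candidates(score_df, threshold=threshold, ref=ref)
    cand_path = os.path.join(outdir, "candidates.tsv")
    _scoring.candidates_to_frame(candidates).to_csv(
        cand_path, sep="\t", index=False, float_format="%.6g"
    )
    artifact_paths["candidates"] = cand_path

    profiles = _projection.profiles_from_reference(ref)
    sites = _projection.aggregate_isoacceptor(candidates, profiles, ref)
    sites_path = os.path.join(outdir, "isoacceptor_sites.tsv")
    sites.to_csv(sites_path, sep="\t", index=False, float_format="%.6g")
    artifact_paths["isoacceptor_sites"] = sites_path

    lengths = {c: len(s) for c, s in ref.contigs.items()}
    for condition in ("treated", "untreated"):
        depth = _counts.coverage_profile(filtered[condition], lengths)
        bg = os.path.join(outdir, f"coverage_{condition}.bedgraph")
        _counts.write_bedgraph(depth, bg)
        artifact_paths[f"coverage_{condition}"] = bg
        hm = heatmap_matrix(depth, ref, profiles, condition=condition)
        hm_path = os.path.join(outdir, f"heatmap_{condition}.tsv")
        hm.to_tsv(hm_path)
        artifact_paths[f"heatmap_{condition}"] = hm_path

    profile_df = score_profile_export(score_df, candidates, ref, profiles)
    prof_path = os.path.join(outdir, "score_profiles.tsv")
    profile_df.to_csv(prof_path, sep="\t", index=False, float_format="%.6g")
    artifact_paths["score_profiles"] = prof_path

    manifest = {
        "parameters": {
            "seed": seed,
            "n_contigs": n_contigs,
            "n_modified": n_modified,
            "n_reads": n_reads,
            "efficiency": efficiency,
            "pretrna_fraction": pretrna_fraction,
            "alpha": alpha,
            "threshold": threshold,
            "min_support": min_support,
            "mapq_min": mapq_min,
            "simulation": study["config"].to_dict(),
        },
        "stage_stats": {
            condition: tables[condition].filters_applied
            for condition in tables
        },
        "n_candidates": len(candidates),
        "checksums": {
            name: _sha256(path) for name, path in sorted(artifact_paths.items())
        },
    }
    manifest_path = os.path.join(outdir, "manifest.yaml")
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
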