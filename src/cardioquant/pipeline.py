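"""End-to-end runs: read inputs, quantify, write tables, plots and a run log.

The two entry points mirror the two analyses:

* :func:`run_polii_pipeline` — coverage tracks + gene table (+ peaks) ->
  per-gene 25-block profile matrices, gene score table, filtered ranked
  list, metagene profiles per gene set (TSV + plot).
* :func:`run_imaging_pipeline` — a directory of 3-channel TIFF fields +
  a metadata CSV -> per-cell measurement table and per-condition summary.

Every run writes ``run_log.txt``: tool version, resolved configuration
(every parameter that affects output, including derived policies such as
the fold-ratio pseudocount), and SHA-256 checksums of all inputs.  Reruns
with identical inputs and configuration produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import imaging, polii, track_io

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


class InputError(ValueError):
    """Invalid or missing inputs (CLI exit code 2)."""


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_log(path, entries: Dict[str, object]) -> None:
    """Machine-readable key-value run log, one ``key = value`` per line."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"cardioquant_version = {__version__}\n")
        for k, v in entries.items():
            fh.write(f"{k} = {v}\n")


def _read_track(path, fmt: str, normalized: bool) -> track_io.BinnedTrack:
    if fmt == "wig":
        return track_io.read_wig(path, normalized=normalized)
    if fmt == "bedgraph":
        return track_io.read_bedgraph(path, normalized=normalized)
    raise InputError(f"unknown track format {fmt!r}")


def run_polii_pipeline(
    track_control,
    track_treatment,
    genes_path,
    out_dir,
    *,
    depth_control: Optional[int] = None,
    depth_treatment: Optional[int] = None,
    peaks_path=None,
    track_format: str = "wig",
    tracks_prenormalized: bool = False,
    fold_threshold: float = 1.5,
    rank_by: str = "fold",
    bound_only: bool = False,
    upstream_bp: int = 1000,
    make_plots: bool = True,
) -> pd.DataFrame:
    """Run the full Pol II gene-body enrichment analysis.

    Reads two coverage tracks (WIG or bedGraph), depth-normalizes them to
    density per million mapped reads per bp (unless
    ``tracks_prenormalized``), quantifies every gene's 25-block profile,
    scores both conditions, optionally gates on assigned peaks, and ranks
    genes above ``fold_threshold``.  Writes into ``out_dir``:
    ``profiles_control.tsv`` / ``profiles_treatment.tsv`` (25 block
    columns per gene), ``gene_scores.tsv``, ``ranked_genes.tsv``,
    ``metagene_<set>.tsv`` (+ ``metagene.png``) and ``run_log.txt``.
    Returns the full gene score table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in (track_control, track_treatment, genes_path):
        if not Path(p).exists():
            raise InputError(f"input not found: {p}")

    genes = track_io.read_gene_table(genes_path)
    if not genes:
        raise InputError(f"{genes_path}: no genes")
    ctrl = _read_track(track_control, track_format, tracks_prenormalized)
    treat = _read_track(track_treatment, track_format, tracks_prenormalized)
    if not tracks_prenormalized:
        if depth_control is None or depth_treatment is None:
            raise InputError(
                "depth_control and depth_treatment are required unless the "
                "tracks are already depth-normalized"
            )
        ctrl = polii.normalize_track(ctrl, depth_control)
        treat = polii.normalize_track(treat, depth_treatment)

    missing = track_io.check_chrom_compatibility(ctrl, genes)
    missing += [
        m for m in track_io.check_chrom_compatibility(treat, genes) if m not in missing
    ]
    if missing:
        raise InputError(
            "gene table chromosomes absent from track(s): " + ", ".join(missing)
        )

    prof_ctrl = polii.profile_genes(ctrl, genes)
    prof_treat = polii.profile_genes(treat, genes)

    bound = None
    if peaks_path is not None:
        peaks = track_io.read_peaks(peaks_path)
        assignment = polii.assign_peaks_to_genes(peaks, genes, upstream_bp)
        bound = {name: a.bound for name, a in assignment.items()}

    eps = polii.fold_ratio_epsilon(
        [polii.enrichment_score(p) for p in prof_ctrl]
    )
    scores = polii.score_table(prof_ctrl, prof_treat, bound=bound, epsilon=eps)
    ranked = polii.rank_and_filter(
        {p.gene_name: polii.enrichment_score(p) for p in prof_ctrl},
        {p.gene_name: polii.enrichment_score(p) for p in prof_treat},
        fold_threshold=fold_threshold,
        bound_only=bound_only,
        bound=bound,
        rank_by=rank_by,
        epsilon=eps,
    )

    _write_profiles(prof_ctrl, out / "profiles_control.tsv")
    _write_profiles(prof_treat, out / "profiles_treatment.tsv")
    scores.to_csv(out / "gene_scores.tsv", sep="\t", index=False,
                  float_format=FLOAT_FMT)
    pd.DataFrame(
        [
            {
                "rank": r.rank,
                "gene": r.gene_name,
                "score_control": r.score_control,
                "score_treatment": r.score_treatment,
                "fold_ratio": r.fold_ratio,
                "myc_bound": r.myc_bound,
            }
            for r in ranked
        ]
    ).to_csv(out / "ranked_genes.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    gene_sets = {"all": list(range(len(genes)))}
    if bound is not None:
        gene_sets["bound"] = [i for i, g in enumerate(genes) if bound.get(g.name)]
        gene_sets["unbound"] = [i for i, g in enumerate(genes) if not bound.get(g.name)]
    metagenes = {}
    for label, idx in gene_sets.items():
        if not idx:
            continue
        for cond, profs in (("control", prof_ctrl), ("treatment", prof_treat)):
            mg = polii.metagene_average([profs[i] for i in idx], f"{label}/{cond}")
            metagenes[(label, cond)] = mg
        df = pd.DataFrame(
            {
                "block": np.arange(1, 26),
                "control": metagenes[(label, "control")].values,
                "treatment": metagenes[(label, "treatment")].values,
            }
        )
        df.to_csv(out / f"metagene_{label}.tsv", sep="\t", index=False,
                  float_format=FLOAT_FMT)
    if make_plots:
        _plot_metagenes(metagenes, out / "metagene.png")

    write_run_log(
        out / "run_log.txt",
        {
            "pipeline": "polii-score",
            "track_control": track_control,
            "track_control_sha256": _sha256(track_control),
            "track_treatment": track_treatment,
            "track_treatment_sha256": _sha256(track_treatment),
            "genes": genes_path,
            "genes_sha256": _sha256(genes_path),
            "peaks": peaks_path if peaks_path else "none",
            **({"peaks_sha256": _sha256(peaks_path)} if peaks_path else {}),
            "track_format": track_format,
            "tracks_prenormalized": tracks_prenormalized,
            "depth_control": depth_control,
            "depth_treatment": depth_treatment,
            "n_genes": len(genes),
            "fold_threshold": fold_threshold,
            "rank_by": rank_by,
            "bound_only": bound_only,
            "upstream_bp": upstream_bp,
            "fold_ratio_pseudocount": eps,
            "n_genes_passing_filter": len(ranked),
        },
    )
    return scores


def _write_profiles(profiles: Sequence[polii.BlockProfile], path) -> None:
    cols = (
        [f"up{i}" for i in range(1, 6)]
        + [f"body{i}" for i in range(1, 11)]
        + [f"down{i}" for i in range(1, 11)]
    )
    df = pd.DataFrame(
        [dict(zip(cols, p.values), gene=p.gene_name, clipped=p.clipped)
         for p in profiles]
    )
    df = df[["gene"] + cols + ["clipped"]].sort_values("gene")
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _plot_metagenes(metagenes, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = sorted({label for label, _ in metagenes})
    fig, axes = plt.subplots(1, len(labels), figsize=(4.5 * len(labels), 3.5),
                             squeeze=False)
    x = np.arange(1, 26)
    for ax, label in zip(axes[0], labels):
        for cond, style in (("control", "C0-"), ("treatment", "C3-")):
            mg = metagenes.get((label, cond))
            if mg is not None:
                ax.plot(x, mg.values, style, label=cond)
        ax.axvspan(5.5, 15.5, color="0.9", zorder=0)
        ax.set_title(f"{label} (n={metagenes[(label, 'control')].n_genes})")
        ax.set_xlabel("block (5 up | 10 body | 10 down)")
        ax.set_ylabel("density / bp (per M reads)")
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Imaging pipeline
# ---------------------------------------------------------------------------

@dataclass
class ImagingRunSummary:
    cells: pd.DataFrame
    summary: Optional[pd.DataFrame]
    n_fields_ok: int
    n_fields_failed: int
    failures: List[str] = field(default_factory=list)


def run_imaging_pipeline(
    image_dir,
    meta_path,
    out_dir,
    *,
    channel_order: Sequence[int] = (0, 1, 2),
    pixel_size: Optional[float] = None,
    min_nucleus_area: int = 50,
    nuclei_smoothing_sigma: float = 2.0,
    marker_smoothing_sigma: float = 2.0,
    split_min_distance: int = 10,
    max_cell_radius: Optional[float] = None,
    theta: float = 0.5,
    background_policy: str = "median",
    reference_condition: Optional[str] = None,
) -> ImagingRunSummary:
    """Segment, classify and measure every field listed in the metadata CSV.

    ``meta_path`` is a CSV with columns ``field_id``, ``condition`` and
    ``file`` (TIFF filename relative to ``image_dir``).  Writes
    ``cells.csv`` (one row per segmented cell), ``condition_summary.csv``
    and ``run_log.txt``; per-field failures are logged and skipped, and
    counted in the returned summary.
    """
    image_dir, out = Path(image_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not Path(meta_path).exists():
        raise InputError(f"metadata CSV not found: {meta_path}")
    meta = pd.read_csv(meta_path)
    for col in ("field_id", "condition", "file"):
        if col not in meta.columns:
            raise InputError(f"{meta_path}: missing column {col!r}")
    if len(meta) == 0:
        raise InputError(f"{meta_path}: no fields listed")

    params = dict(
        min_nucleus_area=min_nucleus_area,
        nuclei_smoothing_sigma=nuclei_smoothing_sigma,
        marker_smoothing_sigma=marker_smoothing_sigma,
        split_min_distance=split_min_distance,
        max_cell_radius=max_cell_radius,
        theta=theta,
        background_policy=background_policy,
    )
    tables, failures = [], []
    for rec in meta.itertuples():
        tiff = image_dir / rec.file
        try:
            fld = imaging.read_field_tiff(
                tiff, field_id=str(rec.field_id),
                channel_order=channel_order, pixel_size=pixel_size,
            )
            _, df = imaging.quantify_field(fld, **params)
        except Exception as e:  # per-field isolation
            logger.error("field %s (%s) failed: %s", rec.field_id, tiff, e)
            failures.append(f"{rec.field_id}: {e}")
            continue
        df["condition"] = rec.condition
        tables.append(df)
    if not tables:
        raise InputError("every field failed; nothing to report")

    cells = pd.concat(tables, ignore_index=True)
    cells.to_csv(out / "cells.csv", index=False, float_format=FLOAT_FMT)
    summary = None
    try:
        summary = imaging.summarize_condition(cells, reference=reference_condition)
        summary.to_csv(out / "condition_summary.csv", index=False,
                       float_format=FLOAT_FMT)
    except ValueError as e:
        logger.warning("condition summary skipped: %s", e)
        failures.append(f"summary: {e}")

    write_run_log(
        out / "run_log.txt",
        {
            "pipeline": "cellquant",
            "image_dir": image_dir,
            "meta": meta_path,
            "meta_sha256": _sha256(meta_path),
            "channel_order": ",".join(map(str, channel_order)),
            "pixel_size": pixel_size,
            **params,
            "reference_condition": reference_condition,
            "n_fields": len(meta),
            "n_fields_failed": len(failures),
            "n_cells": len(cells),
        },
    )
    return ImagingRunSummary(
        cells=cells,
        summary=summary,
        n_fields_ok=len(tables),
        n_fields_failed=len(failures),
        failures=failures,
    )
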