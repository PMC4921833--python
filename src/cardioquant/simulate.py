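"""Ground-truthed synthetic inputs for both quantification pipelines.

Two generators:

* :func:`simulate_tracks` — two-condition binned Pol II ChIP-seq coverage
  with a promoter-proximal accumulation at every TSS and a configurable
  gene-body fold-enrichment on a designated gene subset in the treatment
  condition.  Per-bin read counts are Poisson around the expected rate,
  scaled so the realized library depth matches the configured depth.
* :func:`simulate_image_fields` — three-channel microscopy fields of
  disk-shaped cells (nucleus disk inside cell disk) with marker-positive
  and marker-negative populations and distinct nuclear / cytosolic EU
  levels, plus additive Gaussian noise.

Both record per-gene / per-cell ground truth and are seeded: identical
configuration and seed give byte-identical outputs.

The treatment condition's gene-body enrichment multiplies the *entire*
local control rate (background plus any promoter-peak overlap) by the
configured fold, modelling proportional Pol II recruitment along the
body; the expected score ratio then equals the configured fold exactly,
independent of promoter geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .imaging import ImageField
from .track_io import BinnedTrack, GeneModel, GenomicInterval


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------

@dataclass
class TrackSimConfig:
    """Two-condition Pol II coverage simulation settings.

    Defaults are the desk-scale study conditions: 200 genes, 20% of them
    body-enriched at fold 2 under treatment, 1e6 mapped reads per
    condition, 10 bp bins, Poisson per-bin counts.
    """

    n_genes: int = 200
    gene_length_range: Tuple[int, int] = (1000, 5000)
    gene_spacing: int = 12000       # bp between consecutive gene bodies
    genes_per_chromosome: int = 50
    depth: int = 1_000_000          # mapped reads per condition
    bin_width: int = 10
    background_rate: float = 0.1    # expected reads/bp before depth scaling
    promoter_peak_fold: float = 5.0  # TSS-proximal rate, fold over background
    promoter_width: Optional[int] = None  # bp; default one body-block width
    body_fold: float = 2.0          # treatment gene-body enrichment
    enriched_gene_fraction: float = 0.2
    noise: str = "poisson"          # 'poisson' or 'none' (exact expectations)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.gene_length_range
        if lo < 10 or hi < lo:
            raise ValueError("gene lengths must satisfy 10 <= lo <= hi")
        if not 0.0 <= self.enriched_gene_fraction <= 1.0:
            raise ValueError("enriched_gene_fraction must be in [0, 1]")
        if self.background_rate <= 0 or self.body_fold <= 0:
            raise ValueError("rates and folds must be positive")
        if self.noise not in ("poisson", "none"):
            raise ValueError(f"unknown noise family {self.noise!r}")
        flank = 2 * (hi // 10) * 10  # widest flank span on either side
        if self.gene_spacing < flank:
            raise ValueError(
                f"gene_spacing {self.gene_spacing} bp cannot fit the flanking "
                f"blocks of the longest genes; use at least {flank} bp"
            )


@dataclass
class TrackSimResult:
    genes: List[GeneModel]
    control: BinnedTrack
    treatment: BinnedTrack
    ground_truth: pd.DataFrame  # gene, chrom, start, end, strand, enriched, body_fold
    control_scale: float = 1.0   # depth / pre-scale expected total, per condition
    treatment_scale: float = 1.0


def simulate_tracks(config: TrackSimConfig) -> TrackSimResult:
    """Simulate gene annotation plus control and treatment coverage tracks.

    Genes are laid out non-overlapping along synthetic chromosomes
    (``chrS1``, ``chrS2``, ...) with alternating strands.  The expected
    per-bp rate is ``background`` everywhere, ``background *
    promoter_peak_fold`` in a window centered on each TSS (both
    conditions), and — treatment condition, enriched genes only —
    ``body_fold`` times the local control rate over the gene body.
    Per-bin counts are Poisson draws around the expected rate scaled so
    the expected genome-wide total equals ``depth``; each returned track
    carries its realized total as ``total_mapped_reads``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_length_range

    # --- gene layout -------------------------------------------------------
    genes: List[GeneModel] = []
    rows = []
    n_chroms = -(-config.n_genes // config.genes_per_chromosome)
    chrom_bp: Dict[str, int] = {}
    gi = 0
    for ci in range(n_chroms):
        chrom = f"chrS{ci + 1}"
        cursor = config.gene_spacing
        n_here = min(config.genes_per_chromosome, config.n_genes - gi)
        for _ in range(n_here):
            length = int(rng.integers(lo, hi + 1))
            strand = "+" if gi % 2 == 0 else "-"
            start, end = cursor, cursor + length
            name = f"gene{gi + 1:04d}"
            genes.append(GeneModel(GenomicInterval(chrom, start, end, strand), name))
            rows.append(
                {
                    "gene": name,
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "length": length,
                }
            )
            cursor = end + config.gene_spacing
            gi += 1
        chrom_bp[chrom] = cursor

    # --- enriched subset ---------------------------------------------------
    n_enriched = int(round(config.enriched_gene_fraction * config.n_genes))
    enriched_idx = rng.choice(config.n_genes, size=n_enriched, replace=False)
    enriched = np.zeros(config.n_genes, dtype=bool)
    enriched[enriched_idx] = True

    # --- expected per-bp rates --------------------------------------------
    bg = config.background_rate
    rate_ctrl = {c: np.full(n, bg) for c, n in chrom_bp.items()}
    for g in genes:
        w = (
            config.promoter_width
            if config.promoter_width is not None
            else g.body_length // 10
        )
        p0 = max(g.tss - w // 2, 0)
        p1 = min(g.tss + (w - w // 2), chrom_bp[g.chrom])
        rate_ctrl[g.chrom][p0:p1] = bg * config.promoter_peak_fold
    rate_treat = {c: r.copy() for c, r in rate_ctrl.items()}
    for g, is_enr in zip(genes, enriched):
        if is_enr:
            s, e = g.interval.start, g.interval.end
            rate_treat[g.chrom][s:e] *= config.body_fold

    # --- draw per-bin counts ----------------------------------------------
    def draw(rates: Dict[str, np.ndarray]):
        w = config.bin_width
        expected = {}
        total_expected = 0.0
        for chrom, r in rates.items():
            n_bins = -(-r.size // w)
            padded = np.pad(r, (0, n_bins * w - r.size))
            per_bin = padded.reshape(n_bins, w).sum(axis=1)
            expected[chrom] = per_bin
            total_expected += per_bin.sum()
        scale = config.depth / total_expected
        values = {}
        for chrom in sorted(expected):
            mu = expected[chrom] * scale
            if config.noise == "poisson":
                values[chrom] = rng.poisson(mu).astype(float)
            else:
                values[chrom] = mu
        total = sum(v.sum() for v in values.values())
        track = BinnedTrack(
            bin_width=w,
            values=values,
            total_mapped_reads=max(int(round(total)), 1),
            normalized=False,
        )
        return track, scale

    control, s_ctrl = draw(rate_ctrl)
    treatment, s_treat = draw(rate_treat)

    gt = pd.DataFrame(rows)
    gt["enriched"] = enriched
    gt["body_fold"] = np.where(enriched, config.body_fold, 1.0)
    return TrackSimResult(genes, control, treatment, gt, s_ctrl, s_treat)


def write_gene_table(genes: List[GeneModel], path) -> None:
    """Write genes as the 5-column tab-separated table track_io reads."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.interval.start}\t{g.interval.end}\t"
                f"{g.name}\t{g.strand}\n"
            )


# ---------------------------------------------------------------------------
# Imaging fields
# ---------------------------------------------------------------------------

@dataclass
class ImageSimConfig:
    """Microscopy-field simulation settings.

    Cells are disks with a concentric nucleus disk; intensity levels are
    absolute channel values (the measurable contrast of a compartment is
    therefore level minus ``eu_background``).  Defaults emulate a
    20x-objective cytometer field at modest confluency with
    signal-to-noise around 45:1 for nuclei and 10:1 for the dimmest
    (cytosolic) EU compartment.
    """

    shape: Tuple[int, int] = (384, 384)
    n_cells_range: Tuple[int, int] = (5, 8)
    marker_positive_fraction: float = 0.6
    nucleus_radius_range: Tuple[float, float] = (8.0, 10.0)
    cell_radius_range: Tuple[float, float] = (26.0, 34.0)
    min_spacing: Optional[float] = None  # centroid spacing; default 2*r_max + 4
    nuclear_eu: float = 500.0
    cytosolic_eu: float = 150.0
    eu_background: float = 50.0
    marker_level: float = 300.0
    marker_background: float = 20.0
    nuclei_level: float = 400.0
    nuclei_background: float = 20.0
    noise_sigma: float = 10.0
    pixel_size: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.marker_positive_fraction <= 1.0:
            raise ValueError("marker_positive_fraction must be in [0, 1]")
        for lo, hi in (self.nucleus_radius_range, self.cell_radius_range):
            if lo <= 0 or hi < lo:
                raise ValueError("radius ranges must satisfy 0 < lo <= hi")
        if self.nucleus_radius_range[1] >= self.cell_radius_range[0]:
            raise ValueError("nucleus radii must be strictly below cell radii")
        for name in ("nuclear_eu", "cytosolic_eu", "marker_level", "nuclei_level"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def spacing(self) -> float:
        if self.min_spacing is not None:
            return self.min_spacing
        return 2 * self.cell_radius_range[1] + 4


def _disk_mask(shape, cy: float, cx: float, radius: float) -> np.ndarray:
    rr, cc = np.indices(shape)
    return (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2


def simulate_image_fields(
    config: ImageSimConfig, n_fields: int = 1
) -> Tuple[List[ImageField], pd.DataFrame]:
    """Simulate three-channel fields with per-cell ground truth.

    Cells (disks) are placed by rejection sampling at minimum centroid
    spacing ``config.spacing`` and kept clear of the field border, so
    ground-truth areas are exact disk pixel counts.  Exactly
    ``round(marker_positive_fraction * n)`` cells per field are
    marker-positive.  Ground-truth columns: field_id, cell, cy, cx,
    nucleus_radius, cell_radius, marker_positive, cell_area_px,
    nucleus_area_px plus the configured intensity levels.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    fields: List[ImageField] = []
    rows = []
    for fi in range(n_fields):
        field_id = f"field{fi + 1:03d}"
        n_cells = int(rng.integers(config.n_cells_range[0], config.n_cells_range[1] + 1))
        radii = rng.uniform(*config.cell_radius_range, size=n_cells)
        nuc_radii = rng.uniform(*config.nucleus_radius_range, size=n_cells)
        centers = []
        for r in radii:
            margin = r + 2
            placed = False
            for _ in range(5000):
                cy = rng.uniform(margin, h - margin)
                cx = rng.uniform(margin, w - margin)
                if all(
                    (cy - py) ** 2 + (cx - px) ** 2 >= config.spacing**2
                    for py, px in centers
                ):
                    centers.append((cy, cx))
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place {n_cells} cells at spacing "
                    f"{config.spacing:.0f} px in a {h}x{w} field; reduce "
                    "n_cells or spacing"
                )
        n_pos = int(round(config.marker_positive_fraction * n_cells))
        positive = np.zeros(n_cells, dtype=bool)
        positive[rng.permutation(n_cells)[:n_pos]] = True

        nuclei = np.full(config.shape, config.nuclei_background)
        marker = np.full(config.shape, config.marker_background)
        eu = np.full(config.shape, config.eu_background)
        for i, ((cy, cx), r, nr, pos) in enumerate(
            zip(centers, radii, nuc_radii, positive)
        ):
            cell = _disk_mask(config.shape, cy, cx, r)
            nuc = _disk_mask(config.shape, cy, cx, nr)
            cyt = cell & ~nuc
            nuclei[nuc] = config.nuclei_level
            if pos:
                marker[cell] = config.marker_level
            eu[cyt] = config.cytosolic_eu
            eu[nuc] = config.nuclear_eu
            rows.append(
                {
                    "field_id": field_id,
                    "cell": i + 1,
                    "cy": cy,
                    "cx": cx,
                    "nucleus_radius": nr,
                    "cell_radius": r,
                    "marker_positive": bool(pos),
                    "cell_area_px": int(cell.sum()),
                    "nucleus_area_px": int(nuc.sum()),
                    "nuclear_eu": config.nuclear_eu,
                    "cytosolic_eu": config.cytosolic_eu,
                    "eu_background": config.eu_background,
                }
            )
        if config.noise_sigma > 0:
            nuclei = nuclei + rng.normal(0, config.noise_sigma, config.shape)
            marker = marker + rng.normal(0, config.noise_sigma, config.shape)
            eu = eu + rng.normal(0, config.noise_sigma, config.shape)
        fields.append(
            ImageField(
                nuclei=np.clip(nuclei, 0, None),
                marker=np.clip(marker, 0, None),
                eu=np.clip(eu, 0, None),
                field_id=field_id,
                pixel_size=config.pixel_size,
            )
        )
    return fields, pd.DataFrame(rows)
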