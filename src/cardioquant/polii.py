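"""Per-gene RNA Pol II occupancy profiling and gene-body enrichment scoring.

The statistic implemented here summarizes Pol II ChIP-seq occupancy per
gene from depth-normalized binned coverage:

1. Coverage (reads per bin) is normalized to read density per million
   mapped reads per bp.
2. The gene body — TSS to transcript end — is divided into 10 blocks;
   together with 5 upstream and 10 downstream flanking blocks of one
   body-block width each, this yields a 25-block axis oriented 5'->3' in
   the direction of transcription.
3. Each block's value is the average density/bp over the block, with bins
   straddling a block boundary contributing pro-rata by overlap length.
4. The gene's enrichment score is the sum of the 10 body-block values
   (density/bp, length-normalized by construction); flanks are
   descriptive only.
5. Genes are compared between two conditions by the ratio of their scores
   and filtered at a fold threshold (default 1.5); peak calls can gate
   the list to genes with an assigned peak (gene body plus 1000 bp
   upstream of the TSS).

Block boundaries are measured from the TSS along the transcription
direction as ``d_i = round(i * L / n_body)``, so body blocks tile the
gene exactly with widths differing by at most 1 bp, and a strand-reflected
gene over mirrored coverage yields the exactly reversed profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .track_io import BinnedTrack, GeneModel, GenomicInterval, PeakCall

logger = logging.getLogger(__name__)

N_UPSTREAM = 5
N_BODY = 10
N_DOWNSTREAM = 10


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_track(
    track: BinnedTrack, total_mapped_reads: Optional[int] = None
) -> BinnedTrack:
    """Convert raw per-bin read counts to density per million mapped reads per bp.

    Each bin value v becomes ``v / bin_width / (total_mapped_reads / 1e6)``.
    The input track is not modified.  Raises if the track is already
    normalized (double normalization) or if no depth is available.
    """
    if track.normalized:
        raise ValueError("track is already depth-normalized")
    depth = total_mapped_reads if total_mapped_reads is not None else track.total_mapped_reads
    if depth is None:
        raise ValueError(
            "total_mapped_reads is required for normalization and was not "
            "supplied (WIG files do not carry library depth)"
        )
    if depth < 1:
        raise ValueError(f"total_mapped_reads must be >= 1, got {depth}")
    scale = 1.0 / (track.bin_width * (depth / 1e6))
    values = {c: a * scale for c, a in track.values.items()}
    return BinnedTrack(
        bin_width=track.bin_width,
        values=values,
        total_mapped_reads=int(depth),
        normalized=True,
    )


# ---------------------------------------------------------------------------
# Block partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    """One block of the 25-block axis.

    ``interval`` is the genomically clipped extent (None if the block lies
    entirely outside the valid coordinate range); ``nominal_width`` is the
    unclipped width in bp; ``clipped`` marks any truncation.
    """

    interval: Optional[GenomicInterval]
    nominal_width: int
    clipped: bool

    @property
    def width(self) -> int:
        """Clipped width actually covered, in bp."""
        return 0 if self.interval is None else len(self.interval)


@dataclass(frozen=True)
class BlockPartition:
    gene: GeneModel
    blocks: Tuple[Block, ...]  # ordered 5'->3' in transcription direction
    n_up: int
    n_body: int
    n_down: int

    @property
    def any_clipped(self) -> bool:
        return any(b.clipped for b in self.blocks)

    @property
    def body_blocks(self) -> Tuple[Block, ...]:
        return self.blocks[self.n_up : self.n_up + self.n_body]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def block_partition(
    gene: GeneModel,
    n_up: int = N_UPSTREAM,
    n_body: int = N_BODY,
    n_down: int = N_DOWNSTREAM,
    flank_block_bp: Optional[int] = None,
    chrom_length: Optional[int] = None,
) -> BlockPartition:
    """Lay the 25-block axis over a gene.

    Body blocks tile [start, end) exactly with integer boundaries at
    cumulative rounded positions (widths differ by <= 1 bp).  Flank blocks
    default to one body-block width, ``floor(L / n_body)`` bp each
    (override in bp via ``flank_block_bp``), extending upstream of the TSS
    and downstream of the TES in the transcription direction.  Flank
    blocks reaching below position 0 or past ``chrom_length`` are clipped
    and flagged; a clipped *body* (gene past the declared chromosome end)
    raises, since the body score is the headline quantity.
    """
    L = gene.body_length
    if L < n_body:
        raise ValueError(
            f"gene {gene.name!r}: body {L} bp shorter than n_body={n_body}"
        )
    chrom = gene.chrom
    g0, g1 = gene.interval.start, gene.interval.end
    if chrom_length is not None and g1 > chrom_length:
        raise ValueError(
            f"gene {gene.name!r}: body extends past declared chromosome "
            f"length {chrom_length}"
        )
    fw = flank_block_bp if flank_block_bp is not None else L // n_body
    if fw < 1:
        raise ValueError(f"flank block width must be >= 1 bp, got {fw}")

    # distances from TSS along transcription direction; d[0]=0, d[n_body]=L
    d = [_round_half_up(i * L / n_body) for i in range(n_body + 1)]

    def clip(a: int, b: int, width: int) -> Block:
        ca, cb = max(a, 0), b
        if chrom_length is not None:
            cb = min(cb, chrom_length)
        if cb <= ca:
            return Block(None, width, True)
        iv = GenomicInterval(chrom, ca, cb, gene.strand)
        return Block(iv, width, (ca != a) or (cb != b))

    blocks: List[Block] = []
    if gene.strand == "+":
        for i in range(n_up, 0, -1):  # most-upstream first
            blocks.append(clip(g0 - i * fw, g0 - (i - 1) * fw, fw))
        for i in range(n_body):
            iv = GenomicInterval(chrom, g0 + d[i], g0 + d[i + 1], "+")
            blocks.append(Block(iv, d[i + 1] - d[i], False))
        for i in range(n_down):
            blocks.append(clip(g1 + i * fw, g1 + (i + 1) * fw, fw))
    else:
        # transcription runs right-to-left: upstream is at higher coordinates
        for i in range(n_up, 0, -1):
            blocks.append(clip(g1 + (i - 1) * fw, g1 + i * fw, fw))
        for i in range(n_body):
            iv = GenomicInterval(chrom, g1 - d[i + 1], g1 - d[i], "-")
            blocks.append(Block(iv, d[i + 1] - d[i], False))
        for i in range(n_down):
            blocks.append(clip(g0 - (i + 1) * fw, g0 - i * fw, fw))
    return BlockPartition(gene, tuple(blocks), n_up, n_body, n_down)


# ---------------------------------------------------------------------------
# Block quantification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockProfile:
    """25 average-density values for one gene in one sample, 5'->3'."""

    gene_name: str
    values: np.ndarray  # shape (n_up + n_body + n_down,)
    block_width: int    # body block width floor(L / n_body), bp
    n_up: int = N_UPSTREAM
    n_body: int = N_BODY
    n_down: int = N_DOWNSTREAM
    clipped: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        expected = self.n_up + self.n_body + self.n_down
        if vals.shape != (expected,):
            raise ValueError(
                f"profile for {self.gene_name!r} has {vals.shape} values, "
                f"expected ({expected},)"
            )
        if np.any(~np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError(
                f"profile for {self.gene_name!r} has negative or non-finite values"
            )
        object.__setattr__(self, "values", vals)

    @property
    def body_values(self) -> np.ndarray:
        return self.values[self.n_up : self.n_up + self.n_body]


def block_quantify(
    track: BinnedTrack, partition: BlockPartition, gene: Optional[GeneModel] = None
) -> BlockProfile:
    """Average density per bp in each block of a partition.

    ``track`` must be depth-normalized.  Per block the per-bp density is
    integrated over the (clipped) block extent — bins partially overlapping
    a block contribute pro-rata by overlap length, bins absent from the
    track count as 0 — and divided by the covered width.  Fully clipped
    blocks get value 0.
    """
    if not track.normalized:
        raise ValueError("block_quantify requires a depth-normalized track")
    gene = gene if gene is not None else partition.gene
    if gene.chrom not in track.values:
        raise KeyError(
            f"gene {gene.name!r}: chromosome {gene.chrom!r} absent from track"
        )
    vals = np.zeros(len(partition.blocks))
    for i, blk in enumerate(partition.blocks):
        if blk.interval is None or blk.width == 0:
            continue
        integral = track.interval_integral(
            gene.chrom, blk.interval.start, blk.interval.end
        )
        vals[i] = integral / blk.width
    return BlockProfile(
        gene_name=gene.name,
        values=vals,
        block_width=gene.body_length // partition.n_body,
        n_up=partition.n_up,
        n_body=partition.n_body,
        n_down=partition.n_down,
        clipped=partition.any_clipped,
    )


def profile_genes(
    track: BinnedTrack,
    genes: Sequence[GeneModel],
    chrom_lengths: Optional[Mapping[str, int]] = None,
    **partition_kwargs,
) -> List[BlockProfile]:
    """Partition and quantify every gene against one normalized track."""
    out = []
    for g in genes:
        cl = chrom_lengths.get(g.chrom) if chrom_lengths else None
        part = block_partition(g, chrom_length=cl, **partition_kwargs)
        out.append(block_quantify(track, part, g))
    return out


# ---------------------------------------------------------------------------
# Score, metagene, peak assignment, ranking
# ---------------------------------------------------------------------------

def enrichment_score(profile: BlockProfile) -> float:
    """Gene-body Pol II enrichment score: the sum of the body-block average
    densities (density/bp); upstream and downstream flanks are excluded."""
    return float(profile.body_values.sum())


@dataclass(frozen=True)
class MetageneProfile:
    """Position-wise mean of BlockProfiles over a gene set."""

    values: np.ndarray
    n_genes: int
    gene_set_label: str


def metagene_average(
    profiles: Sequence[BlockProfile], label: str = ""
) -> MetageneProfile:
    """Arithmetic mean of profiles, position-wise, over >= 1 genes."""
    if not profiles:
        raise ValueError("metagene_average requires at least one profile")
    shape = profiles[0].values.shape
    if any(p.values.shape != shape for p in profiles):
        raise ValueError("profiles have inconsistent block counts")
    mat = np.stack([p.values for p in profiles])
    return MetageneProfile(mat.mean(axis=0), len(profiles), label)


@dataclass
class PeakAssignment:
    gene_name: str
    bound: bool
    peaks: List[PeakCall] = field(default_factory=list)


def assign_peaks_to_genes(
    peaks: Sequence[PeakCall],
    genes: Sequence[GeneModel],
    upstream_bp: int = 1000,
) -> Dict[str, PeakAssignment]:
    """Assign peaks to genes by >= 1 bp overlap with the gene body extended
    ``upstream_bp`` bp 5' of the TSS (in transcription direction).

    A peak may be assigned to several genes.  The upstream window is
    half-open: a peak ending exactly at the window start shares no base
    pair and is not assigned.  Windows are clipped at position 0.
    """
    by_chrom: Dict[str, List[PeakCall]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    out: Dict[str, PeakAssignment] = {}
    for g in genes:
        if g.strand == "+":
            start = max(g.interval.start - upstream_bp, 0)
            end = g.interval.end
        else:
            start = g.interval.start
            end = g.interval.end + upstream_bp
        hits = [
            p
            for p in by_chrom.get(g.chrom, ())
            if p.interval.start < end and start < p.interval.end
        ]
        out[g.name] = PeakAssignment(g.name, bool(hits), hits)
    return out


@dataclass(frozen=True)
class GeneScoreRecord:
    """Per-gene score in both conditions plus fold ratio, rank and flags."""

    gene_name: str
    score_control: float
    score_treatment: float
    fold_ratio: float
    rank: Optional[int] = None
    myc_bound: bool = False
    clipped: bool = False


def fold_ratio_epsilon(control_scores: Sequence[float]) -> float:
    """Pseudocount for fold ratios: the 5th percentile of the positive
    control scores (1.0 when no control score is positive)."""
    pos = np.asarray([s for s in control_scores if s > 0], dtype=float)
    if pos.size == 0:
        return 1.0
    return float(np.percentile(pos, 5))


def compute_fold_ratio(
    score_control: float, score_treatment: float, epsilon: float
) -> float:
    """(treatment + eps) / (control + eps); genes with both scores zero
    get ratio exactly 1."""
    if score_control == 0 and score_treatment == 0:
        return 1.0
    return (score_treatment + epsilon) / (score_control + epsilon)


def rank_and_filter(
    scores_control: Mapping[str, float],
    scores_treatment: Mapping[str, float],
    *,
    fold_threshold: float = 1.5,
    bound_only: bool = False,
    bound: Optional[Mapping[str, bool]] = None,
    rank_by: str = "fold",
    epsilon: Optional[float] = None,
    clipped: Optional[Mapping[str, bool]] = None,
) -> List[GeneScoreRecord]:
    """Filter genes whose treatment/control score ratio strictly exceeds
    ``fold_threshold`` (optionally requiring an assigned peak), ranked by
    ``rank_by`` in {'fold', 'score'} descending, ties broken by gene name.

    Both mappings must cover the same gene universe.  Returned records
    carry ranks 1..K over the filtered set.
    """
    universe_a, universe_b = set(scores_control), set(scores_treatment)
    if universe_a != universe_b:
        diff = sorted(universe_a ^ universe_b)
        raise ValueError(
            f"gene universes differ between conditions; symmetric difference: {diff}"
        )
    if rank_by not in ("fold", "score"):
        raise ValueError(f"rank_by must be 'fold' or 'score', got {rank_by!r}")
    if epsilon is None:
        epsilon = fold_ratio_epsilon(list(scores_control.values()))

    records = []
    for name in scores_control:
        a, b = scores_control[name], scores_treatment[name]
        if a < 0 or b < 0:
            raise ValueError(f"gene {name!r}: scores must be non-negative")
        records.append(
            GeneScoreRecord(
                gene_name=name,
                score_control=a,
                score_treatment=b,
                fold_ratio=compute_fold_ratio(a, b, epsilon),
                myc_bound=bool(bound.get(name, False)) if bound else False,
                clipped=bool(clipped.get(name, False)) if clipped else False,
            )
        )

    kept = [r for r in records if r.fold_ratio > fold_threshold]
    if bound_only:
        kept = [r for r in kept if r.myc_bound]
    keyfn = (
        (lambda r: r.fold_ratio) if rank_by == "fold" else (lambda r: r.score_treatment)
    )
    kept.sort(key=lambda r: (-keyfn(r), r.gene_name))
    return [replace(r, rank=i + 1) for i, r in enumerate(kept)]


def score_table(
    profiles_control: Sequence[BlockProfile],
    profiles_treatment: Sequence[BlockProfile],
    *,
    bound: Optional[Mapping[str, bool]] = None,
    epsilon: Optional[float] = None,
):
    """Full per-gene score table as a pandas DataFrame (no filtering).

    Rows are sorted by gene name; columns: gene, score_control,
    score_treatment, fold_ratio, myc_bound, clipped.
    """
    import pandas as pd

    a = {p.gene_name: enrichment_score(p) for p in profiles_control}
    b = {p.gene_name: enrichment_score(p) for p in profiles_treatment}
    if set(a) != set(b):
        diff = sorted(set(a) ^ set(b))
        raise ValueError(f"profile gene sets differ; symmetric difference: {diff}")
    if epsilon is None:
        epsilon = fold_ratio_epsilon(list(a.values()))
    clip_a = {p.gene_name: p.clipped for p in profiles_control}
    clip_b = {p.gene_name: p.clipped for p in profiles_treatment}
    rows = []
    for name in sorted(a):
        rows.append(
            {
                "gene": name,
                "score_control": a[name],
                "score_treatment": b[name],
                "fold_ratio": compute_fold_ratio(a[name], b[name], epsilon),
                "myc_bound": bool(bound.get(name, False)) if bound else False,
                "clipped": clip_a[name] or clip_b[name],
            }
        )
    return pd.DataFrame(rows)
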