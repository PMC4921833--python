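"""Rank genes by Pol II gene-body enrichment between two conditions.

Simulates a two-condition ChIP-seq experiment (200 genes, 20% of them
carrying a twofold gene-body enrichment under treatment, one million
mapped reads per condition), depth-normalizes the coverage, computes each
gene's 25-block occupancy profile and body enrichment score, and ranks
genes by their treatment/control score ratio.
"""

import numpy as np

from cardioquant import (
    TrackSimConfig,
    enrichment_score,
    normalize_track,
    profile_genes,
    rank_and_filter,
    simulate_tracks,
)

res = simulate_tracks(TrackSimConfig(seed=42))
print(f"simulated {len(res.genes)} genes; "
      f"control depth {res.control.total_mapped_reads:,} reads, "
      f"treatment depth {res.treatment.total_mapped_reads:,} reads")

ctrl = normalize_track(res.control)      # -> density per M mapped reads per bp
treat = normalize_track(res.treatment)

scores_ctrl = {p.gene_name: enrichment_score(p)
               for p in profile_genes(ctrl, res.genes)}
scores_treat = {p.gene_name: enrichment_score(p)
                for p in profile_genes(treat, res.genes)}

# genes whose score ratio exceeds 1.5-fold, strongest fold change first
ranked = rank_and_filter(scores_ctrl, scores_treat,
                         fold_threshold=1.5, epsilon=0.0)
truth = res.ground_truth.set_index("gene")

print(f"\n{len(ranked)} genes exceed the 1.5-fold threshold "
      f"(the generator enriched {int(truth.enriched.sum())}).")
print("\ntop 5 by fold ratio (score = summed body density/bp):")
print(f"{'rank':>4} {'gene':>9} {'ctrl':>6} {'treat':>6} {'fold':>5}  truly enriched?")
for r in ranked[:5]:
    print(f"{r.rank:>4} {r.gene_name:>9} {r.score_control:>6.2f} "
          f"{r.score_treatment:>6.2f} {r.fold_ratio:>5.2f}  "
          f"{bool(truth.loc[r.gene_name, 'enriched'])}")

enr_folds = [r.fold_ratio for r in ranked if truth.loc[r.gene_name, "enriched"]]
print(f"\nmedian recovered fold over designed-enriched genes: "
      f"{np.median(enr_folds):.3f} (designed: 2.0; per-million depth "
      "normalization pulls it slightly below 2, see docs/methods.md)")
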