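"""Evaluate ranking quality with AUROC, EF@5% and BEDROC(alpha=20).

Builds labeled score rankings at three enrichment levels and prints the three
retrieval metrics for each, showing their behavior between the random
baseline (AUROC 0.5, EF 1) and perfect early recognition (all metrics at
their maxima; EF@5% tops out at 1/0.05 = 20 when every top item is positive).
"""

from pocketmap import bedroc, enrichment_factor, auroc, make_labeled_ranking
from pocketmap.retrieval import RankedList

print(f"{'ranking':<22s} {'AUROC':>7s} {'EF@5%':>7s} {'BEDROC':>7s}")
for label, kind, kwargs in [
    ("random", "random", {}),
    ("graded (mu shift 1.5)", "graded", {"mu_shift": 1.5}),
    ("perfect", "perfect", {}),
]:
    fx = make_labeled_ranking(2000, 100, kind, seed=11, **kwargs)
    ranked = RankedList.from_binary(fx.scores, fx.labels)
    print(f"{label:<22s} {auroc(ranked):7.3f} "
          f"{enrichment_factor(ranked, 0.05):7.2f} {bedroc(ranked, 20.0):7.3f}")
# AUROC measures global separation of positives from negatives; EF and BEDROC
# reward putting positives at the very top of the list (early recognition).
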