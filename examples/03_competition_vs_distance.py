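"""Is loop competition more informative than genomic distance?

Distance and loop competition are correlated (the further apart two sites,
the more competing loops fit between them), so this example disentangles
them with matched sampling: for each positive pair, draw a negative with
the same orientation and anchor occupancies and a matched distance term
(leaving competition free), or vice versa.  Competition separates the
classes where distance cannot.
"""

from loopcomp import SyntheticConfig, generate_labels, generate_sites, score_pairs
from loopcomp.evaluation import auroc, matched_negatives

cfg = SyntheticConfig(seed=2)
sites = generate_sites(cfg)
pairs = generate_labels(sites, cfg)
# score with an exponential distance term so D_ij reflects distance
scoring = cfg.params.replace(lam=300_000.0, decay_kind="exponential")
scored = score_pairs(sites, pairs, scoring)
scored["label"] = pairs["label"]

dm, dropped_d = matched_negatives(scored, "distance", seed=1)
lm, dropped_l = matched_negatives(scored, "loop_competition", seed=1)
print(f"distance-matched set: {len(dm) // 2} positive/negative pairs ({dropped_d} dropped)")
print(f"competition-matched set: {len(lm) // 2} pairs ({dropped_l} dropped)")

print(f"\nfull model AUROC on distance-matched negatives:   "
      f"{auroc(dm['p_ij'], dm['label']):.3f}")
print(f"distance-only AUROC on competition-matched negatives: "
      f"{auroc(lm['D_ij'], lm['label']):.3f}")
print(
    "\nCompetition stays strongly predictive when distance is matched away, "
    "while distance alone is a coin flip once competition is matched: the "
    "apparent distance dependence of looping is a proxy for competition."
)
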