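"""Train the two stringency ladders and score held-out guides.

Two synthetic efficacy tables (standing in for the FACS-depletion and
mutation-rate data sources) are used to train 10-forest ladders with
false-positive penalties 0.2..2.0; a guide's combined score is the highest
rung it passes in BOTH ladders.
"""

from scipy import stats

from croatan import combined_forest_score, label_records, train_ensemble
from croatan.potency import EnsembleConfig
from croatan import simulate as sim

# two independent "data sources" (different seeds emulate different assays)
doench_df, _ = sim.make_efficacy_dataset(sim.EfficacyConfig(rng_seed=3))
chari_df, _ = sim.make_efficacy_dataset(sim.EfficacyConfig(rng_seed=4))

cfg = EnsembleConfig(trees_per_forest=60, rng_seed=17)
doench = train_ensemble(doench_df.iloc[:300], "doench-like", cfg)
chari = train_ensemble(chari_df.iloc[:300], "chari-like", cfg)

held_out = doench_df.iloc[300:].reset_index(drop=True)
potent, weak, _ = label_records(held_out)

for name, sub in (("potent", potent), ("weak", weak)):
    d = doench.score_many(sub["context30"])
    c = chari.score_many(sub["context30"])
    combined = [combined_forest_score(a, b) for a, b in zip(d, c)]
    print(f"{name:6s} held-out guides: n={len(sub)}, "
          f"mean combined score {sum(combined) / len(combined):.2f}")

sp = doench.score_many(potent["context30"])
sw = doench.score_many(weak["context30"])
p = stats.ranksums(sp, sw).pvalue
print(f"rank-sum p (potent vs weak, single ladder): {p:.2e}")
# Higher combined scores mean the guide clears more stringent forests in
# both data sources; the rank-sum test shows held-out potent guides separate.
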