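"""Train the multi-label MLP on a planted synthetic fixture.

The fixture plants a rank-8 structure: pair features are noisy sums of two
drug latent vectors and each side effect fires with probability
sigmoid(<u_a + u_b, v_s> + b_s). A classifier that recovers the latents
scores well above chance on held-out pairs.
"""

import polysides as ps

table, pair_features, _, _ = ps.standard_fixture(seed=7)
targets = table.multihot
print(f"fixture: {len(table)} pairs, {targets.shape[1]} side effects")

config = ps.toy_mlp_config(output_dim=targets.shape[1], seed=7)
split = ps.split_rows(len(table), ps.SplitSpec(seed=7))
model = ps.build_mlp(config, pair_features.shape[1])
model, log = ps.train_mlp(model, pair_features, targets, split, config)
print(f"trained for {len(log)} epochs "
      f"(final val loss {log[-1]['val_loss']:.4f})")

probs = ps.predict_mlp(model, pair_features[split.test])
report = ps.columnwise_report(probs, targets[split.test])
print(f"test macro-AUROC {report.macro['auroc']:.3f}, "
      f"macro-AUPRC {report.macro['auprc']:.3f}")

# macro averages treat every side effect equally; micro pools all
# (pair, side effect) cells, so frequent side effects dominate it.
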