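"""The three threshold-free metrics on a tiny hand-checkable example."""

import polysides as ps

scores = [0.9, 0.8, 0.3, 0.2]
labels = [1, 0, 1, 0]
scored = ps.ScoredLabels(scores, labels)

print(f"AUROC  {ps.auroc(scored):.4f}   "
      "(3 of 4 positive/negative pairs correctly ordered)")
print(f"AUPRC  {ps.auprc(scored):.4f}   "
      "(precision summed over recall increments)")
print(f"AP@50  {ps.ap_at_50(scored):.4f}   "
      "(mean top-k precision, k truncated to n=4 here)")

# per-side-effect reporting with best/worst tables
groups = [
    ps.ScoredLabels([3, 2, 1, 0], [1, 1, 0, 0], group="SE001", group_name="nausea"),
    ps.ScoredLabels([3, 2, 1, 0], [0, 1, 1, 0], group="SE002", group_name="rash"),
]
report = ps.per_side_effect_report(groups)
print(f"\nmacro AUROC {report.macro['auroc']:.3f}, micro {report.micro['auroc']:.3f}")
print(report.per_group[["group", "name", "auroc", "auprc", "n_positives"]])
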