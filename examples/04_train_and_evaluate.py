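"""Train the dual-channel model on planted-signal chains and evaluate it.

A short run (10 chains, 12 epochs) that already recovers most of the
planted interface signal; the packaged defaults train for 50 epochs.
"""

import eqppis as eq

ds = eq.generate_dataset(10, seed=42, residue_range=(30, 50))
print(f"dataset: {len(ds.train)} training / {len(ds.test)} held-out chains, "
      f"positive fraction {ds.positive_fraction:.2f}")

cfg = eq.ModelConfig(seed=42)
params, history = eq.train(ds.train, cfg, eq.TrainConfig(seed=42, epochs=12))
print(f"cross-entropy: epoch 0 {history[0]['train_loss']:.3f} -> "
      f"epoch {len(history)-1} {history[-1]['train_loss']:.3f}")

rep = eq.evaluate(
    eq.predict_scores(ds.test, cfg, params),
    [g.labels for g in ds.test],
    chain_ids=[c.name for c in ds.test_chains],
)
print(f"held-out: ACC {rep.acc:.3f}  Precision {rep.precision:.3f}  "
      f"Recall {rep.recall:.3f}  F1 {rep.f1:.3f}")
print(f"          MCC {rep.mcc:.3f}  AUROC {rep.auroc:.3f}  AUPRC {rep.auprc:.3f}")
print("per-chain confusion counts (chain, TP, TN, FP, FN):")
for row in rep.per_chain:
    print("  ", row)
print()
print("AUROC well above 0.5 on held-out chains shows the network recovered")
print("the geometric interface rule planted by the generator.")
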