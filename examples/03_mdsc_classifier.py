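"""Identify MDSCs in a query cohort by projection onto an annotated reference.

Trains on one simulated patient cohort with known cell types, projects a
second cohort into the frozen PCA space, and reports MDSC precision/recall
against the simulation's ground truth.
"""

from sig2screen import classify, sc, simulate

ref, _ = simulate.gen_scrna(simulate.ScSimConfig(n_patients=10, cells_per_patient=150, seed=5))
query, truth = simulate.gen_scrna(
    simulate.ScSimConfig(n_patients=10, cells_per_patient=150, seed=6)
)
sc.lognormalize(ref)
sc.lognormalize(query)

model = classify.train(ref, n_pcs=30, seed=0)
pred = classify.predict(model, classify.project(model, query))

lab = pred["label"].to_numpy()
true = truth.true_cell_types.to_numpy()
tp = ((lab == "MDSC") & (true == "MDSC")).sum()
print(f"informative PCs per class: { {str(c): len(v) for c, v in model.selected_pcs.items()} }")
print(f"MDSC precision {tp / max((lab == 'MDSC').sum(), 1):.3f}, "
      f"recall {tp / (true == 'MDSC').sum():.3f}, "
      f"unassigned fraction {(lab == classify.UNASSIGNED).mean():.3f}")
# Cells whose best one-vs-rest probability stays below 0.55 are left
# unassigned rather than forced into a type.
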