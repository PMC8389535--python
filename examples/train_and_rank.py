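"""Train the druggability classifier and rank descriptors by SHAP impact.

A labelled synthetic descriptor table (druggable pockets: low psa_r, high
fr_buried_sl_atoms, high hsa) is generated, the boosted model is trained
with early stopping, and descriptors are pruned by mean |SHAP| until the
validation accuracy would degrade.
"""

from pocketdrug import eliminate_descriptors, evaluate, shap_rank, train_model
from pocketdrug.fixtures import make_labeled_table
from pocketdrug.model import confusion_counts

train = make_labeled_table(n=200, effect=1.0, noise_sd=0.1, seed=1)
valid = make_labeled_table(n=100, effect=1.0, noise_sd=0.1, seed=2)

model = train_model(train, valid, seed=7)
metrics = evaluate(confusion_counts(model, valid))
print(f"validation accuracy (12 descriptors): {metrics['accuracy']:.2f}")

print("top descriptors by mean |SHAP|:")
for name, value in shap_rank(model, train)[:5]:
    print(f"  {name:>20s}  {value:.3f}")

final, trace = eliminate_descriptors(train, valid, seed=7)
print(f"after elimination: {len(final.descriptor_subset)} descriptors kept: "
      f"{final.descriptor_subset}")
# The generative descriptors (psa_r, fr_buried_sl_atoms, hsa) should top the
# SHAP ranking and survive elimination; pure-noise columns are dropped first.
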