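# Binary classification case definitions.
# Bonn sets A-D and Delhi preictal/interictal are non-seizure (label 0);
# Bonn set E and Delhi ictal are seizure (label 1).
# `negative_sets` order is the listing order used for deterministic assembly.
case1:  {task: "Healthy vs. Epileptic",   dataset: bonn,  negative_sets: [A],          positive_sets: [E]}
case2:  {task: "Healthy vs. Epileptic",   dataset: bonn,  negative_sets: [B],          positive_sets: [E]}
case3:  {task: "Interictal vs. Ictal",    dataset: bonn,  negative_sets: [C],          positive_sets: [E]}
case4:  {task: "Interictal vs. Ictal",    dataset: bonn,  negative_sets: [D],          positive_sets: [E]}
case5:  {task: "Healthy vs. Epileptic",   dataset: bonn,  negative_sets: [A, B],       positive_sets: [E]}
case6:  {task: "Nonictal vs. Ictal",      dataset: bonn,  negative_sets: [A, C],       positive_sets: [E]}
case7:  {task: "Nonictal vs. Ictal",      dataset: bonn,  negative_sets: [A, D],       positive_sets: [E]}
case8:  {task: "Nonictal vs. Ictal",      dataset: bonn,  negative_sets: [B, C],       positive_sets: [E]}
case9:  {task: "Nonictal vs. Ictal",      dataset: bonn,  negative_sets: [B, D],       positive_sets: [E]}
case10: {task: "Interictal vs. Ictal",    dataset: bonn,  negative_sets: [C, D],       positive_sets: [E]}
case11: {task: "Nonictal vs. Ictal",      dataset: bonn,  negative_sets: [A, B, C],    positive_sets: [E]}
case12: {task: "Nonictal vs. Ictal",      dataset: bonn,  negative_sets: [A, B, D],    positive_sets: [E]}
case13: {task: "Nonictal vs. Ictal",      dataset: bonn,  negative_sets: [A, C, D],    positive_sets: [E]}
case14: {task: "Nonictal vs. Ictal",      dataset: bonn,  negative_sets: [B, C, D],    positive_sets: [E]}
case15: {task: "Interictal vs. Ictal",    dataset: bonn,  negative_sets: [A, B, C, D], positive_sets: [E]}
case16: {task: "Interictal vs. Ictal",    dataset: delhi, negative_sets: [interictal], positive_sets: [ictal]}
case17: {task: "Preictal vs. Ictal",      dataset: delhi, negative_sets: [preictal],   positive_sets: [ictal]}
case18: {task: "Nonictal vs. Ictal",      dataset: delhi, negative_sets: [preictal, interictal], positive_sets: [ictal]}
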