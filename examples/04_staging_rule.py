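"""The fluorosis staging rule, including the small-opaque shortcut.

Applies the rule to the published per-image opaque/brown percentages of
the seven-image training set and shows why the shortcut matters for
shadow-induced brown pixels.
"""

from fluoroseg import classify_fluorosis, classify_fluorosis_ablated

training_set = [
    ("N1", 7.25, 0.00, "Normal"),
    ("N2", 15.07, 0.00, "Normal"),
    ("F1_1", 12.59, 0.00, "Stage 1"),
    ("F1_2", 11.16, 0.00, "Stage 1"),
    ("F2_1", 37.85, 0.00, "Stage 2"),
    ("F2_2", 9.20, 1.19, "Stage 2"),
    ("F3_1", 36.37, 1.67, "Stage 3"),
]

print(f"{'image':6s} {'r_opaque':>8s} {'r_brown':>8s} {'expert':>8s}  predicted")
hits = 0
for name, ro, rb, expert in training_set:
    pred = classify_fluorosis(ro / 100, rb / 100)
    hits += pred == expert
    print(f"{name:6s} {ro:7.2f}% {rb:7.2f}% {expert:>8s}  {pred}")
print(f"expert agreement: {hits}/7 = {100 * hits / 7:.2f}%")

ro, rb = 0.0163, 0.0135  # healthy tooth; shadow behind the lower lip
print(f"\nshadow case (r_opaque {100*ro:.2f}%, r_brown {100*rb:.2f}%):")
print(f"  with the small-opaque shortcut:    {classify_fluorosis(ro, rb)}")
print(f"  without it (prior-work rule):      {classify_fluorosis_ablated(ro, rb)}")
print("A brown area only indicates severe fluorosis when a fair amount of")
print("opaque enamel is present too; the shortcut encodes exactly that.")
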