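"""Train -> segment -> stage, end to end on synthetic mouth images.

Optimizes the cluster count with cuckoo search at desk scale, segments the
12-image synthetic fixture suite, and compares recovered stages and
opaque/brown ratios against the generator's ground truth.
"""

from fluoroseg import (CSConfig, classify_fluorosis, make_fixture_suite,
                       run_cuckoo_search, sample_labeled_pixels, segment_image)

X, y = sample_labeled_pixels((400, 400, 200, 100, 180), seed=1)
Xv, yv = sample_labeled_pixels((400, 400, 200, 100, 180), seed=2)

cfg = CSConfig(n_nests=10, bounds=(20, 120), t_max=3, seed=1)
print("cuckoo search over cluster counts in [20, 120] (10 nests, 3 generations)...")
search = run_cuckoo_search(X, y, cfg, val_data=(Xv, yv))
print(f"selected {search.best_eta} clusters, validation accuracy "
      f"{100 * search.accuracy:.2f}%, fitness {search.best_fitness:.2e}")

images, manifest = make_fixture_suite(seed=3)
print(f"\n{'true stage':>10s} {'r_op true':>9s} {'r_op est':>9s} "
      f"{'r_br true':>9s} {'r_br est':>9s}  predicted")
correct = 0
for mouth in images:
    seg = segment_image(mouth.image, search.prototypes)
    stage = classify_fluorosis(seg.r_opaque, seg.r_brown)
    correct += stage == mouth.stage
    print(f"{mouth.stage:>10s} {mouth.r_opaque:9.4f} {seg.r_opaque:9.4f} "
          f"{mouth.r_brown:9.4f} {seg.r_brown:9.4f}  {stage}")
print(f"\nstage recovery: {correct}/12; ratios are fractions of the tooth "
      "area occupied by opaque patches and brown stains.")
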