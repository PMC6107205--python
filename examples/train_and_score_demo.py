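"""End-to-end demo: synthetic tiles -> small CNN -> slide scores and a map.

Generates a labelled fibrosis tile tree, trains the desk-scale CNN, then
scores three virtual slides of increasing fibrotic burden and renders a
score map. Compare the CNN slide means with the ground-truth means.
"""

import tempfile
from pathlib import Path

import numpy as np

from histoscore import ASHCROFT, score_tile_grid, slide_score
from histoscore.classifier import TrainConfig, build_model, train
from histoscore.dataset import load_labelled_folders, split_train_val
from histoscore.scoring import render_score_map
from histoscore.synthetic import generate_labelled_folders, generate_virtual_slide
from histoscore.tiling import SlideImage, slice_tiles

TILE_PX = 96

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp) / "tiles"
    generate_labelled_folders(root, "fibrosis", 40, seed=7, tile_px=TILE_PX)
    ds = split_train_val(load_labelled_folders(root, ASHCROFT.all_labels), 0.1, seed=7)
    model = build_model("small_cnn", ASHCROFT.all_labels, seed=7, input_px=32,
                        scheme_name="ashcroft")
    model, curve = train(model, ds, TrainConfig.desk_scale(max_epochs=25, seed=7))
    print(f"trained {len(curve)} epochs; "
          f"final validation accuracy {curve.val_accuracy[-1]:.3f}")

    fields = {
        "healthy": np.full((3, 3), "0", dtype=object),
        "moderate": np.array([["1", "3", "1"], ["3", "3", "1"], ["1", "3", "3"]],
                             dtype=object),
        "severe": np.array([["7", "5", "7"], ["5", "7", "7"], ["7", "7", "5"]],
                           dtype=object),
    }
    for name, field in fields.items():
        slide, truth = generate_virtual_slide(3, 3, field, seed=11, tile_px=TILE_PX)
        smap = score_tile_grid(model, slice_tiles(SlideImage(slide), TILE_PX), ASHCROFT)
        sc = slide_score(smap)
        truth_mean = np.mean([ASHCROFT.weight_of(l) for l in truth.ravel()])
        print(f"{name:8s}: CNN slide score {sc.mean:.3f} "
              f"(ground truth {truth_mean:.3f}, {sc.n_ignored} tiles ignored)")
        if name == "severe":
            render_score_map(smap, "severe_score_map.png")
            print("wrote severe_score_map.png")
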