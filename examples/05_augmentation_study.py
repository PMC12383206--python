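"""Compare augmentation regimes for the downstream U-Net segmenter.

Runs the comparison harness over the classic regimes (none, affine, elastic,
intensity, CutMix) on a phantom dataset and prints the Dice/IoU table.  The
diffusion regime needs trained stage-1/2 checkpoints (see examples 03-04 or
the CLI); here we demonstrate the harness with the classic regimes only.
"""

from cardiacdiff.phantoms import PhantomSpec, generate_dataset
from cardiacdiff.segmentation import (ExperimentConfig, metrics_table,
                                      run_experiment, toy_seg_config)

ds = generate_dataset(60, PhantomSpec(grid_size=32), seed=3)
cfg = ExperimentConfig(regimes=("none", "affine", "elastic", "intensity", "cutmix"),
                       seg_cfg=toy_seg_config(epochs=10), seed=0)
results = run_experiment(ds, cfg)
print(metrics_table(results))
print("rows are one segmenter each, trained with equal budgets on the same")
print("real data plus regime-specific augmented pairs, scored on a shared")
print("held-out test split (higher Dice/IoU is better)")
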