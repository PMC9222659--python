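# medfuse

Saliency-weighted fusion of co-registered CT/MRI image pairs.

CT resolves dense structure (bone, implants) but little soft-tissue detail;
MRI does the opposite.  `medfuse` combines one registered pair into a single
image that keeps both: a **siamese encoder** (multi-scale dense convolution
block + parallel channel/spatial attention) extracts feature stacks
`F_CT = f_En(I_CT)`, `F_MRI = f_En(I_MRI)` with shared weights; a
**visual-saliency fusion rule** computes a per-pixel weight map `w1` from
the CT features (channel l1 activity → min–max normalisation → histogram
saliency `f(v) = Σ_m M(m)·|v − m|` → min–max normalisation) and blends

```
F_fused = γ·w1·F_CT + (1−γ)·w1·F_MRI + (1−w1)·F_MRI
```

so dense structure is a γ-mix of both modalities and everything else comes
from MRI; a five-layer **decoder** reconstructs the fused image
`I_F = f_De(F_fused)`.  Training removes the fusion stage and fits the
encoder–decoder as an autoencoder with the mixed loss

```
L = (1/WH) · ( μ·‖I_F − I_in‖₂² + φ·‖∇I_F − ∇I_in‖₂² ),   ∇ = Sobel
```

The package also ships the six standard fusion-quality metrics (CC, MI, SF,
PC, NCIE, SCD), element-wise baselines (avg/max/sum/l1-norm), and a seeded
CT/MRI **phantom generator** so everything is testable without any image
download.  The network runs on an in-package numpy autodiff core — no deep
learning framework is required — and all runs are bit-reproducible on CPU
for a fixed seed.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
import numpy as np
from medfuse import (FusionParams, NetConfig, PhantomSpec, TrainConfig,
                     evaluate_dataset, fuse_images, make_dataset, train)

ds = make_dataset(12, PhantomSpec(size=64), seed=0)
images = [im for i in ds.train_idx for im in (ds.pairs[i].ct, ds.pairs[i].mri)]
weights, history = train(images, TrainConfig(epochs=25, batch_size=8, seed=0),
                         NetConfig.small())
print(f"loss {history[0].total:.3f} -> {history[-1].total:.3f}")

pair = ds.pairs[ds.test_idx[0]]
fused = fuse_images(pair, weights, FusionParams(strategy="vsm", gamma=0.5))
report = evaluate_dataset([(fused, pair.ct, pair.mri)])
print(f"CC={report.cc:.3f} MI={report.mi:.3f} SF={report.sf:.3f} "
      f"PC={report.pc:.3f} NCIE={report.ncie:.3f} SCD={report.scd:.3f}")
```

prints (seeds fixed, CPU):

```
loss 1.190 -> 0.323
CC=0.547 MI=2.929 SF=0.080 PC=0.017 NCIE=0.850 SCD=0.270
```

The loss line shows the autoencoder descending; the metrics line scores the
fused phantom against its sources — CC/MI/NCIE/SCD measure how much of both
sources the fused image retains, SF its texture richness (on the [0,1]
intensity scale), PC the preservation of phase-congruent features (near
zero here: 25 epochs on twelve pairs is a quick demo, not a converged
model — the reference CPU study below trains longer on more pairs).

The same operations are available from the shell:

```
medfuse make-phantoms --n 20 --size 64 --seed 0 --out data/
medfuse train --config cfg.yaml --data data/ --out run/
medfuse fuse --ct data/pair_0000_ct.png --mri data/pair_0000_mri.png \
             --weights run/weights.npz --out fused.png
medfuse evaluate --fused fused/ --ct data/ --mri data/ --out report.csv
```

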