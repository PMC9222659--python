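"""Canonical experiment profiles.

``CPU_STUDY`` is the package's reference CPU experiment: the phantom dataset
size, image size and optimisation settings used by the test suite and by
``scripts/acceptance.py``.  It keeps the published optimisation settings
(batch 16, Adam at 1e-4, pixel+gradient loss at equal weight) and scales the
data volume and encoder width down to something a single CPU core finishes
in minutes; ``FULL_STUDY`` records the full-scale settings for completeness
(thousands of augmented pairs, 1000 epochs, 240-channel encoder) but is not
exercised by the tests.
"""

from __future__ import annotations

from .network import NetConfig
from .training import TrainConfig

__all__ = ["CPU_STUDY", "FULL_STUDY"]

CPU_STUDY = {
    "n_pairs": 100,
    "image_size": 64,
    "net_config": NetConfig.small,
    "train_config": lambda seed: TrainConfig(
        mu=1.0, phi=1.0, lr=1e-4, batch_size=16, epochs=50, seed=seed
    ),
    "psnr_threshold_db": 30.0,
    "min_eval_pairs": 20,
}

FULL_STUDY = {
    "n_pairs": 4000,
    "image_size": 256,
    "net_config": NetConfig,
    "train_config": lambda seed: TrainConfig(
        mu=1.0, phi=1.0, lr=1e-4, batch_size=16, epochs=1000, seed=seed
    ),
}
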