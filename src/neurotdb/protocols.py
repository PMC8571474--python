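"""Reference desk-scale experiment protocol.

One CPU-budget configuration used by the acceptance checks and reports:
8 synthetic neurons (~200 blocks), a narrow-width image branch with the
reference stage layout, reduced epochs, and a high-persistence difficulty
process so sequence context is informative.
"""

from __future__ import annotations

from .ssm import TrainConfig
from .synth import SynthConfig

__all__ = ["desk_scale_synth_config", "desk_scale_train_config"]


def desk_scale_synth_config(seed: int = 0) -> SynthConfig:
    return SynthConfig(
        seed=seed,
        n_neurons=8,
        nodes_per_neuron=2500,
        label_persistence=0.9,
    )


def desk_scale_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(
        base_channels=8,
        epochs_sfe=6,
        epochs_sie=40,
        epochs_mf_warmup=30,
        epochs_joint=3,
        sequence_length=3,
        augment=False,  # the ×3 rotation rule is verified separately
        seed=seed,
    )
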