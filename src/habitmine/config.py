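"""Pipeline configuration: one YAML-serialisable object drives every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .mining import MiningConfig


@dataclass
class PipelineConfig:
    """End-to-end settings: simulate -> preprocess -> train -> classify ->
    mine -> filter -> evaluate.

    Defaults reproduce the default synthetic scenario at desk scale: the
    depth-scaled U-Net with embedding at SEW 25 trains in a couple of
    minutes on one CPU. Set ``depth_scale: 1.0`` for the full-size network.
    """

    seed: int = 7
    n_days: int = 60

    # preprocessing
    window_size: int = 25
    step: int = 1
    label_mode: str = "last"
    numeric_bin_width: float = 5.0
    include_other: bool = True      # keep "Other" windows in training

    # model
    model: str = "unet"             # unet | fcn | lstm
    embedding: bool = True
    depth_scale: float = 0.125

    # training
    train_frac: float = 0.70
    folds: int = 3
    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 25
    patience: int = 5
    max_windows: int = 3000         # stratified subsample cap (0 = no cap)

    # rule mining
    use_true_labels: bool = False
    mining: MiningConfig = field(default_factory=MiningConfig)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        mining = payload.pop("mining", None)
        cfg = cls(**payload)
        if mining is not None:
            cfg.mining = MiningConfig(**mining)
        return cfg
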