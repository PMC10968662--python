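"""Run configuration: every tunable of the pipeline in one dataclass.

Defaults follow the training recipe the method was developed with
(Adam, learning rate 0.001, weight decay 0.005, dropout 0.1, 3000 epochs,
75/25 train/test split) and conventional choices where the recipe is
silent (STRING combined-score threshold 700, node2vec reference walk
parameters, a 2-layer GCN of width 64 with a 2-iteration CRF block).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class Node2vecConfig:
    """Hyperparameters of the biased random-walk embedding."""

    dim: int = 20
    walk_length: int = 80
    walks_per_node: int = 10
    window: int = 5
    return_p: float = 1.0
    inout_q: float = 1.0
    negative_samples: int = 5
    epochs: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.dim < 1:
            raise ValueError(f"node2vec dim must be >= 1, got {self.dim}")
        if self.return_p <= 0 or self.inout_q <= 0:
            raise ValueError("node2vec return_p and inout_q must be > 0")
        if self.walk_length < 2 or self.walks_per_node < 1:
            raise ValueError("walks must have length >= 2 and count >= 1")


@dataclass
class RunConfig:
    """Full pipeline configuration."""

    # network construction
    string_score_threshold: float = 700.0
    deg_alpha: float = 0.05
    deg_lfc: float = 2.0
    # structural embedding
    node2vec: Node2vecConfig = field(default_factory=Node2vecConfig)
    # model
    hidden_dim: int = 64
    crf_alpha: float = 1.0
    crf_beta: float = 1.0
    crf_iterations: int = 2
    positive_weight: float = 1.0
    learning_rate: float = 0.001
    weight_decay: float = 0.005
    dropout: float = 0.1
    epochs: int = 3000
    # evaluation protocol
    test_fraction: float = 0.25
    cv_folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        for name in ("learning_rate", "dropout", "test_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.positive_weight < 1:
            raise ValueError("positive_weight must be >= 1")
        if self.crf_alpha < 0 or self.crf_beta < 0:
            raise ValueError("crf_alpha and crf_beta must be >= 0")
        self.node2vec.validate()

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        n2v = d.pop("node2vec", {}) or {}
        cfg = cls(node2vec=Node2vecConfig(**n2v), **d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def override(self, **kwargs) -> "RunConfig":
        """Return a copy with non-None keyword overrides applied."""
        d = self.to_dict()
        n2v = d.pop("node2vec")
        for k, v in kwargs.items():
            if v is None:
                continue
            if k.startswith("node2vec_"):
                n2v[k[len("node2vec_"):]] = v
            else:
                d[k] = v
        return self.from_dict({**d, "node2vec": n2v})
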