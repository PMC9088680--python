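"""Run configuration: a validated YAML schema for the two pipelines."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .encoders import WINDOW_ENCODERS


class EmbeddingSettings(BaseModel):
    window: int = 5
    epochs: int = 10
    negatives: int = 5
    min_count: int = 1

    def kwargs(self) -> dict:
        return self.model_dump()


class GoKnnSettings(BaseModel):
    neighbor_counts: list[int] = [2, 4, 8, 16, 32, 64, 128, 256, 512, 1024]


class BalanceSettings(BaseModel):
    strategy: Literal["rus", "smote", "rus_then_smote", "none"] = "rus_then_smote"
    target_ratio: float = 1.0
    rus_ratio: float = 0.5
    smote_neighbors: int = 5


class ClassifierSettings(BaseModel):
    name: Literal["rf", "svm", "knn", "xgb", "stacking"] = "stacking"
    hyperparameters: dict = Field(default_factory=dict)


class RunConfig(BaseModel):
    """Everything a pipeline run needs; seeds included, so runs replay exactly."""

    task: Literal["protein", "site"]
    encoders: list[str] = ["tpc", "aai", "onehot", "pseaac", "cksaap"]
    delta: int = 28
    embedding: EmbeddingSettings = Field(default_factory=EmbeddingSettings)
    go_knn: GoKnnSettings = Field(default_factory=GoKnnSettings)
    selection_k: Optional[int] = 600
    balance: Optional[BalanceSettings] = None
    classifier: Optional[ClassifierSettings] = None
    folds: int = 10
    seed: int = 0

    @field_validator("encoders")
    @classmethod
    def _known_encoders(cls, v):
        unknown = set(v) - set(WINDOW_ENCODERS)
        if unknown:
            raise ValueError(f"unknown encoders {sorted(unknown)}; known: {sorted(WINDOW_ENCODERS)}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def default_classifier_name(self) -> str:
        # pipeline defaults mirror the best-performing engines per task:
        # boosting for proteins, the stacking ensemble for sites
        if self.classifier is not None:
            return self.classifier.name
        return "xgb" if self.task == "protein" else "stacking"
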