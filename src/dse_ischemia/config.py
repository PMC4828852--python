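"""Study-level configuration.

A :class:`StudyConfig` bundles the two cohort configurations (construction
and held-out validation) with every analysis choice that is a genuine
degree of freedom: the screening significance level, the optimal-threshold
criterion, the stepwise selection criterion, the CI method, the decision
threshold and the strict-fidelity rescaling flag.  All randomness flows
from the single ``seed``: the two cohort seeds are derived from it
deterministically, so equal configurations produce byte-identical runs.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .synthetic import CohortConfig

__all__ = ["StudyConfig"]


class StudyConfig(BaseModel):
    """Complete, validated configuration for one study run."""

    seed: int = Field(default=0, ge=0)
    train: CohortConfig = Field(default_factory=CohortConfig)
    validation: CohortConfig = Field(
        default_factory=lambda: CohortConfig.validation_default()
    )
    alpha: float = Field(default=0.05, ge=0.0, le=1.0)
    threshold_criterion: Literal["youden", "accuracy"] = "youden"
    stepwise_criterion: Literal["aic", "pvalue"] = "aic"
    ci_method: Literal["wilson", "clopper-pearson"] = "wilson"
    decision_threshold: float = Field(default=0.5, gt=0.0, le=1.0)
    decision_threshold_mode: Literal["fixed", "youden_train"] = "fixed"
    strict_linear_branch: bool = False

    @model_validator(mode="after")
    def _derive_cohort_seeds(self) -> "StudyConfig":
        """Cohort seeds derive from the global seed unless set explicitly.

        Two independent 31-bit streams are spawned so the train and
        validation cohorts never share randomness.
        """
        if "train" not in self.model_fields_set or "seed" in self.model_fields_set:
            ss = np.random.SeedSequence(self.seed)
            s_train, s_valid = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
            object.__setattr__(self.train, "seed", s_train)
            object.__setattr__(self.validation, "seed", s_valid)
        return self

    def config_hash(self) -> str:
        """Short stable hash of the full configuration, for provenance."""
        import hashlib
        import json

        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)
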