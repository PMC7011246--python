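"""Pydantic models for the pipeline's JSON outputs.

The exported JSON-schema documents under ``radiotex/schemas/`` are generated
from these models; :func:`validate_json` is the single validation entry point
used by the pipeline and the tests.
"""

from __future__ import annotations

from pydantic import BaseModel


class ReductionReportModel(BaseModel):
    kept: list[str]
    dropped: list[dict]
    threshold: float


class SelectionLevelModel(BaseModel):
    k: int
    best_subset: list[str] | None
    loo_accuracy: float | None
    n_subsets_evaluated: int


class SelectionTraceModel(BaseModel):
    levels: list[SelectionLevelModel]
    stopped_at: int
    selected: list[str]
    selected_accuracy: float


class KMCurveModel(BaseModel):
    time: list[float]
    survival_prob: list[float]


class KMModel(BaseModel):
    curves: dict[str, KMCurveModel]
    logrank_chi2: float | None
    logrank_p: float | None


class RunManifestModel(BaseModel):
    config_hash: str
    seed: int
    n_subjects: int
    n_features: int
    library_versions: dict[str, str]
    wall_clock_seconds: float
    schema_version: str = "1"


MODELS = {
    "reduction": ReductionReportModel,
    "trace": SelectionTraceModel,
    "km": KMModel,
    "run_manifest": RunManifestModel,
}


def validate_json(kind: str, payload: dict) -> None:
    """Raise pydantic.ValidationError if ``payload`` violates the schema."""
    MODELS[kind].model_validate(payload)
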