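"""Pipeline configuration: every tunable constant in one validated object.

The defaults are the published weighting scheme — changing a weight for a
sensitivity experiment needs only a YAML file, never a code change.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "GeneScoreWeights",
    "ExpertScoreWeights",
    "CampaignPolicy",
    "PipelineConfig",
    "load_config",
]


class GeneScoreWeights(BaseModel):
    """Weights of the pilot-cycle gene prioritization score.

    totalScore = GO score + evidence score + page_views / page_view_divisor
                 + n_publications + ortholog_weight·[ortholog]
                 + omim_weight·[ortholog in OMIM]
    """

    page_view_divisor: float = Field(10.0, gt=0)
    ortholog_weight: float = Field(20.0, ge=0)
    omim_weight: float = Field(50.0, ge=0)
    root_term_points: float = Field(0.5, ge=0)
    term_points: float = Field(1.0, ge=0)
    bp_points: float = Field(200.0, ge=0)
    mf_points: float = Field(100.0, ge=0)
    cc_points: float = Field(50.0, ge=0)


class ExpertScoreWeights(BaseModel):
    """Weights of the author expert score.

    score = (recent / recent_divisor + mutagen / mutagen_divisor)
            × (g500 / g500_divisor + classical_weight·clasAl
               + expgo_weight·expGO + expab_weight·expAB + source_weight·src)
    """

    recent_divisor: float = Field(10.0, gt=0)
    mutagen_divisor: float = Field(5.0, gt=0)
    g500_divisor: float = Field(5.0, gt=0)
    classical_weight: float = Field(3.0, ge=0)
    expgo_weight: float = Field(10.0, ge=0)
    expab_weight: float = Field(10.0, ge=0)
    source_weight: float = Field(10.0, ge=0)
    recent_window_years: int = Field(10, ge=1)
    high_throughput_gene_count: int = Field(500, ge=1)


class CampaignPolicy(BaseModel):
    """Reminder/escalation policy and batching constants."""

    max_reminders: int = Field(2, ge=1, le=2)
    escalate_after_exhaustion: bool = True
    individual_batch_limit: int = Field(5, ge=1)  # ≤5 genes → individual mails
    individual_deadline_days: int = Field(7, ge=1)
    spreadsheet_deadline_days: int = Field(28, ge=1)


class PipelineConfig(BaseModel):
    gene_score: GeneScoreWeights = GeneScoreWeights()
    expert_score: ExpertScoreWeights = ExpertScoreWeights()
    policy: CampaignPolicy = CampaignPolicy()
    email_recency_years: int = Field(5, ge=1)
    reference_year: int = Field(2016, gt=1900)
    load_cap: int | None = Field(None, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        return self


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file; ``None`` gives the defaults."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return PipelineConfig.model_validate(data)
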