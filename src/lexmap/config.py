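"""Pipeline configuration.

Collects the knobs of the harmonization cascade: the candidate count K, the
blend weights W1 (match-classifier probability) and W2 (normalized
Levenshtein similarity), the elimination threshold applied to the raw class
probability, the prior-knowledge flag, and the embedding dimension.
"""

from __future__ import annotations

from pydantic import BaseModel, Field


class HarmonizationConfig(BaseModel):
    """Configuration of the retrieve-and-rerank harmonization cascade.

    Defaults follow common practice for this pipeline: K=5 candidates is a
    sufficient standard, candidates with match probability below 0.5 are
    eliminated, and the classifier alone decides (W1=1, W2=0). W1 and W2
    are independent weights in [0, 1]; they are not constrained to sum to 1.
    """

    K: int = Field(default=5, ge=1)
    W1: float = Field(default=1.0, ge=0.0, le=1.0)
    W2: float = Field(default=0.0, ge=0.0, le=1.0)
    threshold: float = Field(default=0.5, ge=0.0, le=1.0)
    use_prior_knowledge: bool = False
    seed: int = 0
    embedding_dim: int = Field(default=768, ge=1)

    model_config = {"frozen": True}
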