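"""End-to-end orchestration: tracks + counts -> target classification.

Thin glue over the stage modules, used by the CLI and by whole-pipeline
parameter-recovery checks: score binding from coverage, run the three
condition-vs-control contrasts, and classify targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import binding, diffexpr
from .genome_model import CountMatrix, CoverageTrack, GeneModel
from .synthetic_data import SimStudy
from .target_classifier import TargetClassification, classify_targets, signed_calls

__all__ = ["PipelineResult", "run_pipeline", "run_study_pipeline"]

CONTRASTS = {"wt": "dsBRM_WT", "mut": "dsBRM_K804R", "depl": "dsBRM"}


@dataclass
class PipelineResult:
    binding: pd.DataFrame
    de: dict[str, pd.DataFrame]  # keys: wt, mut, depl
    classification: TargetClassification


def run_pipeline(
    ip: CoverageTrack,
    input_: CoverageTrack,
    genes: list[GeneModel],
    counts: CountMatrix,
    flank: int = 200,
    pseudocount: float = 0.5,
    bound_threshold: float = binding.BOUND_THRESHOLD,
    q_threshold: float = 0.05,
) -> PipelineResult:
    bind = binding.score_genes(
        ip, input_, genes, flank=flank, pseudocount=pseudocount, threshold=bound_threshold
    )
    de = {
        key: diffexpr.run_contrast(counts, cond, q_threshold=q_threshold)
        for key, cond in CONTRASTS.items()
    }
    classification = classify_targets(
        bound=bind["bound"],
        de_wt=signed_calls(de["wt"]),
        de_mut=signed_calls(de["mut"]),
        de_depl=signed_calls(de["depl"]),
    )
    return PipelineResult(binding=bind, de=de, classification=classification)


def run_study_pipeline(study: SimStudy, **kwargs) -> PipelineResult:
    """Run the full pipeline on an in-memory synthetic study."""
    return run_pipeline(study.ip, study.input_, study.genes, study.counts, **kwargs)
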