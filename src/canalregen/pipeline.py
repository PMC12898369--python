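"""End-to-end orchestration: volume + geometry in, verdicts + report out."""

from __future__ import annotations

from dataclasses import dataclass

from .criteria import ScoringParams, SectionVerdict, score_sections
from .geometry import DefectInterval, defect_interval, resample_sections
from .phantom import PhantomSpec, PhantomTruth, build_phantom
from .quantify import RegenerationReport, regeneration_report
from .volume_io import Centerline, LandmarkPair, Volume

__all__ = ["CaseResult", "score_case", "analyze_phantom"]


@dataclass
class CaseResult:
    """Everything the pipeline computes for one case."""

    verdicts: list[SectionVerdict]
    interval: DefectInterval
    report: RegenerationReport


def score_case(
    volume: Volume,
    centerline: Centerline,
    landmarks: LandmarkPair,
    params: ScoringParams | None = None,
    step_mm: float = 0.3,
    patch_mm: float = 10.8,
    in_plane_mm: float = 0.3,
) -> CaseResult:
    """Run the full single-case analysis.

    Resamples perpendicular sections along the centerline, scores the four
    criteria per section at both density thresholds, locates the defect
    interval from the implant apices and computes the regeneration report.
    """
    p = params or ScoringParams()
    sections = resample_sections(volume, centerline, step_mm, patch_mm, in_plane_mm)
    verdicts = score_sections(sections, p)
    di = defect_interval(centerline, landmarks)
    report = regeneration_report(verdicts, di, p)
    return CaseResult(verdicts=verdicts, interval=di, report=report)


def analyze_phantom(
    spec: PhantomSpec,
    params: ScoringParams | None = None,
    step_mm: float = 0.3,
    patch_mm: float = 10.8,
    in_plane_mm: float = 0.3,
) -> tuple[CaseResult, PhantomTruth]:
    """Render a phantom and push it through the full pipeline."""
    volume, truth = build_phantom(spec)
    result = score_case(
        volume, truth.centerline, truth.landmarks, params, step_mm, patch_mm, in_plane_mm
    )
    return result, truth
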