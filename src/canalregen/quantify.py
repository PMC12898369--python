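"""Regeneration percentage per case and cohort-level summaries.

The per-case statistic is

    Regeneration (%) = length of regenerated canal / defined defect length x 100

where the defect length is the straight-line distance between the mesial apex
of the mesial implant and the distal apex of the distal implant, and the
regenerated length is the total extent of section runs passing all four
criteria inside the defect interval. Because the defect length is a chord
while the regenerated length follows the (possibly curved) canal axis, the
ratio can exceed 100% on curved axes; it is clipped at 100 with a provenance
flag.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .criteria import ScoringParams, SectionVerdict, find_runs, _infer_step
from .errors import InputError
from .geometry import DefectInterval

__all__ = [
    "RegenerationReport",
    "CohortSummary",
    "regeneration_percentage",
    "regeneration_report",
    "summarize_cohort",
]


def regeneration_percentage(regen_length_mm: float, defect_length_mm: float) -> tuple[float, bool]:
    """Apply the regeneration formula; clip at 100% and flag the clip."""
    if defect_length_mm <= 0:
        raise InputError("defect length must be positive")
    pct = 100.0 * regen_length_mm / defect_length_mm
    if pct > 100.0 + 1e-9:
        return 100.0, True
    return min(pct, 100.0), False


@dataclass
class RegenerationReport:
    """Per-case regeneration outcome at both density thresholds."""

    defect_length: float
    regen_length_800: float
    regen_length_400: float
    regen_pct_800: float
    regen_pct_400: float
    runs_800: list[tuple[float, float]]
    runs_400: list[tuple[float, float]]
    clipped: bool
    params: ScoringParams

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = self.params.to_dict()
        d["runs_800"] = [list(r) for r in self.runs_800]
        d["runs_400"] = [list(r) for r in self.runs_400]
        return d


def _run_measure(
    verdicts: list[SectionVerdict],
    runs: list[tuple[float, float]],
    threshold_kind: str,
    di: DefectInterval,
    step: float,
) -> float:
    """Length of the union of passing-station cells, truncated at the interval.

    Each passing station represents the cell [s - step/2, s + step/2]; runs
    crossing the defect boundary are truncated there, and gap stations inside
    a run contribute nothing, so tolerated gaps never inflate length.
    """
    total = 0.0
    for s_lo, s_hi in runs:
        for v in verdicts:
            if s_lo - 1e-9 <= v.station_s <= s_hi + 1e-9:
                passing = v.pass_mature if threshold_kind == "mature" else v.pass_early
                if not passing:
                    continue
                cell_lo = max(v.station_s - step / 2.0, di.s_start)
                cell_hi = min(v.station_s + step / 2.0, di.s_end)
                total += max(cell_hi - cell_lo, 0.0)
    return total


def regeneration_report(
    verdicts: list[SectionVerdict],
    di: DefectInterval,
    p: ScoringParams,
) -> RegenerationReport:
    """Quantify regeneration inside the defect interval at both thresholds.

    Only sections whose station lies inside [s_start, s_end] contribute; runs
    are recomputed on that restriction so continuity cannot leak across the
    implant apices.
    """
    sel = [v for v in verdicts if di.s_start - 1e-9 <= v.station_s <= di.s_end + 1e-9]
    if len(sel) < 2:
        raise InputError(
            f"defect interval [{di.s_start:.2f}, {di.s_end:.2f}] mm contains "
            f"{len(sel)} stations; need at least 2"
        )
    step = _infer_step(np.array([v.station_s for v in sel]))

    lengths = {}
    runs = {}
    for kind, key in (("mature", "800"), ("early", "400")):
        r = find_runs(sel, kind, p)
        runs[key] = r
        lengths[key] = _run_measure(sel, r, kind, di, step)

    pct800, clip800 = regeneration_percentage(lengths["800"], di.defect_length)
    pct400, clip400 = regeneration_percentage(lengths["400"], di.defect_length)
    return RegenerationReport(
        defect_length=di.defect_length,
        regen_length_800=lengths["800"],
        regen_length_400=lengths["400"],
        regen_pct_800=pct800,
        regen_pct_400=pct400,
        runs_800=runs["800"],
        runs_400=runs["400"],
        clipped=clip800 or clip400,
        params=p,
    )


@dataclass
class CohortSummary:
    """Descriptive cohort statistics at both thresholds (mean +/- SD)."""

    n: int
    mean_800: float
    mean_400: float
    sd_800: float | None
    sd_400: float | None
    shapiro_p_800: float | None
    shapiro_p_400: float | None
    count_above_70_800: int
    count_below_50_800: int
    count_below_40_800: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_text(self) -> str:
        def pm(mean: float, sd: float | None) -> str:
            return f"{mean:.1f}%" if sd is None else f"{mean:.1f}% ± {sd:.1f}%"

        lines = [
            f"n = {self.n} cases",
            f">800 HU (mature bone):   {pm(self.mean_800, self.sd_800)}",
            f">400 HU (early bone):    {pm(self.mean_400, self.sd_400)}",
            f"cases above 70% (>800 HU): {self.count_above_70_800}",
            f"cases below 50% (>800 HU): {self.count_below_50_800}",
            f"cases below 40% (>800 HU): {self.count_below_40_800}",
        ]
        if self.shapiro_p_800 is not None:
            lines.append(
                f"Shapiro-Wilk p: {self.shapiro_p_800:.3f} (>800 HU), "
                f"{self.shapiro_p_400:.3f} (>400 HU)"
            )
        return "\n".join(lines)


def _shapiro_p(x: np.ndarray) -> float | None:
    if len(x) < 3 or np.ptp(x) == 0:
        return None
    return float(stats.shapiro(x).pvalue)


def summarize_cohort(reports: list[RegenerationReport]) -> CohortSummary:
    """Mean, SD (n-1), normality p-values and clinically-reported counts.

    With a single case only the means are defined; SD and Shapiro-Wilk p are
    None. Counts use the >800 HU percentages (cases above 70%, below 50% and
    below 40%).
    """
    if not reports:
        raise InputError("no reports to summarize")
    p800 = np.array([r.regen_pct_800 for r in reports])
    p400 = np.array([r.regen_pct_400 for r in reports])
    n = len(reports)
    return CohortSummary(
        n=n,
        mean_800=float(p800.mean()),
        mean_400=float(p400.mean()),
        sd_800=float(p800.std(ddof=1)) if n >= 2 else None,
        sd_400=float(p400.std(ddof=1)) if n >= 2 else None,
        shapiro_p_800=_shapiro_p(p800),
        shapiro_p_400=_shapiro_p(p400),
        count_above_70_800=int((p800 > 70).sum()),
        count_below_50_800=int((p800 < 50).sum()),
        count_below_40_800=int((p800 < 40).sum()),
    )
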