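"""Cell-cycle phase durations from partially observed live-imaging tracks.

The estimator treats an asynchronous population observed through a short
window as a renewal process: each cell in a phase was captured at an
arbitrary time within that phase, so the average phase duration equals the
total time all observed cells spent in the phase divided by the number of
observed transitions out of it. Censored dwell intervals (window end,
dropout) contribute time but no exit; cells entering the phase during the
window contribute both. Omitting entering cells biases the estimate low,
because a cell caught mid-phase reveals only its residual dwell per exit.

S-phase cannot be followed directly (most S-phase cells show neither
reporter), so its duration is inferred from the fixed-sample S fraction
``fS``: S = (G1 + G2 + M) * fS / (1 - fS).

Transitions between phases are placed at the midpoint between the bounding
frames, which is unbiased when the true transition time is uniform within
the frame gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    InvalidParameterError,
    NoTransitionsError,
)
from .track_io import CellTrack

logger = logging.getLogger(__name__)

#: Cyclic phase order; the only legal transitions are successor steps
#: (M -> G1 closes the cycle at division).
_NEXT_PHASE = {"G1": "S", "S": "G2", "G2": "M", "M": "G1"}


@dataclass(frozen=True)
class PhaseInterval:
    """One contiguous stay of a cell in a phase, midpoint-bounded.

    ``entry_observed``/``exit_observed`` are False when the corresponding
    boundary is censored by the start or end of the track.
    """

    phase: str
    start_min: float
    end_min: float
    entry_observed: bool
    exit_observed: bool

    @property
    def dwell_min(self) -> float:
        return self.end_min - self.start_min


@dataclass
class ClassifiedTrack:
    """Phase-labeled intervals for one track.

    ``valid`` is False when the frame labels violate the cyclic phase order
    (such tracks are excluded from dwell summaries). ``s_start_ambiguous``
    marks tracks that begin colorless: assigned to S by default, but their
    initial S interval is excluded from S dwell sums because the history of
    cells first seen colorless is unknown.
    """

    cell_id: str
    germarium_id: str
    layer: str
    intervals: list[PhaseInterval] = field(default_factory=list)
    valid: bool = True
    reason: Optional[str] = None
    s_start_ambiguous: bool = False


@dataclass(frozen=True)
class PhaseDwellSummary:
    """Sufficient statistic of the dwell estimator for one phase.

    ``total_observed_min`` pools the minutes all cells were observed in the
    phase; ``exits`` counts observed transitions out of it.
    """

    phase: str
    total_observed_min: float
    exits: int
    cells_tracked: int

    def __post_init__(self) -> None:
        if self.total_observed_min < 0:
            raise InvalidParameterError("total_observed_min must be >= 0")
        if self.exits < 0:
            raise InvalidParameterError("exits must be >= 0")


@dataclass(frozen=True)
class CellCycleEstimate:
    """Per-phase durations (minutes) and total cycle time for one cell class."""

    g1_min: float
    s_min: float
    g2_min: float
    m_min: float
    s_fraction_used: float
    n_cells: int

    def __post_init__(self) -> None:
        if not 0 <= self.s_fraction_used < 1:
            raise InvalidParameterError("s_fraction_used must be in [0, 1)")

    @property
    def total_min(self) -> float:
        return self.g1_min + self.s_min + self.g2_min + self.m_min

    def rounded(self) -> dict:
        """Reporting view: durations to the nearest minute."""
        return {
            "g1_min": round(self.g1_min),
            "s_min": round(self.s_min),
            "g2_min": round(self.g2_min),
            "m_min": round(self.m_min),
            "total_min": round(self.total_min),
        }


def frame_phase_label(gfp: bool, rfp: bool, mitotic: bool) -> str:
    """Map one frame's reporter state to a phase label.

    Mitotic morphology overrides color; GFP-only is G1, GFP+RFP is G2,
    RFP-only and colorless are both S (early S-phase cells have not yet
    accumulated detectable RFP).
    """
    if mitotic:
        return "M"
    if gfp and rfp:
        return "G2"
    if gfp:
        return "G1"
    return "S"


def classify_track(track: CellTrack) -> ClassifiedTrack:
    """Convert a track's frames into phase-labeled, midpoint-bounded intervals.

    Consecutive frames with the same label merge into one interval. Interval
    boundaries interior to the track are placed at the midpoint between the
    bounding frames; the first and last observed frames bound the censored
    ends. A label sequence violating the cyclic order G1->S->G2->M->G1
    invalidates the track (``valid=False``) with a logged reason.
    """
    labels = [frame_phase_label(f.gfp, f.rfp, f.mitotic) for f in track.frames]
    times = [f.time_min for f in track.frames]

    runs: list[tuple[str, float, float]] = []  # (label, first_time, last_time)
    for label, t in zip(labels, times):
        if runs and runs[-1][0] == label:
            runs[-1] = (label, runs[-1][1], t)
        else:
            runs.append((label, t, t))

    out = ClassifiedTrack(
        cell_id=track.cell_id, germarium_id=track.germarium_id, layer=track.layer
    )
    for (a, _, _), (b, _, _) in zip(runs, runs[1:]):
        if _NEXT_PHASE[a] != b:
            out.valid = False
            out.reason = f"illegal transition {a} -> {b} (cyclic order violated)"
            logger.info("track %s excluded: %s", track.cell_id, out.reason)
            return out

    first_frame = track.frames[0]
    if runs[0][0] == "S" and not first_frame.rfp and not first_frame.gfp and not first_frame.mitotic:
        out.s_start_ambiguous = True

    for i, (label, t_first, t_last) in enumerate(runs):
        if i == 0:
            start, entry_observed = t_first, False
        else:
            start, entry_observed = 0.5 * (runs[i - 1][2] + t_first), True
        if i == len(runs) - 1:
            end, exit_observed = t_last, False
        else:
            end, exit_observed = 0.5 * (t_last + runs[i + 1][1]), True
        out.intervals.append(
            PhaseInterval(
                phase=label,
                start_min=start,
                end_min=end,
                entry_observed=entry_observed,
                exit_observed=exit_observed,
            )
        )
    return out


def _classified(tracks: Iterable[CellTrack | ClassifiedTrack]) -> list[ClassifiedTrack]:
    out = []
    for t in tracks:
        out.append(t if isinstance(t, ClassifiedTrack) else classify_track(t))
    return out


def summarize_tracks(
    tracks: Sequence[CellTrack | ClassifiedTrack],
    phase: str,
    *,
    include_entering: bool = True,
    include_ambiguous_s_start: bool = False,
) -> PhaseDwellSummary:
    """Pool observed dwell minutes and exits for one phase across tracks.

    Dwell time accumulates over every interval in the phase — including cells
    already in the phase at the window start and, by default, cells entering
    during the window. Censored exits contribute time but no exit.
    ``include_entering=False`` restricts to intervals already in progress at
    track start (this demonstrably biases the estimate low; it exists for
    diagnostics). Initial colorless S intervals are excluded from S sums
    unless ``include_ambiguous_s_start`` is set. Tracks violating the cyclic
    order are skipped with a logged count.
    """
    if phase not in _NEXT_PHASE:
        raise InvalidParameterError(f"unknown phase {phase!r}")
    tracks = list(tracks)
    if not tracks:
        raise EmptyInputError("no tracks supplied")
    classified = _classified(tracks)
    n_invalid = sum(not c.valid for c in classified)
    if n_invalid:
        logger.info("summarize_tracks: excluded %d ambiguous track(s)", n_invalid)
    total = 0.0
    exits = 0
    cells = 0
    for c in classified:
        if not c.valid:
            continue
        contributed = False
        for i, iv in enumerate(c.intervals):
            if iv.phase != phase:
                continue
            if not include_entering and iv.entry_observed:
                continue
            if (
                phase == "S"
                and i == 0
                and c.s_start_ambiguous
                and not include_ambiguous_s_start
            ):
                continue
            total += iv.dwell_min
            exits += int(iv.exit_observed)
            contributed = True
        cells += int(contributed)
    return PhaseDwellSummary(
        phase=phase, total_observed_min=total, exits=exits, cells_tracked=cells
    )


def estimate_phase_duration(summary: PhaseDwellSummary) -> float:
    """Average phase duration: pooled observed minutes / observed exits.

    Raises :class:`NoTransitionsError` when no exits were observed (the
    duration is then not identifiable from the window). Returns the
    unrounded value; report durations rounded to the nearest minute.
    """
    if summary.exits < 1:
        raise NoTransitionsError(
            f"no observed transitions out of {summary.phase}; duration not estimable"
        )
    return summary.total_observed_min / summary.exits


def infer_s_duration(g1_min: float, g2_min: float, m_min: float, s_fraction: float) -> float:
    """S duration from the snapshot S fraction: (G1+G2+M) * fS / (1 - fS).

    ``s_fraction`` is the fraction of cells in S among all cells of the
    class in fixed samples, i.e. S as a fraction of the whole cycle.
    """
    if not 0 <= s_fraction < 1:
        raise InvalidParameterError(f"s_fraction must be in [0, 1), got {s_fraction}")
    return (g1_min + g2_min + m_min) * s_fraction / (1.0 - s_fraction)


def count_phase_exits(tracks: Iterable[CellTrack | ClassifiedTrack], phase: str) -> int:
    """Observed transitions out of ``phase`` across valid tracks."""
    n = 0
    for c in _classified(tracks):
        if not c.valid:
            continue
        n += sum(iv.exit_observed for iv in c.intervals if iv.phase == phase)
    return n


def filter_active_germaria(
    tracks: Sequence[CellTrack],
) -> tuple[list[CellTrack], int]:
    """Drop germaria with zero observed G1 and zero G2 exits.

    Mirrors the exclusion of inert imaging sessions in which no transitions
    were seen (often accompanied by minimal cell movement). Note this
    selects toward active germaria. Returns (kept tracks, germaria dropped).
    """
    by_germarium: dict[str, list[CellTrack]] = {}
    for t in tracks:
        by_germarium.setdefault(t.germarium_id, []).append(t)
    kept: list[CellTrack] = []
    dropped = 0
    for gid, group in by_germarium.items():
        if count_phase_exits(group, "G1") + count_phase_exits(group, "G2") > 0:
            kept.extend(group)
        else:
            dropped += 1
            logger.info("germarium %s excluded: no G1 or G2 exits observed", gid)
    return kept, dropped


def estimate_cell_cycle(
    tracks: Sequence[CellTrack],
    s_fraction: float,
    *,
    exclude_inert_germaria: bool = True,
) -> CellCycleEstimate:
    """Full pipeline: tracks + snapshot S fraction -> per-phase durations.

    G1, G2 and M come from the dwell/exit estimator; S from
    :func:`infer_s_duration` applied to their sum.
    """
    tracks = list(tracks)
    if not tracks:
        raise EmptyInputError("no tracks supplied")
    if exclude_inert_germaria:
        tracks, n_dropped = filter_active_germaria(tracks)
        if not tracks:
            raise NoTransitionsError(
                "all germaria excluded: no G1 or G2 exits observed anywhere"
            )
    g1 = estimate_phase_duration(summarize_tracks(tracks, "G1"))
    g2 = estimate_phase_duration(summarize_tracks(tracks, "G2"))
    m = estimate_phase_duration(summarize_tracks(tracks, "M"))
    s = infer_s_duration(g1, g2, m, s_fraction)
    n_cells = len({t.cell_id for t in tracks})
    return CellCycleEstimate(
        g1_min=g1, s_min=s, g2_min=g2, m_min=m, s_fraction_used=s_fraction, n_cells=n_cells
    )


def cycle_ratio(est_a, est_b) -> float:
    """Ratio of total cycle times, reported to one decimal place.

    Accepts :class:`CellCycleEstimate` objects or raw total minutes.
    """
    total_a = float(getattr(est_a, "total_min", est_a))
    total_b = float(getattr(est_b, "total_min", est_b))
    if total_a <= 0 or total_b <= 0:
        raise InvalidParameterError("cycle totals must be > 0")
    return round(total_a / total_b, 1)


@dataclass(frozen=True)
class BootstrapResult:
    point_estimate_min: float
    lower_min: float
    upper_min: float
    n_reps: int
    n_skipped: int


def bootstrap_ci(
    tracks: Sequence[CellTrack],
    phase: str,
    n_reps: int,
    seed: int,
    *,
    alpha: float = 0.05,
) -> BootstrapResult:
    """Percentile bootstrap CI for a phase duration, resampling germaria.

    Germaria (the natural independent unit) are resampled with replacement;
    replicates with zero pooled exits are recorded and skipped.
    """
    if n_reps < 1:
        raise InvalidParameterError(f"n_reps must be >= 1, got {n_reps}")
    classified = [c for c in _classified(tracks) if c.valid]
    by_germarium: dict[str, list[ClassifiedTrack]] = {}
    for c in classified:
        by_germarium.setdefault(c.germarium_id, []).append(c)
    gids = sorted(by_germarium)
    if len(gids) < 2:
        raise InvalidParameterError("bootstrap requires tracks from >= 2 germaria")
    per_germarium = np.array(
        [
            (s.total_observed_min, s.exits)
            for gid in gids
            for s in [summarize_tracks(by_germarium[gid], phase)]
        ]
    )
    point = estimate_phase_duration(
        PhaseDwellSummary(
            phase=phase,
            total_observed_min=float(per_germarium[:, 0].sum()),
            exits=int(per_germarium[:, 1].sum()),
            cells_tracked=len(classified),
        )
    )
    rng = np.random.default_rng(seed)
    estimates = []
    skipped = 0
    for _ in range(n_reps):
        idx = rng.integers(0, len(gids), size=len(gids))
        total = per_germarium[idx, 0].sum()
        exits = per_germarium[idx, 1].sum()
        if exits == 0:
            skipped += 1
            continue
        estimates.append(total / exits)
    if not estimates:
        raise NoTransitionsError("every bootstrap replicate had zero exits")
    lower, upper = np.percentile(estimates, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(
        point_estimate_min=float(point),
        lower_min=float(lower),
        upper_min=float(upper),
        n_reps=n_reps,
        n_skipped=skipped,
    )
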