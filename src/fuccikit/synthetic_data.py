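"""Synthetic asynchronous cell populations, imaging windows, snapshots and
label-dilution series.

The simulator reproduces the statistical structure that the downstream
estimators assume, so the whole pipeline can be exercised without microscopy
data:

* An asynchronous population in steady state. Sampling a cycling population
  at an arbitrary instant is length-biased: a cell is found in a phase with
  probability proportional to the phase's duration, and the elapsed time
  within the phase is uniform. With ``cv > 0`` each cell draws its own phase
  durations from independent gamma distributions sharing that coefficient of
  variation.
* Finite imaging windows sampled on a regular frame grid, with FUCCI reporter
  color derived from the true phase plus reporter onset lags (early S-phase
  cells are colorless until RFP becomes detectable), mitosis detection, cell
  division into two G1 daughters, and optional permanent dropout of cells
  from the observed z-range.
* Fixed snapshots with a pulse of EdU before fixation: a cell is EdU-positive
  iff any part of the pulse window overlapped S-phase.
* Exponential dilution of a stable nuclear label, halving per division, with
  optional multiplicative (log-normal) measurement noise.

All randomness flows through one named stream per germarium, so adding
germaria to a simulation never perturbs the ones already generated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .track_io import CellTrack, Frame

PHASES = ("G1", "S", "G2", "M")


@dataclass(frozen=True)
class PhaseDurations:
    """Mean durations of the four cell-cycle phases, in minutes.

    ``cv`` is the per-cell coefficient of variation: 0 (default) makes every
    cell's phase durations exactly the stated means; cv > 0 draws each phase
    duration independently per cell from a gamma distribution with that mean
    and coefficient of variation.
    """

    g1_min: float
    s_min: float
    g2_min: float
    m_min: float
    cv: float = 0.0

    def __post_init__(self) -> None:
        for name in ("g1_min", "s_min", "g2_min", "m_min"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.cv < 0:
            raise InvalidParameterError(f"cv must be >= 0, got {self.cv}")

    @property
    def total_min(self) -> float:
        return self.g1_min + self.s_min + self.g2_min + self.m_min

    def as_array(self) -> np.ndarray:
        """Durations in phase order G1, S, G2, M."""
        return np.array([self.g1_min, self.s_min, self.g2_min, self.m_min], dtype=float)


@dataclass(frozen=True)
class ReporterConfig:
    """Detection properties of the FUCCI reporters and the EdU pulse.

    ``rfp_onset_lag_min`` is the delay after S entry before RFP is detectable
    (cells are colorless in that interval); ``gfp_onset_lag_min`` the delay
    after S exit before GFP reappears; ``edu_pulse_min`` the length of the
    EdU incorporation window immediately before fixation.
    """

    rfp_onset_lag_min: float = 114.0
    gfp_onset_lag_min: float = 0.0
    edu_pulse_min: float = 60.0

    def __post_init__(self) -> None:
        if self.rfp_onset_lag_min < 0 or self.gfp_onset_lag_min < 0:
            raise InvalidParameterError("reporter onset lags must be >= 0")
        if not self.edu_pulse_min > 0:
            raise InvalidParameterError("edu_pulse_min must be > 0")


@dataclass(frozen=True)
class ImagingConfig:
    """Live-imaging protocol: window length, frame interval, dropout, seed.

    ``dropout_prob`` is the per-frame probability that a cell permanently
    leaves the observed z-range (right-censoring; cells never re-enter).
    """

    window_min: float = 150.0
    frame_interval_min: float = 20.0
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.window_min > 0:
            raise InvalidParameterError("window_min must be > 0")
        if not 0 < self.frame_interval_min <= self.window_min:
            raise InvalidParameterError(
                "frame_interval_min must satisfy 0 < interval <= window_min"
            )
        if not 0 <= self.dropout_prob < 1:
            raise InvalidParameterError("dropout_prob must be in [0, 1)")


@dataclass(frozen=True)
class SimCell:
    """A cell sampled from the steady-state population.

    ``durations`` holds the cell's own phase durations (equal to the
    population means when cv = 0), ``phase`` its current phase and
    ``time_in_phase_min`` the elapsed time within it.
    """

    cell_id: str
    germarium_id: str
    layer: str
    phase: str
    time_in_phase_min: float
    durations: tuple[float, float, float, float]


def _germarium_rng(seed: int, g_index: int, stream: int) -> np.random.Generator:
    # one named stream per (germarium, purpose); adding germaria appends streams
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(g_index, stream)))


def _draw_durations(base: PhaseDurations, rng: np.random.Generator) -> tuple:
    means = base.as_array()
    if base.cv == 0:
        return tuple(means)
    shape = 1.0 / base.cv**2
    return tuple(rng.gamma(shape, mean * base.cv**2) for mean in means)


def simulate_population(
    durations: PhaseDurations,
    n_cells: int,
    seed: int,
    *,
    n_germaria: int = 1,
    layer: str = "1",
) -> list[SimCell]:
    """Sample ``n_cells`` cells from an asynchronous steady-state population.

    Each cell's phase is drawn with probability proportional to (its own)
    phase durations — the length-biased occupancy of a cycling population
    observed at an arbitrary instant — and the elapsed time within the phase
    is uniform on the phase. Reproducible given ``seed``.
    """
    if n_cells < 1:
        raise InvalidParameterError(f"n_cells must be >= 1, got {n_cells}")
    if n_germaria < 1:
        raise InvalidParameterError(f"n_germaria must be >= 1, got {n_germaria}")
    counts = [n_cells // n_germaria + (1 if i < n_cells % n_germaria else 0) for i in range(n_germaria)]
    cells: list[SimCell] = []
    for g, count in enumerate(counts):
        rng = _germarium_rng(seed, g, 0)
        for j in range(count):
            d = _draw_durations(durations, rng)
            arr = np.asarray(d)
            phase_idx = int(rng.choice(4, p=arr / arr.sum()))
            elapsed = float(rng.uniform(0.0, arr[phase_idx]))
            cells.append(
                SimCell(
                    cell_id=f"g{g}c{j}",
                    germarium_id=f"g{g}",
                    layer=layer,
                    phase=PHASES[phase_idx],
                    time_in_phase_min=elapsed,
                    durations=d,
                )
            )
    return cells


def _reporter_state(phase: str, elapsed: float, reporters: ReporterConfig) -> tuple[bool, bool]:
    """(gfp, rfp) visible for a cell at ``elapsed`` minutes into ``phase``."""
    if phase == "G1":
        return True, False
    if phase == "S":
        if elapsed < reporters.rfp_onset_lag_min:
            return False, False  # colorless early S
        return False, True
    if phase == "G2":
        if elapsed < reporters.gfp_onset_lag_min:
            return False, True  # early G2 before GFP reaccumulates
        return True, True
    return True, True  # M retains both reporters until RFP degrades at M exit


def _lineage_segments(
    start_phase_idx: int,
    elapsed: float,
    initial_durations: Sequence[float],
    t_start: float,
    window: float,
    base: PhaseDurations,
    rng: np.random.Generator,
):
    """Phase segments for one tracked cell line, spawning one daughter per division.

    The tracked line follows one daughter through each division (the other
    daughter is returned as a spawn to start its own track). Segments are
    ``(phase, t0, t1)`` in absolute minutes; the last segment may extend past
    the window.
    """
    segments = []
    spawns = []  # (birth_time, durations) of the second daughter
    d = tuple(initial_durations)
    pi = start_phase_idx
    t = t_start - elapsed
    while t < window:
        t_end = t + d[pi]
        segments.append((PHASES[pi], t, t_end))
        t = t_end
        if t >= window:
            break
        if pi == 3:  # M exit: division into two G1 daughters with fresh draws
            d = _draw_durations(base, rng)
            spawns.append((t, _draw_durations(base, rng)))
            pi = 0
        else:
            pi += 1
    return segments, spawns


def _emit_track(
    cell_id: str,
    germarium_id: str,
    layer: str,
    segments,
    birth: float,
    frame_times: np.ndarray,
    dt: float,
    reporters: ReporterConfig,
    dropout_prob: float,
    rng: np.random.Generator,
) -> Optional[CellTrack]:
    frames = []
    first = True
    for ft in frame_times:
        if ft < birth - 1e-9:
            continue
        if not first and dropout_prob > 0 and rng.random() < dropout_prob:
            break
        seg = next(s for s in segments if s[1] - 1e-9 <= ft < s[2] - 1e-9 or s is segments[-1])
        phase, t0, _ = seg
        gfp, rfp = _reporter_state(phase, ft - t0, reporters)
        # Mitosis is detected as an event (rounded morphology, daughter
        # appearance), not a point sample: flag the frame if the cell is in M
        # now, or if an M phase began since the previous frame and has already
        # completed (division fell entirely inside the frame gap).
        mitotic = phase == "M"
        if not mitotic and not first:
            mitotic = any(
                s[0] == "M" and ft - dt < s[1] <= ft and s[2] <= ft + 1e-9 for s in segments
            )
        frames.append(Frame(time_min=float(ft), gfp=gfp, rfp=rfp, mitotic=mitotic))
        first = False
    if not frames:
        return None
    return CellTrack(cell_id=cell_id, germarium_id=germarium_id, layer=layer, frames=frames)


def simulate_imaging(
    population: Iterable[SimCell],
    durations: PhaseDurations,
    reporters: ReporterConfig,
    imaging: ImagingConfig,
    *,
    retain_both_daughters: bool = False,
) -> list[CellTrack]:
    """Observe a population through a finite imaging window.

    Each cell progresses through its phases from its sampled starting point;
    at each M exit it divides into two G1 daughters with fresh duration
    draws. One daughter continues the parent's track. By default the tracked
    pool is homeostatic — each division nets one cycling stem cell, matching
    a tissue whose stem-cell count is constant — so the second daughter
    differentiates: it appears in the field as a G1 track at the first frame
    after division and then leaves. With ``retain_both_daughters=True`` both
    daughters keep cycling and the tracked pool grows exponentially; note
    that regime violates the stationarity the dwell/exit estimator assumes
    and inflates short-window G1 estimates. Frames lie on a regular grid of
    ``frame_interval_min``; dropout truncates tracks permanently.
    """
    dt = imaging.frame_interval_min
    # frames lie strictly inside [0, window): a window equal to the frame
    # interval yields single-frame tracks with no observable transitions
    frame_times = np.arange(0.0, imaging.window_min - 1e-9, dt)
    tracks: list[CellTrack] = []
    rngs: dict[str, np.random.Generator] = {}
    for cell in population:
        if cell.germarium_id not in rngs:
            rngs[cell.germarium_id] = _germarium_rng(imaging.seed, len(rngs), 1)
        rng = rngs[cell.germarium_id]
        queue = [
            (cell.cell_id, PHASES.index(cell.phase), cell.time_in_phase_min, cell.durations, 0.0, True)
        ]
        while queue:
            cid, pi, elapsed, durs, birth, cycling = queue.pop(0)
            if cycling:
                horizon = imaging.window_min
            else:
                # differentiating daughter: observed at its first frame only
                later = frame_times[frame_times >= birth - 1e-9]
                if later.size == 0:
                    continue
                horizon = float(later[0]) + 1e-6
            segments, spawns = _lineage_segments(
                pi, elapsed, durs, birth, horizon, durations, rng
            )
            if cycling:
                for k, (t_birth, d_birth) in enumerate(spawns, start=1):
                    queue.append((f"{cid}.{k}", 0, 0.0, d_birth, t_birth, retain_both_daughters))
            track = _emit_track(
                cid,
                cell.germarium_id,
                cell.layer,
                segments,
                birth,
                frame_times if cycling else frame_times[frame_times <= horizon],
                dt,
                reporters,
                imaging.dropout_prob,
                rng,
            )
            if track is not None:
                tracks.append(track)
    return tracks


def simulate_snapshot(
    durations: PhaseDurations,
    n_cells: int,
    reporters: ReporterConfig,
    seed: int,
    *,
    n_germaria: int = 1,
    location: str = "1",
    genotype: str = "control",
    include_edu: bool = True,
) -> pd.DataFrame:
    """Fixed-sample cell table after a pre-fixation EdU pulse.

    Returns a DataFrame in the snapshot.csv schema. A cell is EdU-positive
    iff any part of the pulse window ``[t_fix - edu_pulse_min, t_fix]``
    overlapped S-phase; reporter colors are evaluated at the fixation
    instant. With ``include_edu=False`` the edu column is missing and every
    cell is DAPI-stained instead.
    """
    cells = simulate_population(durations, n_cells, seed, n_germaria=n_germaria, layer=location)
    rows = []
    for cell in cells:
        g1, s, g2, m = cell.durations
        gfp, rfp = _reporter_state(cell.phase, cell.time_in_phase_min, reporters)
        if include_edu:
            if cell.phase == "S":
                since_s_exit = -1.0  # still in S: pulse necessarily overlaps
            elif cell.phase == "G2":
                since_s_exit = cell.time_in_phase_min
            elif cell.phase == "M":
                since_s_exit = cell.time_in_phase_min + g2
            else:  # G1: previous S-phase ended before the mother's G2 + M
                since_s_exit = cell.time_in_phase_min + m + g2
            edu = since_s_exit < reporters.edu_pulse_min
        else:
            edu = None
        rows.append(
            {
                "cell_id": cell.cell_id,
                "germarium_id": cell.germarium_id,
                "location": location,
                "gfp": int(gfp),
                "rfp": int(rfp),
                "edu": pd.NA if edu is None else int(edu),
                "dapi": 1,
                "genotype": genotype,
            }
        )
    return pd.DataFrame(rows)


def simulate_dilution(
    initial_intensities,
    divisions_per_cell,
    noise_cv: float = 0.0,
    seed: int = 0,
    *,
    germarium_id: str = "g0",
    layer: str = "1",
    chase_day: float = 0.0,
) -> pd.DataFrame:
    """Dilute a stable nuclear label two-fold per division.

    ``intensity = initial * 2**(-divisions) * noise`` where the noise is
    multiplicative log-normal with unit mean and coefficient of variation
    ``noise_cv`` (0 disables noise). Returns a DataFrame in the
    intensities.csv schema plus a ``true_divisions`` column.
    """
    initial = np.atleast_1d(np.asarray(initial_intensities, dtype=float))
    divisions = np.broadcast_to(
        np.atleast_1d(np.asarray(divisions_per_cell, dtype=float)), initial.shape
    ).astype(float)
    if (initial <= 0).any():
        raise InvalidParameterError("initial intensities must be > 0")
    if (divisions < 0).any():
        raise InvalidParameterError("divisions must be >= 0")
    if noise_cv < 0:
        raise InvalidParameterError("noise_cv must be >= 0")
    intensity = initial * np.power(2.0, -divisions)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        intensity = intensity * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=initial.shape)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(initial.size)],
            "germarium_id": germarium_id,
            "layer": layer,
            "intensity": intensity,
            "chase_day": chase_day,
            "true_divisions": divisions,
        }
    )
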