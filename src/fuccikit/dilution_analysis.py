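"""H2B-RFP label-dilution analysis: per-germarium normalization,
fold-threshold classification, and approximate division counting.

A stable chromatin-bound label halves with each division, so intensity after
a chase period reports how often a cell divided. Raw intensities are
normalized to the mean of layer-3 cells in the same germarium (the
slowest-cycling layer, whose label is essentially undiluted over the chase
periods considered). Because initial labeling differs systematically between
layers, the fold-dilution threshold is applied against per-layer pre-chase
baselines by default.

Division-count estimates (log2 of baseline over observed intensity) are
approximate: heterogeneous initial labeling among equivalent cells limits
quantitative inference, and cells exchange layers during a chase.
"""

from __future__ import annotations

import logging
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidParameterError

logger = logging.getLogger(__name__)


def normalize_to_layer3(records: pd.DataFrame) -> pd.DataFrame:
    """Divide each cell's intensity by its germarium's mean layer-3 intensity.

    Returns a copy with a ``relative_intensity`` column. Germaria without
    layer-3 cells cannot be normalized; they are excluded with a logged
    warning. Idempotent on already-normalized data in the sense that
    re-normalizing the ``relative_intensity`` column leaves it unchanged
    (layer-3 relative means are 1 by construction).
    """
    if records.empty:
        raise EmptyInputError("no intensity records supplied")
    if (records["intensity"] <= 0).any():
        raise InvalidParameterError("intensities must be > 0")
    out = []
    for gid, group in records.groupby("germarium_id", sort=False):
        layer3 = group.loc[group["layer"].astype(str) == "3", "intensity"]
        if layer3.empty:
            logger.warning("germarium %s has no layer-3 cells; excluded", gid)
            continue
        g = group.copy()
        g["relative_intensity"] = g["intensity"] / layer3.mean()
        out.append(g)
    if not out:
        raise EmptyInputError("no germarium contained layer-3 cells")
    return pd.concat(out, ignore_index=True)


def fraction_below_threshold(
    records: pd.DataFrame,
    baseline: Union[Mapping[str, float], float],
    fold: float = 4.0,
) -> pd.DataFrame:
    """Fraction of cells diluted at least ``fold``-fold below baseline.

    ``records`` needs ``layer`` and ``relative_intensity`` columns (and
    optionally ``chase_day``). ``baseline`` gives the pre-chase mean relative
    intensity per layer (a mapping), or one global value. A cell counts as
    diluted when relative_intensity < baseline / fold. Returns per-layer (and
    per-chase-day) fractions with raw counts. Monotone non-increasing in
    ``fold``.
    """
    if not fold > 1:
        raise InvalidParameterError(f"fold must be > 1, got {fold}")
    if records.empty:
        raise EmptyInputError("no records supplied")
    df = records.copy()
    df["layer"] = df["layer"].astype(str)
    if isinstance(baseline, Mapping):
        base = df["layer"].map({str(k): float(v) for k, v in baseline.items()})
        if base.isna().any():
            missing = sorted(df.loc[base.isna(), "layer"].unique())
            raise InvalidParameterError(f"no baseline supplied for layer(s) {missing}")
    else:
        base = pd.Series(float(baseline), index=df.index)
    df["below"] = df["relative_intensity"] < base / fold
    keys = ["layer"] + (["chase_day"] if "chase_day" in df.columns else [])
    out = (
        df.groupby(keys, sort=True)["below"]
        .agg(n_below="sum", n_cells="size")
        .reset_index()
    )
    out["fraction_below"] = out["n_below"] / out["n_cells"]
    return out


def divisions_from_dilution(baseline_intensity, observed_intensity):
    """Approximate divisions implied by dilution: log2(baseline / observed).

    Clipped at zero (an intensity above baseline implies no divisions, not a
    negative count). Treat as approximate: initial labeling is uneven between
    cells. Vectorized over array inputs.
    """
    baseline = np.asarray(baseline_intensity, dtype=float)
    observed = np.asarray(observed_intensity, dtype=float)
    if (baseline <= 0).any() or (observed <= 0).any():
        raise InvalidParameterError("intensities must be > 0")
    result = np.clip(np.log2(baseline / observed), 0.0, None)
    if result.ndim == 0:
        return float(result)
    return result


def summarize_dilution(
    records: pd.DataFrame,
    baseline: Union[Mapping[str, float], float],
    fold: float = 4.0,
) -> pd.DataFrame:
    """Per layer and chase day: mean relative intensity, fold-threshold
    fraction, counts, and the approximate mean division count.

    ``records`` must already carry ``relative_intensity`` (see
    :func:`normalize_to_layer3`).
    """
    frac = fraction_below_threshold(records, baseline, fold)
    df = records.copy()
    df["layer"] = df["layer"].astype(str)
    keys = ["layer"] + (["chase_day"] if "chase_day" in df.columns else [])
    means = (
        df.groupby(keys, sort=True)["relative_intensity"]
        .mean()
        .rename("mean_relative_intensity")
        .reset_index()
    )
    out = means.merge(frac, on=keys)
    if isinstance(baseline, Mapping):
        base = out["layer"].map({str(k): float(v) for k, v in baseline.items()})
    else:
        base = float(baseline)
    out["approx_mean_divisions"] = divisions_from_dilution(
        base, out["mean_relative_intensity"]
    )
    return out
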