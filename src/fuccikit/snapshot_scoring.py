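"""Phase scoring of fixed samples and the associated proportion statistics.

Fixed-sample cells are classified from their FUCCI state: GFP-only is G1,
GFP+RFP is G2/M, and both RFP-only and colorless cells are S (early S-phase
cells have not yet accumulated detectable RFP; DAPI or EdU makes colorless
cells countable). Per-location phase fractions carry the standard error of a
proportion, sqrt(p(1-p)/n). Two-proportion comparisons use the "N-1"
chi-squared test: the classical Pearson statistic scaled by (N-1)/N.

EdU indices (fraction of cells incorporating EdU during a fixed pulse) are
normalized between experiments by the layer-1 control index, and a genotype's
per-layer EdU pattern can be compared against the expectation derived from
the control pattern at the genotype's overall (layer-weighted) index.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError, InvalidParameterError
from .track_io import SnapshotRecord, snapshot_frame

PHASE_LABELS = ("G1", "S", "G2/M")


def classify_phase(record: Union[SnapshotRecord, tuple]) -> str:
    """Phase label of one fixed-sample cell from its reporter state.

    Accepts a :class:`SnapshotRecord` or a ``(gfp, rfp)`` pair. GFP-only ->
    G1; GFP+RFP -> G2/M; RFP-only or colorless -> S. Total on the state
    vocabulary: every combination maps to a phase.
    """
    if isinstance(record, SnapshotRecord):
        gfp, rfp = record.gfp, record.rfp
    else:
        gfp, rfp = record
    if gfp and rfp:
        return "G2/M"
    if gfp:
        return "G1"
    return "S"


def _to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    records = list(records)
    if records and isinstance(records[0], SnapshotRecord):
        return snapshot_frame(records)
    return pd.DataFrame(records)


def fraction_table(
    records: Union[pd.DataFrame, Iterable[SnapshotRecord]],
    group_keys: Sequence[str] = ("location", "genotype"),
) -> pd.DataFrame:
    """Per-group G1/S/G2-M fractions with counts and proportion SEs.

    Fractions sum to 1 within each group; SE = sqrt(p(1-p)/n).
    """
    df = _to_frame(records)
    if df.empty:
        raise EmptyInputError("no snapshot records supplied")
    df["phase"] = [
        classify_phase((bool(g), bool(r))) for g, r in zip(df["gfp"], df["rfp"])
    ]
    rows = []
    for keys, group in df.groupby(list(group_keys), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        n = len(group)
        row = dict(zip(group_keys, keys))
        row["n_cells"] = n
        for label, col in (("G1", "g1"), ("S", "s"), ("G2/M", "g2m")):
            p = float((group["phase"] == label).sum()) / n
            row[f"fraction_{col}"] = p
            row[f"se_{col}"] = float(np.sqrt(p * (1 - p) / n))
        rows.append(row)
    return pd.DataFrame(rows)


def n1_chisq(successes1: int, n1: int, successes2: int, n2: int) -> tuple[float, float]:
    """'N-1' chi-squared test comparing two proportions.

    Returns (statistic, p-value): the classical (uncorrected) Pearson 2x2
    chi-squared statistic multiplied by (N-1)/N with N = n1 + n2, referred to
    a chi-squared distribution with 1 degree of freedom. Identical (or
    degenerate all-success / all-failure) proportions give statistic 0 and
    p = 1.
    """
    if n1 < 1 or n2 < 1:
        raise InvalidParameterError("group sizes must be >= 1")
    if not 0 <= successes1 <= n1 or not 0 <= successes2 <= n2:
        raise InvalidParameterError("successes must lie in [0, n]")
    a, b = successes1, n1 - successes1
    c, d = successes2, n2 - successes2
    n = n1 + n2
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        return 0.0, 1.0
    pearson = n * (a * d - b * c) ** 2 / (n1 * n2 * col1 * col2)
    statistic = pearson * (n - 1) / n
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def edu_index_table(
    records: Union[pd.DataFrame, Iterable[SnapshotRecord]],
    group_keys: Sequence[str] = ("location", "genotype"),
) -> pd.DataFrame:
    """EdU index (fraction EdU+) per group, among cells with an EdU call."""
    df = _to_frame(records)
    scored = df[df["edu"].notna()].copy()
    if scored.empty:
        raise EmptyInputError("no cells carry an EdU call")
    scored["edu"] = scored["edu"].astype(bool)
    out = (
        scored.groupby(list(group_keys), sort=True)["edu"]
        .agg(edu_index="mean", n_cells="size")
        .reset_index()
    )
    out["edu_index"] = out["edu_index"].astype(float)
    return out


def normalize_edu(
    experiment: pd.DataFrame,
    global_control_layer1: float,
    experiment_control_layer1: float,
    *,
    ec_locations: Sequence[str] = ("r2a", "r1"),
) -> pd.DataFrame:
    """Scale an experiment's per-layer EdU indices to the global control level.

    Each FSC-layer index is multiplied by (global control layer-1 index) /
    (this experiment's control layer-1 index), correcting inter-experiment
    labeling variation. Escort-cell locations are never normalized (their
    indices are zero in controls, so the ratio is undefined for them).
    """
    if not experiment_control_layer1 > 0:
        raise InvalidParameterError("experiment_control_layer1 must be > 0")
    if not global_control_layer1 > 0:
        raise InvalidParameterError("global_control_layer1 must be > 0")
    out = experiment.copy()
    scale = global_control_layer1 / experiment_control_layer1
    fsc = ~out["location"].isin(ec_locations)
    out.loc[fsc, "edu_index"] = out.loc[fsc, "edu_index"] * scale
    return out


def expected_edu_distribution(
    genotype_index: Mapping[str, float],
    control_index: Mapping[str, float],
    layer_weights: Mapping[str, float],
    *,
    mode: str = "normalized",
) -> dict:
    """Expected per-layer EdU indices if a genotype followed the control pattern.

    The genotype's overall index is its per-layer indices averaged with
    ``layer_weights`` (the normal distribution of cells among layers). The
    expected pattern redistributes that overall index across layers in
    proportion to the control per-layer indices. ``mode="normalized"``
    (default) scales the control pattern so that the weighted average of the
    expected indices equals the genotype's overall index; ``mode="literal"``
    multiplies the overall index directly by each control index. A
    chi-squared statistic compares observed and expected indices per layer.
    """
    layers = list(layer_weights)
    w = np.array([layer_weights[l] for l in layers], dtype=float)
    if not np.isclose(w.sum(), 1.0):
        raise InvalidParameterError("layer_weights must sum to 1")
    g = np.array([genotype_index[l] for l in layers], dtype=float)
    c = np.array([control_index[l] for l in layers], dtype=float)
    if np.all(c == 0):
        raise InvalidParameterError("control indices are zero in every layer")
    overall = float(w @ g)
    if mode == "normalized":
        expected = c * overall / float(w @ c)
    elif mode == "literal":
        expected = overall * c
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    nonzero = expected > 0
    chi2 = float(((g[nonzero] - expected[nonzero]) ** 2 / expected[nonzero]).sum())
    df = int(nonzero.sum()) - 1
    p = float(stats.chi2.sf(chi2, df=max(df, 1)))
    return {
        "overall_index": overall,
        "expected": dict(zip(layers, expected.tolist())),
        "chi2": chi2,
        "df": df,
        "p_value": p,
    }


def pooled_s_fraction(records: Union[pd.DataFrame, Iterable[SnapshotRecord]]) -> float:
    """Fraction of cells in S pooled across germaria (weighted by cell counts)."""
    df = _to_frame(records)
    if df.empty:
        raise EmptyInputError("no snapshot records supplied")
    phases = [classify_phase((bool(g), bool(r))) for g, r in zip(df["gfp"], df["rfp"])]
    return sum(p == "S" for p in phases) / len(phases)
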