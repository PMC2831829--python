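"""Spatiotemporal anisotropy read-outs.

The model output is the cleavage of an effector-caspase substrate. The
central read-out is the **end-to-end delay**: the difference between the
times at which the far (x = L) and near (x = 0) cell ends cross a given
cleavage-fraction threshold. Onset of cleavage is scored at 1% and
half-maximal cleavage at 50% by convention; both are configurable. Delays
are compared across diffusivity-impairment sweeps and between network
variants and the unperturbed reference (negative differences = reduced
spatial anisotropy).

Delay tables are plain pandas DataFrames with columns
``scenario_id, scale, threshold, near_time_s, far_time_s, delay_s``;
crossings that never happen are NaN (missing), never an exception.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .network import ReactionNetwork, apply_variant
from .solver import ConcentrationField, simulate
from .transport import SpatialGrid, WaveInput

__all__ = [
    "SYNCHRONY_TOLERANCE",
    "DELAY_TABLE_COLUMNS",
    "substrate_cleavage_fraction",
    "threshold_crossing_time",
    "end_to_end_delay",
    "delay_table",
    "diffusivity_sweep",
    "delta_to_reference",
]

#: Delay (s) below which near/far cleavage kinetics count as superimposed.
SYNCHRONY_TOLERANCE = 10.0

DELAY_TABLE_COLUMNS = [
    "scenario_id",
    "scale",
    "threshold",
    "near_time_s",
    "far_time_s",
    "delay_s",
]

#: Default ripple tolerance when enforcing trace monotonicity.
RIPPLE_TOLERANCE = 1.0e-6


def substrate_cleavage_fraction(
    field: ConcentrationField, pair: tuple[str, str] = ("substrate", "substrate_cleaved")
) -> np.ndarray:
    """Fraction of output substrate cleaved, per (node, time); in [0, 1].

    ``pair`` names the (uncleaved, cleaved) output species. NaN where no
    substrate is present (undefined fraction, reported as missing rather
    than raised).
    """
    names = field.species_names
    if pair[0] in names and pair[1] in names:
        uncleaved, cleaved = field.get(pair[0]), field.get(pair[1])
    else:
        raise ValueError("field does not contain the substrate/cleaved-substrate pair")
    total = uncleaved + cleaved
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0.0, cleaved / np.where(total > 0.0, total, 1.0), np.nan)
    return np.clip(frac, 0.0, 1.0)


def threshold_crossing_time(
    times: np.ndarray,
    trace: np.ndarray,
    threshold: float,
    ripple_tolerance: float = RIPPLE_TOLERANCE,
) -> float:
    """First time the trace reaches ``threshold``, linearly interpolated.

    The trace must be monotone non-decreasing up to numerical ripple below
    ``ripple_tolerance`` (which is clipped away by a running maximum);
    larger decreases raise. Returns NaN if the threshold is never reached.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if np.isnan(trace).all():
        return float("nan")
    mono = np.maximum.accumulate(np.nan_to_num(trace, nan=0.0))
    ripple = float(np.max(mono - np.nan_to_num(trace, nan=0.0)))
    if ripple > ripple_tolerance:
        raise ValueError(
            f"trace decreases by {ripple:.3g} (> ripple tolerance {ripple_tolerance:g}); "
            "not a cleavage-fraction trace"
        )
    if mono[-1] < threshold:
        return float("nan")
    i = int(np.argmax(mono >= threshold))
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    f0, f1 = mono[i - 1], mono[i]
    if f1 == f0:  # exact plateau hit
        return float(t1)
    return float(t0 + (threshold - f0) / (f1 - f0) * (t1 - t0))


def end_to_end_delay(
    field: ConcentrationField,
    threshold: float,
    scenario_id: str = "",
    scale: float = 1.0,
) -> pd.Series:
    """One delay-table row: far-end minus near-end crossing time at ``threshold``.

    The near end is the first grid node (x = 0), the far end the last
    (x = L). Missing crossings propagate as NaN.
    """
    frac = substrate_cleavage_fraction(field)
    t = field.time_points
    near = threshold_crossing_time(t, frac[0], threshold)
    far = threshold_crossing_time(t, frac[-1], threshold)
    return pd.Series(
        {
            "scenario_id": scenario_id,
            "scale": float(scale),
            "threshold": float(threshold),
            "near_time_s": near,
            "far_time_s": far,
            "delay_s": far - near,
        }
    )


def delay_table(
    field: ConcentrationField,
    thresholds: Sequence[float],
    scenario_id: str = "",
    scale: float = 1.0,
) -> pd.DataFrame:
    """Delay-table rows for one simulated field at several thresholds."""
    rows = [end_to_end_delay(field, thr, scenario_id, scale) for thr in thresholds]
    return pd.DataFrame(rows, columns=DELAY_TABLE_COLUMNS)


def diffusivity_sweep(
    network: ReactionNetwork,
    grid: SpatialGrid,
    inputs: Sequence[WaveInput],
    scales: Sequence[float],
    thresholds: Sequence[float] = (0.01, 0.5),
    t_end: float = 3600.0,
    scenario_id: str = "reference",
    save_interval: float = 5.0,
    **simulate_kwargs,
) -> pd.DataFrame:
    """End-to-end delays across fold-reductions of every diffusivity.

    ``scales`` are fold-impairments (every D divided by the scale); the
    symbolic no-diffusion limit can be requested as ``np.inf``, which sets
    all diffusivities to exactly zero. One simulation per scale.
    """
    tables = []
    for scale in scales:
        net = apply_variant(network, f"diffusivity_scale:{scale}")
        field = simulate(
            net, grid, inputs, t_end, save_interval=save_interval, **simulate_kwargs
        )
        tables.append(delay_table(field, thresholds, scenario_id, scale))
    return pd.concat(tables, ignore_index=True)


def delta_to_reference(
    variant_table: pd.DataFrame, reference_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-(scale, threshold) delay difference: variant minus reference (s).

    Negative values represent reduced spatial anisotropy in the variant.
    Both tables must cover the same (scale, threshold) keys.
    """
    keys = ["scale", "threshold"]
    merged = variant_table.merge(
        reference_table[keys + ["delay_s"]].rename(columns={"delay_s": "reference_delay_s"}),
        on=keys,
        how="left",
        validate="one_to_one",
    )
    if merged["reference_delay_s"].isna().any() and not merged["delay_s"].isna().any():
        missing = merged.loc[merged["reference_delay_s"].isna(), keys]
        raise ValueError(f"reference table lacks keys:\n{missing}")
    merged["delta_s"] = merged["delay_s"] - merged["reference_delay_s"]
    return merged
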