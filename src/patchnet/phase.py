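"""Phase-diagram sweeps and per-condition state classification.

Each parameter point is simulated from a random start; the label is derived
from the last 20 recorded frames only, with network density as the principal
metric and island size as the secondary determinant:

* ``gas`` — the largest island, averaged over the window, stays below 24
  particles (a state whose biggest island only transiently grazes the
  threshold is a fluctuating gas, not an assembled phase);
* ``dla`` — diffusion-limited-aggregation proxy: essentially no accepted
  bond breaking over the window and a large ramified island (border ratio
  above 0.9 at size >= 100), the kinetic fingerprint of the
  infinite-interaction-strength limit;
* otherwise ``short_like`` when the mean eligible-island ND clears
  ``nd_cut`` AND the typical largest island clears ``short_min_island``
  (island size is the secondary determinant: the long-monomer regime forms
  smaller assemblies), else ``long_like``.

Thresholds are explicit, recorded in the output, and a pure function of the
stored observables (re-classification of a stored report is bit-identical).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .mc import MoveSchedule, Trajectory, run_mc
from .model import ModelParams
from .morphology import FrameReport, analyze_trajectory

__all__ = ["StateLabel", "ClassifyThresholds", "classify_state",
           "classify_trajectory", "sweep", "PhaseDiagram", "locate_boundary"]

log = logging.getLogger(__name__)


class StateLabel(str, enum.Enum):
    GAS = "gas"
    SHORT_LIKE = "short_like"
    LONG_LIKE = "long_like"
    DLA = "dla"
    FAILED = "failed"


@dataclass(frozen=True)
class ClassifyThresholds:
    """Classification knobs (the labelling cutoffs are not printed anywhere;
    these defaults were calibrated once on the reference short/long parameter
    sets and are stored with every diagram)."""

    nd_cut: float = 0.75
    gas_max_island: int = 24
    short_min_island: int = 42
    dla_bondbreak: float = 1e-6
    dla_border: float = 0.9
    dla_min_island: int = 100
    window: int = 20


def classify_state(
    reports: Sequence[FrameReport],
    bondbreak_rate: float,
    thresholds: Optional[ClassifyThresholds] = None,
) -> StateLabel:
    """Label one condition from its last-window frame reports.

    ``reports`` must cover at least the classification window;
    ``bondbreak_rate`` is the mean accepted bond-breaking rate per attempted
    move over the same window.
    """
    th = thresholds or ClassifyThresholds()
    if len(reports) < th.window:
        raise ValueError(f"need >= {th.window} frames, got {len(reports)}")
    window = list(reports)[-th.window:]

    sizes = []
    for rep in window:
        big = rep.largest_island
        sizes.append(big.island.size if big else 0)
    if float(np.mean(sizes)) < th.gas_max_island:
        return StateLabel.GAS

    k = int(np.argmax(sizes))
    biggest = window[k].largest_island
    if (bondbreak_rate < th.dla_bondbreak
            and biggest is not None
            and biggest.island.size >= th.dla_min_island
            and biggest.border > th.dla_border):
        return StateLabel.DLA

    nds = [rep.weighted_nd for rep in window]
    mean_nd = float(np.nanmean(nds)) if not all(np.isnan(nds)) else np.nan
    if np.isnan(mean_nd):
        return StateLabel.GAS
    if mean_nd >= th.nd_cut and float(np.mean(sizes)) >= th.short_min_island:
        return StateLabel.SHORT_LIKE
    return StateLabel.LONG_LIKE


def classify_trajectory(
    traj: Trajectory,
    thresholds: Optional[ClassifyThresholds] = None,
) -> tuple[StateLabel, float, int]:
    """Classify a trajectory; returns (label, mean window ND, max island)."""
    th = thresholds or ClassifyThresholds()
    reports = analyze_trajectory(traj, last=th.window)
    bb = float(np.nanmean(traj.observables["bondbreak_rate"].tail(th.window))) \
        if traj.observables is not None else np.nan
    label = classify_state(reports, bb, th)
    nds = [r.weighted_nd for r in reports]
    mean_nd = float(np.nanmean(nds)) if not all(np.isnan(nds)) else np.nan
    max_isl = max((r.largest_island.island.size if r.largest_island else 0)
                  for r in reports)
    return label, mean_nd, max_isl


@dataclass
class PhaseDiagram:
    """Grid of labelled state points with full provenance."""

    axis1: str
    axis2: str
    values1: list[float]
    values2: list[float]
    points: pd.DataFrame          # axis1, axis2, replicate, seed, label, mean_nd, max_island
    thresholds: ClassifyThresholds
    base_params: ModelParams
    seed: int

    def majority_labels(self) -> pd.DataFrame:
        """Per-point majority label; ties resolved by the replicate whose
        mean ND is the median of the tied set."""
        rows = []
        for (v1, v2), grp in self.points.groupby(["axis1_value", "axis2_value"],
                                                 sort=True):
            counts = grp["label"].value_counts()
            top = counts[counts == counts.max()]
            if len(top) == 1:
                label = top.index[0]
            else:
                tied = grp[grp["label"].isin(top.index)].sort_values("mean_nd")
                label = tied.iloc[len(tied) // 2]["label"]
            rows.append({"axis1_value": v1, "axis2_value": v2, "label": label,
                         "mean_nd": grp["mean_nd"].mean(),
                         "max_island": grp["max_island"].max(),
                         "n_replicates": len(grp)})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)


def sweep(
    axis1: tuple[str, Sequence[float]],
    axis2: tuple[str, Sequence[float]],
    base: Optional[ModelParams] = None,
    schedule: Optional[MoveSchedule] = None,
    replicates: int = 3,
    n_sweeps: int = 500_000,
    record_every: Optional[int] = None,
    seed: int = 0,
    thresholds: Optional[ClassifyThresholds] = None,
    progress: bool = False,
) -> PhaseDiagram:
    """Run one MC + classification per (grid point, replicate).

    Per-run seeds derive from stable hashing of (master seed, point indices,
    replicate), so any sub-grid reproduces the full grid's runs.  Failed runs
    are labelled ``failed`` and kept, never dropped.
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    if not len(vals1) or not len(vals2):
        raise ValueError("axis grids must be non-empty")
    base = base or ModelParams.for_area_fraction(0.1, 150)
    th = thresholds or ClassifyThresholds()
    if record_every is None:
        record_every = max(1, n_sweeps // 200)
    rows = []
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            params = base.with_(**{name1: v1, name2: v2})
            for rep in range(replicates):
                run_seed = int(np.random.SeedSequence(
                    [seed, i, j, rep]).generate_state(1, dtype=np.uint32)[0]
                    & 0x7FFFFFFF)
                try:
                    traj = run_mc(params, schedule=schedule, n_sweeps=n_sweeps,
                                  record_every=record_every, seed=run_seed)
                    label, mean_nd, max_isl = classify_trajectory(traj, th)
                except Exception as exc:
                    log.error("run failed at %s=%s %s=%s rep %d: %s",
                              name1, v1, name2, v2, rep, exc)
                    label, mean_nd, max_isl = StateLabel.FAILED, np.nan, -1
                rows.append({"axis1_value": v1, "axis2_value": v2,
                             "replicate": rep, "seed": run_seed,
                             "label": label.value, "mean_nd": mean_nd,
                             "max_island": max_isl})
                if progress:
                    print(f"{name1}={v1} {name2}={v2} rep={rep}: "
                          f"{label.value} nd={mean_nd:.3f} max={max_isl}",
                          flush=True)
    return PhaseDiagram(axis1=name1, axis2=name2,
                        values1=list(vals1), values2=list(vals2),
                        points=pd.DataFrame(rows), thresholds=th,
                        base_params=base, seed=seed)


def locate_boundary(
    diagram: PhaseDiagram,
    between: tuple[str, str],
    along: str = "axis1",
    at: Optional[float] = None,
) -> list[tuple[float, float, float]]:
    """Bracketing grid intervals for a label transition along one axis.

    Returns ``(low, high, midpoint)`` for every adjacent pair of grid points
    whose majority labels switch between the two requested labels (either
    direction).  Never extrapolates.  Raises when the scanned line shows no
    such transition.
    """
    la, lb = (b.value if isinstance(b, StateLabel) else b for b in between)
    maj = diagram.majority_labels()
    if along == "axis1":
        scan_col, fix_col = "axis1_value", "axis2_value"
    elif along == "axis2":
        scan_col, fix_col = "axis2_value", "axis1_value"
    else:
        raise ValueError("along must be 'axis1' or 'axis2'")
    if at is None:
        fixed = maj[fix_col].unique()
        if len(fixed) != 1:
            raise ValueError("ambiguous line: give `at=` for the other axis")
        at = fixed[0]
    line = maj[np.isclose(maj[fix_col], at)].sort_values(scan_col)
    labels = list(line["label"])
    values = list(line[scan_col])
    if la not in labels or lb not in labels:
        raise ValueError(f"labels {la!r}/{lb!r} do not both occur along the line "
                         f"(found {sorted(set(labels))})")
    out = []
    for k in range(len(labels) - 1):
        if {labels[k], labels[k + 1]} == {la, lb}:
            lo, hi = values[k], values[k + 1]
            out.append((lo, hi, 0.5 * (lo + hi)))
    if not out:
        # the two labels never sit on adjacent grid points: report every
        # label-change interval instead of extrapolating
        for k in range(len(labels) - 1):
            if labels[k] != labels[k + 1]:
                lo, hi = values[k], values[k + 1]
                out.append((lo, hi, 0.5 * (lo + hi)))
    if not out:
        raise ValueError("no transition: the line is uniformly labelled")
    return out
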