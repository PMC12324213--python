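"""Per-cycle fate classification and per-condition summary statistics.

A stretch-relax cycle is assigned one of three fates:

* ``complete`` - the stretch released at least a configurable fraction
  (default 0.9) of the expected full contour length;
* ``locked_unfolded`` - no rips and essentially zero net contour-length
  change, in a molecule that had already reached the unfolded branch in an
  earlier cycle (first pulls are never labelled locked);
* ``misfolded`` - everything else: intermediates that resist full unfolding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .fec import AnalyzedTrace, ForceExtensionTrace, delta_lc

__all__ = [
    "TraceClassification",
    "classify_trace",
    "fate_fractions",
    "hysteresis_area",
    "condition_summary",
]

FATES = ("complete", "misfolded", "locked_unfolded")


@dataclass
class TraceClassification:
    molecule_id: str
    cycle_index: int
    fate: str
    total_dlc: float                      # nm, from the stretch sweep
    max_unfold_force: Optional[float]     # pN, max per-rip force (stretch)
    max_refold_force: Optional[float]     # pN, max per-rip force (relax)
    hysteresis_area: Optional[float]      # pN nm
    n_transitions_stretch: int
    n_transitions_relax: int


def classify_trace(
    stretch: AnalyzedTrace,
    relax: Optional[AnalyzedTrace],
    expected_dlc: float,
    completeness_fraction: float = 0.9,
    locked_tol: float = 20.0,
    prior_unfolded: bool = False,
) -> TraceClassification:
    """Assign a fate to one stretch(-relax) cycle.

    ``prior_unfolded`` records whether an earlier cycle of the same molecule
    reached the unfolded branch; without it a flat trace counts as
    misfolded, never locked.
    """
    d = delta_lc(stretch)
    total = d["total_dlc"]
    n_s = len(stretch.transitions)
    unfold_forces = [t.force_before for t in stretch.transitions]

    if total >= completeness_fraction * expected_dlc:
        fate = "complete"
    elif n_s == 0 and abs(total) < locked_tol and prior_unfolded:
        fate = "locked_unfolded"
    else:
        fate = "misfolded"

    max_refold = None
    n_r = 0
    hyst = None
    if relax is not None:
        n_r = len(relax.transitions)
        refold_forces = [t.force_before for t in relax.transitions]
        max_refold = max(refold_forces) if refold_forces else None
        hyst = hysteresis_area(stretch.trace, relax.trace)

    return TraceClassification(
        molecule_id=stretch.trace.molecule_id,
        cycle_index=stretch.trace.cycle_index,
        fate=fate,
        total_dlc=float(total),
        max_unfold_force=max(unfold_forces) if unfold_forces else None,
        max_refold_force=max_refold,
        hysteresis_area=hyst,
        n_transitions_stretch=n_s,
        n_transitions_relax=n_r,
    )


def fate_fractions(classifications: Sequence[TraceClassification]) -> dict:
    """Fraction of each fate; fractions sum to exactly 1 (the last fate is
    computed as the complement so the identity holds in floating point)."""
    if len(classifications) == 0:
        raise ValueError("no classifications")
    n = len(classifications)
    counts = {f: 0 for f in FATES}
    for c in classifications:
        counts[c.fate] += 1
    out = {f: counts[f] / n for f in FATES[:-1]}
    out[FATES[-1]] = 1.0 - sum(out.values())
    return out


def hysteresis_area(
    stretch: ForceExtensionTrace, relax: ForceExtensionTrace, n_grid: int = 256
) -> float:
    """Area between the stretch and relax force curves over their common
    extension range (pN nm); positive for dissipative cycles."""
    lo = max(stretch.extension.min(), relax.extension.min())
    hi = min(stretch.extension.max(), relax.extension.max())
    if hi <= lo:
        raise ValueError("no overlapping extension range")
    grid = np.linspace(lo, hi, n_grid)

    def interp(tr: ForceExtensionTrace) -> np.ndarray:
        order = np.argsort(tr.extension, kind="stable")
        return np.interp(grid, tr.extension[order], tr.force[order])

    return float(np.trapezoid(interp(stretch) - interp(relax), grid))


def _box_stats(values: np.ndarray) -> dict:
    """Box-plot statistics: 10/90 whiskers, quartiles, median, mean."""
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "median": float(np.percentile(values, 50)),
        "q1": float(np.percentile(values, 25)),
        "q3": float(np.percentile(values, 75)),
        "p10": float(np.percentile(values, 10)),
        "p90": float(np.percentile(values, 90)),
    }


def condition_summary(values_by_condition: Mapping[str, Sequence[float]]) -> dict:
    """Box-plot stats per condition plus pairwise Welch t-tests.

    Percentiles use linear interpolation between order statistics.  The
    Welch test is two-sided with unequal variances.
    """
    stats_out, welch = {}, {}
    arrays = {}
    for cond, vals in values_by_condition.items():
        a = np.asarray([v for v in vals if v is not None and np.isfinite(v)],
                       dtype=float)
        if a.size < 3:
            raise ValueError(f"condition {cond!r} needs >= 3 values")
        arrays[cond] = a
        stats_out[cond] = _box_stats(a)
    conds = sorted(arrays)
    for i, a_name in enumerate(conds):
        for b_name in conds[i + 1:]:
            t, p = stats.ttest_ind(arrays[a_name], arrays[b_name],
                                   equal_var=False)
            welch[f"{a_name}_vs_{b_name}"] = {"t": float(t), "p": float(p)}
    return {"conditions": stats_out, "welch": welch}
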