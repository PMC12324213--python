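"""Force-extension-curve analysis.

Turns raw stretch/relax sweeps into detected transitions (rips), per-branch
contour lengths, and contour-length-change (dLc) statistics.

Detection strategy: a rip is an extension discontinuity between the elastic
branch before and the branch after, compared *at matched force*.  Candidates
are screened on the sample-to-sample extension jump plus the force
signature of a rip under load (a dip during stretch, a rise during relax)
and measured with a local linear pre-branch model.  Detected rips then get
a refined jump from full WLC branch fits; rips whose refined jump falls
below the minimum size are dropped (their neighbouring branches merged and
refitted), so per-rip dLc values always telescope to the branch-difference
total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .polymer import TetherModel, tether_extension

__all__ = [
    "AnalysisError",
    "ForceExtensionTrace",
    "Transition",
    "BranchFit",
    "AnalyzedTrace",
    "DlcDistribution",
    "downsample",
    "detect_transitions",
    "fit_branch_lc",
    "analyze_trace",
    "delta_lc",
    "dlc_distribution",
    "validate_tether",
]


class AnalysisError(ValueError):
    """Raised when a trace cannot be analysed (with a machine-readable reason)."""


@dataclass
class ForceExtensionTrace:
    """One stretch or relax sweep of a single molecule."""

    molecule_id: str
    cycle_index: int
    direction: str                # "stretch" | "relax"
    time: np.ndarray              # s
    extension: np.ndarray         # nm
    force: np.ndarray             # pN
    sample_rate: float            # Hz

    def __post_init__(self) -> None:
        if self.direction not in ("stretch", "relax"):
            raise ValueError(f"bad direction {self.direction!r}")
        n = len(self.time)
        if n < 2 or len(self.extension) != n or len(self.force) != n:
            raise ValueError("time/extension/force must be equal length >= 2")
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class Transition:
    """One detected rip."""

    index: int                    # last pre-rip sample
    force_before: float           # pN, mean over the pre-rip window
    jump_nm: float                # branch-to-branch extension gap (>= 0)
    dlc_nm: float                 # contour length released/absorbed (>= 0)
    direction: str                # "unfold" | "refold"


@dataclass
class BranchFit:
    """WLC fit of one elastic branch (protein contour length free)."""

    lc_nm: float
    rms_residual: float
    sample_range: tuple[int, int]
    flagged: bool = False
    reason: str = ""


@dataclass
class AnalyzedTrace:
    trace: ForceExtensionTrace
    transitions: list[Transition]
    branches: list[BranchFit]


def downsample(trace: ForceExtensionTrace, target_rate: float) -> ForceExtensionTrace:
    """Block-mean average a trace down to ``target_rate``.

    The block size is ``round(sample_rate / target_rate)``; trailing samples
    that do not fill a block are discarded, so for divisible lengths the
    grand mean of every channel is preserved exactly.
    """
    if target_rate >= trace.sample_rate:
        raise ValueError("target_rate must be below the trace sample rate")
    block = int(round(trace.sample_rate / target_rate))
    n_out = len(trace) // block
    if n_out < 2:
        raise ValueError("trace too short to downsample to target_rate")

    def blockmean(a: np.ndarray) -> np.ndarray:
        return a[: n_out * block].reshape(n_out, block).mean(axis=1)

    return ForceExtensionTrace(
        molecule_id=trace.molecule_id,
        cycle_index=trace.cycle_index,
        direction=trace.direction,
        time=blockmean(trace.time),
        extension=blockmean(trace.extension),
        force=blockmean(trace.force),
        sample_rate=trace.sample_rate / block,
    )


def _pre_branch_gap(
    ext: np.ndarray, force: np.ndarray, i: int, w: int, sign: float
) -> float:
    """Matched-force extension gap at a candidate rip between samples i, i+1.

    A local linear model of extension vs force is fitted on the pre-rip
    window [i-w+1, i] and evaluated at the forces of the post-rip samples
    [i+2, i+w+1] (the sample straddling the rip is skipped - block
    averaging smears it between branches).  The gap is the mean residual of
    those samples from the extrapolated pre-branch, signed so unfolding is
    positive on stretch and refolding positive on relax.
    """
    fx = force[i - w + 1 : i + 1]
    fy = ext[i - w + 1 : i + 1]
    mx, my = fx.mean(), fy.mean()
    var = np.mean((fx - mx) ** 2)
    slope = float(np.mean((fx - mx) * (fy - my)) / var) if var > 1e-12 else 0.0
    post = slice(i + 2, min(i + 2 + w, len(ext)))
    resid = ext[post] - (my + slope * (force[post] - mx))
    return float(sign * resid.mean())


def detect_transitions(
    trace: ForceExtensionTrace,
    min_jump: float = 10.0,
    window: int = 6,
    force_window: int = 10,
    force_drop_min: float = 0.25,
    jump_floor_frac: float = 0.25,
    screen_only: bool = False,
) -> list[Transition]:
    """Locate rips with a branch-to-branch extension gap >= ``min_jump`` nm.

    Candidate samples must show (a) a sample-to-sample extension jump of at
    least ``jump_floor_frac * min_jump`` in the sweep direction and (b) the
    force signature of a rip under load: a dip of at least
    ``force_drop_min`` pN right after the jump (a rise, for refolding).
    Each candidate's jump is then measured branch-to-branch at matched
    force with a local pre-branch model (:func:`_pre_branch_gap`) and gated
    at ``min_jump``.  Stretch sweeps yield unfold transitions, relax sweeps
    refold transitions; ``force_before`` is the mean force over the
    ``force_window`` samples up to and including the last pre-rip sample.
    The reported ``dlc_nm`` is NaN until branches are fitted (see
    :func:`analyze_trace`).

    With ``screen_only=True`` the final ``min_jump`` gate is skipped and all
    positive-jump candidates are returned; :func:`analyze_trace` uses this
    mode and applies the gate on the WLC-refined branch-to-branch jump
    instead (the local linear model underestimates the gap where the
    elastic branches are strongly curved).
    """
    if min_jump <= 0:
        raise ValueError("min_jump must be > 0")
    n = len(trace)
    if n < 2 * window + 2:
        raise AnalysisError("trace shorter than detection window")
    sign = 1.0 if trace.direction == "stretch" else -1.0
    ext, f = trace.extension, trace.force

    dext = sign * np.diff(ext)            # dext[i]: jump between i and i+1
    # force extreme in the post window relative to the candidate sample
    post_extreme = np.zeros(n - 1)
    for i in range(n - 1):
        seg = f[i + 1 : min(n, i + 1 + window)]
        post_extreme[i] = (seg.min() if sign > 0 else seg.max()) - f[i]
    force_ok = sign * post_extreme <= -force_drop_min

    # a rip can straddle a block-averaged sample, splitting its jump over
    # two consecutive samples; screen on the two-sample jump as well
    dext2 = np.full(n - 1, -np.inf)
    dext2[: n - 2] = sign * (ext[2:] - ext[:-2])
    floor = jump_floor_frac * min_jump
    valid = np.zeros(n - 1, dtype=bool)
    valid[window - 1 : n - window - 1] = True
    cand = np.flatnonzero(
        ((dext >= floor) | (dext2 >= 1.6 * floor)) & force_ok & valid
    )
    direction = "unfold" if trace.direction == "stretch" else "refold"
    transitions: list[Transition] = []
    if cand.size == 0:
        return transitions

    # one representative (largest raw jump) per cluster of nearby candidates
    splits = np.flatnonzero(np.diff(cand) > window)
    for g in np.split(cand, splits + 1):
        i = int(g[np.argmax(dext[g])])
        jump = _pre_branch_gap(ext, f, i, window, sign)
        if jump < (0.0 if screen_only else min_jump):
            continue
        lo = max(0, i - force_window + 1)
        transitions.append(
            Transition(
                index=i,
                force_before=float(np.mean(f[lo : i + 1])),
                jump_nm=float(jump),
                dlc_nm=float("nan"),
                direction=direction,
            )
        )
    return transitions


def fit_branch_lc(
    extension: np.ndarray,
    force: np.ndarray,
    tether: TetherModel,
    sample_range: tuple[int, int] = (0, 0),
    min_samples: int = 5,
    min_force_range: float = 1.0,
) -> BranchFit:
    """Fit one elastic branch for the unfolded protein contour length.

    All elastic parameters are fixed; only the unfolded contour length is
    free, bounded to [0, 1.2 x full length].  Branches that are too short or
    span too little force are flagged rather than fitted.
    """
    ext = np.asarray(extension, dtype=float)
    f = np.asarray(force, dtype=float)
    f = np.clip(f, 0.0, None)     # tolerate small negative noise excursions
    if len(ext) < min_samples:
        return BranchFit(np.nan, np.nan, sample_range, True, "too few samples")
    if np.ptp(f) < min_force_range:
        return BranchFit(np.nan, np.nan, sample_range, True, "force range < 1 pN")

    hi = tether.full_unfolded_lc

    def ssr(lc: float) -> float:
        resid = ext - tether_extension(f, tether.with_unfolded_lc(lc))
        return float(np.dot(resid, resid))

    res = minimize_scalar(ssr, bounds=(0.0, hi), method="bounded",
                          options={"xatol": 1e-4})
    lc = float(res.x)
    rms = float(np.sqrt(res.fun / len(ext)))
    flagged = not res.success or lc > hi - 0.5
    reason = "" if not flagged else "fit at bound or non-convergence"
    return BranchFit(lc, rms, sample_range, flagged, reason)


def analyze_trace(
    trace: ForceExtensionTrace,
    tether: TetherModel,
    min_jump: float = 10.0,
    window: int = 6,
    force_window: int = 10,
) -> AnalyzedTrace:
    """Full per-trace pipeline: detect rips, fit branches, refine jumps.

    Rips whose WLC-refined jump falls below ``min_jump`` are dropped and the
    adjacent branches merged and refitted, so the surviving per-rip dLc
    values telescope exactly to the first-to-last branch difference.
    """
    transitions = detect_transitions(trace, min_jump, window, force_window,
                                     screen_only=True)
    n = len(trace)
    sign = 1.0 if trace.direction == "stretch" else -1.0

    while True:
        # branch k spans (rip k-1, rip k]; the sample straddling each rip is
        # excluded from the following branch (block averaging smears it
        # between the two elastic states)
        starts = [0] + [min(t.index + 2, n) for t in transitions]
        stops = [t.index + 1 for t in transitions] + [n]
        branches = [
            fit_branch_lc(
                trace.extension[a:b], trace.force[a:b], tether,
                sample_range=(a, b),
            )
            for a, b in zip(starts, stops)
        ]
        # closely spaced rips can leave an interior branch too short (or
        # spanning too little force) to fit: drop the rip at its right edge
        # so the two rips count as one transition with the combined release
        short = next(
            (k for k in range(1, len(branches) - 1) if branches[k].flagged),
            None,
        )
        if short is not None:
            del transitions[short]
            continue
        # refine jumps from branch fits; where a neighbouring branch is
        # unfittable fall back on the local screening estimate so spurious
        # candidates cannot deadlock the pruning
        weakest, weakest_jump = None, np.inf
        for k, t in enumerate(transitions):
            pre, post = branches[k], branches[k + 1]
            if pre.flagged or post.flagged:
                signed_jump = t.jump_nm
            else:
                f0 = max(t.force_before, 0.0)
                x_pre = tether_extension(f0, tether.with_unfolded_lc(pre.lc_nm))
                x_post = tether_extension(f0, tether.with_unfolded_lc(post.lc_nm))
                signed_jump = sign * (x_post - x_pre)
                t.jump_nm = abs(x_post - x_pre)
                t.dlc_nm = abs(post.lc_nm - pre.lc_nm)
            if signed_jump < min_jump and abs(signed_jump) < weakest_jump:
                weakest, weakest_jump = k, abs(signed_jump)
        if weakest is None:
            break
        del transitions[weakest]   # merge branches across the dropped rip

    return AnalyzedTrace(trace=trace, transitions=transitions, branches=branches)


def delta_lc(analyzed: AnalyzedTrace) -> dict:
    """Total and per-rip contour-length change of an analysed sweep.

    ``total_dlc`` is the contour-length difference between the final and the
    initial fitted branch (positive for net unfolding).  ``per_rip`` holds
    signed values (+ unfold, - refold) that telescope to the same total.
    """
    first, last = analyzed.branches[0], analyzed.branches[-1]
    if first.flagged:
        raise AnalysisError(f"initial branch unfittable: {first.reason}")
    if last.flagged:
        raise AnalysisError(f"final branch unfittable: {last.reason}")
    total = last.lc_nm - first.lc_nm
    per_rip = []
    for k, t in enumerate(analyzed.transitions):
        pre, post = analyzed.branches[k], analyzed.branches[k + 1]
        if pre.flagged or post.flagged:
            raise AnalysisError("interior branch unfittable")
        per_rip.append(post.lc_nm - pre.lc_nm)
    return {"total_dlc": float(total), "per_rip": [float(v) for v in per_rip]}


@dataclass
class DlcDistribution:
    counts: np.ndarray
    bin_edges: np.ndarray
    peaks_nm: list[float]         # KDE local maxima, descending height
    peak_heights: list[float]
    mode_nm: float                # global KDE maximum
    mode_se_nm: float             # bootstrap standard error of the mode
    bandwidth_nm: float


def _silverman_bw(v: np.ndarray) -> float:
    """Robust Silverman bandwidth: 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    sd = float(v.std(ddof=1))
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * scale * v.size ** (-0.2)


def _kde(values: np.ndarray) -> gaussian_kde:
    bw = _silverman_bw(values)
    return gaussian_kde(values, bw_method=bw / values.std(ddof=1))


def _kde_mode(values: np.ndarray, grid: np.ndarray) -> float:
    dens = _kde(values)(grid)
    return float(grid[np.argmax(dens)])


def dlc_distribution(
    values: Sequence[float],
    bin_width: float = 10.0,
    bootstrap_n: int = 200,
    seed: int = 0,
    prominence_frac: float = 0.1,
) -> DlcDistribution:
    """Histogram + kernel-density peak report for a set of dLc values.

    Peaks are local maxima of a Gaussian KDE (Silverman bandwidth) with
    prominence of at least ``prominence_frac`` of the density maximum; the
    global mode's uncertainty is a bootstrap standard error.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    lo = np.floor(v.min() / bin_width) * bin_width
    hi = np.ceil(v.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(v, bins=edges)

    if np.ptp(v) < 1e-12:         # degenerate: all values identical
        val = float(v[0])
        return DlcDistribution(counts, edges, [val], [np.inf], val, 0.0, 0.0)

    kde = _kde(v)
    bw = float(kde.factor * v.std(ddof=1))
    grid = np.linspace(v.min() - 3 * bw, v.max() + 3 * bw, 2048)
    dens = kde(grid)
    pk, _ = find_peaks(dens, prominence=prominence_frac * dens.max())
    order = np.argsort(dens[pk])[::-1]
    peaks = [float(grid[i]) for i in pk[order]]
    heights = [float(dens[i]) for i in pk[order]]
    mode = float(grid[np.argmax(dens)])

    rng = np.random.default_rng(seed)
    boot = np.empty(bootstrap_n)
    for b in range(bootstrap_n):
        res = rng.choice(v, size=v.size, replace=True)
        if np.ptp(res) < 1e-12:
            boot[b] = res[0]
        else:
            boot[b] = _kde_mode(res, grid)
    return DlcDistribution(counts, edges, peaks, heights, mode,
                           float(boot.std(ddof=1)), bw)


def _find_rupture(force: np.ndarray, baseline_pN: float) -> Optional[int]:
    """First index after the force maximum where the tether has broken
    (force at baseline and staying there); None if no rupture."""
    peak_i = int(np.argmax(force))
    below = force < baseline_pN
    for i in range(peak_i + 1, len(force)):
        if below[i] and bool(np.all(force[i:] < 2 * baseline_pN)):
            return i
    return None


def truncate_at_rupture(
    trace: ForceExtensionTrace, baseline_pN: float = 0.5
) -> ForceExtensionTrace:
    """Return the part of a sweep before tether rupture (or the sweep
    itself if no rupture is present)."""
    r = _find_rupture(trace.force, baseline_pN)
    if r is None:
        return trace
    peak = float(trace.force.max())
    j = r
    while j > 0 and trace.force[j - 1] < 0.7 * peak:
        j -= 1
    return ForceExtensionTrace(
        molecule_id=trace.molecule_id,
        cycle_index=trace.cycle_index,
        direction=trace.direction,
        time=trace.time[:j],
        extension=trace.extension[:j],
        force=trace.force[:j],
        sample_rate=trace.sample_rate,
    )


def validate_tether(
    traces: Sequence[ForceExtensionTrace],
    tether: TetherModel,
    expected_dlc: float,
    tol: float = 20.0,
    baseline_pN: float = 0.5,
    step_frac: float = 0.25,
    min_jump: float = 10.0,
) -> dict:
    """Single-tether QC for one molecule.

    Checks that (a) the largest per-cycle total dLc (analysed up to any
    rupture) matches the expected full release within ``tol`` and (b) the
    final rupture, if present, is a single force drop to baseline.
    Returns ``{"single_tether": bool|None, "reasons": [...]}``.
    """
    stretches = sorted(
        (t for t in traces if t.direction == "stretch"),
        key=lambda t: t.cycle_index,
    )
    if not stretches:
        return {"single_tether": None, "reasons": ["no stretch sweeps"]}
    reasons: list[str] = []
    totals = []
    for tr in stretches:
        try:
            a = analyze_trace(truncate_at_rupture(tr, baseline_pN), tether,
                              min_jump=min_jump)
            totals.append(delta_lc(a)["total_dlc"])
        except AnalysisError:
            continue
    if not totals:
        return {"single_tether": None, "reasons": ["no analysable stretch"]}
    max_dlc = max(totals)
    length_ok = abs(max_dlc - expected_dlc) <= tol
    if not length_ok:
        reasons.append(
            f"unfolded length mismatch: {max_dlc:.1f} vs expected {expected_dlc:.1f}"
        )

    # rupture structure on the final stretch sweep
    force = stretches[-1].force
    r = _find_rupture(force, baseline_pN)
    if r is None:
        reasons.append("no rupture observed")
        return {"single_tether": None if length_ok else False, "reasons": reasons}
    peak = float(force.max())
    lo = max(0, r - 5)
    df = np.diff(force[lo : r + 1])
    n_steps = int(np.sum(df < -step_frac * peak))
    if n_steps > 1:
        reasons.append("multi-step rupture")
    single = length_ok and n_steps <= 1
    return {"single_tether": bool(single), "reasons": reasons}
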