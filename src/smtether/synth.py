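"""Seeded synthetic-data generators for every pipeline input.

Force-extension sweeps are produced by a kinetic Monte Carlo scheme: the
trap separation advances at constant velocity, the force at each step solves
the trap + tether force balance for the currently-unfolded contour length,
and each folded domain unfolds (or each unfolded domain refolds, during
relax) as an inhomogeneous Poisson process with the Bell rate
``k(F) = k0 * exp(+-F dx / kT)``.  Measurement noise is Gaussian and added
after block-averaging to the analysis rate.

Misfolded cycles freeze a random subset of domains (unfolding rate zero),
capping the achievable contour-length release; locked cycles start fully
unfolded with refolding disabled.  Every sweep carries ground-truth labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .config import DEFAULTS
from .fec import ForceExtensionTrace, downsample
from .polymer import TetherModel, make_tether, tether_extension

__all__ = [
    "DomainKinetics",
    "EnsembleSpec",
    "CyclePlan",
    "simulate_fec",
    "build_plans",
    "inject_misfold",
    "inject_locked",
    "calibrate_unfolding_rate",
    "mean_complete_unfold_force",
    "make_preset",
    "simulate_titration",
    "simulate_melt",
    "PRESET_NAMES",
]

_F_HI = 150.0   # pN, upper bracket for the force balance


@dataclass(frozen=True)
class DomainKinetics:
    """One cooperatively-unfolding domain of the tandem-repeat protein."""

    dlc_nm: float        # contour length released on unfolding
    k0_unfold: float     # 1/s at zero force
    dx_unfold: float     # nm, distance to the unfolding barrier
    k0_refold: float     # 1/s at zero force
    dx_refold: float     # nm, distance to the refolding barrier

    def __post_init__(self) -> None:
        for name in ("dlc_nm", "k0_unfold", "dx_unfold", "k0_refold", "dx_refold"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class EnsembleSpec:
    """Full description of a synthetic pulling ensemble."""

    domains: tuple[DomainKinetics, ...]
    pulling_speed: float = 100.0        # nm/s
    trap_stiffness: float = 0.3         # pN/nm (single effective spring)
    noise_sd_ext: float = 1.0           # nm, at the analysis rate
    noise_sd_force: float = 0.1         # pN, at the analysis rate
    p_misfold: float = 0.0              # per post-first cycle
    p_locked: float = 0.0               # per post-first cycle
    n_molecules: int = 1
    cycles_per_molecule: int = 1
    seed: int = 0
    sim_rate: float = 1000.0            # Hz, kinetic time step
    output_rate: float = 100.0          # Hz, analysis rate after averaging
    max_force: float = 18.0             # pN, stretch turnaround
    start_force: float = 2.5            # pN, sweep preload at the low end
    include_relax: bool = True
    rupture: Optional[str] = None       # None | "single" | "double"
    tether_cfg: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULTS))

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_misfold <= 1.0:
            raise ValueError("p_misfold must be in [0, 1]")
        if not 0.0 <= self.p_locked <= 1.0:
            raise ValueError("p_locked must be in [0, 1]")
        if not self.pulling_speed > 0:
            raise ValueError("pulling_speed must be > 0")
        if self.rupture not in (None, "single", "double"):
            raise ValueError("rupture must be None, 'single' or 'double'")

    @property
    def total_dlc(self) -> float:
        return sum(d.dlc_nm for d in self.domains)


@dataclass
class CyclePlan:
    molecule: int
    cycle: int                          # 1-based
    misfold_domains: Optional[tuple[int, ...]] = None
    locked: bool = False


class _ForceBalance:
    """Interpolated inverse of X_total(F) per unfolded-Lc state."""

    def __init__(self, tether: TetherModel, k_trap: float) -> None:
        self.tether = tether
        self.k_trap = k_trap
        # dense at low force where curvature is largest
        self.f_grid = np.concatenate(
            [np.linspace(0.0, 3.0, 300, endpoint=False),
             np.linspace(3.0, _F_HI, 600)]
        )
        self._tables: dict[float, np.ndarray] = {}

    def solve(self, x: np.ndarray, lc_unf: float) -> np.ndarray:
        key = round(lc_unf, 6)
        table = self._tables.get(key)
        if table is None:
            model = self.tether.with_unfolded_lc(lc_unf)
            table = tether_extension(self.f_grid, model) + self.f_grid / self.k_trap
            self._tables[key] = table
        return np.interp(x, table, self.f_grid)


def _sweep(
    rng: np.random.Generator,
    x: np.ndarray,
    dt: float,
    folded: np.ndarray,
    spec: EnsembleSpec,
    fb: _ForceBalance,
    direction: str,
    frozen: frozenset[int],
    refold_enabled: bool,
) -> tuple[np.ndarray, list[tuple[int, int]], np.ndarray]:
    """Simulate one sweep; returns (force, events, final folded mask).

    ``events`` are (sim-sample index, domain index) pairs; the state flip is
    effective from the following sample.
    """
    kT = spec.tether_cfg["kT_pN_nm"]
    domains = spec.domains
    n = len(x)
    force = np.empty(n)
    folded = folded.copy()
    events: list[tuple[int, int]] = []
    i = 0
    while i < n:
        lc_unf = sum(d.dlc_nm for d, f in zip(domains, folded) if not f)
        f_rem = fb.solve(x[i:], lc_unf)
        best_j, best_d = None, None
        for di, dom in enumerate(domains):
            if direction == "stretch":
                if not folded[di] or di in frozen:
                    continue
                rate = dom.k0_unfold * np.exp(f_rem * dom.dx_unfold / kT)
            else:
                if folded[di] or not refold_enabled:
                    continue
                rate = dom.k0_refold * np.exp(-f_rem * dom.dx_refold / kT)
            hazard = np.cumsum(rate) * dt
            j = int(np.searchsorted(hazard, rng.exponential()))
            if j < len(f_rem) and (best_j is None or j < best_j):
                best_j, best_d = j, di
        if best_j is None:
            force[i:] = f_rem
            break
        force[i : i + best_j + 1] = f_rem[: best_j + 1]
        folded[best_d] = not folded[best_d]
        events.append((i + best_j, best_d))
        i += best_j + 1
    return force, events, folded


def build_plans(spec: EnsembleSpec) -> list[CyclePlan]:
    """One plan entry per (molecule, cycle), all unperturbed."""
    return [
        CyclePlan(molecule=m, cycle=c)
        for m in range(spec.n_molecules)
        for c in range(1, spec.cycles_per_molecule + 1)
    ]


def inject_misfold(
    plans: Sequence[CyclePlan],
    p_misfold: float,
    rng: np.random.Generator | int,
    n_domains: int,
) -> list[CyclePlan]:
    """Mark post-first cycles as misfolded with probability ``p_misfold``.

    A misfolded cycle freezes a random non-empty proper subset of domains
    (unfolding rate zero), so the achievable release stays below the full
    length.  First pulls are never eligible.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    out = []
    for plan in plans:
        plan = replace(plan)
        if plan.cycle >= 2 and not plan.locked and rng.random() < p_misfold:
            size = int(rng.integers(1, n_domains))  # 1 .. n_domains-1
            chosen = rng.choice(n_domains, size=size, replace=False)
            plan.misfold_domains = tuple(sorted(int(d) for d in chosen))
        out.append(plan)
    return out


def inject_locked(
    plans: Sequence[CyclePlan],
    p_locked: float,
    rng: np.random.Generator | int,
) -> list[CyclePlan]:
    """Mark post-first cycles as locked-unfolded with probability ``p_locked``."""
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    out = []
    for plan in plans:
        plan = replace(plan)
        if plan.cycle >= 2 and rng.random() < p_locked:
            plan.locked = True
            plan.misfold_domains = None
        out.append(plan)
    return out


def _append_rupture(
    x: np.ndarray, force: np.ndarray, mode: str, k_trap: float,
    v: float, dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Extend a stretch sweep with a tether-rupture tail (sim rate)."""
    n_tail = 60
    x_tail = x[-1] + v * dt * (1 + np.arange(n_tail))
    peak = force[-1]
    f_tail = np.full(n_tail, 0.05)
    if mode == "double":
        f_tail[:30] = 0.5 * peak    # intermediate level: second tether holds
    return np.concatenate([x, x_tail]), np.concatenate([force, f_tail])


def simulate_fec(
    spec: EnsembleSpec, plans: Optional[Sequence[CyclePlan]] = None
) -> tuple[list[ForceExtensionTrace], list[dict]]:
    """Simulate a pulling ensemble.

    Returns analysis-rate traces (stretch, and relax if enabled, per cycle)
    and one ground-truth label dict per sweep with keys ``molecule_id``,
    ``cycle_index``, ``direction``, ``fate``, ``rips`` (index / dlc_nm /
    force_pN at the analysis rate), ``total_dlc`` and the unfolded contour
    length at the sweep boundaries.
    """
    rng = np.random.default_rng(spec.seed)
    cfg = spec.tether_cfg
    tether = make_tether(cfg)
    fb = _ForceBalance(tether, spec.trap_stiffness)
    n_dom = len(spec.domains)
    kT = cfg["kT_pN_nm"]

    if plans is None:
        plans = build_plans(spec)
        plans = inject_locked(plans, spec.p_locked, rng)
        plans = inject_misfold(plans, spec.p_misfold, rng, n_dom)
    plan_map = {(p.molecule, p.cycle): p for p in plans}

    # sweep geometry: from low force (folded) to max force (fully unfolded)
    x_lo = float(
        tether_extension(spec.start_force, tether.with_unfolded_lc(0.0))
        + spec.start_force / spec.trap_stiffness
    )
    x_hi = float(
        tether_extension(spec.max_force, tether.with_unfolded_lc(spec.total_dlc))
        + spec.max_force / spec.trap_stiffness
    )
    dt = 1.0 / spec.sim_rate
    n_steps = int(round((x_hi - x_lo) / (spec.pulling_speed * dt)))
    x_up = x_lo + spec.pulling_speed * dt * np.arange(n_steps)
    block = int(round(spec.sim_rate / spec.output_rate))
    fw = int(DEFAULTS["force_window_samples"])

    traces: list[ForceExtensionTrace] = []
    labels: list[dict] = []

    for m in range(spec.n_molecules):
        mol_id = f"mol{m:04d}"
        folded = np.ones(n_dom, dtype=bool)
        for c in range(1, spec.cycles_per_molecule + 1):
            plan = plan_map.get((m, c), CyclePlan(m, c))
            frozen = frozenset(plan.misfold_domains or ())
            if plan.locked:
                folded[:] = False
            elif c > 1:
                folded[:] = True    # full refolding between cycles

            for direction in ("stretch", "relax") if spec.include_relax else ("stretch",):
                if direction == "stretch":
                    x_cmd = x_up
                else:
                    x_cmd = x_up[::-1]
                lc_start = sum(
                    d.dlc_nm for d, f in zip(spec.domains, folded) if not f
                )
                force, events, folded = _sweep(
                    rng, x_cmd, dt, folded, spec, fb, direction,
                    frozen, refold_enabled=not plan.locked,
                )
                x_used = x_cmd
                if (
                    direction == "stretch"
                    and spec.rupture is not None
                    and c == spec.cycles_per_molecule
                ):
                    x_used, force = _append_rupture(
                        x_cmd, force, spec.rupture, spec.trap_stiffness,
                        spec.pulling_speed, dt,
                    )
                ext = x_used - force / spec.trap_stiffness
                hi = ForceExtensionTrace(
                    molecule_id=mol_id,
                    cycle_index=c,
                    direction=direction,
                    time=np.arange(len(x_used)) * dt,
                    extension=ext,
                    force=force,
                    sample_rate=spec.sim_rate,
                )
                ds = downsample(hi, spec.output_rate)
                f_clean = ds.force.copy()
                ds.extension = ds.extension + rng.normal(
                    0.0, spec.noise_sd_ext, len(ds)
                )
                ds.force = ds.force + rng.normal(
                    0.0, spec.noise_sd_force, len(ds)
                )
                rips = []
                for (i_sim, di) in events:
                    i_out = min(i_sim // block, len(ds) - 1)
                    lo = max(0, i_out - fw + 1)
                    rips.append({
                        "index": int(i_out),
                        "domain": int(di),
                        "dlc_nm": float(spec.domains[di].dlc_nm),
                        "force_pN": float(np.mean(f_clean[lo : i_out + 1])),
                    })
                lc_end = sum(
                    d.dlc_nm for d, f in zip(spec.domains, folded) if not f
                )
                if plan.locked:
                    fate = "locked_unfolded"
                elif frozen:
                    fate = "misfolded"
                elif direction == "stretch" and lc_end < spec.total_dlc - 1e-9:
                    fate = "misfolded"   # stochastic failure to fully unfold
                else:
                    fate = "complete"
                traces.append(ds)
                labels.append({
                    "molecule_id": mol_id,
                    "cycle_index": c,
                    "direction": direction,
                    "fate": fate,
                    "rips": rips,
                    "total_dlc": float(
                        (lc_end - lc_start) if direction == "stretch"
                        else (lc_start - lc_end)
                    ),
                    "lc_unf_start": float(lc_start),
                    "lc_unf_end": float(lc_end),
                })
    return traces, labels


def mean_complete_unfold_force(labels: Sequence[dict]) -> float:
    """Mean force of the final unfolding rip over complete stretch sweeps."""
    forces = [
        lab["rips"][-1]["force_pN"]
        for lab in labels
        if lab["direction"] == "stretch" and lab["fate"] == "complete"
        and lab["rips"]
    ]
    if not forces:
        raise ValueError("no complete stretch sweeps with rips")
    return float(np.mean(forces))


def scale_unfold_rates(
    domains: Sequence[DomainKinetics], factor: float
) -> tuple[DomainKinetics, ...]:
    return tuple(replace(d, k0_unfold=d.k0_unfold * factor) for d in domains)


def calibrate_unfolding_rate(
    spec: EnsembleSpec,
    target_force: float,
    n_traces: int = 200,
    seed: int = 12345,
    tol: float = 0.05,
    max_iter: int = 25,
) -> tuple[EnsembleSpec, float]:
    """Bisection on a common k0_unfold scale factor to hit a target mean
    complete-unfolding force.

    Returns the calibrated spec (same seed as the input spec) and the scale
    factor.  Evaluations use a fixed internal seed so the objective is a
    deterministic, monotone-decreasing function of the scale.
    """
    base = replace(
        spec, n_molecules=n_traces, cycles_per_molecule=1,
        include_relax=False, p_misfold=0.0, p_locked=0.0, seed=seed,
    )

    def mean_force(log_s: float) -> float:
        trial = replace(base, domains=scale_unfold_rates(spec.domains, 10.0 ** log_s))
        _, labels = simulate_fec(trial)
        return mean_complete_unfold_force(labels)

    lo, hi = -4.0, 4.0   # mean force decreases with log_s
    f_lo, f_hi = mean_force(lo), mean_force(hi)
    if not (f_hi <= target_force <= f_lo):
        raise ValueError(
            f"target {target_force} pN outside achievable range "
            f"[{f_hi:.2f}, {f_lo:.2f}]"
        )
    mid = 0.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = mean_force(mid)
        if abs(f_mid - target_force) < tol:
            break
        if f_mid > target_force:
            lo = mid
        else:
            hi = mid
    factor = 10.0 ** mid
    return replace(spec, domains=scale_unfold_rates(spec.domains, factor)), factor


# ---------------------------------------------------------------------------
# condition presets
# ---------------------------------------------------------------------------

PRESET_NAMES = ("no_smap", "atux", "dbk")

# Zero-force unfolding rates below were fixed by running
# calibrate_unfolding_rate against the condition's target mean
# complete-unfolding force at 100 nm/s (see make_preset docstring).
_BASE_REFOLD = {"k0_refold": 1000.0, "dx_refold": 6.0}

_PRESET_DOMAINS = {
    # heterogeneous stabilities; dlc values sum to the condition total
    "no_smap": [
        dict(dlc_nm=40.0, k0_unfold=2.60e-4, dx_unfold=6.0, **_BASE_REFOLD),
        dict(dlc_nm=50.0, k0_unfold=1.73e-4, dx_unfold=6.0, **_BASE_REFOLD),
        dict(dlc_nm=52.0, k0_unfold=1.30e-4, dx_unfold=6.0, **_BASE_REFOLD),
        dict(dlc_nm=56.0, k0_unfold=8.66e-5, dx_unfold=6.0, **_BASE_REFOLD),
    ],
    # globally stabilised: same architecture, higher barriers
    "atux": [
        dict(dlc_nm=40.0, k0_unfold=8.22e-6, dx_unfold=6.0, **_BASE_REFOLD),
        dict(dlc_nm=50.0, k0_unfold=5.48e-6, dx_unfold=6.0, **_BASE_REFOLD),
        dict(dlc_nm=50.0, k0_unfold=4.11e-6, dx_unfold=6.0, **_BASE_REFOLD),
        dict(dlc_nm=56.0, k0_unfold=2.74e-6, dx_unfold=6.0, **_BASE_REFOLD),
    ],
    # weak folded-state binding: no-SMAP-like stabilities, but locking
    "dbk": [
        dict(dlc_nm=40.0, k0_unfold=2.60e-4, dx_unfold=6.0, **_BASE_REFOLD),
        dict(dlc_nm=50.0, k0_unfold=1.73e-4, dx_unfold=6.0, **_BASE_REFOLD),
        dict(dlc_nm=52.0, k0_unfold=1.30e-4, dx_unfold=6.0, **_BASE_REFOLD),
        dict(dlc_nm=56.0, k0_unfold=8.66e-5, dx_unfold=6.0, **_BASE_REFOLD),
    ],
}


def make_preset(
    name: str,
    cfg: Optional[Mapping[str, float]] = None,
    n_molecules: int = 16,
    cycles_per_molecule: int = 2,
    seed: int = 0,
    include_relax: bool = True,
    **overrides,
) -> EnsembleSpec:
    """Build the EnsembleSpec for one experimental condition.

    * ``no_smap``: heterogeneous four-domain kinetics, misfolding enabled.
    * ``atux``: misfolding disabled, higher unfolding barriers.
    * ``dbk``: locking enabled from the second cycle onward.

    Domain kinetic constants are not observable quantities; they were tuned
    with :func:`calibrate_unfolding_rate` so the simulated ensembles
    reproduce the configured condition observables (mean unfolding force,
    total release, misfolded/locked fractions).
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    cfg = dict(DEFAULTS) if cfg is None else dict(cfg)
    domains = tuple(DomainKinetics(**d) for d in _PRESET_DOMAINS[name])
    p_misfold = cfg["p_misfold_no_smap"] if name == "no_smap" else 0.0
    p_locked = cfg["p_locked_dbk"] if name == "dbk" else 0.0
    return EnsembleSpec(
        domains=domains,
        pulling_speed=cfg["pulling_speed_nm_s"],
        trap_stiffness=cfg["trap_stiffness_pN_nm"],
        noise_sd_ext=cfg["noise_sd_ext_nm"],
        noise_sd_force=cfg["noise_sd_force_pN"],
        p_misfold=p_misfold,
        p_locked=p_locked,
        n_molecules=n_molecules,
        cycles_per_molecule=cycles_per_molecule,
        seed=seed,
        sim_rate=cfg["sim_rate_hz"],
        output_rate=cfg["analysis_rate_hz"],
        max_force=cfg["max_force_pN"],
        include_relax=include_relax,
        tether_cfg=cfg,
        **overrides,
    )


# ---------------------------------------------------------------------------
# ensemble assay generators
# ---------------------------------------------------------------------------

def simulate_titration(
    kd: float,
    pmax: float,
    concs: Sequence[float],
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
    background: float = 0.0,
):
    """Synthetic one-site FP titrations: P = Pmax C / (Kd + C) + noise.

    Returns a list of :class:`~smtether.binding.TitrationSeries` with the
    ground truth attached as ``.ground_truth``.
    """
    from .binding import TitrationSeries

    rng = np.random.default_rng(seed)
    c = np.asarray(list(concs), dtype=float)
    series = []
    for r in range(n_replicates):
        p = background + pmax * c / (kd + c) + rng.normal(0.0, noise_sd, c.size)
        s = TitrationSeries(protein_conc=c, polarization_mP=p,
                            replicate=f"r{r + 1}")
        s.ground_truth = {"kd": kd, "pmax": pmax, "background": background}
        series.append(s)
    return series


def simulate_melt(
    tm: float,
    transition_width: float = 4.0,
    baselines: tuple[float, float] = (0.85, 1.10),
    ramp: tuple[float, float, float] = (20.0, 90.0, 1.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    f330_level: float = 10000.0,
):
    """Synthetic two-state nanoDSF melt curve.

    The 350/330 ratio follows a logistic between the two baselines with
    midpoint ``tm``; ``transition_width`` is the 10-90% width in deg C.
    ``noise_sd`` is the relative (fractional) noise applied independently to
    both fluorescence channels.  Returns a
    :class:`~smtether.binding.MeltCurve` with ``.ground_truth`` attached.
    """
    from .binding import MeltCurve

    rng = np.random.default_rng(seed)
    t0, t1, step = ramp
    t = np.arange(t0, t1 + 0.5 * step, step)
    scale = transition_width / (2.0 * math.log(9.0))
    frac = 1.0 / (1.0 + np.exp(-(t - tm) / scale))
    ratio = baselines[0] + (baselines[1] - baselines[0]) * frac
    f330 = np.full_like(t, f330_level)
    f350 = f330 * ratio
    f330 = f330 * (1.0 + rng.normal(0.0, noise_sd, t.size))
    f350 = f350 * (1.0 + rng.normal(0.0, noise_sd, t.size))
    curve = MeltCurve(temperature=t, f330=f330, f350=f350)
    curve.ground_truth = {
        "tm": tm, "transition_width": transition_width, "baselines": baselines,
    }
    return curve
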