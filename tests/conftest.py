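"""Shared fixtures and trace-construction helpers."""

from __future__ import annotations

import numpy as np
import pytest

from smtether.config import DEFAULTS
from smtether.fec import ForceExtensionTrace
from smtether.polymer import WLCParams, make_tether, tether_extension
from smtether.synth import make_preset, simulate_fec


@pytest.fixture(scope="session")
def cfg():
    return dict(DEFAULTS)


@pytest.fixture(scope="session")
def tether(cfg):
    return make_tether(cfg)


@pytest.fixture(scope="session")
def protein_unit(cfg):
    """Unit-contour-length unfolded-protein WLC (fractional extension helper)."""
    return WLCParams(
        persistence_length=cfg["lp_protein_nm"],
        contour_length=1.0,
        stretch_modulus=cfg["k_protein_pN"],
        kT=cfg["kT_pN_nm"],
    )


@pytest.fixture(scope="session")
def small_ensemble(cfg):
    """50 stretch+relax cycles of the no-SMAP preset, with labels."""
    spec = make_preset("no_smap", cfg, n_molecules=50, cycles_per_molecule=1,
                       seed=123, include_relax=True)
    traces, labels = simulate_fec(spec)
    return spec, traces, labels


def make_trap_trace(
    tether,
    lc_before: float,
    lc_after: float,
    switch_force: float,
    k_trap: float = 0.3,
    f_lo: float = 2.5,
    f_hi: float = 12.0,
    n: int = 400,
    direction: str = "stretch",
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_rate: float = 100.0,
):
    """Noiseless (by default) constant-velocity sweep with one state switch.

    The trap separation ramps linearly between the balance points of
    (f_lo, lc_before) and (f_hi, lc_after); the unfolded contour length
    switches when the instantaneous force first crosses ``switch_force``.
    Returns (trace, rip_index) where rip_index is the last pre-switch
    sample (None if lc_before == lc_after).
    """
    def balance_x(force, lc):
        return tether_extension(force, tether.with_unfolded_lc(lc)) + force / k_trap

    x = np.linspace(balance_x(f_lo, lc_before), balance_x(f_hi, lc_after), n)
    f_grid = np.linspace(0.0, 60.0, 2000)

    def solve(xv, lc):
        table = tether_extension(f_grid, tether.with_unfolded_lc(lc)) + f_grid / k_trap
        return np.interp(xv, table, f_grid)

    force = solve(x, lc_before)
    rip = None
    if lc_after != lc_before:
        crossed = np.flatnonzero(force >= switch_force)
        rip = int(crossed[0])
        force[rip + 1:] = solve(x[rip + 1:], lc_after)
    ext = x - force / k_trap
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ext = ext + rng.normal(0.0, noise_sd, n)
    if direction == "relax":
        ext, force = ext[::-1].copy(), force[::-1].copy()
        rip = None if rip is None else n - 2 - rip
    trace = ForceExtensionTrace(
        molecule_id="test", cycle_index=1, direction=direction,
        time=np.arange(n) / sample_rate, extension=ext, force=force,
        sample_rate=sample_rate,
    )
    return trace, rip


def gap_to_dlc(gap_nm: float, force: float, protein_unit) -> float:
    """Contour-length change whose branch-to-branch extension gap at the
    given force equals ``gap_nm`` (WLC extension is linear in Lc)."""
    from smtether.polymer import wlc_extension

    return gap_nm / wlc_extension(force, protein_unit)
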