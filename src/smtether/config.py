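"""Run configuration: defaults, file loading, merging, and provenance hashing.

Every analysis and simulation entry point takes a plain dict built from
:data:`DEFAULTS`, optionally updated from a YAML file and keyword overrides.
Outputs embed :func:`config_hash` so that any result can be traced back to the
exact parameter set that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

#: Default parameter set. Values with a literal experimental provenance
#: (elastic constants, acquisition rates, condition observables) live here so
#: a single file controls every stage of the pipeline.
DEFAULTS: dict[str, Any] = {
    # --- polymer / tether elasticity -------------------------------------
    "lp_dna_nm": 30.0,            # dsDNA handle persistence length
    "lp_protein_nm": 0.5,         # unfolded polypeptide persistence length
    "k_dna_pN": 500.0,            # handle stretch modulus (midpoint of 400-600)
    "k_protein_pN": 300.0,        # polypeptide stretch modulus
    "kT_pN_nm": 4.114,            # thermal energy at 298 K
    "handle_bp": 600,             # basepairs per handle
    "n_handles": 2,               # handles on each terminus
    "bp_to_nm": 0.338,            # dsDNA rise per basepair
    "residues": 585,              # 15 repeats x 39 aa
    "nm_per_residue": 0.365,      # contour length per unfolded residue
    "folded_core_nm": 13.525,     # rigid folded-state end-to-end contribution
    # --- acquisition / trace processing ----------------------------------
    "acquisition_rate_hz": 78000.0,
    "analysis_rate_hz": 100.0,
    "pulling_speed_nm_s": 100.0,
    "min_jump_nm": 10.0,          # minimum branch-to-branch extension jump
    "force_window_samples": 10,   # pre-rip averaging window for F_before
    "detect_window_samples": 6,   # rolling-fit window for rip candidates
    "bin_width_nm": 10.0,         # default histogram bin width for dLc
    "bootstrap_n": 200,           # resamples for mode standard error
    "single_tether_tol_nm": 20.0, # |max dLc - expected| gate for tether QC
    # --- classification ---------------------------------------------------
    "completeness_fraction": 0.9,
    "locked_tol_nm": 20.0,
    # --- simulation -------------------------------------------------------
    "trap_stiffness_pN_nm": 0.3,
    "sim_rate_hz": 1000.0,
    "noise_sd_ext_nm": 1.0,
    "noise_sd_force_pN": 0.1,
    "max_force_pN": 18.0,         # stretch turnaround force (fully unfolded)
    # --- condition observables (used to parameterise synthetic presets) ---
    "dlc_total_no_smap_nm": 198.0,
    "dlc_total_atux_nm": 196.0,
    "mean_unfold_force_pN": 7.2,
    "p_misfold_no_smap": 0.22,
    "p_locked_dbk": 0.33,
    # --- binding assays ---------------------------------------------------
    "kd_uM": 4.7,
    "pmax_mP": 100.0,
    "tm_apo_C": 52.7,
    "tm_holo_C": 53.5,
    "melt_t_start_C": 20.0,
    "melt_t_stop_C": 90.0,
    "melt_t_step_C": 1.0,
    "melt_width_C": 4.0,          # 10-90% transition width of the melt sigmoid
    "savgol_window_C": 5.0,
    "savgol_order": 2,
}


def load_config(path: str | Path | None = None, **overrides: Any) -> dict[str, Any]:
    """Build a config dict: defaults <- YAML file (if given) <- overrides.

    Unknown keys in the file or overrides are rejected to catch typos.
    """
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        _check_keys(loaded)
        cfg.update(loaded)
    _check_keys(overrides)
    cfg.update(overrides)
    return cfg


def _check_keys(mapping: Mapping[str, Any]) -> None:
    unknown = set(mapping) - set(DEFAULTS)
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Short stable hash of a config dict, for output provenance stamps."""
    canon = json.dumps(dict(sorted(cfg.items())), sort_keys=True, default=float)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def save_config(cfg: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
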