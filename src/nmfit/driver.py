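"""Orchestration of the fitting loop over replicas.

Three methods share one cycle/convergence skeleton:

* ``mdff``      — continuous map-biased MD, chunked into cycles for logging;
* ``mdff_nm``   — each cycle recomputes elastic-network modes on the current
                  structure, draws mode combinations until one improves the
                  map cross-correlation, injects Ek kcal/mol of kinetic
                  energy along it, then runs a biased MD segment;
* ``cmdff``     — cascade: plain biased MD against progressively less
                  blurred maps, finishing on the native map.

A replica converges when the reference cross-correlation fails to increase
for ``window`` consecutive cycles (the biased-MD segment is not gated, so
c.c can decrease; the best-scoring structure seen is tracked and returned
alongside the final one). Replicas are independent: replica ``i`` uses seed
``master_seed + i`` and its own RNG streams, so an ensemble gives identical
results run serially or concurrently.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .density import DensityMap, blur_map, cc_structure, potential_grid
from .dynamics import (ForceFieldConfig, HeatSchedule, MDState,
                       build_forcefield, heat_and_equilibrate,
                       maxwell_boltzmann_velocities, md_segment)
from .excitation import combine_modes, excite_velocities, select_modes, trial_test
from .model_io import Structure, select_ca, rmsd
from .nma import rtb_modes

__all__ = ["FitConfig", "FitTrajectory", "ReplicaState",
           "run_replica_mdff_nm", "run_replica_mdff", "run_replica_cmdff",
           "run_replica", "run_ensemble", "save_checkpoint", "load_checkpoint"]


@dataclass
class FitConfig:
    """Run configuration; defaults follow the reference protocol
    (3-mode combinations from the lowest-frequency 1% of the spectrum,
    Ek = 50 kcal/mol, gscale = 0.3, convergence after 2 non-improving
    cycles)."""

    method: str = "mdff_nm"
    replicas: int = 10
    k_modes: int = 3
    pool_fraction: float = 0.01
    Ek: float = 50.0
    gscale: float = 0.3
    resolution: float = 5.0
    segment_ps: float = 1.0
    dt: float = 1.0                # fs
    temperature: float = 300.0
    gamma: float = 1.0             # ps^-1
    max_cycles: int = 200
    window: int = 2
    amplitude: float = 0.5         # mass-weighted RMS trial displacement, Å
    seed: int = 0
    cascade: tuple | None = None   # resolutions coarse->fine, e.g. (9,8,7,6,5)
    cascade_stage_cycles: int = 2  # cycles per blurred stage (2 ps at 1 ps/cycle)
    selection_law: str = "inverse"
    retry_budget: int = 50
    recompute_modes_every: int = 1
    use_rtb: bool = True
    equilibrate: bool = False      # run heat/equilibrate before the loop
    heat_schedule: HeatSchedule = field(default_factory=HeatSchedule)
    ff_config: ForceFieldConfig = field(default_factory=ForceFieldConfig)

    def __post_init__(self):
        if self.replicas < 1 or self.k_modes < 1:
            raise ValueError("replicas and k_modes must be >= 1")
        if not (0 < self.pool_fraction <= 1):
            raise ValueError("pool_fraction must be in (0, 1]")
        if self.Ek <= 0 or self.window < 1:
            raise ValueError("Ek must be > 0 and window >= 1")

    @property
    def segment_steps(self) -> int:
        return max(1, int(round(self.segment_ps * 1000.0 / self.dt)))


@dataclass
class FitTrajectory:
    """Per-cycle record of a replica run."""

    rows: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)  # (N,3) coords per cycle

    def append(self, row: dict, coords: np.ndarray):
        self.rows.append(row)
        self.snapshots.append(coords.copy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def __len__(self):
        return len(self.rows)


@dataclass
class ReplicaState:
    replica_id: int
    seed: int
    cycle: int
    structure: Structure
    md: MDState
    cc_ref: float
    history: FitTrajectory
    best_cc: float
    best_coords: np.ndarray
    best_cycle: int
    no_improve: int = 0
    converged: bool = False
    mode_rng_state: dict | None = None

    @property
    def best_structure(self) -> Structure:
        return self.structure.with_coords(self.best_coords)


def _init_replica(S1: Structure, tm: DensityMap, cfg: FitConfig, seed: int,
                  replica_id: int, ff):
    """Common setup: RNG streams, initial velocities, reference c.c."""
    rng_md = np.random.default_rng([seed, 2])
    if cfg.equilibrate:
        st = heat_and_equilibrate(S1, ff, cfg.heat_schedule, rng=rng_md)
        st.temperature, st.gamma, st.dt = cfg.temperature, cfg.gamma, cfg.dt
        structure = S1.with_coords(st.coords)
    else:
        v0 = maxwell_boltzmann_velocities(S1.masses, cfg.temperature, rng_md)
        st = MDState(coords=S1.coords.copy(), velocities=v0, dt=cfg.dt,
                     temperature=cfg.temperature, gamma=cfg.gamma, rng=rng_md)
        structure = S1.copy()
    cc_ref = cc_structure(structure, tm, cfg.resolution)
    return ReplicaState(
        replica_id=replica_id, seed=seed, cycle=0, structure=structure,
        md=st, cc_ref=cc_ref, history=FitTrajectory(),
        best_cc=cc_ref, best_coords=structure.coords.copy(), best_cycle=0)


def _post_cycle(state: ReplicaState, tm, cfg, target, target_sel, sel_self,
                row_extra, t0):
    """Re-measure c.c from the segment's last frame, update best-so-far and
    the convergence counter, and append the history row."""
    s_new = state.structure.with_coords(state.md.coords)
    cc_new = cc_structure(s_new, tm, cfg.resolution)
    state.cycle += 1
    improved = cc_new > state.cc_ref
    state.no_improve = 0 if improved else state.no_improve + 1
    state.cc_ref = cc_new
    state.structure = s_new
    if cc_new > state.best_cc:
        state.best_cc = cc_new
        state.best_coords = state.md.coords.copy()
        state.best_cycle = state.cycle
    row = {"cycle": state.cycle, "cc_ref": cc_new,
           "rmsd_target": np.nan, "wall_time": time.perf_counter() - t0}
    if target is not None:
        # map-frame RMSD: the target map fixes the reference frame, so no
        # superposition is applied (matching how fitting quality is scored)
        row["rmsd_target"] = rmsd(s_new, target, sel_self, target_sel,
                                  superpose=False)
    row.update(row_extra)
    state.history.append(row, state.md.coords)
    if state.no_improve >= cfg.window:
        state.converged = True
    return state


def _target_selections(structure, target):
    if target is None:
        return None, None
    return select_ca(structure), select_ca(target)


def run_replica_mdff_nm(S1: Structure, tm: DensityMap, cfg: FitConfig,
                        seed: int, target: Structure | None = None,
                        replica_id: int = 0,
                        resume: ReplicaState | None = None) -> ReplicaState:
    """One replica of the mode-excited fitting loop.

    Per cycle: recompute elastic-network modes on the current structure,
    stochastically select/combine modes, accept a combination only if the
    trial displacement raises the map cross-correlation (both signs tried,
    bounded retries), inject Ek along it into the velocities, run a biased
    MD segment, then re-measure the reference c.c from the last frame.
    """
    ff = build_forcefield(S1, cfg.ff_config)
    pg = potential_grid(tm, cfg.gscale)
    if resume is not None:
        state = resume
        rng_modes = np.random.default_rng([seed, 1])
        if state.mode_rng_state is not None:
            rng_modes.bit_generator.state = state.mode_rng_state
    else:
        state = _init_replica(S1, tm, cfg, seed, replica_id, ff)
        rng_modes = np.random.default_rng([seed, 1])
    sel_self, target_sel = _target_selections(state.structure, target)
    modes = None
    t0 = time.perf_counter()
    while state.cycle < cfg.max_cycles and not state.converged:
        if modes is None or state.cycle % cfg.recompute_modes_every == 0:
            modes = _compute_modes(state.structure, cfg)
        accepted, n_rejected, combo, dcc = None, 0, None, 0.0
        while n_rejected < cfg.retry_budget:
            idx = select_modes(modes, cfg.k_modes, cfg.pool_fraction,
                               rng_modes, law=cfg.selection_law)
            combo = combine_modes(modes, idx, rng=rng_modes)
            ok, dcc, trial, q_signed = trial_test(
                state.structure, combo.Q, cfg.amplitude, tm,
                cfg.resolution, state.cc_ref)
            if ok:
                accepted = (idx, combo.alphas, q_signed, trial)
                break
            n_rejected += 1
        if accepted is not None:
            idx, alphas, q_signed, trial = accepted
            lam, q_exct, v_tot = excite_velocities(
                q_signed, state.structure.masses, cfg.Ek,
                state.md.velocities)
            state.md.coords = trial.coords.copy()
            state.md.velocities = v_tot
            row_extra = {"accepted_modes": idx.tolist(),
                         "alphas": np.round(alphas, 6).tolist(),
                         "dcc_trial": dcc, "n_rejected": n_rejected,
                         "excited": True}
        else:  # no productive mode found: plain biased MD this cycle
            row_extra = {"accepted_modes": [], "alphas": [],
                         "dcc_trial": 0.0, "n_rejected": n_rejected,
                         "excited": False}
        state.md, _ = md_segment(state.md, state.structure, ff, pg,
                                 cfg.segment_steps, thermostat=True)
        state = _post_cycle(state, tm, cfg, target, target_sel, sel_self,
                            row_extra, t0)
        state.mode_rng_state = rng_modes.bit_generator.state
    return state


def _compute_modes(structure, cfg: FitConfig):
    from .nma import ENMParams, full_modes
    params = ENMParams()
    n_avail = _available_modes(structure, cfg.use_rtb)
    n_req = max(cfg.k_modes,
                int(np.ceil(cfg.pool_fraction * n_avail)))
    n_req = min(max(n_req, cfg.k_modes), n_avail)
    if cfg.use_rtb:
        return rtb_modes(structure, params, n_req)
    return full_modes(structure, params, n_req)


def _available_modes(structure, use_rtb: bool) -> int:
    if not use_rtb:
        return 3 * structure.n_atoms - 6
    keys = structure.residue_keys()
    counts = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    dof = sum(6 if c > 1 else 3 for c in counts.values())
    return dof - 6


def run_replica_mdff(S1: Structure, tm: DensityMap, cfg: FitConfig,
                     seed: int, target: Structure | None = None,
                     replica_id: int = 0,
                     resume: ReplicaState | None = None,
                     _pg=None, _tm_cc=None,
                     _max_cycles=None, _gate=True) -> ReplicaState:
    """Plain map-biased MD baseline: identical loop and convergence rule,
    minus the mode machinery (one MD segment per cycle)."""
    ff = build_forcefield(S1, cfg.ff_config)
    pg = _pg if _pg is not None else potential_grid(tm, cfg.gscale)
    tm_cc = _tm_cc if _tm_cc is not None else tm
    state = resume if resume is not None \
        else _init_replica(S1, tm_cc, cfg, seed, replica_id, ff)
    sel_self, target_sel = _target_selections(state.structure, target)
    t0 = time.perf_counter()
    max_cycles = _max_cycles if _max_cycles is not None else cfg.max_cycles
    while state.cycle < max_cycles:
        state.md, _ = md_segment(state.md, state.structure, ff, pg,
                                 cfg.segment_steps, thermostat=True)
        state = _post_cycle(state, tm_cc, cfg, target, target_sel, sel_self,
                            {"accepted_modes": [], "alphas": [],
                             "dcc_trial": 0.0, "n_rejected": 0,
                             "excited": False}, t0)
        if not _gate:
            state.converged = False
        elif state.converged:
            break
    return state


def run_replica_cmdff(S1: Structure, tm: DensityMap, cfg: FitConfig,
                      seed: int, target: Structure | None = None,
                      replica_id: int = 0) -> ReplicaState:
    """Cascade baseline: fixed-length plain-MDFF stages against maps
    blurred to each scheduled resolution (coarse to fine), then a full
    plain-MDFF run against the native map. A single-entry schedule equal
    to the native resolution reduces exactly to ``run_replica_mdff``."""
    schedule = cfg.cascade if cfg.cascade else (cfg.resolution,)
    native = cfg.resolution
    state = None
    for res in schedule[:-1]:
        stage_tm = blur_map(tm, native, res) if res > native else tm
        stage_cfg = _stage_config(cfg, res)
        pg = potential_grid(stage_tm, cfg.gscale)
        done = state.cycle if state is not None else 0
        state = run_replica_mdff(
            S1, stage_tm, stage_cfg, seed, target, replica_id,
            resume=state, _pg=pg, _tm_cc=stage_tm,
            _max_cycles=done + cfg.cascade_stage_cycles, _gate=False)
        state.converged = False
        state.no_improve = 0
    if state is not None:
        # re-reference c.c against the native map for the final stage
        state.cc_ref = cc_structure(state.structure, tm, native)
    return run_replica_mdff(S1, tm, cfg, seed, target, replica_id,
                            resume=state)


def _stage_config(cfg: FitConfig, res: float) -> FitConfig:
    import copy
    stage = copy.copy(cfg)
    stage.resolution = res
    return stage


_RUNNERS = {"mdff": run_replica_mdff, "mdff_nm": run_replica_mdff_nm,
            "cmdff": run_replica_cmdff}


def run_replica(S1, tm, cfg: FitConfig, seed: int, target=None,
                replica_id: int = 0) -> ReplicaState:
    """Dispatch one replica by ``cfg.method``."""
    try:
        runner = _RUNNERS[cfg.method]
    except KeyError:
        raise ValueError(f"unknown method {cfg.method!r}") from None
    return runner(S1, tm, cfg, seed, target=target, replica_id=replica_id)


def run_ensemble(S1: Structure, tm: DensityMap, cfg: FitConfig,
                 target: Structure | None = None):
    """Run ``cfg.replicas`` independent replicas (seed = master seed +
    replica id) and return ``(states, summary DataFrame)``."""
    states = []
    for rid in range(cfg.replicas):
        states.append(run_replica(S1, tm, cfg, cfg.seed + rid,
                                  target=target, replica_id=rid))
    rows = []
    for st in states:
        hist = st.history.to_dataframe()
        rows.append({
            "replica": st.replica_id, "seed": st.seed,
            "cycles": st.cycle, "converged": st.converged,
            "final_cc": st.cc_ref, "best_cc": st.best_cc,
            "best_cycle": st.best_cycle,
            "final_rmsd": hist["rmsd_target"].iloc[-1] if len(hist) else np.nan,
            "best_rmsd": float(np.nanmin(hist["rmsd_target"]))
            if len(hist) and hist["rmsd_target"].notna().any() else np.nan,
        })
    return states, pd.DataFrame(rows)


def save_checkpoint(state: ReplicaState, path) -> None:
    """Serialise a replica mid-run so it can be resumed bitwise."""
    s = state.structure
    np.savez(
        path,
        coords=state.md.coords, velocities=state.md.velocities,
        structure_coords=s.coords, names=s.names, elements=s.elements,
        res_names=s.res_names, res_ids=s.res_ids, chain_ids=s.chain_ids,
        masses=s.masses, ss=s.ss,
        best_coords=state.best_coords,
        snapshots=np.array(state.history.snapshots),
        meta=json.dumps({
            "replica_id": state.replica_id, "seed": state.seed,
            "cycle": state.cycle, "cc_ref": state.cc_ref,
            "best_cc": state.best_cc, "best_cycle": state.best_cycle,
            "no_improve": state.no_improve, "converged": state.converged,
            "rows": state.history.rows,
            "md_rng": state.md.rng.bit_generator.state,
            "mode_rng": state.mode_rng_state,
            "dt": state.md.dt, "temperature": state.md.temperature,
            "gamma": state.md.gamma,
        }))


def load_checkpoint(path) -> ReplicaState:
    with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz",
                 allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        s = Structure(names=z["names"], elements=z["elements"],
                      res_names=z["res_names"], res_ids=z["res_ids"],
                      chain_ids=z["chain_ids"], coords=z["structure_coords"],
                      masses=z["masses"], ss=z["ss"])
        rng = np.random.default_rng(0)
        rng.bit_generator.state = meta["md_rng"]
        md = MDState(coords=z["coords"], velocities=z["velocities"],
                     dt=meta["dt"], temperature=meta["temperature"],
                     gamma=meta["gamma"], rng=rng)
        hist = FitTrajectory(rows=meta["rows"],
                             snapshots=list(z["snapshots"]))
        return ReplicaState(
            replica_id=meta["replica_id"], seed=meta["seed"],
            cycle=meta["cycle"], structure=s, md=md,
            cc_ref=meta["cc_ref"], history=hist,
            best_cc=meta["best_cc"], best_coords=z["best_coords"],
            best_cycle=meta["best_cycle"], no_improve=meta["no_improve"],
            converged=meta["converged"], mode_rng_state=meta["mode_rng"])
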