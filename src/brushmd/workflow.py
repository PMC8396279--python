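"""Run orchestration: single state points and isotherm scans.

``run_state_point`` is the end-to-end unit (build -> protocol ->
observables) reused by the isotherm scan, the CLI, and the acceptance
measurements; ``run_isotherm`` loops it over fluid densities and
replicate seeds and merges the replicate statistics.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from . import observables as obs
from .build import Configuration, build_flat_brush, build_hairy_particle, insert_fluid
from .config import RunConfig
from .engine import Protocol, Trajectory, run_protocol
from .model import PARTICLE, SEGMENT, make_interaction_table

__all__ = ["run_state_point", "analyze_trajectory", "run_isotherm", "protocol_from_config"]

log = logging.getLogger("brushmd")


def protocol_from_config(config: RunConfig) -> Protocol:
    return Protocol(
        anneal_schedule=[tuple(p) for p in config.anneal],
        equilibration_steps=config.equilibration_steps,
        production_steps=config.production_steps,
        sample_interval=config.sample_interval,
        dt=config.dt,
        T_star=config.T_star,
        tau_damp=config.tau_damp,
    )


def build_system(config: RunConfig, rho0: float, seed: int) -> Configuration:
    table = make_interaction_table(
        config.variant, eps_Ps=config.eps_Ps, sigma_c=config.sigma_c,
        sigma_P=config.sigma_P, kss=config.kss,
    )
    if config.geometry == "sphere":
        cfg = build_hairy_particle(
            config.sigma_c, config.f, config.M, variant=config.variant,
            box=config.L, seed=seed, table=table,
        )
    else:
        cfg = build_flat_brush(
            config.f, config.M, rho_gr=config.rho_gr, Lz=config.Lz,
            seed=seed, variant=config.variant, table=table,
        )
    return insert_fluid(cfg, rho0, seed=seed + 10_000, T_star=config.T_star, table=table)


def analyze_trajectory(
    traj: Trajectory,
    config: RunConfig,
    rho0: float,
    bulk_window: tuple | None = None,
) -> dict:
    """Profiles -> rho_b -> Gamma/Gamma* (both routes) -> H/H* for one run."""
    bw = config.bin_width
    seg = traj.species == SEGMENT
    flu = traj.species == PARTICLE
    out: dict = {"rho0": rho0}
    if config.geometry == "sphere":
        L = traj.box.lengths[0]
        center = 0.5 * np.asarray(traj.box.lengths)
        Rc = 0.5 * config.sigma_c
        Rp = 0.5 * L
        seg_prof = obs.radial_profile(traj.frames, seg, bw, center, r_min=Rc, r_max=Rp)
        out["segment_profile"] = seg_prof
        H = obs.corona_thickness_spherical(seg_prof, Rc)
        if flu.any() and rho0 > 0:
            flu_prof = obs.radial_profile(traj.frames, flu, bw, center, r_min=Rc, r_max=Rp)
            out["fluid_profile"] = flu_prof
            rho_b = obs.estimate_bulk_density(flu_prof, bulk_window)
            Gamma = obs.excess_adsorption_spherical(flu_prof, rho_b)
            n_in = flu_prof.total_count()
            v_acc = 4 * np.pi / 3 * (Rp**3 - Rc**3)
            Gamma_mb = obs.excess_adsorption_mass_balance(n_in, v_acc, rho_b=rho_b)
        else:
            rho_b, Gamma, Gamma_mb = 0.0, 0.0, 0.0
        Gamma_star = obs.normalize_adsorption(Gamma, "sphere", config.sigma_c)
    else:
        area = traj.box.lengths[0] * traj.box.lengths[1]
        Lz = traj.box.lengths[2]
        seg_prof = obs.planar_profile(traj.frames, seg, bw, area=area, z_max=Lz)
        out["segment_profile"] = seg_prof
        H = obs.brush_thickness_flat(seg_prof)
        if flu.any() and rho0 > 0:
            flu_prof = obs.planar_profile(traj.frames, flu, bw, area=area, z_max=Lz)
            out["fluid_profile"] = flu_prof
            rho_b = obs.estimate_bulk_density(flu_prof, bulk_window)
            Gamma = obs.excess_adsorption_flat(flu_prof, rho_b)
            n_in = flu_prof.total_count() * 1.0
            Gamma_mb = obs.excess_adsorption_mass_balance(
                n_in / area, Lz, rho_b=rho_b
            )
        else:
            rho_b, Gamma, Gamma_mb = 0.0, 0.0, 0.0
        Gamma_star = Gamma
    out.update(
        rho_b=rho_b,
        Gamma=Gamma,
        Gamma_mass_balance=Gamma_mb,
        Gamma_star=Gamma_star,
        H=H,
        H_star=obs.relative_thickness(H, config.M),
        T_mean=traj.production_temperature(),
        equilibrated=bool(traj.equilibrated),
    )
    return out


def run_state_point(config: RunConfig, rho0: float, seed: int) -> dict:
    """Build, simulate and analyze one (rho0, seed) state point."""
    t0 = time.perf_counter()
    system = build_system(config, rho0, seed)
    traj = run_protocol(
        system,
        make_interaction_table(
            config.variant, eps_Ps=config.eps_Ps, sigma_c=config.sigma_c,
            sigma_P=config.sigma_P, kss=config.kss,
        ),
        protocol_from_config(config),
    )
    result = analyze_trajectory(traj, config, rho0, config.bulk_window)
    result["seed"] = seed
    result["wall_time_s"] = time.perf_counter() - t0
    log.info(
        "state point rho0=%g seed=%d done in %.1fs (rho_b=%.4g, Gamma*=%.4g)",
        rho0, seed, result["wall_time_s"], result["rho_b"], result["Gamma_star"],
    )
    result["trajectory"] = traj
    return result


def run_isotherm(config: RunConfig, keep_profiles: bool = False) -> tuple[pd.DataFrame, list[dict]]:
    """Scan every rho0 x seed; failures are recorded per point, the scan
    continues.  Returns (merged isotherm table, per-point records)."""
    records: list[dict] = []
    for rho0 in config.rho0:
        for seed in config.seeds:
            try:
                rec = run_state_point(config, rho0, seed)
                rec.pop("trajectory")
                if not keep_profiles:
                    rec.pop("segment_profile", None)
                    rec.pop("fluid_profile", None)
                records.append(rec)
            except Exception as exc:  # noqa: BLE001 - per-point fault isolation
                log.error("state point rho0=%g seed=%d failed: %s", rho0, seed, exc)
                records.append({"rho0": rho0, "seed": seed, "error": str(exc)})
    ok = [r for r in records if "error" not in r]
    if not ok:
        return pd.DataFrame(), records
    df = pd.DataFrame(
        [
            {k: r[k] for k in ("rho0", "seed", "rho_b", "Gamma", "Gamma_star", "H", "H_star")}
            for r in ok
        ]
    )
    grouped = df.groupby("rho0")
    merged = grouped.agg(
        rho_b=("rho_b", "mean"),
        rho_b_sem=("rho_b", "sem"),
        Gamma_star=("Gamma_star", "mean"),
        Gamma_star_sem=("Gamma_star", "sem"),
        H_star=("H_star", "mean"),
        H_star_sem=("H_star", "sem"),
        n_replicates=("seed", "count"),
    ).reset_index()
    merged = merged.fillna(0.0)
    return merged, records
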