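"""Reproducible experiment drivers tying the model modules together.

Each driver recomputes one headline analysis — a suppression-maximum curve,
an equilibrium scan, a closed-form comparison, an ecological scan or a
trajectory pair — and returns plain pandas/dict structures.  ``run_experiment``
wraps a driver with config validation, CSV/JSON serialization and a
provenance log so that a config fully determines its outputs (the engine is
deterministic and genotype ordering is fixed, so reruns are byte-identical).
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import clvr, ecology, sib_homing, theory, two_drive

__all__ = [
    "resistance_free_curve",
    "sib_homing_panel",
    "clvr_panel",
    "mean_fitness_curves",
    "ecology_limits",
    "extinction_trajectories",
    "robustness_two_drive",
    "robustness_sib_mating",
    "run_experiment",
    "EXPERIMENTS",
]

#: birth rates compared in the ecology scans.  The population multiplies by
#: b/2 per generation when unregulated, so persistence under a drive of
#: effect up to ~0.43 requires b >= 2/(1-0.43) ~ 3.5; these span slow to
#: fast rebound from a 4-fold knockdown while keeping every drive-free and
#: sub-threshold trial viable.
ECOLOGY_BIRTH_RATES = (4.0, 6.0, 8.0)


# ---------------------------------------------------------------------------
# headline-analysis drivers

def resistance_free_curve(n_drives: int = 2, sex_of_effect: str = "females_only",
                          introduction: str = "sequential",
                          init_resistance_grid=None, d: float = 1.0,
                          h: float = 0.0, init_drive: float | None = None,
                          grid_step: float = 0.01) -> pd.DataFrame:
    """Maximum resistance-free combined suppression versus the initial
    frequency of the resistance allele (one curve of the 1-vs-2-drives
    comparison).  Resistance frequencies start at 0.005 and step by 0.01."""
    if init_resistance_grid is None:
        init_resistance_grid = np.round(np.arange(0.005, 1.0, 0.01), 10)
    if init_drive is None:
        init_drive = 0.005 if n_drives == 2 else 0.01
    if n_drives == 1:
        introduction = "single"
    rows = []
    for r0 in init_resistance_grid:
        params = two_drive.DriveParams(
            s1=0.0, d=d, h=h, sex_of_effect=sex_of_effect,
            introduction=introduction, init_drive=init_drive,
            init_resistance=float(r0))
        max_s = two_drive.max_resistance_free_s(params, grid_step=grid_step)
        rows.append({"init_resistance": float(r0), "max_resistance_free_s": max_s})
    return pd.DataFrame(rows, columns=["init_resistance", "max_resistance_free_s"])


def sib_homing_panel(m: float, d: float = 1.0, h: float = 0.0) -> pd.DataFrame:
    """Equilibrium curves of the sib-mating homing model for one value of m:
    drive frequency, Q frequency, mean fitness, and the no-sib-mating
    reference 1-s, over the 0.01 grid of s."""
    return sib_homing.scan_equilibria(m, d=d, h=h)


def clvr_panel(m: float) -> tuple[pd.DataFrame, dict]:
    """ClvR versus sib mating for one value of m: mean fitness with and
    without sib mating over the sigma grid, plus the smallest sigma at which
    Q invades."""
    table = clvr.scan_sigma(m)
    selected = table[table.q_selected]
    threshold = float(selected.sigma.min()) if len(selected) else float("nan")
    return table, {"m": m, "sigma_invasion_threshold": threshold}


def mean_fitness_curves(grid_step: float = 0.01) -> pd.DataFrame:
    """Closed-form equilibrium mean fitness of the three drive systems on a
    grid of the homozygote fitness effect."""
    s_grid = np.round(np.arange(0.0, 1.0 + 1e-9, grid_step), 10)
    return pd.DataFrame({
        "s": s_grid,
        "onesex_homing": [theory.onesex_homing_mean_fitness(s) for s in s_grid],
        "twosex_homing": [theory.twosex_homing_mean_fitness(s) for s in s_grid],
        "clvr": [theory.clvr_mean_fitness(s) for s in s_grid],
    })


def ecology_limits(knockdown: tuple[int, float] | None = None,
                   birth_rates=ECOLOGY_BIRTH_RATES,
                   grid_step: float = 0.01) -> pd.DataFrame:
    """Resistance-free upper limits of the ecology model: the largest sb
    (density-independent) and sK (density-dependent) at which the drive
    fixes, per birth rate, with or without periodic knockdown."""
    rows = []
    for b in birth_rates:
        for mode in ("DI", "DD"):
            limit = ecology.max_resistance_free_eco(
                mode, b=b, knockdown=knockdown, grid_step=grid_step)
            rows.append({"mode": mode, "b": b,
                         "knockdown": knockdown is not None,
                         "max_resistance_free": limit})
    return pd.DataFrame(rows)


def extinction_trajectories(b: float = 3.0, s_effect: float = 0.4,
                            K: float = 1e9) -> tuple[pd.DataFrame, dict]:
    """Extinction-versus-persistence trajectory pair: the same viability
    coefficient (0.4) applied density-independently (sb) versus
    density-dependently (sK)."""
    frames = []
    outcomes = {}
    for mode in ("DI", "DD"):
        params = ecology.EcoParams(
            b=b, K=K,
            sb=s_effect if mode == "DI" else 0.0,
            sK=s_effect if mode == "DD" else 0.0)
        traj, summary = ecology.run_ecology(params)
        frame = traj.to_frame()
        frame["relative_density"] = frame["population_size"] / K
        frame["mode"] = mode
        frames.append(frame)
        outcomes[mode] = {
            "outcome": "extinct" if summary.outcome == "extinct" else "persists",
            "relative_density": summary.extra.get("relative_density"),
            "generations": summary.generations,
        }
    return pd.concat(frames, ignore_index=True), outcomes


# ---------------------------------------------------------------------------
# robustness drivers

def robustness_two_drive(init_resistance_grid=None, h_values=(0.0, 0.1),
                         d_values=(1.0, 0.9),
                         grid_step: float = 0.01) -> pd.DataFrame:
    """Sensitivity of the 1-vs-2-drive comparison to drive imperfection and
    heterozygote costs: two male drives introduced simultaneously, equal
    fitness effects in both sexes, against a single male drive.

    Both scans step the *combined* suppression in ``grid_step`` increments
    (100 trials per scan), so one- and two-drive maxima are commensurable
    when differenced.
    """
    if init_resistance_grid is None:
        init_resistance_grid = np.round(np.arange(0.005, 1.0, 0.05), 10)
    rows = []
    for r0 in init_resistance_grid:
        for d in d_values:
            for h in h_values:
                for n_drives, intro in ((1, "single"), (2, "simultaneous")):
                    params = two_drive.DriveParams(
                        s1=0.0, d=d, h=h, sex_of_effect="both",
                        introduction=intro,
                        init_drive=0.005 if n_drives == 2 else 0.01,
                        init_resistance=float(r0))
                    max_s = two_drive.max_resistance_free_s(
                        params, grid_step=grid_step, grid_scale="combined")
                    rows.append({"init_resistance": float(r0), "d": d, "h": h,
                                 "n_drives": n_drives,
                                 "max_resistance_free_s": max_s})
    return pd.DataFrame(rows)


def two_drive_advantage_shift(table: pd.DataFrame, h: float = 0.0) -> float:
    """Largest absolute change, across the resistance-frequency grid, of the
    (two-drive minus one-drive) maximum resistance-free s when distortion
    drops from 1.0 to 0.9."""
    sub = table[table.h == h]
    pivot = sub.pivot_table(index="init_resistance", columns=["d", "n_drives"],
                            values="max_resistance_free_s")
    diff_perfect = pivot[(1.0, 2)] - pivot[(1.0, 1)]
    diff_imperfect = pivot[(0.9, 2)] - pivot[(0.9, 1)]
    return float((diff_perfect - diff_imperfect).abs().max())


def heterozygote_cost_gain(table: pd.DataFrame, d: float = 1.0) -> pd.DataFrame:
    """Gain in maximum resistance-free s from a 0.1 heterozygote fitness
    cost, per initial resistance frequency and number of drives."""
    sub = table[table.d == d]
    pivot = sub.pivot_table(index="init_resistance", columns=["h", "n_drives"],
                            values="max_resistance_free_s")
    out = pd.DataFrame({
        "gain_one_drive": pivot[(0.1, 1)] - pivot[(0.0, 1)],
        "gain_two_drives": pivot[(0.1, 2)] - pivot[(0.0, 2)],
    })
    return out.reset_index()


def _fixation_upper_limit(panel: pd.DataFrame) -> float:
    fixed = panel[panel.outcome == "fixed"]
    return float(fixed.s.max()) if len(fixed) else 0.0


def robustness_sib_mating(m_values=(0.2, 0.5, 0.95),
                          s_grid=None) -> pd.DataFrame:
    """Sensitivity of the sib-mating homing equilibria to drive imperfection
    (d = 0.9) and a heterozygote cost (h = 0.1): per m, the reduction in the
    drive-fixation range and the largest mean-fitness increase inside the
    perfect-drive polymorphic zone."""
    rows = []
    for m in m_values:
        base = sib_homing.scan_equilibria(m, d=1.0, h=0.0, s_grid=s_grid)
        zone = base[base.outcome == "polymorphic"].s
        for d, h in ((0.9, 0.0), (1.0, 0.1), (0.9, 0.1)):
            alt = sib_homing.scan_equilibria(m, d=d, h=h, s_grid=s_grid)
            merged = base.merge(alt, on="s", suffixes=("_base", "_alt"))
            in_zone = merged[merged.s.isin(zone)]
            rise = (in_zone.mean_fitness_alt - in_zone.mean_fitness_base).max()
            rows.append({
                "m": m, "d": d, "h": h,
                "fixation_limit_perfect": _fixation_upper_limit(base),
                "fixation_limit_alt": _fixation_upper_limit(alt),
                "fixation_range_reduction": _fixation_upper_limit(base) - _fixation_upper_limit(alt),
                "max_mean_fitness_increase": float(rise) if len(in_zone) else float("nan"),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# config-driven runner

def _cfg(config: dict, key: str, default=None, required: bool = False):
    if required and key not in config:
        raise ValueError(f"missing required config key: {key!r}")
    return config.get(key, default)


def run_experiment(config: dict, out_dir) -> dict:
    """Run one named experiment from a flat config dict.

    Writes ``<name>.csv`` (tabular result), ``summary.json`` and ``run.log``
    (provenance: full config and timing) into ``out_dir`` and returns the
    summary dict.  Unknown experiment names or invalid fields raise before
    any output is written.
    """
    name = _cfg(config, "experiment", required=True)
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; choose from {sorted(EXPERIMENTS)}")
    out_dir = Path(out_dir)
    started = time.time()
    table, summary = EXPERIMENTS[name](config)
    if len(table) == 0:
        raise ValueError(f"experiment {name!r} produced an empty result; check the grid")
    out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_dir / f"{name}.csv", index=False)
    payload = {"experiment": name, "summary": summary}
    (out_dir / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    log = {
        "experiment": name,
        "config": {k: v for k, v in sorted(config.items())},
        "elapsed_seconds": round(time.time() - started, 3),
        "rows": int(len(table)),
    }
    (out_dir / "run.log").write_text(json.dumps(log, indent=2, sort_keys=True))
    return payload


def _run_suppression_max(config):
    table = resistance_free_curve(
        n_drives=int(_cfg(config, "drives", 2)),
        sex_of_effect=_cfg(config, "effect_sex", "females_only"),
        introduction=_cfg(config, "mode", "sequential"),
        d=float(_cfg(config, "distortion", 1.0)),
        h=float(_cfg(config, "het_cost", 0.0)),
        init_resistance_grid=_cfg(config, "init_resistance_grid"),
    )
    return table, {"max_over_grid": float(table.max_resistance_free_s.max())}


def _run_sib_homing_panel(config):
    m = float(_cfg(config, "m", required=True))
    table = sib_homing_panel(m, d=float(_cfg(config, "distortion", 1.0)),
                             h=float(_cfg(config, "het_cost", 0.0)))
    bounds = theory.sib_thresholds(m)
    return table, {"m": m, "fixation_bound": bounds[0], "loss_bound": bounds[1]}


def _run_clvr_panel(config):
    m = float(_cfg(config, "m", required=True))
    table, summary = clvr_panel(m)
    return table, summary


def _run_fitness_floors(config):
    return mean_fitness_curves(), {}


def _run_eco_limits(config):
    knockdown = _cfg(config, "knockdown")
    if knockdown is not None:
        period, fraction = knockdown
        knockdown = (int(period), float(fraction))
    birth = _cfg(config, "birth")
    rates = (float(birth),) if birth is not None else ECOLOGY_BIRTH_RATES
    table = ecology_limits(knockdown=knockdown, birth_rates=rates)
    return table, {"limits": table.to_dict("records")}


def _run_eco_trajectories(config):
    table, outcomes = extinction_trajectories(
        b=float(_cfg(config, "birth", 3.0)),
        s_effect=float(_cfg(config, "effect", 0.4)))
    return table, outcomes


def _run_robustness_two_drive(config):
    table = robustness_two_drive(
        init_resistance_grid=_cfg(config, "init_resistance_grid"))
    summary = {
        "advantage_shift_h0": two_drive_advantage_shift(table, h=0.0),
        "het_cost_gains_perfect": heterozygote_cost_gain(table, d=1.0).to_dict("records"),
    }
    return table, summary


def _run_robustness_sib(config):
    table = robustness_sib_mating()
    return table, {"rows": table.to_dict("records")}


EXPERIMENTS = {
    "suppression-max": _run_suppression_max,
    "sib-homing-panel": _run_sib_homing_panel,
    "clvr-panel": _run_clvr_panel,
    "fitness-floors": _run_fitness_floors,
    "eco-limits": _run_eco_limits,
    "eco-trajectories": _run_eco_trajectories,
    "robustness_two_drive": _run_robustness_two_drive,
    "robustness_sib_mating": _run_robustness_sib,
}
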