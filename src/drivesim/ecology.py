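"""Population dynamics of a male-limited homing drive under ceiling density
dependence.

Discrete generations, random mating of diploid males and females.  The
number of progeny born is N = b x (adult females); males are never limiting.
The drive's viability cost hits AA offspring of either sex and can act
density-independently (factor 1 - sb) and/or density-dependently: under
ceiling regulation every offspring survives with probability min(1, K/N),
but AA offspring see a lowered ceiling, min(1, K(1-sK)/N).  Relative
selection against AA therefore vanishes when N < K(1-sK), ramps up between
K(1-sK) and K, and saturates at 1-sK above K --- which is what lets external
population knockdown relax selection on a density-dependent drive.

Genetics follow the single-drive homing model: drive allele A (males only,
complete distortion unless blocked), unlinked dominant cost-free resistance
allele R.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import DiploidModel, OutcomeSummary, StoppingRule, Trajectory, hardy_weinberg_state
from .two_drive import DriveParams, build_model

__all__ = [
    "EcoParams",
    "EcoState",
    "offspring_viability",
    "step_ecology",
    "run_ecology",
    "max_resistance_free_eco",
    "classify_persistence",
    "DEFAULT_STOP",
]

#: generation cap for ecology runs; every scanned scenario settles (or goes
#: extinct) well within this horizon
DEFAULT_STOP = StoppingRule(max_generations=5_000)

EXTINCTION_THRESHOLD = 1.0  # less than one absolute adult


@dataclass(frozen=True)
class EcoParams:
    """b: per-female birth rate (genotype-independent); K: ceiling threshold
    on progeny number; sb / sK: density-independent / density-dependent
    viability reductions of AA offspring; knockdown: optional (period,
    retained fraction) cull of progeny numbers."""

    b: float
    K: float = 1e9
    sb: float = 0.0
    sK: float = 0.0
    knockdown: tuple[int, float] | None = None
    knockdown_mode: str = "proportional"  # or "reset" (to fraction * init_N)
    init_N: float = 1e9
    init_drive: float = 0.0005
    init_resistance: float = 0.0005
    d: float = 1.0

    def __post_init__(self):
        if self.b <= 0 or self.K <= 0:
            raise ValueError("b and K must be positive")
        for name in ("sb", "sK"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.knockdown is not None:
            period, fraction = self.knockdown
            if period < 1 or not 0.0 < fraction <= 1.0:
                raise ValueError("knockdown requires period >= 1 and fraction in (0, 1]")
        if self.knockdown_mode not in ("proportional", "reset"):
            raise ValueError("knockdown_mode must be 'proportional' or 'reset'")


@dataclass
class EcoState:
    """Adult genotype counts (absolute numbers, sexes identical so a single
    vector is tracked; females are half of each count)."""

    counts: np.ndarray
    generation: int = 0
    progeny_born: float = 0.0

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def freqs(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def offspring_viability(genotype, N: float, params: EcoParams,
                        loci=("A", "R")) -> float:
    """Net survival of an offspring of the given genotype when N progeny
    were born: density-independent times ceiling density-dependent factor;
    only AA at the drive locus is penalized."""
    if N < 0:
        raise ValueError("N must be non-negative")
    if N == 0:
        return 1.0
    a_count = genotype[loci.index("A")]
    if a_count == 2:
        return (1.0 - params.sb) * min(1.0, params.K * (1.0 - params.sK) / N)
    return min(1.0, params.K / N)


def _genetics_model(params: EcoParams) -> DiploidModel:
    # adult fitnesses are all 1; selection acts on offspring via
    # offspring_viability, not through the genetic model
    gen = DriveParams(s1=0.0, d=params.d, sex_of_effect="both",
                      introduction="single",
                      init_drive=params.init_drive,
                      init_resistance=params.init_resistance)
    return build_model(gen, loci=("A", "R"))


def initial_eco_state(params: EcoParams, model: DiploidModel | None = None) -> EcoState:
    model = model or _genetics_model(params)
    freqs = hardy_weinberg_state(model.table, (params.init_drive, params.init_resistance))
    return EcoState(counts=freqs * params.init_N, generation=0)


def step_ecology(state: EcoState, params: EcoParams,
                 model: DiploidModel | None = None) -> EcoState:
    """One generation: births from adult females, random mating with
    male-only homing, knockdown if scheduled, genotype-specific offspring
    viability, survivors become the next adults (sexes 1:1)."""
    model = model or _genetics_model(params)
    total = state.total
    if total <= 0:
        return EcoState(counts=np.zeros_like(state.counts),
                        generation=state.generation + 1, progeny_born=0.0)
    females = total / 2.0
    N = params.b * females
    if params.knockdown is not None:
        period, fraction = params.knockdown
        if (state.generation + 1) % period == 0:
            if params.knockdown_mode == "proportional":
                N *= fraction
            else:
                N = min(N, fraction * params.init_N)
    freqs = state.freqs()
    offspring_dist = model.next_generation(freqs)
    viab = np.array([offspring_viability(g, N, params, model.table.loci)
                     for g in model.table.genotypes])
    survivors = N * offspring_dist * viab
    return EcoState(counts=survivors, generation=state.generation + 1,
                    progeny_born=float(N))


def _di_race_fixes(freqs: np.ndarray, params: EcoParams, model: DiploidModel,
                   stop: StoppingRule, generation: int, a_pos: int) -> bool:
    """Continue the density-independent frequency recursion (relative AA
    viability is 1-sb at every census size when sK=0) to the cap and report
    whether the drive allele reaches the fixation threshold."""
    viab_rel = np.array([1.0 - params.sb if g[a_pos] == 2 else 1.0
                         for g in model.table.genotypes])
    for gen in range(generation, stop.max_generations):
        offspring = model.next_generation(freqs)
        nxt = offspring * viab_rel
        nxt = nxt / nxt.sum()
        delta = np.max(np.abs(nxt - freqs))
        freqs = nxt
        if model.allele_freqs(freqs)[a_pos] >= stop.fixation_threshold:
            return True
        if delta < stop.delta_tolerance:
            break
    return bool(model.allele_freqs(freqs)[a_pos] >= stop.fixation_threshold)


def run_ecology(params: EcoParams,
                stop: StoppingRule = DEFAULT_STOP) -> tuple[Trajectory, OutcomeSummary]:
    """Run the coupled genetics/dynamics model and classify the outcome.

    Outcome is "extinct" when adults drop below one individual; otherwise
    the drive is classed as fixed or not and the final density relative to K
    is reported.
    """
    model = _genetics_model(params)
    a_pos = model.table.loci.index("A")
    state = initial_eco_state(params, model)
    traj = Trajectory(loci=model.table.loci)
    traj.append(0, model.allele_freqs(state.freqs()), 1.0, size=state.total)
    prev_freqs = state.freqs()
    prev_total = state.total
    drive_fixed = False  # fixation is absorbing, so track it as it happens
    for _ in range(stop.max_generations):
        state = step_ecology(state, params, model)
        if state.total < EXTINCTION_THRESHOLD:
            if not drive_fixed and params.sK == 0.0:
                # with a purely density-independent effect the genotype
                # frequencies evolve by the usual population-genetics rules,
                # unaffected by census size, so the drive-vs-resistance race
                # stays well-defined past extinction: settle it on the
                # frequency recursion alone
                drive_fixed = _di_race_fixes(state.freqs(), params, model,
                                             stop, state.generation, a_pos)
            traj.append(state.generation, traj.allele_freqs[-1], 1.0, size=0.0)
            summary = OutcomeSummary(
                outcome="extinct",
                final_freqs=traj.final_allele_freqs(),
                generations=state.generation,
                mean_fitness=float("nan"),
                extra={"extinction_generation": state.generation,
                       "relative_density": 0.0,
                       "drive_fixed": drive_fixed},
            )
            return traj, summary
        freqs = state.freqs()
        allele = model.allele_freqs(freqs)
        drive_fixed = drive_fixed or allele[a_pos] >= stop.fixation_threshold
        traj.append(state.generation, allele, 1.0, size=state.total)
        delta = max(np.max(np.abs(freqs - prev_freqs)),
                    abs(state.total - prev_total) / params.K)
        # a periodic knockdown keeps the dynamics cyclic, so the steady-state
        # stop only applies without one (a retained fraction of 1 is a no-op)
        culling = params.knockdown is not None and params.knockdown[1] < 1.0
        steady = not culling and delta < stop.delta_tolerance
        prev_freqs, prev_total = freqs, state.total
        if steady:
            break
    af = traj.final_allele_freqs()
    summary = OutcomeSummary(
        outcome="fixed" if drive_fixed else "not_fixed",
        final_freqs=af,
        generations=traj.generations[-1],
        mean_fitness=float("nan"),
        extra={"relative_density": state.total / params.K,
               "drive_fixed": drive_fixed},
    )
    return traj, summary


def _fixes(params: EcoParams, mode: str, coeff: float, stop: StoppingRule) -> bool:
    p = replace(params, sb=coeff if mode == "DI" else 0.0,
                sK=coeff if mode == "DD" else 0.0)
    _, summary = run_ecology(p, stop)
    # a trial is resistance-free when the drive fixed, even if the fixed
    # drive subsequently pushed the population to extinction
    return bool(summary.extra["drive_fixed"])


def max_resistance_free_eco(mode: str, b: float, knockdown=None,
                            grid_step: float = 0.01,
                            params: EcoParams | None = None,
                            stop: StoppingRule = DEFAULT_STOP,
                            method: str = "bisect") -> float:
    """Largest viability coefficient (sb in DI mode, sK in DD mode) at which
    the drive still fixes, scanned on a grid of ``grid_step``.

    Fixation is monotone in the coefficient along the grid, so the default
    bisects on grid indices; ``method="scan"`` checks every point.
    """
    if mode not in ("DI", "DD"):
        raise ValueError("mode must be 'DI' or 'DD'")
    base = params or EcoParams(b=b, knockdown=knockdown)
    base = replace(base, b=b, knockdown=knockdown)
    grid = np.round(np.arange(0.0, 1.0, grid_step), 10)
    if method == "scan":
        best = 0.0
        for c in grid:
            if _fixes(base, mode, float(c), stop):
                best = float(c)
        return best
    if not _fixes(base, mode, float(grid[0]), stop):
        return 0.0
    lo, hi = 0, len(grid) - 1
    if _fixes(base, mode, float(grid[hi]), stop):
        return float(grid[hi])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _fixes(base, mode, float(grid[mid]), stop):
            lo = mid
        else:
            hi = mid
    return float(grid[lo])


def classify_persistence(params: EcoParams,
                         stop: StoppingRule = DEFAULT_STOP) -> OutcomeSummary:
    """Run to the cap and report extinction (with its generation) or the
    final density relative to K."""
    _, summary = run_ecology(params, stop)
    if summary.outcome != "extinct":
        summary.outcome = "persists"
    return summary
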