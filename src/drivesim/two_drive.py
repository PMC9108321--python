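"""Homing drives in males confronting an unlinked, dominant, cost-free
mechanism-blocking (type-M) resistance allele.

Up to two unlinked homing drives (alleles A and B) segregate alongside a
resistance locus (allele R).  Drive operates in males only: a male
heterozygous at a drive locus transmits the drive allele with probability d
(d = 1 is perfect homing), independently across drive loci --- unless the male
carries at least one copy of R, in which case segregation is Mendelian at
every locus.  Females always segregate Mendelianly.  Fitness costs are
recessive per drive locus (drive homozygote 1 - s_i, heterozygote 1 - h) and
multiplicative over loci; the resistance locus is cost-free.  Costs can be
confined to females.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import (
    DiploidModel,
    GenotypeTable,
    OutcomeSummary,
    StoppingRule,
    Trajectory,
    enumerate_genotypes,
    hardy_weinberg_state,
    FIX_THRESHOLD,
)

__all__ = [
    "DriveParams",
    "male_gamete_distribution",
    "genotype_fitness",
    "build_model",
    "initial_state",
    "run_two_drive",
    "max_resistance_free_s",
    "combined_suppression",
]

#: stopping rule used for all homing-vs-resistance runs; fixation or a
#: stalled equilibrium is always reached well before this cap at the
#: parameter ranges scanned here.
DEFAULT_STOP = StoppingRule(max_generations=10_000)


@dataclass(frozen=True)
class DriveParams:
    """Parameters of the homing-drive / type-M resistance model.

    s1, s2 : homozygote fitness reductions of drives A and B (s2 ignored
        when ``n_drives == 1``).
    d : segregation distortion, fraction of drive gametes from a male
        drive heterozygote; 0.5 is Mendelian, 1.0 perfect homing.
    h : heterozygote fitness reduction, applied per heterozygous drive locus.
    sex_of_effect : "both" or "females_only".
    introduction : "single", "simultaneous" or "sequential"; sequential
        injects drive B once drive A reaches ``sequential_trigger``.
    """

    s1: float
    s2: float = 0.0
    d: float = 1.0
    h: float = 0.0
    sex_of_effect: str = "both"
    introduction: str = "single"
    sequential_trigger: float = 0.9995
    init_drive: float = 0.005
    init_resistance: float = 0.005

    def __post_init__(self):
        for name in ("s1", "s2", "h"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.5 <= self.d <= 1.0:
            raise ValueError("distortion d must be in [0.5, 1]")
        if self.sex_of_effect not in ("both", "females_only"):
            raise ValueError("sex_of_effect must be 'both' or 'females_only'")
        if self.introduction not in ("single", "simultaneous", "sequential"):
            raise ValueError("unknown introduction mode")

    @property
    def n_drives(self) -> int:
        return 1 if self.introduction == "single" else 2

    @property
    def combined_s(self) -> float:
        if self.n_drives == 1:
            return self.s1
        return combined_suppression(self.s1, self.s2)


def combined_suppression(s1: float, s2: float) -> float:
    """Combined suppression of two multiplicative drives: 1 - (1-s1)(1-s2)."""
    return 1.0 - (1.0 - s1) * (1.0 - s2)


def _drive_locus_indices(table: GenotypeTable) -> list[int]:
    return [i for i, name in enumerate(table.loci) if name != "R"]


def male_gamete_distribution(genotype, d: float,
                             loci=("A", "B", "R")) -> dict[tuple[int, ...], float]:
    """Gamete haplotype distribution of a male of the given genotype.

    ``genotype`` is a tuple of marked-allele counts per locus.  Drive loci in
    heterozygotes transmit the drive allele with probability d, independently
    across loci; any R copy restores Mendelian segregation at all loci, as
    does being female (use d = 0.5 for females).
    """
    r_pos = loci.index("R")
    blocked = genotype[r_pos] >= 1
    probs = []
    for pos, count in enumerate(genotype):
        if count == 0:
            probs.append(0.0)
        elif count == 2:
            probs.append(1.0)
        else:
            probs.append(0.5 if (blocked or pos == r_pos) else d)
    out = {}
    n = len(genotype)
    for hap in np.ndindex(*([2] * n)):
        p = 1.0
        for bit, q in zip(hap, probs):
            p *= q if bit else 1.0 - q
        if p:
            out[tuple(hap)] = p
    return out


def genotype_fitness(genotype, params: DriveParams, sex: str,
                     loci=("A", "B", "R")) -> float:
    """Viability/fertility weight of a genotype: recessive cost 1 - s_i per
    drive homozygote, 1 - h per drive heterozygote, multiplicative over
    loci; the resistance locus is cost-free."""
    if params.sex_of_effect == "females_only" and sex != "female":
        return 1.0
    s_by_locus = {"A": params.s1, "B": params.s2}
    w = 1.0
    for name, count in zip(loci, genotype):
        if name == "R":
            continue
        if count == 2:
            w *= 1.0 - s_by_locus[name]
        elif count == 1:
            w *= 1.0 - params.h
    return w


def build_model(params: DriveParams, loci=None) -> DiploidModel:
    """Assemble the DiploidModel for the requested number of drives."""
    if loci is None:
        loci = ("A", "R") if params.n_drives == 1 else ("A", "B", "R")
    table = enumerate_genotypes(loci)
    n_g, n_h = len(table), 2 ** len(loci)
    female_g = np.zeros((n_g, n_h))
    male_g = np.zeros((n_g, n_h))
    hap_table = enumerate_genotypes(loci, ploidy=1)
    for gi, g in enumerate(table.genotypes):
        for hap, p in male_gamete_distribution(g, params.d, loci).items():
            male_g[gi, hap_table.index[hap]] = p
        for hap, p in male_gamete_distribution(g, 0.5, loci).items():
            female_g[gi, hap_table.index[hap]] = p
    wf = np.array([genotype_fitness(g, params, "female", loci) for g in table.genotypes])
    wm = np.array([genotype_fitness(g, params, "male", loci) for g in table.genotypes])
    return DiploidModel(table, female_g, male_g, wf, wm)


def initial_state(model: DiploidModel, params: DriveParams) -> np.ndarray:
    """Hardy-Weinberg start: drive(s) at init_drive, R at init_resistance.

    In sequential mode drive B starts absent and is injected later.
    """
    freqs = []
    for name in model.table.loci:
        if name == "R":
            freqs.append(params.init_resistance)
        elif name == "B" and params.introduction == "sequential":
            freqs.append(0.0)
        else:
            freqs.append(params.init_drive)
    return hardy_weinberg_state(model.table, freqs)


def _inject_drive(model: DiploidModel, freq: np.ndarray, locus: str,
                  allele_freq: float) -> np.ndarray:
    """Replace wild-type homozygotes at `locus` with drive genotypes at
    Hardy-Weinberg proportions, evenly across backgrounds at other loci."""
    loci = model.table.loci
    pos = loci.index(locus)
    shape = tuple(3 for _ in loci)
    cube = freq.reshape(shape)
    marg = cube.sum(axis=pos)
    q = allele_freq
    hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    cube = np.tensordot(np.expand_dims(marg, pos), hwe, axes=0)
    cube = np.moveaxis(cube.squeeze(pos), -1, pos)
    return cube.reshape(-1)


def run_two_drive(params: DriveParams,
                  stop: StoppingRule = DEFAULT_STOP) -> tuple[Trajectory, OutcomeSummary]:
    """Run one trial and classify the outcome.

    The outcome is "resistance-free fixation" when every introduced drive
    allele reaches the fixation threshold by the generation cap (the
    resistance allele persists but is inert once the drives are fixed).
    """
    model = build_model(params)
    freq = initial_state(model, params)
    drives = [name for name in model.table.loci if name != "R"]
    callback = None
    if params.introduction == "sequential":
        a_pos = model.table.loci.index("A")
        injected = {"done": False}

        def callback(gen, f):
            if not injected["done"]:
                if model.allele_freqs(f)[a_pos] >= params.sequential_trigger:
                    injected["done"] = True
                    return _inject_drive(model, f, "B", params.init_drive)
            return None

    final, traj = model.iterate(freq, stop, callback=callback)
    af = dict(zip(model.table.loci, model.allele_freqs(final)))
    all_fixed = all(af[dv] >= stop.fixation_threshold for dv in drives)
    if params.introduction == "sequential" and not injected["done"]:
        all_fixed = False
    summary = OutcomeSummary(
        outcome="fixed" if all_fixed else "not_fixed",
        final_freqs={k: float(v) for k, v in af.items()},
        generations=traj.generations[-1],
        mean_fitness=traj.mean_fitness[-1],
        extra={"final_resistance": float(af["R"])},
    )
    return traj, summary


def _fixes(params: DriveParams, s: float, stop: StoppingRule) -> bool:
    p = replace(params, s1=s, s2=s if params.n_drives == 2 else 0.0)
    _, summary = run_two_drive(p, stop)
    return summary.outcome == "fixed"


def max_resistance_free_s(params: DriveParams,
                          grid_step: float = 0.01,
                          stop: StoppingRule = DEFAULT_STOP,
                          method: str = "bisect",
                          grid_scale: str = "per_drive") -> float:
    """Largest combined suppression s for which all introduced drives fix.

    Fitness effects are scanned on a grid of ``grid_step`` (both drives
    share the same per-drive s); the returned value is the combined
    suppression 1 - (1-s1)(1-s2) at the largest fixing grid point, or 0.0 if
    no grid point fixes.  With ``grid_scale="per_drive"`` the grid steps the
    per-drive effect; with ``"combined"`` it steps the combined suppression
    (per-drive effect 1 - sqrt(1-s)), which keeps one- and two-drive maxima
    commensurable at the same resolution.  Fixation is monotone in s along
    the grid, so the default search bisects on grid indices;
    ``method="scan"`` checks every point (used to validate the monotone
    assumption).
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if grid_scale not in ("per_drive", "combined"):
        raise ValueError("grid_scale must be 'per_drive' or 'combined'")
    grid = np.arange(0.0, 1.0, grid_step)

    def per_drive(i):
        if params.n_drives == 2 and grid_scale == "combined":
            return 1.0 - np.sqrt(1.0 - grid[i])
        return grid[i]

    def value(i):
        s = per_drive(i)
        return combined_suppression(s, s) if params.n_drives == 2 else s

    def fixes(i):
        return _fixes(params, per_drive(i), stop)

    if method == "scan":
        best = None
        for i in range(len(grid)):
            if fixes(i):
                best = i
        return 0.0 if best is None else value(best)

    if not fixes(0):
        return 0.0
    lo, hi = 0, len(grid) - 1
    if fixes(hi):
        return value(hi)
    # invariant: grid[lo] fixes, grid[hi] does not
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if fixes(mid):
            lo = mid
        else:
            hi = mid
    return value(lo)
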