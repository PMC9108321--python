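"""A two-sex homing drive confronting genetically enforced sib mating.

Sexual haploids mate to form a brief diploid phase.  Homing acts in Aa
diploids (they transmit the drive allele A with probability d) and the
recessive cost s is manifested as viability of progeny from AA diploids.
The unlinked allele Q forces a fraction m of a Q mother's daughters to mate
with their brothers (type-P resistance: sib mating partitions drive costs
across families without touching the drive mechanism).

Closed-form regimes (with Q fixed): the drive fixes if s < 1 - m, is lost if
s > 1/m - 1, and for 1-m < s < min(1/m - 1, 1) sits at the polymorphic
frequency 1/s - m/(1-m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import OutcomeSummary, StoppingRule, Trajectory, enumerate_genotypes
from .families import FamilyModel, random_mating_families

__all__ = [
    "SibParams",
    "diploid_offspring_rule",
    "build_sib_model",
    "run_sib_homing",
    "analytic_classification",
    "scan_equilibria",
    "smallest_s_selecting_q",
    "q_selected",
    "type_M_comparison",
    "DEFAULT_STOP",
]

#: outcomes in this model are assessed at 1e5 generations
DEFAULT_STOP = StoppingRule(max_generations=100_000)

#: Q counts as invading when it grows 10-fold from its initial frequency
INVASION_FACTOR = 10.0


@dataclass(frozen=True)
class SibParams:
    """s: viability of progeny from AA diploids is 1-s; m: sib-mating
    fraction enforced by Q mothers; d: distortion in Aa diploids; h:
    viability reduction of progeny from Aa diploids."""

    s: float
    m: float
    d: float = 1.0
    h: float = 0.0
    init_drive: float = 0.01
    init_Q: float = 0.01

    def __post_init__(self):
        if not 0.0 <= self.s <= 1.0 or not 0.0 <= self.m <= 1.0:
            raise ValueError("s and m must be in [0, 1]")
        if not 0.5 <= self.d <= 1.0:
            raise ValueError("d must be in [0.5, 1]")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must be in [0, 1]")


def diploid_offspring_rule(n_drive: int, s: float, d: float, h: float) -> tuple[float, float]:
    """(progeny viability, P(progeny carries drive allele)) for a diploid
    with ``n_drive`` copies of A: aa Mendelian; Aa homing at rate d with
    viability 1-h; AA only A with viability 1-s."""
    if n_drive == 0:
        return 1.0, 0.0
    if n_drive == 1:
        return 1.0 - h, d
    return 1.0 - s, 1.0


def build_sib_model(params: SibParams) -> FamilyModel:
    """FamilyModel over haplotypes at the (A, Q) loci."""
    haps = enumerate_genotypes(("A", "Q"), ploidy=1)
    n = len(haps)
    progeny = np.zeros((n, n, n))
    viability = np.zeros((n, n))
    for i, mh in enumerate(haps.genotypes):
        for j, fh in enumerate(haps.genotypes):
            v, p_drive = diploid_offspring_rule(mh[0] + fh[0], params.s, params.d, params.h)
            p_q = (mh[1] + fh[1]) / 2.0  # Q segregates Mendelianly
            viability[i, j] = v
            for k, ch in enumerate(haps.genotypes):
                p = (p_drive if ch[0] else 1.0 - p_drive)
                p *= (p_q if ch[1] else 1.0 - p_q)
                progeny[i, j, k] = p
    sib = np.array([params.m if mh[1] else 0.0 for mh in haps.genotypes])
    return FamilyModel(haps, progeny, viability, sib)


def run_sib_homing(params: SibParams,
                   stop: StoppingRule = DEFAULT_STOP) -> tuple[Trajectory, OutcomeSummary]:
    model = build_sib_model(params)
    fams = random_mating_families(model.haplotypes, (params.init_drive, params.init_Q))
    final, traj = model.iterate(fams, stop)
    return traj, model.classify(final, traj, stop, "A")


def analytic_classification(s: float, m: float):
    """Regime of the drive given sib-mating allele Q, from the closed forms.

    Returns ("fixed", 1.0), ("lost", 0.0) or ("polymorphic", freq) with
    freq = 1/s - m/(1-m).  At m = 1 any costly drive is lost.
    """
    if not (0.0 < m <= 1.0):
        raise ValueError("classification requires 0 < m <= 1")
    if m == 1.0:
        return ("lost", 0.0) if s > 0 else ("fixed", 1.0)
    if s < 1.0 - m:
        return ("fixed", 1.0)
    if m > 0 and s > 1.0 / m - 1.0:
        return ("lost", 0.0)
    return ("polymorphic", 1.0 / s - m / (1.0 - m))


def q_selected(params: SibParams, summary: OutcomeSummary) -> bool:
    """Whether sib mating was selected to (at least partly) block the drive:
    Q rose at least 10-fold and the drive failed to fix."""
    q_final = summary.final_freqs["Q"]
    return summary.outcome != "fixed" and q_final > INVASION_FACTOR * params.init_Q


def scan_equilibria(m: float, s_grid=None, d: float = 1.0, h: float = 0.0,
                    init: float = 0.01,
                    stop: StoppingRule = DEFAULT_STOP) -> pd.DataFrame:
    """Equilibrium outcomes across a grid of drive costs s (one sib-mating
    level m per panel): drive and Q frequencies, mean fitness, the
    no-sib-mating reference mean fitness 1-s, and whether Q was selected."""
    if s_grid is None:
        s_grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 10)
    rows = []
    for s in s_grid:
        params = SibParams(s=float(s), m=m, d=d, h=h, init_drive=init, init_Q=init)
        traj, summary = run_sib_homing(params, stop)
        rows.append({
            "s": float(s),
            "drive_freq": summary.final_freqs["A"],
            "Q_freq": summary.final_freqs["Q"],
            "mean_fitness": summary.mean_fitness,
            "mean_fitness_no_sib": 1.0 - float(s),
            "outcome": summary.outcome,
            "q_selected": q_selected(params, summary),
        })
    return pd.DataFrame(rows)


def smallest_s_selecting_q(m: float, s_grid=None, d: float = 1.0, h: float = 0.0,
                           init: float = 0.01,
                           stop: StoppingRule = DEFAULT_STOP) -> float:
    """Smallest drive cost s on the grid at which Q is selected (ascending
    scan with early exit)."""
    if s_grid is None:
        s_grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 10)
    for s in s_grid:
        params = SibParams(s=float(s), m=m, d=d, h=h, init_drive=init, init_Q=init)
        _, summary = run_sib_homing(params, stop)
        if q_selected(params, summary):
            return float(s)
    return float("nan")


def type_M_comparison(s: float, d: float = 1.0, h: float = 0.0,
                      init: float = 0.01,
                      stop: StoppingRule = DEFAULT_STOP) -> bool:
    """Does an unlinked, dominant, cost-free type-M resistance allele evolve
    to block this (haploid-sex) homing drive?

    Two loci: A (drive) and R (resistance).  R is dominant in the diploid
    phase and completely blocks distortion; progeny of AA diploids survive
    at 1-s regardless of R.  Returns True when the drive fails to fix by the
    generation cap.
    """
    haps = enumerate_genotypes(("A", "R"), ploidy=1)
    n = len(haps)
    progeny = np.zeros((n, n, n))
    viability = np.zeros((n, n))
    for i, mh in enumerate(haps.genotypes):
        for j, fh in enumerate(haps.genotypes):
            n_a = mh[0] + fh[0]
            blocked = (mh[1] + fh[1]) >= 1
            if n_a == 1:
                v, p_a = 1.0 - h, (0.5 if blocked else d)
            else:
                v, p_a = diploid_offspring_rule(n_a, s, d, h)[:2]
            viability[i, j] = v
            p_r = (mh[1] + fh[1]) / 2.0
            for k, ch in enumerate(haps.genotypes):
                p = (p_a if ch[0] else 1.0 - p_a) * (p_r if ch[1] else 1.0 - p_r)
                progeny[i, j, k] = p
    model = FamilyModel(haps, progeny, viability, np.zeros(n))
    fams = random_mating_families(haps, (init, init))
    final, traj = model.iterate(fams, stop)
    summary = model.classify(final, traj, stop, "A")
    return summary.outcome != "fixed"
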