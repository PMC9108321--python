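"""Family-structured recursion for haploid-sex life cycles with maternally
enforced sib mating.

Adults are haploid males and females.  A mated pair forms a single brief
diploid phase (the "family"), indexed by the ordered pair (mother haplotype,
father haplotype).  The diploid produces haploid progeny according to a
model-specific rule: a viability weight (manifested as survival of the
family's progeny) and a distribution over progeny haplotypes, already
incorporating any segregation distortion or allelic conversion.  Sexes are
assigned 1:1.

Mothers carrying the sib-mating allele Q force a fraction m of their
daughters to mate with brothers drawn from the same family's progeny pool;
those brothers are removed from the random mating pool so that sib mating
gains no automatic transmission advantage.  All other progeny join a single
random mating pool from which the remaining families are formed.  Because a
family's sons and daughters survive at the same rate, a family either has
progeny of both sexes or none, so sib-mated daughters never lack brothers.

Mean fitness is the average survival of the female-destined progeny cohort,
i.e. the family-frequency-weighted viability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    GenotypeTable,
    InviablePopulationError,
    OutcomeSummary,
    StoppingRule,
    Trajectory,
    enumerate_genotypes,
)

__all__ = ["FamilyModel", "FamilyState", "independent_pool", "random_mating_families"]

_NORM_TOL = 1e-12


@dataclass
class FamilyState:
    """Frequencies over family types (mother haplotype x father haplotype)."""

    families: np.ndarray  # (H, H), rows = mother haplotype
    generation: int = 0

    def normalize(self) -> "FamilyState":
        total = self.families.sum()
        if total <= 0:
            raise InviablePopulationError(self.generation)
        self.families = self.families / total
        return self


class FamilyModel:
    """Deterministic recursion over family-type frequencies.

    Parameters
    ----------
    haplotypes
        Haploid genotype table over the model's loci.
    progeny
        (H, H, H) array: progeny[i, j, k] is the probability that a family
        with mother haplotype i and father haplotype j produces a progeny of
        haplotype k (post-distortion / post-conversion).
    viability
        (H, H) survival of the family's progeny, in [0, 1].
    sib_fraction
        (H,) fraction of daughters forced to sib mate, indexed by the
        *mother's* haplotype (m for Q mothers, 0 otherwise).
    """

    def __init__(self, haplotypes: GenotypeTable, progeny, viability, sib_fraction):
        self.haplotypes = haplotypes
        self.progeny = np.asarray(progeny, dtype=float)
        self.viability = np.asarray(viability, dtype=float)
        self.sib_fraction = np.asarray(sib_fraction, dtype=float)
        n = len(haplotypes)
        if self.progeny.shape != (n, n, n):
            raise ValueError("progeny must be (H, H, H)")
        sums = self.progeny.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=_NORM_TOL):
            raise ValueError("each progeny distribution must sum to 1")
        if np.any(self.viability < 0) or np.any(self.viability > 1):
            raise ValueError("viabilities must lie in [0, 1]")
        if np.any(self.sib_fraction < 0) or np.any(self.sib_fraction > 1):
            raise ValueError("sib fractions must lie in [0, 1]")
        self._dosage = haplotypes.dosage()  # (H, L)

    @property
    def loci(self):
        return self.haplotypes.loci

    def allele_freqs(self, families: np.ndarray) -> np.ndarray:
        """Marked-allele frequencies among the current parents (sexes
        averaged; they are identical under this life cycle up to the
        sib-mating bookkeeping)."""
        mothers = families.sum(axis=1)
        fathers = families.sum(axis=0)
        return 0.5 * (mothers + fathers) @ self._dosage

    def mean_fitness(self, families: np.ndarray) -> float:
        return float(np.sum(families * self.viability))

    def next_generation(self, families: np.ndarray, generation: int = 0) -> np.ndarray:
        """Advance one generation of the family-type distribution."""
        w = families * self.viability  # surviving progeny mass per family
        total = w.sum()
        if total <= 0:
            raise InviablePopulationError(generation)
        sib = w * self.sib_fraction[:, None]
        rem = w - sib  # progeny mass joining the random pool, per family
        # sib-mated families: random union of two progeny of the same family
        sib_fams = np.einsum("ij,ijk,ijl->kl", sib, self.progeny, self.progeny)
        # random pool: one brother removed per sib-mated daughter, so female
        # and male pools are identical
        pool = np.einsum("ij,ijk->k", rem, self.progeny)
        pool_mass = pool.sum()
        out = sib_fams
        if pool_mass > 0:
            out = out + np.outer(pool, pool) / pool_mass
        total_out = out.sum()
        if total_out <= 0:
            raise InviablePopulationError(generation)
        return out / total_out

    def iterate(self, families: np.ndarray, stop: StoppingRule) -> tuple[np.ndarray, Trajectory]:
        families = np.asarray(families, dtype=float)
        traj = Trajectory(loci=self.loci)
        traj.append(0, self.allele_freqs(families), self.mean_fitness(families))
        for gen in range(1, stop.max_generations + 1):
            nxt = self.next_generation(families, gen)
            delta = np.max(np.abs(nxt - families))
            families = nxt
            traj.append(gen, self.allele_freqs(families), self.mean_fitness(families))
            if delta < stop.delta_tolerance:
                break
        return families, traj

    def classify(self, families: np.ndarray, traj: Trajectory,
                 stop: StoppingRule, drive_locus: str) -> OutcomeSummary:
        """Classify the drive allele as fixed / lost / polymorphic."""
        af = dict(zip(self.loci, self.allele_freqs(families)))
        p = af[drive_locus]
        if p >= stop.fixation_threshold:
            outcome = "fixed"
        elif p <= 1.0 - stop.fixation_threshold:
            outcome = "lost"
        else:
            outcome = "polymorphic"
        return OutcomeSummary(
            outcome=outcome,
            final_freqs={k: float(v) for k, v in af.items()},
            generations=traj.generations[-1],
            mean_fitness=traj.mean_fitness[-1],
        )


def independent_pool(haplotypes: GenotypeTable, allele_freqs) -> np.ndarray:
    """Haplotype pool with independent per-locus marked-allele frequencies."""
    allele_freqs = np.asarray(allele_freqs, dtype=float)
    pool = np.empty(len(haplotypes))
    for i, hap in enumerate(haplotypes.genotypes):
        p = 1.0
        for bit, q in zip(hap, allele_freqs):
            p *= q if bit else 1.0 - q
        pool[i] = p
    return pool


def random_mating_families(haplotypes: GenotypeTable, allele_freqs) -> np.ndarray:
    """Initial family distribution from random union of independent pools."""
    pool = independent_pool(haplotypes, allele_freqs)
    return np.outer(pool, pool)
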