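"""Generic deterministic engine for multilocus genotype-frequency recursions.

Offspring genotype distributions are built by exhaustive enumeration of all
parental matings weighted by each parent's gamete-production rule, under
random mating this collapses to the product of the two sex-specific gamete
pools.  Selection enters as a fertility weight on parental genotypes during
gamete production, which in a discrete-generation life cycle is equivalent
to viability selection on offspring before the mating census.

All loci are unlinked and biallelic.  A diploid genotype is represented by a
tuple giving, per locus, the count (0, 1 or 2) of the "marked" allele --- the
drive or resistance allele written in uppercase (A, B, R, C, G, Q).  A
haplotype is a tuple of 0/1 per locus.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "FrequencyState",
    "StoppingRule",
    "Trajectory",
    "OutcomeSummary",
    "DiploidModel",
    "enumerate_genotypes",
    "hardy_weinberg_state",
    "FIX_THRESHOLD",
    "LOSS_THRESHOLD",
]

# Deterministic recursions only approach the boundaries asymptotically, so
# fixation/loss are declared at a numerical threshold.
FIX_THRESHOLD = 1.0 - 1e-8
LOSS_THRESHOLD = 1e-8

_NORM_TOL = 1e-12


class InviablePopulationError(RuntimeError):
    """Raised when total post-selection mass is zero."""

    def __init__(self, generation: int):
        self.generation = generation
        super().__init__(f"population inviable at generation {generation}")


@dataclass(frozen=True)
class GenotypeTable:
    """Complete, stably ordered enumeration of multilocus genotypes.

    ``genotypes`` are tuples of per-locus marked-allele counts, ordered
    lexicographically so outputs are reproducible bit-for-bit.  For L diploid
    loci there are 3**L genotypes; for L haploid loci, 2**L haplotypes.
    """

    loci: tuple[str, ...]
    ploidy: int  # 1 or 2, uniform across loci
    genotypes: tuple[tuple[int, ...], ...]
    index: dict[tuple[int, ...], int]

    def __len__(self) -> int:
        return len(self.genotypes)

    def label(self, genotype: tuple[int, ...]) -> str:
        """Human-readable label, e.g. (1, 0, 2) over (A,B,R) -> 'AabbRR'."""
        parts = []
        for locus, count in zip(self.loci, genotype):
            upper, lower = locus.upper(), locus.lower()
            if self.ploidy == 2:
                parts.append(upper * count + lower * (2 - count))
            else:
                parts.append(upper if count else lower)
        return "".join(parts)

    def dosage(self) -> np.ndarray:
        """(n_genotypes, n_loci) marked-allele frequency of each genotype."""
        return np.array(self.genotypes, dtype=float) / self.ploidy


def enumerate_genotypes(loci, ploidy: int = 2) -> GenotypeTable:
    """Enumerate every multilocus genotype for unlinked biallelic loci.

    Unordered heterozygotes are collapsed (Aa and aA are the same genotype).
    Ordering is lexicographic over per-locus marked-allele counts.
    """
    loci = tuple(loci)
    if not 1 <= len(loci) <= 4:
        raise ValueError("between 1 and 4 loci supported")
    if len(set(loci)) != len(loci):
        raise ValueError(f"duplicate locus labels in {loci}")
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    counts = range(ploidy + 1)
    genotypes = tuple(itertools.product(counts, repeat=len(loci)))
    index = {g: i for i, g in enumerate(genotypes)}
    return GenotypeTable(loci=loci, ploidy=ploidy, genotypes=genotypes, index=index)


@dataclass
class FrequencyState:
    """Normalized genotype-frequency vectors, one per class (e.g. per sex)."""

    freqs: dict[str, np.ndarray]
    generation: int = 0

    def normalize(self) -> "FrequencyState":
        for name, vec in self.freqs.items():
            total = vec.sum()
            if total <= 0:
                raise InviablePopulationError(self.generation)
            self.freqs[name] = vec / total
        return self

    def check(self) -> None:
        for name, vec in self.freqs.items():
            if np.any(vec < -_NORM_TOL) or abs(vec.sum() - 1.0) > _NORM_TOL:
                raise ValueError(f"class {name!r} is not a normalized frequency vector")


@dataclass(frozen=True)
class StoppingRule:
    """When to stop iterating a recursion.

    Iteration ends at ``max_generations`` or as soon as the largest absolute
    per-genotype frequency change in one generation drops below
    ``delta_tolerance`` (the state is then numerically at equilibrium).
    """

    max_generations: int = 100_000
    fixation_threshold: float = FIX_THRESHOLD
    delta_tolerance: float = 1e-13

    def __post_init__(self):
        if not 0 < self.fixation_threshold < 1:
            raise ValueError("fixation_threshold must be in (0, 1)")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")


@dataclass
class Trajectory:
    """Per-generation record of allele frequencies and mean fitness."""

    loci: tuple[str, ...]
    generations: list[int] = field(default_factory=list)
    allele_freqs: list[np.ndarray] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    population_size: list[float] | None = None

    def append(self, generation, freqs, fitness, size=None):
        self.generations.append(int(generation))
        self.allele_freqs.append(np.asarray(freqs, dtype=float))
        self.mean_fitness.append(float(fitness))
        if size is not None:
            if self.population_size is None:
                self.population_size = []
            self.population_size.append(float(size))

    def final_allele_freqs(self) -> dict[str, float]:
        last = self.allele_freqs[-1]
        return {locus: float(f) for locus, f in zip(self.loci, last)}

    def allele_series(self, locus: str) -> np.ndarray:
        i = self.loci.index(locus)
        return np.array([f[i] for f in self.allele_freqs])

    def to_frame(self) -> pd.DataFrame:
        data = {"generation": self.generations}
        for i, locus in enumerate(self.loci):
            data[f"freq_{locus}"] = [f[i] for f in self.allele_freqs]
        data["mean_fitness"] = self.mean_fitness
        if self.population_size is not None:
            data["population_size"] = self.population_size
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class OutcomeSummary:
    """Classification of a finished run plus final statistics."""

    outcome: str
    final_freqs: dict[str, float]
    generations: int
    mean_fitness: float
    extra: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "outcome": self.outcome,
            "final_freqs": self.final_freqs,
            "generations": self.generations,
            "mean_fitness": self.mean_fitness,
            **self.extra,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _haplotype_table(loci) -> GenotypeTable:
    return enumerate_genotypes(loci, ploidy=1)


def _zygote_map(table: GenotypeTable, haplotypes: GenotypeTable) -> np.ndarray:
    """(H, H) integer map from (maternal, paternal) haplotype to genotype."""
    n = len(haplotypes)
    out = np.empty((n, n), dtype=np.intp)
    for i, hi in enumerate(haplotypes.genotypes):
        for j, hj in enumerate(haplotypes.genotypes):
            g = tuple(a + b for a, b in zip(hi, hj))
            out[i, j] = table.index[g]
    return out


class DiploidModel:
    """A two-sex diploid random-mating model over unlinked biallelic loci.

    Parameters
    ----------
    table
        Diploid genotype table.
    female_gametes, male_gametes
        (G, H) arrays: per-genotype distribution over gamete haplotypes.
    female_fitness, male_fitness
        (G,) fertility weights in [0, 1] applied during gamete production.
    """

    def __init__(self, table, female_gametes, male_gametes,
                 female_fitness, male_fitness):
        self.table = table
        self.haplotypes = _haplotype_table(table.loci)
        self.female_gametes = np.asarray(female_gametes, dtype=float)
        self.male_gametes = np.asarray(male_gametes, dtype=float)
        self.female_fitness = np.asarray(female_fitness, dtype=float)
        self.male_fitness = np.asarray(male_fitness, dtype=float)
        for arr in (self.female_gametes, self.male_gametes):
            if not np.allclose(arr.sum(axis=1), 1.0, atol=_NORM_TOL):
                raise ValueError("gamete distributions must each sum to 1")
        for arr in (self.female_fitness, self.male_fitness):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError("fitnesses must lie in [0, 1]")
        zmap = _zygote_map(table, self.haplotypes)
        n_g = len(table)
        # (G, H*H) fold matrix: offspring outer product -> genotype vector
        self._fold = np.zeros((n_g, len(self.haplotypes) ** 2))
        self._fold[zmap.ravel(), np.arange(zmap.size)] = 1.0
        self._dosage = table.dosage()

    @property
    def loci(self):
        return self.table.loci

    def allele_freqs(self, freq: np.ndarray) -> np.ndarray:
        return freq @ self._dosage

    def mean_fitness(self, freq: np.ndarray) -> float:
        """Mean fitness of the current cohort (sexes averaged)."""
        return float(freq @ (self.female_fitness + self.male_fitness) / 2.0)

    def next_generation(self, freq: np.ndarray, generation: int = 0) -> np.ndarray:
        """One generation: selection, gamete pools, random union, census."""
        wf = freq * self.female_fitness
        wm = freq * self.male_fitness
        tf, tm = wf.sum(), wm.sum()
        if tf <= 0 or tm <= 0:
            raise InviablePopulationError(generation)
        pool_f = (wf / tf) @ self.female_gametes
        pool_m = (wm / tm) @ self.male_gametes
        zygotes = np.outer(pool_f, pool_m).ravel()
        out = self._fold @ zygotes
        return out / out.sum()

    def iterate(self, freq: np.ndarray, stop: StoppingRule,
                callback=None) -> tuple[np.ndarray, Trajectory]:
        """Iterate to the stopping condition, recording a trajectory.

        ``callback(generation, freq)`` may return a replacement frequency
        vector (used e.g. to inject a second drive mid-run).
        """
        freq = np.asarray(freq, dtype=float)
        traj = Trajectory(loci=self.table.loci)
        traj.append(0, self.allele_freqs(freq), self.mean_fitness(freq))
        for gen in range(1, stop.max_generations + 1):
            nxt = self.next_generation(freq, gen)
            if callback is not None:
                replaced = callback(gen, nxt)
                if replaced is not None:
                    nxt = replaced
            delta = np.max(np.abs(nxt - freq))
            freq = nxt
            traj.append(gen, self.allele_freqs(freq), self.mean_fitness(freq))
            if delta < stop.delta_tolerance:
                break
        return freq, traj


def hardy_weinberg_state(table: GenotypeTable, allele_freqs) -> np.ndarray:
    """Genotype frequencies at independent per-locus Hardy-Weinberg
    proportions for the given marked-allele frequencies."""
    allele_freqs = np.asarray(allele_freqs, dtype=float)
    if len(allele_freqs) != len(table.loci):
        raise ValueError("one allele frequency per locus required")
    out = np.empty(len(table))
    for k, g in enumerate(table.genotypes):
        p = 1.0
        for count, q in zip(g, allele_freqs):
            if table.ploidy == 2:
                p *= q * q if count == 2 else 2 * q * (1 - q) if count == 1 else (1 - q) ** 2
            else:
                p *= q if count == 1 else (1 - q)
        out[k] = p
    return out
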