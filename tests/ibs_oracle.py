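"""Individual-based stochastic simulators used as one-generation oracles.

These sample finite populations through the same life cycles the
deterministic engines integrate exactly, so a single generation of the
deterministic recursion must agree with the sampled frequencies to within
binomial sampling error.  Drift lives only here, never in the package.
"""

from __future__ import annotations

import numpy as np


def _draw_rows(rng, row_dists, rows):
    """For each index in ``rows``, draw one column from the categorical
    distribution in ``row_dists[row]``."""
    cum = np.cumsum(row_dists, axis=1)
    u = rng.random(len(rows))
    return (u[:, None] > cum[rows]).sum(axis=1)


def sample_diploid_generation(model, freq, n, rng):
    """One generation of a two-sex diploid model with n offspring.

    Mothers and fathers are drawn from the fitness-weighted genotype
    distribution, each contributes one gamete from its own gamete rule, and
    gametes unite at random.  Returns offspring genotype frequencies.
    """
    wf = freq * model.female_fitness
    wm = freq * model.male_fitness
    mothers = rng.choice(len(model.table), size=n, p=wf / wf.sum())
    fathers = rng.choice(len(model.table), size=n, p=wm / wm.sum())
    egg = _draw_rows(rng, model.female_gametes, mothers)
    sperm = _draw_rows(rng, model.male_gametes, fathers)
    haps = model.haplotypes.genotypes
    index = model.table.index
    zygote = np.array([index[tuple(a + b for a, b in zip(haps[i], haps[j]))]
                       for i in range(len(haps)) for j in range(len(haps))]
                      ).reshape(len(haps), len(haps))
    counts = np.bincount(zygote[egg, sperm], minlength=len(model.table))
    return counts / n


def sample_family_generation(fm, families, n_families, brood, rng):
    """One generation of a family-structured haploid-sex model.

    ``n_families`` founder families are sampled from the family-type
    distribution; each produces ``brood`` juveniles that survive
    independently with the family's viability; survivors are sexed 1:1.
    Each daughter of a Q mother sib-mates with probability m, pairing with a
    random surviving brother of her own family (the brother leaves the
    pool); all remaining juveniles join the random pool and pair at random.
    Returns the realized family-type frequency matrix.
    """
    n_h = len(fm.haplotypes)
    flat = families.ravel() / families.sum()
    fam_counts = rng.multinomial(n_families, flat).reshape(n_h, n_h)

    sib_pairs = np.zeros((n_h, n_h), dtype=np.int64)  # new sib families
    pool_daughters = np.zeros(n_h, dtype=np.int64)
    pool_sons = np.zeros(n_h, dtype=np.int64)

    for i in range(n_h):
        for j in range(n_h):
            k = fam_counts[i, j]
            if k == 0:
                continue
            survivors = rng.binomial(brood, fm.viability[i, j], size=k)
            daughters = rng.binomial(survivors, 0.5)
            sons = survivors - daughters
            wish = rng.binomial(daughters, fm.sib_fraction[i])
            mated = np.minimum(wish, sons)  # a brother per sib-mated daughter
            # haplotypes of sib pairs are iid draws from the family's
            # progeny distribution, so tally pair types multinomially
            total_pairs = int(mated.sum())
            if total_pairs:
                pair_dist = np.outer(fm.progeny[i, j], fm.progeny[i, j]).ravel()
                sib_pairs += rng.multinomial(total_pairs, pair_dist).reshape(n_h, n_h)
            d_left = int((daughters - mated).sum())
            s_left = int((sons - mated).sum())
            if d_left:
                pool_daughters += rng.multinomial(d_left, fm.progeny[i, j])
            if s_left:
                pool_sons += rng.multinomial(s_left, fm.progeny[i, j])

    # random pool: shuffle and pair
    f_ids = np.repeat(np.arange(n_h), pool_daughters)
    m_ids = np.repeat(np.arange(n_h), pool_sons)
    rng.shuffle(f_ids)
    rng.shuffle(m_ids)
    n_pairs = min(len(f_ids), len(m_ids))
    new = sib_pairs.astype(float)
    if n_pairs:
        np.add.at(new, (f_ids[:n_pairs], m_ids[:n_pairs]), 1.0)
    return new / new.sum()
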