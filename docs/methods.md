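# Methods

`drivesim` implements deterministic, discrete-generation genotype-frequency
recursions for suppression gene drives facing unlinked resistance, plus one
population-dynamic extension. Every model builds the next generation by
exhaustive enumeration of parental matings weighted by gamete-production
rules — under random mating this collapses to the product of the two
sex-specific gamete pools — followed by selection and renormalization.
There is no mutation, no migration, no linkage (all loci unlinked,
biallelic) and no drift; a stochastic individual-based simulator exists only
in the test suite, as a one-generation oracle.

## Model families

**Homing drives vs. mechanism-blocking (type-M) resistance**
(`two_drive`). Diploid two-sex model with up to two homing drives (A, B)
and a resistance locus (R). A male heterozygous at a drive locus transmits
the drive allele with probability d (d = 1 is perfect homing, 0.5
Mendelian), independently across drive loci; one copy of R — dominant,
cost-free, unlinked — restores Mendelian segregation at every locus.
Females always segregate Mendelianly. Fitness is multiplicative over drive
loci (homozygote 1−s_i, heterozygote 1−h, resistance neutral) and acts as a
fertility weight on adults during gamete production, which in this
discrete-generation life cycle is the same dynamical system as viability
selection on offspring before the census. Costs can be confined to
females. The combined suppression of two drives is 1−(1−s1)(1−s2).
Sequential introduction injects drive B (replacing wild-type B-locus
genotypes at Hardy–Weinberg proportions, evenly across backgrounds) once
drive A reaches 0.9995.

**Homing drive vs. evolving sib mating (type-P resistance)**
(`sib_homing`, engine in `families`). Sexual haploids; a mated pair forms
one brief diploid. Homing acts in Aa diploids (→ A gametes with
probability d); the recessive cost s is the viability of progeny from AA
diploids; the heterozygote cost h that of Aa progeny. The unlinked allele Q
makes a fraction m of a Q *mother's* daughters mate with brothers drawn from
the same family's post-drive progeny pool; one brother per daughter is
removed from the random pool so sib mating earns no automatic transmission
advantage. There is no inbreeding depression. Mean fitness is the average
survival of the female-destined progeny cohort. Because a family's sons
and daughters survive at the same rate, a family has either progeny of both
sexes or none, so sib-mated daughters never lack brothers — the
"orphaned-daughter" corner case cannot arise in this accounting.

With Q fixed the model admits closed-form regimes that the recursion
reproduces to numerical precision: the drive fixes if s < 1−m, is lost if
s > 1/m−1, and otherwise equilibrates at frequency 1/s − m/(1−m)
(`theory.sib_thresholds`). A type-M comparison variant replaces Q by a
dominant distortion-blocking allele in the same haploid-sex life cycle.

**ClvR toxin–antidote drive** (`clvr`). Same haploid-sex life cycle, loci
C/c (construct: nuclease + rescue) and g/G (essential gene; G = destroyed).
Any diploid carrying C converts all of its g alleles to G before gamete
production; ccGG dies; CC pays σ; gametes are Mendelian after conversion.
Under random mating the attractor has G fixed and C held overdominantly at
p̂ = (1−fσ)/[(1+σ)(1−f)] for inbreeding coefficient f, hence mean fitness
1/(1+σ) at f = 0. The sib-mating allele Q is layered on through the same
family machinery. "Sib mating selected" is classified the way the
comparison is drawn: final Q above its initial frequency *and* equilibrium
mean fitness above 1/(1+σ) by more than 1e−3. A fixed-multiple criterion
fails here because Q turns neutral the instant ClvR is purged and freezes
mid-sweep.

**Ecology** (`ecology`). Diploid two-sex homing drive (single drive + R,
as above, no adult fitness effects) coupled to numbers: N = b × (adult
females) progeny are born; every offspring survives the ceiling term
min(1, K/N), but AA offspring face a lowered ceiling min(1, K(1−sK)/N) and a
density-independent factor 1−sb; survivors are the next adults, sexed 1:1.
Relative selection against AA therefore vanishes below K(1−sK), ramps up to
1−sK at K, and is constant at 1−sb density-independently. Optional
knockdown multiplies the progeny count by a retained fraction every few
generations (a proportional cull; a reset-to-absolute-size variant is
available behind `knockdown_mode="reset"` since the verbal description of
the protocol admits both readings, but only the proportional one remains
meaningful once the population has moved away from its initial size).
Extinction is declared below one absolute adult.

## Numerical conventions

- Genotypes are tuples of per-locus marked-allele counts in lexicographic
  order; all outputs are reproducible bit-for-bit.
- Fixation: allele frequency ≥ 1−1e−8; loss: ≤ 1e−8. Deterministic
  recursions only approach boundaries asymptotically, so these are
  conventions, not dynamics.
- Iteration stops at a generation cap (1e4 for the two-drive scans, 1e5 for
  the sib-mating homing model, 2e4 for ClvR, 5e3 for ecology runs — caps
  chosen so every scanned scenario settles or cycles well within them) or
  when the largest per-class frequency change falls below 1e−13.
- Grid searches for "largest coefficient at which the drive fixes" step
  0.01 and bisect on grid indices; fixation is monotone along every scanned
  grid (a test compares bisection against exhaustive scanning). For the
  one-vs-two-drive comparison the grid steps the *combined* suppression
  (`grid_scale="combined"`), because differencing maxima from a per-drive
  grid mixes two incommensurable resolutions (the combined value moves by
  up to ~0.02 per per-drive step); single-quantity maxima use the per-drive
  grid.
- Ecology fixation classification: a trial counts as resistance-free when
  the drive fixes even if the fixed drive then extinguishes the population.
  When extinction truncates a run with a purely density-independent effect,
  the drive-vs-resistance race is settled by continuing the frequency
  recursion to the cap — with sK = 0 the genotype frequencies evolve
  independently of census size, so the continuation is exact, not an
  approximation.

## The σ = 1 degeneracy of ClvR

At exactly σ = 1 (both CC and unrescued GG lethal) the random-mating ClvR
recursion conserves the ratio of the CG to the cg haplotype pool — both are
multiplied by the same factor (1−u)/W̄ each generation, where u is the CG
pool frequency. The state space therefore carries a line of neutrally
stable equilibria, and a rare introduction (C at 0.07, G at 0) freezes on
that line with G far from fixation and mean fitness ≈ 0.95: complete-cost
ClvR cannot establish from rare in this deterministic model. For every
σ < 1 the recursion reaches the closed forms exactly (G fixed, C at p̂,
mean fitness 1/(1+σ)), and the 0.5 floor is the σ → 1 limit. The
*established* population — G already fixed, reachable by any σ < 1 history —
snaps to C = 1/2 and mean fitness 1/2 in one generation at σ = 1 from any
interior C frequency; `run_clvr(..., init_G=1.0)` computes that state, and
it is what the σ = 1 floor quantities report.

## Study conditions and problem sizes

Defaults pin the conditions of the analyses the package reproduces:
initial drive frequencies 0.005 (two drives) / 0.01 (one drive), initial
resistance 0.005 stepping by 0.01 across its grid; sib-mating panels at
m ∈ {0.2, 0.5, 0.95} with initial frequencies 0.01; ClvR panels with
initial C and Q at 0.07 assessed at 20,000 generations; ecology with
K = 1e9, initial population 1e9, initial drive and resistance 0.0005, and
knockdown to 1/4 every 5 generations. Birth rates for the ecology scans
are {4, 6, 8}: adults multiply by b/2 per generation when unregulated, so
b must exceed 2 for bare viability and ≈ 2/(1−0.43) ≈ 3.5 for the
population to persist at every coefficient inside the resistance-free
range — below that, the drive's own suppression pulls the population under
the ceiling mid-sweep and relaxes density-dependent selection, which
inflates the no-knockdown sK limit (at b = 3 it reaches 0.85 by exactly the
mechanism that knockdown exploits deliberately). The extinction-contrast
trajectories use b = 3 deliberately, since extinction under a 0.4
density-independent cost requires b < 2/(1−0.4) ≈ 3.3. The robustness
comparison of one vs. two drives samples the resistance-frequency grid at
0.02 spacing (its conclusion is a uniform bound across the grid, not a
curve shape).

## Classifier sensitivity near regime boundaries

With imperfect drive (d = 0.9) the joint (drive, Q) system is bistable in
initial conditions near the Q-invasion boundary: at m = 0.2, s = 0.77, Q
invades from initial frequency 0.2 but not from 0.01. The placement of the
invasion boundary on a 0.01 grid is therefore decided by a transient race
and is sensitive to life-cycle bookkeeping choices that the regime
thresholds themselves cannot discriminate (an independently hand-coded
recursion of the stated rules reproduces this package's boundary exactly).
The d = 0.9 fixation-range reduction (0.01 at m = 0.2) and polymorphic-zone
mean-fitness rise (up to ≈ 0.19) reported by `experiments.robustness_sib_mating`
should be read with that sensitivity in mind; the directions — imperfection
shrinks the fixation range and raises polymorphic-zone fitness, more
strongly at small m — are robust.

## What the deterministic models do and do not show

These recursions are infinite-population limits: "fixation despite
resistance" means the resistance allele's expected frequency stays bounded
while the drive's goes to one, not that resistance cannot win by drift in a
small release. Real populations add drift, Allee effects, spatial
structure, demographic stochasticity at low density (especially relevant to
the extinction classifications), non-ceiling density dependence, and
allelic (target-site) resistance — all outside this package's scope. The
test suite's stochastic oracle checks only that one generation of sampling
noise brackets the deterministic step at N = 10^6, i.e. that the recursion
is the correct mean-field limit of the stated life cycles.
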