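"""Closed-form equilibrium results for the drive systems.

These are the analytic counterparts of the recursion modules and double as
oracles in the test suite: equilibrium mean-fitness curves for one-sex and
two-sex homing drives and for ClvR, and the sib-mating regime thresholds.
"""

from __future__ import annotations

__all__ = [
    "onesex_homing_mean_fitness",
    "twosex_homing_mean_fitness",
    "clvr_mean_fitness",
    "sib_thresholds",
]


def _check_unit(name, value):
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def onesex_homing_mean_fitness(s: float) -> float:
    """Equilibrium mean fitness of a one-sex homing drive with complete
    distortion and recessive cost s in both sexes.

    For s <= 0.5 the drive fixes and mean fitness is 1-s.  For s > 0.5 the
    population stays polymorphic (the non-driving sex keeps supplying
    wild-type gametes) and mean fitness is pinned at 0.5 for all 0.5 < s < 1:
    a one-sex drive cannot suppress mean fitness below one half.
    """
    _check_unit("s", s)
    return 1.0 - s if s <= 0.5 else 0.5


def twosex_homing_mean_fitness(s: float) -> float:
    """Equilibrium mean fitness of a two-sex homing drive with complete
    distortion: the drive fixes for any s, so mean fitness is 1-s, reaching
    0 at s = 1."""
    _check_unit("s", s)
    return 1.0 - s


def clvr_mean_fitness(sigma: float) -> float:
    """Equilibrium mean fitness of ClvR under random mating: 1/(1 + sigma),
    with floor 0.5 at sigma = 1 (only Cc heterozygotes viable)."""
    _check_unit("sigma", sigma)
    return 1.0 / (1.0 + sigma)


def sib_thresholds(m: float):
    """Regime bounds for a two-sex homing drive facing sib-mating fraction m.

    Returns (fixation bound, loss bound, polymorphic frequency function):
    the drive fixes for s < 1-m, is lost for s > min(1/m - 1, 1), and in
    between sits at frequency 1/s - m/(1-m).  m = 0 is degenerate (the drive
    always fixes).
    """
    _check_unit("m", m)
    if m == 0.0:
        return 1.0, float("inf"), lambda s: 1.0
    fixation_bound = 1.0 - m
    loss_bound = min(1.0 / m - 1.0, 1.0)

    def poly_freq(s: float) -> float:
        if m == 1.0:
            raise ValueError("no polymorphic zone at m = 1")
        return 1.0 / s - m / (1.0 - m)

    return fixation_bound, loss_bound, poly_freq
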