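"""How low can each drive system push mean fitness?

Compares the closed-form equilibrium mean-fitness curves of one-sex homing,
two-sex homing and ClvR drives, and confirms two of the floors by running
the recursions.
"""

from drivesim import theory
from drivesim.clvr import ClvRParams, run_clvr
from drivesim.core import StoppingRule
from drivesim.two_drive import DriveParams, build_model, initial_state

print(f"{'s or sigma':>10} {'one-sex homing':>15} {'two-sex homing':>15} {'ClvR':>8}")
for s in (0.25, 0.5, 0.75, 1.0):
    print(f"{s:10.2f} {theory.onesex_homing_mean_fitness(s):15.3f} "
          f"{theory.twosex_homing_mean_fitness(s):15.3f} "
          f"{theory.clvr_mean_fitness(s):8.3f}")

params = DriveParams(s1=0.75, init_drive=0.01, init_resistance=0.0)
model = build_model(params)
_, traj = model.iterate(initial_state(model, params),
                        StoppingRule(max_generations=100_000))
print(f"\none-sex homing recursion at s=0.75: mean fitness {traj.mean_fitness[-1]:.6f}")

_, summary = run_clvr(ClvRParams(sigma=1.0, init_G=1.0), with_sib_mating=False)
print(f"established ClvR recursion at sigma=1: mean fitness {summary.mean_fitness:.6f}")

print()
print("Only a two-sex homing drive can push mean fitness below 0.5: a one-sex")
print("drive stalls polymorphic (the non-driving sex keeps supplying wild-type")
print("gametes) and ClvR is capped by its heterozygote-only equilibrium.")
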