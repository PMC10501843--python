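"""Solve one split feasibility problem with all four projection schemes.

Builds a seeded feasible instance (random 20x10 operator, L2-ball
constraint set, target set containing the planted image) and runs each
scheme until the split residual f_n = 0.5*||(I - P_Q)Aw||^2 drops below
1e-10.  The iteration counts show the acceleration from the inertial and
Mann modifications; the distance column confirms each final iterate sits
near the planted solution (the problem may have many solutions, so exact
recovery is not expected).
"""

import numpy as np

from relaxedcq import SolverConfig, make_sfp_instance, solve

problem = make_sfp_instance(m=20, n=10, constraint="l2_ball", seed=42)
config = SolverConfig(max_iter=5000, tol=1e-10)

print(f"instance: A {problem.shape}, constraint {problem.Cset.label}, "
      f"gamma {problem.meta['gamma']}")
print(f"{'method':>8} {'iterations':>10} {'residual':>12} {'dist to w*':>12}")
for method in ("imrcqm", "dang", "igrcq", "byrne"):
    run = solve(problem, method=method, config=config)
    dist = np.linalg.norm(run.final - problem.known_solution)
    print(f"{method:>8} {run.n_iter:>10} {run.residuals[-1]:>12.2e} {dist:>12.4f}")
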