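"""Compare the three relaxed schemes under both norm budgets.

Runs {inertial Mann, inertial relaxed CQ, self-adaptive generalized
relaxed CQ} x {L1 ball gamma=7, L2 ball gamma=17} on one synthetic
marginal-matched table with 5-fold cross-validation, mirroring the layout
of a method-comparison table: per-fold iteration average plus the four
confusion-matrix metrics in percent.
"""

import numpy as np

from relaxedcq import SolverConfig, SyntheticSpec, cross_validate, make_classification_table

table = make_classification_table(SyntheticSpec(seed=1))
config = SolverConfig(max_iter=300, tol=1e-10)

print(f"{'method':>8} {'set':>8} {'iters':>6} {'acc':>7} {'prec':>7} "
      f"{'recall':>7} {'f1':>7}")
for method in ("imrcqm", "dang", "igrcq"):
    for constraint, gamma in (("l1_ball", 7.0), ("l2_ball", 17.0)):
        res = cross_validate(
            table, n_hidden=160, constraint=constraint, gamma=gamma,
            method=method, config=config, k=5, seed=1, record_curves=False,
        )
        m = res.mean_metrics
        print(f"{method:>8} {constraint[:7]:>8} "
              f"{np.mean(res.fold_iterations):>6.0f} {m['accuracy']:>7.2f} "
              f"{m['precision']:>7.2f} {m['recall']:>7.2f} {m['f1']:>7.2f}")
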