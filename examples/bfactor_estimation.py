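"""Estimate atomic B-factors from Q-scores by the CC-mean scaling scan.

Renders a map from isolated atoms with known heterogeneous B-factors
(derived from chosen per-atom Q and a true scaling factor f* = 120), then
scans f over 0..300 and shows that the scan recovers f* and that the
optimal model-map correlates better with the map than the all-B=0 one.
"""

import numpy as np

from qscore3d import (
    FixtureSpec,
    QScoreParams,
    make_isolated_model,
    make_map,
    scan_scaling,
)
from qscore3d.qscore import AtomQ, QScoreTable

F_TRUE = 120.0
model = make_isolated_model(n_atoms=6, spacing=7.0)
q_true = np.random.default_rng(8).uniform(0.3, 0.95, 6)
b_true = (1 - q_true) * F_TRUE
grid = make_map(model, FixtureSpec(pad=5.0), b_factors=b_true)

table = QScoreTable(
    [AtomQ(a, q, 30) for a, q in zip(model.scoreable_atoms(), q_true)],
    QScoreParams(),
)
scan = scan_scaling(model, table, grid)

print("per-atom Q:", np.round(q_true, 2))
print("true B (Å²):", np.round(b_true, 1))
print(f"recovered f_opt = {scan.f_opt:g}  (true {F_TRUE:g})")
print(f"CC-mean at f_opt = {max(scan.cc_values):.4f}; at B=0: {scan.cc_values[0]:.4f}")
print("estimated B (Å²):", np.round(scan.b_factors, 1))
# CC at the optimum exceeds CC at B=0: heterogeneous blur in the map is
# explained by the Q-derived B-factors
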