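"""One edge changes, every angle responds: the 4-node alignment demo.

Nodes A and D start with identical coupling profiles (0.3 to B, 0.7 to
C) and no direct edge, so their position vectors in the dominant-
eigenvector frame coincide. Raising the B-D weight from 0.3 to 1.0 pulls
D toward B — tightening the B-D alignment — and in doing so breaks the
A-D alignment, although nothing about A's own edges changed. Plain
edge-weight monitoring would only ever notice the B-D change.
"""

import numpy as np

import eigenalign as ea

config = ea.PipelineConfig(scaling_mode="unit", use_cst=False)
labels = "ABCD"

for boost in (0.3, 1.0):
    result = ea.run_subject(ea.toy_network(boost), config)
    theta = result.angles.angles
    print(f"B-D weight = {boost}:")
    for i, j in [(0, 3), (1, 3), (0, 1)]:
        print(f"  theta({labels[i]},{labels[j]}) = {theta[i, j]:.3f} rad")
    print()

print(
    "Boosting B-D tightens that pair's alignment while the untouched A-D\n"
    "pair swings from near-perfect alignment (~0 rad) to more than a\n"
    "radian apart: alignment reads the whole network, not single edges."
)
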