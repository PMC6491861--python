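"""Peel-and-zoom: resolve remote relatedness by removing close pairs.

An 'empirical' set of FS, HS, FC and UN pairs is classified round by round;
after each round the pairs assigned to the peeled category are removed and
the log-ratio PCA is refitted on a reference set without that relationship,
zooming in on the remaining, remoter structure.
"""

import numpy as np

from lrkin import build_reference_set, peel_and_zoom
from lrkin.pedigree import HweFounders

founders = HweFounders(0.5, 5_000)
emp = build_reference_set(("FS", "HS", "FC", "UN"), founders, 15, seed=77)


def builder(labels, seed):
    return build_reference_set(labels, founders, 25, seed=seed)


iters = peel_and_zoom(
    emp.compositions(),
    builder,
    relationships=("FS", "HS", "FC", "UN"),
    peel_schedule=[["FS"], ["HS"]],
    n_pcs=3,
    seed=11,
)

for r, it in enumerate(iters):
    print(f"round {r}: reference = {it.reference_labels}")
    lab, cnt = np.unique(it.peeled_predicted, return_counts=True) if len(it.peeled_predicted) else ([], [])
    print(f"  peeled {len(it.peeled_rows)} pairs as {dict(zip(map(str, lab), map(int, cnt)))}")
    print(f"  {len(it.kept_rows)} pairs remain")
truth = emp.labels[iters[-1].kept_rows]
lab, cnt = np.unique(truth, return_counts=True)
print("\ntrue labels of the surviving pairs:", dict(zip(map(str, lab), map(int, cnt))))
# After peeling FS and HS the survivors are the FC and UN pairs: each round
# removes the dominant close cluster so the next fit spreads the remoter
# relationships over the leading components.
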