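"""Synthetic 2-kb toy superhelical domain for demos and tests.

Deterministically generated (no data file): a G/C-rich background with one
long A/T-rich island a fixed distance upstream of a nominal TSS, mimicking
the geometry of a destabilized far-upstream element, plus a shorter A/T
patch downstream.  Entirely synthetic — not the mouse *Myc* sequence.
"""

from __future__ import annotations

import numpy as np

TOY_LENGTH = 2000
TOY_TSS = 1800            # nominal TSS position within the domain (0-based)
TOY_ISLAND = (520, 700)   # A/T-rich island: the intended strongest melt site
TOY_PATCH = (1500, 1560)  # weaker downstream A/T patch
_SEED = 20201001


def toy_myc_domain_sequence() -> str:
    """2000-bp synthetic domain; deterministic across calls."""
    rng = np.random.default_rng(_SEED)
    # background: 70% G/C
    bases = np.array(list("ACGT"))
    probs = np.array([0.15, 0.35, 0.35, 0.15])
    seq = rng.choice(bases, size=TOY_LENGTH, p=probs)
    for lo, hi in (TOY_ISLAND, TOY_PATCH):
        at = rng.choice(
            np.array(list("AT")), size=hi - lo, p=np.array([0.5, 0.5])
        )
        gc_sprinkle = rng.random(hi - lo) < 0.05
        at[gc_sprinkle] = rng.choice(np.array(list("GC")), size=int(gc_sprinkle.sum()))
        seq[lo:hi] = at
    return "".join(seq)
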