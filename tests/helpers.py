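"""Shared test helpers and independent oracles."""

import math

import numpy as np

from srnapipe.seqio import revcomp


def binomial_tail_oracle(x, y, n1, n2):
    """Brute-force conditional-binomial tail summation with exact binomial
    coefficients; independent of the scipy-based implementation."""
    n = x + y
    if n == 0:
        return 1.0
    q = n2 / (n1 + n2)
    pmf = [math.comb(n, k) * q**k * (1 - q) ** (n - k) for k in range(n + 1)]
    lower = sum(pmf[: y + 1])
    upper = sum(pmf[y:])
    return min(1.0, 2.0 * min(lower, upper))


def perfect_hairpin(rng, mature_len=21, ext=9, loop=8):
    """A precursor whose 5' arm starts with the mature sequence."""
    nts = np.array(list("ACGT"))
    arm = "".join(rng.choice(nts, mature_len + ext))
    pre = arm + "".join(rng.choice(nts, loop)) + revcomp(arm)
    return pre, arm[:mature_len]
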