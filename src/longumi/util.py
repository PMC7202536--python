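"""Small sequence utilities used across stages."""

from __future__ import annotations

import numpy as np

_RC = str.maketrans("ACGTN", "TGCAN")

#: default seed used by CLI entry points when the user gives none
DEFAULT_SEED = 1


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_RC)[::-1]


def phred_to_prob(q) -> np.ndarray:
    """P(base call correct) for Phred score(s) q: 1 - 10**(-q/10)."""
    return 1.0 - 10.0 ** (-np.asarray(q, dtype=float) / 10.0)


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive `n` independent generators from one seed.

    Single-seed determinism across pipeline stages: each stage receives its
    own child stream of ``SeedSequence(seed)`` so that adding reads to one
    stage never perturbs another.
    """
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
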