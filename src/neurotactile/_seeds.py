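"""Deterministic seed fan-out.

A single master seed reproduces a whole experiment.  Every consumer of
randomness (stimulus noise, innervation, nociceptor gain jitter, CV splits,
fault subsets) derives its own child seed from the master through a named
domain plus a counter, so adding one consumer never shifts the seeds of the
others.
"""

from __future__ import annotations

import numpy as np

# Stable domain codes; order is part of the reproducibility contract.
_DOMAINS = {
    "stimulus": 0,
    "innervation": 1,
    "nociceptor": 2,
    "split": 3,
    "fault": 4,
    "misc": 5,
}


def derive_seed(master_seed: int, domain: str, index: int = 0) -> int:
    """Derive a child seed (< 2**31) for *domain* / *index* from *master_seed*."""
    if domain not in _DOMAINS:
        raise KeyError(f"unknown seed domain {domain!r}; one of {sorted(_DOMAINS)}")
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(_DOMAINS[domain], int(index)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
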