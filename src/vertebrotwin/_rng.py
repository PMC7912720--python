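"""Deterministic stream splitting.

All randomness in the package flows from one integer master seed.  Named
substreams are derived with :class:`numpy.random.SeedSequence` spawn keys so
that every stage (cohort, phenotypes, geometry, noise) can be re-run in
isolation and still reproduce bit-identical output.
"""

from __future__ import annotations

import numpy as np

# Fixed stream indices: changing these renumbers every downstream draw.
_STREAMS = {
    "cohort": 0,
    "phenotype": 1,
    "geometry": 2,
    "perturb": 3,
    "analysis": 4,
}


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    ``index`` distinguishes repeated uses within a stage (e.g. one vessel
    network per subject).
    """
    if name not in _STREAMS:
        raise KeyError(f"unknown stream name {name!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[name], int(index)))
    return np.random.Generator(np.random.PCG64(ss))
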