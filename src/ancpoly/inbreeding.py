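"""Expected heterozygosity decay under full-sib (brother x sister) mating.

Inbred laboratory strains are propagated by sibling mating; the inbreeding
coefficient follows the classical recurrence

    F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4,    F_0 = F_1 = 0,

and the expected fraction of initially heterozygous loci still segregating at
generation t is H_t / H_0 = 1 - F_t.  Asymptotically the retention decays
geometrically with ratio (1 + sqrt(5)) / 4 ~= 0.809 per generation, so after
~37 generations only a few parts in 10^4 of the founder heterozygosity
remain -- the magnitude observed as residual heterozygosity in long-inbred
strains.
"""

from __future__ import annotations

import functools
import math

import numpy as np

#: Asymptotic per-generation retention ratio of heterozygosity, (1+sqrt(5))/4.
FULL_SIB_DECAY: float = (1.0 + math.sqrt(5.0)) / 4.0


@functools.lru_cache(maxsize=None)
def _coefficients(max_generation: int) -> tuple[float, ...]:
    f = [0.0, 0.0]
    for _ in range(2, max_generation + 1):
        f.append((1.0 + 2.0 * f[-1] + f[-2]) / 4.0)
    return tuple(f[: max_generation + 1])


def inbreeding_coefficient(generation: int) -> float:
    """Inbreeding coefficient F_t after `generation` rounds of full-sib mating."""
    if generation < 0:
        raise ValueError("generation must be >= 0")
    return _coefficients(max(generation, 1))[generation]


def het_retention(generation: int) -> float:
    """Expected fraction of founder heterozygosity retained, 1 - F_t."""
    return 1.0 - inbreeding_coefficient(generation)


def retention_curve(max_generation: int, multiplier: float = 1.0) -> np.ndarray:
    """Retention R(t) = min(1, (1 - F_t) * multiplier) for t = 0..max_generation.

    The multiplier models balancing selection at a locus: values > 1 delay
    loss of heterozygosity (capped at full retention), 1.0 is neutral decay.
    """
    if multiplier < 0:
        raise ValueError("multiplier must be >= 0")
    f = np.asarray(_coefficients(max(max_generation, 1))[: max_generation + 1])
    return np.minimum(1.0, (1.0 - f) * multiplier)


def balancing_multiplier(target_retention: float, generation: int) -> float:
    """Multiplier making retention equal `target_retention` at `generation`.

    Convenience inverse of :func:`retention_curve`: under neutral full-sib
    decay essentially no heterozygosity survives 100 generations, so loci
    under balancing selection are parameterized by the retention one wants to
    observe at the end of the breeding history.
    """
    if not 0.0 < target_retention <= 1.0:
        raise ValueError("target_retention must be in (0, 1]")
    return target_retention / het_retention(generation)
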