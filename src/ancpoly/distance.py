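"""Pairwise strain distances by symmetric difference of mutation sets.

The distance between two strains is the number of homozygous non-reference
mutations observed in exactly one of them: |A triangle B| on (chrom, pos, alt)
keys.  Because keys are allele-level, two strains homozygous for *different*
alternate alleles at one site contribute 2 (two mutation events), not 1; the
counts are a metric on variant sets and, with a configured aligned-length
denominator, convert to substitutions per 10,000 bases for display.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import StrainVariantSet


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal.

    `unit` is "mutations" for raw symmetric-difference counts or
    "per10kb" after normalization by an aligned-length denominator.
    """

    strains: list[str]
    values: np.ndarray
    unit: str = "mutations"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.strains)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match strain count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0) or np.any(np.isnan(self.values)):
            raise ValueError("distances must be finite and non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.strains.index(a), self.strains.index(b)])

    def normalized(self, aligned_length: int) -> "DistanceMatrix":
        """Convert raw counts to substitutions per 10,000 aligned bases."""
        if aligned_length <= 0:
            raise ValueError("aligned_length must be positive")
        return DistanceMatrix(
            list(self.strains), self.values / (aligned_length / 10_000.0), unit="per10kb"
        )

    def to_tsv(self, path: str | os.PathLike, header_lines: Sequence[str] = ()) -> None:
        frame = pd.DataFrame(self.values, index=self.strains, columns=self.strains)
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            frame.to_csv(fh, sep="\t", index_label="strain")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, unit: str = "mutations") -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        return cls(list(frame.columns), frame.to_numpy(dtype=float), unit=unit)


def pairwise_distance(set_a: StrainVariantSet, set_b: StrainVariantSet) -> int:
    """|mutations_a triangle mutations_b| on (chrom, pos, alt) keys."""
    return len(set_a.mutations ^ set_b.mutations)


def distance_matrix(
    sets: Sequence[StrainVariantSet], restrict_to: str | None = None
) -> DistanceMatrix:
    """All-pairs symmetric-difference distances.

    `restrict_to` filters mutation keys to one chromosome before
    differencing, which is how per-chromosome trees are built.
    """
    if len(sets) < 3:
        raise ValueError("at least 3 strains are required for a distance matrix")
    names = [s.strain for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strain names")
    keys = [
        s.mutations
        if restrict_to is None
        else frozenset(k for k in s.mutations if k[0] == restrict_to)
        for s in sets
    ]
    n = len(sets)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = len(keys[i] ^ keys[j])
    return DistanceMatrix(names, values)
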