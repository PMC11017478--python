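"""Shared data containers.

The package works on four substrates: diploid multi-allelic genotypes
(:class:`GenotypeTable`), 2-D landmark configurations (:class:`LandmarkSet`),
labelled distance matrices (scikit-bio :class:`~skbio.stats.distance.DistanceMatrix`
is used directly), and plain :class:`pandas.DataFrame` tables for environments,
phenotypes and capture histories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeTable", "LandmarkSet"]

#: allele code used for a missing allele call (GENEPOP "000")
MISSING = 0


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls with population labels.

    Parameters
    ----------
    alleles
        Integer array of shape ``(n_individuals, n_loci, 2)``.  Allele codes
        are positive integers; ``0`` marks a missing allele.  A genotype is
        either fully typed (both alleles > 0) or fully missing (both 0).
    populations
        Population label per individual.
    individuals
        Unique individual identifiers.
    loci
        Locus names, identical for every individual.
    """

    alleles: np.ndarray
    populations: np.ndarray
    individuals: np.ndarray
    loci: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        self.populations = np.asarray(self.populations, dtype=object)
        self.individuals = np.asarray(self.individuals, dtype=object)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n, n_loci, 2)")
        n = self.alleles.shape[0]
        if len(self.populations) != n or len(self.individuals) != n:
            raise ValueError("populations/individuals length mismatch")
        if self.alleles.shape[1] != len(self.loci):
            raise ValueError("locus names do not match allele array")
        if np.any(self.alleles < 0):
            raise ValueError("allele codes must be non-negative")
        half = (self.alleles == MISSING).sum(axis=2)
        if np.any(half == 1):
            raise ValueError("half-missing genotype calls are not allowed")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def population_names(self) -> list[str]:
        """Population labels in order of first appearance."""
        return list(pd.unique(pd.Series(self.populations)))

    def typed_mask(self) -> np.ndarray:
        """Boolean ``(n, n_loci)`` mask of fully typed genotype calls."""
        return np.all(self.alleles != MISSING, axis=2)

    def subset_populations(self, names) -> "GenotypeTable":
        names = list(names)
        missing = set(names) - set(self.population_names)
        if missing:
            raise KeyError(f"unknown populations: {sorted(missing)}")
        keep = np.isin(self.populations, names)
        return GenotypeTable(
            self.alleles[keep], self.populations[keep], self.individuals[keep], list(self.loci)
        )

    def counts(self):
        """Allele-count array ``(n_pops, n_loci, n_allele_codes)``.

        Returns
        -------
        counts : ndarray
            ``counts[p, l, a]`` is the number of copies of allele code
            ``a + 1`` at locus ``l`` in population ``p`` (missing excluded).
        pops : list of str
            Population order (order of first appearance).
        n_typed : ndarray
            ``(n_pops, n_loci)`` typed-individual counts.
        """
        pops = self.population_names
        a_max = int(self.alleles.max(initial=0))
        counts = np.zeros((len(pops), self.n_loci, max(a_max, 1)), dtype=np.int64)
        typed = self.typed_mask()
        n_typed = np.zeros((len(pops), self.n_loci), dtype=np.int64)
        for p, pop in enumerate(pops):
            rows = self.populations == pop
            sub = self.alleles[rows]
            sub_typed = typed[rows]
            n_typed[p] = sub_typed.sum(axis=0)
            for l in range(self.n_loci):
                calls = sub[sub_typed[:, l], l, :].ravel()
                if calls.size:
                    np.add.at(counts[p, l], calls - 1, 1)
        return counts, pops, n_typed


@dataclass
class LandmarkSet:
    """Per-specimen 2-D landmark configurations with metadata.

    ``coords`` has shape ``(n_specimens, n_landmarks, 2)``.  ``sliding``
    lists the semilandmark indices; each must appear in ``chains`` as a
    ``(before, index, after)`` neighbour triple defining the chord it may
    slide along.  ``head_subset`` optionally records the landmark indices
    used for head-only analyses.
    """

    coords: np.ndarray
    specimen_ids: np.ndarray
    populations: np.ndarray
    fork_length: np.ndarray
    sliding: list[int] = field(default_factory=list)
    chains: list[tuple[int, int, int]] = field(default_factory=list)
    head_subset: list[int] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.populations = np.asarray(self.populations, dtype=object)
        self.specimen_ids = np.asarray(self.specimen_ids, dtype=object)
        self.fork_length = np.asarray(self.fork_length, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (n, k, 2)")
        n = self.coords.shape[0]
        if not (len(self.populations) == len(self.specimen_ids) == len(self.fork_length) == n):
            raise ValueError("metadata length mismatch")
        chain_idx = {c[1] for c in self.chains}
        for s in self.sliding:
            if s not in chain_idx:
                raise ValueError(f"sliding landmark {s} has no neighbour chain")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    def subset_landmarks(self, indices) -> "LandmarkSet":
        """New set restricted to the given landmark indices (e.g. the head)."""
        indices = list(indices)
        remap = {old: new for new, old in enumerate(indices)}
        sliding = [remap[s] for s in self.sliding if s in remap]
        chains = [
            (remap[a], remap[b], remap[c])
            for a, b, c in self.chains
            if a in remap and b in remap and c in remap
        ]
        # a semilandmark whose neighbours were dropped becomes fixed
        sliding = [s for s in sliding if any(c[1] == s for c in chains)]
        return LandmarkSet(
            self.coords[:, indices, :],
            self.specimen_ids,
            self.populations,
            self.fork_length,
            sliding=sliding,
            chains=chains,
        )
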