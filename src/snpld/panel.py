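"""Core in-memory containers: variant records and diploid genotype panels.

Genotypes are stored as allele-B dosages in a samples x loci ``int8`` matrix.
``MISSING`` (-1) marks a missing call and is distinguishable from every valid
dosage {0, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import SnpldError

#: Sentinel for a missing genotype call in the dosage matrix.
MISSING: int = -1

#: Bos taurus autosome labels ("1".."29"); the default set of chromosomes kept by QC.
CATTLE_AUTOSOMES: frozenset[str] = frozenset(str(i) for i in range(1, 30))


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP: map position plus the two allele codes.

    ``alleleB`` is the allele counted by the dosage matrix.  For a locus that
    is monomorphic in the data, only one allele code is observed and the other
    is the placeholder ``"0"``.
    """

    chrom: str
    pos: int
    vid: str
    alleleA: str
    alleleB: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.vid!r}: position must be >= 1, got {self.pos}")
        if self.alleleA == self.alleleB:
            raise ValueError(f"variant {self.vid!r}: alleleA == alleleB ({self.alleleA!r})")


@dataclass
class GenotypePanel:
    """Samples x loci allele-B dosage matrix with population labels.

    Attributes
    ----------
    dosages
        ``(n_samples, n_loci)`` int8 array with entries in {0, 1, 2, MISSING}.
    sample_ids
        One unique identifier per row.
    population_of
        Mapping from sample identifier to population label; every sample has
        exactly one label.
    variants
        One :class:`VariantRecord` per column, in column order.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    population_of: dict[str, str]
    variants: list[VariantRecord]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise SnpldError("dosages must be a 2-D samples x loci matrix")
        n_s, n_l = self.dosages.shape
        if n_s != len(self.sample_ids):
            raise SnpldError(f"{n_s} dosage rows but {len(self.sample_ids)} sample ids")
        if n_l != len(self.variants):
            raise SnpldError(f"{n_l} dosage columns but {len(self.variants)} variants")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SnpldError("duplicate sample ids")
        missing_labels = [s for s in self.sample_ids if s not in self.population_of]
        if missing_labels:
            raise SnpldError(f"samples without a population label: {missing_labels[:5]}")
        valid = (self.dosages >= 0) & (self.dosages <= 2) | (self.dosages == MISSING)
        if not valid.all():
            raise SnpldError("dosage entries must be in {0, 1, 2, MISSING}")

    # ------------------------------------------------------------------ shape
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance among samples."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.population_of[s], None)
        return list(seen)

    # -------------------------------------------------------------- selection
    def sample_indices(self, population: str | None = None) -> np.ndarray:
        """Row indices of samples belonging to *population* (all if None)."""
        if population is None:
            return np.arange(self.n_samples)
        idx = [i for i, s in enumerate(self.sample_ids) if self.population_of[s] == population]
        if not idx:
            raise SnpldError(f"unknown population label {population!r}")
        return np.asarray(idx)

    def subset(
        self,
        samples: Sequence[int] | np.ndarray | None = None,
        loci: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypePanel":
        """New panel restricted to the given sample rows and/or locus columns."""
        s_idx = np.arange(self.n_samples) if samples is None else np.asarray(samples, dtype=np.int64)
        l_idx = np.arange(self.n_loci) if loci is None else np.asarray(loci, dtype=np.int64)
        ids = [self.sample_ids[i] for i in s_idx]
        return GenotypePanel(
            dosages=self.dosages[np.ix_(s_idx, l_idx)].copy(),
            sample_ids=ids,
            population_of={s: self.population_of[s] for s in ids},
            variants=[self.variants[j] for j in l_idx],
        )

    def restrict_population(self, population: str) -> "GenotypePanel":
        return self.subset(samples=self.sample_indices(population))

    # ----------------------------------------------------------- orientation
    def flip_loci(self, loci: Iterable[int]) -> "GenotypePanel":
        """Swap alleleA/alleleB at the given loci, mapping dosage d -> 2 - d.

        Missing calls stay missing.  LD magnitudes (r2, |D'|), MAF, call rate
        and the HWE test are invariant under this relabeling; the sign of D
        flips.
        """
        out = self.dosages.copy()
        variants = list(self.variants)
        for j in loci:
            col = out[:, j]
            obs = col != MISSING
            col[obs] = 2 - col[obs]
            v = variants[j]
            variants[j] = replace(v, alleleA=v.alleleB, alleleB=v.alleleA)
        return GenotypePanel(out, list(self.sample_ids), dict(self.population_of), variants)

    def canonicalize_orientation(self) -> "GenotypePanel":
        """Flip loci whose first non-missing genotype is homozygous alleleB.

        After canonicalisation the first-observed allele at every locus (the
        orientation a PED reader infers) is alleleA, which makes the PED/MAP
        round trip an exact identity on the dosage matrix.
        """
        to_flip = []
        for j in range(self.n_loci):
            col = self.dosages[:, j]
            obs = np.nonzero(col != MISSING)[0]
            if obs.size and col[obs[0]] == 2:
                to_flip.append(j)
        return self.flip_loci(to_flip) if to_flip else self

    # ------------------------------------------------------------------ misc
    def sorted_by_position(self) -> "GenotypePanel":
        """Panel with loci ordered by (chromosome label, position, vid)."""
        order = sorted(
            range(self.n_loci),
            key=lambda j: (_chrom_key(self.variants[j].chrom), self.variants[j].pos,
                           self.variants[j].vid),
        )
        if order == list(range(self.n_loci)):
            return self
        return self.subset(loci=order)


def _chrom_key(chrom: str) -> tuple[int, str]:
    """Sort numeric chromosome labels numerically, others lexically after them."""
    try:
        return (0, f"{int(chrom):09d}")
    except ValueError:
        return (1, chrom)


def make_panel(
    dosages: np.ndarray,
    *,
    chrom: str | Sequence[str] = "1",
    positions: Sequence[int] | None = None,
    populations: Mapping[str, str] | str = "pop1",
    sample_ids: Sequence[str] | None = None,
) -> GenotypePanel:
    """Convenience constructor used heavily in tests and examples.

    Builds variant records with alleles A/B, default 10-kb spaced positions,
    and a single population label unless an explicit mapping is given.
    """
    dosages = np.asarray(dosages, dtype=np.int8)
    n_s, n_l = dosages.shape
    ids = list(sample_ids) if sample_ids is not None else [f"s{i}" for i in range(n_s)]
    if isinstance(populations, str):
        pop_of = {s: populations for s in ids}
    else:
        pop_of = dict(populations)
    chroms = [chrom] * n_l if isinstance(chrom, str) else list(chrom)
    pos = list(positions) if positions is not None else [10_000 * (j + 1) for j in range(n_l)]
    variants = [
        VariantRecord(chrom=chroms[j], pos=pos[j], vid=f"snp{j}", alleleA="A", alleleB="B")
        for j in range(n_l)
    ]
    return GenotypePanel(dosages, ids, pop_of, variants)
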