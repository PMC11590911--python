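"""SNP quality control: MAF, call rate, exact Hardy-Weinberg test, the staged
QC cascade, per-population MAF spectra and monomorphic-marker overlap.

The cascade removes loci in three ordered stages, each locus counted once:

1. non-autosomal (X, Y, mitochondrial) loci;
2. Hardy-Weinberg exact-test p-value below threshold (computed on the panel
   pooled across populations);
3. call rate or pooled minor-allele frequency below threshold (one merged
   stage, reported as a single count).

All inequalities are strict: a locus exactly at a threshold is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats

from .errors import SnpldError, UndefinedStatisticError
from .panel import CATTLE_AUTOSOMES, MISSING, GenotypePanel
from .plink_io import write_table

#: Default per-population MAF histogram bin edges.
DEFAULT_MAF_EDGES: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class QCThresholds:
    """Locus-filter thresholds. Loci strictly below a threshold are removed."""

    hwe_p_min: float = 1e-7
    maf_min: float = 0.05
    call_rate_min: float = 0.90
    autosomes: frozenset[str] = CATTLE_AUTOSOMES
    hwe_method: str = "exact"  # "exact" or "chisq"

    def __post_init__(self) -> None:
        for name in ("hwe_p_min", "maf_min", "call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SnpldError(f"{name} must be in [0, 1], got {v}")
        if self.hwe_method not in ("exact", "chisq"):
            raise SnpldError(f"hwe_method must be 'exact' or 'chisq', got {self.hwe_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QCThresholds":
        """Load thresholds from a flat YAML mapping; absent keys keep defaults."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("hwe_p_min", "maf_min", "call_rate_min", "hwe_method"):
            if key in raw:
                kwargs[key] = raw[key]
        if "autosomes" in raw:
            kwargs["autosomes"] = frozenset(str(c) for c in raw["autosomes"])
        return cls(**kwargs)


@dataclass
class QCReport:
    """Stage-by-stage accounting of the QC cascade.

    Invariant: ``n_input = n_removed_nonautosomal + n_removed_hwe +
    n_removed_callrate_or_maf + n_retained`` and every removed vid appears in
    exactly one stage.
    """

    n_input: int
    n_removed_nonautosomal: int
    n_removed_hwe: int
    n_removed_callrate_or_maf: int
    n_retained: int
    removed_ids_by_stage: dict[str, list[str]] = field(default_factory=dict)

    def check_partition(self) -> None:
        total = (self.n_removed_nonautosomal + self.n_removed_hwe
                 + self.n_removed_callrate_or_maf + self.n_retained)
        if total != self.n_input:
            raise SnpldError(f"QC partition identity violated: {total} != {self.n_input}")

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            ("input", self.n_input),
            ("removed_nonautosomal", self.n_removed_nonautosomal),
            ("removed_hwe", self.n_removed_hwe),
            ("removed_callrate_or_maf", self.n_removed_callrate_or_maf),
            ("retained", self.n_retained),
        ]
        write_table(rows, path, columns=("stage", "n_loci"))


# ----------------------------------------------------------------- per-column
def maf(dosage_column: np.ndarray) -> float:
    """Minor-allele frequency of one locus: min(f, 1-f) with
    f = (sum of dosages) / (2 * non-missing samples).

    Raises
    ------
    UndefinedStatisticError
        If every genotype is missing.
    """
    col = np.asarray(dosage_column)
    obs = col != MISSING
    n = int(obs.sum())
    if n == 0:
        raise UndefinedStatisticError("MAF undefined: all genotypes missing")
    f = float(col[obs].sum()) / (2 * n)
    return min(f, 1.0 - f)


def call_rate(dosage_column: np.ndarray) -> float:
    """Fraction of samples with a non-missing call at this locus."""
    col = np.asarray(dosage_column)
    if col.size == 0:
        raise UndefinedStatisticError("call rate undefined for an empty column")
    return float((col != MISSING).sum()) / col.size


def _maf_array(dosages: np.ndarray) -> np.ndarray:
    """Vectorised per-column MAF; NaN where a column is all-missing."""
    obs = dosages != MISSING
    n = obs.sum(axis=0)
    s = np.where(obs, dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = s / (2.0 * n)
    f = np.where(n > 0, f, np.nan)
    return np.minimum(f, 1.0 - f)


# ------------------------------------------------------------------ HWE tests
def _hwe_weights(n: int, n_A: int) -> tuple[range, list[int]]:
    """Integer weights proportional to P(heterozygote count = h | n, n_A).

    P(h) = 2^h * C(n, h) * C(n-h, (n_A-h)/2) / C(2n, n_A); the common
    denominator cancels in both the comparison and the normalisation, so all
    arithmetic stays in exact integers.
    """
    # h <= n_A, h <= 2n - n_A, and h shares n_A's parity (n_AA = (n_A - h)/2)
    h_max = min(n_A, 2 * n - n_A)
    hs = range(n_A % 2, h_max + 1, 2)
    weights = [comb(n, h) * comb(n - h, (n_A - h) // 2) * (1 << h) for h in hs]
    return hs, weights


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided conditional exact Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed that of
    the observed count (probability-mass two-sidedness, no mid-p).  Computed
    in exact rational arithmetic; the returned float is the correctly rounded
    p-value, always in (0, 1].

    Raises
    ------
    UndefinedStatisticError
        If all three counts are zero.
    """
    for name, v in (("n_AA", n_AA), ("n_Aa", n_Aa), ("n_aa", n_aa)):
        if v < 0 or int(v) != v:
            raise SnpldError(f"{name} must be a nonnegative integer, got {v}")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise UndefinedStatisticError("HWE test undefined: no genotyped samples")
    n_A = 2 * n_AA + n_Aa
    hs, weights = _hwe_weights(n, n_A)
    w_obs = weights[(n_Aa - hs.start) // 2]
    num = sum(w for w in weights if w <= w_obs)
    return float(Fraction(num, sum(weights)))


def hwe_chisq_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-degree-of-freedom chi-square Hardy-Weinberg test (no continuity
    correction); offered as a faster asymptotic alternative to the exact test."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise UndefinedStatisticError("HWE test undefined: no genotyped samples")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    x2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(x2, df=1))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    """(n homozygous-B, n het, n homozygous-A) among non-missing calls."""
    obs = col[col != MISSING]
    return int((obs == 2).sum()), int((obs == 1).sum()), int((obs == 0).sum())


# -------------------------------------------------------------------- cascade
def apply_qc(
    panel: GenotypePanel, thresholds: QCThresholds = QCThresholds()
) -> tuple[GenotypePanel, QCReport]:
    """Run the staged QC cascade on the pooled panel.

    All per-locus statistics are computed across every sample regardless of
    population (the study design pools breeds for QC).  Returns the retained
    panel (locus order preserved) and the stage accounting.  A configuration
    that removes every locus returns an empty panel rather than raising.
    """
    n_input = panel.n_loci
    removed: dict[str, list[str]] = {"nonautosomal": [], "hwe": [], "callrate_or_maf": []}
    hwe_test = hwe_exact_p if thresholds.hwe_method == "exact" else hwe_chisq_p

    keep: list[int] = []
    for j in range(n_input):
        v = panel.variants[j]
        if v.chrom not in thresholds.autosomes:
            removed["nonautosomal"].append(v.vid)
            continue
        col = panel.dosages[:, j]
        counts = _genotype_counts(col)
        if sum(counts) > 0:
            if hwe_test(*counts) < thresholds.hwe_p_min:
                removed["hwe"].append(v.vid)
                continue
        if call_rate(col) < thresholds.call_rate_min:
            removed["callrate_or_maf"].append(v.vid)
            continue
        if sum(counts) > 0 and maf(col) < thresholds.maf_min:
            removed["callrate_or_maf"].append(v.vid)
            continue
        keep.append(j)

    report = QCReport(
        n_input=n_input,
        n_removed_nonautosomal=len(removed["nonautosomal"]),
        n_removed_hwe=len(removed["hwe"]),
        n_removed_callrate_or_maf=len(removed["callrate_or_maf"]),
        n_retained=len(keep),
        removed_ids_by_stage=removed,
    )
    report.check_partition()
    out = panel.subset(loci=keep) if len(keep) < n_input else panel
    return out, report


# ---------------------------------------------------------------- MAF spectra
def maf_histogram(
    panel: GenotypePanel,
    population: str,
    bin_edges: Sequence[float] = DEFAULT_MAF_EDGES,
) -> np.ndarray:
    """Histogram of within-population MAF over the panel's loci.

    Bins are half-open [lo, hi) with the last bin closed at 0.5, so a MAF of
    exactly 0.5 lands in the last bin.  Loci with no non-missing call in the
    population are skipped; the counts sum to the number of loci assessed.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise SnpldError("bin_edges must be ascending with at least two edges")
    sub = panel.restrict_population(population)
    mafs = _maf_array(sub.dosages)
    mafs = mafs[~np.isnan(mafs)]
    counts, _ = np.histogram(mafs, bins=edges)
    return counts


def monomorphic_loci(panel: GenotypePanel, population: str) -> np.ndarray:
    """Column indices of loci with within-population MAF exactly 0."""
    sub = panel.restrict_population(population)
    mafs = _maf_array(sub.dosages)
    return np.nonzero(mafs == 0.0)[0]


def monomorphic_overlap(
    panel: GenotypePanel, pop_ref: str, pops_other: Sequence[str]
) -> float:
    """Fraction of loci monomorphic in *pop_ref* that are also monomorphic in
    every population of *pops_other*.

    Intended to be run on the QC-retained panel; pooled QC can leave loci
    monomorphic within individual populations, and a large overlap between the
    monomorphic sets of two populations suggests shared ancestry.

    Raises
    ------
    UndefinedStatisticError
        If *pop_ref* has no monomorphic locus.
    """
    m_ref = set(monomorphic_loci(panel, pop_ref).tolist())
    if not m_ref:
        raise UndefinedStatisticError(f"no monomorphic loci in population {pop_ref!r}")
    m_other = None
    for pop in pops_other:
        s = set(monomorphic_loci(panel, pop).tolist())
        m_other = s if m_other is None else (m_other & s)
    if m_other is None:
        raise SnpldError("pops_other must name at least one population")
    return len(m_ref & m_other) / len(m_ref)
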