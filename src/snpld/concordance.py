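"""Genotype-concordance scoring for duplicate-genotyped or called-vs-true pairs.

A called-vs-true cross-tabulation over the three dosage classes {0, 1, 2}
yields the observed agreement Po (diagonal fraction), the chance agreement Pc
expected from the marginals, and the quality score

    Q = (Po - Pc) / (1 - Pc),

i.e. agreement rescaled so that chance level is 0 and perfect agreement is 1
(Cohen's kappa).  Q is the per-sample reliability score reported for
re-genotyped samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SnpldError, UndefinedStatisticError
from .panel import MISSING, GenotypePanel

N_CLASSES = 3  # dosage classes 0, 1, 2


@dataclass
class ConcordanceTable:
    """K x K cross-tabulation; rows = called class, columns = true class."""

    counts: np.ndarray
    n_excluded_missing: int = 0  # locus pairs dropped because either call was missing

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise SnpldError("concordance counts must be a square matrix")
        if (self.counts < 0).any():
            raise SnpldError("concordance counts must be nonnegative")
        if self.counts.sum() == 0:
            raise SnpldError("concordance table is empty (no jointly called loci)")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


def observed_agreement(table: ConcordanceTable) -> float:
    """Po: fraction of comparisons where called class equals true class."""
    return float(np.trace(table.counts)) / table.n_total


def chance_agreement(table: ConcordanceTable) -> float:
    """Pc: agreement expected by chance from the row/column marginals,
    sum_i (n_i. * n_.i) / n..^2."""
    n = table.n_total
    row = table.counts.sum(axis=1)
    col = table.counts.sum(axis=0)
    return float((row * col).sum()) / (n * n)


def quality_score(table: ConcordanceTable) -> float:
    """Q = (Po - Pc) / (1 - Pc); 1 iff agreement is perfect, 0 at chance level.

    Raises
    ------
    UndefinedStatisticError
        If Pc = 1 (all mass in one class on both margins), where Q is 0/0.
    """
    po = observed_agreement(table)
    pc = chance_agreement(table)
    if pc >= 1.0:
        raise UndefinedStatisticError("quality score undefined when chance agreement is 1")
    return (po - pc) / (1.0 - pc)


def concordance_from_panels(
    panel_called: GenotypePanel,
    panel_true: GenotypePanel,
    sample_pairs: list[tuple[str, str]],
) -> ConcordanceTable:
    """Cross-tabulate dosages over all loci for the given (called, true)
    sample-id pairs, pooled into one table.

    Both panels must carry the same loci in the same order.  Locus pairs where
    either call is missing are excluded from the table and counted in
    ``n_excluded_missing``.
    """
    vids_c = [v.vid for v in panel_called.variants]
    vids_t = [v.vid for v in panel_true.variants]
    if vids_c != vids_t:
        raise SnpldError("called and true panels must share an identical locus list")

    idx_c = {s: i for i, s in enumerate(panel_called.sample_ids)}
    idx_t = {s: i for i, s in enumerate(panel_true.sample_ids)}
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    n_excluded = 0
    for called_id, true_id in sample_pairs:
        try:
            gc = panel_called.dosages[idx_c[called_id]]
            gt = panel_true.dosages[idx_t[true_id]]
        except KeyError as exc:
            raise SnpldError(f"unknown sample id in pair ({called_id!r}, {true_id!r})") from exc
        ok = (gc != MISSING) & (gt != MISSING)
        n_excluded += int((~ok).sum())
        np.add.at(counts, (gc[ok].astype(int), gt[ok].astype(int)), 1)
    return ConcordanceTable(counts, n_excluded_missing=n_excluded)


def concordance_report(
    panel_called: GenotypePanel,
    panel_true: GenotypePanel,
    sample_pairs: list[tuple[str, str]],
) -> list[dict]:
    """Per-pair rows (sample, Po, Pc, Q, n_loci_used) for the TSV report."""
    rows = []
    for pair in sample_pairs:
        table = concordance_from_panels(panel_called, panel_true, [pair])
        rows.append(
            {
                "sample": pair[0],
                "Po": observed_agreement(table),
                "Pc": chance_agreement(table),
                "Q": quality_score(table),
                "n_loci_used": table.n_total,
            }
        )
    return rows
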