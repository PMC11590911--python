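"""Aggregation of pairwise LD into decay profiles.

All summaries operate on the per-pair table produced by
:func:`pairwise_syntenic_ld` — a pandas DataFrame with one row per syntenic
SNP pair (chrom, vid_i, vid_j, distance_bp, n_alleles, D, Dmax, Dprime, r2,
r2_corrected, converged).  Summaries report the mean, population standard
deviation (divisor n) and pair count of a chosen statistic, grouped by
distance class, point-distance window, or chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import ld as _ld
from .errors import SnpldError
from .panel import MISSING, GenotypePanel, _chrom_key

#: distance classes: 1-50 kb, 50-100 kb, 100-500 kb, 0.5-1 Mb
DEFAULT_BINS: tuple[tuple[int, int], ...] = (
    (1, 50_000),
    (50_000, 100_000),
    (100_000, 500_000),
    (500_000, 1_000_000),
)

DEFAULT_POINT_CENTERS: tuple[int, ...] = (1_000, 10_000, 100_000)

STATISTICS = ("r2", "r2_corrected", "D", "Dprime")

PAIR_COLUMNS = [
    "chrom", "vid_i", "vid_j", "distance_bp", "n_alleles",
    "D", "Dmax", "Dprime", "r2", "r2_corrected", "converged",
]


@dataclass(frozen=True)
class DistanceBins:
    """Ordered, non-overlapping (lo, hi] distance intervals in bp; the first
    interval is closed at its lower edge (so a 1-bp pair is counted)."""

    edges: tuple[tuple[int, int], ...] = DEFAULT_BINS

    def __post_init__(self) -> None:
        prev_hi = None
        for lo, hi in self.edges:
            if hi <= lo:
                raise SnpldError(f"empty distance bin ({lo}, {hi}]")
            if prev_hi is not None and lo < prev_hi:
                raise SnpldError("distance bins overlap or are out of order")
            prev_hi = hi

    def label(self, k: int) -> str:
        lo, hi = self.edges[k]
        return f"{lo}-{hi}bp"

    def assign(self, distances: np.ndarray) -> np.ndarray:
        """Bin index per distance, -1 for out-of-range.  Ties at an upper edge
        go to the lower bin ((lo, hi] convention)."""
        d = np.asarray(distances)
        out = np.full(d.shape, -1, dtype=np.int64)
        for k, (lo, hi) in enumerate(self.edges):
            if k == 0:
                sel = (d >= lo) & (d <= hi)
            else:
                sel = (d > lo) & (d <= hi)
            out[sel & (out == -1)] = k
        return out


@dataclass
class BinSummary:
    bin: str
    mean: float
    sd: float
    n_pairs: int
    statistic: str
    population: str | None = None


# ------------------------------------------------------------------- scanning
def pairwise_syntenic_ld(
    panel: GenotypePanel,
    population: str | None = None,
    max_distance_bp: int = 1_000_000,
    chunk_pairs: int = 200_000,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """LD estimates for every within-chromosome locus pair up to a distance
    ceiling, restricted to one population's samples.

    Loci are grouped by chromosome and sorted by position internally.  Pairs
    with distance 0 (co-located markers) or beyond ``max_distance_bp`` are not
    enumerated as analysable pairs; pairs skipped for data reasons are counted
    in the returned dict under ``monomorphic`` and ``insufficient_data``.

    Returns
    -------
    (estimates, skipped)
        *estimates* is a DataFrame with :data:`PAIR_COLUMNS`; *skipped* maps a
        reason to a pair count and includes ``n_pairs_enumerated``.
    """
    sub = panel if population is None else panel.restrict_population(population)
    sub = sub.sorted_by_position()
    dos = sub.dosages
    chroms = np.array([v.chrom for v in sub.variants])
    pos = np.array([v.pos for v in sub.variants], dtype=np.int64)
    vids = np.array([v.vid for v in sub.variants])

    frames: list[pd.DataFrame] = []
    skipped = {"monomorphic": 0, "insufficient_data": 0, "zero_distance": 0,
               "n_pairs_enumerated": 0}
    for chrom in dict.fromkeys(chroms.tolist()):
        idx = np.nonzero(chroms == chrom)[0]
        ii, jj = _pairs_within(pos[idx], max_distance_bp)
        skipped["zero_distance"] += int((pos[idx][jj] == pos[idx][ii]).sum())
        keep = pos[idx][jj] > pos[idx][ii]
        ii, jj = ii[keep], jj[keep]
        skipped["n_pairs_enumerated"] += ii.size
        for lo in range(0, ii.size, chunk_pairs):
            sl = slice(lo, lo + chunk_pairs)
            frame, sk = _ld_batch_frame(
                dos, idx[ii[sl]], idx[jj[sl]], chroms, pos, vids
            )
            frames.append(frame)
            for k, v in sk.items():
                skipped[k] += v
    if frames:
        est = pd.concat(frames, ignore_index=True)
    else:
        est = pd.DataFrame(columns=PAIR_COLUMNS)
    return est, skipped


def _pairs_within(pos_sorted: np.ndarray, max_d: int) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i < j) of a sorted position array with pos[j] - pos[i] <= max_d."""
    n = pos_sorted.size
    hi = np.searchsorted(pos_sorted, pos_sorted + max_d, side="right")
    counts = hi - np.arange(n) - 1
    ii = np.repeat(np.arange(n), counts)
    jj = np.concatenate([np.arange(i + 1, h) for i, h in enumerate(hi)]) if n else np.array([], int)
    return ii, jj.astype(np.int64)


def _ld_batch_frame(dosages, li, lj, chroms, pos, vids):
    """Vectorised LD for locus-index pairs (li, lj); returns (frame, skipped)."""
    skipped = {"monomorphic": 0, "insufficient_data": 0}
    if li.size == 0:
        return pd.DataFrame(columns=PAIR_COLUMNS), skipped
    g1 = dosages[:, li]
    g2 = dosages[:, lj]
    ok = (g1 != MISSING) & (g2 != MISSING)
    code = np.where(ok, g1.astype(np.int64) * 3 + g2.astype(np.int64), 0)
    flat = code + 9 * np.arange(li.size)[None, :]
    n9 = np.bincount(flat[ok].ravel(), minlength=9 * li.size).reshape(li.size, 9)

    n_ind = n9.sum(axis=1)
    enough = n_ind >= 2
    poly = _ld.polymorphic_mask(n9)
    valid = enough & poly
    skipped["insufficient_data"] = int((~enough).sum())
    skipped["monomorphic"] = int((enough & ~poly).sum())
    if not valid.any():
        return pd.DataFrame(columns=PAIR_COLUMNS), skipped

    n9v = n9[valid]
    p, conv, _, _ = _ld.em_haplotype_freqs_batch(n9v)
    pAB, pAb, paB, pab = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    pA = pAB + pAb
    pB = pAB + paB
    d = pAB * pab - pAb * paB
    dmax = np.where(
        d >= 0,
        np.minimum(pA * (1 - pB), (1 - pA) * pB),
        np.minimum(pA * pB, (1 - pA) * (1 - pB)),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        dprime = np.where(d == 0, 0.0, d / dmax)
        r2 = d * d / (pA * (1 - pA) * pB * (1 - pB))
    n_alleles = 2 * n_ind[valid]
    r2c = np.maximum((r2 - 1.0 / n_alleles) / (1.0 - 1.0 / n_alleles), 0.0)

    liv, ljv = li[valid], lj[valid]
    frame = pd.DataFrame(
        {
            "chrom": chroms[liv],
            "vid_i": vids[liv],
            "vid_j": vids[ljv],
            "distance_bp": pos[ljv] - pos[liv],
            "n_alleles": n_alleles,
            "D": d,
            "Dmax": dmax,
            "Dprime": dprime,
            "r2": r2,
            "r2_corrected": r2c,
            "converged": conv,
        }
    )
    return frame, skipped


def estimates_frame(estimates: Iterable[_ld.LDEstimate] | pd.DataFrame) -> pd.DataFrame:
    """Normalise a list of LDEstimate (or a per-pair DataFrame) to a DataFrame."""
    if isinstance(estimates, pd.DataFrame):
        return estimates
    rows = [vars(e) for e in estimates]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS) if rows else pd.DataFrame(columns=PAIR_COLUMNS)


# ----------------------------------------------------------------- summaries
def _check_statistic(statistic: str) -> None:
    if statistic not in STATISTICS:
        raise SnpldError(f"statistic must be one of {STATISTICS}, got {statistic!r}")


def bin_by_distance(
    estimates,
    bins: DistanceBins = DistanceBins(),
    statistic: str = "r2_corrected",
    population: str | None = None,
) -> list[BinSummary]:
    """Mean +- SD of an LD statistic within each distance class.

    SD is the population standard deviation (divisor n).  Pairs at a shared
    bin boundary go to the lower bin; pairs outside every bin are ignored.
    An empty bin reports n_pairs 0 and NaN mean/SD.
    """
    _check_statistic(statistic)
    df = estimates_frame(estimates)
    out: list[BinSummary] = []
    assignment = bins.assign(df["distance_bp"].to_numpy()) if len(df) else np.array([], int)
    for k in range(len(bins.edges)):
        vals = df[statistic].to_numpy()[assignment == k] if len(df) else np.array([])
        out.append(
            BinSummary(
                bin=bins.label(k),
                mean=float(np.mean(vals)) if vals.size else float("nan"),
                sd=float(np.std(vals)) if vals.size else float("nan"),
                n_pairs=int(vals.size),
                statistic=statistic,
                population=population,
            )
        )
    return out


def point_distance_summary(
    estimates,
    centers: Sequence[int] = DEFAULT_POINT_CENTERS,
    tolerance_fraction: float = 0.10,
    statistic: str = "r2",
    population: str | None = None,
) -> list[BinSummary]:
    """Mean LD "at" a set of focal distances.

    Each centre c is summarised over pairs with distance in
    [max(1, c*(1 - tol)), c*(1 + tol)] — a symmetric relative window floored
    at the 1-bp minimum pair distance.
    """
    _check_statistic(statistic)
    df = estimates_frame(estimates)
    d = df["distance_bp"].to_numpy() if len(df) else np.array([])
    out = []
    for c in centers:
        lo = max(1.0, c * (1.0 - tolerance_fraction))
        hi = c * (1.0 + tolerance_fraction)
        vals = df[statistic].to_numpy()[(d >= lo) & (d <= hi)] if len(df) else np.array([])
        out.append(
            BinSummary(
                bin=f"@{c}bp",
                mean=float(np.mean(vals)) if vals.size else float("nan"),
                sd=float(np.std(vals)) if vals.size else float("nan"),
                n_pairs=int(vals.size),
                statistic=statistic,
                population=population,
            )
        )
    return out


def per_chromosome_summary(estimates, statistic: str = "r2") -> pd.DataFrame:
    """Mean, SD (divisor n) and pair count of a statistic per chromosome, over
    all analysed syntenic pairs."""
    _check_statistic(statistic)
    df = estimates_frame(estimates)
    if not len(df):
        return pd.DataFrame(columns=["chrom", "mean", "sd", "n_pairs"])
    g = df.groupby("chrom", sort=False)[statistic]
    res = pd.DataFrame(
        {"chrom": g.mean().index, "mean": g.mean().to_numpy(),
         "sd": g.std(ddof=0).to_numpy(), "n_pairs": g.count().to_numpy()}
    )
    order = sorted(range(len(res)), key=lambda i: _chrom_key(res["chrom"].iloc[i]))
    return res.iloc[order].reset_index(drop=True)


def adjacent_snp_summary(
    panel: GenotypePanel, population: str | None = None
) -> tuple[dict[str, float], dict[str, int]]:
    """Mean r2 between consecutive (map-adjacent) SNPs, per chromosome.

    Pairs where either locus is monomorphic in the population (or lacks two
    pairwise-complete individuals) are skipped and counted.  A chromosome
    whose every adjacent pair is skipped gets no entry.

    Returns
    -------
    (means, skipped)
        ``means`` maps chromosome to mean adjacent-pair r2; ``skipped`` maps
        chromosome to its skipped-pair count.
    """
    sub = panel if population is None else panel.restrict_population(population)
    sub = sub.sorted_by_position()
    chroms = np.array([v.chrom for v in sub.variants])
    means: dict[str, float] = {}
    skipped: dict[str, int] = {}
    for chrom in dict.fromkeys(chroms.tolist()):
        idx = np.nonzero(chroms == chrom)[0]
        r2s = []
        n_skipped = 0
        for a, b in zip(idx[:-1], idx[1:]):
            try:
                r2s.append(_ld.ld_pair(sub, int(a), int(b)).r2)
            except (_ld.MonomorphicPairError, _ld.InsufficientDataError):
                n_skipped += 1
        if r2s:
            means[chrom] = float(np.mean(r2s))
        if n_skipped:
            skipped[chrom] = n_skipped
    return means, skipped


def decay_curve(estimates, n_log_bins: int = 20, statistic: str = "r2_corrected") -> pd.DataFrame:
    """Mean LD in log-spaced distance bins from the minimum to the maximum
    observed pair distance; columns (distance_mid_bp, mean, n_pairs)."""
    _check_statistic(statistic)
    if n_log_bins < 1:
        raise SnpldError("n_log_bins must be >= 1")
    df = estimates_frame(estimates)
    if not len(df):
        return pd.DataFrame(columns=["distance_mid_bp", "mean", "n_pairs"])
    d = df["distance_bp"].to_numpy().astype(float)
    lo, hi = d.min(), d.max()
    if lo == hi:
        edges = np.array([lo - 0.5, hi + 0.5])
    else:
        edges = np.geomspace(lo, hi, n_log_bins + 1)
        edges[0] -= 1e-9
        edges[-1] += 1e-9
    which = np.digitize(d, edges) - 1
    rows = []
    vals = df[statistic].to_numpy()
    for k in range(len(edges) - 1):
        sel = which == k
        if not sel.any():
            continue
        rows.append(
            {
                "distance_mid_bp": float(np.sqrt(max(edges[k], 1e-12) * edges[k + 1])),
                "mean": float(vals[sel].mean()),
                "n_pairs": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)
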