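"""Two-locus linkage disequilibrium from unphased diploid genotypes.

Haplotype (gamete) frequencies are estimated by expectation-maximisation on
the two-locus genotype table.  Writing A/a for the counted/other allele at the
first locus and B/b at the second, the only phase-ambiguous genotype is the
double heterozygote, which is either AB/ab or Ab/aB; every other genotype
contributes its two gametes deterministically.  The E-step splits the double
heterozygotes in proportion p_AB*p_ab : p_Ab*p_aB and the M-step is gamete
counting, which preserves the observed allele frequencies exactly.

From the fitted frequencies:

    D   = p_AB*p_ab - p_Ab*p_aB  (= p_AB - pA*pB)
    D'  = D / Dmax, Dmax = min(pA*pb, pa*pB) if D > 0 else min(pA*pB, pa*pb)
    r2  = D^2 / (pA*pa*pB*pb)
    r2_corrected = (r2 - 1/n) / (1 - 1/n),  n = number of sampled alleles,

the last removing the 1/n expectation of r2 under linkage equilibrium in a
finite sample (floored at 0 by default).

The EM is deterministic via a three-point multi-start (linkage equilibrium
and D = +-Dmax/2), keeping the highest-likelihood solution and breaking
near-ties toward smaller |D|.  A vectorised batch engine processes many locus
pairs at once; the scalar API wraps it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, MonomorphicPairError, SnpldError
from .panel import MISSING, GenotypePanel

EM_TOL = 1e-10
EM_MAX_ITER = 1000
TIE_TOL = 1e-8  # log-likelihood difference treated as a tie in multi-start


@dataclass(frozen=True)
class HaplotypeFrequencies:
    """The four two-locus gamete frequencies (nonnegative, summing to 1)."""

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float

    def __post_init__(self) -> None:
        v = (self.p_AB, self.p_Ab, self.p_aB, self.p_ab)
        if min(v) < -1e-12:
            raise SnpldError(f"negative haplotype frequency in {v}")
        if abs(sum(v) - 1.0) > 1e-9:
            raise SnpldError(f"haplotype frequencies sum to {sum(v)}, not 1")

    @property
    def pA(self) -> float:
        return self.p_AB + self.p_Ab

    @property
    def pB(self) -> float:
        return self.p_AB + self.p_aB


@dataclass
class EMResult:
    freqs: HaplotypeFrequencies
    converged: bool
    n_iter: int
    loglik: float


@dataclass
class LDEstimate:
    """All LD statistics for one syntenic SNP pair."""

    chrom: str
    vid_i: str
    vid_j: str
    distance_bp: int
    n_alleles: int
    D: float
    Dmax: float
    Dprime: float
    r2: float
    r2_corrected: float
    converged: bool


# ---------------------------------------------------------------- counts
def two_locus_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 genotype table over individuals non-missing at both loci; rows are
    the dosage at locus 1, columns at locus 2.  Pairing is by sample index."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise SnpldError("dosage columns must have equal length")
    ok = (g1 != MISSING) & (g2 != MISSING)
    code = g1[ok].astype(np.int64) * 3 + g2[ok].astype(np.int64)
    return np.bincount(code, minlength=9).reshape(3, 3)


# ---------------------------------------------------------------- batch EM
def _gamete_sufficient_stats(n9: np.ndarray):
    """Fixed gamete counts and double-het count from (P, 9) genotype tables.

    Cell index is 3 * dosage1 + dosage2.  Returns (c (P,4) in order
    [AB, Ab, aB, ab], n_dh (P,), n_gametes (P,)).
    """
    n9 = np.asarray(n9, dtype=np.float64)
    c = np.empty((n9.shape[0], 4))
    c[:, 0] = 2 * n9[:, 8] + n9[:, 7] + n9[:, 5]  # AB: (2,2), (2,1), (1,2)
    c[:, 1] = 2 * n9[:, 6] + n9[:, 7] + n9[:, 3]  # Ab: (2,0), (2,1), (1,0)
    c[:, 2] = 2 * n9[:, 2] + n9[:, 1] + n9[:, 5]  # aB: (0,2), (0,1), (1,2)
    c[:, 3] = 2 * n9[:, 0] + n9[:, 1] + n9[:, 3]  # ab: (0,0), (0,1), (1,0)
    n_dh = n9[:, 4]
    n_gam = 2.0 * n9.sum(axis=1)
    return c, n_dh, n_gam


def _loglik_batch(p: np.ndarray, n9: np.ndarray) -> np.ndarray:
    """Multinomial log-likelihood of (P, 9) genotype tables under (P, 4)
    gamete frequencies [AB, Ab, aB, ab], assuming random union of gametes."""
    pAB, pAb, paB, pab = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    probs = np.empty((p.shape[0], 9))
    probs[:, 0] = pab**2
    probs[:, 1] = 2 * pab * paB
    probs[:, 2] = paB**2
    probs[:, 3] = 2 * pab * pAb
    probs[:, 4] = 2 * (pAB * pab + pAb * paB)
    probs[:, 5] = 2 * pAB * paB
    probs[:, 6] = pAb**2
    probs[:, 7] = 2 * pAB * pAb
    probs[:, 8] = pAB**2
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n9 > 0, n9 * np.log(probs), 0.0)
    # a zero-probability cell with observations gives -inf, as it should
    terms = np.where((n9 > 0) & (probs <= 0), -np.inf, terms)
    return terms.sum(axis=1)


def _em_iterate(
    p0: np.ndarray, c: np.ndarray, n_dh: np.ndarray, n_gam: np.ndarray,
    tol: float, max_iter: int,
):
    """Run EM from start (P, 4) p0; returns (p, converged, n_iter per pair).

    Converged pairs are compacted out of the working arrays each iteration so
    late stragglers do not keep the whole batch iterating.
    """
    n_pairs = p0.shape[0]
    p_out = p0.copy()
    converged = np.zeros(n_pairs, dtype=bool)
    iters = np.full(n_pairs, max_iter, dtype=np.int64)
    idx = np.arange(n_pairs)
    p, cc, dh, ng = p0.copy(), c, n_dh, n_gam
    for it in range(1, max_iter + 1):
        if idx.size == 0:
            break
        coupling = p[:, 0] * p[:, 3]
        repulsion = p[:, 1] * p[:, 2]
        denom = coupling + repulsion
        q = np.where(denom > 0, coupling / np.where(denom > 0, denom, 1.0), 0.5)
        new = np.empty_like(p)
        new[:, 0] = (cc[:, 0] + q * dh) / ng
        new[:, 3] = (cc[:, 3] + q * dh) / ng
        new[:, 1] = (cc[:, 1] + (1 - q) * dh) / ng
        new[:, 2] = (cc[:, 2] + (1 - q) * dh) / ng
        done = np.abs(new - p).max(axis=1) < tol
        if done.any():
            p_out[idx[done]] = new[done]
            converged[idx[done]] = True
            iters[idx[done]] = it
            keep = ~done
            idx, p = idx[keep], new[keep]
            cc, dh, ng = cc[keep], dh[keep], ng[keep]
        else:
            p = new
    if idx.size:
        p_out[idx] = p
    return p_out, converged, iters


def _em_starts(c: np.ndarray, n_dh: np.ndarray, n_gam: np.ndarray) -> np.ndarray:
    """Three deterministic starts (3, P, 4): linkage equilibrium, D = +Dmax/2,
    D = -Dmax/2, all with the observed allele-frequency marginals."""
    pA = (c[:, 0] + c[:, 1] + n_dh) / n_gam
    pB = (c[:, 0] + c[:, 2] + n_dh) / n_gam
    pa, pb = 1.0 - pA, 1.0 - pB
    dmax_pos = np.minimum(pA * pb, pa * pB)
    dmax_neg = np.minimum(pA * pB, pa * pb)
    starts = np.empty((3, c.shape[0], 4))
    for k, d in enumerate((np.zeros_like(pA), dmax_pos / 2, -dmax_neg / 2)):
        starts[k, :, 0] = pA * pB + d
        starts[k, :, 1] = pA * pb - d
        starts[k, :, 2] = pa * pB - d
        starts[k, :, 3] = pa * pb + d
    return np.clip(starts, 0.0, 1.0)


def em_haplotype_freqs_batch(
    n9: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER
):
    """Vectorised EM over a batch of (P, 9) two-locus genotype tables.

    Returns (p (P,4) in order [AB, Ab, aB, ab], converged (P,), loglik (P,),
    n_iter (P,)).  Monomorphic pairs must be filtered out beforehand (their
    haplotype frequencies are degenerate; see :func:`polymorphic_mask`).
    """
    n9 = np.asarray(n9, dtype=np.float64)
    c, n_dh, n_gam = _gamete_sufficient_stats(n9)
    if (n_gam <= 0).any():
        raise InsufficientDataError("empty genotype table in batch")
    starts = _em_starts(c, n_dh, n_gam)
    sols, convs, iters, logliks = [], [], [], []
    for k in range(3):
        p, conv, it = _em_iterate(starts[k], c, n_dh, n_gam, tol, max_iter)
        sols.append(p)
        convs.append(conv)
        iters.append(it)
        logliks.append(_loglik_batch(p, n9))
    lls = np.stack(logliks)            # (3, P)
    ps = np.stack(sols)                # (3, P, 4)
    dd = ps[:, :, 0] * ps[:, :, 3] - ps[:, :, 1] * ps[:, :, 2]
    best_ll = lls.max(axis=0)
    # among starts within TIE_TOL of the best likelihood, take smallest |D|
    tied = lls >= best_ll - TIE_TOL
    absd = np.where(tied, np.abs(dd), np.inf)
    pick = absd.argmin(axis=0)
    ar = np.arange(n9.shape[0])
    return (
        ps[pick, ar, :],
        np.stack(convs)[pick, ar],
        lls[pick, ar],
        np.stack(iters)[pick, ar],
    )


def polymorphic_mask(n9: np.ndarray) -> np.ndarray:
    """True where both loci of a (P, 9) genotype-table batch are polymorphic."""
    n9 = np.asarray(n9, dtype=np.float64)
    n = n9.sum(axis=1)
    d1 = n9.reshape(-1, 3, 3).sum(axis=2) @ np.array([0.0, 1.0, 2.0])
    d2 = n9.reshape(-1, 3, 3).sum(axis=1) @ np.array([0.0, 1.0, 2.0])
    return (d1 > 0) & (d1 < 2 * n) & (d2 > 0) & (d2 < 2 * n)


# ---------------------------------------------------------------- scalar API
def em_haplotype_freqs(
    counts: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER
) -> EMResult:
    """EM haplotype-frequency estimate from one 3x3 two-locus genotype table.

    A table with a monomorphic locus is allowed and returns the degenerate
    (fully determined) frequencies; the LD statistics, not the frequencies,
    are undefined in that case and raise :class:`MonomorphicPairError`.
    """
    n9 = np.asarray(counts, dtype=np.float64).reshape(1, 9)
    if n9.sum() < 1:
        raise InsufficientDataError("genotype table must contain at least one individual")
    p, conv, ll, it = em_haplotype_freqs_batch(n9, tol=tol, max_iter=max_iter)
    p0 = np.clip(p[0], 0.0, 1.0)
    p0 = p0 / p0.sum()
    return EMResult(
        freqs=HaplotypeFrequencies(*p0.tolist()),
        converged=bool(conv[0]),
        n_iter=int(it[0]),
        loglik=float(ll[0]),
    )


def loglik_table(hf: HaplotypeFrequencies, counts: np.ndarray) -> float:
    """Log-likelihood of a 3x3 genotype table under given gamete frequencies."""
    p = np.array([[hf.p_AB, hf.p_Ab, hf.p_aB, hf.p_ab]])
    return float(_loglik_batch(p, np.asarray(counts, dtype=float).reshape(1, 9))[0])


# ---------------------------------------------------------------- statistics
def compute_D(hf: HaplotypeFrequencies) -> float:
    """Gametic disequilibrium D = p_AB*p_ab - p_Ab*p_aB (= p_AB - pA*pB).

    The sign depends on which allele is labelled B at each locus; magnitudes
    and r2 do not.
    """
    return hf.p_AB * hf.p_ab - hf.p_Ab * hf.p_aB


def compute_Dmax(hf: HaplotypeFrequencies) -> float:
    """Maximum |D| attainable at the given allele frequencies, on D's side."""
    _require_polymorphic(hf)
    d = compute_D(hf)
    pA, pB = hf.pA, hf.pB
    if d >= 0:
        return min(pA * (1 - pB), (1 - pA) * pB)
    return min(pA * pB, (1 - pA) * (1 - pB))


def compute_Dprime(hf: HaplotypeFrequencies) -> float:
    """Lewontin's D' = D / Dmax, with D' = 0 by convention when D = 0."""
    _require_polymorphic(hf)
    d = compute_D(hf)
    if d == 0.0:
        return 0.0
    return d / compute_Dmax(hf)


def compute_r2(hf: HaplotypeFrequencies) -> float:
    """Squared allelic correlation r2 = D^2 / (pA*pa*pB*pb)."""
    _require_polymorphic(hf)
    d = compute_D(hf)
    pA, pB = hf.pA, hf.pB
    return d * d / (pA * (1 - pA) * pB * (1 - pB))


def correct_r2(r2_computed: float, n_alleles: int, floor: bool = True) -> float:
    """Finite-sample adjustment (r2 - 1/n) / (1 - 1/n).

    n is the number of sampled alleles (twice the diploid count).  Under
    linkage equilibrium E[r2] is approximately 1/n, so the adjustment
    re-centres chance-level LD at 0.  Negative values (r2 < 1/n) are floored
    at 0 unless ``floor=False`` (exact-formula mode).
    """
    if n_alleles < 2:
        raise SnpldError(f"n_alleles must be >= 2, got {n_alleles}")
    out = (r2_computed - 1.0 / n_alleles) / (1.0 - 1.0 / n_alleles)
    if floor:
        out = max(out, 0.0)
    return out


def _require_polymorphic(hf: HaplotypeFrequencies) -> None:
    if not (0.0 < hf.pA < 1.0 and 0.0 < hf.pB < 1.0):
        raise MonomorphicPairError(
            f"monomorphic marginal (pA={hf.pA:.6g}, pB={hf.pB:.6g})"
        )


# ---------------------------------------------------------------- per pair
def ld_pair(panel: GenotypePanel, locus_i: int, locus_j: int) -> LDEstimate:
    """Full LD estimate for one syntenic locus pair of a panel.

    Uses the individuals non-missing at both loci (pairwise-complete
    deletion); ``n_alleles`` is twice that count and is the n used in the r2
    correction.

    Raises
    ------
    SnpldError
        If the loci lie on different chromosomes.
    InsufficientDataError
        Fewer than 2 pairwise-complete individuals.
    MonomorphicPairError
        Either locus monomorphic in the pairwise-complete subset.
    """
    vi, vj = panel.variants[locus_i], panel.variants[locus_j]
    if vi.chrom != vj.chrom:
        raise SnpldError(f"loci {vi.vid}/{vj.vid} are not syntenic ({vi.chrom} vs {vj.chrom})")
    counts = two_locus_counts(panel.dosages[:, locus_i], panel.dosages[:, locus_j])
    n_ind = int(counts.sum())
    if n_ind < 2:
        raise InsufficientDataError(
            f"{vi.vid}/{vj.vid}: {n_ind} pairwise-complete individuals"
        )
    if not polymorphic_mask(counts.reshape(1, 9))[0]:
        raise MonomorphicPairError(
            f"{vi.vid}/{vj.vid}: a locus is monomorphic in the pairwise-complete subset"
        )
    res = em_haplotype_freqs(counts)
    hf = res.freqs
    n_alleles = 2 * n_ind
    d = compute_D(hf)
    r2 = compute_r2(hf)
    return LDEstimate(
        chrom=vi.chrom,
        vid_i=vi.vid,
        vid_j=vj.vid,
        distance_bp=abs(vj.pos - vi.pos),
        n_alleles=n_alleles,
        D=d,
        Dmax=compute_Dmax(hf),
        Dprime=compute_Dprime(hf),
        r2=r2,
        r2_corrected=correct_r2(r2, n_alleles),
        converged=res.converged,
    )
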