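"""Synthetic genotype panels with controllable LD decay, plus a two-locus
Wright-Fisher simulator for theory-based checks.

The panel generator emulates the structure of a multi-breed SNP-chip study:
a few populations of ~12 diploids each, thousands of mapped autosomal SNPs,
an allele-frequency spectrum with a low-MAF excess, LD that decays with
physical distance, per-call missingness, and planted QC defects (extreme
heterozygote excess, rare alleles, low call rate, non-autosomal placement,
per-population monomorphic loci) whose identities are recorded in a truth
record so every downstream statistic can be checked against construction.

Haplotypes come from a latent stationary AR(1) Gaussian process along each
chromosome: latent values at neighbouring loci have correlation
exp(-d / decay_lambda_bp), and each locus thresholds its latent value at the
quantile of its target allele frequency (a Gaussian copula).  Diploids are
random unions of two independent haplotypes, so Hardy-Weinberg holds except
where violations are planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from . import ld as _ld
from .errors import InfeasibleConfigError, SnpldError
from .panel import MISSING, GenotypePanel, VariantRecord
from .qc import hwe_exact_p

_NONAUTOSOMAL_CYCLE = ("X", "Y", "MT")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the panel generator.

    Defaults mirror the emulated study: five breeds of twelve diploids,
    chip-density markers (~15 kb median spacing), LD decaying on a 100-kb
    length scale, a MAF spectrum that is uniform on [0.05, 0.5] with a 20%
    low-MAF excess, and 2% missing calls.
    """

    n_populations: int = 5
    n_samples_per_pop: int = 12
    n_loci: int = 2000
    n_chromosomes: int = 2
    chrom_length_bp: int = 15_000_000
    decay_lambda_bp: float = 100_000.0
    maf_spectrum: tuple = ("uniform", 0.05, 0.5)
    low_maf_fraction: float = 0.2
    missing_rate: float = 0.02
    n_hwe_violations: int = 0
    n_planted_low_maf: int = 0
    n_planted_low_callrate: int = 0
    n_nonautosomal: int = 0
    monomorphic_plan: Mapping[str, tuple[int, ...]] | None = None
    duplicate_error_rate: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_populations", "n_samples_per_pop", "n_loci", "n_chromosomes",
                     "n_hwe_violations", "n_planted_low_maf", "n_planted_low_callrate",
                     "n_nonautosomal"):
            if getattr(self, name) < 0:
                raise SnpldError(f"{name} must be >= 0")
        for name in ("missing_rate", "low_maf_fraction", "duplicate_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise SnpldError(f"{name} must be in [0, 1]")
        n_planted = (self.n_hwe_violations + self.n_planted_low_maf
                     + self.n_planted_low_callrate + self.n_nonautosomal)
        if n_planted > self.n_loci:
            raise InfeasibleConfigError(
                f"{n_planted} planted loci exceed n_loci={self.n_loci}"
            )
        if self.monomorphic_plan:
            for pop, idx in self.monomorphic_plan.items():
                if any(j < 0 or j >= self.n_loci for j in idx):
                    raise InfeasibleConfigError(
                        f"monomorphic plan for {pop!r} references loci outside the panel"
                    )

    @property
    def population_names(self) -> list[str]:
        return [f"pop{k + 1}" for k in range(self.n_populations)]


@dataclass
class TruthRecord:
    """Construction bookkeeping emitted alongside a simulated panel."""

    target_freq: np.ndarray  # per-locus target frequency of the counted allele
    decay_lambda_bp: float
    hwe_violation_loci: list[int] = field(default_factory=list)
    low_maf_loci: list[int] = field(default_factory=list)
    low_callrate_loci: list[int] = field(default_factory=list)
    nonautosomal_loci: list[int] = field(default_factory=list)
    monomorphic_plan: dict[str, list[int]] = field(default_factory=dict)

    def latent_correlation(self, distance_bp: float) -> float:
        """Latent-Gaussian correlation between loci separated by distance_bp."""
        return float(np.exp(-distance_bp / self.decay_lambda_bp))

    def to_json_dict(self) -> dict:
        return {
            "target_freq": [float(x) for x in self.target_freq],
            "decay_lambda_bp": self.decay_lambda_bp,
            "hwe_violation_loci": self.hwe_violation_loci,
            "low_maf_loci": self.low_maf_loci,
            "low_callrate_loci": self.low_callrate_loci,
            "nonautosomal_loci": self.nonautosomal_loci,
            "monomorphic_plan": self.monomorphic_plan,
        }


# ----------------------------------------------------------------- internals
def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct sorted positions in [1, length]."""
    if n > length:
        raise InfeasibleConfigError(f"cannot place {n} distinct loci on {length} bp")
    pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=n))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos)


def _draw_target_freqs(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """Per-locus frequency of the counted allele (minor or major at random)."""
    fam = cfg.maf_spectrum[0]
    if fam == "uniform":
        lo, hi = cfg.maf_spectrum[1], cfg.maf_spectrum[2]
        m = rng.uniform(lo, hi, size=cfg.n_loci)
    elif fam == "beta":
        a, b = cfg.maf_spectrum[1], cfg.maf_spectrum[2]
        m = 0.5 * rng.beta(a, b, size=cfg.n_loci)
    else:
        raise SnpldError(f"unknown maf_spectrum family {fam!r}")
    low = rng.random(cfg.n_loci) < cfg.low_maf_fraction
    m = np.where(low, rng.uniform(0.005, 0.05, size=cfg.n_loci), m)
    # counted allele is the minor one for a random half of loci
    flip = rng.random(cfg.n_loci) < 0.5
    return np.where(flip, 1.0 - m, m)


def _ar1_haplotypes(
    rng: np.random.Generator,
    n_haplotypes: int,
    pos: np.ndarray,
    thresholds: np.ndarray,
    lam: float,
) -> np.ndarray:
    """0/1 haplotype matrix (n_haplotypes x loci) from the latent AR(1) copula."""
    n_loci = pos.size
    if n_loci == 0:
        return np.empty((n_haplotypes, 0), dtype=np.int8)
    z = np.empty((n_haplotypes, n_loci))
    z[:, 0] = rng.standard_normal(n_haplotypes)
    if lam <= 0:
        z[:, 1:] = rng.standard_normal((n_haplotypes, n_loci - 1))
    else:
        rho = np.exp(-np.diff(pos) / lam)
        eps = rng.standard_normal((n_haplotypes, n_loci - 1))
        for l in range(1, n_loci):
            r = rho[l - 1]
            z[:, l] = r * z[:, l - 1] + np.sqrt(1.0 - r * r) * eps[:, l - 1]
    return (z < thresholds[None, :]).astype(np.int8)


# ----------------------------------------------------------------- panel
def simulate_panel(config: SimulationConfig) -> tuple[GenotypePanel, TruthRecord]:
    """Generate a genotype panel and its construction truth record.

    Deterministic under ``config.seed``.  Stages: map + target frequencies,
    AR(1)-copula haplotypes per population, random union into diploids,
    per-call missingness, then planted defects (which overwrite whole loci),
    and finally orientation canonicalisation so the panel round-trips exactly
    through PED/MAP.

    Raises
    ------
    InfeasibleConfigError
        If planted heterozygote-excess loci cannot reach exact-test
        p < 1e-10 at the pooled sample size (needs roughly >= 40 diploids).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_populations * cfg.n_samples_per_pop

    # --- map
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_loci // cfg.n_chromosomes)
    per_chrom[: cfg.n_loci % cfg.n_chromosomes] += 1
    chroms: list[str] = []
    positions: list[int] = []
    for c in range(cfg.n_chromosomes):
        p = _draw_positions(rng, int(per_chrom[c]), cfg.chrom_length_bp)
        chroms += [str(c + 1)] * p.size
        positions += p.tolist()
    pos_arr = np.asarray(positions, dtype=np.int64)

    # --- frequencies and haplotypes
    freq = _draw_target_freqs(rng, cfg)
    thresholds = _stats.norm.ppf(np.clip(freq, 1e-12, 1 - 1e-12))
    dosages = np.empty((n_total, cfg.n_loci), dtype=np.int8)
    pop_of: dict[str, str] = {}
    sample_ids: list[str] = []
    row = 0
    for pop in cfg.population_names:
        hap_rows = 2 * cfg.n_samples_per_pop
        hap = np.empty((hap_rows, cfg.n_loci), dtype=np.int8)
        start = 0
        for c in range(cfg.n_chromosomes):
            n_c = int(per_chrom[c])
            sl = slice(start, start + n_c)
            hap[:, sl] = _ar1_haplotypes(
                rng, hap_rows, pos_arr[sl], thresholds[sl], cfg.decay_lambda_bp
            )
            start += n_c
        dosages[row: row + cfg.n_samples_per_pop] = hap[0::2] + hap[1::2]
        for i in range(cfg.n_samples_per_pop):
            sid = f"{pop}_s{i + 1}"
            sample_ids.append(sid)
            pop_of[sid] = pop
        row += cfg.n_samples_per_pop

    # --- missingness (before planting; planted loci are overwritten whole)
    if cfg.missing_rate > 0:
        miss = rng.random(dosages.shape) < cfg.missing_rate
        dosages[miss] = MISSING

    # --- planted defects on disjoint autosomal loci
    n_planted = (cfg.n_hwe_violations + cfg.n_planted_low_maf
                 + cfg.n_planted_low_callrate + cfg.n_nonautosomal)
    planted = rng.choice(cfg.n_loci, size=n_planted, replace=False) if n_planted else np.array([], int)
    cursor = 0

    hwe_loci = planted[cursor: cursor + cfg.n_hwe_violations].tolist()
    cursor += cfg.n_hwe_violations
    if hwe_loci:
        p_all_het = hwe_exact_p(0, n_total, 0)
        if p_all_het >= 1e-10:
            raise InfeasibleConfigError(
                f"all-heterozygote planting reaches only p={p_all_het:.3g} "
                f"at {n_total} pooled samples; need p < 1e-10"
            )
        for j in hwe_loci:
            dosages[:, j] = 1  # every sample heterozygous: extreme het excess

    low_maf_loci = planted[cursor: cursor + cfg.n_planted_low_maf].tolist()
    cursor += cfg.n_planted_low_maf
    for j in low_maf_loci:
        dosages[:, j] = 0
        dosages[0, j] = 1  # single heterozygote: MAF = 1/(2n), HWE p = 1

    low_cr_loci = planted[cursor: cursor + cfg.n_planted_low_callrate].tolist()
    cursor += cfg.n_planted_low_callrate
    n_miss = max(int(np.ceil(0.2 * n_total)), 1)
    for j in low_cr_loci:
        dosages[:, j] = 1 - (np.arange(n_total) % 2)  # alternating 1/0: benign HWE/MAF
        dosages[rng.choice(n_total, size=n_miss, replace=False), j] = MISSING

    nonauto_loci = planted[cursor: cursor + cfg.n_nonautosomal].tolist()

    # --- per-population planted monomorphic loci
    mono_plan: dict[str, list[int]] = {}
    if cfg.monomorphic_plan:
        for pop, idx in cfg.monomorphic_plan.items():
            if pop not in cfg.population_names:
                raise InfeasibleConfigError(f"monomorphic plan names unknown population {pop!r}")
            rows = [i for i, s in enumerate(sample_ids) if pop_of[s] == pop]
            for j in idx:
                dosages[rows, j] = 0  # counted allele absent within this population
            mono_plan[pop] = sorted(int(j) for j in idx)

    # --- variant records
    variants = []
    nonauto_set = set(nonauto_loci)
    cyc = 0
    for j in range(cfg.n_loci):
        chrom = chroms[j]
        if j in nonauto_set:
            chrom = _NONAUTOSOMAL_CYCLE[cyc % len(_NONAUTOSOMAL_CYCLE)]
            cyc += 1
        variants.append(
            VariantRecord(chrom=chrom, pos=int(pos_arr[j]), vid=f"snp{j}",
                          alleleA="A", alleleB="B")
        )

    panel = GenotypePanel(dosages, sample_ids, pop_of, variants)
    flipped = _canonical_flips(panel)
    panel = panel.flip_loci(flipped)
    truth = TruthRecord(
        target_freq=np.where(np.isin(np.arange(cfg.n_loci), flipped), 1.0 - freq, freq),
        decay_lambda_bp=cfg.decay_lambda_bp,
        hwe_violation_loci=sorted(hwe_loci),
        low_maf_loci=sorted(low_maf_loci),
        low_callrate_loci=sorted(low_cr_loci),
        nonautosomal_loci=sorted(nonauto_loci),
        monomorphic_plan=mono_plan,
    )
    return panel, truth


def _canonical_flips(panel: GenotypePanel) -> list[int]:
    flips = []
    for j in range(panel.n_loci):
        col = panel.dosages[:, j]
        obs = np.nonzero(col != MISSING)[0]
        if obs.size and col[obs[0]] == 2:
            flips.append(j)
    return flips


# ----------------------------------------------------------------- duplicates
def simulate_duplicates(
    panel: GenotypePanel,
    sample_ids: Sequence[str],
    error_rate: float,
    seed: int,
) -> GenotypePanel:
    """Re-genotyped copies of chosen samples with a per-call error rate.

    Each non-missing call is replaced, with probability ``error_rate``, by one
    of the two other dosage classes (uniformly).  Duplicate sample ids get a
    ``_dup`` suffix; population labels are inherited.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise SnpldError("error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    idx = {s: i for i, s in enumerate(panel.sample_ids)}
    rows = []
    ids = []
    pops = {}
    for s in sample_ids:
        if s not in idx:
            raise SnpldError(f"unknown sample id {s!r}")
        g = panel.dosages[idx[s]].copy()
        obs = np.nonzero(g != MISSING)[0]
        err = obs[rng.random(obs.size) < error_rate]
        if err.size:
            shift = rng.integers(1, 3, size=err.size)  # +1 or +2 mod 3: a different class
            g[err] = (g[err] + shift) % 3
        rows.append(g)
        dup = f"{s}_dup"
        ids.append(dup)
        pops[dup] = panel.population_of[s]
    return GenotypePanel(np.array(rows, dtype=np.int8), ids, pops, list(panel.variants))


# -------------------------------------------------------------- Wright-Fisher
def simulate_two_locus_wf(
    Ne: int,
    c: float,
    n_generations: int | None = None,
    n_sample: int = 50,
    n_replicates: int = 2000,
    seed: int = 0,
) -> np.ndarray:
    """Sampled raw r2 from replicate two-locus Wright-Fisher populations.

    Each replicate starts at linkage equilibrium with both allele frequencies
    0.5 and evolves 2*Ne gametes per generation by multinomial resampling of
    the four haplotypes, with recombination (fraction ``c``) applied to the
    expected gamete frequencies.  After ``n_generations`` (default 4*Ne),
    ``n_sample`` diploids are drawn by random union of gametes and raw r2 is
    computed from the unphased genotypes via the EM estimator.  Replicates
    where either locus fixes in the population — or is monomorphic in the
    drawn sample — are dropped and regenerated, so exactly ``n_replicates``
    values are returned.  Deterministic under ``seed``.
    """
    if Ne < 2:
        raise SnpldError("Ne must be >= 2")
    if not 0.0 <= c <= 0.5:
        raise SnpldError("recombination fraction c must be in [0, 0.5]")
    if n_generations is None:
        n_generations = 4 * Ne
    rng = np.random.default_rng(seed)
    out: list[np.ndarray] = []
    collected = 0
    while collected < n_replicates:
        batch = max(2 * (n_replicates - collected), 500)
        r2 = _wf_batch(rng, Ne, c, n_generations, n_sample, batch)
        out.append(r2)
        collected += r2.size
    return np.concatenate(out)[:n_replicates]


def _wf_batch(rng, Ne, c, n_gen, n_sample, n_rep) -> np.ndarray:
    two_ne = 2 * Ne
    # haplotype order [AB, Ab, aB, ab]; start at LE, p = q = 0.5
    counts = rng.multinomial(two_ne, [0.25] * 4, size=n_rep).astype(np.float64)
    alive = np.ones(n_rep, dtype=bool)
    for _ in range(n_gen):
        f = counts[alive] / two_ne
        d = f[:, 0] * f[:, 3] - f[:, 1] * f[:, 2]
        f[:, 0] -= c * d
        f[:, 3] -= c * d
        f[:, 1] += c * d
        f[:, 2] += c * d
        f = np.clip(f, 0.0, 1.0)
        f /= f.sum(axis=1, keepdims=True)
        counts[alive] = rng.multinomial(two_ne, f)
        g = counts[alive]
        pA = (g[:, 0] + g[:, 1]) / two_ne
        pB = (g[:, 0] + g[:, 2]) / two_ne
        still = (pA > 0) & (pA < 1) & (pB > 0) & (pB < 1)
        idx = np.nonzero(alive)[0]
        alive[idx[~still]] = False
        if not alive.any():
            return np.array([])
    # sample n_sample diploids = 2*n_sample iid gametes from the final pool
    surv = counts[alive] / two_ne
    n_surv = surv.shape[0]
    cum = np.cumsum(surv, axis=1)
    u = rng.random((n_surv, 2 * n_sample))
    gametes = (u[:, :, None] > cum[:, None, :]).sum(axis=2)  # 0..3 per gamete
    a1 = gametes[:, 0::2]
    a2 = gametes[:, 1::2]
    # haplotype index -> allele pair: locus1 allele = idx < 2, locus2 = idx % 2 == 0
    d1 = (a1 < 2).astype(np.int64) + (a2 < 2)
    d2 = ((a1 == 0) | (a1 == 2)).astype(np.int64) + ((a2 == 0) | (a2 == 2))
    code = d1 * 3 + d2
    n9 = np.stack([np.bincount(code[i], minlength=9) for i in range(n_surv)])
    poly = _ld.polymorphic_mask(n9)
    if not poly.any():
        return np.array([])
    p, _, _, _ = _ld.em_haplotype_freqs_batch(n9[poly].astype(float))
    pAB, pAb, paB, pab = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    pA = pAB + pAb
    pB = pAB + paB
    d = pAB * pab - pAb * paB
    return d * d / (pA * (1 - pA) * pB * (1 - pB))
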