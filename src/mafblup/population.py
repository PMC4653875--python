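"""Simulation of LD- and family-structured SNP genotype panels.

The generator emulates a beef-cattle genotyping study: a dense SNP panel with a
U-shaped allele-frequency spectrum, nested sparser marker arrays biased towards
common variants, and a half-sib family structure (many sires, few progeny
each).  Haplotypes are drawn from a latent-Gaussian copula whose correlation
decays exponentially with inter-SNP distance, which yields adjacent-marker
dosage r2 that falls off with distance, the feature of real data that drives
imperfect marker-QTL linkage disequilibrium.

Dosages count copies of the second allele (0/1/2); missing calls are NaN.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

__all__ = [
    "SnpRecord",
    "GenotypePanel",
    "FamilySpec",
    "QcReport",
    "sample_ushape_frequencies",
    "make_snp_map",
    "simulate_genotypes",
    "simulate_study_population",
    "assign_marker_panels",
    "inject_genotype_errors",
    "qc_filter",
    "exclude_close_relatives",
]

PANEL_TAGS = ("sparse7", "sparse50", "dense")


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP: identifier, map position, target MAF, panel tags."""

    snp_id: str
    chrom: int
    pos: int
    target_freq: float
    panel_tags: frozenset = frozenset({"dense"})

    def __post_init__(self):
        if not (0.0 < self.target_freq <= 0.5):
            raise ValueError(
                f"{self.snp_id}: target_freq must lie in (0, 0.5], got {self.target_freq}"
            )
        tags = frozenset(self.panel_tags)
        if not tags <= set(PANEL_TAGS):
            raise ValueError(f"{self.snp_id}: unknown panel tags {tags - set(PANEL_TAGS)}")
        if "dense" not in tags:
            raise ValueError(f"{self.snp_id}: every SNP must carry the dense tag")
        if "sparse7" in tags and "sparse50" not in tags:
            raise ValueError(f"{self.snp_id}: sparse7 implies sparse50 (nested panels)")
        object.__setattr__(self, "panel_tags", tags)


class GenotypePanel:
    """Animals x SNPs dosage matrix plus map, panel tags and sire pedigree.

    Parameters
    ----------
    animal_ids : sequence of str
    snps : sequence of SnpRecord, position-sorted within chromosome
    dosages : (n_animals, n_snps) array of {0, 1, 2} or NaN for missing
    sire_of : mapping animal_id -> sire_id (optional)
    """

    def __init__(self, animal_ids, snps, dosages, sire_of=None):
        self.animal_ids = list(animal_ids)
        self.snps = list(snps)
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(self.animal_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.snps)} SNPs"
            )
        finite = dosages[np.isfinite(dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")
        self.dosages = dosages
        self.sire_of = dict(sire_of) if sire_of else {}
        self._check_map_sorted()

    # -- basic accessors ---------------------------------------------------
    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list:
        return [s.snp_id for s in self.snps]

    @property
    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.snps])

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.snps])

    def _check_map_sorted(self):
        chroms, pos = self.chroms, self.positions
        for c in np.unique(chroms):
            p = pos[chroms == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    # -- statistics --------------------------------------------------------
    def allele_freq(self) -> np.ndarray:
        """Observed frequency of the second allele per SNP (non-missing calls)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return np.isfinite(self.dosages).mean(axis=0)

    def validate(self) -> list:
        """Soft invariant check; returns a list of warnings (empty if clean)."""
        issues = []
        p = self.allele_freq()
        mono = np.where(~((p > 0) & (p < 1)))[0]
        if mono.size:
            issues.append(f"{mono.size} monomorphic or all-missing SNPs")
        if np.any(~np.isfinite(self.dosages).any(axis=0)):
            issues.append("SNP with missing fraction of 1")
        return issues

    # -- panel-tag helpers -------------------------------------------------
    def panel_indices(self, tag: str) -> np.ndarray:
        if tag not in PANEL_TAGS:
            raise ValueError(f"unknown panel tag {tag!r}")
        return np.array([i for i, s in enumerate(self.snps) if tag in s.panel_tags], dtype=int)

    def candidate_qtl_indices(self) -> np.ndarray:
        """SNPs on no sparse array: the candidate-QTL pool."""
        return np.array(
            [
                i
                for i, s in enumerate(self.snps)
                if "sparse50" not in s.panel_tags and "sparse7" not in s.panel_tags
            ],
            dtype=int,
        )

    # -- subsetting --------------------------------------------------------
    def subset_snps(self, indices) -> "GenotypePanel":
        indices = np.asarray(indices, dtype=int)
        return GenotypePanel(
            self.animal_ids,
            [self.snps[i] for i in indices],
            self.dosages[:, indices],
            self.sire_of,
        )

    def subset_animals(self, indices) -> "GenotypePanel":
        indices = np.asarray(indices, dtype=int)
        ids = [self.animal_ids[i] for i in indices]
        sire_of = {a: self.sire_of[a] for a in ids if a in self.sire_of}
        return GenotypePanel(ids, self.snps, self.dosages[indices, :], sire_of)

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(self.animal_ids, self.snps, self.dosages.copy(), self.sire_of)

    def index_of(self, snp_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown SNP id {e.args[0]!r}") from None


@dataclass
class FamilySpec:
    """Half-sib family law: progeny counts per sire.

    Counts are drawn from a geometric distribution on {1, 2, ...} truncated at
    ``max_progeny``, with the success parameter solved so that the truncated
    mean equals ``mean_progeny``.  If ``n_sires`` is given, exactly that many
    sires are used and counts are adjusted (within [1, max_progeny]) to sum to
    the population size; otherwise sires are added until all animals have one.
    """

    mean_progeny: float = 3.1
    max_progeny: int = 24
    n_sires: int | None = None
    _theta: float = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not (1.0 <= self.mean_progeny <= self.max_progeny):
            raise ValueError("mean_progeny must lie in [1, max_progeny]")

    def _truncated_geometric_theta(self) -> float:
        """Success probability giving the target mean on {1..max_progeny}."""
        if self._theta is not None:
            return self._theta
        k = np.arange(1, self.max_progeny + 1)

        def mean_minus_target(theta):
            pmf = theta * (1 - theta) ** (k - 1)
            pmf = pmf / pmf.sum()
            return float(k @ pmf) - self.mean_progeny

        if self.mean_progeny <= 1.0 + 1e-12:
            theta = 1.0 - 1e-12
        else:
            theta = optimize.brentq(mean_minus_target, 1e-9, 1 - 1e-9)
        object.__setattr__(self, "_theta", theta)
        return theta

    def draw_counts(self, n_animals: int, rng: np.random.Generator) -> np.ndarray:
        """Progeny counts per sire, each in [1, max_progeny], summing to n_animals."""
        theta = self._truncated_geometric_theta()

        def draw_one():
            while True:
                c = rng.geometric(theta)
                if c <= self.max_progeny:
                    return int(c)

        if self.n_sires is None:
            counts, total = [], 0
            while total < n_animals:
                c = min(draw_one(), n_animals - total)
                counts.append(c)
                total += c
            return np.array(counts, dtype=int)

        if self.n_sires * self.max_progeny < n_animals or self.n_sires > n_animals:
            raise ValueError("n_sires incompatible with n_animals and max_progeny")
        counts = np.array([draw_one() for _ in range(self.n_sires)], dtype=int)
        # nudge counts to the exact total, respecting the [1, max] bounds
        while counts.sum() != n_animals:
            diff = n_animals - counts.sum()
            if diff > 0:
                j = rng.choice(np.where(counts < self.max_progeny)[0])
                counts[j] += 1
            else:
                j = rng.choice(np.where(counts > 1)[0])
                counts[j] -= 1
        return counts


@dataclass
class QcReport:
    """Per-locus and per-animal removals with the first failing rule."""

    removed_snps: list = field(default_factory=list)  # (snp_id, reason)
    removed_animals: list = field(default_factory=list)  # (animal_id, max |kinship|)

    @property
    def removed_snp_ids(self) -> list:
        return [s for s, _ in self.removed_snps]

    @property
    def removed_animal_ids(self) -> list:
        return [a for a, _ in self.removed_animals]


# ---------------------------------------------------------------------------
# frequency sampling
# ---------------------------------------------------------------------------

def sample_ushape_frequencies(n: int, lo: float = 0.01, hi: float = 0.5, seed=None):
    """Draw allele frequencies from f(p) proportional to 1/(p(1-p)) on [lo, hi].

    The antiderivative of 1/(p(1-p)) is ln(p/(1-p)), so the inverse CDF is the
    logistic map of a uniform draw on [logit(lo), logit(hi)].
    """
    if not (0.0 < lo < hi <= 0.5):
        raise ValueError(f"require 0 < lo < hi <= 0.5, got lo={lo}, hi={hi}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(logit(lo), logit(hi), size=int(n))
    return expit(u)


def make_snp_map(
    n_snps: int,
    n_chrom: int = 4,
    spacing_bp: int = 5000,
    lo: float = 0.01,
    hi: float = 0.5,
    seed=None,
    jitter_spacing: bool = False,
):
    """Evenly spaced map over ``n_chrom`` chromosomes with U-shaped target MAFs.

    With ``jitter_spacing`` the inter-SNP gaps are exponential with the given
    mean, which is handy for LD-decay checks across a range of distances.
    """
    rng = np.random.default_rng(seed)
    freqs = sample_ushape_frequencies(n_snps, lo, hi, seed=rng.integers(2**31))
    per_chrom = np.full(n_chrom, n_snps // n_chrom, dtype=int)
    per_chrom[: n_snps % n_chrom] += 1
    snps, j = [], 0
    for c in range(1, n_chrom + 1):
        pos = 0
        for _ in range(per_chrom[c - 1]):
            gap = spacing_bp
            if jitter_spacing:
                gap = max(1, int(rng.exponential(spacing_bp)))
            pos += gap
            snps.append(
                SnpRecord(
                    snp_id=f"snp{j + 1:06d}",
                    chrom=c,
                    pos=pos,
                    target_freq=float(freqs[j]),
                )
            )
            j += 1
    return snps


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

def _draw_haplotypes(n_hap, snps, ld_decay, rng):
    """Binary haplotypes from a latent Gaussian first-order copula.

    Along each chromosome the latent series follows z[j+1] = rho*z[j] +
    sqrt(1-rho^2)*eps with rho = exp(-gap/ld_decay); the allele indicator is
    z < Phi^-1(target_freq), so marginal allele-1 frequency equals the target.
    """
    m = len(snps)
    chroms = np.array([s.chrom for s in snps])
    pos = np.array([s.pos for s in snps])
    thresh = stats.norm.ppf([s.target_freq for s in snps])
    hap = np.empty((n_hap, m), dtype=np.int8)
    z = None
    for j in range(m):
        if j == 0 or chroms[j] != chroms[j - 1]:
            z = rng.standard_normal(n_hap)
        else:
            gap = pos[j] - pos[j - 1]
            rho = math.exp(-gap / ld_decay) if ld_decay > 0 else 0.0
            z = rho * z + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(n_hap)
        hap[:, j] = z < thresh[j]
    return hap


def simulate_genotypes(
    snps,
    n_animals: int,
    family: FamilySpec | None = None,
    ld_decay: float = 100_000.0,
    seed=None,
) -> GenotypePanel:
    """Simulate a diploid panel with LD along the map and half-sib families.

    Each animal receives one gamete from its sire (one of the sire's two
    haplotypes, chosen independently per chromosome) and one haplotype drawn
    fresh from the population process, giving half-sib additive relationships
    of ~0.25 among paternal sibs.
    """
    if n_animals < 2:
        raise ValueError("n_animals must be >= 2")
    if not snps:
        raise ValueError("snps must be non-empty")
    order = sorted(range(len(snps)), key=lambda i: (snps[i].chrom, snps[i].pos))
    if order != list(range(len(snps))):
        raise ValueError("snps must be sorted by (chrom, pos)")
    family = family or FamilySpec()
    rng = np.random.default_rng(seed)

    counts = family.draw_counts(n_animals, rng)
    n_sires = len(counts)
    sire_ids = [f"S{k + 1:05d}" for k in range(n_sires)]
    sire_hap = _draw_haplotypes(2 * n_sires, snps, ld_decay, rng)
    dam_hap = _draw_haplotypes(n_animals, snps, ld_decay, rng)

    chroms = np.array([s.chrom for s in snps])
    chrom_slices = [np.where(chroms == c)[0] for c in np.unique(chroms)]

    dosages = np.empty((n_animals, len(snps)), dtype=float)
    animal_ids, sire_of = [], {}
    a = 0
    for k, cnt in enumerate(counts):
        for _ in range(cnt):
            aid = f"A{a + 1:05d}"
            animal_ids.append(aid)
            sire_of[aid] = sire_ids[k]
            paternal = np.empty(len(snps), dtype=np.int8)
            for idx in chrom_slices:
                which = rng.integers(2)
                paternal[idx] = sire_hap[2 * k + which, idx]
            dosages[a] = paternal + dam_hap[a]
            a += 1
    return GenotypePanel(animal_ids, snps, dosages, sire_of)


def simulate_study_population(
    n_animals: int = 1000,
    n_snps: int = 5000,
    n_chrom: int = 4,
    spacing_bp: int = 5000,
    ld_decay: float = 100_000.0,
    sparse50_frac: float = 0.08,
    sparse7_frac: float = 0.015,
    high_maf_bias: float = 1.0,
    family: FamilySpec | None = None,
    seed=None,
) -> GenotypePanel:
    """One-call study population: map, genotypes, and nested marker panels."""
    ss = np.random.SeedSequence(seed)
    s_map, s_geno, s_panel = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    snps = make_snp_map(n_snps, n_chrom=n_chrom, spacing_bp=spacing_bp, seed=s_map)
    panel = simulate_genotypes(snps, n_animals, family=family, ld_decay=ld_decay, seed=s_geno)
    return assign_marker_panels(
        panel,
        n_sparse7=int(round(sparse7_frac * n_snps)),
        n_sparse50=int(round(sparse50_frac * n_snps)),
        high_maf_bias=high_maf_bias,
        seed=s_panel,
    )


# ---------------------------------------------------------------------------
# marker panel assignment
# ---------------------------------------------------------------------------

def _weighted_sample_without_replacement(weights, k, rng):
    """Gumbel top-k trick: O(n log n), exact for weights > 0."""
    with np.errstate(divide="ignore"):
        keys = np.log(weights) + rng.gumbel(size=len(weights))
    return np.sort(np.argpartition(-keys, k - 1)[:k])


def assign_marker_panels(
    panel: GenotypePanel,
    n_sparse7: int,
    n_sparse50: int,
    high_maf_bias: float = 1.0,
    seed=None,
) -> GenotypePanel:
    """Tag nested sparse marker arrays; the rest becomes the candidate-QTL pool.

    The sparse50 array is sampled with probability proportional to MAF raised
    to ``high_maf_bias``, reproducing the high-MAF skew of commercial arrays
    relative to the dense panel; sparse7 is sampled from within sparse50 with
    the same weighting.  ``high_maf_bias = 0`` gives uniform sampling.
    """
    if not (0 <= n_sparse7 <= n_sparse50 <= panel.n_snps):
        raise ValueError(
            f"need 0 <= n_sparse7 ({n_sparse7}) <= n_sparse50 ({n_sparse50}) "
            f"<= n_snps ({panel.n_snps})"
        )
    rng = np.random.default_rng(seed)
    maf = panel.maf()
    weights = np.where(maf > 0, maf, 0.0) ** high_maf_bias if high_maf_bias != 0 else np.ones(
        panel.n_snps
    )
    idx50 = _weighted_sample_without_replacement(weights, n_sparse50, rng) if n_sparse50 else np.array([], dtype=int)
    if n_sparse7:
        within = _weighted_sample_without_replacement(weights[idx50], n_sparse7, rng)
        idx7 = idx50[within]
    else:
        idx7 = np.array([], dtype=int)
    in50, in7 = set(idx50.tolist()), set(idx7.tolist())
    snps = []
    for i, s in enumerate(panel.snps):
        tags = {"dense"}
        if i in in50:
            tags.add("sparse50")
        if i in in7:
            tags.add("sparse7")
        snps.append(replace(s, panel_tags=frozenset(tags)))
    return GenotypePanel(panel.animal_ids, snps, panel.dosages, panel.sire_of)


# ---------------------------------------------------------------------------
# genotype error injection (stand-in for imputation error)
# ---------------------------------------------------------------------------

def inject_genotype_errors(
    panel: GenotypePanel, target_correlation: float, seed=None
) -> GenotypePanel:
    """Perturb dosages so E[cor(original, perturbed)] per SNP equals the target.

    Each observed call is independently replaced, with probability
    1 - target_correlation, by a fresh Binomial(2, p_hat) draw at the SNP's
    observed allele frequency.  Because the replacement is independent of the
    original with the same marginal, the population correlation between the
    two columns is exactly the target (cov = target * var).
    """
    if not (0.0 < target_correlation <= 1.0):
        raise ValueError("target_correlation must lie in (0, 1]")
    if target_correlation == 1.0:
        return panel.copy()
    rng = np.random.default_rng(seed)
    eps = 1.0 - target_correlation
    X = panel.dosages.copy()
    p = panel.allele_freq()
    for j in range(panel.n_snps):
        obs = np.isfinite(X[:, j])
        flip = obs & (rng.random(panel.n_animals) < eps)
        if flip.any():
            X[flip, j] = rng.binomial(2, p[j], size=int(flip.sum()))
    return GenotypePanel(panel.animal_ids, panel.snps, X, panel.sire_of)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def _hwe_chisq_pvalue(dosage_col: np.ndarray) -> float:
    """1-df chi-square goodness-of-fit of genotype counts to HWE proportions."""
    x = dosage_col[np.isfinite(dosage_col)]
    n = x.size
    if n == 0:
        return 1.0
    n2 = int((x == 2).sum())
    n1 = int((x == 1).sum())
    n0 = n - n1 - n2
    p = (2 * n2 + n1) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    chisq = float(((np.array([n0, n1, n2]) - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chisq, df=1))


def qc_filter(
    panel: GenotypePanel,
    maf_min: float = 0.01,
    call_rate_min: float = 0.95,
    hwe_alpha: float = 0.001,
) -> tuple[GenotypePanel, QcReport]:
    """Drop SNPs failing MAF, call-rate, or HWE rules (first failing rule logged)."""
    if panel.n_snps == 0:
        raise ValueError("panel has no SNPs")
    report = QcReport()
    maf = panel.maf()
    call = panel.call_rate()
    keep = []
    for j, s in enumerate(panel.snps):
        if not np.isfinite(maf[j]) or maf[j] < maf_min:
            report.removed_snps.append((s.snp_id, "maf"))
        elif call[j] < call_rate_min:
            report.removed_snps.append((s.snp_id, "call_rate"))
        elif _hwe_chisq_pvalue(panel.dosages[:, j]) < hwe_alpha:
            report.removed_snps.append((s.snp_id, "hwe"))
        else:
            keep.append(j)
    if not keep:
        raise ValueError("QC removed every SNP")
    return panel.subset_snps(keep), report


def exclude_close_relatives(
    panel: GenotypePanel, grm, cutoff: float = 0.4
) -> tuple[GenotypePanel, QcReport]:
    """Greedily drop animals until no |off-diagonal| relationship exceeds cutoff.

    The animal with the most violations is removed first; ties break by id
    order.  ``grm`` may be a Grm object or a plain square matrix over the
    panel's animals.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    G = np.asarray(getattr(grm, "matrix", grm), dtype=float)
    n = panel.n_animals
    if G.shape != (n, n):
        raise ValueError(f"GRM shape {G.shape} does not match {n} animals")
    A = np.abs(G.copy())
    np.fill_diagonal(A, 0.0)
    active = np.ones(n, dtype=bool)
    report = QcReport()
    while True:
        viol = (A > cutoff) & active[:, None] & active[None, :]
        counts = viol.sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        worst = int(np.flatnonzero(counts == counts.max())[0])  # id order tie-break
        report.removed_animals.append(
            (panel.animal_ids[worst], float(A[worst, active].max()))
        )
        active[worst] = False
    return panel.subset_animals(np.flatnonzero(active)), report
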