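"""QTL sampling by MAF category, substitution effects, and trait simulation.

Causal loci are drawn from the candidate pool (dense-only SNPs), stratified by
minor allele frequency: low (0.01 <= MAF <= 0.05), high (0.05 < MAF <= 0.5),
or all.  Under the U-shaped frequency law f(p) ~ 1/(p(1-p)) the all-MAF
category mixes the two strata in the closed-form integral ratio, 0.36 : 0.64.

Two effect models are supported: gamma-distributed magnitudes independent of
frequency, and the equal-variance model b_j = 1/sqrt(2 p_j (1-p_j)) in which
every locus contributes the same genetic variance (rare alleles get large
effects).  After sign assignment the effects are rescaled by one scalar so the
realized population variance of the true breeding values equals 100 * h2; the
residual variance sigma_g2 * (1/h2 - 1) then yields total phenotypic variance
100 at every heritability setting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logit

from .population import GenotypePanel

__all__ = [
    "MafCategory",
    "QtlSet",
    "TraitSimulation",
    "ushape_interval_shares",
    "sample_qtls",
    "draw_effects",
    "standardize_effects",
    "compute_tbv",
    "simulate_phenotypes",
]

LOW_BOUNDS = (0.01, 0.05)   # boundary 0.05 belongs to low
HIGH_BOUNDS = (0.05, 0.5)
ALL_BOUNDS = (0.01, 0.5)


@dataclass(frozen=True)
class MafCategory:
    """Named MAF stratum; the 0.05 boundary belongs to the low stratum."""

    name: str

    _BOUNDS = {"low": LOW_BOUNDS, "high": HIGH_BOUNDS, "all": ALL_BOUNDS}

    def __post_init__(self):
        if self.name not in self._BOUNDS:
            raise ValueError(f"unknown MAF category {self.name!r}; use low/high/all")

    @property
    def bounds(self):
        return self._BOUNDS[self.name]

    def contains(self, maf: np.ndarray) -> np.ndarray:
        maf = np.asarray(maf, dtype=float)
        if self.name == "low":
            return (maf >= LOW_BOUNDS[0]) & (maf <= LOW_BOUNDS[1])
        if self.name == "high":
            return (maf > HIGH_BOUNDS[0]) & (maf <= HIGH_BOUNDS[1])
        return (maf >= ALL_BOUNDS[0]) & (maf <= ALL_BOUNDS[1])


@dataclass
class QtlSet:
    """Sampled causal loci with frequencies and substitution effects."""

    qtl_indices: np.ndarray
    snp_ids: list
    p: np.ndarray                     # frequency of the second allele
    category: str = "all"
    b: np.ndarray | None = None       # substitution effects, trait units/allele
    effect_model: str | None = None
    sigma_g2: float | None = None     # Var(TBV) after standardization

    def __post_init__(self):
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=int)
        self.p = np.asarray(self.p, dtype=float)
        if len(np.unique(self.qtl_indices)) != len(self.qtl_indices):
            raise ValueError("QTL indices must be unique")

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_indices)

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.p, 1.0 - self.p)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"snp_id": self.snp_ids, "p": self.p, "b": self.b, "category": self.category}
        )


@dataclass
class TraitSimulation:
    """Per-animal true breeding values and phenotypes for one replicate."""

    animal_ids: list
    tbv: np.ndarray
    y: np.ndarray
    h2_true: float
    sigma_g2: float
    sigma_e2: float
    seed: int | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"animal_id": self.animal_ids, "tbv": self.tbv, "y": self.y})


def ushape_interval_shares(lo: float = 0.01, split: float = 0.05, hi: float = 0.5):
    """Low/high shares of the integral of 1/(p(1-p)) over [lo, hi], split at ``split``.

    Uses the closed form integral ln(p/(1-p)); the shares sum to 1.  With the
    defaults the shares round to (0.36, 0.64).
    """
    if not (0.0 < lo < 1.0 and 0.0 < hi < 1.0 and 0.0 < split < 1.0):
        raise ValueError("bounds must lie in (0, 1)")
    if not (lo < split <= hi):
        raise ValueError("require lo < split <= hi")
    total = logit(hi) - logit(lo)
    low = (logit(split) - logit(lo)) / total
    return float(low), float(1.0 - low)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def sample_qtls(
    panel: GenotypePanel, category, n_qtl: int, seed=None
) -> QtlSet:
    """Uniformly sample QTLs from the candidate pool within a MAF category.

    For the all-MAF category the low/high composition is fixed (not binomial):
    round-half-up of the exact U-shape low share times ``n_qtl`` loci come from
    the low stratum and the remainder from the high stratum, the 0.36 : 0.64
    ratio at the default bounds.
    """
    if isinstance(category, str):
        category = MafCategory(category)
    rng = np.random.default_rng(seed)
    pool = panel.candidate_qtl_indices()
    maf = panel.maf()
    p = panel.allele_freq()

    def pick(cat: MafCategory, k: int) -> np.ndarray:
        members = pool[cat.contains(maf[pool])]
        if len(members) < k:
            raise ValueError(
                f"candidate pool has only {len(members)} SNPs in MAF category "
                f"{cat.name!r}; {k} requested"
            )
        return rng.choice(members, size=k, replace=False)

    if category.name == "all":
        low_share, _ = ushape_interval_shares()
        n_low = _round_half_up(low_share * n_qtl)
        idx = np.concatenate(
            [pick(MafCategory("low"), n_low), pick(MafCategory("high"), n_qtl - n_low)]
        )
    else:
        idx = pick(category, n_qtl)
    idx = np.sort(idx)
    return QtlSet(
        qtl_indices=idx,
        snp_ids=[panel.snps[i].snp_id for i in idx],
        p=p[idx],
        category=category.name,
    )


def draw_effects(
    qtls: QtlSet,
    model: str = "equal_variance",
    shape: float = 0.4,
    scale: float = 1.66,
    seed=None,
) -> QtlSet:
    """Assign substitution effects under the gamma or equal-variance model.

    gamma: |b_j| ~ Gamma(shape, scale) i.i.d., independent of frequency.
    equal_variance: |b_j| = 1/sqrt(2 p_j (1 - p_j)), so each locus contributes
    genetic variance 2 p_j (1 - p_j) b_j^2 = 1 before standardization.
    Signs are i.i.d. +-1 in both models.
    """
    rng = np.random.default_rng(seed)
    if model == "gamma":
        mag = rng.gamma(shape, scale, size=qtls.n_qtl)
    elif model == "equal_variance":
        het = 2.0 * qtls.p * (1.0 - qtls.p)
        if np.any(het <= 0):
            raise ValueError("equal-variance model requires polymorphic QTLs")
        mag = 1.0 / np.sqrt(het)
    else:
        raise ValueError(f"unknown effect model {model!r}; use gamma or equal_variance")
    signs = rng.choice([-1.0, 1.0], size=qtls.n_qtl)
    qtls.b = mag * signs
    qtls.effect_model = model
    qtls.sigma_g2 = None
    return qtls


def compute_tbv(panel: GenotypePanel, qtls: QtlSet) -> np.ndarray:
    """True breeding values: tbv_i = sum_j x_ij b_j over the QTL columns."""
    if qtls.b is None:
        raise ValueError("effects not drawn; call draw_effects first")
    X = panel.dosages[:, qtls.qtl_indices]
    if not np.isfinite(X).all():
        raise ValueError("missing dosage at a QTL column; TBV requires complete calls")
    return X @ qtls.b


def standardize_effects(qtls: QtlSet, panel: GenotypePanel, h2: float) -> QtlSet:
    """Scale all effects by one constant so Var(TBV) = 100 * h2 exactly.

    The variance is the realized population variance (denominator n) of the
    TBV over the panel's animals, so the identity holds in-sample, not merely
    in HWE expectation.  Idempotent.
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError("h2 must lie in (0, 1)")
    tbv = compute_tbv(panel, qtls)
    v = float(np.var(tbv))  # population convention, ddof=0
    if v <= 0:
        raise ValueError("TBV variance is zero before scaling; degenerate trait")
    target = 100.0 * h2
    qtls.b = qtls.b * np.sqrt(target / v)
    qtls.sigma_g2 = target
    return qtls


def simulate_phenotypes(
    tbv: np.ndarray,
    h2: float,
    seed=None,
    animal_ids=None,
    sigma_g2: float | None = None,
) -> TraitSimulation:
    """Add i.i.d. Normal residuals with variance sigma_g2 * (1/h2 - 1).

    With standardized effects (sigma_g2 = 100*h2) the residual variance is
    100*(1 - h2) and total phenotypic variance is 100.
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError("h2 must lie in (0, 1)")
    tbv = np.asarray(tbv, dtype=float)
    if sigma_g2 is None:
        sigma_g2 = float(np.var(tbv))
    sigma_e2 = sigma_g2 * (1.0 / h2 - 1.0)
    rng = np.random.default_rng(seed)
    e = rng.normal(0.0, np.sqrt(sigma_e2), size=tbv.shape)
    if animal_ids is None:
        animal_ids = [f"A{i + 1:05d}" for i in range(len(tbv))]
    return TraitSimulation(
        animal_ids=list(animal_ids),
        tbv=tbv,
        y=tbv + e,
        h2_true=h2,
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        seed=seed,
    )
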