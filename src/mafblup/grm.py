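"""Genomic relationship matrices: VanRaden, Yang, and LD-weighted (Speed) forms.

Given dosages x_ij and second-allele frequencies p_j computed on the full
analysis sample, with z_ij = x_ij - 2 p_j:

* VanRaden:  G_V = Z Z' / (2 sum_j p_j (1 - p_j))
* Yang:      G_Y = Zbar Zbar' / m,   zbar_ij = z_ij / sqrt(2 p_j (1 - p_j))
* Speed:     G_S = W W' / sum_j k_j, w_ij = sqrt(k_j) zbar_ij

The LD weights k_j make local sums of decayed r2 approximately one, so blocks
of redundant SNPs share a unit of weight instead of each counting fully; they
are obtained by non-negative least squares on the windowed decayed-r2 system.
A small constant added to the diagonal keeps the matrices comfortably positive
definite for the mixed-model solves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy.optimize import nnls

from .population import GenotypePanel

__all__ = [
    "Grm",
    "allele_frequencies",
    "build_grm_vanraden",
    "build_grm_yang",
    "build_grm_speed",
    "compute_ld_weights",
    "partition_grms_by_maf",
    "regularize",
    "write_gcta_grm",
    "read_gcta_grm",
]

GRM_KINDS = ("vanraden", "yang", "speed", "partition_low", "partition_high")


@dataclass
class Grm:
    """An n x n relationship matrix with its builder provenance."""

    matrix: np.ndarray
    kind: str
    animal_ids: list
    snp_ids: list
    weights: np.ndarray | None = None  # per-SNP k_j; None means all 1
    jitter: float = 0.0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.animal_ids)
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix shape {self.matrix.shape} != ({n}, {n})")
        if self.kind not in GRM_KINDS:
            raise ValueError(f"unknown GRM kind {self.kind!r}")

    @property
    def n(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def submatrix(self, row_idx, col_idx=None) -> np.ndarray:
        row_idx = np.asarray(row_idx, dtype=int)
        col_idx = row_idx if col_idx is None else np.asarray(col_idx, dtype=int)
        return self.matrix[np.ix_(row_idx, col_idx)]

    def subset(self, indices) -> "Grm":
        indices = np.asarray(indices, dtype=int)
        return dc_replace(
            self,
            matrix=self.matrix[np.ix_(indices, indices)],
            animal_ids=[self.animal_ids[i] for i in indices],
        )


def _resolve_subset(panel: GenotypePanel, snp_subset) -> np.ndarray:
    if snp_subset is None:
        return np.arange(panel.n_snps)
    snp_subset = list(snp_subset)
    if len(snp_subset) == 0:
        raise ValueError("SNP subset must be non-empty")
    if isinstance(snp_subset[0], str):
        return panel.index_of(snp_subset)
    return np.asarray(snp_subset, dtype=int)


def allele_frequencies(panel: GenotypePanel, snp_subset=None) -> np.ndarray:
    """Second-allele frequency per subset SNP, from non-missing calls."""
    idx = _resolve_subset(panel, snp_subset)
    return panel.allele_freq()[idx]


def _centered_dosages(panel: GenotypePanel, idx: np.ndarray):
    """Mean-imputed, centered dosage block and allele frequencies."""
    X = panel.dosages[:, idx].copy()
    p = allele_frequencies(panel, idx)
    mu = 2.0 * p
    miss = ~np.isfinite(X)
    if miss.any():
        X[miss] = np.broadcast_to(mu, X.shape)[miss]
    return X - mu, p


def build_grm_vanraden(panel: GenotypePanel, snp_subset=None) -> Grm:
    """G_V = Z Z' / (2 sum p(1-p)); monomorphic SNPs contribute nothing."""
    idx = _resolve_subset(panel, snp_subset)
    Z, p = _centered_dosages(panel, idx)
    het = p * (1.0 - p)
    denom = 2.0 * float(het.sum())
    if denom <= 0:
        raise ValueError("all subset SNPs are monomorphic; VanRaden GRM undefined")
    G = (Z @ Z.T) / denom
    return Grm(
        matrix=G,
        kind="vanraden",
        animal_ids=panel.animal_ids,
        snp_ids=[panel.snps[i].snp_id for i in idx],
    )


def _yang_matrix(panel: GenotypePanel, idx: np.ndarray) -> np.ndarray:
    Z, p = _centered_dosages(panel, idx)
    het = 2.0 * p * (1.0 - p)
    if np.any(het <= 0):
        bad = [panel.snps[i].snp_id for i, h in zip(idx, het) if h <= 0]
        raise ValueError(
            f"monomorphic SNPs in Yang GRM subset (division by zero): {bad[:5]}"
        )
    Zbar = Z / np.sqrt(het)
    return (Zbar @ Zbar.T) / len(idx), Zbar


def build_grm_yang(panel: GenotypePanel, snp_subset=None) -> Grm:
    """G_Y = Zbar Zbar' / m with per-SNP unit-variance scaling."""
    idx = _resolve_subset(panel, snp_subset)
    G, _ = _yang_matrix(panel, idx)
    return Grm(
        matrix=G,
        kind="yang",
        animal_ids=panel.animal_ids,
        snp_ids=[panel.snps[i].snp_id for i in idx],
    )


def compute_ld_weights(
    panel: GenotypePanel,
    snp_subset=None,
    window_bp: int = 1_000_000,
    decay_halflife_bp: float = 125_000.0,
    passes: int = 1,
    ridge: float = 1e-8,
) -> np.ndarray:
    """LD-adjusted SNP weights: local decayed-r2 sums driven towards one.

    Minimizes sum_j (sum_k d_jk r2_jk w_k - 1)^2 subject to w >= 0, where
    d_jk = exp(-ln2 * distance_jk / halflife) within ``window_bp`` (same
    chromosome) and d_jj r2_jj = 1.  A tiny ridge augmentation selects the
    minimum-norm solution on ties, so q exact copies of a SNP each get ~1/q.
    With ``passes=2`` (recommended for dense panels) the system is re-solved
    with columns scaled by the first-pass weights and the product returned.
    """
    idx = _resolve_subset(panel, snp_subset)
    chroms = panel.chroms[idx]
    pos = panel.positions[idx]
    for c in np.unique(chroms):
        if np.any(np.diff(pos[chroms == c]) < 0):
            raise ValueError("subset SNPs must be position-sorted within chromosome")
    Z, p = _centered_dosages(panel, idx)
    weights = np.ones(len(idx))
    for i in np.where(p * (1 - p) <= 0)[0]:
        weights[i] = 0.0  # monomorphic: no LD information, excluded downstream

    def solve_block(A):
        m = A.shape[0]
        aug = np.vstack([A, np.sqrt(ridge) * np.eye(m)])
        b = np.concatenate([np.ones(m), np.zeros(m)])
        w, _ = nnls(aug, b)
        return w

    ln2 = np.log(2.0)
    out = np.ones(len(idx))
    for c in np.unique(chroms):
        sel = np.where((chroms == c) & (weights > 0))[0]
        if len(sel) == 0:
            continue
        Xc = Z[:, sel]
        sd = Xc.std(axis=0)
        R = (Xc / sd).T @ (Xc / sd) / Xc.shape[0]
        r2 = R**2
        dist = np.abs(pos[sel][:, None] - pos[sel][None, :])
        decay = np.exp(-ln2 * dist / decay_halflife_bp)
        decay[dist > window_bp] = 0.0
        A = decay * r2
        np.fill_diagonal(A, 1.0)
        w = solve_block(A)
        if passes >= 2:
            w2 = solve_block(A * w[None, :])
            w = w * w2
        out[sel] = w
    out[weights == 0] = 0.0
    return out


def build_grm_speed(panel: GenotypePanel, snp_subset=None, weights=None) -> Grm:
    """G_S = W W' / sum k_j with w_ij = sqrt(k_j) * zbar_ij."""
    idx = _resolve_subset(panel, snp_subset)
    if weights is None:
        weights = compute_ld_weights(panel, idx)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(idx),):
        raise ValueError("weights length must match SNP subset size")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = float(weights.sum())
    if total <= 0:
        raise ValueError("all-zero weights; Speed GRM undefined")
    keep = weights > 0
    _, Zbar = _yang_matrix(panel, idx[keep])
    W = Zbar * np.sqrt(weights[keep])
    G = (W @ W.T) / total
    return Grm(
        matrix=G,
        kind="speed",
        animal_ids=panel.animal_ids,
        snp_ids=[panel.snps[i].snp_id for i in idx],
        weights=weights,
    )


def partition_grms_by_maf(
    panel: GenotypePanel, snp_subset=None, threshold: float = 0.05
) -> tuple[Grm, Grm]:
    """Yang GRMs from the low-MAF (maf <= threshold) and high-MAF strata.

    The boundary MAF belongs to the low stratum, matching the low category
    definition 0.01 <= MAF <= 0.05.
    """
    idx = _resolve_subset(panel, snp_subset)
    maf = panel.maf()[idx]
    low = idx[(maf > 0) & (maf <= threshold)]
    high = idx[maf > threshold]
    if len(low) == 0:
        raise ValueError("empty low-MAF stratum; cannot partition")
    if len(high) == 0:
        raise ValueError("empty high-MAF stratum; cannot partition")
    g_low = build_grm_yang(panel, low)
    g_high = build_grm_yang(panel, high)
    g_low.kind = "partition_low"
    g_high.kind = "partition_high"
    return g_low, g_high


def regularize(grm: Grm, jitter: float = 1e-5) -> Grm:
    """Add ``jitter`` to the diagonal (shifts every eigenvalue by +jitter)."""
    G = grm.matrix.copy()
    G[np.diag_indices_from(G)] += jitter
    return dc_replace(grm, matrix=G, jitter=grm.jitter + jitter)


# ---------------------------------------------------------------------------
# GCTA-style text interchange
# ---------------------------------------------------------------------------

def write_gcta_grm(grm: Grm, prefix: str) -> None:
    """Lower-triangle triplets (i, j, n_snps, value) plus an id file."""
    with open(prefix + ".grm.txt", "w") as fh:
        for i in range(grm.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.n_snps}\t{grm.matrix[i, j]:.10g}\n")
    with open(prefix + ".grm.id", "w") as fh:
        for aid in grm.animal_ids:
            fh.write(f"FAM\t{aid}\n")


def read_gcta_grm(prefix: str, kind: str = "yang") -> Grm:
    with open(prefix + ".grm.id") as fh:
        ids = [line.split()[1] for line in fh if line.strip()]
    n = len(ids)
    G = np.zeros((n, n))
    n_snps = 0
    with open(prefix + ".grm.txt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{prefix}.grm.txt:{lineno}: expected 4 columns")
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            n_snps = int(parts[2])
            G[i, j] = G[j, i] = float(parts[3])
    return Grm(
        matrix=G,
        kind=kind,
        animal_ids=ids,
        snp_ids=[f"snp{k}" for k in range(n_snps)],
    )
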