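"""Genomic relationship matrix (VanRaden method 1), blending, H-inverse terms
and principal components of population structure."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genoqc import GenotypePanel


class GrmError(ValueError):
    """Degenerate or incompatible genomic-relationship inputs."""


@dataclass
class GenomicRelationship:
    """Dense symmetric genomic relationship matrix over genotyped animals."""

    ids: list[str]
    values: np.ndarray
    allele_freqs: pd.Series
    blend_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise GrmError("matrix dimension does not match id list")


def allele_frequencies(panel: GenotypePanel) -> pd.Series:
    """Observed counted-allele frequency per SNP among non-missing calls."""
    nonmiss = panel.calls >= 0
    counts = nonmiss.sum(axis=0)
    if np.any(counts == 0):
        warnings.warn(f"{int((counts == 0).sum())} SNPs have all-missing calls; excluded")
    with np.errstate(invalid="ignore"):
        p = np.where(nonmiss, panel.calls, 0).sum(axis=0) / (2 * np.maximum(counts, 1))
    p = np.where(counts > 0, p, np.nan)
    return pd.Series(p, index=pd.Index(panel.snp_ids, name="snp"), name="freq")


def genomic_relationship_vanraden1(
    panel: GenotypePanel, freqs: pd.Series | None = None
) -> GenomicRelationship:
    """G = ZZ' / (2 sum p(1-p)) with Z the 2p-centred genotype matrix.

    Missing calls are mean-filled at 2p before centring (imputation proper is
    out of scope).  Monomorphic SNPs (p in {0,1}) carry no information and
    are excluded with a warning.
    """
    if freqs is None:
        freqs = allele_frequencies(panel)
    p = freqs.reindex(panel.snp_ids).to_numpy(dtype=float)
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    if not usable.all():
        warnings.warn(f"{int((~usable).sum())} monomorphic/uninformative SNPs excluded from G")
    p = p[usable]
    denom = float(2.0 * np.sum(p * (1 - p)))
    if denom <= 0:
        raise GrmError("sum 2p(1-p) is zero; panel carries no genomic information")
    M = panel.calls[:, usable].astype(float)
    twop = 2 * p
    M = np.where(M >= 0, M, twop)
    Z = M - twop
    G = (Z @ Z.T) / denom
    return GenomicRelationship(list(panel.animal_ids), G, freqs)


def tune_to_pedigree(G: GenomicRelationship, A22: np.ndarray) -> GenomicRelationship:
    """Rescale G so its mean diagonal and mean off-diagonal match A22.

    Observed-frequency centring puts G on the current-population base while
    A22 is on the pedigree founder base; the affine adjustment a + bG with
    means matched to A22 reconciles the two so the genotyped block of H adds
    information without distorting the genetic base.
    """
    A22 = np.asarray(A22, dtype=float)
    if A22.shape != G.values.shape:
        raise GrmError("A22 dimension does not match G")
    n = A22.shape[0]
    off = ~np.eye(n, dtype=bool)
    gd, ad = float(np.mean(np.diag(G.values))), float(np.mean(np.diag(A22)))
    go = float(np.mean(G.values[off])) if n > 1 else 0.0
    ao = float(np.mean(A22[off])) if n > 1 else 0.0
    b = (ad - ao) / (gd - go) if abs(gd - go) > 1e-12 else 1.0
    a = ad - b * gd
    return GenomicRelationship(list(G.ids), a + b * G.values, G.allele_freqs, G.blend_weight)


def blend_with_pedigree(
    G: GenomicRelationship, A22: np.ndarray, weight: float = 0.95
) -> GenomicRelationship:
    """Convex combination weight*G + (1-weight)*A22 for invertibility."""
    if not 0 < weight <= 1:
        raise ValueError("blend weight must be in (0, 1]")
    A22 = np.asarray(A22, dtype=float)
    if A22.shape != G.values.shape:
        raise GrmError("A22 dimension does not match G")
    return GenomicRelationship(
        list(G.ids), weight * G.values + (1 - weight) * A22, G.allele_freqs, weight
    )


def h_inverse_terms(G_b: GenomicRelationship, A22: np.ndarray) -> np.ndarray:
    """Genotyped-block correction Delta = G_b^-1 - A22^-1.

    Added onto A^-1 at the genotyped rows/columns this yields H^-1, the
    combined relationship inverse of single-step BLUP.
    """
    A22 = np.asarray(A22, dtype=float)
    if A22.shape != G_b.values.shape:
        raise GrmError("A22 dimension does not match G")
    try:
        Gi = np.linalg.inv(G_b.values)
        Ai = np.linalg.inv(A22)
    except np.linalg.LinAlgError as e:
        raise GrmError(f"singular matrix in H-inverse construction: {e}") from e
    return Gi - Ai


def build_h_inverse(
    a_inv: sp.spmatrix, delta: np.ndarray, positions: np.ndarray
) -> sp.csr_matrix:
    """Scatter the genotyped-block correction onto A^-1, giving H^-1."""
    positions = np.asarray(positions)
    m = positions.size
    if delta.shape != (m, m):
        raise GrmError("delta dimension does not match position list")
    rows = np.repeat(positions, m)
    cols = np.tile(positions, m)
    add = sp.coo_matrix((delta.ravel(), (rows, cols)), shape=a_inv.shape)
    return (a_inv + add).tocsr()


def principal_components(panel: GenotypePanel, k: int = 2):
    """PCA of the column-centred genotype matrix (eigenstructure of G).

    Returns (scores, variance_fractions): projections of the animals on the
    first k axes and the fraction of total genotypic variance each explains.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    M = panel.calls.astype(float)
    nonmiss = M >= 0
    colmean = np.where(nonmiss, M, 0).sum(axis=0) / np.maximum(nonmiss.sum(axis=0), 1)
    M = np.where(nonmiss, M, colmean) - colmean
    total = float(np.sum(M * M))
    if total <= 1e-12:
        warnings.warn("panel has zero genotypic variance; PCA undefined")
        return np.zeros((panel.n_samples, k)), np.zeros(k)
    rank = min(M.shape)
    if k > rank:
        warnings.warn(f"k={k} exceeds rank {rank}; truncated")
        k = rank
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    scores = U[:, :k] * s[:k]
    fractions = (s[:k] ** 2) / total
    return scores, fractions
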