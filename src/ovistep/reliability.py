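"""Reliability and accuracy of (genomic) breeding values.

Exact reliabilities come from prediction-error variances on the inverse of
the mixed-model coefficient matrix; at population scale that inverse is out
of reach, so a two-step approximation is provided: per-animal record
information after contemporary-group absorption, then iterative propagation
of information between parents and offspring.  Accuracy is the square root
of reliability, and the stratified accuracy comparison quantifies what
genotypes add for animals with and without phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse.linalg as spla

from .pedigree import Pedigree
from .varcomp import VarianceComponents


class ReliabilityError(RuntimeError):
    pass


def exact_reliability(
    system,
    vc: VarianceComponents,
    F: pd.Series,
    kin_diag: np.ndarray | None = None,
    max_equations: int = 20000,
) -> pd.Series:
    """rel_i = 1 - PEV_i / (k_ii sigma2_a) from the MME inverse.

    ``system`` is an assembled :class:`~ovistep.mme.LinearSystem` in lambda
    form, so PEV_i = sigma2_e * [C^-1]_ii on the animal block.  The
    denominator uses the diagonal of the relationship structure actually
    fitted: k_ii = 1 + F_i under A, the blended genomic diagonal for
    genotyped animals under H (passed via ``kin_diag``).  Dense inversion
    via the sparse factorization; guarded by ``max_equations``.
    """
    n_eq = system.n_equations
    if n_eq > max_equations:
        raise ReliabilityError(
            f"system has {n_eq} equations (> {max_equations}); "
            "use approximate_reliability"
        )
    lu = spla.splu(system.coeff, permc_spec="MMD_AT_PLUS_A")
    a0, an = system.blocks["animal"]
    rhs = np.zeros((n_eq, an))
    rhs[a0 + np.arange(an), np.arange(an)] = 1.0
    diag = lu.solve(rhs)[a0 + np.arange(an), np.arange(an)]
    pev = system.sigma2_e * diag
    if kin_diag is None:
        Fv = F.reindex(system.ped_ids).fillna(0.0).to_numpy(dtype=float)
        kin_diag = 1.0 + Fv
    rel = 1.0 - pev / (np.asarray(kin_diag, dtype=float) * vc.sigma2_a)
    return pd.Series(np.clip(rel, 0.0, 1.0), index=system.ped_ids, name="reliability")


def effective_records(phen: pd.DataFrame, ped: Pedigree, cg_col: str = "cg") -> np.ndarray:
    """Per-animal record information after contemporary-group absorption.

    For n_i records of an animal in a group of N records the contribution is
    n_i (1 - n_i / N); summed over groups.  Without a CG column the whole
    table is one group (the overall mean is absorbed).
    """
    m = np.zeros(ped.n)
    if len(phen) == 0:
        return m
    df = phen[["animal"]].copy()
    df["cg"] = phen[cg_col].astype(str) if cg_col in phen.columns else "_all_"
    sizes = df.groupby("cg")["cg"].transform("size")
    counts = df.groupby(["animal", "cg"]).size()
    cg_total = df.drop_duplicates("cg").set_index("cg").join(
        sizes.groupby(df["cg"]).first().rename("N")
    )["N"]
    for (animal, cg), n_i in counts.items():
        if animal in ped.index:
            N = float(cg_total.loc[cg])
            m[ped.index[animal]] += n_i * (1.0 - n_i / N)
    return m


def _effective_records_design(phen: pd.DataFrame, spec, ped: Pedigree) -> np.ndarray:
    """Record information after absorbing the full fixed-effect design.

    Generalizes CG absorption to every fitted fixed effect via leverages:
    m_i = n_i - s_i' (X'X)^-1 s_i with s_i the sum of animal i's design
    rows.  Reduces to n_i(1 - n_i/N) when X codes contemporary groups only.
    """
    from .mme import build_design

    _, X, _, _ = build_design(phen, spec, ped)
    data = phen[phen["trait"] == spec.trait] if "trait" in phen.columns else phen
    XtXi = np.linalg.inv(X.T @ X)
    S = np.zeros((ped.n, X.shape[1]))
    nrec = np.zeros(ped.n)
    for r, a in enumerate(data["animal"]):
        i = ped.index[a]
        S[i] += X[r]
        nrec[i] += 1
    m = nrec - np.einsum("ip,pq,iq->i", S, XtXi, S)
    return np.clip(m, 0.0, None)


def approximate_reliability(
    phen: pd.DataFrame,
    ped: Pedigree,
    vc: VarianceComponents,
    mode: str = "pblup",
    delta_diag: np.ndarray | None = None,
    genotyped_positions: np.ndarray | None = None,
    cg_col: str = "cg",
    tol: float = 1e-6,
    max_rounds: int = 1000,
    spec=None,
    delta: np.ndarray | None = None,
) -> pd.Series:
    """Two-step reliability approximation for the animal model.

    Step 1 scores each animal's own-record information: contemporary-group
    absorption (or full fixed-design leverage absorption when ``spec`` is
    given) plus, in single-step mode, a genomic term from the genotyped-block
    correction Delta = G_b^-1 - A22^-1 - its diagonal net of absorbing the
    other genotyped animals' equations through the Delta couplings, so the
    genomic precision is discounted by how well the connected reference
    animals are themselves estimated.  Step 2 iterates parent/offspring
    information exchange over the pedigree until the largest reliability
    change is below ``tol``; reliability is t / (t + lambda) on the
    accumulated information t.
    """
    lam = vc.sigma2_e / vc.sigma2_a
    n = ped.n
    if spec is not None:
        base0 = _effective_records_design(phen, spec, ped)
    else:
        base0 = effective_records(phen, ped, cg_col=cg_col)
    gpos = D2 = gdiag = None
    if mode == "ssblup":
        if delta is not None and delta_diag is None:
            delta_diag = np.diag(delta)
        if delta_diag is None or genotyped_positions is None:
            raise ReliabilityError("single-step approximation needs delta_diag and positions")
        gpos = np.asarray(genotyped_positions)
        gdiag = np.asarray(delta_diag, dtype=float)
        if delta is not None:
            D2 = np.asarray(delta, dtype=float) ** 2
            np.fill_diagonal(D2, 0.0)

    # Two-pass absorption of the animal block Q = diag(base) + lam*A^-1 over
    # the pedigree graph (mate couplings neglected).  Mendelian-sampling
    # variances use the unknown-parent conventions; inbreeding is ignored at
    # this approximation level.
    sire, dam = ped.sire, ped.dam
    d_ms = np.where((sire >= 0) & (dam >= 0), 0.5,
                    np.where((sire >= 0) | (dam >= 0), 0.75, 1.0))
    eps = 1e-12
    t_up_s = np.zeros(n)     # child i's absorbed contribution to its sire
    t_up_d = np.zeros(n)
    down = np.zeros(n)       # net prior + ancestor information
    Phi = np.full(n, lam)    # full effective diagonals from previous round
    rel = np.zeros(n)
    prev = None
    for _ in range(max_rounds):
        base = base0.copy()
        if mode == "ssblup":
            if D2 is not None:
                g = lam * gdiag - lam**2 * (D2 @ (1.0 / np.maximum(Phi[gpos], eps)))
            else:
                g = lam * gdiag * float(np.mean(rel[gpos]))  # crude diag-only fallback
            base[gpos] += np.clip(g, 0.0, None)
        S = base.copy()      # own + descendant information (lambda units)
        # upward: children first (larger positions), absorb into parents
        for c in range(n - 1, -1, -1):
            phi = S[c] + lam / d_ms[c]
            t = (lam / (4.0 * d_ms[c])) * S[c] / max(phi, eps)
            t_up_s[c] = t if sire[c] >= 0 else 0.0
            t_up_d[c] = t if dam[c] >= 0 else 0.0
            if sire[c] >= 0:
                S[sire[c]] += t
            if dam[c] >= 0:
                S[dam[c]] += t
        # downward: parents first; jointly absorb both parents (2x2 with the
        # sire-dam coupling lam/(4d) contributed by this animal's A^-1 row)
        for i in range(n):
            s, d = sire[i], dam[i]
            cpl = lam / (4.0 * d_ms[i])
            if s >= 0 and d >= 0:
                psi_s = max(S[s] - t_up_s[i] + down[s] + cpl, eps)
                psi_d = max(S[d] - t_up_d[i] + down[d] + cpl, eps)
                det = psi_s * psi_d - cpl * cpl
                term = (psi_s + psi_d - 2.0 * cpl) / max(det, eps)
            elif s >= 0 or d >= 0:
                p, t_excl = (s, t_up_s[i]) if s >= 0 else (d, t_up_d[i])
                psi = max(S[p] - t_excl + down[p] + cpl, eps)
                term = 1.0 / psi
            else:
                term = 0.0
            down[i] = lam / d_ms[i] - (lam / (2.0 * d_ms[i])) ** 2 * term
            Phi[i] = S[i] + down[i]
            rel[i] = 1.0 - lam / max(Phi[i], eps)
        rel = np.clip(rel, 0.0, 1.0)
        if prev is not None and np.max(np.abs(rel - prev)) < tol:
            break
        prev = rel.copy()
    else:
        raise ReliabilityError(f"information propagation did not converge in {max_rounds} rounds")
    return pd.Series(rel, index=ped.ids, name="reliability")


def accuracy_from_reliability(rel: pd.Series) -> pd.Series:
    """Element-wise square root; the published accuracy scale."""
    vals = np.asarray(rel, dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("reliabilities must lie in [0, 1]")
    return pd.Series(np.sqrt(vals), index=rel.index, name="accuracy")


@dataclass
class AccuracyComparison:
    """Per-animal accuracy deltas and genotyped x phenotyped strata summary."""

    per_animal: pd.DataFrame
    strata: pd.DataFrame
    gain_ratio: float | None  # mean delta genotyped-unphenotyped / genotyped-phenotyped


def compare_accuracies(
    res_p,
    res_ss,
    genotyped: set | None = None,
    phenotyped: set | None = None,
) -> AccuracyComparison:
    """Stratified single-step minus conventional accuracy comparison.

    Every animal gets delta = acc_ssblup - acc_pblup; strata over the
    genotyped x phenotyped cross report n, mean, min, max and SD of delta,
    plus the ratio of mean gains (genotyped-unphenotyped over
    genotyped-phenotyped), the headline contrast of the method.
    """
    if list(res_p.accuracy.index) != list(res_ss.accuracy.index):
        raise ValueError("evaluation results cover different animal sets")
    genotyped = genotyped if genotyped is not None else set(res_ss.genotyped)
    phenotyped = phenotyped if phenotyped is not None else set(res_ss.phenotyped)
    ids = list(res_p.accuracy.index)
    df = pd.DataFrame(
        {
            "animal": ids,
            "genotyped": [a in genotyped for a in ids],
            "phenotyped": [a in phenotyped for a in ids],
            "acc_pblup": res_p.accuracy.to_numpy(),
            "acc_ssblup": res_ss.accuracy.to_numpy(),
        }
    )
    df["delta"] = df["acc_ssblup"] - df["acc_pblup"]
    rows = []
    for (g, ph), grp in df.groupby(["genotyped", "phenotyped"]):
        rows.append(
            {
                "genotyped": g, "phenotyped": ph, "n": len(grp),
                "avg": grp["delta"].mean(), "min": grp["delta"].min(),
                "max": grp["delta"].max(), "sd": grp["delta"].std(ddof=1) if len(grp) > 1 else 0.0,
            }
        )
    strata = pd.DataFrame(rows)
    gain_ratio = None
    gu = strata[(strata.genotyped) & (~strata.phenotyped)]
    gp = strata[(strata.genotyped) & (strata.phenotyped)]
    if len(gu) and len(gp) and abs(float(gp["avg"].iloc[0])) > 1e-12:
        gain_ratio = float(gu["avg"].iloc[0] / gp["avg"].iloc[0])
    return AccuracyComparison(per_animal=df, strata=strata, gain_ratio=gain_ratio)
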