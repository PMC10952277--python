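"""Henderson mixed-model equations for the evaluation model and its solvers.

One linear model covers every trait: y = Xb + Za + (maternal and
permanent-environment terms where the trait calls for them) + e, with the
additive effect structured by A (pedigree BLUP) or H (single-step BLUP).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .pedigree import Pedigree, a_inverse, inbreeding_array, mendelian_variances, relationship_submatrix
from .varcomp import VarianceComponents


class ModelError(ValueError):
    """Mis-specified model or data/model mismatch."""


class SingularSystemError(RuntimeError):
    """Coefficient matrix singular after estimability constraints."""


#: biologically accepted phenotype ranges (trait units)
TABLE1_RANGES = {
    "bwt": (2.0, 10.0),
    "eww": (5.0, 50.0),
    "swt": (10.0, 150.0),
    "md": (5.0, 55.0),
    "fd": (0.1, 20.0),
}

RANDOM_EFFECT_KINDS = ("animal", "maternal", "pe_dam", "pe_animal")


@dataclass
class ModelSpec:
    """Per-trait effect layout.

    ``fixed_factors``/``covariates`` name columns of the phenotype table;
    ``random_effects`` is a subset of animal / maternal / pe_dam /
    pe_animal.  The direct animal effect is always present.
    """

    trait: str
    fixed_factors: list[str] = field(default_factory=lambda: ["cg"])
    covariates: list[str] = field(default_factory=list)
    random_effects: list[str] = field(default_factory=lambda: ["animal"])
    transform: str | None = None
    repeated: bool = False
    fit_intercept: bool = True

    def __post_init__(self) -> None:
        if "animal" not in self.random_effects:
            raise ModelError("the direct animal effect must always be fitted")
        bad = set(self.random_effects) - set(RANDOM_EFFECT_KINDS)
        if bad:
            raise ModelError(f"unknown random effects: {sorted(bad)}")


#: default effect layouts per trait (production CG = flock-season-sex;
#: CMT uses month-year and farm-year contemporary groups)
TRAIT_SPECS = {
    "bwt": ModelSpec("bwt", ["lsb", "dam_age", "dam_breed", "et", "cg"], [],
                     ["animal", "maternal", "pe_dam"]),
    "eww": ModelSpec("eww", ["lsb", "dam_age", "dam_breed", "foster", "cg"], [],
                     ["animal", "maternal", "pe_dam"]),
    "swt": ModelSpec("swt", ["lsb", "dam_age", "dam_breed", "cg"], ["age_at_scan"],
                     ["animal"]),
    "md": ModelSpec("md", ["lsb", "dam_age", "dam_breed", "cg"], ["age_at_scan"],
                    ["animal"]),
    "fd": ModelSpec("fd", ["lsb", "dam_age", "dam_breed", "cg"], ["age_at_scan"],
                    ["animal"]),
    "footrot": ModelSpec("footrot", ["dam_age", "scorer", "vax", "flock"], [],
                         ["animal"], transform="ln_sum1", repeated=True),
    "cmt": ModelSpec("cmt", ["lambing", "lsb", "scorer", "cg2"], [],
                     ["animal", "pe_animal"], transform="ln_sum1", repeated=True),
}


def health_score_transform(site_scores) -> float:
    """ln(1 + sum of 0-4 site scores) - the analysed scale of footrot/CMT."""
    total = 0
    for s in site_scores:
        s = int(s)
        if not 0 <= s <= 4:
            raise ValueError(f"site score {s} outside the 0-4 scale")
        total += s
    return math.log1p(total)


def apply_data_edits(
    phen: pd.DataFrame,
    ranges: dict | None = None,
    cg_min: int = 5,
    parameter_estimation: bool = False,
    year_window: tuple[int, int] = (2011, 2021),
    cg_col: str = "cg",
) -> tuple[pd.DataFrame, dict]:
    """Phenotype edits: biological ranges, and (for parameter estimation)
    foster/embryo-transfer/large-litter exclusions, a birth-year window, and
    contemporary groups of at least ``cg_min`` records (pruned last).
    """
    if ranges is None:
        ranges = TABLE1_RANGES
    report: dict[str, int] = {}
    out = phen.copy()
    if len(out) == 0:
        return out, report

    if "trait" in out.columns and "value" in out.columns:
        bad = pd.Series(False, index=out.index)
        for trait, (lo, hi) in ranges.items():
            m = out["trait"] == trait
            bad |= m & ((out["value"] < lo) | (out["value"] > hi))
        report["out_of_range"] = int(bad.sum())
        out = out[~bad]

    if parameter_estimation:
        for col, label in (("foster", "fostered"), ("et", "embryo_transfer")):
            if col in out.columns:
                m = out[col].astype(float) > 0
                report[label] = int(m.sum())
                out = out[~m]
        if "lsb" in out.columns:
            m = pd.to_numeric(out["lsb"], errors="coerce") > 4
            report["litter_over_4"] = int(m.sum())
            out = out[~m]
        if "birth_year" in out.columns and year_window is not None:
            lo, hi = year_window
            m = (out["birth_year"] < lo) | (out["birth_year"] > hi)
            report["outside_year_window"] = int(m.sum())
            out = out[~m]
        if cg_col in out.columns:
            removed = 0
            while True:
                sizes = out.groupby(cg_col)[cg_col].transform("size")
                m = sizes < cg_min
                if not m.any():
                    break
                removed += int(m.sum())
                out = out[~m]
            report["small_cg"] = removed
    return out.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

def _drop_collinear(X: np.ndarray, labels: list, rtol: float = 1e-8):
    """Remove linearly dependent fixed-effect columns (pivoted QR).

    Drop-first dummy coding removes the obvious intercept confounding, but
    factors can still be jointly collinear (e.g. a covariate constant within
    contemporary groups); the MME needs a full-rank X.
    """
    from scipy.linalg import qr

    if X.shape[1] <= 1:
        return X, labels
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > rtol * diag[0]))
    if rank == X.shape[1]:
        return X, labels
    keep = np.sort(piv[:rank])
    dropped = [labels[j] for j in np.sort(piv[rank:])]
    warnings.warn(
        f"{len(dropped)} confounded fixed-effect columns dropped: {dropped[:5]}"
    )
    return X[:, keep], [labels[j] for j in keep]


def build_design(phen: pd.DataFrame, spec: ModelSpec, ped: Pedigree):
    """Assemble (y, X, random blocks) for one trait.

    Returns ``y`` (n,), dense full-rank ``X`` (intercept + drop-first dummy
    coding per fixed factor + centred covariates), a list of random blocks
    ``(name, Z, K_inverse_or_None, logdet_K)`` and the fixed-effect column
    labels.  Animal and maternal effects span the full pedigree;
    permanent-environment levels are the subjects present in the data.
    """
    data = phen[phen["trait"] == spec.trait] if "trait" in phen.columns else phen
    if len(data) == 0:
        raise ModelError(f"no records for trait {spec.trait!r}")
    y = data["value"].to_numpy(dtype=float)
    n = len(data)

    missing_animals = [a for a in data["animal"] if a not in ped.index]
    if missing_animals:
        raise ModelError(
            f"phenotyped animal {missing_animals[0]!r} is not in the pedigree"
        )

    if spec.fit_intercept:
        cols = [np.ones(n)]
        labels = [("intercept", "")]
    else:
        cols = []
        labels = []
    for fac in spec.fixed_factors:
        if fac not in data.columns:
            raise ModelError(f"fixed factor column {fac!r} missing from phenotypes")
        vals = data[fac].astype(str).to_numpy()
        levels = sorted(pd.unique(vals))
        for lev in levels[1:]:  # first level constrained to zero
            cols.append((vals == lev).astype(float))
            labels.append((fac, lev))
    for cov in spec.covariates:
        if cov not in data.columns:
            raise ModelError(f"covariate column {cov!r} missing from phenotypes")
        v = data[cov].to_numpy(dtype=float)
        cols.append(v - v.mean())
        labels.append((cov, "covariate"))
    if not cols:
        X = np.zeros((n, 0))
    else:
        X = np.column_stack(cols)
        X, labels = _drop_collinear(X, labels)

    apos = np.array([ped.index[a] for a in data["animal"]])
    rows = np.arange(n)
    rand = []
    Ainv = None
    logdetA = None
    for name in spec.random_effects:
        if name in ("animal", "maternal"):
            if Ainv is None:
                F = inbreeding_array(ped)
                Ainv = a_inverse(ped, F)
                logdetA = float(np.sum(np.log(mendelian_variances(ped, F))))
            if name == "animal":
                Z = sp.coo_matrix(
                    (np.ones(n), (rows, apos)), shape=(n, ped.n)
                ).tocsr()
            else:
                dams = ped.dam[apos]
                ok = dams >= 0
                Z = sp.coo_matrix(
                    (np.ones(int(ok.sum())), (rows[ok], dams[ok])), shape=(n, ped.n)
                ).tocsr()
            rand.append((name, Z, Ainv, logdetA))
        else:
            if name == "pe_dam":
                subj_pos = ped.dam[apos]
                keep = subj_pos >= 0
            else:
                subj_pos = apos
                keep = np.ones(n, dtype=bool)
            levels = np.unique(subj_pos[keep])
            lookup = {int(s): k for k, s in enumerate(levels)}
            r = rows[keep]
            c = np.array([lookup[int(s)] for s in subj_pos[keep]])
            Z = sp.coo_matrix(
                (np.ones(len(r)), (r, c)), shape=(n, len(levels))
            ).tocsr()
            Z.pe_level_ids = [ped.ids[int(s)] for s in levels]  # type: ignore[attr-defined]
            rand.append((name, Z, None, 0.0))
    return y, X, rand, labels


@dataclass
class LinearSystem:
    """Assembled mixed-model equations in lambda form: (W'W + K) s = W'y."""

    coeff: sp.csc_matrix
    rhs: np.ndarray
    effect_index: dict
    blocks: dict           # effect name -> (start, size)
    lambdas: dict          # random effect -> sigma2_e / sigma2_effect
    W: sp.csr_matrix
    y: np.ndarray
    sigma2_e: float
    ped_ids: list[str]
    fixed_labels: list

    @property
    def n_equations(self) -> int:
        return self.coeff.shape[0]


def _lambda_for(name: str, vc: VarianceComponents) -> float:
    if name == "animal":
        s2 = vc.sigma2_a
    elif name == "maternal":
        s2 = vc.sigma2_m
    else:
        s2 = vc.sigma2_pe
    if not s2 or s2 <= 0:
        raise ModelError(f"variance component for {name!r} must be positive")
    return vc.sigma2_e / s2


def build_mme(
    phen: pd.DataFrame,
    spec: ModelSpec,
    vc: VarianceComponents,
    ped: Pedigree,
    kinship_inverse: sp.spmatrix | None = None,
    mode: str = "pblup",
) -> LinearSystem:
    """Assemble Henderson's MME for one trait.

    ``kinship_inverse`` is A^-1 (pedigree BLUP) or H^-1 (single-step) over
    the full pedigree; omitted, A^-1 is computed.  The same inverse
    structures the maternal effect; permanent environment has identity
    covariance; all contemporary groups are fixed.
    """
    if mode not in ("pblup", "ssblup"):
        raise ModelError(f"unknown mode {mode!r}")
    y, X, rand, fixed_labels = build_design(phen, spec, ped)
    if kinship_inverse is not None:
        if kinship_inverse.shape != (ped.n, ped.n):
            raise ModelError("kinship inverse dimension does not match pedigree")
        rand = [
            (name, Z, kinship_inverse if name in ("animal", "maternal") else K, ld)
            for name, Z, K, ld in rand
        ]
    n, p = X.shape
    W = sp.hstack([sp.csr_matrix(X)] + [Z for _, Z, _, _ in rand], format="csr")
    lambdas = {name: _lambda_for(name, vc) for name, _, _, _ in rand}
    blocks = {"fixed": (0, p)}
    prior = [sp.csr_matrix((p, p))]
    start = p
    effect_index: dict = {}
    for name, Z, K, _ in rand:
        q = Z.shape[1]
        blocks[name] = (start, q)
        B = K if K is not None else sp.identity(q, format="csr")
        prior.append(B * lambdas[name])
        if name in ("animal", "maternal"):
            for k, a in enumerate(ped.ids):
                effect_index[(name, a)] = start + k
        else:
            ids = getattr(Z, "pe_level_ids", [str(k) for k in range(q)])
            for k, a in enumerate(ids):
                effect_index[(name, a)] = start + k
        start += q
    for k, lab in enumerate(fixed_labels):
        effect_index[lab] = k
    coeff = (W.T @ W + sp.block_diag(prior)).tocsc()
    rhs = W.T @ y
    return LinearSystem(
        coeff=coeff, rhs=rhs, effect_index=effect_index, blocks=blocks,
        lambdas=lambdas, W=W, y=y, sigma2_e=vc.sigma2_e, ped_ids=list(ped.ids),
        fixed_labels=fixed_labels,
    )



def solve_mme(
    system: LinearSystem, method: str = "direct", tol: float = 1e-10
) -> np.ndarray:
    """Solve the assembled MME.

    Direct: sparse LU on the (already full-rank, drop-first constrained)
    coefficient matrix.  Iterative: Jacobi-preconditioned conjugate
    gradients to relative residual < tol.
    """
    A = system.coeff
    b = system.rhs
    if method == "direct":
        try:
            lu = spla.splu(A, permc_spec="MMD_AT_PLUS_A")
            sol = lu.solve(b)
        except RuntimeError as e:
            raise SingularSystemError(
                "coefficient matrix is singular after drop-first constraints; "
                f"check fixed factors {sorted({l[0] for l in system.fixed_labels})} "
                f"for confounding ({e})"
            ) from e
        if not np.all(np.isfinite(sol)):
            raise SingularSystemError("solver produced non-finite solutions")
        return sol
    if method == "iterative":
        d = A.diagonal()
        if np.any(d <= 0):
            raise SingularSystemError("non-positive diagonal; system not SPD")
        Mpre = spla.LinearOperator(A.shape, matvec=lambda v: v / d)
        sol, info = spla.cg(A, b, rtol=tol, maxiter=20000, M=Mpre)
        if info != 0:
            raise SingularSystemError(f"conjugate gradients did not converge (info={info})")
        return sol
    raise ValueError(f"unknown solve method {method!r}")


@dataclass
class EvaluationResult:
    """Per-animal EBVs with reliabilities and accuracies for one trait."""

    method: str
    trait: str
    ebv: pd.Series
    fixed_solutions: dict
    reliability: pd.Series
    accuracy: pd.Series
    genotyped: set = field(default_factory=set)
    phenotyped: set = field(default_factory=set)


def run_evaluation(
    ped: Pedigree,
    panel,
    phen: pd.DataFrame,
    spec: ModelSpec,
    vc: VarianceComponents,
    mode: str = "pblup",
    blend_weight: float = 0.95,
    tune_grm: bool = True,
    apply_range_edits: bool = True,
    reliability_method: str = "auto",
    max_exact_equations: int = 8000,
    solver: str = "direct",
) -> EvaluationResult:
    """End-to-end breeding-value run for one trait.

    Orchestrates edits, kinship construction (A^-1 or H^-1), MME assembly,
    solving, and reliability/accuracy, returning EBVs for every pedigree
    animal including unphenotyped ones.
    """
    from .grm import (
        allele_frequencies, blend_with_pedigree, build_h_inverse,
        genomic_relationship_vanraden1, h_inverse_terms, tune_to_pedigree,
    )
    from .reliability import accuracy_from_reliability, approximate_reliability, exact_reliability

    if mode == "ssblup" and panel is None:
        raise ModelError("single-step evaluation needs a genotype panel; use mode='pblup'")
    data = phen[phen["trait"] == spec.trait] if "trait" in phen.columns else phen
    if apply_range_edits:
        data, _ = apply_data_edits(data, parameter_estimation=False)

    F = inbreeding_array(ped)
    Ainv = a_inverse(ped, F)
    delta = None
    positions = None
    kin_diag = 1.0 + F
    if mode == "ssblup":
        missing = [a for a in panel.animal_ids if a not in ped.index]
        if missing:
            raise ModelError(f"genotyped animal {missing[0]!r} missing from pedigree")
        A22 = relationship_submatrix(ped, panel.animal_ids)
        G = genomic_relationship_vanraden1(panel, allele_frequencies(panel))
        if tune_grm:
            G = tune_to_pedigree(G, A22)
        Gb = blend_with_pedigree(G, A22, blend_weight)
        delta = h_inverse_terms(Gb, A22)
        positions = np.array([ped.index[a] for a in panel.animal_ids])
        kinship = build_h_inverse(Ainv, delta, positions)
        kin_diag = kin_diag.copy()
        kin_diag[positions] = np.diag(Gb.values)
    else:
        kinship = Ainv

    system = build_mme(data, spec, vc, ped, kinship_inverse=kinship, mode=mode)
    sol = solve_mme(system, method=solver)
    a0, an = system.blocks["animal"]
    ebv = pd.Series(sol[a0:a0 + an], index=ped.ids, name="ebv")
    fixed = {lab: float(sol[k]) for k, lab in enumerate(system.fixed_labels)}

    use_exact = reliability_method == "exact" or (
        reliability_method == "auto" and system.n_equations <= max_exact_equations
    )
    if use_exact:
        rel = exact_reliability(system, vc, pd.Series(F, index=ped.ids), kin_diag=kin_diag)
    else:
        rel = approximate_reliability(
            data, ped, vc, mode=mode, delta=delta,
            genotyped_positions=positions, spec=spec,
        )
    acc = accuracy_from_reliability(rel)
    return EvaluationResult(
        method=mode, trait=spec.trait, ebv=ebv, fixed_solutions=fixed,
        reliability=rel, accuracy=acc,
        genotyped=set(panel.animal_ids) if panel is not None else set(),
        phenotyped=set(data["animal"]),
    )
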