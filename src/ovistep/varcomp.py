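"""REML variance components for the animal model, and genetic correlations.

Univariate estimation uses EM-REML (guaranteed likelihood ascent) with
average-information (AI) acceleration once the EM trajectory is stable;
bivariate estimation uses EM on a two-trait model with a 2x2 direct-genetic
and a 2x2 residual covariance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .pedigree import Pedigree


class RemlError(RuntimeError):
    """REML failed to produce a usable estimate."""


@dataclass
class VarianceComponents:
    """Variance components of the single-trait mixed model.

    ``sigma2_a`` direct genetic, ``sigma2_m`` maternal genetic, ``sigma2_pe``
    permanent environment, ``sigma2_e`` residual; all in squared trait units.
    Phenotypic variance and heritability are derived, so the identities
    sigma2_p = sum(components) and h2 = sigma2_a / sigma2_p hold by
    construction.
    """

    sigma2_a: float
    sigma2_e: float
    sigma2_m: float | None = None
    sigma2_pe: float | None = None
    se: dict = field(default_factory=dict)
    boundary: bool = False

    def __post_init__(self) -> None:
        for name in ("sigma2_a", "sigma2_e", "sigma2_m", "sigma2_pe"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def sigma2_p(self) -> float:
        return (
            self.sigma2_a
            + self.sigma2_e
            + (self.sigma2_m or 0.0)
            + (self.sigma2_pe or 0.0)
        )

    @property
    def h2(self) -> float:
        p = self.sigma2_p
        if p <= 0:
            raise ValueError("phenotypic variance is zero; heritability undefined")
        return self.sigma2_a / p


def heritability(vc: VarianceComponents) -> float:
    """h2 = sigma2_a / sigma2_p."""
    return vc.h2


@dataclass
class CorrelationEstimate:
    """Bivariate genetic/phenotypic correlation between two traits."""

    traits: tuple[str, str]
    genetic_correlation: float | None
    phenotypic_correlation: float | None
    se: dict = field(default_factory=dict)
    estimable: bool = True
    reason: str | None = None
    components: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# univariate EM/AI REML
# ---------------------------------------------------------------------------

def _design(phen: pd.DataFrame, spec, ped: Pedigree):
    """Assemble y, X and random-effect incidence blocks for one trait."""
    from .mme import build_design  # local import to avoid cycle

    return build_design(phen, spec, ped)


#: SuperLU options for SPD systems: no equilibration so |det| = prod |U_ii|
_SPLU_OPTS = {"Equil": False, "SymmetricMode": True, "DiagPivotThresh": 0.0}


def _factor(M):
    return spla.splu(M, permc_spec="MMD_AT_PLUS_A", options=dict(_SPLU_OPTS))


def _logdet_splu(lu) -> float:
    dU = np.abs(lu.U.diagonal())
    dL = np.abs(lu.L.diagonal())
    return float(np.sum(np.log(dU)) + np.sum(np.log(dL)))


def reml_univariate(
    phen: pd.DataFrame,
    spec,
    ped: Pedigree,
    init: VarianceComponents | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    use_ai: bool = True,
    em_warmup: int = 5,
    verbose: bool = False,
) -> VarianceComponents:
    """EM-REML with AI acceleration for the Model-(1) animal model.

    The model may include a direct genetic effect (always), a maternal
    genetic effect, and a permanent-environment effect (dam- or
    animal-level) as dictated by ``spec.random_effects``.  EM steps are used
    for the first ``em_warmup`` iterations and whenever an AI step would
    decrease the restricted likelihood or leave the parameter space;
    convergence is on the maximum relative parameter change.
    """
    y, X, rand, _labels = _design(phen, spec, ped)
    n = y.shape[0]
    p = X.shape[1]
    names = [r[0] for r in rand]
    Zs = [r[1] for r in rand]
    Kinvs = [r[2] for r in rand]  # None means identity
    logdetKs = [r[3] for r in rand]
    qs = [Z.shape[1] for Z in Zs]

    W = sp.hstack([sp.csr_matrix(X)] + Zs, format="csr")
    WtW = (W.T @ W).tocsc()
    Wty = W.T @ y
    yty = float(y @ y)
    nq = W.shape[1]
    starts = [p + int(sum(qs[:k])) for k in range(len(qs))]

    vp0 = float(np.var(y)) if np.var(y) > 0 else 1.0
    if init is None:
        k = len(rand) + 1
        theta = {name: vp0 / (k + 1) for name in names}
        theta["e"] = vp0 - sum(theta.values()) + vp0 / (k + 1)
        theta["e"] = max(theta["e"], vp0 / (k + 1))
    else:
        theta = {"e": init.sigma2_e}
        defaults = {"animal": init.sigma2_a, "maternal": init.sigma2_m,
                    "pe_dam": init.sigma2_pe, "pe_animal": init.sigma2_pe}
        for name in names:
            v = defaults.get(name)
            theta[name] = v if v else vp0 / (len(rand) + 2)
    floor = 1e-8 * vp0

    rand_idx = np.arange(p, nq)
    eye_rand = np.zeros((nq, len(rand_idx)))
    eye_rand[rand_idx, np.arange(len(rand_idx))] = 1.0

    def assemble(th):
        D_blocks = [sp.csr_matrix((p, p))]
        for name, K, q in zip(names, Kinvs, qs):
            B = K if K is not None else sp.identity(q, format="csr")
            D_blocks.append(B / th[name])
        return (WtW / th["e"] + sp.block_diag(D_blocks, format="csc")).tocsc()

    def loglik(th, lu, sol):
        ypy = (yty - float(sol @ Wty)) / th["e"]
        ld = _logdet_splu(lu)
        val = ld + n * np.log(th["e"]) + ypy
        for name, ldK, q in zip(names, logdetKs, qs):
            val += q * np.log(th[name]) + ldK
        return -0.5 * val

    ll = -np.inf
    traj = []
    ai_cov = None
    for it in range(1, max_iter + 1):
        M = assemble(theta)
        lu = _factor(M)
        sol = lu.solve(Wty / theta["e"])
        ll = loglik(theta, lu, sol)
        # selected columns of C = M^-1 over random-effect equations
        Ccols = lu.solve(eye_rand)
        traces = []
        uKu = []
        for k, (name, K, q) in enumerate(zip(names, Kinvs, qs)):
            s0 = starts[k]
            Cb = Ccols[s0:s0 + q, s0 - p:s0 - p + q]
            u = sol[s0:s0 + q]
            if K is None:
                traces.append(float(np.trace(Cb)))
                uKu.append(float(u @ u))
            else:
                Kc = K.tocoo()
                traces.append(float(np.sum(Kc.data * Cb[Kc.col, Kc.row])))
                uKu.append(float(u @ (K @ u)))
        ehat = y - W @ sol
        ete = float(ehat @ ehat)

        new = dict(theta)
        used_ai = False
        if use_ai and it > em_warmup:
            # gradient
            g = np.empty(len(names) + 1)
            for k, name in enumerate(names):
                s2 = theta[name]
                g[k] = -0.5 * (qs[k] / s2 - traces[k] / s2**2 - uKu[k] / s2**2)
            tr_sum = sum(traces[k] / theta[names[k]] for k in range(len(names)))
            se2 = theta["e"]
            g[-1] = -0.5 * ((n - p - sum(qs) + tr_sum) / se2 - ete / se2**2)
            # average information
            fs = [Zs[k] @ sol[starts[k]:starts[k] + qs[k]] / theta[names[k]]
                  for k in range(len(names))]
            fs.append(ehat / se2)
            Pf = []
            for f in fs:
                sf = lu.solve((W.T @ f) / se2)
                Pf.append((f - W @ sf) / se2)
            m = len(fs)
            AI = np.empty((m, m))
            for a in range(m):
                for b in range(a, m):
                    AI[a, b] = AI[b, a] = 0.5 * float(fs[a] @ Pf[b])
            try:
                step = np.linalg.solve(AI, g)
                # damp the Newton step so no component leaves the parameter
                # space (standard practice when an estimate heads for zero)
                labels = names + ["e"]
                alpha = 1.0
                for k, lab in enumerate(labels):
                    if step[k] < 0 and theta[lab] + step[k] <= floor:
                        alpha = min(alpha, 0.9 * (theta[lab] - floor) / -step[k])
                step = step * alpha
                cand = dict(theta)
                for k, name in enumerate(names):
                    cand[name] = theta[name] + step[k]
                cand["e"] = theta["e"] + step[-1]
                if all(v > floor for v in cand.values()):
                    Mc = assemble(cand)
                    luc = _factor(Mc)
                    solc = luc.solve(Wty / cand["e"])
                    llc = loglik(cand, luc, solc)
                    if llc >= ll - 1e-10:
                        new = cand
                        used_ai = True
                        ai_cov = np.linalg.inv(AI)
            except np.linalg.LinAlgError:
                pass
        if not used_ai:
            # EM updates (guaranteed ascent)
            for k, name in enumerate(names):
                new[name] = max((uKu[k] + traces[k]) / qs[k], floor)
            tr_sum = sum(traces[k] / theta[names[k]] for k in range(len(names)))
            new["e"] = max((ete + theta["e"] * (p + sum(qs) - tr_sum)) / n, floor)

        # relative change, damped for components collapsing to the boundary
        rel = max(
            abs(new[k] - theta[k]) / max(theta[k], 1e-3 * vp0) for k in theta
        )
        traj.append({"iter": it, "loglik": ll, "ai": used_ai, **theta})
        if verbose:
            print(f"iter {it:3d} logL {ll:.6f} {'AI' if used_ai else 'EM'} "
                  + " ".join(f"{k}={v:.4g}" for k, v in theta.items()))
        theta = new
        if rel < tol and it > 1:
            break
    else:
        raise RemlError(
            f"REML did not converge in {max_iter} iterations; trajectory: {traj[-5:]}"
        )

    se: dict[str, float] = {}
    if ai_cov is not None:
        labels = names + ["e"]
        for k, lab in enumerate(labels):
            se[lab] = float(np.sqrt(max(ai_cov[k, k], 0.0)))
        # delta-method SE for h2
        th_vec = np.array([theta[k] for k in labels])
        vp = th_vec.sum()
        grad = np.full(len(labels), -theta["animal"] / vp**2)
        grad[labels.index("animal")] += 1.0 / vp
        se["h2"] = float(np.sqrt(max(grad @ ai_cov @ grad, 0.0)))

    at_floor = any(theta[k] <= floor * 1.01 for k in names)
    vc = VarianceComponents(
        sigma2_a=theta.get("animal", 0.0),
        sigma2_e=theta["e"],
        sigma2_m=theta.get("maternal"),
        sigma2_pe=theta.get("pe_dam", theta.get("pe_animal")),
        se=se,
        boundary=at_floor,
    )
    vc.trajectory = traj  # type: ignore[attr-defined]
    return vc


# ---------------------------------------------------------------------------
# bivariate EM REML
# ---------------------------------------------------------------------------

def reml_bivariate(
    phen: pd.DataFrame,
    trait1: str,
    trait2: str,
    ped: Pedigree,
    specs: dict | None = None,
    init: dict | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
    min_overlap: int = 30,
) -> CorrelationEstimate:
    """Two-trait EM-REML: 2x2 direct-genetic and residual covariances.

    Records are matched by animal (one record per animal per trait; animals
    must have both traits).  Other random effects are not crossed between
    traits.  If a genetic variance collapses to its floor the correlation is
    flagged non-estimable, mirroring how negative sums of squares surface in
    sequential REML software.
    """
    from .mme import ModelSpec, build_design

    if specs is None:
        specs = {
            trait1: ModelSpec(trait=trait1, fixed_factors=["cg"], covariates=[],
                              random_effects=["animal"]),
            trait2: ModelSpec(trait=trait2, fixed_factors=["cg"], covariates=[],
                              random_effects=["animal"]),
        }
    d1 = phen[phen["trait"] == trait1]
    d2 = phen[phen["trait"] == trait2]
    common = sorted(set(d1["animal"]) & set(d2["animal"]))
    if len(common) < min_overlap:
        raise RemlError(
            f"only {len(common)} animals have both traits (minimum {min_overlap})"
        )
    d1 = d1[d1["animal"].isin(common)].drop_duplicates("animal").sort_values("animal")
    d2 = d2[d2["animal"].isin(common)].drop_duplicates("animal").sort_values("animal")

    y1, X1, r1, _l1 = build_design(d1, specs[trait1], ped)
    y2, X2, r2, _l2 = build_design(d2, specs[trait2], ped)
    (_, Z1, Kinv, logdetK) = r1[0]
    (_, Z2, _, _) = r2[0]
    n = y1.shape[0]
    q = Z1.shape[1]
    p1, p2 = X1.shape[1], X2.shape[1]

    W1 = sp.hstack([sp.csr_matrix(X1), Z1], format="csr")
    W2 = sp.hstack([sp.csr_matrix(X2), Z2], format="csr")
    m1, m2 = W1.shape[1], W2.shape[1]
    W11 = (W1.T @ W1).tocsr()
    W22 = (W2.T @ W2).tocsr()
    W12 = (W1.T @ W2).tocsr()

    vp1, vp2 = float(np.var(y1)), float(np.var(y2))
    if init is None:
        Sa = np.array([[vp1 / 3, 0.0], [0.0, vp2 / 3]])
        Se = np.array([[2 * vp1 / 3, 0.0], [0.0, 2 * vp2 / 3]])
    else:
        Sa = np.array(init["Sa"], dtype=float)
        Se = np.array(init["Se"], dtype=float)
    floor1, floor2 = 1e-8 * vp1, 1e-8 * vp2

    Kd = Kinv if Kinv is not None else sp.identity(q, format="csr")
    Kcoo = Kd.tocoo()

    def assemble(Sa, Se):
        Ri = np.linalg.inv(Se)
        M = sp.bmat(
            [[W11 * Ri[0, 0], W12 * Ri[0, 1]],
             [W12.T * Ri[0, 1], W22 * Ri[1, 1]]], format="csc"
        )
        Gi = np.linalg.inv(Sa)
        # Gi kron A^-1 scattered onto the genetic-effect blocks
        A11 = sp.block_diag([sp.csr_matrix((p1, p1)), Kd * Gi[0, 0]])
        A22 = sp.block_diag([sp.csr_matrix((p2, p2)), Kd * Gi[1, 1]])
        A12 = sp.bmat(
            [[sp.csr_matrix((p1, p2)), sp.csr_matrix((p1, q))],
             [sp.csr_matrix((q, p2)), Kd * Gi[0, 1]]]
        )
        add = sp.bmat([[A11, A12], [A12.T, A22]], format="csc")
        rhs = np.concatenate([
            W1.T @ (Ri[0, 0] * y1 + Ri[0, 1] * y2),
            W2.T @ (Ri[0, 1] * y1 + Ri[1, 1] * y2),
        ])
        return (M + add), rhs, Ri

    prev = np.array([Sa[0, 0], Sa[0, 1], Sa[1, 1], Se[0, 0], Se[0, 1], Se[1, 1]])
    estimable = True
    reason = None
    for it in range(max_iter):
        M, rhs, Ri = assemble(Sa, Se)
        C = np.linalg.inv(M.toarray())
        sol = C @ rhs
        t1 = sol[:m1]
        t2 = sol[m1:]
        u1 = t1[p1:]
        u2 = t2[p2:]
        e1 = y1 - W1 @ t1
        e2 = y2 - W2 @ t2
        # genetic covariance update
        sl1 = slice(p1, m1)
        sl2 = slice(m1 + p2, m1 + m2)
        C11 = C[sl1, sl1]
        C22 = C[sl2, sl2]
        C12 = C[sl1, sl2]

        def trK(Cb):
            return float(np.sum(Kcoo.data * Cb[Kcoo.col, Kcoo.row]))

        Sa_new = np.empty((2, 2))
        Sa_new[0, 0] = (float(u1 @ (Kd @ u1)) + trK(C11)) / q
        Sa_new[1, 1] = (float(u2 @ (Kd @ u2)) + trK(C22)) / q
        Sa_new[0, 1] = Sa_new[1, 0] = (float(u1 @ (Kd @ u2)) + trK(C12)) / q
        # residual covariance update: E[e_i'e_j | y] = e_i'e_j + tr(W_i C_ij W_j')
        Cb11 = C[:m1, :m1]
        Cb22 = C[m1:, m1:]
        Cb12 = C[:m1, m1:]
        tr11 = float(np.sum(Cb11 * W11.toarray()))
        tr22 = float(np.sum(Cb22 * W22.toarray()))
        tr12 = float(np.sum(Cb12 * W12.toarray()))
        Se_new = np.empty((2, 2))
        Se_new[0, 0] = (float(e1 @ e1) + tr11) / n
        Se_new[1, 1] = (float(e2 @ e2) + tr22) / n
        Se_new[0, 1] = Se_new[1, 0] = (float(e1 @ e2) + tr12) / n

        Sa_new[0, 0] = max(Sa_new[0, 0], floor1)
        Sa_new[1, 1] = max(Sa_new[1, 1], floor2)
        cur = np.array([Sa_new[0, 0], Sa_new[0, 1], Sa_new[1, 1],
                        Se_new[0, 0], Se_new[0, 1], Se_new[1, 1]])
        rel = np.max(np.abs(cur - prev) / np.maximum(np.abs(prev), 1e-8))
        Sa, Se = Sa_new, Se_new
        prev = cur
        if rel < tol and it > 2:
            break

    if Sa[0, 0] <= floor1 * 1.01 or Sa[1, 1] <= floor2 * 1.01:
        estimable = False
        reason = "negative sum of squares"
    rg = rp = None
    if estimable:
        denom = np.sqrt(Sa[0, 0] * Sa[1, 1])
        rg = float(np.clip(Sa[0, 1] / denom, -1.0, 1.0))
        Sp = Sa + Se
        rp = float(np.clip(Sp[0, 1] / np.sqrt(Sp[0, 0] * Sp[1, 1]), -1.0, 1.0))
    return CorrelationEstimate(
        traits=(trait1, trait2),
        genetic_correlation=rg,
        phenotypic_correlation=rp,
        estimable=estimable,
        reason=reason,
        components={"Sa": Sa, "Se": Se, "n": n},
    )
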