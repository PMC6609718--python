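"""Direct + social genetic effects animal model, fitted by REML.

For animals housed in pens of size n, the phenotype of animal i is modelled
as

    Y = X b + Z_D a_D + Z_S a_S + W l + V g + e

where a_D are direct breeding values (an animal's genetic effect on its own
phenotype), a_S are social breeding values (its genetic effect on each
pen-mate's phenotype), l and g are random litter and pen (group) effects and
e is the residual.  Row i of Z_S carries 1 at the columns of i's pen-mates
and 0 elsewhere (the animal's own social effect never enters its own
phenotype).  (a_D, a_S) have covariance G0 (x) A with G0 the 2x2 direct/
social genetic (co)variance matrix and A the pedigree numerator relationship
matrix, which may include non-phenotyped ancestors.

Variance components are estimated by average-information REML with damped,
feasibility-projected updates (the 2x2 genetic block is projected to the PSD
cone by eigenvalue clipping; plain variances are floored), so the restricted
log-likelihood never decreases across iterations.  Standard errors come from
the inverse average-information matrix at the optimum.

From a converged fit the module derives the summaries breeders report —
classical heritability h^2 = sigma^2_A / sigma^2_P, total heritable variance
sigma^2_TBV = var(a_D + (n-1) a_S), total heritability T^2, and the
direct-social genetic correlation — plus the per-animal pseudo-phenotypes
(fitted genetic effect + residual) that downstream genome scans use as
responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve
from scipy.linalg.lapack import dpotrf, dpotri

from .relatedness import Pedigree, RelationshipMatrix, numerator_relationship

__all__ = [
    "GroupedPhenotypes",
    "SocialModelSpec",
    "VarianceComponents",
    "ModelFit",
    "DesignBundle",
    "assemble_design",
    "reml_fit",
    "fit_social_model",
    "derive_summaries",
    "pseudo_phenotypes",
    "heritability",
    "genetic_correlation",
    "total_heritable_variance",
    "total_heritability",
]

COMPONENT_NAMES = ("var_Ad", "cov_DS", "var_As", "var_litter", "var_group", "var_e")


class ModelError(ValueError):
    pass


@dataclass
class GroupedPhenotypes:
    """Per-animal trait values with sex, year-month, litter and pen labels.

    ``data`` columns: animal_id, <trait>, sex, yearmonth, litter, pen.
    One row per animal; every phenotyped animal sits in exactly one pen.
    ``truth`` optionally stores the simulator's generating components.
    """

    data: pd.DataFrame
    trait: str = "y"
    truth: dict | None = None

    def __post_init__(self) -> None:
        need = {"animal_id", self.trait, "sex", "yearmonth", "litter", "pen"}
        missing = need - set(self.data.columns)
        if missing:
            raise ModelError(f"phenotype table missing columns {sorted(missing)}")
        if self.data["animal_id"].duplicated().any():
            raise ModelError("one phenotype row per animal required")
        if self.data["pen"].isna().any():
            bad = self.data.loc[self.data["pen"].isna(), "animal_id"].tolist()
            raise ModelError(f"animals without a pen assignment: {bad[:5]}")

    @property
    def animal_ids(self) -> list:
        return list(self.data["animal_id"])

    def pen_members(self) -> dict:
        return self.data.groupby("pen")["animal_id"].apply(list).to_dict()

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class SocialModelSpec:
    """What to fit: trait, fixed factors, variance-structure toggles."""

    trait: str = "y"
    fixed_factors: tuple = ("sex", "yearmonth")
    include_social: bool = True
    include_litter: bool = True
    include_group: bool = True
    pen_size: int | None = None  # checked against the data when given

    def component_names(self) -> list[str]:
        names = ["var_Ad"]
        if self.include_social:
            names += ["cov_DS", "var_As"]
        if self.include_litter:
            names.append("var_litter")
        if self.include_group:
            names.append("var_group")
        names.append("var_e")
        return names


@dataclass
class VarianceComponents:
    """Fitted variance components with standard errors."""

    var_Ad: float
    cov_DS: float
    var_As: float
    var_litter: float
    var_group: float
    var_e: float
    se: dict = field(default_factory=dict)
    converged: bool = True
    n_iter: int = 0

    def genetic_block(self) -> np.ndarray:
        return np.array([[self.var_Ad, self.cov_DS], [self.cov_DS, self.var_As]])

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in COMPONENT_NAMES}


@dataclass
class DesignBundle:
    """Design matrices and precomputed covariance structure for one trait."""

    y: np.ndarray
    X: np.ndarray
    record_ids: list
    pedigree_ids: list
    record_to_pedigree: np.ndarray  # pedigree row of each record's animal
    S: np.ndarray  # n x n pen-mate indicator among records (self excluded)
    W_labels: np.ndarray  # litter label per record
    V_labels: np.ndarray  # pen label per record
    fixed_names: list
    spec: SocialModelSpec
    singleton_records: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.y)

    def litter_matrix(self) -> np.ndarray:
        return _indicator(self.W_labels)[0]

    def group_matrix(self) -> np.ndarray:
        return _indicator(self.V_labels)[0]


def _indicator(labels) -> tuple[np.ndarray, list]:
    levels = list(pd.unique(labels))
    lut = {v: j for j, v in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), [lut[v] for v in labels]] = 1.0
    return Z, levels


def assemble_design(phenos: GroupedPhenotypes, spec: SocialModelSpec,
                    pedigree_ids=None) -> DesignBundle:
    """Build y, X and the incidence structure of the social animal model.

    The pen-mate matrix S has S[i, j] = 1 iff records i and j share a pen
    (i != j); a record whose pen has no other member gets an all-zero row
    and is flagged in ``singleton_records``.  Fixed-effect factors are
    dummy-coded with the first observed level as reference.
    """
    df = phenos.data.reset_index(drop=True)
    y = df[spec.trait].to_numpy(float)
    if np.isnan(y).any():
        raise ModelError(f"missing values in trait {spec.trait!r}")

    cols = [np.ones(len(df))]
    names = ["intercept"]
    for fac in spec.fixed_factors:
        if fac not in df.columns:
            raise ModelError(f"fixed factor {fac!r} absent from phenotypes")
        Z, levels = _indicator(df[fac])
        if Z.shape[1] < 2:
            continue  # single level: absorbed by the intercept
        cols.append(Z[:, 1:])
        names += [f"{fac}[{lv}]" for lv in levels[1:]]
    X = np.column_stack(cols)

    ids = list(df["animal_id"])
    if pedigree_ids is None:
        pedigree_ids = ids
    ped_index = {a: i for i, a in enumerate(pedigree_ids)}
    try:
        r2p = np.array([ped_index[a] for a in ids])
    except KeyError as e:
        raise ModelError(f"phenotyped animal {e.args[0]!r} absent from pedigree") from None

    pens = df["pen"].to_numpy()
    n = len(df)
    S = np.zeros((n, n))
    singletons = []
    for pen in pd.unique(pens):
        rows = np.flatnonzero(pens == pen)
        if spec.pen_size is not None and len(rows) != spec.pen_size:
            raise ModelError(f"pen {pen!r} has {len(rows)} members, expected {spec.pen_size}")
        if len(rows) < 2:
            singletons.extend(df["animal_id"].iloc[rows])
            continue
        S[np.ix_(rows, rows)] = 1.0
        S[rows, rows] = 0.0
    if spec.include_social and singletons and spec.pen_size is not None:
        raise ModelError(f"singleton pens with social effects requested: {singletons[:5]}")

    return DesignBundle(
        y=y, X=X, record_ids=ids, pedigree_ids=list(pedigree_ids),
        record_to_pedigree=r2p, S=S,
        W_labels=df["litter"].to_numpy(), V_labels=df["pen"].to_numpy(),
        fixed_names=names, spec=spec, singleton_records=singletons,
    )


# ---------------------------------------------------------------------------
# REML engine


def _structure_matrices(bundle: DesignBundle, A: np.ndarray) -> dict:
    """Phenotype-covariance structure matrices for each component.

    With Arec the relationship block among phenotyped records and S the
    pen-mate indicator: cov(y) = var_Ad*Arec + cov_DS*(S Arec + Arec S')
    + var_As*(S Arec S') + var_litter*WW' + var_group*VV' + var_e*I.
    """
    idx = bundle.record_to_pedigree
    Arec = A[np.ix_(idx, idx)]
    Ks = {"var_Ad": Arec}
    if bundle.spec.include_social:
        SA = bundle.S @ Arec
        Ks["cov_DS"] = SA + SA.T
        Ks["var_As"] = bundle.S @ Arec @ bundle.S.T
    if bundle.spec.include_litter:
        W = bundle.litter_matrix()
        Ks["var_litter"] = W @ W.T
    if bundle.spec.include_group:
        V = bundle.group_matrix()
        Ks["var_group"] = V @ V.T
    Ks["var_e"] = np.eye(bundle.n)
    return Ks


def _sym_inv(V: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of a symmetric PD matrix via Cholesky."""
    L, info = dpotrf(V, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("covariance matrix not positive definite")
    logdet = 2.0 * np.log(np.diag(L)).sum()
    Vi, info = dpotri(L, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("inversion failed")
    Vi = np.tril(Vi) + np.tril(Vi, -1).T
    return Vi, logdet


def _restricted_loglik(theta, Ks_list, y, X, return_cache=False):
    """Closed-form restricted log-likelihood at a component vector."""
    V = sum(t * K for t, K in zip(theta, Ks_list))
    Vi, logdetV = _sym_inv(V)
    ViX = Vi @ X
    XtViX = X.T @ ViX
    c = cho_factor(XtViX)
    logdetX = 2.0 * np.log(np.diag(c[0])).sum()
    beta = cho_solve(c, ViX.T @ y)
    Py = Vi @ y - ViX @ beta
    ll = -0.5 * (logdetV + logdetX + float(y @ Py))
    if return_cache:
        return ll, (Vi, ViX, c, beta, Py)
    return ll


def _project_feasible(theta, names, floor):
    """Clip the 2x2 genetic block to PSD and floor plain variances."""
    th = dict(zip(names, theta))
    if "var_As" in th:
        G = np.array([[th["var_Ad"], th["cov_DS"]], [th["cov_DS"], th["var_As"]]])
        w, U = np.linalg.eigh(G)
        lo = 1e-8 * max(np.trace(G), floor)
        if w.min() < lo:
            G = U @ np.diag(np.maximum(w, lo)) @ U.T
        th["var_Ad"], th["cov_DS"], th["var_As"] = G[0, 0], G[0, 1], G[1, 1]
    else:
        th["var_Ad"] = max(th["var_Ad"], 1e-10 * floor)
    for k in ("var_litter", "var_group"):
        if k in th:
            th[k] = max(th[k], 1e-10 * floor)
    th["var_e"] = max(th["var_e"], 1e-8 * floor)
    return np.array([th[k] for k in names])


def reml_fit(
    bundle: DesignBundle,
    A: RelationshipMatrix | np.ndarray,
    start: VarianceComponents | dict | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    keep_history: bool = False,
    structure_cache: dict | None = None,
) -> "ModelFit":
    """Estimate variance components by average-information REML.

    AI steps are damped (step-halving) and projected into the feasible
    region, so the restricted log-likelihood is non-decreasing across
    iterations.  Non-convergence within ``max_iter`` is reported through
    ``components.converged``, never silently.
    """
    Amat = A.values if isinstance(A, RelationshipMatrix) else np.asarray(A, float)
    if isinstance(A, RelationshipMatrix):
        if list(A.ids) != list(bundle.pedigree_ids):
            raise ModelError("relationship matrix ids do not match the pedigree ids")
    y, X = bundle.y, bundle.X
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ModelError("singular fixed-effects design: drop or merge factor levels")

    Ks = structure_cache if structure_cache is not None else _structure_matrices(bundle, Amat)
    names = list(Ks)
    Ks_list = [Ks[k] for k in names]
    vp = float(np.var(y - X @ np.linalg.lstsq(X, y, rcond=None)[0], ddof=p))
    if vp <= 0:
        raise ModelError("degenerate phenotype: zero residual variance")

    theta = _default_start(names, vp)
    if start is not None:
        given = start.as_dict() if isinstance(start, VarianceComponents) else dict(start)
        theta = np.array([given.get(k, t) for k, t in zip(names, theta)], float)
    theta = _project_feasible(theta, names, vp)

    ll, vcache = _restricted_loglik(theta, Ks_list, y, X, return_cache=True)
    history = [ll]
    converged = False
    AI = np.eye(len(names))
    idx_of = {k: j for j, k in enumerate(names)}
    pinnable = [k for k in ("var_Ad", "var_As", "var_litter", "var_group") if k in idx_of]
    pinned: set = set()
    pin_count = dict.fromkeys(pinnable, 0)
    unpins_left = 2
    edge_s = None  # +/-1 while the genetic correlation is held at the cone edge
    edge_count = 0
    warm_rung = None  # (lambda, damp) that produced the last accepted step
    deltas: list = []
    it = 0
    for it in range(1, max_iter + 1):
        Vi, ViX, c, beta, Py = vcache  # factorisation at the current theta

        grad = np.empty(len(names))
        u = []
        for j, K in enumerate(Ks_list):
            KViX = K @ ViX
            trPK = float((Vi * K).sum()) - float(np.trace(cho_solve(c, ViX.T @ KViX)))
            uj = K @ Py
            u.append(uj)
            grad[j] = -0.5 * (trPK - float(Py @ uj))
        U = np.column_stack(u)
        PU = Vi @ U - ViX @ cho_solve(c, ViX.T @ U)
        AI = 0.5 * (U.T @ PU)
        AI = 0.5 * (AI + AI.T)

        # components stuck at the zero boundary with an outward gradient are
        # pinned there (the standard REML treatment of collapsing variances);
        # pinning var_As or var_Ad also pins the covariance, keeping G0 PSD
        for k in pinnable:
            j = idx_of[k]
            if k not in pinned and theta[j] <= 2e-9 * vp and grad[j] < 0:
                pin_count[k] += 1
                if pin_count[k] >= 2:
                    pinned.add(k)
                    theta[j] = 1e-10 * vp
                    if k in ("var_As", "var_Ad") and "cov_DS" in idx_of:
                        pinned.add("cov_DS")
                        theta[idx_of["cov_DS"]] = 0.0
            else:
                pin_count[k] = 0

        # correlation boundary: when the genetic block sticks to the PSD cone
        # edge (|r| -> 1), plain projected steps crawl; instead optimise on
        # the edge with cov = s * sqrt(var_Ad * var_As), releasing the
        # constraint as soon as the covariance gradient points inward again
        if "cov_DS" in idx_of and "cov_DS" not in pinned:
            jAd, jc, jAs = idx_of["var_Ad"], idx_of["cov_DS"], idx_of["var_As"]
            denom = np.sqrt(max(theta[jAd] * theta[jAs], 1e-300))
            r_now = theta[jc] / denom
            if edge_s is not None and edge_s * grad[jc] < 0:
                edge_s, edge_count = None, 0
            elif edge_s is None:
                if abs(r_now) > 0.9999:
                    edge_count += 1
                    if edge_count >= 2:
                        edge_s = 1.0 if r_now >= 0 else -1.0
                else:
                    edge_count = 0
        else:
            edge_s = None

        free = [j for j, k in enumerate(names) if k not in pinned]
        J = np.eye(len(names))[:, free]
        if edge_s is not None:
            jAd, jc, jAs = idx_of["var_Ad"], idx_of["cov_DS"], idx_of["var_As"]
            col_of = {j: c for c, j in enumerate(free)}
            J[jc, :] = 0.0
            if jAd in col_of:
                J[jc, col_of[jAd]] = 0.5 * edge_s * np.sqrt(
                    max(theta[jAs], 1e-300) / max(theta[jAd], 1e-300))
            if jAs in col_of:
                J[jc, col_of[jAs]] = 0.5 * edge_s * np.sqrt(
                    max(theta[jAd], 1e-300) / max(theta[jAs], 1e-300))
            if jc in col_of:  # cov is no longer an independent coordinate
                keep = [c for c, j in enumerate(free) if j != jc]
                J = J[:, keep]
                free = [j for j in free if j != jc]

        grad_r = J.T @ grad
        AI_r = J.T @ AI @ J

        # Levenberg-Marquardt ladder on the free coordinates: the raw AI step
        # first, then steps regularised toward gradient ascent whenever the
        # AI matrix is near-singular or the step overshoots.  The rung that
        # worked last iteration is tried first (near boundaries successive
        # iterations keep needing the same regularisation, and every probe
        # costs a full factorisation).
        scale = max(np.trace(AI_r) / max(len(free), 1), 1e-300)
        ladder = [(0.0, 1.0 / 4**d) for d in range(6)]
        for lam in (1e-6, 1e-3, 1e-1, 10.0, 1e3, 1e5):
            ladder += [(lam, 1.0 / 4**d) for d in range(3)]
        trials = list(ladder)
        if warm_rung is not None and warm_rung != (0.0, 1.0):
            trials.insert(1, warm_rung)  # raw AI step first, then last resort

        def _try(lam, damp):
            try:
                sub = solve(AI_r + lam * scale * np.eye(AI_r.shape[0]),
                            grad_r, assume_a="sym")
            except np.linalg.LinAlgError:
                return None
            cand = theta + damp * (J @ sub)
            if edge_s is not None:
                jAd, jc, jAs = (idx_of["var_Ad"], idx_of["cov_DS"],
                                idx_of["var_As"])
                cand[jc] = edge_s * np.sqrt(max(cand[jAd], 0.0)
                                            * max(cand[jAs], 0.0))
            cand = _project_feasible(cand, names, vp)
            cand[[idx_of[k] for k in pinned]] = theta[[idx_of[k] for k in pinned]]
            try:
                return (*_restricted_loglik(cand, Ks_list, y, X,
                                            return_cache=True), cand)
            except np.linalg.LinAlgError:
                return None

        new_ll, new_theta = -np.inf, theta
        for lam, damp in trials:
            out = _try(lam, damp)
            if out is not None and out[0] > ll:
                new_ll, vcache, new_theta = out
                warm_rung = (lam, damp)
                break

        at_optimum = False
        if not np.isfinite(new_ll):
            # even a vanishing (projected) gradient step cannot improve the
            # restricted likelihood: stationary or boundary optimum
            at_optimum = True
        else:
            delta = new_ll - ll
            theta, ll = new_theta, new_ll
            history.append(ll)
            deltas.append(delta)
            at_optimum = abs(delta) < tol
            # flat-crawl stop: along a nearly unidentified direction the
            # per-iteration gain decays sub-geometrically and iterations are
            # expensive; when a 25-iteration window gains under 0.05
            # log-units in total, the optimum is reached for every practical
            # purpose (small fits are simplex-polished afterwards anyway)
            if (not at_optimum and len(deltas) >= 25
                    and sum(deltas[-25:]) < 0.05):
                at_optimum = True
        if at_optimum:
            # let a pinned component re-enter if its gradient turned inward
            reentry = [k for k in pinned if k != "cov_DS" and grad[idx_of[k]] > 0]
            if reentry and unpins_left > 0:
                unpins_left -= 1
                for k in reentry:
                    pinned.discard(k)
                    pin_count[k] = 0
                pinned.discard("cov_DS")
                continue
            converged = True
            break

    if not converged:
        # a bounded derivative-free polish settles fits that still crawl
        # (e.g. near-singular V); larger problems get a shorter budget
        # because each evaluation is O(n^3)
        theta, ll, polished = _simplex_polish(theta, names, vp, Ks_list, y, X, ll,
                                              maxfev=1500 if n <= 1000 else 200)
        converged = polished
        vcache = None
        history.append(ll)
    elif n <= 300:
        # tiny datasets have cheap evaluations and awkward boundary optima:
        # polish unconditionally so the optimum is sharp to ~1e-6 log-units
        theta, ll, _ = _simplex_polish(theta, names, vp, Ks_list, y, X, ll, maxfev=4000)
        vcache = None
        history.append(ll)

    se = {}
    try:
        cov_theta = np.linalg.inv(AI)
        se = {k: float(np.sqrt(max(cov_theta[j, j], 0.0))) for j, k in enumerate(names)}
    except np.linalg.LinAlgError:
        pass

    full = dict.fromkeys(COMPONENT_NAMES, 0.0)
    full.update(dict(zip(names, theta)))
    comps = VarianceComponents(**full, se=se, converged=converged, n_iter=it)
    fit = _solve_effects(bundle, Amat, Ks_list, names, theta, comps, ll, vcache)
    if keep_history:
        fit.loglik_history = history
    return fit


def _simplex_polish(theta, names, vp, Ks_list, y, X, ll, maxfev):
    """Nelder-Mead ascent on the feasibility-projected restricted likelihood."""
    from scipy.optimize import minimize

    def neg(th):
        th = _project_feasible(th, names, vp)
        try:
            return -_restricted_loglik(th, Ks_list, y, X)
        except np.linalg.LinAlgError:
            return np.inf

    res = minimize(neg, theta, method="Nelder-Mead",
                   options={"maxfev": maxfev, "xatol": 1e-10 * vp, "fatol": 1e-10})
    if np.isfinite(res.fun) and -res.fun >= ll:
        return _project_feasible(res.x, names, vp), float(-res.fun), True
    return theta, ll, False


def _default_start(names, vp):
    base = {
        "var_Ad": 0.40 * vp, "cov_DS": 0.0, "var_As": 0.025 * vp,
        "var_litter": 0.0375 * vp, "var_group": 0.0375 * vp, "var_e": 0.50 * vp,
    }
    return np.array([base[k] for k in names])


@dataclass
class ModelFit:
    """A fitted social animal model: components, BLUPs and residuals."""

    components: VarianceComponents
    fixed_solutions: pd.Series
    blup_direct: pd.Series  # indexed by pedigree id
    blup_social: pd.Series
    blup_litter: pd.Series
    blup_group: pd.Series
    residuals: pd.Series  # indexed by record animal id
    loglik: float
    bundle: DesignBundle
    loglik_history: list = field(default_factory=list)

    def fitted_values(self) -> np.ndarray:
        """Reconstruct X b + Z_D a_D + Z_S a_S + W l + V g (adds to y - e)."""
        b = self.bundle
        aD = self.blup_direct.to_numpy()[b.record_to_pedigree]
        aS_rec = self.blup_social.to_numpy()[b.record_to_pedigree]
        social = b.S @ aS_rec
        litter = self.blup_litter.reindex(b.W_labels).to_numpy()
        group = self.blup_group.reindex(b.V_labels).to_numpy()
        return b.X @ self.fixed_solutions.to_numpy() + aD + social + litter + group


def _solve_effects(bundle, Amat, Ks_list, names, theta, comps, ll, cache=None) -> ModelFit:
    y, X = bundle.y, bundle.X
    if cache is not None:
        _, _, _, beta, Py = cache
    else:
        V = sum(t * K for t, K in zip(theta, Ks_list))
        Vi, _ = _sym_inv(V)
        ViX = Vi @ X
        c = cho_factor(X.T @ ViX)
        beta = cho_solve(c, ViX.T @ y)
        Py = Vi @ y - ViX @ beta

    idx = bundle.record_to_pedigree
    Arec_cols = Amat[:, idx]  # q x n
    StPy = bundle.S.T @ Py
    aD = Arec_cols @ (comps.var_Ad * Py + comps.cov_DS * StPy)
    aS = Arec_cols @ (comps.cov_DS * Py + comps.var_As * StPy)

    W, litters = _indicator(bundle.W_labels)
    Vg, pens = _indicator(bundle.V_labels)
    l_hat = comps.var_litter * (W.T @ Py)
    g_hat = comps.var_group * (Vg.T @ Py)
    e_hat = comps.var_e * Py

    return ModelFit(
        components=comps,
        fixed_solutions=pd.Series(beta, index=bundle.fixed_names),
        blup_direct=pd.Series(aD, index=bundle.pedigree_ids),
        blup_social=pd.Series(aS, index=bundle.pedigree_ids),
        blup_litter=pd.Series(l_hat, index=litters),
        blup_group=pd.Series(g_hat, index=pens),
        residuals=pd.Series(e_hat, index=bundle.record_ids),
        loglik=ll,
        bundle=bundle,
    )


def fit_social_model(
    phenos: GroupedPhenotypes,
    pedigree: Pedigree | RelationshipMatrix,
    spec: SocialModelSpec | None = None,
    **kwargs,
) -> ModelFit:
    """Convenience wrapper: assemble the design and run REML."""
    spec = spec or SocialModelSpec(trait=phenos.trait)
    if isinstance(pedigree, Pedigree):
        A = numerator_relationship(pedigree)
    else:
        A = pedigree
    bundle = assemble_design(phenos, spec, pedigree_ids=A.ids)
    return reml_fit(bundle, A, **kwargs)


# ---------------------------------------------------------------------------
# derived summaries


def heritability(var_a: float, var_p: float) -> float:
    """Classical heritability h^2 = sigma^2_A / sigma^2_P."""
    if var_p <= 0:
        raise ValueError("phenotypic variance must be positive")
    return var_a / var_p


def genetic_correlation(var_ad: float, cov_ds: float, var_as: float) -> float:
    """Direct-social genetic correlation; 0 (by convention) if either
    variance is zero."""
    if var_ad <= 0 or var_as <= 0:
        return 0.0
    return cov_ds / np.sqrt(var_ad * var_as)


def total_heritable_variance(var_ad: float, cov_ds: float, var_as: float, n: int) -> float:
    """Variance of total breeding values a_D + (n-1) a_S:
    sigma^2_TBV = var_Ad + 2(n-1) cov_DS + (n-1)^2 var_As."""
    m = n - 1
    return var_ad + 2.0 * m * cov_ds + m * m * var_as

def total_heritability(var_tbv: float, var_tp: float) -> float:
    """T^2 = sigma^2_TBV / sigma^2_TP (may exceed classical h^2)."""
    if var_tp <= 0:
        raise ValueError("total phenotypic variance must be positive")
    return var_tbv / var_tp


def derive_summaries(fit: ModelFit, n: int, mean_mate_relationship: float = 0.0) -> dict:
    """Heritabilities and total heritable variance from a fitted model.

    The classical phenotypic variance counts only single-animal terms,
    sigma^2_P = var_Ad + var_litter + var_group + var_e.  The total
    phenotypic variance adds the pen-mate phenotypic covariance implied by
    the fitted components, sigma^2_TP = sigma^2_P + (n-1) * (2 cov_DS Abar
    + (n-2) var_As Abar + var_group), with Abar the mean pen-mate
    relationship (0 for unrelated pen mates).
    """
    c = fit.components
    var_p = c.var_Ad + c.var_litter + c.var_group + c.var_e
    cov_mates = 2.0 * c.cov_DS * mean_mate_relationship \
        + (n - 2) * c.var_As * mean_mate_relationship + c.var_group
    var_tp = var_p + (n - 1) * cov_mates
    var_tbv = total_heritable_variance(c.var_Ad, c.cov_DS, c.var_As, n)
    return {
        "var_P": var_p,
        "h2": heritability(c.var_Ad, var_p),
        "var_TBV": var_tbv,
        "var_TP": var_tp,
        "T2": total_heritability(var_tbv, var_tp),
        "r_ADS": genetic_correlation(c.var_Ad, c.cov_DS, c.var_As),
    }


def pseudo_phenotypes(fit: ModelFit, which: str, animal_ids=None) -> pd.Series:
    """Genome-scan responses: fitted genetic effect + residual.

    ``which="dge"`` returns Z_D a_D + e per record (the animal's own direct
    effect plus residual); ``which="sge"`` returns Z_S a_S + e (the summed
    social effects acting on the record plus residual).  ``animal_ids``
    restricts and orders the output to the genotyped sample.
    """
    if not fit.components.converged:
        raise ModelError("pseudo-phenotypes require a converged fit")
    b = fit.bundle
    if which == "dge":
        vals = fit.blup_direct.to_numpy()[b.record_to_pedigree]
    elif which == "sge":
        vals = b.S @ fit.blup_social.to_numpy()[b.record_to_pedigree]
    else:
        raise ValueError("which must be 'dge' or 'sge'")
    out = pd.Series(vals + fit.residuals.to_numpy(), index=b.record_ids, name=which)
    if animal_ids is not None:
        missing = [a for a in animal_ids if a not in out.index]
        if missing:
            raise ModelError(f"genotyped animals without phenotype records: {missing[:5]}")
        out = out.loc[list(animal_ids)]
    return out
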