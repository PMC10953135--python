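"""Pedigree-based linear animal models estimated by REML.

Model: y = Xb + Z_a a + (Z_m m) + e with a ~ N(0, A sigma2_a),
m ~ N(0, I sigma2_m) an optional maternal (dam) environmental effect,
and e ~ N(0, I sigma2_e).  Estimation works on Henderson's sparse
mixed-model equations; the restricted log-likelihood is evaluated
through the standard identity

    -2 l_R = ln|R| + ln|G| + ln|C| + y' P y   (+ constant),

where C is the MME coefficient matrix, ln|A| comes for free from the
pedigree's Mendelian-sampling variances, and ln|C| from a sparse LU
factorization.

Two REML algorithms are provided: expectation-maximization (monotone in
the likelihood, needs the inverse of C so it is reserved for small to
medium systems) and direct derivative-free maximization of the
restricted likelihood over log-variances (Nelder-Mead; the default, and
the only practical route for systems with many thousands of equations).
Standard errors come from a finite-difference observed-information
matrix at the optimum; SEs of derived ratios use the delta method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import qr as dense_qr
from scipy.optimize import minimize
from scipy.sparse.linalg import splu
from scipy.stats import chi2

from .pedigree import PedigreeRelationship

logger = logging.getLogger(__name__)

VARIANCE_FLOOR_FRAC = 1e-8  # of the phenotypic variance


class ModelError(ValueError):
    pass


@dataclass
class ModelSpec:
    """One trait's linear model: response, fixed factors, covariates.

    ``animal`` names the column linking records to the pedigree;
    ``maternal`` adds the random dam environmental effect (requires a
    ``dam`` column in the data).
    """

    response: str
    fixed: tuple = ()
    covariates: tuple = ()
    animal: str = "animal"
    dam: str = "dam"
    maternal: bool = False


@dataclass
class VarCompFit:
    sigma2_a: float
    sigma2_e: float
    sigma2_m: float | None = None
    sigma_a12: float | None = None
    sigma2_a2: float | None = None
    sigma2_e2: float | None = None
    sigma_e12: float | None = None
    loglik: float = np.nan
    n_iter: int = 0
    converged: bool = False
    method: str = ""
    n_records: int = 0
    rank_X: int = 0
    se: dict = field(default_factory=dict)
    boundary: dict = field(default_factory=dict)
    mean: float = np.nan
    loglik_history: list = field(default_factory=list)

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_a + (self.sigma2_m or 0.0) + self.sigma2_e


def build_fixed_design(
    spec: ModelSpec, data: pd.DataFrame, strict: bool = False
) -> tuple[np.ndarray, list[str], int]:
    """Full-rank fixed-effect design: intercept, drop-first dummies, covariates.

    Redundant columns (e.g. batch nested within location when both enter
    the model) are detected by pivoted QR.  By default they are dropped,
    mirroring how mixed-model software applies constraints automatically;
    with ``strict=True`` a ModelError names the confounded factors.
    """
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for f in spec.fixed:
        d = pd.get_dummies(data[f].astype("category"), prefix=f, drop_first=True)
        for c in d.columns:
            cols.append(d[c].to_numpy(dtype=float))
            names.append(c)
    for cv in spec.covariates:
        cols.append(data[cv].to_numpy(dtype=float))
        names.append(cv)
    X = np.column_stack(cols)
    # rank check via pivoted QR on X'X factorization of X
    _, Rq, piv = dense_qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(Rq))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        dropped = [names[j] for j in piv[rank:]]
        factors = sorted({d.split("_")[0] for d in dropped if d != "intercept"})
        if strict:
            raise ModelError(
                "rank-deficient fixed effects; confounded factors: "
                + ", ".join(factors)
            )
        logger.info("dropping %d redundant fixed-effect columns (%s)",
                    X.shape[1] - rank, ", ".join(factors))
        keep = np.sort(piv[:rank])
        X = X[:, keep]
        names = [names[j] for j in keep]
    return X, names, rank


def _incidence(codes: np.ndarray, n_levels: int) -> sparse.csr_matrix:
    n = len(codes)
    return sparse.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


@dataclass
class _UniParts:
    """Precomputed design pieces reused across likelihood evaluations."""

    y: np.ndarray
    X: sparse.csr_matrix
    Za: sparse.csr_matrix
    Zm: sparse.csr_matrix | None
    Ainv: sparse.csr_matrix
    log_det_A: float
    rank_X: int
    WtW: sparse.csr_matrix
    Wty: np.ndarray
    yty: float
    n: int
    p: int
    q: int
    qm: int


def _prepare_univariate(
    spec: ModelSpec, data: pd.DataFrame, rel: PedigreeRelationship,
    strict: bool = False,
) -> _UniParts:
    data = data.dropna(subset=[spec.response]).reset_index(drop=True)
    if len(data) == 0:
        raise ModelError(f"no records for response {spec.response!r}")
    y = data[spec.response].to_numpy(dtype=float)
    Xd, _, _ = build_fixed_design(spec, data, strict=strict)
    X = sparse.csr_matrix(Xd)
    Za = _incidence(rel.positions(data[spec.animal]), rel.n)
    Zm = None
    qm = 0
    if spec.maternal:
        dams = data[spec.dam].astype("category")
        Zm = _incidence(dams.cat.codes.to_numpy(), len(dams.cat.categories))
        qm = Zm.shape[1]
    blocks = [X, Za] + ([Zm] if Zm is not None else [])
    W = sparse.hstack(blocks, format="csr")
    WtW = (W.T @ W).tocsc()
    Wty = W.T @ y
    return _UniParts(
        y=y, X=X, Za=Za, Zm=Zm, Ainv=rel.A_inv.tocsc(),
        log_det_A=rel.log_det_A, rank_X=Xd.shape[1],
        WtW=WtW, Wty=Wty, yty=float(y @ y),
        n=len(y), p=Xd.shape[1], q=rel.n, qm=qm,
    )


def build_mme(
    spec: ModelSpec, data: pd.DataFrame, rel: PedigreeRelationship,
    varcomps: dict, strict: bool = False,
):
    """Henderson's MME C s = rhs for given variance components.

    ``varcomps`` holds sigma2_a, sigma2_e and (if maternal) sigma2_m.
    Returns (C, rhs, parts); the solution orders fixed effects, then
    animal effects (pedigree order), then dam effects.
    """
    parts = _prepare_univariate(spec, data, rel, strict=strict)
    C, rhs = _assemble(parts, varcomps["sigma2_a"], varcomps.get("sigma2_m"),
                       varcomps["sigma2_e"])
    return C, rhs, parts


def _assemble(parts: _UniParts, s2a: float, s2m: float | None, s2e: float):
    blocks = [sparse.csr_matrix((parts.p, parts.p)), parts.Ainv * (s2e / s2a)]
    if parts.Zm is not None:
        blocks.append(sparse.eye(parts.qm, format="csr") * (s2e / (s2m or np.inf)))
    C = (parts.WtW + sparse.block_diag(blocks, format="csc")) / s2e
    return C.tocsc(), parts.Wty / s2e


def _logdet_from_splu(lu) -> float:
    diag = lu.U.diagonal()
    return float(np.sum(np.log(np.abs(diag))))


def _factor_mme(C: sparse.csc_matrix, p: int):
    """Factor the MME with Schur elimination of the dense fixed block.

    The p fixed-effect equations couple densely to everything and cause
    heavy fill-in under sparse orderings; eliminating them against the
    (pedigree-sparse, well-orderable) random block keeps the sparse
    factor small.  Returns ``(solve, logdet)`` where ``solve`` maps a
    right-hand side to the full solution vector.
    """
    n = C.shape[0]
    if p == 0:
        lu = splu(C, permc_spec="MMD_AT_PLUS_A")
        return lu.solve, _logdet_from_splu(lu)
    Crr = C[p:, p:].tocsc()
    Crf = np.asarray(C[p:, :p].todense())       # (n-p) x p
    F = np.asarray(C[:p, :p].todense())
    lur = splu(Crr, permc_spec="MMD_AT_PLUS_A")
    Y = lur.solve(Crf)
    S = F - Crf.T @ Y
    sign, ldS = np.linalg.slogdet(S)
    if sign <= 0:
        raise RuntimeError("indefinite fixed-effect Schur complement")
    logdet = _logdet_from_splu(lur) + float(ldS)

    def solve(r):
        r1, r2 = r[:p], r[p:]
        u2 = lur.solve(r2)
        b = np.linalg.solve(S, r1 - Crf.T @ u2)
        u = u2 - Y @ b
        return np.concatenate([b, u])

    return solve, logdet


def solve_mme(C, rhs, p: int = 0):
    solve, _ = _factor_mme(sparse.csc_matrix(C), p)
    return solve(rhs)


def _m2ll_univariate(parts: _UniParts, s2a: float, s2m: float | None, s2e: float):
    """-2 restricted log-likelihood (up to an additive constant)."""
    C, rhs = _assemble(parts, s2a, s2m, s2e)
    solve, ldC = _factor_mme(C, parts.p)
    s = solve(rhs)
    ypy = (parts.yty - s @ parts.Wty) / s2e
    ldR = parts.n * np.log(s2e)
    ldG = parts.q * np.log(s2a) + parts.log_det_A
    if parts.Zm is not None:
        ldG += parts.qm * np.log(s2m)
    return ldR + ldG + ldC + ypy, s, solve


def reml_fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    rel: PedigreeRelationship,
    max_iter: int = 50,
    method: str = "auto",
    tol_ll: float = 1e-6,
    tol_par: float = 1e-4,
    nm_options: dict | None = None,
    compute_se: bool = True,
    strict: bool = False,
) -> VarCompFit:
    """Univariate REML variance components.

    method 'em': monotone EM-REML iterations (dense trace path).
    method 'direct': Nelder-Mead on the restricted likelihood over
    log-variances.  'auto' picks 'direct'.  Variances are floored at
    ``1e-8 * var(y)``; an estimate at the floor is flagged as boundary
    (statistical significance of a component is judged via the LRT, not
    the floor).
    """
    parts = _prepare_univariate(spec, data, rel, strict=strict)
    vary = float(np.var(parts.y, ddof=1))
    if vary <= 0:
        raise ModelError("response has zero variance")
    floor = VARIANCE_FLOOR_FRAC * vary
    s2a0 = 0.1 * vary
    s2m0 = 0.1 * vary if spec.maternal else None
    s2e0 = vary - s2a0 - (s2m0 or 0.0)

    if method == "auto":
        method = "direct"

    if method == "em":
        fit = _em_reml(parts, s2a0, s2m0, s2e0, floor, max_iter, tol_ll, tol_par)
    elif method == "direct":
        fit = _direct_reml(parts, s2a0, s2m0, s2e0, floor, nm_options)
    else:
        raise ValueError(f"unknown REML method {method!r}")

    fit.n_records = parts.n
    fit.rank_X = parts.rank_X
    fit.mean = float(parts.y.mean())
    fit.boundary = {"sigma2_a": fit.sigma2_a <= floor * 1.01}
    if spec.maternal:
        fit.boundary["sigma2_m"] = (fit.sigma2_m or 0.0) <= floor * 1.01
    if compute_se:
        _univariate_se(parts, fit, floor)
    return fit


def _em_reml(parts, s2a, s2m, s2e, floor, max_iter, tol_ll, tol_par) -> VarCompFit:
    n_eq = parts.p + parts.q + parts.qm
    if n_eq > 4000:
        raise ModelError(
            "EM-REML trace computation needs a dense inverse; system too large"
        )
    Ainv_d = parts.Ainv.toarray()
    prev_ll = -np.inf
    it = 0
    converged = False
    history: list[float] = []
    for it in range(1, max_iter + 1):
        # MME at the current ratios (unscaled by sigma2_e)
        blocks = [sparse.csr_matrix((parts.p, parts.p)),
                  parts.Ainv * (s2e / s2a)]
        if parts.Zm is not None:
            blocks.append(sparse.eye(parts.qm, format="csr") * (s2e / s2m))
        Cstar = (parts.WtW + sparse.block_diag(blocks, format="csc")).toarray()
        Cinv = np.linalg.inv(Cstar)
        sol = Cinv @ parts.Wty
        a = sol[parts.p:parts.p + parts.q]
        Caa = Cinv[parts.p:parts.p + parts.q, parts.p:parts.p + parts.q]
        new_s2a = (a @ (Ainv_d @ a) + np.trace(Ainv_d @ Caa) * s2e) / parts.q
        if parts.Zm is not None:
            m = sol[parts.p + parts.q:]
            Cmm = Cinv[parts.p + parts.q:, parts.p + parts.q:]
            new_s2m = (m @ m + np.trace(Cmm) * s2e) / parts.qm
        else:
            new_s2m = None
        new_s2e = (parts.yty - sol @ parts.Wty) / (parts.n - parts.rank_X)
        new_s2a = max(new_s2a, floor)
        if new_s2m is not None:
            new_s2m = max(new_s2m, floor)
        rel_par = abs(new_s2a - s2a) / max(s2a, floor)
        if new_s2m is not None:
            rel_par = max(rel_par, abs(new_s2m - s2m) / max(s2m, floor))
        rel_par = max(rel_par, abs(new_s2e - s2e) / s2e)
        s2a, s2m, s2e = new_s2a, new_s2m, new_s2e
        m2ll, _, _ = _m2ll_univariate(parts, s2a, s2m, s2e)
        ll = -0.5 * m2ll
        history.append(ll)
        if it > 1 and abs(ll - prev_ll) / max(abs(prev_ll), 1.0) < tol_ll \
                and rel_par < tol_par:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return VarCompFit(
        sigma2_a=float(s2a), sigma2_e=float(s2e),
        sigma2_m=None if s2m is None else float(s2m),
        loglik=float(prev_ll), n_iter=it, converged=converged, method="em",
        loglik_history=history,
    )


def _profiled_m2ll(parts: _UniParts, lam_a: float, lam_m: float | None):
    """-2 l_R with sigma2_e profiled out, as a function of variance ratios.

    With lambda = sigma2/sigma2_e per random term, the residual variance
    maximizing the restricted likelihood is sigma2_e = y'Py*sigma2_e /
    (n - p) = T / (n - p) with T = y'y - s'W'y from the ratio-scaled MME.
    """
    blocks = [sparse.csr_matrix((parts.p, parts.p)), parts.Ainv / lam_a]
    if parts.Zm is not None:
        blocks.append(sparse.eye(parts.qm, format="csr") / lam_m)
    Cstar = (parts.WtW + sparse.block_diag(blocks, format="csc")).tocsc()
    try:
        solve, ldC = _factor_mme(Cstar, parts.p)
    except RuntimeError:
        return 1e30, np.nan, None
    s = solve(parts.Wty)
    T = parts.yty - s @ parts.Wty
    if T <= 0:
        return 1e30, np.nan, None
    df = parts.n - parts.rank_X
    s2e = T / df
    m2ll = (
        df * np.log(s2e) + df
        + parts.q * np.log(lam_a) + parts.log_det_A
        + (parts.qm * np.log(lam_m) if parts.Zm is not None else 0.0)
        + ldC
    )
    return float(m2ll), float(s2e), s


_LAM_LO, _LAM_HI = 1e-8, 1e4


def _direct_reml(parts, s2a0, s2m0, s2e0, floor, nm_options) -> VarCompFit:
    """Maximize the profiled restricted likelihood over log variance ratios.

    Scalar coarse-grid + Brent search for the additive-only model;
    Nelder-Mead with restarts over the two ratios when a maternal
    component is present.
    """
    has_m = parts.Zm is not None
    nfev = 0

    if not has_m:
        def obj(u):
            nonlocal nfev
            nfev += 1
            return _profiled_m2ll(parts, float(np.exp(u)), None)[0]

        lo, hi = np.log(_LAM_LO), np.log(_LAM_HI)
        grid = np.linspace(lo, hi, 15)
        vals = [obj(u) for u in grid]
        k = int(np.argmin(vals))
        a = grid[max(k - 1, 0)]
        b = grid[min(k + 1, len(grid) - 1)]
        from scipy.optimize import minimize_scalar

        xatol = (nm_options or {}).get("xatol", 1e-6)
        res = minimize_scalar(obj, bounds=(a, b), method="bounded",
                              options={"xatol": xatol})
        lam_a = float(np.exp(res.x))
        m2ll, s2e, _ = _profiled_m2ll(parts, lam_a, None)
        s2a = max(lam_a * s2e, floor)
        return VarCompFit(
            sigma2_a=s2a, sigma2_e=s2e, sigma2_m=None,
            loglik=float(-0.5 * m2ll), n_iter=nfev,
            converged=bool(res.success), method="direct",
        )

    def objective(theta):
        lam = np.exp(np.clip(theta, np.log(_LAM_LO), np.log(_LAM_HI)))
        return _profiled_m2ll(parts, float(lam[0]), float(lam[1]))[0]

    x0 = np.log([s2a0 / s2e0, s2m0 / s2e0])
    opts = {"xatol": 1e-5, "fatol": 1e-7, "maxiter": 600, "maxfev": 600}
    if nm_options:
        opts.update(nm_options)
    res = _nelder_mead_restarts(objective, x0, opts, max_restarts=2)
    lam = np.exp(np.clip(res.x, np.log(_LAM_LO), np.log(_LAM_HI)))
    m2ll, s2e, _ = _profiled_m2ll(parts, float(lam[0]), float(lam[1]))
    return VarCompFit(
        sigma2_a=max(float(lam[0] * s2e), floor), sigma2_e=s2e,
        sigma2_m=max(float(lam[1] * s2e), floor),
        loglik=float(-0.5 * m2ll), n_iter=int(res.nit),
        converged=bool(res.success), method="direct",
    )


def _nelder_mead_restarts(objective, x0, opts, max_restarts: int = 3,
                          improve_tol: float = 1e-6):
    """Nelder-Mead with simplex restarts at the incumbent optimum.

    Restarting rebuilds a fresh simplex around the previous solution,
    which escapes the narrow curved valleys that a collapsed simplex
    cannot follow (e.g. jointly drifting genetic and residual
    correlations).  Stops when a restart improves the objective by less
    than ``improve_tol``.
    """
    res = minimize(objective, x0, method="Nelder-Mead", options=opts)
    total_nit = res.nit
    for _ in range(max_restarts):
        res2 = minimize(objective, res.x, method="Nelder-Mead", options=opts)
        total_nit += res2.nit
        improved = res.fun - res2.fun
        if res2.fun <= res.fun:
            res = res2
        if improved < improve_tol:
            break
    res.nit = total_nit
    return res


def _fd_hessian(f, x, steps):
    """Central finite-difference Hessian of scalar f at x."""
    p = len(x)
    H = np.zeros((p, p))
    for i in range(p):
        hi = steps[i]
        for j in range(i, p):
            hj = steps[j]
            if i == j:
                fpp = f(x + 2 * hi * _e(p, i))
                fp = f(x)
                fmm = f(x - 2 * hi * _e(p, i))
                H[i, i] = (fpp - 2 * fp + fmm) / (4 * hi * hi)
            else:
                fpp = f(x + hi * _e(p, i) + hj * _e(p, j))
                fpm = f(x + hi * _e(p, i) - hj * _e(p, j))
                fmp = f(x - hi * _e(p, i) + hj * _e(p, j))
                fmm = f(x - hi * _e(p, i) - hj * _e(p, j))
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hi * hj)
    return H


def _e(p, i):
    v = np.zeros(p)
    v[i] = 1.0
    return v


def _univariate_se(parts: _UniParts, fit: VarCompFit, floor: float) -> None:
    """SEs from the finite-difference observed information in sigma2 space."""
    has_m = fit.sigma2_m is not None
    x = [fit.sigma2_a] + ([fit.sigma2_m] if has_m else []) + [fit.sigma2_e]
    x = np.array(x)
    if np.any(x <= floor * 1.01):
        return  # information degenerate at the boundary

    def f(v):
        if np.any(v <= 0):
            return 1e30
        s2a = v[0]
        s2m = v[1] if has_m else None
        s2e = v[-1]
        return _m2ll_univariate(parts, s2a, s2m, s2e)[0]

    steps = 1e-3 * np.abs(x)
    try:
        H = 0.5 * _fd_hessian(f, x, steps)
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.any(d <= 0):
            return
        names = ["sigma2_a"] + (["sigma2_m"] if has_m else []) + ["sigma2_e"]
        fit.se = dict(zip(names, np.sqrt(d)))
        fit.se["_cov"] = cov
        fit.se["_names"] = names
    except np.linalg.LinAlgError:
        return


# ---------------------------------------------------------------------------
# bivariate


@dataclass
class _BiParts:
    """Precomputed pattern matrices for the bivariate likelihood.

    R^{-1} is a linear combination of five fixed diagonal/cross patterns
    (singles and paired records per trait), and G^{-1} of three Kronecker
    patterns E_ij (x) A^{-1}; each likelihood evaluation is then one
    weighted sum plus a sparse LU factorization.
    """

    y: np.ndarray
    W: sparse.csr_matrix
    R_patterns: dict  # name -> (WtPW csc, WtPy, ytPy, P csr)
    G_patterns: dict  # (i,j) -> csc pattern of the C random block
    log_det_A: float
    p: int
    q: int
    n1: int
    n2: int
    n_both: int
    rank_X: int
    overlap: bool
    paired_y: np.ndarray | None = None


def _prepare_bivariate(spec1, spec2, data, rel, strict=False) -> _BiParts:
    d1 = data.dropna(subset=[spec1.response]).reset_index(drop=True)
    d2 = data.dropna(subset=[spec2.response]).reset_index(drop=True)
    if len(d1) == 0 or len(d2) == 0:
        raise ModelError("each trait needs at least one record")
    y = np.concatenate([
        d1[spec1.response].to_numpy(dtype=float),
        d2[spec2.response].to_numpy(dtype=float),
    ])
    X1, _, _ = build_fixed_design(spec1, d1, strict=strict)
    X2, _, _ = build_fixed_design(spec2, d2, strict=strict)
    X = sparse.block_diag(
        [sparse.csr_matrix(X1), sparse.csr_matrix(X2)], format="csr"
    )
    q = rel.n
    Za1 = _incidence(rel.positions(d1[spec1.animal]), q)
    Za2 = _incidence(rel.positions(d2[spec2.animal]), q)
    Z = sparse.bmat(
        [[Za1, None], [None, Za2]], format="csr"
    )  # columns: trait1 animals, then trait2 animals
    W = sparse.hstack([X, Z], format="csr")

    a1 = d1[spec1.animal].to_numpy()
    a2 = d2[spec2.animal].to_numpy()
    pos2 = {a: i for i, a in enumerate(a2)}
    pairs = []
    single1 = []
    for i, a in enumerate(a1):
        j = pos2.get(a)
        if j is None:
            single1.append(i)
        else:
            pairs.append((i, len(a1) + j))
    paired2 = {j - len(a1) for _, j in pairs}
    single2 = [len(a1) + j for j in range(len(a2)) if j not in paired2]
    pairs = np.array(pairs, dtype=int).reshape(-1, 2)
    single1 = np.array(single1, dtype=int)
    single2 = np.array(single2, dtype=int)
    n = len(a1) + len(a2)

    def diag_pattern(idx):
        return sparse.csr_matrix(
            (np.ones(len(idx)), (idx, idx)), shape=(n, n)
        )

    patterns = {
        "s1": diag_pattern(single1),
        "s2": diag_pattern(single2),
        "p1": diag_pattern(pairs[:, 0]),
        "p2": diag_pattern(pairs[:, 1]),
    }
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        patterns["x"] = sparse.csr_matrix(
            (np.ones(2 * len(i)), (np.r_[i, j], np.r_[j, i])), shape=(n, n)
        )
    R_patterns = {}
    for name, P in patterns.items():
        WtP = W.T @ P
        R_patterns[name] = (
            (WtP @ W).tocsc(), WtP @ y, float(y @ (P @ y)),
        )
    # G^{-1} patterns on the random block of C (size p + 2q)
    Ainv = rel.A_inv.tocoo()
    m = X.shape[1] + 2 * q

    def g_pattern(bi, bj):
        r = Ainv.row + X.shape[1] + bi * q
        c = Ainv.col + X.shape[1] + bj * q
        M = sparse.coo_matrix((Ainv.data, (r, c)), shape=(m, m))
        if bi != bj:
            M = M + M.T
        return M.tocsc()

    G_patterns = {(0, 0): g_pattern(0, 0), (1, 1): g_pattern(1, 1),
                  (0, 1): g_pattern(0, 1)}
    return _BiParts(
        y=y, W=W, R_patterns=R_patterns, G_patterns=G_patterns,
        log_det_A=rel.log_det_A,
        p=X.shape[1], q=q, n1=len(d1), n2=len(d2), n_both=len(pairs),
        rank_X=X.shape[1], overlap=len(pairs) > 0,
        paired_y=(np.column_stack([y[pairs[:, 0]], y[pairs[:, 1]]])
                  if len(pairs) else None),
    )


def _m2ll_bivariate(parts: _BiParts, s2a1, s2a2, sa12, s2e1, s2e2, se12):
    detG0 = s2a1 * s2a2 - sa12 * sa12
    if detG0 <= 0 or s2a1 <= 0 or s2a2 <= 0:
        return 1e30, None
    # R^{-1} coefficients: singles get 1/sigma2_e, paired records the
    # elements of the inverse 2x2 residual covariance
    det_e = s2e1 * s2e2 - se12 * se12
    if det_e <= 0 or s2e1 <= 0 or s2e2 <= 0:
        return 1e30, None
    coef = {"s1": 1.0 / s2e1, "s2": 1.0 / s2e2}
    ldR = (parts.n1 - parts.n_both) * np.log(s2e1) \
        + (parts.n2 - parts.n_both) * np.log(s2e2)
    if parts.n_both:
        coef["p1"] = s2e2 / det_e
        coef["p2"] = s2e1 / det_e
        coef["x"] = -se12 / det_e
        ldR += parts.n_both * np.log(det_e)
    else:
        coef["p1"] = coef["p2"] = 0.0
    WtRW = None
    rhs = None
    ytRy = 0.0
    for name, c in coef.items():
        if c == 0.0 or name not in parts.R_patterns:
            continue
        M, v, s_ = parts.R_patterns[name]
        WtRW = M * c if WtRW is None else WtRW + M * c
        rhs = v * c if rhs is None else rhs + v * c
        ytRy += s_ * c
    # G^{-1} = G0^{-1} (x) A^{-1}
    g11 = s2a2 / detG0
    g22 = s2a1 / detG0
    g12 = -sa12 / detG0
    C = WtRW + parts.G_patterns[(0, 0)] * g11 + parts.G_patterns[(1, 1)] * g22
    if g12 != 0.0:
        C = C + parts.G_patterns[(0, 1)] * g12
    try:
        solve, ldC = _factor_mme(C.tocsc(), parts.p)
    except (RuntimeError, np.linalg.LinAlgError):
        return 1e30, None
    s = solve(rhs)
    ypy = ytRy - s @ rhs
    ldG = parts.q * np.log(detG0) + 2.0 * parts.log_det_A
    return float(ldR + ldG + ldC + ypy), s


def reml_fit_bivariate(
    spec1: ModelSpec,
    spec2: ModelSpec,
    data: pd.DataFrame,
    rel: PedigreeRelationship,
    estimate_residual_cov: bool | None = None,
    estimate_genetic_cov: bool = True,
    nm_options: dict | None = None,
    compute_se: bool = True,
    start: dict | None = None,
) -> VarCompFit:
    """Bivariate REML with a 2x2 additive covariance through the pedigree.

    The residual covariance is estimated from animals carrying both
    traits; when no animal has both (traits linked only through the
    relationship matrix) it is fixed at zero, and requesting it raises.
    Returns a VarCompFit with trait-1 components in sigma2_a/sigma2_e,
    trait-2 components in sigma2_a2/sigma2_e2, and sigma_a12/sigma_e12.
    """
    parts = _prepare_bivariate(spec1, spec2, data, rel)
    if estimate_residual_cov is None:
        estimate_residual_cov = parts.overlap
    if estimate_residual_cov and not parts.overlap:
        raise ModelError(
            "residual covariance requested but no animal has both traits"
        )
    y1 = parts.y[:parts.n1]
    y2 = parts.y[parts.n1:]
    v1, v2 = np.var(y1, ddof=1), np.var(y2, ddof=1)
    floor1, floor2 = VARIANCE_FLOOR_FRAC * v1, VARIANCE_FLOOR_FRAC * v2
    st = {
        "sigma2_a": 0.1 * v1, "sigma2_a2": 0.1 * v2,
        "sigma2_e": 0.9 * v1, "sigma2_e2": 0.9 * v2,
        "r_a": 0.0, "r_e": 0.0,
    }
    # warm-start correlations from the phenotypic correlation of animals
    # carrying both traits (keeps the search on the right branch when the
    # traits are strongly related)
    if parts.n_both >= 3:
        with np.errstate(invalid="ignore"):
            rp = np.corrcoef(parts.paired_y[:, 0], parts.paired_y[:, 1])[0, 1]
        if np.isfinite(rp):
            rp = float(np.clip(rp, -0.95, 0.95))
            st["r_e"] = rp
            st["r_a"] = 0.5 * rp
    if start:
        st.update(start)

    def unpack(theta):
        s2a1 = max(np.exp(theta[0]), floor1)
        s2a2 = max(np.exp(theta[1]), floor2)
        ra = 0.99999 * np.tanh(theta[2])
        s2e1 = max(np.exp(theta[3]), floor1)
        s2e2 = max(np.exp(theta[4]), floor2)
        # the residual correlation is capped slightly inside (-1, 1): at
        # |r_e| -> 1 the residual covariance degenerates and the restricted
        # likelihood of duplicated traits is unbounded
        re = 0.999 * np.tanh(theta[5]) if estimate_residual_cov else 0.0
        return (s2a1, s2a2, ra * np.sqrt(s2a1 * s2a2),
                s2e1, s2e2, re * np.sqrt(s2e1 * s2e2))

    def objective(theta):
        m2ll, _ = _m2ll_bivariate(parts, *unpack(theta))
        return m2ll

    x0 = [np.log(st["sigma2_a"]), np.log(st["sigma2_a2"]),
          np.arctanh(np.clip(st["r_a"], -0.99, 0.99)),
          np.log(st["sigma2_e"]), np.log(st["sigma2_e2"])]
    if estimate_residual_cov:
        x0.append(np.arctanh(np.clip(st["r_e"], -0.99, 0.99)))
    else:
        x0.append(0.0)
    x0 = np.array(x0)
    free = [0, 1] + ([2] if estimate_genetic_cov else []) + [3, 4] \
        + ([5] if estimate_residual_cov else [])
    free = np.array(free)
    if not estimate_genetic_cov:
        x0[2] = 0.0

    def obj_free(tf):
        t = x0.copy()
        t[free] = tf
        return objective(t)

    opts = {"xatol": 1e-4, "fatol": 1e-6, "maxiter": 3000, "maxfev": 3000}
    if nm_options:
        opts.update(nm_options)
    res = _nelder_mead_restarts(obj_free, x0[free], opts)
    theta = x0.copy()
    theta[free] = res.x
    s2a1, s2a2, sa12, s2e1, s2e2, se12 = unpack(theta)
    fit = VarCompFit(
        sigma2_a=float(s2a1), sigma2_e=float(s2e1),
        sigma2_a2=float(s2a2), sigma2_e2=float(s2e2),
        sigma_a12=float(sa12), sigma_e12=float(se12),
        loglik=float(-0.5 * res.fun), n_iter=int(res.nit),
        converged=bool(res.success), method="direct-bivariate",
        n_records=parts.n1 + parts.n2, rank_X=parts.rank_X,
    )
    if compute_se:
        _bivariate_se(parts, fit, estimate_residual_cov)
    return fit


def _bivariate_se(parts: _BiParts, fit: VarCompFit, est_re: bool) -> None:
    x = np.array([fit.sigma2_a, fit.sigma2_a2, fit.sigma_a12,
                  fit.sigma2_e, fit.sigma2_e2]
                 + ([fit.sigma_e12] if est_re else []))

    def f(v):
        se12 = v[5] if est_re else 0.0
        m2ll, _ = _m2ll_bivariate(parts, v[0], v[1], v[2], v[3], v[4], se12)
        return m2ll

    steps = 1e-3 * np.maximum(np.abs(x), 1e-4 * max(x[0], x[3]))
    try:
        H = 0.5 * _fd_hessian(f, x, steps)
        cov = np.linalg.inv(H)
        names = ["sigma2_a", "sigma2_a2", "sigma_a12", "sigma2_e", "sigma2_e2"] \
            + (["sigma_e12"] if est_re else [])
        d = np.diag(cov)
        if np.any(d <= 0):
            return
        fit.se = dict(zip(names, np.sqrt(d)))
        fit.se["_cov"] = cov
        fit.se["_names"] = names
    except np.linalg.LinAlgError:
        return


def lrt_variance_component(
    fit_without: VarCompFit, fit_with: VarCompFit
) -> tuple[float, float]:
    """LRT for one variance component: 2*(l1 - l0) against chi2(1).

    The statistic is floored at zero (a numerically lower full-model
    likelihood is logged).  Significance at p <= 0.05, tendency at
    p <= 0.10, following the usual reporting convention.
    """
    if fit_without.n_records != fit_with.n_records:
        raise ModelError("LRT requires the same data in both fits")
    stat = 2.0 * (fit_with.loglik - fit_without.loglik)
    if stat < 0:
        if stat < -1e-6:
            warnings.warn(
                "full-model log-likelihood below reduced model; statistic floored at 0"
            )
        stat = 0.0
    p = float(chi2.sf(stat, df=1))
    return float(stat), p
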