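"""Pedigree relationship algebra and the animal mixed model.

The model for one trait is

    y = Xb + Za + sum_j W_j c_j + e,

with a ~ N(0, A sigma2_a) for the pedigree numerator relationship matrix A,
four i.i.d. random factors c_j ~ N(0, I sigma2_j), and e ~ N(0, I sigma2_e).
Fixed effects X hold the declared categorical factors plus, per tested
window, the ROH-class indicators (reference = the non-ROH class) and the
centered allele-count covariates of the SNPs inside the window (the additive
correction).  Variance components are supplied, held fixed across windows.

Henderson's mixed-model equations are solved by absorbing the random-effect
block: with Zt the stacked random design and M = Zt'Zt + D (D carrying
A-inverse and identity blocks times their variance ratios), the fixed-effect
normal matrix after absorption is

    S = X'X - (Zt'X)' M^{-1} (Zt'X),

whose inverse times sigma2_e is the sampling covariance of the fixed
solutions, from which class contrasts, standard errors and one-tailed t
tests are read.  M is factorized once per trait and reused for every window,
with per-SNP solve columns cached, which is what makes scanning thousands of
windows tractable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.linalg import splu
from scipy.stats import t as t_dist

from .data import Pedigree, VarianceComponents

logger = logging.getLogger("rohscan")

#: pivot tolerance for dropping collinear fixed-effect columns
RANK_TOL = 1e-8


class ModelError(RuntimeError):
    """Raised when a window model cannot be fitted."""


# ---------------------------------------------------------------------------
# Pedigree inbreeding and A-inverse
# ---------------------------------------------------------------------------

def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F by the Meuwissen & Luo recursion.

    Computes each diagonal a_ii = 1 + F_i of the numerator relationship
    matrix directly from the ancestral path coefficients, in O(n * depth)
    without forming A.
    """
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    D = np.zeros(n)  # Mendelian-sampling variance coefficients
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            D[i] = 0.75 - 0.25 * F[max(s, d)]
        else:
            D[i] = 1.0
            continue  # founder: F = 0
        if s < 0 or d < 0:
            continue  # one unknown parent: F = 0 (unrelated to known stock)
        # a_ii = sum over ancestors j of L_ij^2 * D_j
        coeff: dict[int, float] = {i: 1.0}
        aii = 0.0
        for j in range(i, -1, -1):
            c = coeff.pop(j, 0.0)
            if c == 0.0:
                continue
            aii += c * c * D[j]
            if sire[j] >= 0:
                coeff[sire[j]] = coeff.get(sire[j], 0.0) + 0.5 * c
            if dam[j] >= 0:
                coeff[dam[j]] = coeff.get(dam[j], 0.0) + 0.5 * c
        F[i] = aii - 1.0
    return F


def a_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sparse.csr_matrix:
    """Sparse inverse of the numerator relationship matrix.

    Henderson's rules with the inbreeding adjustment: each animal
    contributes 1/d_i to its own diagonal, -1/(2 d_i) to animal-parent
    cells and 1/(4 d_i) to parent-parent cells, where d_i is the
    Mendelian-sampling variance given the parents' inbreeding.
    """
    n = len(ped)
    if F is None:
        F = inbreeding(ped)
    sire, dam = ped.sire, ped.dam
    both = (sire >= 0) & (dam >= 0)
    one = (sire >= 0) ^ (dam >= 0)
    d = np.ones(n)
    d[both] = 0.5 - 0.25 * (F[sire[both]] + F[dam[both]])
    known = np.maximum(sire, dam)
    d[one] = 0.75 - 0.25 * F[known[one]]
    alpha = 1.0 / d

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    idx = np.arange(n)
    rows.append(idx); cols.append(idx); vals.append(alpha)
    for par in (sire, dam):
        has = par >= 0
        i, p = idx[has], par[has]
        half = -0.5 * alpha[has]
        rows.extend((i, p)); cols.extend((p, i)); vals.extend((half, half))
        quarter = 0.25 * alpha[has]
        rows.append(p); cols.append(p); vals.append(quarter)
    cross = both
    i, s, dd = idx[cross], sire[cross], dam[cross]
    q = 0.25 * alpha[cross]
    rows.extend((s, dd)); cols.extend((dd, s)); vals.extend((q, q))
    ainv = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n)).tocsr()
    ainv.sum_duplicates()
    return ainv


def relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    Quadratic in pedigree size; intended for moderate pedigrees and for
    generating correlated breeding values, not for model fitting.
    """
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


# ---------------------------------------------------------------------------
# Fixed-effect design helpers
# ---------------------------------------------------------------------------

def factor_design(column: pd.Series, drop_first: bool = True) -> np.ndarray:
    """Dense 0/1 dummy design for a categorical column (reference coding)."""
    codes, _ = pd.factorize(column, sort=True)
    k = codes.max() + 1
    X = np.zeros((len(codes), k))
    X[np.arange(len(codes)), codes] = 1.0
    return X[:, 1:] if drop_first else X


def factor_sparse(column: pd.Series) -> sparse.csr_matrix:
    """Sparse full-rank-free incidence matrix (one column per level)."""
    codes, uniq = pd.factorize(column, sort=True)
    n = len(codes)
    return sparse.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, len(uniq)))


# ---------------------------------------------------------------------------
# Absorption solver
# ---------------------------------------------------------------------------

@dataclass
class ClassEffect:
    """Contrast of one ROH class against the non-ROH reference."""

    class_id: str
    n_carriers: int
    effect: float
    se: float
    t: float
    p: float  # one-tailed, in the trait's unfavorable direction


@dataclass
class WindowFit:
    """Mixed-model results for one candidate window."""

    effects: list[ClassEffect]
    n_records: int
    fixed_rank: int
    dropped_covariates: list[int]  # SNP column indices dropped as collinear
    skipped_classes: list[str]


class MixedModelContext:
    """One trait's mixed-model machinery, reusable across windows.

    Parameters
    ----------
    y : response vector over phenotyped records (missing already removed).
    X_base : dense base fixed-effect design (intercept + factor dummies).
    animal_index : pedigree row index of each record's animal.
    ainv : sparse A-inverse over the full pedigree.
    iid_factors : list of per-record level codes for the i.i.d. random
        factors (each an int array).
    vc : variance components; components equal to zero drop their term.
    """

    def __init__(self, y: np.ndarray, X_base: np.ndarray,
                 animal_index: np.ndarray, ainv: sparse.spmatrix | None,
                 iid_factors: list[np.ndarray],
                 vc: VarianceComponents) -> None:
        self.y = np.asarray(y, dtype=float)
        self.n = len(self.y)
        self.X0 = np.asarray(X_base, dtype=float)
        self.vc = vc
        self.sigma2_e = vc.sigma2_e

        blocks: list[sparse.spmatrix] = []
        dblocks: list[sparse.spmatrix] = []
        n = self.n
        if vc.sigma2_a > 0:
            if ainv is None:
                raise ModelError("sigma2_a > 0 requires an A-inverse")
            q = ainv.shape[0]
            Za = sparse.csr_matrix(
                (np.ones(n), (np.arange(n), animal_index)), shape=(n, q))
            blocks.append(Za)
            dblocks.append(ainv * (vc.sigma2_e / vc.sigma2_a))
        for codes, s2 in zip(iid_factors, vc.iid_components):
            if s2 <= 0:
                continue
            q = int(codes.max()) + 1
            W = sparse.csr_matrix(
                (np.ones(n), (np.arange(n), codes)), shape=(n, q))
            blocks.append(W)
            dblocks.append(sparse.identity(q) * (vc.sigma2_e / s2))

        if blocks:
            self.Z = sparse.hstack(blocks, format="csr")
            D = sparse.block_diag(dblocks, format="csc")
            M = (self.Z.T @ self.Z + D).tocsc()
            self._lu = splu(M)
            self.Zt = self.Z.T.tocsr()
            self.Zy = self.Zt @ self.y
            self.my = self._lu.solve(self.Zy)  # M^{-1} Z'y
            T0 = np.asarray((self.Zt @ self.X0))
            self.T0 = T0
            self.U0 = self._lu.solve(T0) if T0.size else T0
        else:
            self.Z = None

        # absorbed base blocks
        self.X0y = self.X0.T @ self.y
        self.S00 = self.X0.T @ self.X0
        self.r0 = self.X0y.copy()
        if self.Z is not None and self.X0.size:
            self.S00 = self.S00 - self.T0.T @ self.U0
            self.r0 = self.r0 - self.T0.T @ self.my
        self.yy = float(self.y @ self.y)

        # genotype covariate caches (set by attach_genotypes)
        self.G = None

    # -- genotype covariates -------------------------------------------------

    def attach_genotypes(self, genotypes: np.ndarray) -> None:
        """Precompute absorbed cross-products for all SNP covariate columns.

        ``genotypes`` is the records x SNPs allele-count matrix; columns are
        centered here.  Memory is O(M^2 + q*M); for desk-scale genomes (a few
        thousand SNPs) this is the fast path that makes per-window fits a
        matter of slicing.
        """
        G = np.asarray(genotypes, dtype=float)
        G = G - G.mean(axis=0, keepdims=True)
        self.G = G
        self.Gy = G.T @ self.y
        self.QG = G.T @ G
        self.B0G = self.X0.T @ G if self.X0.size else np.zeros((0, G.shape[1]))
        if self.Z is not None:
            self.TG = np.asarray(self.Zt @ G)
            self.UG = self._lu.solve(self.TG)
            self.QG = self.QG - self.TG.T @ self.UG
            self.Gy = self.Gy - self.TG.T @ self.my
            if self.X0.size:
                self.B0G = self.B0G - self.T0.T @ self.UG

    # -- fitting -------------------------------------------------------------

    def fit_fixed(self, class_cols: np.ndarray,
                  snp_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, int,
                                                list[int]]:
        """Solve the absorbed fixed-effect system for [base | class | snp].

        Returns (solutions for class columns, covariance diag of class
        columns /sigma2_e, fixed rank, dropped snp column positions).
        Collinear SNP covariates (and degenerate base columns) are dropped
        by in-order pivoted elimination; class indicator columns are never
        dropped -- if one pivots to zero the window is unidentifiable and a
        ModelError is raised.
        """
        C = np.asarray(class_cols, dtype=float)
        k = C.shape[1]
        p0 = self.X0.shape[1]
        snp_idx = np.asarray(snp_idx, dtype=int)
        ns = len(snp_idx)
        if ns and self.G is None:
            raise ModelError("attach_genotypes() required for SNP covariates")

        m = p0 + k + ns
        S = np.empty((m, m))
        r = np.empty(m)
        sl0 = slice(0, p0)
        slc = slice(p0, p0 + k)
        sls = slice(p0 + k, m)

        S[sl0, sl0] = self.S00
        r[sl0] = self.r0
        # class columns: absorb via individual solves (k is small)
        Cy = C.T @ self.y
        X0C = self.X0.T @ C if p0 else np.zeros((0, k))
        CC = C.T @ C
        if self.Z is not None:
            TC = np.asarray(self.Zt @ C)
            UC = self._lu.solve(TC) if k else TC
            CC = CC - TC.T @ UC
            Cy = Cy - TC.T @ self.my
            if p0:
                X0C = X0C - self.T0.T @ UC
        S[slc, slc] = CC
        S[sl0, slc] = X0C
        S[slc, sl0] = X0C.T
        r[slc] = Cy
        if ns:
            Gw = self.G[:, snp_idx]
            S[sls, sls] = self.QG[np.ix_(snp_idx, snp_idx)]
            S[sl0, sls] = self.B0G[:, snp_idx]
            S[sls, sl0] = S[sl0, sls].T
            CG = C.T @ Gw
            if self.Z is not None:
                CG = CG - UC.T @ self.TG[:, snp_idx]
            S[slc, sls] = CG
            S[sls, slc] = CG.T
            r[sls] = self.Gy[snp_idx]

        # in-order symmetric elimination to find droppable columns
        A = S.copy()
        scale = np.maximum(np.abs(np.diag(S)), 1.0)
        dropped: list[int] = []
        for j in range(m):
            if A[j, j] <= RANK_TOL * scale[j]:
                if p0 <= j < p0 + k:
                    raise ModelError(
                        "ROH class indicator collinear with other fixed "
                        "effects; window not identifiable")
                dropped.append(j)
                A[j, :] = 0.0
                A[:, j] = 0.0
                continue
            piv = A[j, j]
            v = A[j + 1:, j] / piv
            A[j + 1:, j + 1:] -= np.outer(v, A[j, j + 1:])
            A[j + 1:, j] = 0.0
            A[j, j + 1:] = 0.0

        keep = np.setdiff1d(np.arange(m), np.array(dropped, dtype=int))
        Sk = S[np.ix_(keep, keep)]
        try:
            cf = cho_factor(Sk)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise ModelError(f"singular coefficient matrix: {exc}") from exc
        beta = cho_solve(cf, r[keep])
        cls_pos = np.searchsorted(keep, np.arange(p0, p0 + k))
        eye = np.zeros((len(keep), k))
        eye[cls_pos, np.arange(k)] = 1.0
        cov_cols = cho_solve(cf, eye)
        var_diag = cov_cols[cls_pos, np.arange(k)]
        dropped_snps = [int(snp_idx[j - p0 - k]) for j in dropped if j >= p0 + k]
        rank = len(keep)
        return beta[cls_pos], var_diag, rank, dropped_snps


def one_tailed_p(t: float, df: float, direction: str) -> float:
    """One-tailed p in the unfavorable direction of the trait."""
    if direction == "lower":
        return float(t_dist.cdf(t, df))
    return float(t_dist.sf(t, df))


def fit_window_model(ctx: MixedModelContext,
                     class_carriers: list[tuple[str, np.ndarray]],
                     snp_idx: np.ndarray,
                     direction: str) -> WindowFit:
    """Fit one window: ROH-class contrasts against the non-ROH reference.

    ``class_carriers`` maps class ids to boolean record masks (or index
    arrays) of their carriers.  Classes with fewer than 2 phenotyped
    carriers are skipped.  The one-tailed p is taken in the trait's
    unfavorable direction with df = N - rank(fixed).
    """
    n = ctx.n
    cols = []
    kept: list[tuple[str, int]] = []
    skipped: list[str] = []
    for cid, members in class_carriers:
        col = np.zeros(n)
        col[members] = 1.0
        nc = int(col.sum())
        if nc < 2:
            skipped.append(cid)
            logger.info("class %s skipped: %d phenotyped carriers", cid, nc)
            continue
        cols.append(col)
        kept.append((cid, nc))
    if not kept:
        return WindowFit([], n, 0, [], skipped)
    C = np.column_stack(cols)
    beta, vdiag, rank, dropped = ctx.fit_fixed(C, snp_idx)
    df = n - rank
    if df <= 0:
        raise ModelError("no residual degrees of freedom")
    effects = []
    for j, (cid, nc) in enumerate(kept):
        se = float(np.sqrt(max(vdiag[j], 0.0) * ctx.sigma2_e))
        if se <= 0:
            raise ModelError(f"non-positive standard error for class {cid}")
        t = float(beta[j]) / se
        effects.append(ClassEffect(cid, nc, float(beta[j]), se, t,
                                   one_tailed_p(t, df, direction)))
    return WindowFit(effects, n, rank, dropped, skipped)


# ---------------------------------------------------------------------------
# EM-REML variance components
# ---------------------------------------------------------------------------

def estimate_variance_components(
        y: np.ndarray, X: np.ndarray, animal_index: np.ndarray,
        ped: Pedigree, iid_factors: list[np.ndarray] | None = None,
        start: VarianceComponents | None = None,
        tol: float = 1e-6, max_iter: int = 500) -> VarianceComponents:
    """EM-REML for the null animal model (no ROH term).

    Dense implementation suitable for moderate data sizes; intended to
    produce the components that are then held fixed across all window fits.
    Deterministic: EM from a fixed start, with guarded Aitken extrapolation
    every few iterations to counter EM's slow linear convergence near a
    zero-variance boundary.  Convergence is declared when the largest
    component change, relative to the phenotypic variance, falls below
    ``tol``.  Components drifting negative are clamped at 1e-12 and flagged
    in the log.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.asarray(X, dtype=float)
    iid_factors = iid_factors or []
    var_y = float(np.var(y))
    if start is None:
        k = 2 + len(iid_factors)
        parts = [var_y / k] * 4
        s2 = dict(zip(("sigma2_HY", "sigma2_HRYS", "sigma2_SS", "sigma2_AIT"),
                      [var_y / k if j < len(iid_factors) else 0.0
                       for j in range(4)]))
        start = VarianceComponents(sigma2_a=var_y / k, sigma2_e=var_y / k,
                                   **s2)

    ainv = a_inverse(ped).toarray()
    nq = ainv.shape[0]
    Za = np.zeros((n, nq))
    Za[np.arange(n), animal_index] = 1.0
    designs = [("sigma2_a", Za, ainv)]
    names_iid = ("sigma2_HY", "sigma2_HRYS", "sigma2_SS", "sigma2_AIT")
    for j, codes in enumerate(iid_factors):
        q = int(codes.max()) + 1
        W = np.zeros((n, q))
        W[np.arange(n), codes] = 1.0
        designs.append((names_iid[j], W, np.eye(q)))

    p = X.shape[1]
    rank_x = np.linalg.matrix_rank(X) if p else 0
    comp = {name: getattr(start, name) for name, _, _ in designs}
    s2e = start.sigma2_e
    trace: list[dict[str, float]] = []

    # constant part of the coefficient matrix (D blocks added per iteration)
    dims = [p] + [Z.shape[1] for _, Z, _ in designs]
    tot = sum(dims)
    offs = np.cumsum([0] + dims)
    C0 = np.zeros((tot, tot))
    rhs = np.zeros(tot)
    mats = [X] + [Z for _, Z, _ in designs]
    for a in range(len(mats)):
        rhs[offs[a]:offs[a + 1]] = mats[a].T @ y
        for b in range(a, len(mats)):
            blk = mats[a].T @ mats[b]
            C0[offs[a]:offs[a + 1], offs[b]:offs[b + 1]] = blk
            if b != a:
                C0[offs[b]:offs[b + 1], offs[a]:offs[a + 1]] = blk.T

    def em_step(comp: dict[str, float], s2e: float
                ) -> tuple[dict[str, float], float]:
        C = C0.copy()
        for j, (name, _, K) in enumerate(designs):
            lam = s2e / max(comp[name], 1e-12)
            sl = slice(offs[j + 1], offs[j + 2])
            C[sl, sl] += K * lam
        Cinv = np.linalg.pinv(C) if p and rank_x < p else np.linalg.inv(C)
        sol = Cinv @ rhs
        new = {}
        for j, (name, _, K) in enumerate(designs):
            sl = slice(offs[j + 1], offs[j + 2])
            u = sol[sl]
            val = (u @ (K @ u)
                   + s2e * np.trace(K @ Cinv[sl, sl])) / dims[j + 1]
            if val < 1e-12:
                logger.warning("EM-REML: %s clamped at 1e-12", name)
                val = 1e-12
            new[name] = float(val)
        return new, float((y @ y - sol @ rhs) / (n - rank_x))

    names = [name for name, _, _ in designs] + ["sigma2_e"]
    hist: list[np.ndarray] = []
    converged = False
    prev = np.array([comp[nm] for nm, _, _ in designs] + [s2e])
    for it in range(max_iter):
        new, s2e_new = em_step(comp, s2e)
        vec = np.array([new[nm] for nm, _, _ in designs] + [s2e_new])
        hist.append(vec)
        jumped = False
        # guarded Aitken extrapolation against slow linear convergence
        if len(hist) >= 3 and it % 4 == 3:
            d1 = hist[-2] - hist[-3]
            d2 = hist[-1] - hist[-2]
            denom = d2 - d1
            with np.errstate(divide="ignore", invalid="ignore"):
                acc = hist[-1] - np.where(np.abs(denom) > 1e-300,
                                          d2 * d2 / denom, 0.0)
            # extrapolate only monotone, contracting component sequences;
            # sigma2_e (last entry) converges fast and a spurious jump to
            # zero residual variance would be absorbing, so leave it alone
            ok = (np.isfinite(acc) & (acc >= 1e-12) & (acc <= 10 * var_y)
                  & (d1 * d2 > 0) & (np.abs(d2) < np.abs(d1)))
            ok[-1] = False
            if ok.any():
                vec = np.where(ok, acc, vec)
                jumped = True
            hist = [vec]
        rel = float(np.max(np.abs(vec - prev))) / max(var_y, 1e-12)
        prev = vec
        comp = dict(zip([nm for nm, _, _ in designs], vec[:-1]))
        s2e = float(vec[-1])
        trace.append(dict(zip(names, vec)))
        # a convergence claim must come from a plain EM step, not a jump
        if rel < tol and not jumped:
            converged = True
            break
    if not converged:
        raise ModelError(
            f"EM-REML did not converge in {max_iter} iterations; "
            f"trace tail: {trace[-3:]}")

    full = {nm: 0.0 for nm in names_iid}
    full.update({nm: v for nm, v in comp.items() if nm in names_iid})
    return VarianceComponents(sigma2_a=comp["sigma2_a"], sigma2_e=s2e, **full)
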