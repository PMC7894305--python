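"""Expected joint SFS under a two-population multi-epoch demography.

The expected unfolded spectrum is computed by integrating the closed
system of ordinary differential equations satisfied by the moments of
the two-population Wright-Fisher diffusion, evaluated directly at the
sample sizes of interest (the approach of moment-based SFS inference):

* genetic drift in each population contributes a tridiagonal operator in
  that population's derived-allele-count index, closed at the sample
  order;
* migration couples the two indices and requires the spectrum at one
  additional sample in the source population.  That order-(n+1) spectrum
  is estimated from the order-n spectrum with a jackknife that is exact
  for locally quadratic allele-frequency densities and then corrected to
  satisfy, exactly, the hypergeometric downward-projection identity
  linking the two orders (the correction removes most of the error the
  plain quadratic fit makes on the 1/x-singular SFS density and on
  boundary classes that mix in point masses of fixed differences);
* an infinite-sites mutation influx feeds the single-derived-copy class
  of each population at rate ``n/2`` per unit theta.

Time is measured in units of ``2 N_ref`` generations, migration rates in
units of ``2 N_ref m``, and spectra are reported per unit
``theta = 4 N_ref mu L``.  Within an epoch coefficients are constant and
the linear system is advanced by Crank-Nicolson steps with a prefactored
sparse LU.  Spectra are integrated at an internal order ``n + buffer``
and projected down: the exact moment hierarchy is sampling-consistent,
so closure error enters only at the top order, where the jackknife is
most accurate.

Genomic islands use a mixture applied at epoch boundaries: the state at
an epoch's end is ``(1 - P) * [state evolved at the epoch's migration
rates] + P * [state evolved with rates scaled by b]``, both branches
starting from the mixed state at the epoch's start.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.special import gammaln

from .demography import DemographicModel, Epoch, bind_parameters
from .sfs import JointSFS, projection_matrix


class EngineError(RuntimeError):
    """Numerical failure in the spectrum computation."""


@dataclass(frozen=True)
class EngineConfig:
    """Numerical knobs for the ODE integration.

    dt_fac
        Time-step factor: the Crank-Nicolson step is
        ``dt_fac * min(nu1, nu2, 1 / (1 + m12 + m21))``, capped by the
        epoch duration.  Halving it quarters the O(dt^2) stepping error.
    order_buffer
        Extra samples per population at which the system is integrated
        before exact projection down to the requested sizes.
    neg_tol
        Entries more negative than ``-neg_tol * max(|spectrum|)`` raise
        an error; smaller negative round-off is clipped to zero.
    """

    dt_fac: float = 0.02
    order_buffer: int = 5
    neg_tol: float = 1e-2
    scheme: str = "split"   # "split" (fast Strang ADI) or "cn" (full CN)


DEFAULT_CONFIG = EngineConfig()


# -- operators ---------------------------------------------------------------

@lru_cache(maxsize=64)
def drift_matrix(n: int) -> sp.csr_matrix:
    """Tridiagonal drift operator at sample size n (rate 1/nu applied later)."""
    D = sp.lil_matrix((n + 1, n + 1))
    for i in range(n + 1):
        D[i, i] = -2.0 * i * (n - i)
        if i >= 1:
            D[i, i - 1] = (i - 1) * (n - i + 1)
        if i + 1 <= n:
            D[i, i + 1] = (i + 1) * (n - i - 1)
    return (0.5 * D).tocsr()


def _bernstein_moments(m: int, i: int) -> np.ndarray:
    """Integrals of 1, x, x^2 against the Bernstein sampling kernel C(m,i)x^i(1-x)^(m-i)."""
    return np.array([
        1.0 / (m + 1),
        (i + 1) / ((m + 1) * (m + 2)),
        (i + 1) * (i + 2) / ((m + 1) * (m + 2) * (m + 3)),
    ])


@lru_cache(maxsize=64)
def jackknife_matrix(n: int) -> np.ndarray:
    """(n+2, n+1) closure estimating the order-(n+1) spectrum from order n.

    A 3-point quadratic-exactness fit per target entry, projected onto the
    affine manifold of extensions that reproduce the order-n spectrum
    exactly under hypergeometric downward projection.  Requires n >= 4.
    """
    if n < 4:
        raise EngineError("jackknife closure requires sample size >= 4")
    J = np.zeros((n + 2, n + 1))
    for ip in range(n + 2):
        c = int(round(ip * n / (n + 1.0)))
        c = min(max(c, 2), n - 2)
        cols = [c - 1, c, c + 1]
        A = np.column_stack([_bernstein_moments(n, j) for j in cols])
        J[ip, cols] = np.linalg.solve(A, _bernstein_moments(n + 1, ip))
    # exact projection identity: P @ Phi^{n+1} = Phi^n
    P = np.zeros((n + 1, n + 2))
    for i in range(n + 1):
        P[i, i] = (n + 1 - i) / (n + 1)
        P[i, i + 1] = (i + 1) / (n + 1)
    return J + np.linalg.pinv(P) @ (np.eye(n + 1) - P @ J)


def _migration_entries(n1: int, n2: int, into_pop1: bool):
    """Sparse triplets of the exact migration term against the extended order."""
    rows, cols, vals = [], [], []
    next2 = n2 + 2 if into_pop1 else n2 + 1
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            r = i * (n2 + 1) + j
            if into_pop1:
                terms = [(i - 1, j + 1, (j + 1) * (n1 - i + 1)),
                         (i, j + 1, -(j + 1) * (n1 - i)),
                         (i, j, -i * (n2 + 1 - j)),
                         (i + 1, j, (i + 1) * (n2 + 1 - j))]
                imax, jmax, denom = n1, n2 + 1, n2 + 1
            else:
                terms = [(i + 1, j - 1, (i + 1) * (n2 - j + 1)),
                         (i + 1, j, -(i + 1) * (n2 - j)),
                         (i, j, -j * (n1 + 1 - i)),
                         (i, j + 1, (j + 1) * (n1 + 1 - i))]
                imax, jmax, denom = n1 + 1, n2, n1 + 1
            for ii, jj, v in terms:
                if 0 <= ii <= imax and 0 <= jj <= jmax and v != 0:
                    rows.append(r)
                    cols.append(ii * next2 + jj)
                    vals.append(v / denom)
    shape = ((n1 + 1) * (n2 + 1),
             (n1 + 1) * (n2 + 2) if into_pop1 else (n1 + 2) * (n2 + 1))
    return sp.csr_matrix((vals, (rows, cols)), shape=shape)


@lru_cache(maxsize=16)
def _operators(n1: int, n2: int):
    """Cached constant operators at a given sample-size pair."""
    I1 = sp.identity(n1 + 1, format="csr")
    I2 = sp.identity(n2 + 1, format="csr")
    A_d1 = sp.kron(drift_matrix(n1), I2, format="csr")
    A_d2 = sp.kron(I1, drift_matrix(n2), format="csr")
    ext2 = sp.kron(I1, sp.csr_matrix(jackknife_matrix(n2)), format="csr")
    ext1 = sp.kron(sp.csr_matrix(jackknife_matrix(n1)), I2, format="csr")
    A_m12 = (_migration_entries(n1, n2, True) @ ext2).tocsr()
    A_m21 = (_migration_entries(n1, n2, False) @ ext1).tocsr()
    src = np.zeros((n1 + 1) * (n2 + 1))
    src[1 * (n2 + 1)] = n1 / 2.0
    src[1] = n2 / 2.0
    if src.size <= _DENSE_LIMIT:  # dense algebra is faster at fitting sizes
        return (A_d1.toarray(), A_d2.toarray(), A_m12.toarray(),
                A_m21.toarray(), src)
    return A_d1, A_d2, A_m12, A_m21, src


# -- integration -------------------------------------------------------------

def equilibrium_1d(n: int) -> np.ndarray:
    """Standard neutral equilibrium spectrum xi_i = theta/i (per unit theta)."""
    phi = np.zeros(n + 1)
    phi[1:n] = 1.0 / np.arange(1, n)
    return phi


#: above this dimension the Crank-Nicolson step uses sparse LU instead of dense
_DENSE_LIMIT = 1600


def _crank_nicolson(x: np.ndarray, A: sp.spmatrix, src: np.ndarray,
                    T: float, dt: float) -> np.ndarray:
    if T <= 0:
        return x
    nsteps = max(int(np.ceil(T / dt)), 1)
    dt = T / nsteps
    dim = A.shape[0]
    try:
        if dim <= _DENSE_LIMIT or not sp.issparse(A):
            from scipy.linalg import lu_factor, lu_solve
            Ad = A.toarray() if sp.issparse(A) else np.asarray(A)
            lhs = lu_factor(np.eye(dim) - (dt / 2.0) * Ad)
            rhs = np.eye(dim) + (dt / 2.0) * Ad
            for _ in range(nsteps):
                x = lu_solve(lhs, rhs @ x + dt * src)
        else:
            I = sp.identity(dim, format="csc")
            lu = splu((I - (dt / 2.0) * A).tocsc())
            rhs = (I + (dt / 2.0) * A).tocsr()
            for _ in range(nsteps):
                x = lu.solve(rhs @ x + dt * src)
    except (RuntimeError, np.linalg.LinAlgError) as exc:
        raise EngineError(f"integration failed: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise EngineError(f"non-finite spectrum during integration (T={T}, dt={dt})")
    return x


def integrate_1d(phi: np.ndarray, nu: float, T: float,
                 config: EngineConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Advance a single-population spectrum (drift + mutation influx)."""
    n = len(phi) - 1
    src = np.zeros(n + 1)
    src[1] = n / 2.0
    A = (1.0 / nu) * drift_matrix(n)
    dt = min(config.dt_fac * nu, T) if T > 0 else 1.0
    return _crank_nicolson(phi.copy(), A, src, T, dt)


def _drift_tridiag(n: int):
    """(sub, diag, super) bands of the drift operator at sample size n."""
    i = np.arange(n + 1, dtype=np.float64)
    diag = -1.0 * i * (n - i)
    sub = 0.5 * (i[1:] - 1) * (n - i[1:] + 1)      # coefficient of phi_{i-1}
    sup = 0.5 * (i[:-1] + 1) * (n - i[:-1] - 1)    # coefficient of phi_{i+1}
    return sub, diag, sup


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a soft dependency
    _njit = None


def _py_strang_epoch(x, sub1, dia1, sup1, sub2, dia2, sup2,
                     mig_indptr, mig_indices, mig_data, src, T, dt0, nsub):
    """Strang-split epoch integrator (pure-python reference).

    Per step: half-step implicit (Crank-Nicolson) drift along each axis,
    a full RK2 step of migration + mutation influx, then the drift
    half-steps in reverse order.  Second-order accurate in dt.
    """
    n1p, n2p = x.shape
    nsteps = max(int(np.ceil(T / dt0)), 1)
    dt = T / nsteps

    def cn_half(x, sub, dia, sup, axis):
        a = dt / 4.0
        if axis == 1:
            x = x.T
        m = x.shape[0]
        rhs = x * (1.0 + a * dia)[:, None]
        rhs[:-1] += a * sup[:, None] * x[1:]
        rhs[1:] += a * sub[:, None] * x[:-1]
        # Thomas on (I - a D)
        dl = -a * sub
        d = 1.0 - a * dia
        du = -a * sup
        cp = np.empty_like(du)
        xp = np.empty_like(rhs)
        cp[0] = du[0] / d[0]
        xp[0] = rhs[0] / d[0]
        for i in range(1, m):
            denom = d[i] - (dl[i - 1] * cp[i - 1] if i - 1 < len(dl) else 0.0)
            if i < m - 1:
                cp[i] = du[i] / denom
            xp[i] = (rhs[i] - dl[i - 1] * xp[i - 1]) / denom
        out = np.empty_like(rhs)
        out[m - 1] = xp[m - 1]
        for i in range(m - 2, -1, -1):
            out[i] = xp[i] - cp[i] * out[i + 1]
        return out.T if axis == 1 else out

    def mig_rate(v):
        out = np.zeros_like(v)
        for r in range(len(out)):
            acc = 0.0
            for k in range(mig_indptr[r], mig_indptr[r + 1]):
                acc += mig_data[k] * v[mig_indices[k]]
            out[r] = acc
        return out + src

    for _ in range(nsteps):
        x = cn_half(x, sub1, dia1, sup1, 0)
        x = cn_half(x, sub2, dia2, sup2, 1)
        v = x.ravel().copy()
        h = dt / nsub
        for _s in range(nsub):
            k1 = mig_rate(v)
            k2 = mig_rate(v + 0.5 * h * k1)
            v = v + h * k2
        x = v.reshape(n1p, n2p)
        x = cn_half(x, sub2, dia2, sup2, 1)
        x = cn_half(x, sub1, dia1, sup1, 0)
    return x


if _njit is not None:
    @_njit(cache=True)
    def _nb_strang_epoch(x, sub1, dia1, sup1, sub2, dia2, sup2,
                         mig_indptr, mig_indices, mig_data, src, T, dt0,
                         nsub):
        n1p, n2p = x.shape
        nsteps = max(int(np.ceil(T / dt0)), 1)
        dt = T / nsteps
        a = dt / 4.0
        v = np.empty(n1p * n2p)
        k1 = np.empty(n1p * n2p)
        k2 = np.empty(n1p * n2p)
        vmid = np.empty(n1p * n2p)
        rhs0 = np.empty((n1p, n2p))
        cp0 = np.empty(n1p)
        rhs1 = np.empty((n2p, n1p))
        cp1 = np.empty(n2p)
        for _ in range(nsteps):
            for half in range(2):
                # axis 0 CN half-step
                for j in range(n2p):
                    for i in range(n1p):
                        r = (1.0 + a * dia1[i]) * x[i, j]
                        if i + 1 < n1p:
                            r += a * sup1[i] * x[i + 1, j]
                        if i > 0:
                            r += a * sub1[i - 1] * x[i - 1, j]
                        rhs0[i, j] = r
                for j in range(n2p):
                    d0 = 1.0 - a * dia1[0]
                    cp0[0] = -a * sup1[0] / d0
                    rhs0[0, j] = rhs0[0, j] / d0
                    for i in range(1, n1p):
                        dl = -a * sub1[i - 1]
                        denom = (1.0 - a * dia1[i]) - dl * cp0[i - 1]
                        if i < n1p - 1:
                            cp0[i] = -a * sup1[i] / denom
                        rhs0[i, j] = (rhs0[i, j] - dl * rhs0[i - 1, j]) / denom
                    for i in range(n1p - 2, -1, -1):
                        rhs0[i, j] -= cp0[i] * rhs0[i + 1, j]
                for j in range(n2p):
                    for i in range(n1p):
                        x[i, j] = rhs0[i, j]
                # axis 1 CN half-step
                for i in range(n1p):
                    for j in range(n2p):
                        r = (1.0 + a * dia2[j]) * x[i, j]
                        if j + 1 < n2p:
                            r += a * sup2[j] * x[i, j + 1]
                        if j > 0:
                            r += a * sub2[j - 1] * x[i, j - 1]
                        rhs1[j, i] = r
                for i in range(n1p):
                    d0 = 1.0 - a * dia2[0]
                    cp1[0] = -a * sup2[0] / d0
                    rhs1[0, i] = rhs1[0, i] / d0
                    for j in range(1, n2p):
                        dl = -a * sub2[j - 1]
                        denom = (1.0 - a * dia2[j]) - dl * cp1[j - 1]
                        if j < n2p - 1:
                            cp1[j] = -a * sup2[j] / denom
                        rhs1[j, i] = (rhs1[j, i] - dl * rhs1[j - 1, i]) / denom
                    for j in range(n2p - 2, -1, -1):
                        rhs1[j, i] -= cp1[j] * rhs1[j + 1, i]
                for i in range(n1p):
                    for j in range(n2p):
                        x[i, j] = rhs1[j, i]
                if half == 0:
                    # migration + mutation influx between the half-steps:
                    # nsub RK2 subcycles keep the explicit substep stable
                    # without shrinking the (implicit) drift step
                    idx = 0
                    for i in range(n1p):
                        for j in range(n2p):
                            v[idx] = x[i, j]
                            idx += 1
                    h = dt / nsub
                    for _s in range(nsub):
                        for r in range(n1p * n2p):
                            acc = 0.0
                            for k in range(mig_indptr[r], mig_indptr[r + 1]):
                                acc += mig_data[k] * v[mig_indices[k]]
                            k1[r] = acc + src[r]
                        for r in range(n1p * n2p):
                            vmid[r] = v[r] + 0.5 * h * k1[r]
                        for r in range(n1p * n2p):
                            acc = 0.0
                            for k in range(mig_indptr[r], mig_indptr[r + 1]):
                                acc += mig_data[k] * vmid[mig_indices[k]]
                            k2[r] = acc + src[r]
                        for r in range(n1p * n2p):
                            v[r] = v[r] + h * k2[r]
                    idx = 0
                    for i in range(n1p):
                        for j in range(n2p):
                            x[i, j] = v[idx]
                            idx += 1
        return x
else:  # pragma: no cover
    _nb_strang_epoch = None


@lru_cache(maxsize=16)
def _split_operators(n1: int, n2: int):
    """Cached pieces for the Strang-split integrator: drift bands per axis,
    the two migration CSR operators on a shared (aligned) sparsity pattern,
    their row-sum norms, and the mutation source."""
    I1 = sp.identity(n1 + 1, format="csr")
    I2 = sp.identity(n2 + 1, format="csr")
    ext2 = sp.kron(I1, sp.csr_matrix(jackknife_matrix(n2)), format="csr")
    ext1 = sp.kron(sp.csr_matrix(jackknife_matrix(n1)), I2, format="csr")
    A12 = (_migration_entries(n1, n2, True) @ ext2).tocsr()
    A21 = (_migration_entries(n1, n2, False) @ ext1).tocsr()
    union = (abs(A12) + abs(A21)).tocsr()
    union.sort_indices()
    rows, cols = union.nonzero()
    d12 = np.asarray(A12[rows, cols]).ravel()
    d21 = np.asarray(A21[rows, cols]).ravel()
    def _rho(A):
        # power iteration on |A|: a realistic stability scale for the
        # explicit substep (the row-sum norm overestimates severalfold)
        B = abs(A)
        v = np.ones(B.shape[1])
        for _ in range(50):
            w = B @ v
            nrm = np.linalg.norm(w)
            if nrm == 0:
                return 0.0
            v = w / nrm
        return float(nrm)

    norm12 = _rho(A12)
    norm21 = _rho(A21)
    src = np.zeros((n1 + 1) * (n2 + 1))
    src[1 * (n2 + 1)] = n1 / 2.0
    src[1] = n2 / 2.0
    return {"indptr": union.indptr, "indices": union.indices,
            "d12": d12, "d21": d21, "norm12": norm12, "norm21": norm21,
            "bands1": _drift_tridiag(n1), "bands2": _drift_tridiag(n2),
            "src": src}


def integrate_epoch(Phi: np.ndarray, epoch: Epoch, island_branch: bool = False,
                    config: EngineConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Advance the joint spectrum through one epoch (one migration class)."""
    n1, n2 = Phi.shape[0] - 1, Phi.shape[1] - 1
    scale = epoch.b if island_branch else 1.0
    m12, m21 = scale * epoch.m12, scale * epoch.m21
    dt = config.dt_fac * min(epoch.nu1, epoch.nu2, 1.0)
    if epoch.T <= 0:
        return Phi.copy()
    if config.scheme == "split":
        ops = _split_operators(n1, n2)
        data = m12 * ops["d12"] + m21 * ops["d21"]
        # the drift-migration splitting error grows as m * dt^2, so the
        # step shrinks with the migration rate; the explicit migration
        # substep is additionally subcycled to stay inside its stability
        # region
        dt = dt / (1.0 + m12 + m21)
        rate = m12 * ops["norm12"] + m21 * ops["norm21"]
        nsub = max(1, int(np.ceil(1.25 * dt * rate)))
        sub1, dia1, sup1 = ops["bands1"]
        sub2, dia2, sup2 = ops["bands2"]
        kernel = _nb_strang_epoch if _nb_strang_epoch is not None \
            else _py_strang_epoch
        x = kernel(Phi.astype(np.float64).copy(),
                   sub1 / epoch.nu1, dia1 / epoch.nu1, sup1 / epoch.nu1,
                   sub2 / epoch.nu2, dia2 / epoch.nu2, sup2 / epoch.nu2,
                   ops["indptr"], ops["indices"], data, ops["src"],
                   float(epoch.T), dt, nsub)
        if not np.all(np.isfinite(x)):
            raise EngineError(f"non-finite spectrum during integration "
                              f"(T={epoch.T}, dt={dt})")
        return x
    A_d1, A_d2, A_m12, A_m21, src = _operators(n1, n2)
    A = ((1.0 / epoch.nu1) * A_d1 + (1.0 / epoch.nu2) * A_d2
         + m12 * A_m12 + m21 * A_m21)
    # Crank-Nicolson is A-stable; the step only needs to resolve the
    # slowest-decaying drift scale, not the stiff migration modes
    x = _crank_nicolson(Phi.ravel().copy(), A, src, epoch.T, dt)
    return x.reshape(Phi.shape)


def split_spectrum(phi_anc: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Partition an ancestral 1-D spectrum into the joint spectrum at a split."""
    n = n1 + n2
    if len(phi_anc) != n + 1:
        raise EngineError("ancestral spectrum must have n1+n2 alleles")
    lg = gammaln(np.arange(n + 2))

    def logc(a, b):
        return lg[a + 1] - lg[b + 1] - lg[a - b + 1]

    Phi = np.zeros((n1 + 1, n2 + 1))
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            k = i + j
            Phi[i, j] = phi_anc[k] * np.exp(logc(n1, i) + logc(n2, j) - logc(n, k))
    return Phi


def _clip_negatives(counts: np.ndarray, config: EngineConfig) -> np.ndarray:
    floor = -config.neg_tol * max(np.abs(counts).max(), 1e-300)
    if counts.min() < floor:
        raise EngineError(
            f"negative spectrum entries beyond tolerance: min={counts.min():.3e}, "
            f"allowed {floor:.3e}; refine dt_fac or check parameters")
    return np.clip(counts, 0.0, None)


def expected_sfs(model: DemographicModel, values, n1: int, n2: int,
                 config: EngineConfig = DEFAULT_CONFIG,
                 pop_labels: tuple[str, str] = ("pop1", "pop2")) -> JointSFS:
    """Expected unfolded joint SFS per unit theta for a bound model.

    Starts from the ancestral equilibrium (optionally perturbed by an
    ancestral size change), splits, integrates each epoch's drift,
    migration and mutation influx, applies the island mixture at epoch
    boundaries, and projects to the requested sample sizes.
    """
    if n1 < 2 or n2 < 2:
        raise EngineError("sample sizes must be >= 2")
    anc, epochs = bind_parameters(model, values)
    N1, N2 = n1 + config.order_buffer, n2 + config.order_buffer
    phi = equilibrium_1d(N1 + N2)
    if anc is not None:
        phi = integrate_1d(phi, anc.nu1, anc.T, config)
    Phi = split_spectrum(phi, N1, N2)
    for epoch in epochs:
        if epoch.P > 0 and epoch.b < 1 and (epoch.m12 > 0 or epoch.m21 > 0):
            Phi_main = integrate_epoch(Phi, epoch, False, config)
            Phi_isl = integrate_epoch(Phi, epoch, True, config)
            Phi = (1.0 - epoch.P) * Phi_main + epoch.P * Phi_isl
        else:
            Phi = integrate_epoch(Phi, epoch, False, config)
    if config.order_buffer:
        P1 = projection_matrix(N1, n1)
        P2 = projection_matrix(N2, n2)
        Phi = P1 @ Phi @ P2.T
    return JointSFS(_clip_negatives(Phi, config), polarized=True,
                    pop_labels=pop_labels)


def mixture_sfs(model: DemographicModel, values, n1: int, n2: int,
                config: EngineConfig = DEFAULT_CONFIG) -> JointSFS:
    """Expected SFS for a genomic-island mixture model (requires islands)."""
    if not model.islands:
        raise EngineError(f"model {model.id!r} has no island parameters")
    return expected_sfs(model, values, n1, n2, config)


def residuals(data: JointSFS, model_sfs: JointSFS, theta: float) -> np.ndarray:
    """Variance-stabilized Poisson residuals (data - theta*model)/sqrt(theta*model).

    Masked corner entries are NaN; cells where the model is zero but the
    data are not yield infinite residuals (reported, not raised).
    """
    if data.counts.shape != model_sfs.counts.shape:
        raise EngineError("data and model spectra have different shapes")
    expected = theta * model_sfs.counts
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (data.counts - expected) / np.sqrt(expected)
        r[(expected == 0) & (data.counts > 0)] = np.inf
        r[(expected == 0) & (data.counts == 0)] = 0.0
    r[~data.mask] = np.nan
    return r
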