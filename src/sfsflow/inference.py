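"""Model fitting, ranking, bootstrap uncertainty and unit conversion.

Fitting maximizes the Poisson composite likelihood of the observed joint
SFS: cells are treated as independent Poisson counts with mean
``theta * model``, where the scale ``theta = 4 N_ref mu L`` has the
analytic maximizer ``theta_hat = sum(data) / sum(model)`` over unmasked
entries.  Free parameters are optimized on a log scale by bounded
multi-start Nelder-Mead.  Models are ranked by AIC following the
information-theoretic workflow: per-model delta-AIC, relative likelihood
``exp(-delta/2)``, Akaike weights (model probabilities), and evidence
ratio of the best model against each alternative; the evidence ratio is
carried in log space so ratios of order 1e300 do not overflow.

Uncertainty comes from a nonparametric bootstrap that resamples SNPs
(site-table rows) with replacement, rebuilds the spectrum and refits.
Fitted parameters are converted to natural units with
``N_ref = theta_hat / (4 mu L)``: sizes in individuals, epoch boundaries
in years before present, migration both as fraction replaced per
generation and as migrants per generation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .demography import DemographicModel, bind_parameters
from .engine import DEFAULT_CONFIG, EngineConfig, expected_sfs
from .sfs import JointSFS, build_sfs

LIKELIHOOD_FLOOR = 1e-300


class InferenceError(RuntimeError):
    pass


@dataclass
class FitResult:
    model: DemographicModel
    params: np.ndarray            # natural scale, order = model.param_names
    log_likelihood: float
    theta_hat: float
    n_starts: int = 1
    seed: int | None = None
    converged: bool = True
    start_logliks: tuple[float, ...] = ()
    at_bounds: tuple[str, ...] = ()

    @property
    def aic(self) -> float:
        return 2.0 * self.model.k - 2.0 * self.log_likelihood

    def params_dict(self) -> dict[str, float]:
        return dict(zip(self.model.param_names, map(float, self.params)))


def poisson_loglik(data: JointSFS, model_sfs: JointSFS) -> tuple[float, float]:
    """Composite log-likelihood and analytic scale theta_hat.

    ``theta_hat = sum(data)/sum(model)`` over unmasked entries;
    ``LL = sum d ln(theta m) - theta m - ln Gamma(d+1)``.
    """
    if data.counts.shape != model_sfs.counts.shape:
        raise InferenceError("data and model spectra have different shapes")
    mask = data.mask
    if not mask.any():
        raise InferenceError("all spectrum entries are masked")
    d = data.counts[mask]
    m = np.maximum(model_sfs.counts[mask], LIKELIHOOD_FLOOR)
    msum = m.sum()
    theta = float(d.sum() / msum) if msum > 0 else 0.0
    mu = np.maximum(theta * m, LIKELIHOOD_FLOOR)
    ll = float(np.sum(d * np.log(mu) - mu - gammaln(d + 1.0)))
    return ll, theta


def _objective(logx, model, data, n1, n2, bounds, config):
    x = np.exp(logx)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    xc = np.clip(x, lo, hi)
    # quadratic penalty keeps Nelder-Mead inside the box without a cliff
    penalty = float(np.sum((np.log(x) - np.log(xc)) ** 2)) * 1e3
    try:
        m = expected_sfs(model, xc, n1, n2, config)
    except Exception:
        return 1e12
    ll, _ = poisson_loglik(data, m)
    return -ll + penalty


#: smallest value the log-space optimizer will consider per parameter kind
_LOG_FLOOR = {"nu": 1e-3, "T": 1e-3, "m": 1e-3, "P": 1e-4, "b": 1e-4}


def fit_model(data: JointSFS, model: DemographicModel, n_starts: int = 10,
              seed: int | None = None, init=None,
              config: EngineConfig = DEFAULT_CONFIG,
              maxiter: int | None = None, fold_perturb: float = 3.0,
              polish: bool = True, polish_maxiter: int | None = None) -> FitResult:
    """Multi-start maximum composite-likelihood fit of one model.

    Starts are drawn by log-uniform perturbation (up to ``fold_perturb``-
    fold) around ``init`` (default: typical demographic scales, e.g.
    nu = 1, T = 0.3); each start runs bounded Nelder-Mead on log
    parameters; the best start is then polished by a fresh Nelder-Mead
    restart (a restarted simplex escapes the degenerate simplices the
    first pass can end on).  Fully reproducible for a given seed.
    """
    if n_starts < 1:
        raise InferenceError("n_starts must be >= 1")
    from .demography import param_kind
    kdim = model.k
    floors = np.array([_LOG_FLOOR[param_kind(n)] for n in model.param_names])
    bounds = tuple((max(lo, f), hi)
                   for (lo, hi), f in zip(model.bounds, floors))
    rng = np.random.default_rng(seed)
    if init is None:
        init = np.array(model.typical_start)
    else:
        init = np.asarray(init, dtype=float)
        if init.shape != (kdim,):
            raise InferenceError(f"init must have {kdim} entries")
    if maxiter is None:
        maxiter = 300 * kdim
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    opts = {"maxiter": maxiter, "fatol": 1e-6, "xatol": 1e-5,
            "adaptive": kdim > 4}
    args = (model, data, data.n1, data.n2, bounds, config)
    best = None
    start_lls = []
    for s in range(n_starts):
        x0 = np.clip(init * fold_perturb ** rng.uniform(-1, 1, size=kdim),
                     lo, hi)
        res = minimize(_objective, np.log(x0), method="Nelder-Mead",
                       args=args, options=opts)
        start_lls.append(-res.fun)
        if best is None or -res.fun > -best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise InferenceError(
            f"no optimization start converged for {model.id}; "
            f"start losses: {[-l for l in start_lls]}")
    if polish:
        popts = dict(opts, maxiter=polish_maxiter or 2 * maxiter)
        for _ in range(2):
            res = minimize(_objective, best.x, method="Nelder-Mead",
                           args=args, options=popts)
            gain = best.fun - res.fun
            if res.fun < best.fun:
                best = res
            if gain < 1e-4:
                break
    x = np.clip(np.exp(best.x), lo, hi)
    at_bounds = tuple(
        name for name, v, l, h in zip(model.param_names, x, lo, hi)
        if v <= l * 1.0001 or v >= h * 0.9999)
    m = expected_sfs(model, x, data.n1, data.n2, config)
    ll, theta = poisson_loglik(data, m)
    return FitResult(model=model, params=x, log_likelihood=ll, theta_hat=theta,
                     n_starts=n_starts, seed=seed, converged=bool(best.success),
                     start_logliks=tuple(start_lls), at_bounds=at_bounds)


def rank_models(fits: list[FitResult]) -> pd.DataFrame:
    """Information-theoretic selection table, sorted by AIC (best first).

    Columns: log-likelihood, k, AIC, delta-AIC, relative likelihood,
    Akaike weight, evidence ratio vs best (with a log10 column that never
    overflows).
    """
    if not fits:
        raise InferenceError("no fits to rank")
    ids = [f.model.id for f in fits]
    if len(set(ids)) != len(ids):
        raise InferenceError("duplicate model ids in ranking")
    aic = np.array([f.aic for f in fits])
    delta = aic - aic.min()
    rel = np.exp(-delta / 2.0)
    weights = rel / rel.sum()
    log10_er = delta / (2.0 * np.log(10.0))
    er = np.where(log10_er < 300, np.power(10.0, np.minimum(log10_er, 300)), np.inf)
    tab = pd.DataFrame({
        "model": ids,
        "log_likelihood": [f.log_likelihood for f in fits],
        "k": [f.model.k for f in fits],
        "AIC": aic,
        "delta_AIC": delta,
        "rel_likelihood": rel,
        "weight": weights,
        "evidence_ratio": er,
        "log10_evidence_ratio": log10_er,
    }).sort_values("AIC", kind="mergesort").reset_index(drop=True)
    return tab


def bootstrap(sites: pd.DataFrame, model: DemographicModel,
              n1_target: int, n2_target: int, n_reps: int = 5,
              seed: int | None = None, **fit_kwargs):
    """Nonparametric SNP bootstrap: resample sites, rebuild SFS, refit.

    Returns ``(summary, replicate_fits)`` where summary is a DataFrame of
    per-parameter mean and SD over successful replicates.
    """
    if n_reps < 2:
        raise InferenceError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    # one optimizer seed for all replicates: identical resampled data then
    # yield identical fits, so the SD reflects data variation only
    fit_seed = int(rng.integers(0, 2**31 - 1))
    fits = []
    for rep in range(n_reps):
        idx = rng.integers(0, len(sites), size=len(sites))
        resampled = sites.iloc[idx].reset_index(drop=True)
        sfs = build_sfs(resampled, n1_target, n2_target)
        try:
            fits.append(fit_model(sfs, model, seed=fit_seed, **fit_kwargs))
        except InferenceError as exc:
            warnings.warn(f"bootstrap replicate {rep} failed: {exc}")
    if len(fits) < 2:
        raise InferenceError("fewer than 2 bootstrap replicates succeeded")
    mat = np.array([f.params for f in fits])
    summary = pd.DataFrame({
        "parameter": model.param_names,
        "mean": mat.mean(axis=0),
        "sd": mat.std(axis=0, ddof=1),
    })
    return summary, fits


@dataclass
class ScaledParams:
    """Fitted parameters in demographic units.

    Epoch rows are ordered oldest to newest; ``start_years_bp`` is the
    epoch's older boundary, strictly decreasing toward the present.
    Migration is reported both as the per-generation fraction of the
    recipient population replaced and as migrants (individuals) per
    generation.
    """

    N_ref: float
    epochs: pd.DataFrame
    ancestral: dict | None = None

    def to_dict(self) -> dict:
        return {"N_ref": self.N_ref,
                "ancestral": self.ancestral,
                "epochs": self.epochs.to_dict(orient="records")}


def scale_to_natural_units(fit: FitResult, mu: float, gen_time: float,
                           L: float) -> ScaledParams:
    """Convert a fit to individuals and years.

    ``N_ref = theta_hat / (4 mu L)``; an epoch of duration T (units of
    2 N_ref generations) spans ``2 N_ref T gen_time`` years.
    """
    if mu <= 0 or gen_time <= 0 or L <= 0:
        raise InferenceError("mu, gen_time and L must be positive")
    N_ref = fit.theta_hat / (4.0 * mu * L)
    anc, epochs = bind_parameters(fit.model, fit.params)
    years = [2.0 * N_ref * e.T * gen_time for e in epochs]
    # boundary times accumulate from the present backward
    starts = np.cumsum(years[::-1])[::-1]
    ends = starts - np.array(years)
    rows = []
    for e, epoch in enumerate(epochs):
        m12_frac = epoch.m12 / (2.0 * N_ref)
        m21_frac = epoch.m21 / (2.0 * N_ref)
        rows.append({
            "epoch": e + 1,
            "start_years_bp": starts[e],
            "end_years_bp": ends[e],
            "N1": epoch.nu1 * N_ref,
            "N2": epoch.nu2 * N_ref,
            "m12_frac_per_gen": m12_frac,
            "m21_frac_per_gen": m21_frac,
            "m12_migrants_per_gen": m12_frac * epoch.nu1 * N_ref,
            "m21_migrants_per_gen": m21_frac * epoch.nu2 * N_ref,
            "island_percent": 100.0 * epoch.P,
            "island_factor_b": epoch.b,
        })
    ancestral = None
    if anc is not None:
        ancestral = {"N_A": anc.nu1 * N_ref,
                     "duration_years": 2.0 * N_ref * anc.T * gen_time}
    return ScaledParams(N_ref=N_ref, epochs=pd.DataFrame(rows),
                        ancestral=ancestral)
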