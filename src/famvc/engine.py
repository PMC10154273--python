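"""Block-diagonal Gaussian variance-component engine.

Fits ACE-family models (any subset of A, C, T, S plus the mandatory E) to
pre-residualized phenotypes by maximum likelihood. The phenotypic
covariance is block-diagonal over family clusters, so the log-likelihood
is a sum of small multivariate-normal densities, one per family:

    V_f = sigma^2 * sum_e f_e * M_e(f)

where sigma^2 is the (unbiased, held-fixed) total residual variance, f_e
are variance fractions on the simplex, and M_e are the per-family
observation-level component matrices (genetic relatedness for A, shared
family for C, shared pregnancy for T, shared subject for S, identity
for E). All component matrices have unit diagonal, so the fractions sum to
one and each is the share of total variance its effect explains — the A
fraction is the heritability estimate.

Confidence intervals are profile-likelihood based: the interval endpoints
are where a local quadratic to the profile log-likelihood crosses the
chi-square(1)-derived threshold below the maximum.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from .relatedness import (
    RelatednessMatrix,
    SparseClusteredGRM,
    expand_to_observations,
    sparsify_by_family,
)
from .residualize import ResidualizedPhenotype

__all__ = [
    "RandomEffectDesign",
    "VarianceComponentFit",
    "FitOptions",
    "ModelComparison",
    "ConvergenceError",
    "total_variance",
    "block_covariance",
    "build_family_data",
    "log_likelihood",
    "fit_ml",
    "profile_ci",
    "aic",
    "compare_models",
]

EFFECT_ORDER = "ACTSE"
_Z_BOUND = 30.0       # |log-ratio| beyond this is treated as a boundary
_BOUNDARY_EPS = 1e-8  # fractions below this are projected to exactly 0
_FLAT_CURVATURE = 1e-6


class ConvergenceError(RuntimeError):
    """Raised when no optimizer start converges; carries the best point."""

    def __init__(self, message, best_fractions=None, best_loglik=None):
        super().__init__(message)
        self.best_fractions = best_fractions
        self.best_loglik = best_loglik


@dataclass(frozen=True)
class RandomEffectDesign:
    """Ordered set of variance components; E is mandatory and last.

    A — additive genetic (relatedness block); C — common environment
    (family); T — twin status (shared pregnancy ID); S — subject (stable
    across repeat visits); E — unique environment / error.
    """

    effects: tuple[str, ...]

    def __post_init__(self):
        eff = tuple(self.effects)
        if len(set(eff)) != len(eff):
            raise ValueError(f"repeated effect in design {eff}")
        if not eff or eff[-1] != "E":
            raise ValueError("design must end with the mandatory E effect")
        for e in eff:
            if e not in EFFECT_ORDER:
                raise ValueError(f"unknown effect {e!r}; allowed: A, C, T, S, E")
        order = [EFFECT_ORDER.index(e) for e in eff]
        if order != sorted(order):
            raise ValueError(
                f"effects must be in canonical order {EFFECT_ORDER!r}, got {eff}"
            )

    @classmethod
    def from_string(cls, model: str) -> "RandomEffectDesign":
        return cls(tuple(model.strip().upper()))

    @property
    def model(self) -> str:
        return "".join(self.effects)

    @property
    def n_free(self) -> int:
        """Free fraction parameters under the simplex constraint."""
        return len(self.effects) - 1


@dataclass
class FitOptions:
    """Tuning knobs for the ML fit.

    total_variance overrides the unbiased estimate from the residuals
    (used e.g. to hold the scale fixed across model variants);
    variance_denominator chooses n-p (default) or n-1 in the unbiased
    estimate; jointly_estimate_total profiles sigma^2 by ML instead of
    holding it fixed (sensitivity analysis); psd_repair enables
    nearest-PSD repair of non-positive-definite relatedness blocks.
    """

    ci_level: float = 0.95
    total_variance: float | None = None
    variance_denominator: str = "n-p"
    jointly_estimate_total: bool = False
    psd_repair: bool = False
    compute_ci: bool = True
    max_evals: int = 5000
    loglik_tol: float = 1e-9


@dataclass
class VarianceComponentFit:
    """Result of an ML variance-component fit.

    ``fractions`` are shares of the total residual variance (they sum
    to 1); ``k`` counts the free simplex fractions (total variance is
    estimated separately and not counted); ``ci`` holds per-effect
    profile-likelihood intervals at ``ci_level``.
    """

    model: str
    total_variance: float
    fractions: dict[str, float]
    log_likelihood: float
    k: int
    aic: float
    ci: dict[str, tuple[float, float]]
    ci_level: float
    n_obs: int
    n_families: int
    boundary_effects: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()
    converged: bool = True
    residual_checksum: str = ""
    k_convention: str = "free simplex fractions; total variance profiled out"
    phenotype: str = ""
    _lik: object | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        s = sum(self.fractions.values())
        if self.fractions and abs(s - 1.0) > 1e-8:
            raise ValueError(f"fractions sum to {s}, expected 1 within 1e-8")
        for e, (lo, hi) in self.ci.items():
            f = self.fractions[e]
            if not (lo <= f + 1e-12 and f <= hi + 1e-12):
                raise ValueError(
                    f"CI ({lo}, {hi}) for {e} does not bracket estimate {f}"
                )


@dataclass
class ModelComparison:
    """AIC comparison of two fits plus per-effect estimate differences.

    ``delta_aic`` (extended minus base) is only defined when both fits
    used the identical observation set; otherwise it is None and
    ``reason`` explains the refusal.
    """

    comparable: bool
    delta_aic: float | None
    delta_loglik: float | None
    delta_k: int
    fraction_differences: dict[str, float]
    reason: str = ""


def residual_checksum(residuals: np.ndarray) -> str:
    r = np.ascontiguousarray(np.round(np.asarray(residuals, float), 10))
    h = hashlib.sha256()
    h.update(str(len(r)).encode())
    h.update(r.tobytes())
    return h.hexdigest()


def total_variance(
    residuals, df_used: int | None = None, *, denominator: str = "n-p"
) -> float:
    """Unbiased total variance of pre-residualized data: SSR / (n - df).

    ``denominator="n-p"`` (default) uses the regressor degrees of freedom
    consumed during pre-residualization; ``"n-1"`` ignores them.
    """
    if isinstance(residuals, ResidualizedPhenotype):
        if df_used is None:
            df_used = residuals.df_used
        r = residuals.values.to_numpy(dtype=float)
    else:
        r = np.asarray(residuals, dtype=float)
        if df_used is None:
            df_used = 1
    if r.size == 0:
        raise ValueError("empty residual vector")
    if denominator == "n-1":
        df_used = 1
    elif denominator != "n-p":
        raise ValueError(f"denominator must be 'n-p' or 'n-1', got {denominator!r}")
    n = r.size
    if n <= df_used:
        raise ValueError(f"n_obs ({n}) must exceed df_used ({df_used})")
    ss = float(r @ r)
    if ss == 0.0:
        warnings.warn("all residuals are zero: degenerate fit, total variance 0",
                      stacklevel=2)
        return 0.0
    return ss / (n - df_used)


def block_covariance(
    fractions: dict[str, float],
    total_var: float,
    components: dict[str, np.ndarray],
) -> np.ndarray:
    """Assemble one family's covariance: V = sigma^2 * sum_e f_e M_e.

    All component matrices have unit diagonal so diag(V) = sigma^2.
    """
    eff = list(fractions)
    f = np.array([fractions[e] for e in eff])
    if (f < -1e-12).any() or abs(f.sum() - 1.0) > 1e-8:
        raise ValueError(f"fractions {fractions} not on the simplex")
    V = sum(fractions[e] * components[e] for e in eff)
    return total_var * V


class _FamilyData:
    """Per-family component matrices and residuals, stacked by block size
    so the likelihood evaluates with batched linear algebra."""

    def __init__(self, design, groups, n_obs, n_families, jitter_flag):
        self.design = design
        self.groups = groups  # size -> dict(comps=(m,F,s,s), resid=(F,s), fams=[...])
        self.n_obs = n_obs
        self.n_families = n_families
        self._jitter_used = jitter_flag

    @classmethod
    def build(
        cls,
        observations: pd.DataFrame,
        residuals: np.ndarray,
        sgrm: SparseClusteredGRM,
        design: RandomEffectDesign,
        *,
        psd_repair: bool = False,
    ) -> "_FamilyData":
        obs = observations.reset_index(drop=True)
        r = np.asarray(residuals, dtype=float)
        if len(obs) != r.size:
            raise ValueError("residuals and observations differ in length")
        fam_col = obs["family_id"].astype(str)
        by_size: dict[int, dict] = {}
        n_families = 0
        from .relatedness import nearest_psd

        # canonical family and row order: the likelihood (and hence the
        # whole fit) is then exactly invariant under observation shuffles
        for fid, rows in obs.groupby(fam_col, sort=True):
            rows = rows.sort_values(
                ["subject_id", "visit"], key=lambda s: s.astype(str)
            )
            if fid not in sgrm.blocks:
                raise KeyError(f"family {fid!r} missing from sparse GRM")
            n_families += 1
            block = sgrm.blocks[fid]
            comps = expand_to_observations(sgrm.block_ids[fid], block, rows)
            if psd_repair:
                w = np.linalg.eigvalsh(comps["A"])
                if w.min() < -1e-10:
                    comps["A"] = nearest_psd(comps["A"])
            s = len(rows)
            g = by_size.setdefault(s, {"comps": [], "resid": [], "fams": []})
            g["comps"].append([comps[e] for e in design.effects])
            g["resid"].append(r[rows.index.to_numpy()])
            g["fams"].append(fid)

        groups = {}
        for s, g in by_size.items():
            arr = np.array(g["comps"])            # (F, m, s, s)
            groups[s] = {
                "comps": np.ascontiguousarray(arr.transpose(1, 0, 2, 3)),
                "resid": np.array(g["resid"]),    # (F, s)
                "fams": g["fams"],
            }
        return cls(design, groups, n_obs=r.size, n_families=n_families,
                   jitter_flag=[False])

    def _frac_vector(self, fractions: dict[str, float]) -> np.ndarray:
        return np.array([fractions[e] for e in self.design.effects])

    def loglik(self, fractions: dict[str, float], sigma2: float) -> float:
        """Sum over families of the zero-mean Gaussian log-density."""
        if sigma2 <= 0:
            return -np.inf
        f = self._frac_vector(fractions)
        total = 0.0
        for s, g in self.groups.items():
            V = sigma2 * np.tensordot(f, g["comps"], axes=1)  # (F, s, s)
            y = g["resid"]
            if s == 1:
                # singleton variance is sigma^2 * sum(fractions) = sigma^2
                # exactly: constant in the fractions, so singletons inform
                # the total variance but not the component split
                total += -0.5 * float(
                    V.shape[0] * np.log(2 * np.pi * sigma2)
                    + np.sum(y[:, 0] ** 2) / sigma2
                )
                continue
            L = self._chol(V, sigma2)
            if L is None:
                return -np.inf
            logdet = 2.0 * float(np.sum(np.log(np.diagonal(L, axis1=1, axis2=2))))
            z = np.linalg.solve(L, y[:, :, None])[:, :, 0]
            quad = float(np.sum(z * z))
            total += -0.5 * (V.shape[0] * s * np.log(2 * np.pi) + logdet + quad)
        return total

    def _chol(self, V: np.ndarray, sigma2: float):
        """Batched Cholesky with escalating diagonal jitter; None = singular."""
        try:
            return np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            pass
        eye = np.eye(V.shape[-1])
        for jit in (1e-10, 1e-9, 1e-8, 1e-7, 1e-6):
            try:
                L = np.linalg.cholesky(V + jit * sigma2 * eye)
                self._jitter_used[0] = True
                return L
            except np.linalg.LinAlgError:
                continue
        return None

    def loglik_profiled_sigma(self, fractions) -> tuple[float, float]:
        """ML of sigma^2 given fractions (joint-ML sensitivity mode)."""
        f = self._frac_vector(fractions)
        logdet0 = 0.0
        quad0 = 0.0
        for s, g in self.groups.items():
            C = np.tensordot(f, g["comps"], axes=1)
            L = self._chol(C, 1.0)
            if L is None:
                return -np.inf, np.nan
            logdet0 += 2.0 * float(np.sum(np.log(np.diagonal(L, axis1=1, axis2=2))))
            z = np.linalg.solve(L, g["resid"][:, :, None])[:, :, 0]
            quad0 += float(np.sum(z * z))
        n = self.n_obs
        sigma2 = quad0 / n
        if sigma2 <= 0:
            return -np.inf, np.nan
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet0 + n)
        return ll, sigma2


def build_family_data(
    observations: pd.DataFrame,
    residuals,
    relatedness,
    design,
    *,
    psd_repair: bool = False,
) -> _FamilyData:
    """Prepare per-family component matrices for likelihood evaluation.

    Accepts a full RelatednessMatrix (sparsified by the observations'
    family assignment) or an already-sparse clustered GRM. Observations
    without a pregnancy_id column get per-subject pregnancies.
    """
    if isinstance(design, str):
        design = RandomEffectDesign.from_string(design)
    obs = observations.reset_index(drop=True)
    if isinstance(relatedness, RelatednessMatrix):
        fam_of = dict(
            zip(obs["subject_id"].astype(str), obs["family_id"].astype(str))
        )
        relatedness = sparsify_by_family(relatedness, fam_of)
    if "pregnancy_id" not in obs.columns:
        obs = obs.assign(
            pregnancy_id="preg::own::" + obs["subject_id"].astype(str)
        )
    r = (residuals.values.to_numpy(dtype=float)
         if isinstance(residuals, ResidualizedPhenotype)
         else np.asarray(residuals, dtype=float))
    return _FamilyData.build(obs, r, relatedness, design, psd_repair=psd_repair)


def log_likelihood(
    fractions: dict[str, float],
    total_var: float,
    data: _FamilyData,
) -> float:
    """Block-diagonal Gaussian log-likelihood (nats) at given fractions."""
    return data.loglik(fractions, total_var)


def aic(fit_or_loglik, k: int | None = None) -> float:
    """AIC = -2 ln L + 2 k."""
    if isinstance(fit_or_loglik, VarianceComponentFit):
        return -2.0 * fit_or_loglik.log_likelihood + 2.0 * fit_or_loglik.k
    if k is None:
        raise TypeError("k required when passing a raw log-likelihood")
    return -2.0 * float(fit_or_loglik) + 2.0 * k


# ---------------------------------------------------------------------------
# simplex parameterization: log-ratio transform with E as reference

def _fractions_from_z(z: np.ndarray, effects: tuple[str, ...]) -> dict[str, float]:
    z = np.clip(z, -_Z_BOUND, _Z_BOUND)
    expz = np.exp(z)
    denom = 1.0 + expz.sum()
    f = {e: float(v / denom) for e, v in zip(effects[:-1], expz)}
    f[effects[-1]] = float(1.0 / denom)
    return f

def _z_from_fractions(f: dict[str, float], effects: tuple[str, ...]) -> np.ndarray:
    ref = max(f[effects[-1]], 1e-12)
    return np.array(
        [np.log(max(f[e], 1e-12) / ref) for e in effects[:-1]]
    )

def _starts(effects: tuple[str, ...]) -> list[dict[str, float]]:
    m = len(effects)
    if m == 1:
        return [{effects[0]: 1.0}]
    starts = [{e: 1.0 / m for e in effects}]
    for big in effects:  # each single effect dominant, E included (E-dominant start)
        f = {e: 0.1 / (m - 1) for e in effects}
        f[big] = 0.9
        starts.append(f)
    return starts


def _newton_polish(objective, z, h=1e-4, iters=10):
    """Finite-difference Newton refinement of an interior optimum.

    The likelihood surface is numerically flat below ~1e-13 nats, so any
    value-comparison search leaves ~1e-7 indeterminacy in z; Newton on
    central differences pins the stationary point far more tightly (its
    small truncation bias is a smooth function of the surface shape, so
    equivalent datasets polish to matching optima).
    """
    z = np.asarray(z, dtype=float).copy()
    m = z.size
    for _ in range(iters):
        f0 = objective(z)
        g = np.zeros(m)
        H = np.zeros((m, m))
        for i in range(m):
            ei = np.zeros(m)
            ei[i] = h
            fp, fm = objective(z + ei), objective(z - ei)
            g[i] = (fp - fm) / (2 * h)
            H[i, i] = (fp - 2 * f0 + fm) / h**2
        for i in range(m):
            for j in range(i + 1, m):
                ei = np.zeros(m); ei[i] = h
                ej = np.zeros(m); ej[j] = h
                H[i, j] = H[j, i] = (
                    objective(z + ei + ej) - objective(z + ei - ej)
                    - objective(z - ei + ej) + objective(z - ei - ej)
                ) / (4 * h * h)
        try:
            if np.linalg.eigvalsh(H).min() <= 0:
                break
            step = -np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -0.5, 0.5)
        z = z + step
        if np.max(np.abs(step)) < 1e-11:
            break
    return z


def _maximize(objective, z0, max_evals, tol):
    if z0.size == 0:
        return z0, -objective(z0), True
    res = optimize.minimize(
        objective,
        z0,
        method="Nelder-Mead",
        options={"fatol": tol, "xatol": 1e-9, "maxfev": max_evals,
                 "maxiter": max_evals},
    )
    return res.x, -res.fun, bool(res.success)


def fit_ml(
    residuals,
    observations: pd.DataFrame,
    relatedness,
    design,
    *,
    df_used: int | None = None,
    options: FitOptions | None = None,
    phenotype: str = "",
) -> VarianceComponentFit:
    """Maximum-likelihood variance fractions on the simplex.

    Parameters
    ----------
    residuals : ResidualizedPhenotype or array
        Pre-residualized phenotype values, aligned row-for-row with
        ``observations``.
    observations : DataFrame
        Columns subject_id, family_id, visit; pregnancy_id required when T
        is in the design (derived upstream from family + birth date).
    relatedness : SparseClusteredGRM or RelatednessMatrix
        A full matrix is sparsified by the observations' family
        assignment.
    design : RandomEffectDesign or model string such as "ACE".

    The total variance is estimated once (unbiased) and held fixed while
    the fractions are optimized by Nelder-Mead from a fixed set of
    deterministic starts; the best likelihood wins, ties broken by the
    earliest start. Boundary solutions (a fraction exactly 0) are reached
    by projection when the log-ratio transform saturates.
    """
    if isinstance(design, str):
        design = RandomEffectDesign.from_string(design)
    options = options or FitOptions()

    if isinstance(residuals, ResidualizedPhenotype):
        if df_used is None:
            df_used = residuals.df_used
        r = residuals.values.to_numpy(dtype=float)
        phenotype = phenotype or residuals.phenotype
    else:
        r = np.asarray(residuals, dtype=float)
        if df_used is None:
            df_used = 1

    obs = observations.reset_index(drop=True)
    _validate_design_against_data(design, obs)

    if isinstance(relatedness, RelatednessMatrix):
        fam_of = dict(
            zip(obs["subject_id"].astype(str), obs["family_id"].astype(str))
        )
        relatedness = sparsify_by_family(relatedness, fam_of)
    if "pregnancy_id" not in obs.columns:
        # without birth dates each subject is its own pregnancy (T then
        # rejected above if requested without the column)
        obs = obs.assign(
            pregnancy_id="preg::own::" + obs["subject_id"].astype(str)
        )

    fit_warnings: list[str] = []

    sigma2 = (
        options.total_variance
        if options.total_variance is not None
        else total_variance(r, df_used, denominator=options.variance_denominator)
    )
    if sigma2 <= 0:
        raise ValueError("total variance must be positive to fit fractions")

    # standardize so the optimization sees unit total variance: the
    # objective is then exactly invariant under rescaling the phenotype
    ll_offset = -0.5 * r.size * np.log(sigma2)
    data = _FamilyData.build(
        obs, r / np.sqrt(sigma2), relatedness, design,
        psd_repair=options.psd_repair,
    )

    effects = design.effects
    if options.jointly_estimate_total:
        def objective(z):
            ll, _ = data.loglik_profiled_sigma(_fractions_from_z(z, effects))
            return -ll if np.isfinite(ll) else 1e300
    else:
        def objective(z):
            ll = data.loglik(_fractions_from_z(z, effects), 1.0)
            return -ll if np.isfinite(ll) else 1e300

    best = None
    any_converged = False
    for f0 in _starts(effects):
        z0 = _z_from_fractions(f0, effects)
        z, ll, ok = _maximize(objective, z0, options.max_evals, options.loglik_tol)
        any_converged = any_converged or ok
        if best is None or ll > best[1]:
            best = (z, ll)
    z_best, ll_best = best
    # restart once from the winner: a fresh simplex re-converges and
    # sharpens the optimum well beyond the first pass's tolerance basin
    z2, ll2, _ = _maximize(objective, z_best, options.max_evals,
                           options.loglik_tol)
    if ll2 >= ll_best:
        z_best, ll_best = z2, ll2
    if z_best.size and np.all(np.abs(z_best) < 20.0):  # interior optimum
        z3 = _newton_polish(objective, z_best)
        ll3 = -objective(z3)
        if np.isfinite(ll3) and ll3 >= ll_best - 1e-7:
            z_best, ll_best = z3, ll3  # keep value consistent with the point
    fractions = _fractions_from_z(z_best, effects)

    if not any_converged:
        raise ConvergenceError(
            f"no optimizer start converged for model {design.model}",
            best_fractions=fractions,
            best_loglik=ll_best,
        )

    # project saturated/near-zero fractions onto the boundary
    proj = {e: (0.0 if fractions[e] < _BOUNDARY_EPS else fractions[e])
            for e in effects}
    tot = sum(proj.values())
    proj = {e: v / tot for e, v in proj.items()}
    if any(proj[e] != fractions[e] for e in effects):
        if options.jointly_estimate_total:
            ll_proj, _ = data.loglik_profiled_sigma(proj)
        else:
            ll_proj = data.loglik(proj, 1.0)
        if ll_proj >= ll_best - 1e-7:
            fractions, ll_best = proj, max(ll_proj, ll_best)
    boundary = tuple(e for e in effects if fractions[e] == 0.0)
    if boundary:
        fit_warnings.append(
            f"boundary solution: fraction(s) {','.join(boundary)} estimated at 0"
        )

    if options.jointly_estimate_total:
        ll_best, s2_std = data.loglik_profiled_sigma(fractions)
        sigma2 = s2_std * sigma2  # undo the standardization
        k = design.n_free + 1
        k_conv = "free simplex fractions + jointly estimated total variance"
    else:
        k = design.n_free
        k_conv = "free simplex fractions; total variance profiled out"
    ll_best = float(ll_best + ll_offset)

    if data._jitter_used[0]:
        fit_warnings.append("diagonal jitter applied to near-singular family block")

    state = _ProfileState(data, 1.0, effects, fractions, ll_best,
                          options.jointly_estimate_total, offset=ll_offset)

    ci: dict[str, tuple[float, float]] = {}
    if options.compute_ci:
        for e in effects:
            lo, hi, warn = _profile_ci_impl(state, e, options.ci_level)
            ci[e] = (lo, hi)
            if warn:
                fit_warnings.append(warn)

    fit = VarianceComponentFit(
        model=design.model,
        total_variance=float(sigma2),
        fractions=fractions,
        log_likelihood=float(ll_best),
        k=k,
        aic=aic(ll_best, k),
        ci=ci,
        ci_level=options.ci_level,
        n_obs=data.n_obs,
        n_families=data.n_families,
        boundary_effects=boundary,
        warnings=tuple(fit_warnings),
        converged=True,
        residual_checksum=residual_checksum(r),
        k_convention=k_conv,
        phenotype=phenotype,
        _lik=state,
    )
    return fit


def _validate_design_against_data(design, obs):
    for col in ("subject_id", "family_id", "visit"):
        if col not in obs.columns:
            raise KeyError(f"observations missing required column {col!r}")
    if "S" in design.effects:
        visits_per_subject = obs.groupby(obs["subject_id"].astype(str))["visit"].nunique()
        if (visits_per_subject < 2).all():
            raise ValueError(
                "S effect requires at least one subject with >= 2 visits"
            )
    if "T" in design.effects and "pregnancy_id" not in obs.columns:
        raise KeyError(
            "T effect requires a pregnancy_id column (same family + birth date)"
        )
    if design.effects != ("E",):
        sizes = obs.groupby(obs["family_id"].astype(str)).size()
        if (sizes < 2).all():
            raise ValueError(
                "need at least one family with >= 2 observations to separate "
                "components from E"
            )


@dataclass
class _ProfileState:
    data: _FamilyData
    sigma2: float
    effects: tuple[str, ...]
    fractions: dict[str, float]
    max_loglik: float
    joint_sigma: bool = False
    offset: float = 0.0  # log-likelihood shift from residual standardization

    def loglik_at(self, fractions: dict[str, float]) -> float:
        if self.joint_sigma:
            ll, _ = self.data.loglik_profiled_sigma(fractions)
            return ll + self.offset
        return self.data.loglik(fractions, self.sigma2) + self.offset

    def profile_loglik(self, effect: str, t: float) -> float:
        """Re-maximize the remaining fractions with fraction(effect)=t."""
        rest = tuple(e for e in self.effects if e != effect)
        budget = 1.0 - t
        if budget <= 0:
            f = {e: 0.0 for e in rest}
            f[effect] = 1.0
            return self.loglik_at(f)
        if len(rest) == 1:
            return self.loglik_at({effect: t, rest[0]: budget})

        def obj(z):
            sub = _fractions_from_z(z, rest)
            f = {e: sub[e] * budget for e in rest}
            f[effect] = t
            ll = self.loglik_at(f)
            return -ll if np.isfinite(ll) else 1e300

        starts = []
        cur = {e: self.fractions[e] for e in rest}
        cur_tot = sum(cur.values())
        if cur_tot > 0:
            starts.append({e: v / cur_tot for e, v in cur.items()})
        starts.append({e: 1.0 / len(rest) for e in rest})
        best = -np.inf
        for f0 in starts:
            z0 = _z_from_fractions(f0, rest)
            _, ll, _ = _maximize(obj, z0, 2000, 1e-9)
            best = max(best, ll)
        return best


def _profile_ci_impl(state: _ProfileState, effect: str, level: float):
    """Quadratic approximation to the profile log-likelihood.

    A symmetric three-point stencil (step 0.02 on the fraction scale,
    shifted one-sided at the simplex boundary) fits a parabola; the
    interval is where it crosses max_loglik - qchisq(level, 1)/2,
    truncated to [0, 1].
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    if len(state.effects) == 1:  # E-only: fraction fixed at 1 by the simplex
        return 1.0, 1.0, None
    h = 0.02
    theta = state.fractions[effect]
    if theta < h:
        pts = [theta, theta + h, theta + 2 * h]
    elif theta > 1.0 - h:
        pts = [theta - 2 * h, theta - h, theta]
    else:
        pts = [theta - h, theta, theta + h]
    lls = [
        state.max_loglik if abs(p - theta) < 1e-15 else state.profile_loglik(effect, p)
        for p in pts
    ]
    if not all(np.isfinite(lls)):
        return 0.0, 1.0, (
            f"profile for {effect} not finite at stencil; CI set to (0, 1)"
        )
    a, b, c = np.polyfit(pts, lls, 2)
    delta = chi2.ppf(level, df=1) / 2.0
    target = state.max_loglik - delta
    if a > -_FLAT_CURVATURE:
        return 0.0, 1.0, (
            f"flat profile likelihood for {effect} (non-identifiable "
            "direction, e.g. A vs C on MZ-only data); CI set to (0, 1)"
        )
    disc = b * b - 4.0 * a * (c - target)
    if disc >= 0:
        root = np.sqrt(disc)
        r1 = (-b + root) / (2.0 * a)
        r2 = (-b - root) / (2.0 * a)
        guess_lo, guess_hi = min(r1, r2), max(r1, r2)
    else:  # parabola peak below threshold: fall back to a fixed step
        guess_lo, guess_hi = theta - 3 * h, theta + 3 * h
    # the local quadratic seeds each crossing; the endpoint is then
    # refined against the true (re-maximized) profile likelihood
    lo = _profile_endpoint(state, effect, theta, target, -1, guess_lo)
    hi = _profile_endpoint(state, effect, theta, target, +1, guess_hi)
    lo = float(np.clip(min(lo, theta), 0.0, 1.0))
    hi = float(np.clip(max(hi, theta), 0.0, 1.0))
    return lo, hi, None


def _profile_endpoint(state, effect, theta, target, sign, guess):
    """Locate one CI endpoint: the parameter value (on side ``sign`` of
    the estimate) where the profile log-likelihood crosses ``target``,
    or the simplex edge if the profile never drops that far."""
    bound = 0.0 if sign < 0 else 1.0
    if abs(theta - bound) < 1e-9:
        return bound

    def g(t):
        ll = state.profile_loglik(effect, t)
        if not np.isfinite(ll):  # keep the root-finder on finite values
            ll = -1e12
        return ll - target

    d = abs(guess - theta)
    if not np.isfinite(d) or d < 1e-3:
        d = 0.02
    outer = None
    for _ in range(25):
        t = theta + sign * d
        if (t - bound) * sign >= 0:  # reached the simplex edge
            if g(bound) >= 0:
                return bound
            outer = bound
            break
        if g(t) < 0:
            outer = t
            break
        d *= 1.7
    if outer is None:
        return bound
    lo_b, hi_b = (outer, theta) if sign < 0 else (theta, outer)
    return float(optimize.brentq(g, lo_b, hi_b, xtol=1e-5, maxiter=60))


def profile_ci(
    fit: VarianceComponentFit, effect: str, level: float = 0.95
) -> tuple[float, float]:
    """Profile-likelihood CI for one effect's variance fraction.

    Threshold: the log-likelihood drop qchisq(level, 1)/2 below the
    maximum (1.9207 nats at level 0.95). Requires a fit produced in this
    session (the likelihood machinery is not serialized)."""
    if effect not in fit.fractions:
        raise KeyError(f"effect {effect!r} not in model {fit.model}")
    state = fit._lik
    if state is None:
        raise ValueError(
            "fit carries no likelihood state (was it read from a report?); "
            "re-fit to compute confidence intervals"
        )
    lo, hi, _ = _profile_ci_impl(state, effect, level)
    return lo, hi


def compare_models(
    fit_base: VarianceComponentFit,
    fit_extended: VarianceComponentFit,
    *,
    require_aic: bool = False,
) -> ModelComparison:
    """Delta AIC (extended minus base) plus per-effect estimate differences.

    AIC differences are only meaningful on the identical observation set;
    when row counts or residual checksums differ the comparison reports
    the estimate differences alone. ``require_aic=True`` turns that
    refusal into an error.
    """
    effects = sorted(
        set(fit_base.fractions) | set(fit_extended.fractions),
        key=EFFECT_ORDER.index,
    )
    diffs = {
        e: fit_extended.fractions.get(e, 0.0) - fit_base.fractions.get(e, 0.0)
        for e in effects
    }
    same_sample = (
        fit_base.n_obs == fit_extended.n_obs
        and fit_base.residual_checksum == fit_extended.residual_checksum
        and fit_base.residual_checksum != ""
    )
    if not same_sample:
        if require_aic:
            raise ValueError(
                "AIC comparison requested but the fits use different "
                "observation sets (row count or residual checksum mismatch)"
            )
        return ModelComparison(
            comparable=False,
            delta_aic=None,
            delta_loglik=None,
            delta_k=fit_extended.k - fit_base.k,
            fraction_differences=diffs,
            reason="fits use different observation sets; AIC not comparable",
        )
    d_ll = fit_extended.log_likelihood - fit_base.log_likelihood
    d_k = fit_extended.k - fit_base.k
    return ModelComparison(
        comparable=True,
        delta_aic=-2.0 * d_ll + 2.0 * d_k,
        delta_loglik=d_ll,
        delta_k=d_k,
        fraction_differences=diffs,
    )
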