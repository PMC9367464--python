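"""Bayesian logistic animal model for a binary trait on a pedigree.

The phenotype of animal *i* is Bernoulli with

    logit P(y_i = 1) = eta_i = beta0 + beta_year * year_i + beta_sex * sex_i + a_i

where the breeding value ``a_i`` is built recursively from decorrelated
gametic deviations ``z_i ~ N(0, 1)``:

    a_i = sigma_a * s_i * z_i + (a_sire + a_dam) / 2

with a missing parent contributing 0 and ``s_i`` the Mendelian sampling
standard deviation from :mod:`sequestra.pedigree`.  This "Mendelian sampling
decomposition" makes the prior on z a product of independent standard
normals while a retains the additive-relationship covariance
``sigma_a^2 * A``.  Heritability on the liability scale is

    h^2 = sigma_a^2 / (sigma_a^2 + 1)

with the residual variance of the binary trait fixed at 1 (a flag exposes the
logit-scale pi^2/3 convention instead).

Estimation is MCMC: an adaptive random-walk Metropolis-within-Gibbs sampler
over the blocks beta / sigma_a / z, with proposal scales adapted during
burn-in only, all four chains advanced simultaneously in vectorized numpy.
Any animal whose status is unknown is dropped from the likelihood but kept in
the pedigree recursion, so it still transmits breeding values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm

from .pedigree import Pedigree, mendelian_sampling_sd

__all__ = [
    "PriorSpec",
    "PRIOR_PRESETS",
    "TABLE_PRIOR_SET",
    "ModelData",
    "ParameterState",
    "breeding_values",
    "log_likelihood",
    "log_posterior",
    "run_mcmc",
    "heritability",
    "gelman_rubin",
    "posterior_summary",
    "AnimalModelPosterior",
    "heritability_table",
]

#: prior standard deviation for the intercept, year and sex coefficients
BETA_PRIOR_SD = 4.0

#: default MCMC schedule (iterations, burn-in, thinning)
DEFAULT_SCHEDULE = dict(iterations=60_000, burn_in=30_000, thin=30)


@dataclass(frozen=True)
class PriorSpec:
    """Prior for sigma_a, truncated to (0, inf).

    ``family`` is one of ``cauchy``, ``normal`` (location/scale) or
    ``uniform`` (lower/upper).  Only positive values are in the support.
    """

    family: str
    location: float = 0.0
    scale: float | None = None
    lower: float | None = None
    upper: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("cauchy", "normal", "uniform"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family == "uniform":
            if self.lower is None or self.upper is None or self.lower >= self.upper:
                raise ValueError("uniform prior needs lower < upper")
            if self.lower < 0:
                raise ValueError("sigma_a prior support must be positive")
        elif self.scale is None or self.scale <= 0:
            raise ValueError("scale must be positive")

    def logpdf(self, x) -> np.ndarray:
        """Log density of the (0, inf)-truncated prior; -inf outside support."""
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape, -np.inf)
        if self.family == "uniform":
            lo = max(0.0, self.lower)
            ok = (x > lo) & (x < self.upper)
            out[ok] = -np.log(self.upper - lo)
            return out
        ok = x > 0
        import math

        u = (x[ok] - self.location) / self.scale
        u0 = (0.0 - self.location) / self.scale
        if self.family == "cauchy":
            dens = -np.log(np.pi * self.scale) - np.log1p(u**2)
            tail = math.log1p(-(0.5 + math.atan(u0) / math.pi))
        else:
            dens = -0.5 * np.log(2.0 * np.pi) - np.log(self.scale) - 0.5 * u**2
            tail = math.log(0.5 * math.erfc(u0 / math.sqrt(2.0)))
        out[ok] = dens - tail
        return out


PRIOR_PRESETS: dict[str, PriorSpec] = {
    "cauchy25": PriorSpec("cauchy", 0.0, 2.5, name="Cauchy (0, 2.5)"),
    "cauchy10": PriorSpec("cauchy", 0.0, 10.0, name="Cauchy (0, 10)"),
    "normal10": PriorSpec("normal", 0.0, 10.0, name="Normal (0, 10)"),
    "uniform10": PriorSpec("uniform", lower=0.0, upper=10.0, name="Uniform (0, 10)"),
    "uniform20": PriorSpec("uniform", lower=0.0, upper=20.0, name="Uniform (0, 20)"),
}

#: the four-prior robustness set used for the summary table
TABLE_PRIOR_SET = ("cauchy25", "cauchy10", "normal10", "uniform10")


@dataclass
class ModelData:
    """Per-animal arrays in pedigree order, ready for the sampler."""

    ids: list[str]
    y: np.ndarray          # 0/1, arbitrary where not observed
    observed: np.ndarray   # bool: phenotype enters the likelihood
    year_c: np.ndarray     # centered year of birth (0 where unknown)
    sex: np.ndarray        # male = 1, female = 0, unknown = 0.5
    sire_idx: np.ndarray   # -1 = unknown
    dam_idx: np.ndarray
    s: np.ndarray          # Mendelian sampling SD

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("y", "observed", "year_c", "sex", "sire_idx", "dam_idx", "s"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} has wrong length")
        if np.any(self.sire_idx >= np.arange(n)) or np.any(self.dam_idx >= np.arange(n)):
            raise ValueError("parents must precede offspring")

    @property
    def n(self) -> int:
        return len(self.ids)

    @classmethod
    def from_pedigree(
        cls, ped: Pedigree, mendelian_mode: str = "standard"
    ) -> "ModelData":
        """Build model data; unknown statuses are masked out of the likelihood."""
        s = mendelian_sampling_sd(ped, mode=mendelian_mode).to_numpy()
        status = np.array([r.status for r in ped])
        y = (status == "affected").astype(float)
        observed = status != "unknown"
        years = np.array(
            [np.nan if r.birth_year is None else float(r.birth_year) for r in ped]
        )
        year_mean = np.nanmean(years) if np.any(~np.isnan(years)) else 0.0
        year_c = np.where(np.isnan(years), 0.0, years - year_mean)
        sex_map = {"male": 1.0, "female": 0.0, "unknown": 0.5}
        sex = np.array([sex_map[r.sex] for r in ped])
        return cls(
            ids=ped.ids,
            y=y,
            observed=observed,
            year_c=year_c,
            sex=sex,
            sire_idx=ped.sire_indices,
            dam_idx=ped.dam_indices,
            s=s,
        )


@dataclass
class ParameterState:
    """One point in parameter space."""

    beta0: float
    beta_year: float
    beta_sex: float
    sigma_a: float
    z: np.ndarray

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta_year, self.beta_sex])


def _unit_breeding_values(z: np.ndarray, data: ModelData) -> np.ndarray:
    """a / sigma_a: recursive parental mean plus s_i z_i, in pedigree order."""
    n = data.n
    atil = np.empty(n)
    s_idx, d_idx = data.sire_idx, data.dam_idx
    for i in range(n):
        parent = 0.0
        if s_idx[i] >= 0:
            parent += atil[s_idx[i]]
        if d_idx[i] >= 0:
            parent += atil[d_idx[i]]
        atil[i] = data.s[i] * z[i] + 0.5 * parent
    return atil


def breeding_values(state: ParameterState, data: ModelData) -> np.ndarray:
    """Per-animal breeding values a_i = sigma_a s_i z_i + (a_sire + a_dam)/2."""
    return state.sigma_a * _unit_breeding_values(state.z, data)


def _linear_predictor(state: ParameterState, data: ModelData) -> np.ndarray:
    a = breeding_values(state, data)
    return (
        state.beta0
        + state.beta_year * data.year_c
        + state.beta_sex * data.sex
        + a
    )


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # y*eta - log(1 + exp(eta)), stable for |eta| large
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def log_likelihood(state: ParameterState, data: ModelData) -> float:
    """Bernoulli-logit log likelihood over phenotyped animals."""
    eta = _linear_predictor(state, data)[data.observed]
    return _bernoulli_loglik(data.y[data.observed], eta)


def log_posterior(state: ParameterState, data: ModelData, prior: PriorSpec) -> float:
    """Log likelihood + log priors (beta ~ N(0,4), z ~ N(0,1), sigma_a ~ prior)."""
    lp_sigma = float(prior.logpdf(state.sigma_a))
    if not np.isfinite(lp_sigma):
        return -np.inf
    lp = lp_sigma
    lp += float(np.sum(_norm.logpdf(state.beta, scale=BETA_PRIOR_SD)))
    lp += float(np.sum(_norm.logpdf(state.z)))
    return lp + log_likelihood(state, data)


def heritability(sigma_a, residual_variance: float = 1.0) -> np.ndarray:
    """h2 = sigma_a^2 / (sigma_a^2 + residual variance).

    The residual variance of the binary trait is taken as 1 by default; pass
    ``residual_variance=np.pi**2 / 3`` for the logit-scale convention.
    """
    s2 = np.asarray(sigma_a, dtype=float) ** 2
    return s2 / (s2 + residual_variance)


def gelman_rubin(draws) -> float:
    """Classic potential scale reduction factor over retained draws.

    ``draws`` is (chains, draws_per_chain).  Constant chains (zero
    within-chain variance) return exactly 1 with a warning flag.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (chains >= 2, draws) array")
    if x.shape[1] < 10:
        raise ValueError("need at least 10 retained draws per chain")
    n = x.shape[1]
    W = float(np.mean(np.var(x, axis=1, ddof=1)))
    B_over_n = float(np.var(np.mean(x, axis=1), ddof=1))
    if W == 0.0:
        warnings.warn("all chains constant; PSRF reported as 1", RuntimeWarning)
        return 1.0
    return float(np.sqrt((n - 1) / n + B_over_n / W))


def posterior_summary(draws, level: float = 0.95) -> tuple[float, float, float]:
    """Mean and central interval (linear-interpolation empirical quantiles)."""
    x = np.ravel(np.asarray(draws, dtype=float))
    if x.size < 100:
        raise ValueError("need at least 100 draws for a posterior summary")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
    return float(np.mean(x)), float(lo), float(hi)


def format_interval(lo: float, hi: float, decimals: int = 2) -> str:
    """Printed-style interval; an upper bound that rounds to 1 prints as 'to 1'."""
    hi_r = round(hi, decimals)
    hi_s = "1" if hi_r >= 1.0 else f"{hi_r:.{decimals}f}"
    return f"{round(lo, decimals):.{decimals}f} to {hi_s}"


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


@dataclass
class AnimalModelPosterior:
    """Retained MCMC draws and convergence summaries.

    Scalar draws are (chains, draws); ``z`` is (chains, draws, n) when stored.
    """

    draws: dict[str, np.ndarray]
    z: np.ndarray | None
    prior: PriorSpec
    schedule: dict
    seed: int | None
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def h2(self) -> np.ndarray:
        return heritability(self.draws["sigma_a"])

    def rhat(self) -> dict[str, float]:
        out = {k: gelman_rubin(v) for k, v in self.draws.items()}
        out["h2"] = gelman_rubin(self.h2)
        if self.z is not None:
            zr = [gelman_rubin(self.z[:, :, j]) for j in range(self.z.shape[2])]
            out["z_max"] = float(np.max(zr))
        return out

    def summary(self, level: float = 0.95) -> dict:
        mean, lo, hi = posterior_summary(self.h2, level)
        return {
            "prior": self.prior.name or self.prior.family,
            "h2_mean": mean,
            "h2_low": lo,
            "h2_high": hi,
            "interval_display": format_interval(lo, hi),
            "rhat_max": max(self.rhat().values()),
        }

    def draws_frame(self) -> pd.DataFrame:
        """Long-form (chain, draw, parameter, value) table of scalar draws."""
        rows = []
        for name, arr in {**self.draws, "h2": self.h2}.items():
            c, d = arr.shape
            rows.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), d),
                        "draw": np.tile(np.arange(d), c),
                        "parameter": name,
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _descendant_influence(data: ModelData) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """For each animal with offspring: (index, affected indices, coefficients).

    The coefficient vector gives the change of each unit breeding value per
    unit change of z_j: s_j for j itself, halved along each parent-offspring
    edge below it.
    """
    n = data.n
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        if data.sire_idx[i] >= 0:
            children[data.sire_idx[i]].append(i)
        if data.dam_idx[i] >= 0:
            children[data.dam_idx[i]].append(i)
    out = []
    for j in range(n):
        if not children[j]:
            continue
        c = np.zeros(n)
        c[j] = data.s[j]
        for k in range(j + 1, n):
            acc = 0.0
            if data.sire_idx[k] >= 0:
                acc += c[data.sire_idx[k]]
            if data.dam_idx[k] >= 0:
                acc += c[data.dam_idx[k]]
            if acc != 0.0:
                c[k] = 0.5 * acc
        idx = np.nonzero(c)[0]
        out.append((j, idx, c[idx]))
    return out


class _ParentGroup:
    """A set of parents whose descendant index sets are pairwise disjoint.

    Updates of the members' gametic deviations touch non-overlapping parts of
    the state, so their Metropolis accept/reject steps commute exactly and
    can be carried out in one vectorized sweep (in a cattery the dams form
    one such group and the sires another).
    """

    def __init__(self, members, data: ModelData):
        self.j = np.array([m[0] for m in members], dtype=np.int64)
        self.size = len(members)
        idx_parts, coeff_parts, member_parts = [], [], []
        oidx, ocoeff, oy, omember = [], [], [], []
        for g, (j, idx, coeff) in enumerate(members):
            idx_parts.append(idx)
            coeff_parts.append(coeff)
            member_parts.append(np.full(len(idx), g))
            om = data.observed[idx]
            # pad each observed segment so it is never empty (the pad entry
            # has coefficient 0 and contributes exactly 0 to the likelihood)
            oidx.append(np.concatenate([idx[om], [0]]))
            ocoeff.append(np.concatenate([coeff[om], [0.0]]))
            oy.append(np.concatenate([data.y[idx][om], [0.0]]))
            omember.append(np.full(int(om.sum()) + 1, g))
        self.idx = np.concatenate(idx_parts)
        self.coeff = np.concatenate(coeff_parts)
        self.member = np.concatenate(member_parts)
        self.obs_idx = np.concatenate(oidx)
        self.obs_coeff = np.concatenate(ocoeff)
        self.obs_y = np.concatenate(oy)
        self.obs_member = np.concatenate(omember)
        counts = np.bincount(self.obs_member, minlength=self.size)
        self.obs_segments = np.concatenate([[0], np.cumsum(counts)[:-1]])


def _color_parents(influence, data: ModelData) -> list[_ParentGroup]:
    """Greedy grouping of parents into non-overlapping update groups."""
    groups: list[list] = []
    used: list[np.ndarray] = []
    for j, idx, coeff in influence:
        placed = False
        for g, mask in enumerate(used):
            if not mask[idx].any():
                groups[g].append((j, idx, coeff))
                mask[idx] = True
                placed = True
                break
        if not placed:
            mask = np.zeros(data.n, dtype=bool)
            mask[idx] = True
            used.append(mask)
            groups.append([(j, idx, coeff)])
    return [_ParentGroup(g, data) for g in groups]


def run_mcmc(
    data: ModelData,
    prior: PriorSpec | str = "cauchy25",
    chains: int = 4,
    iterations: int = DEFAULT_SCHEDULE["iterations"],
    burn_in: int = DEFAULT_SCHEDULE["burn_in"],
    thin: int = DEFAULT_SCHEDULE["thin"],
    seed: int | None = None,
    store_z: bool = False,
) -> AnimalModelPosterior:
    """Adaptive Metropolis-within-Gibbs sampler for the animal model.

    Blocks: all terminal animals' z jointly (their updates are mutually
    independent given the rest, so accept/reject is per animal and
    vectorized), the parents' z in disjoint-descendant groups (a change
    propagates to descendants; parents whose descendant sets do not overlap
    are updated in one vectorized sweep), the three regression coefficients
    as one block, and log sigma_a.  A joint (sigma_a, z) rescaling move that
    keeps all breeding values — hence the likelihood — fixed is interleaved
    after the sigma_a step; this ancillarity-sufficiency interweaving breaks
    the funnel-shaped coupling between the additive SD and the gametic
    deviations that otherwise makes the non-centered sampler mix very
    slowly.  Scales adapt toward acceptance 0.44 (scalar/coordinatewise) and
    0.234 (the beta block) during burn-in only.  All chains advance in
    lockstep as vectorized rows, and the whole run is a deterministic
    function of (data, config, seed).
    """
    if isinstance(prior, str):
        prior = PRIOR_PRESETS[prior]
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    n, C = data.n, chains
    n_draws = (iterations - burn_in) // thin

    root = np.random.SeedSequence(seed)
    chain_seeds, stream_seed = root.spawn(2)
    rng = np.random.Generator(np.random.PCG64(stream_seed))

    obs = np.nonzero(data.observed)[0]
    y_obs = data.y[obs]
    xfix = np.column_stack([np.ones(n), data.year_c, data.sex])  # (n, 3)

    influence = _descendant_influence(data)
    groups = _color_parents(influence, data)
    internal = np.array([j for j, _, _ in influence], dtype=np.int64)
    terminal_mask = np.ones(n, dtype=bool)
    terminal_mask[internal] = False
    term = np.nonzero(terminal_mask)[0]
    term_obs_mask = data.observed[term]

    # --- initialization (per-chain jitter from chain-indexed seed streams)
    init_rngs = [np.random.Generator(np.random.PCG64(s))
                 for s in chain_seeds.spawn(C)]
    beta = np.empty((C, 3))
    sigma = np.empty(C)
    z = np.zeros((C, n))
    for c in range(C):
        ok = False
        for _ in range(100):
            beta[c] = init_rngs[c].normal(0.0, 0.1, size=3)
            sigma[c] = init_rngs[c].uniform(0.1, 2.0)
            if np.isfinite(prior.logpdf(sigma[c])):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                "could not find a finite-posterior initial state in 100 tries"
            )

    atil = np.tile(_unit_breeding_values(np.zeros(n), data), (C, 1))  # zeros
    eta_fix = beta @ xfix.T                     # (C, n)
    eta = eta_fix + sigma[:, None] * atil

    def loglik_rows(eta_mat: np.ndarray) -> np.ndarray:
        e = eta_mat[:, obs]
        return np.sum(y_obs * e - np.logaddexp(0.0, e), axis=1)

    ll = loglik_rows(eta)

    # adaptive proposal scales (log scale), per chain
    ls_term = np.full(C, np.log(0.5))
    ls_group = [np.full((C, g.size), np.log(0.5)) for g in groups]
    ls_beta = np.full(C, np.log(0.1))
    ls_sigma = np.full(C, np.log(0.3))
    ls_asis = np.full(C, np.log(0.3))
    acc_term = np.zeros(C)
    acc_group = [np.zeros((C, g.size)) for g in groups]
    acc_beta = np.zeros(C)
    acc_sigma = np.zeros(C)
    acc_asis = np.zeros(C)
    ADAPT_EVERY = 50
    SIGMA_SWEEPS = 3
    n_adapt_batches = 0

    totals = {"terminal_z": 0.0, "parent_z": 0.0, "beta": 0.0,
              "sigma_a": 0.0, "asis": 0.0}
    counts = dict.fromkeys(totals, 0)

    draws = {k: np.empty((C, n_draws)) for k in
             ("beta0", "beta_year", "beta_sex", "sigma_a")}
    z_draws = np.empty((C, n_draws, n)) if store_z else None

    s_term = data.s[term]
    # per-animal likelihood pieces for terminals (0 where unphenotyped)
    yt = np.where(term_obs_mask, data.y[term], 0.0)

    d_idx = 0
    for it in range(1, iterations + 1):
        # --- 1. terminal z, vectorized over animals and chains -------------
        eps = np.exp(ls_term)[:, None] * rng.standard_normal((C, len(term)))
        z_t = z[:, term]
        d_atil = s_term[None, :] * eps
        eta_t = eta[:, term]
        eta_new = eta_t + sigma[:, None] * d_atil
        dll = yt * (eta_new - eta_t) - (
            np.logaddexp(0.0, eta_new) - np.logaddexp(0.0, eta_t)
        )
        dll[:, ~term_obs_mask] = 0.0
        dlp = -0.5 * ((z_t + eps) ** 2 - z_t**2)
        accept = np.log(rng.random((C, len(term)))) < dll + dlp
        z[:, term] = np.where(accept, z_t + eps, z_t)
        atil[:, term] += np.where(accept, d_atil, 0.0)
        eta[:, term] = np.where(accept, eta_new, eta_t)
        ll += np.sum(np.where(accept & term_obs_mask[None, :], dll, 0.0), axis=1)
        acc_term += accept.mean(axis=1)
        totals["terminal_z"] += accept.mean()
        counts["terminal_z"] += 1

        # --- 2. parents' z, vectorized over disjoint-descendant groups -----
        for gi, grp in enumerate(groups):
            eps = np.exp(ls_group[gi]) * rng.standard_normal((C, grp.size))
            # likelihood change, summed per member over its observed descendants
            d_obs = (sigma[:, None] * grp.obs_coeff[None, :]
                     * eps[:, grp.obs_member])
            eta_o = eta[:, grp.obs_idx]
            dll_e = (grp.obs_y[None, :] * d_obs
                     - (np.logaddexp(0.0, eta_o + d_obs)
                        - np.logaddexp(0.0, eta_o)))
            dll = np.add.reduceat(dll_e, grp.obs_segments, axis=1)
            z_g = z[:, grp.j]
            dlp = -0.5 * ((z_g + eps) ** 2 - z_g**2)
            accept = np.log(rng.random((C, grp.size))) < dll + dlp
            amask = accept[:, grp.member]
            d_atil = np.where(amask, grp.coeff[None, :] * eps[:, grp.member], 0.0)
            atil[:, grp.idx] += d_atil
            eta[:, grp.idx] += sigma[:, None] * d_atil
            z[:, grp.j] = np.where(accept, z_g + eps, z_g)
            ll += np.sum(np.where(accept, dll, 0.0), axis=1)
            acc_group[gi] += accept
            totals["parent_z"] += accept.mean() / len(groups)
        counts["parent_z"] += 1

        # --- 3. beta block --------------------------------------------------
        eps_b = np.exp(ls_beta)[:, None] * rng.standard_normal((C, 3))
        eta_new = eta + (eps_b @ xfix.T)
        ll_new = loglik_rows(eta_new)
        dlp_b = np.sum(
            ((beta**2) - (beta + eps_b) ** 2), axis=1
        ) / (2.0 * BETA_PRIOR_SD**2)
        acc = np.log(rng.random(C)) < (ll_new - ll) + dlp_b
        beta[acc] += eps_b[acc]
        eta[acc] = eta_new[acc]
        ll[acc] = ll_new[acc]
        acc_beta += acc
        totals["beta"] += acc.mean()
        counts["beta"] += 1
        eta_fix = beta @ xfix.T

        # --- 4 + 5. log sigma_a, alternated with the interweaved rescaling --
        # the pair is repeated a few times per sweep: both moves are O(C n)
        # and the additive SD is the slowest-mixing coordinate of the model
        for _ in range(SIGMA_SWEEPS):
            eps_s = np.exp(ls_sigma) * rng.standard_normal(C)
            sigma_new = sigma * np.exp(eps_s)
            eta_new = eta_fix + sigma_new[:, None] * atil
            ll_new = loglik_rows(eta_new)
            dprior = prior.logpdf(sigma_new) - prior.logpdf(sigma)
            jac = np.log(sigma_new) - np.log(sigma)
            acc = np.log(rng.random(C)) < (ll_new - ll) + dprior + jac
            sigma[acc] = sigma_new[acc]
            eta[acc] = eta_new[acc]
            ll[acc] = ll_new[acc]
            acc_sigma += acc
            totals["sigma_a"] += acc.mean()
            counts["sigma_a"] += 1

            # interweaved (sigma_a, z) rescaling with breeding values fixed:
            # sigma' = sigma e^eps, z' = z e^-eps leaves a = sigma * atil (and
            # the likelihood) unchanged; accept on the priors plus the
            # e^{(1-n) eps} volume factor of the deterministic rescaling.
            eps_a = np.exp(ls_asis) * rng.standard_normal(C)
            sigma_new = sigma * np.exp(eps_a)
            shrink = np.exp(-eps_a)
            dlp_z = -0.5 * (shrink**2 - 1.0) * np.sum(z**2, axis=1)
            dprior = prior.logpdf(sigma_new) - prior.logpdf(sigma)
            acc = np.log(rng.random(C)) < dlp_z + dprior + (1.0 - n) * eps_a
            if np.any(acc):
                z[acc] *= shrink[acc, None]
                atil[acc] *= shrink[acc, None]
                sigma[acc] = sigma_new[acc]
                # a = sigma * atil and hence eta and ll are unchanged
            acc_asis += acc
            totals["asis"] += acc.mean()
            counts["asis"] += 1

        # --- adaptation during burn-in only ---------------------------------
        if it % ADAPT_EVERY == 0:
            if it <= burn_in:
                n_adapt_batches += 1
                step = min(0.5, 2.0 / np.sqrt(n_adapt_batches))
                ls_term += step * (acc_term / ADAPT_EVERY - 0.44)
                for gi in range(len(groups)):
                    ls_group[gi] += step * (acc_group[gi] / ADAPT_EVERY - 0.44)
                ls_beta += step * (acc_beta / ADAPT_EVERY - 0.234)
                ls_sigma += step * (acc_sigma / (ADAPT_EVERY * SIGMA_SWEEPS) - 0.44)
                ls_asis += step * (acc_asis / (ADAPT_EVERY * SIGMA_SWEEPS) - 0.44)
            acc_term[:] = 0.0
            for gi in range(len(groups)):
                acc_group[gi][:] = 0.0
            acc_beta[:] = 0.0
            acc_sigma[:] = 0.0
            acc_asis[:] = 0.0

        # --- retain ----------------------------------------------------------
        if it > burn_in and (it - burn_in) % thin == 0:
            draws["beta0"][:, d_idx] = beta[:, 0]
            draws["beta_year"][:, d_idx] = beta[:, 1]
            draws["beta_sex"][:, d_idx] = beta[:, 2]
            draws["sigma_a"][:, d_idx] = sigma
            if store_z:
                z_draws[:, d_idx, :] = z
            d_idx += 1

    acceptance = {k: totals[k] / counts[k] for k in totals}
    return AnimalModelPosterior(
        draws=draws,
        z=z_draws,
        prior=prior,
        schedule=dict(iterations=iterations, burn_in=burn_in, thin=thin,
                      chains=chains),
        seed=seed,
        acceptance=acceptance,
    )


def heritability_table(
    ped: Pedigree,
    priors: tuple[str, ...] = TABLE_PRIOR_SET,
    seed: int | None = None,
    **schedule,
) -> pd.DataFrame:
    """Run the model under each prior preset and summarize h2 per prior.

    Mirrors the usual reporting layout: prior, posterior mean h2, central 95%
    interval, worst Gelman-Rubin statistic across the scalar parameters.
    """
    data = ModelData.from_pedigree(ped)
    rows = []
    for i, key in enumerate(priors):
        post = run_mcmc(
            data,
            prior=key,
            seed=None if seed is None else seed + i,
            **schedule,
        )
        summ = post.summary()
        summ["prior_key"] = key
        rows.append(summ)
    return pd.DataFrame(rows)
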