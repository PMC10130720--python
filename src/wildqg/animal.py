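"""GRM-structured linear mixed "animal models" fitted by Gibbs sampling.

The model for a floral trait y measured on replicate flowers is

    y = X b + Z1 a + Z2 s + Z3 i + e

with fixed effects b (intercept and elevation), additive genetic values
a ~ N(0, G V_a) structured by the genome-wide relatedness matrix G, site
effects s ~ N(0, I V_s), permanent-environment plant effects i ~ N(0, I V_i)
and flower-level residuals e ~ N(0, I V_e).  A "naive" variant drops the
elevation and site terms.  Posterior draws of the variance components give
narrow-sense heritability h2 = V_a / (V_a + V_s + V_i + V_e), mean-
standardized evolvability e = V_a / xbar^2, and (from the bivariate model)
the genetic correlation r_G.  Model comparison uses DIC with the
conditional-on-random-effects deviance.

Sampling is blocked Gibbs on the mixed-model equations: all location effects
are drawn jointly from their Gaussian conditional, each variance from its
scaled inverse-chi-squared (inverse-Wishart in the bivariate case)
conditional.  An optional parameter-expansion move (working parameter with a
standard-normal prior, giving a scaled-F / chi-squared-with-1-df style prior
on the component) improves mixing for variances near zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .relatedness import RelatednessMatrix, stabilize_for_inversion

logger = logging.getLogger(__name__)

LOG2PI = float(np.log(2.0 * np.pi))


class SamplerError(RuntimeError):
    """Raised when the Gibbs sampler hits a non-positive-definite system."""


@dataclass
class TraitModelSpec:
    """What goes into the animal model for one (or two) trait(s)."""

    traits: tuple[str, ...]
    fixed: tuple[str, ...] = ("elevation_m",)
    naive: bool = False  # True: drop elevation and site (additive + PE only)
    px: bool = False  # parameter expansion for additive and site components

    def __post_init__(self) -> None:
        if isinstance(self.traits, str):
            self.traits = (self.traits,)
        self.traits = tuple(self.traits)
        if len(self.traits) not in (1, 2):
            raise ValueError("one (univariate) or two (bivariate) traits")
        if self.naive:
            self.fixed = ()


@dataclass
class GibbsPriors:
    """Weakly informative defaults for the variance-component priors.

    Univariate components get scaled-inverse-chi-squared(nu, s2) priors with
    tiny ``nu`` (near-flat); ``s2`` defaults to a quarter of the phenotypic
    variance per component.  Bivariate blocks get inverse-Wishart(nu_mv, S)
    priors with ``nu_mv = p + 2``.  ``px_alpha_var`` is the variance of the
    standard-normal working parameter used by the parameter-expanded move.
    """

    nu: float = 0.002
    s2: dict | None = None  # per-component scale {a, s, i, e}; None -> auto
    nu_mv: float = 4.0
    px_alpha_var: float = 1.0

    def scale_for(self, comp: str, vy: float) -> float:
        if self.s2 and comp in self.s2:
            return float(self.s2[comp])
        return vy / 4.0


@dataclass
class DesignBundle:
    """Aligned response, design matrices and (inverse) relatedness."""

    y: np.ndarray  # (n, T)
    X: np.ndarray  # (n, nf) incl. intercept
    Z1: np.ndarray  # (n, q) plant -> record, GRM-structured
    Z2: np.ndarray | None  # (n, ns) site -> record (None if naive)
    Z3: np.ndarray  # (n, q) plant -> record, identity-structured
    plant_ids: list[str]
    site_names: list[str]
    fixed_names: list[str]
    grm: RelatednessMatrix  # stabilized, subset to plant_ids
    ginv: np.ndarray
    trait_names: tuple[str, ...]
    trait_means: dict


def build_model_matrices(
    data: pd.DataFrame,
    spec: TraitModelSpec,
    grm: RelatednessMatrix,
) -> DesignBundle:
    """Assemble y, X and the Z incidence matrices, aligned to the GRM.

    Rows with a missing trait value are dropped; every phenotyped plant must
    be present in the GRM.  Elevation is centred before entering X.
    """
    cols = list(spec.traits)
    df = data.dropna(subset=cols).reset_index(drop=True)
    if df.empty:
        raise ValueError("no phenotype records")
    plants = list(pd.unique(df["plant_id"]))
    missing = set(plants) - set(grm.individual_ids)
    if missing:
        raise KeyError(
            f"{len(missing)} phenotyped plants missing from GRM: "
            f"{sorted(missing)[:10]}"
        )
    reps = df.groupby("plant_id", sort=False).size()
    if (reps < 2).any():
        warnings.warn(
            f"{int((reps < 2).sum())} plants have a single replicate; "
            "V_i is weakly identified for them",
            stacklevel=2,
        )
    g_sub = stabilize_for_inversion(grm.subset(plants))
    ginv = np.linalg.inv(g_sub.values)
    ginv = (ginv + ginv.T) / 2.0

    n = len(df)
    q = len(plants)
    plant_idx = pd.Categorical(df["plant_id"], categories=plants).codes
    Z1 = np.zeros((n, q))
    Z1[np.arange(n), plant_idx] = 1.0

    fixed_names = ["intercept"]
    Xcols = [np.ones(n)]
    for f in spec.fixed:
        v = df[f].to_numpy(dtype=float)
        if v.std() == 0.0:
            logger.info("fixed covariate %r is constant; dropped", f)
            continue
        Xcols.append(v - v.mean())
        fixed_names.append(f)
    X = np.column_stack(Xcols)

    Z2, site_names = None, []
    if not spec.naive:
        site_names = list(pd.unique(df["site"]))
        site_idx = pd.Categorical(df["site"], categories=site_names).codes
        Z2 = np.zeros((n, len(site_names)))
        Z2[np.arange(n), site_idx] = 1.0

    y = df[cols].to_numpy(dtype=float)
    trait_means = {c: float(df[c].mean()) for c in cols}
    return DesignBundle(
        y, X, Z1, Z2, Z1, plants, site_names, fixed_names,
        g_sub, ginv, spec.traits, trait_means,
    )


# ---------------------------------------------------------------------------
# posterior containers


@dataclass
class PosteriorQuantity:
    """Draws of one derived scalar with its posterior summaries."""

    name: str
    draws: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def median(self) -> float:
        return float(np.median(self.draws))

    @property
    def ci95(self) -> tuple[float, float]:
        lo, hi = np.quantile(self.draws, [0.025, 0.975])
        return float(lo), float(hi)

    @property
    def ess(self) -> float:
        return effective_sample_size(self.draws)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.ci95
        return f"<{self.name}: {self.mean:.4g} [{lo:.4g}, {hi:.4g}]>"


def effective_sample_size(x: np.ndarray) -> float:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(np.asarray(x)[None, :]))


def heritability(draws: pd.DataFrame, prefix: str = "") -> PosteriorQuantity:
    """Per-draw h2 = V_a / (V_a + V_s + V_i + V_error), then summarized.

    Works on a draws table with columns ``V_a``, ``V_s`` (optional, treated
    as 0 when absent — the naive model), ``V_i`` and ``V_error``; a ``prefix``
    selects one trait's columns from a bivariate table.
    """
    va = draws[f"{prefix}V_a"].to_numpy()
    vs = (
        draws[f"{prefix}V_s"].to_numpy()
        if f"{prefix}V_s" in draws
        else np.zeros_like(va)
    )
    vi = draws[f"{prefix}V_i"].to_numpy()
    ve = draws[f"{prefix}V_error"].to_numpy()
    total = va + vs + vi + ve
    ok = total > 0
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("dropping %d draws with zero total variance", n_bad)
    return PosteriorQuantity(f"{prefix}h2", va[ok] / total[ok])


def evolvability(
    draws: pd.DataFrame, trait_mean: float, prefix: str = ""
) -> PosteriorQuantity:
    """Per-draw mean-standardized additive variance e = V_a / xbar^2, in %."""
    if not trait_mean > 0:
        raise ValueError("evolvability requires a positive trait mean")
    va = draws[f"{prefix}V_a"].to_numpy()
    return PosteriorQuantity(
        f"{prefix}evolvability_pct", 100.0 * va / trait_mean**2
    )


# ---------------------------------------------------------------------------
# the model


class AnimalModel:
    """Univariate or bivariate animal model on replicated floral phenotypes.

    Parameters
    ----------
    data : DataFrame with plant_id, site, elevation_m, flower_idx and trait
        columns (one row per flower).
    grm : RelatednessMatrix over (at least) the phenotyped plants.
    traits : one or two trait column names.
    naive : drop elevation and site (relatedness + individual effects only).
    px : parameter-expanded updates for the additive and site components.
    priors : GibbsPriors; defaults are weakly informative.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        grm: RelatednessMatrix,
        traits,
        *,
        fixed: tuple[str, ...] = ("elevation_m",),
        naive: bool = False,
        px: bool = False,
        priors: GibbsPriors | None = None,
    ) -> None:
        self.spec = TraitModelSpec(
            traits if not isinstance(traits, str) else (traits,),
            fixed=fixed, naive=naive, px=px,
        )
        self.priors = priors or GibbsPriors()
        self.bundle = build_model_matrices(data, self.spec, grm)

    @classmethod
    def from_study(cls, study, grm: RelatednessMatrix, traits, **kw) -> "AnimalModel":
        return cls(study.phenotypes, grm, traits, **kw)

    @property
    def bivariate(self) -> bool:
        return len(self.spec.traits) == 2

    def fit(
        self,
        n_iter: int = 5000,
        burnin: int = 1000,
        thin: int = 2,
        seed: int = 0,
    ) -> "AnimalModelResults":
        if min(n_iter, burnin + 1, thin) <= 0 or burnin >= n_iter:
            raise ValueError("chain settings must be positive with burnin < n_iter")
        rng = np.random.default_rng(seed)
        if self.bivariate:
            draws, dic, fitted = _gibbs_bivariate(
                self.bundle, self.priors, self.spec, n_iter, burnin, thin, rng
            )
        else:
            draws, dic, fitted = _gibbs_univariate(
                self.bundle, self.priors, self.spec, n_iter, burnin, thin, rng
            )
        return AnimalModelResults(self, draws, dic, fitted,
                                  chain={"n_iter": n_iter, "burnin": burnin,
                                         "thin": thin, "seed": seed})


def _sample_variance(
    rng: np.random.Generator, ss: float, q: int, nu: float, s2: float
) -> float:
    """Scaled inverse-chi-squared conditional draw."""
    return (ss + nu * s2) / rng.chisquare(q + nu)


def _usable_site_design(Z2):
    """A site term needs >= 2 levels; with one it is the intercept."""
    if Z2 is not None and Z2.shape[1] < 2:
        logger.info("single site level: site random effect dropped from fit")
        return None
    return Z2


def _gibbs_univariate(b: DesignBundle, priors, spec, n_iter, burnin, thin, rng):
    y = b.y[:, 0]
    n = y.size
    q = len(b.plant_ids)
    Z2 = _usable_site_design(b.Z2)
    blocks = [b.X, b.Z1] + ([Z2] if Z2 is not None else []) + [b.Z3]
    W = np.column_stack(blocks)
    nf = b.X.shape[1]
    ns = 0 if Z2 is None else Z2.shape[1]
    sl_f = slice(0, nf)
    sl_a = slice(nf, nf + q)
    sl_s = slice(nf + q, nf + q + ns)
    sl_i = slice(nf + q + ns, nf + q + ns + q)
    p = W.shape[1]
    WtW = W.T @ W
    Wty = W.T @ y
    ginv = b.ginv

    vy = float(np.var(y, ddof=1))
    floor = 1e-10 * vy
    # moment-style starting values
    within = float(
        pd.DataFrame({"p": np.argmax(b.Z1, axis=1), "y": y})
        .groupby("p")["y"].var(ddof=1).mean()
    )
    within = within if np.isfinite(within) and within > 0 else vy / 2
    among = max(vy - within, vy / 10)
    v = {"a": among / 2, "s": max(vy / 10, floor), "i": among / 2, "e": within}
    s2 = {c: priors.scale_for(c, vy) for c in ("a", "s", "i", "e")}

    # Parameter expansion (additive and site components): the random effect
    # enters the model as alpha * Z u with u ~ N(0, K V_u) and a standard
    # normal working parameter alpha ~ N(0, px_alpha_var); the identified
    # variance is alpha^2 V_u, whose implied prior is a heavy-tailed scaled-F
    # (chi-squared with 1 df in the numerator).  Keeping alpha explicit lets
    # the chain escape the near-zero absorbing region of the plain sampler.
    if spec.px:
        px_comps = ("a", "s", "i") if ns else ("a", "i")
    else:
        px_comps = ()
    alpha = {c: 1.0 for c in px_comps}
    scales = np.ones(p)
    sl_of = {"a": sl_a, "s": sl_s, "i": sl_i}

    n_keep = (n_iter - burnin + thin - 1) // thin
    out = np.empty((n_keep, 4 + nf + 2))  # V_a V_s V_i V_e betas h2 deviance
    fitted_sum = np.zeros(n)
    kept = 0
    for it in range(n_iter):
        for c in px_comps:
            scales[sl_of[c]] = alpha[c]
        if px_comps:
            C = WtW * np.outer(scales, scales)
            rhs = Wty * scales
        else:
            C = WtW.copy()
            rhs = Wty
        C[sl_a, sl_a] += (v["e"] / v["a"]) * ginv
        if ns:
            idx = np.arange(nf + q, nf + q + ns)
            C[idx, idx] += v["e"] / v["s"]
        idx = np.arange(nf + q + ns, p)
        C[idx, idx] += v["e"] / v["i"]
        try:
            L = linalg.cholesky(C, lower=True)
        except linalg.LinAlgError as exc:
            raise SamplerError(
                f"MME not positive definite at iteration {it} "
                f"(V = { {k: float(x) for k, x in v.items()} })"
            ) from exc
        mean = linalg.cho_solve((L, True), rhs)
        z = rng.standard_normal(p)
        theta = mean + np.sqrt(v["e"]) * linalg.solve_triangular(
            L, z, lower=True, trans="T"
        )
        e = y - W @ (theta * scales)

        for c in px_comps:
            u = theta[sl_of[c]]
            zu = W[:, sl_of[c]] @ u
            r_u = e + alpha[c] * zu
            prec = zu @ zu / v["e"] + 1.0 / priors.px_alpha_var
            mu_a = (zu @ r_u / v["e"]) / prec
            alpha[c] = mu_a + rng.standard_normal() / np.sqrt(prec)
            e = r_u - alpha[c] * zu

        a = theta[sl_a]
        v["a"] = max(_sample_variance(rng, a @ ginv @ a, q, priors.nu, s2["a"]), floor)
        if ns:
            s = theta[sl_s]
            v["s"] = max(_sample_variance(rng, s @ s, ns, priors.nu, s2["s"]), floor)
        i_eff = theta[sl_i]
        v["i"] = max(_sample_variance(rng, i_eff @ i_eff, q, priors.nu, s2["i"]), floor)
        v["e"] = max(_sample_variance(rng, e @ e, n, priors.nu, s2["e"]), floor)
        cap = 1e8 * vy  # numerical guard against heavy-tail excursions
        for c in v:
            v[c] = min(v[c], cap)

        if it >= burnin and (it - burnin) % thin == 0:
            # identified (marginal) variances fold the working parameter in
            va_id = alpha.get("a", 1.0) ** 2 * v["a"]
            vs_id = (alpha.get("s", 1.0) ** 2 * v["s"]) if ns else 0.0
            vi_id = alpha.get("i", 1.0) ** 2 * v["i"]
            h2 = va_id / (va_id + vs_id + vi_id + v["e"])
            dev = n * (LOG2PI + np.log(v["e"])) + e @ e / v["e"]
            out[kept, :4] = (va_id, vs_id, vi_id, v["e"])
            out[kept, 4:4 + nf] = theta[sl_f]
            out[kept, 4 + nf] = h2
            out[kept, 4 + nf + 1] = dev
            fitted_sum += y - e
            kept += 1

    cols = (
        ["V_a", "V_s", "V_i", "V_error"]
        + [f"beta_{f}" for f in b.fixed_names]
        + ["h2", "deviance"]
    )
    draws = pd.DataFrame(out[:kept], columns=cols)
    fitted_bar = fitted_sum / kept
    ve_bar = float(draws["V_error"].mean())
    resid_bar = y - fitted_bar
    d_hat = n * (LOG2PI + np.log(ve_bar)) + resid_bar @ resid_bar / ve_bar
    d_bar = float(draws["deviance"].mean())
    dic = 2.0 * d_bar - d_hat
    return draws, float(dic), fitted_bar


def _gibbs_bivariate(b: DesignBundle, priors, spec, n_iter, burnin, thin, rng):
    Y = b.y  # (n, 2)
    n, T = Y.shape
    if (Y.std(axis=0) == 0).any():
        raise ValueError("a trait has zero variance; bivariate model undefined")
    q = len(b.plant_ids)
    Z2 = _usable_site_design(b.Z2)
    blocks = [b.X, b.Z1] + ([Z2] if Z2 is not None else []) + [b.Z3]
    W = np.column_stack(blocks)
    nf = b.X.shape[1]
    ns = 0 if Z2 is None else Z2.shape[1]
    p = W.shape[1]
    sl_a = slice(nf, nf + q)
    sl_s = slice(nf + q, nf + q + ns)
    sl_i = slice(nf + q + ns, p)
    WtW = W.T @ W
    WtY = W.T @ Y  # (p, 2)
    ginv = b.ginv

    vy = np.var(Y, axis=0, ddof=1)
    nu0 = priors.nu_mv
    # prior scale matrices: prior mean = diag(vy)/4
    mk = lambda frac: np.diag(vy * frac) * (nu0 - T - 1)
    S0 = {"a": mk(0.25), "s": mk(0.25), "i": mk(0.25), "e": mk(0.25)}
    Sig = {
        "a": np.diag(vy * 0.2),
        "s": np.diag(vy * 0.2),
        "i": np.diag(vy * 0.2),
        "e": np.diag(vy * 0.4),
    }

    n_keep = (n_iter - burnin + thin - 1) // thin
    names = ["a", "s", "i", "e"] if ns else ["a", "i", "e"]
    comp_cols = []
    for c, lab in (("a", "V_a"), ("s", "V_s"), ("i", "V_i"), ("e", "V_error")):
        if c == "s" and not ns:
            continue
        comp_cols += [f"t1_{lab}", f"t2_{lab}", f"cov_{lab[2:]}"]
    cols = comp_cols + ["r_G", "t1_h2", "t2_h2", "deviance"]
    out = np.empty((n_keep, len(cols)))
    fitted_sum = np.zeros((n, T))
    kept = 0

    for it in range(n_iter):
        Rinv = np.linalg.inv(Sig["e"])
        C = np.block(
            [[Rinv[0, 0] * WtW, Rinv[0, 1] * WtW],
             [Rinv[1, 0] * WtW, Rinv[1, 1] * WtW]]
        )
        for c, sl, K in (("a", sl_a, ginv), ("s", sl_s, None), ("i", sl_i, None)):
            if c == "s" and not ns:
                continue
            P = np.linalg.inv(Sig[c])
            for t1 in range(T):
                for t2 in range(T):
                    rows = slice(t1 * p + sl.start, t1 * p + sl.stop)
                    colsl = slice(t2 * p + sl.start, t2 * p + sl.stop)
                    if K is None:
                        idx_r = np.arange(t1 * p + sl.start, t1 * p + sl.stop)
                        idx_c = np.arange(t2 * p + sl.start, t2 * p + sl.stop)
                        C[idx_r, idx_c] += P[t1, t2]
                    else:
                        C[rows, colsl] += P[t1, t2] * K
        rhs = np.concatenate(
            [Rinv[t, 0] * WtY[:, 0] + Rinv[t, 1] * WtY[:, 1] for t in range(T)]
        )
        try:
            L = linalg.cholesky(C, lower=True)
        except linalg.LinAlgError as exc:
            raise SamplerError(f"bivariate MME not PD at iteration {it}") from exc
        mean = linalg.cho_solve((L, True), rhs)
        theta = mean + linalg.solve_triangular(
            L, rng.standard_normal(2 * p), lower=True, trans="T"
        )
        Th = theta.reshape(T, p).T  # (p, 2)
        E = Y - W @ Th

        A = Th[sl_a]
        Sig["a"] = stats.invwishart.rvs(
            df=nu0 + q, scale=S0["a"] + A.T @ ginv @ A, random_state=rng
        )
        if ns:
            S_ = Th[sl_s]
            Sig["s"] = stats.invwishart.rvs(
                df=nu0 + ns, scale=S0["s"] + S_.T @ S_, random_state=rng
            )
        I_ = Th[sl_i]
        Sig["i"] = stats.invwishart.rvs(
            df=nu0 + q, scale=S0["i"] + I_.T @ I_, random_state=rng
        )
        Sig["e"] = stats.invwishart.rvs(
            df=nu0 + n, scale=S0["e"] + E.T @ E, random_state=rng
        )

        if it >= burnin and (it - burnin) % thin == 0:
            vals = []
            for c in ("a", "s", "i", "e"):
                if c == "s" and not ns:
                    continue
                M = Sig[c]
                vals += [M[0, 0], M[1, 1], M[0, 1]]
            Sa = Sig["a"]
            rg = Sa[0, 1] / np.sqrt(Sa[0, 0] * Sa[1, 1])
            h2s = []
            for t in range(T):
                tot = (
                    Sig["a"][t, t]
                    + (Sig["s"][t, t] if ns else 0.0)
                    + Sig["i"][t, t]
                    + Sig["e"][t, t]
                )
                h2s.append(Sig["a"][t, t] / tot)
            Rinv_now = np.linalg.inv(Sig["e"])
            _, logdet = np.linalg.slogdet(Sig["e"])
            dev = n * (2 * LOG2PI + logdet) + float(np.sum((E @ Rinv_now) * E))
            out[kept] = vals + [rg, h2s[0], h2s[1], dev]
            fitted_sum += Y - E
            kept += 1

    draws = pd.DataFrame(out[:kept], columns=cols)
    fitted_bar = fitted_sum / kept
    E_bar = Y - fitted_bar
    Se_bar = np.array(
        [
            [draws["t1_V_error"].mean(), draws["cov_error"].mean()],
            [draws["cov_error"].mean(), draws["t2_V_error"].mean()],
        ]
    )
    _, logdet = np.linalg.slogdet(Se_bar)
    d_hat = n * (2 * LOG2PI + logdet) + float(
        np.sum((E_bar @ np.linalg.inv(Se_bar)) * E_bar)
    )
    d_bar = float(draws["deviance"].mean())
    dic = 2.0 * d_bar - d_hat
    return draws, float(dic), fitted_bar


class AnimalModelResults:
    """Posterior draws and derived quantities from an AnimalModel fit."""

    def __init__(self, model: AnimalModel, draws: pd.DataFrame, dic: float,
                 fitted: np.ndarray, chain: dict) -> None:
        self.model = model
        self.draws = draws
        self.dic = dic
        self.fitted = fitted
        self.chain = chain

    # -- summaries ---------------------------------------------------------
    @property
    def point(self) -> pd.Series:
        return self.draws.mean()

    @property
    def ci95(self) -> pd.DataFrame:
        qs = self.draws.quantile([0.025, 0.975]).T
        qs.columns = ["lower", "upper"]
        return qs

    @property
    def ess(self) -> pd.Series:
        return pd.Series(
            {c: effective_sample_size(self.draws[c].to_numpy())
             for c in self.draws.columns}
        )

    def heritability(self, trait: str | None = None) -> PosteriorQuantity:
        return heritability(self.draws, prefix=self._prefix(trait))

    def evolvability(self, trait: str | None = None) -> PosteriorQuantity:
        name = trait or self.model.spec.traits[0]
        xbar = self.model.bundle.trait_means[name]
        return evolvability(self.draws, xbar, prefix=self._prefix(trait))

    def genetic_correlation(self) -> PosteriorQuantity:
        if "r_G" not in self.draws:
            raise ValueError("genetic correlation requires a bivariate fit")
        return PosteriorQuantity("r_G", self.draws["r_G"].to_numpy())

    def _prefix(self, trait: str | None) -> str:
        traits = self.model.spec.traits
        if len(traits) == 1:
            return ""
        if trait is None:
            raise ValueError(f"bivariate fit: specify one of {traits}")
        return f"t{traits.index(trait) + 1}_"

    def summary(self) -> str:
        traits = self.model.spec.traits
        lines = [
            f"Animal model ({'bivariate' if len(traits) == 2 else 'univariate'}: "
            f"{', '.join(traits)})",
            f"records: {self.model.bundle.y.shape[0]}, "
            f"plants: {len(self.model.bundle.plant_ids)}, "
            f"naive: {self.model.spec.naive}",
            f"chain: {self.chain}",
            f"DIC (conditional): {self.dic:.2f}",
            "",
            f"{'parameter':<22}{'mean':>10}{'2.5%':>10}{'97.5%':>10}{'ESS':>8}",
        ]
        ci = self.ci95
        for c in self.draws.columns:
            if c == "deviance":
                continue
            x = self.draws[c].to_numpy()
            lines.append(
                f"{c:<22}{x.mean():>10.4g}{ci.loc[c, 'lower']:>10.4g}"
                f"{ci.loc[c, 'upper']:>10.4g}{effective_sample_size(x):>8.0f}"
            )
        for t in traits:
            pref = "" if len(traits) == 1 else f"t{traits.index(t) + 1}_"
            h2 = heritability(self.draws, pref)
            e = evolvability(self.draws, self.model.bundle.trait_means[t], pref)
            lo, hi = h2.ci95
            lines.append(f"h2[{t}] = {h2.mean:.3f} [{lo:.3f}, {hi:.3f}]")
            lo, hi = e.ci95
            lines.append(f"e%[{t}] = {e.mean:.3g} [{lo:.3g}, {hi:.3g}]")
        if "r_G" in self.draws:
            rg = self.genetic_correlation()
            lo, hi = rg.ci95
            lines.append(f"r_G = {rg.mean:.3f} [{lo:.3f}, {hi:.3f}]")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        ci = self.ci95
        return {
            "traits": list(self.model.spec.traits),
            "naive": self.model.spec.naive,
            "dic": self.dic,
            "chain": self.chain,
            "point": {c: float(v) for c, v in self.point.items()},
            "ci95": {c: [float(ci.loc[c, "lower"]), float(ci.loc[c, "upper"])]
                     for c in self.draws.columns},
        }


def compare_naive_full(
    data: pd.DataFrame,
    grm: RelatednessMatrix,
    trait: str,
    *,
    px: bool = False,
    priors: GibbsPriors | None = None,
    n_iter: int = 3000,
    burnin: int = 500,
    thin: int = 1,
    seed: int = 0,
) -> dict:
    """Fit the full and naive models on identical data and compare by DIC.

    Returns per-model DIC and posterior-mean h2, the DIC difference
    (naive - full) and which model is preferred (lower DIC).
    """
    full = AnimalModel(data, grm, trait, px=px, priors=priors).fit(
        n_iter=n_iter, burnin=burnin, thin=thin, seed=seed
    )
    naive = AnimalModel(data, grm, trait, naive=True, px=px, priors=priors).fit(
        n_iter=n_iter, burnin=burnin, thin=thin, seed=seed + 1
    )
    delta = naive.dic - full.dic
    return {
        "full": {"dic": full.dic, "h2": full.heritability().mean},
        "naive": {"dic": naive.dic, "h2": naive.heritability().mean},
        "delta_dic": delta,
        "preferred": "full" if delta > 0 else "naive",
        "results": {"full": full, "naive": naive},
    }
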