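"""Nonparametric selection differentials and gradients from a fitness surface.

Fruit set (fruits / flower scars) is the female-fitness proxy.  A penalized
B-spline additive model with a logit link and binomial counts is fitted to
absolute fitness on variance-standardized plant-mean traits (P-splines:
cubic B-spline basis with a second-order difference penalty, smoothing chosen
by AIC = deviance + 2 * effective df); site enters as a ridge-penalized
factor term (random-effect-like) and elevation linearly when it is not
confounded with site.  Standardized selection coefficients are numerical
first and second partial derivatives of relative fitness w(z) = W(z)/Wbar,
averaged over the observed phenotype distribution:

    s or beta_j   = mean_i dw/dz_j |_{z_i}
    c or gamma_jk = mean_i d2w/(dz_j dz_k) |_{z_i}

Univariate fits give the differentials (s, c); a bivariate additive fit gives
the gradients (beta, gamma, including the interaction term from the mixed
partial).  Quadratic gradients follow the averaged-second-derivative
convention (no factor-of-two halving).  Inference is by case bootstrap over
plants.

In the identity-link, unpenalized, quadratic-basis limit the estimator
reduces exactly to Lande-Arnold least-squares gradients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)


class SurfaceFitError(RuntimeError):
    """Fit did not converge (e.g. complete separation)."""


def fruit_set(records: pd.DataFrame) -> pd.Series:
    """Per-plant fruit set = fruits / flower_scars; zero-scar plants dropped."""
    rec = records.set_index("plant_id") if "plant_id" in records else records
    scars = rec["flower_scars"]
    bad = scars <= 0
    if bad.any():
        logger.info("excluding %d plants with zero flower scars", int(bad.sum()))
    rec = rec[~bad]
    if (rec["fruits"] > rec["flower_scars"]).any():
        raise ValueError("fruits exceed flower scars for some plants")
    return rec["fruits"] / rec["flower_scars"]


def plant_table(
    phenotypes: pd.DataFrame, fitness: pd.DataFrame, traits
) -> pd.DataFrame:
    """One row per plant: trait means, site/elevation, fruits and scars."""
    traits = list(traits)
    means = phenotypes.groupby("plant_id", sort=False).agg(
        {**{t: "mean" for t in traits}, "site": "first", "elevation_m": "first"}
    )
    df = means.join(fitness.set_index("plant_id")[["fruits", "flower_scars"]],
                    how="inner")
    df = df[df["flower_scars"] > 0]
    return df.reset_index()


# ---------------------------------------------------------------------------
# penalized IRLS engine


def _bspline_basis(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    return BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()


def _make_knots(x: np.ndarray, df: int, degree: int, pad: float) -> np.ndarray:
    # df basis functions need df - degree + 1 boundary-to-boundary intervals
    n_interior = df - degree - 1
    lo, hi = x.min() - pad, x.max() + pad
    interior = (
        np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
        if n_interior > 0
        else np.empty(0)
    )
    return np.concatenate(
        [np.repeat(lo, degree + 1), interior, np.repeat(hi, degree + 1)]
    )


def _diff_penalty(m: int, order: int = 2) -> np.ndarray:
    d = np.eye(m)
    for _ in range(order):
        d = np.diff(d, axis=0)
    return d.T @ d


@dataclass
class _Smooth:
    """One trait's smooth term: basis, centring constraint and penalty.

    The raw B-spline basis partitions unity, so after column centring the
    constant coefficient direction maps to the zero function; it is removed by
    reparameterizing with an orthonormal complement ``Q`` of the ones vector
    (the usual sum-to-zero constraint absorption), leaving the linear trend in
    the penalty null space.
    """

    trait: str
    knots: np.ndarray
    degree: int
    col_means: np.ndarray
    Q: np.ndarray  # (m, m-1) constraint-absorbing reparameterization
    penalty: np.ndarray  # (m-1, m-1) transformed difference penalty

    def design(self, x: np.ndarray) -> np.ndarray:
        return (_bspline_basis(x, self.knots, self.degree) - self.col_means) @ self.Q


def _irls(
    y: np.ndarray,
    m: np.ndarray | None,
    B: np.ndarray,
    S: np.ndarray,
    family: str,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float, float, bool]:
    """Penalized IRLS.  Returns (coef, deviance, edf, converged).

    family "binomial": y successes of m trials, logit link.
    family "gaussian": identity link, unit weights (single WLS solve).
    """
    n, p = B.shape
    if family == "gaussian":
        A = B.T @ B + S
        coef = np.linalg.solve(A, B.T @ y)
        resid = y - B @ coef
        dev = float(resid @ resid)
        edf = float(np.trace(np.linalg.solve(A, B.T @ B)))
        return coef, dev, edf, True
    mu = (y + 0.5) / (m + 1.0)
    eta = np.log(mu / (1.0 - mu))
    coef = np.zeros(p)
    dev_old = np.inf
    for it in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = m * mu * (1.0 - mu)
        if (w < 1e-12).all():
            raise SurfaceFitError("degenerate working weights")
        z = eta + (y - m * mu) / np.maximum(w, 1e-12)
        BW = B * w[:, None]
        A = BW.T @ B + S
        try:
            coef = np.linalg.solve(A, BW.T @ z)
        except np.linalg.LinAlgError as exc:
            raise SurfaceFitError("singular penalized system") from exc
        eta = B @ coef
        if np.max(np.abs(eta)) > 50:
            raise SurfaceFitError(
                "diverging linear predictor (complete separation?)"
            )
        mu = 1.0 / (1.0 + np.exp(-eta))
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / (m * mu)), 0.0)
            t2 = np.where(m - y > 0, (m - y) * np.log((m - y) / (m - m * mu)), 0.0)
        dev = float(2.0 * np.sum(t1 + t2))
        if abs(dev - dev_old) < tol * (abs(dev) + 0.1):
            w = m * mu * (1.0 - mu)
            BW = B * w[:, None]
            A = BW.T @ B + S
            edf = float(np.trace(np.linalg.solve(A, BW.T @ B)))
            return coef, dev, edf, True
        dev_old = dev
    raise SurfaceFitError(f"IRLS did not converge in {max_iter} iterations")


# ---------------------------------------------------------------------------
# model / results


class FitnessSurfaceModel:
    """Binomial fitness-surface model on standardized plant-mean traits.

    Parameters
    ----------
    plants : one row per plant with trait columns, ``fruits``,
        ``flower_scars`` and (optionally) ``site`` / ``elevation_m``.
    traits : one trait (differentials) or two (gradients).
    covariates : subset of {"site", "elevation_m"}; site is a ridge-penalized
        factor term, elevation a linear term dropped when collinear with site.
    family/link : "binomial"/"logit" (default) or "gaussian"/"identity".
    smoother : "spline" (penalized P-splines) or "quadratic" (z, z^2 and the
        cross term for two traits — the Lande-Arnold limit when unpenalized).
    """

    def __init__(
        self,
        plants: pd.DataFrame,
        traits,
        *,
        covariates=("site", "elevation_m"),
        family: str = "binomial",
        link: str | None = None,
        smoother: str = "spline",
        df: int = 6,
        degree: int = 3,
        penalized: bool = True,
        site_ridge: float = 1.0,
        min_plants: int = 30,
    ) -> None:
        self.traits = [traits] if isinstance(traits, str) else list(traits)
        if len(self.traits) not in (1, 2):
            raise ValueError("one or two traits")
        if family not in ("binomial", "gaussian"):
            raise ValueError(f"unknown family {family!r}")
        self.family = family
        self.link = link or ("logit" if family == "binomial" else "identity")
        self.smoother = smoother
        self.df = df
        self.degree = degree
        self.penalized = penalized and smoother == "spline"
        self.site_ridge = site_ridge
        self.covariates = tuple(c for c in covariates if c in plants.columns)

        plants = plants.loc[plants["flower_scars"] > 0].reset_index(drop=True)
        if len(plants) < min_plants:
            raise ValueError(
                f"need >= {min_plants} plants with fitness records, "
                f"got {len(plants)}"
            )
        self.plants = plants
        self.n = len(plants)

        zraw = plants[self.traits].to_numpy(dtype=float)
        self.trait_mean = zraw.mean(axis=0)
        self.trait_sd = zraw.std(axis=0, ddof=1)
        if (self.trait_sd == 0).any():
            raise ValueError("a trait has zero variance across plants")
        self.z = (zraw - self.trait_mean) / self.trait_sd

        self._build_parametric()
        self._build_smooths()

    # -- design ------------------------------------------------------------
    def _build_parametric(self) -> None:
        cols = [np.ones(self.n)]
        names = ["intercept"]
        ridge = [0.0]
        self.site_levels: list = []
        if "site" in self.covariates:
            self.site_levels = list(pd.unique(self.plants["site"]))
            for lev in self.site_levels:
                cols.append((self.plants["site"] == lev).to_numpy(float))
                names.append(f"site[{lev}]")
                ridge.append(self.site_ridge)
        self.elevation_used = False
        if "elevation_m" in self.covariates:
            ev = self.plants["elevation_m"].to_numpy(float)
            evc = ev - ev.mean()
            M = np.column_stack(cols)
            # collinear with site factor (elevation constant within site)?
            resid = evc - M @ np.linalg.lstsq(M, evc, rcond=None)[0]
            if np.abs(resid).max() > 1e-8 * (np.abs(evc).max() + 1e-12):
                cols.append(evc / (evc.std() + 1e-12))
                names.append("elevation_m")
                ridge.append(0.0)
                self.elevation_used = True
            else:
                logger.info(
                    "elevation is collinear with the site factor; dropped"
                )
        self.Xpar = np.column_stack(cols)
        self.par_names = names
        self.par_ridge = np.asarray(ridge)

    def _build_smooths(self) -> None:
        self.smooths: list[_Smooth] = []
        self.cross = len(self.traits) == 2 and self.smoother == "quadratic"
        for j, t in enumerate(self.traits):
            x = self.z[:, j]
            if self.smoother == "spline":
                pad = 0.1 * (x.max() - x.min()) + 0.1
                knots = _make_knots(x, self.df, self.degree, pad)
                basis = _bspline_basis(x, knots, self.degree)
                m = basis.shape[1]
                from scipy.linalg import null_space

                Q = null_space(np.ones((1, m)))
                P = _diff_penalty(m)
                sm = _Smooth(t, knots, self.degree, basis.mean(axis=0),
                             Q, Q.T @ P @ Q)
            elif self.smoother == "quadratic":
                sm = _Smooth(t, np.empty(0), 0, np.zeros(2), np.eye(2),
                             np.zeros((2, 2)))
            else:
                raise ValueError(f"unknown smoother {self.smoother!r}")
            self.smooths.append(sm)

    def _smooth_design(self, z: np.ndarray, j: int) -> np.ndarray:
        if self.smoother == "quadratic":
            return np.column_stack([z, z**2]) - self.smooths[j].col_means
        return self.smooths[j].design(z)

    def _full_design(self, z: np.ndarray, par_rows: np.ndarray) -> np.ndarray:
        parts = [par_rows]
        for j in range(len(self.traits)):
            parts.append(self._smooth_design(z[:, j], j))
        if self.cross:
            parts.append((z[:, 0] * z[:, 1])[:, None])
        return np.column_stack(parts)

    def _penalty(self, alphas) -> np.ndarray:
        blocks = [np.diag(self.par_ridge)]
        for j, sm in enumerate(self.smooths):
            a = alphas[j] if self.penalized else 0.0
            blocks.append(a * sm.penalty)
        if self.cross:
            blocks.append(np.zeros((1, 1)))
        from scipy.linalg import block_diag

        return block_diag(*blocks)

    # -- fitting -----------------------------------------------------------
    def _fit_once(self, alphas):
        B = self._full_design(self.z, self.Xpar)
        S = self._penalty(alphas)
        y = self.plants["fruits"].to_numpy(float)
        m = self.plants["flower_scars"].to_numpy(float)
        if self.family == "gaussian":
            return _irls(y / m, None, B, S, "gaussian")
        return _irls(y, m, B, S, "binomial")

    def fit(
        self,
        alpha=None,
        alphas_grid=None,
    ) -> "FitnessSurfaceResults":
        """Fit the surface; ``alpha`` fixes the smoothing weights, otherwise
        they are chosen by coordinate descent on AIC over a log grid."""
        T = len(self.traits)
        if not self.penalized:
            best_alpha = [0.0] * T
        elif alpha is not None:
            best_alpha = list(np.broadcast_to(alpha, (T,)))
        else:
            grid = (
                alphas_grid
                if alphas_grid is not None
                else np.logspace(-2, 6, 17)
            )
            best_alpha = [10.0] * T
            for _sweep in range(2):
                for j in range(T):
                    scores = []
                    for a in grid:
                        trial = list(best_alpha)
                        trial[j] = a
                        try:
                            _, dev, edf, _ = self._fit_once(trial)
                            scores.append(dev + 2.0 * edf)
                        except SurfaceFitError:
                            scores.append(np.inf)
                    best_alpha[j] = float(grid[int(np.argmin(scores))])
        coef, dev, edf, conv = self._fit_once(best_alpha)
        return FitnessSurfaceResults(self, coef, best_alpha, dev, edf)


class FitnessSurfaceResults:
    """Fitted fitness surface; prediction and selection-coefficient methods."""

    def __init__(self, model, coef, alpha, deviance, edf) -> None:
        self.model = model
        self.coef = coef
        self.alpha = alpha
        self.deviance = deviance
        self.edf = edf

    def predict(self, z_std: np.ndarray | None = None) -> np.ndarray:
        """Expected absolute fitness (probability scale for binomial) at the
        given standardized trait values, covariates held at each plant's own
        values.  Defaults to the observed trait values."""
        mdl = self.model
        z = mdl.z if z_std is None else np.asarray(z_std, float)
        eta = mdl._full_design(z, mdl.Xpar) @ self.coef
        if mdl.family == "binomial":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta

    def relative_fitness(self) -> np.ndarray:
        """w_i = What_i / mean(What); averages to 1 by construction."""
        w = self.predict()
        return w / w.mean()

    def selection_coefficients(self, step: float = 1e-3) -> "SelectionCoefficients":
        """Averaged-derivative standardized selection coefficients.

        Central finite differences with ``step`` (in SD units) on the fitted
        surface, averaged over observed plants; a step-sensitivity check at
        10x and 0.1x the step is stored in ``diagnostics``.
        """
        if step < 1e-8:
            raise ValueError("derivative step too small")
        vals = self._coeffs_at(step)
        diag = {
            "step": step,
            "step_x10": self._coeffs_at(step * 10.0),
            "step_x0.1": self._coeffs_at(step * 0.1),
        }
        mdl = self.model
        T = len(mdl.traits)
        if T == 1:
            return SelectionCoefficients(
                traits=list(mdl.traits), kind="differential",
                linear={mdl.traits[0]: vals["d1"][0]},
                quadratic={(mdl.traits[0], mdl.traits[0]): vals["d2"][0, 0]},
                diagnostics=diag,
            )
        lin = {t: vals["d1"][j] for j, t in enumerate(mdl.traits)}
        quad = {}
        for j in range(T):
            for k in range(j, T):
                quad[(mdl.traits[j], mdl.traits[k])] = vals["d2"][j, k]
        return SelectionCoefficients(
            traits=list(mdl.traits), kind="gradient",
            linear=lin, quadratic=quad, diagnostics=diag,
        )

    def _coeffs_at(self, h: float) -> dict:
        mdl = self.model
        z0 = mdl.z
        T = z0.shape[1]
        w0 = self.predict(z0)
        wbar = w0.mean()
        d1 = np.empty(T)
        d2 = np.empty((T, T))
        for j in range(T):
            zp, zm = z0.copy(), z0.copy()
            zp[:, j] += h
            zm[:, j] -= h
            fp, fm = self.predict(zp), self.predict(zm)
            d1[j] = np.mean((fp - fm) / (2 * h)) / wbar
            d2[j, j] = np.mean((fp - 2 * w0 + fm) / h**2) / wbar
        for j in range(T):
            for k in range(j + 1, T):
                zpp, zpm, zmp, zmm = (z0.copy() for _ in range(4))
                zpp[:, [j, k]] += h
                zmm[:, [j, k]] -= h
                zpm[:, j] += h
                zpm[:, k] -= h
                zmp[:, j] -= h
                zmp[:, k] += h
                mixed = (
                    self.predict(zpp) - self.predict(zpm)
                    - self.predict(zmp) + self.predict(zmm)
                ) / (4 * h**2)
                d2[j, k] = d2[k, j] = np.mean(mixed) / wbar
        return {"d1": d1, "d2": d2}

    def plot(self, trait: str | None = None, ax=None, n_grid: int = 100):
        """Fruit-set curve over one standardized trait (others at 0)."""
        import matplotlib.pyplot as plt

        mdl = self.model
        trait = trait or mdl.traits[0]
        j = mdl.traits.index(trait)
        lo, hi = mdl.z[:, j].min(), mdl.z[:, j].max()
        grid = np.linspace(lo, hi, n_grid)
        z = np.zeros((n_grid, len(mdl.traits)))
        z[:, j] = grid
        eta = np.column_stack(
            [np.broadcast_to(mdl.Xpar.mean(axis=0), (n_grid, mdl.Xpar.shape[1]))]
            + [mdl._smooth_design(z[:, t], t) for t in range(len(mdl.traits))]
            + ([ (z[:, 0] * z[:, 1])[:, None] ] if mdl.cross else [])
        ) @ self.coef
        pred = 1 / (1 + np.exp(-eta)) if mdl.family == "binomial" else eta
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(grid, pred)
        ax.set_xlabel(f"{trait} (SD units)")
        ax.set_ylabel("expected fruit set")
        return ax


@dataclass
class SelectionCoefficients:
    """Standardized selection coefficients with optional bootstrap inference.

    ``linear`` maps trait -> s (differential) or beta (gradient); ``quadratic``
    maps (trait_j, trait_k) -> c or gamma entries (the off-diagonal pair is
    the interaction term; the gamma matrix is symmetric by construction).
    """

    traits: list[str]
    kind: str  # "differential" | "gradient"
    linear: dict
    quadratic: dict
    se: dict = field(default_factory=dict)
    p: dict = field(default_factory=dict)
    n_boot: int = 0
    n_failed: int = 0
    diagnostics: dict = field(default_factory=dict)

    def gamma_matrix(self) -> np.ndarray:
        T = len(self.traits)
        g = np.empty((T, T))
        for j, tj in enumerate(self.traits):
            for k, tk in enumerate(self.traits):
                key = (tj, tk) if (tj, tk) in self.quadratic else (tk, tj)
                g[j, k] = self.quadratic[key]
        return g

    def to_frame(self) -> pd.DataFrame:
        rows = []
        lab_l = "s" if self.kind == "differential" else "beta"
        lab_q = "c" if self.kind == "differential" else "gamma"
        for t, v in self.linear.items():
            rows.append({"term": f"{lab_l}[{t}]", "estimate": v,
                         "se": self.se.get(("linear", t)),
                         "p": self.p.get(("linear", t))})
        for (tj, tk), v in self.quadratic.items():
            name = f"{lab_q}[{tj}]" if tj == tk else f"{lab_q}[{tj}:{tk}]"
            rows.append({"term": name, "estimate": v,
                         "se": self.se.get(("quadratic", tj, tk)),
                         "p": self.p.get(("quadratic", tj, tk))})
        return pd.DataFrame(rows)


def bootstrap_selection(
    plants: pd.DataFrame,
    traits,
    *,
    n_boot: int = 2000,
    seed: int = 0,
    step: float = 1e-3,
    max_failed_frac: float = 0.10,
    **model_kw,
) -> SelectionCoefficients:
    """Case bootstrap over plants: SEs and sign-test p-values per coefficient.

    The surface is refitted on each resample with the smoothing weights fixed
    at the original fit's values (plants are the independent resampling unit).
    Two-sided p = 2 * min(frac <= 0, frac >= 0) with a +1 continuity
    correction; failed refits are dropped and counted, erroring above
    ``max_failed_frac``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    model = FitnessSurfaceModel(plants, traits, **model_kw)
    res = model.fit()
    coeffs = res.selection_coefficients(step=step)
    rng = np.random.default_rng(seed)
    keys = [("linear", t) for t in coeffs.linear] + [
        ("quadratic", tj, tk) for (tj, tk) in coeffs.quadratic
    ]
    draws = {k: [] for k in keys}
    n_failed = 0
    n = len(model.plants)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = model.plants.iloc[idx].reset_index(drop=True)
        try:
            bres = FitnessSurfaceModel(sample, traits, **model_kw).fit(
                alpha=res.alpha
            )
            bc = bres.selection_coefficients(step=step)
        except (SurfaceFitError, ValueError):
            n_failed += 1
            continue
        for t, v in bc.linear.items():
            draws[("linear", t)].append(v)
        for (tj, tk), v in bc.quadratic.items():
            draws[("quadratic", tj, tk)].append(v)
    if n_failed > max_failed_frac * n_boot:
        raise SurfaceFitError(
            f"{n_failed}/{n_boot} bootstrap refits failed"
        )
    for k in keys:
        x = np.asarray(draws[k])
        b = x.size
        coeffs.se[k] = float(x.std(ddof=1))
        p = 2.0 * min((np.sum(x <= 0) + 1) / (b + 1), (np.sum(x >= 0) + 1) / (b + 1))
        coeffs.p[k] = float(min(p, 1.0))
    coeffs.n_boot = n_boot
    coeffs.n_failed = n_failed
    return coeffs


def estimate_selection(
    phenotypes: pd.DataFrame,
    fitness: pd.DataFrame,
    traits,
    *,
    n_boot: int = 2000,
    seed: int = 0,
    **model_kw,
) -> dict:
    """Differentials (univariate per trait) and gradients (bivariate), with
    bootstrap inference — the full selection table for a pair of traits."""
    traits = [traits] if isinstance(traits, str) else list(traits)
    plants = plant_table(phenotypes, fitness, traits)
    out = {"differentials": {}, "gradients": None}
    for i, t in enumerate(traits):
        out["differentials"][t] = bootstrap_selection(
            plants, [t], n_boot=n_boot, seed=seed + i, **model_kw
        )
    if len(traits) == 2:
        out["gradients"] = bootstrap_selection(
            plants, traits, n_boot=n_boot, seed=seed + len(traits), **model_kw
        )
    return out
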