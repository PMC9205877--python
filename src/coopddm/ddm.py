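"""Drift-diffusion model fitting and nested-model comparison.

``DriftDiffusionModel`` is a statsmodels-style model object holding choice/RT
data, optionally split by a grouping factor (by default the stimulation
condition).  ``fit`` maximises the continuous Wiener likelihood (or an
alternative quantile-binned multinomial likelihood) with all parameters tied
across group levels except an optional single free parameter, which is the
building block of the seven-model nested scan: freeing, one at a time, each of
{a, z, v, t0, eta, sz, st} across the group levels and comparing against the
fully tied model by a chi-square difference test.

Starting points are parameterised as the dimensionless bias b = z/a so fits
are comparable across subjects with different boundary separations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .wfpt import DDMParams, fpt_density, choice_probability

__all__ = [
    "FitConfig",
    "ModelSpec",
    "ChiSquareResult",
    "DriftDiffusionModel",
    "DDMResults",
    "nested_comparison",
    "nested_scan",
    "cohort_nested_comparison",
    "group_parameter_tests",
]

BASE_PARAMS = ("a", "b", "v", "t0")
VAR_PARAMS = ("eta", "sz", "st")
SEVEN_FREE = ("a", "t0", "eta", "b", "sz", "st", "v")

#: density floor: trials whose RT is impossible under the candidate
#: parameters (t <= t0) contribute -2*log(DENSITY_FLOOR) to the deviance
#: instead of an infinite penalty, keeping the objective finite everywhere.
DENSITY_FLOOR = 1e-10


@dataclass(frozen=True)
class FitConfig:
    restarts: int = 5  # jittered restarts around the heuristic start
    fatol: float = 1e-6  # deviance tolerance at convergence
    xatol: float = 1e-5
    maxiter: Optional[int] = None
    rt_floor: float = 0.2  # contaminant guard: faster responses are excluded
    min_trials: int = 10
    jitter_seed: int = 0
    objective: str = "ml"  # "ml" | "qmle"
    quantiles: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters are estimated and which one may differ across levels."""

    include: tuple = BASE_PARAMS
    free: Optional[str] = None  # None = fully tied baseline

    def __post_init__(self) -> None:
        for p in self.include:
            if p not in BASE_PARAMS + VAR_PARAMS:
                raise ValueError(f"unknown parameter {p!r}")
        if self.free is not None and self.free not in self.include:
            raise ValueError(f"free parameter {self.free!r} must be in include={self.include}")

    def nests(self, other: "ModelSpec") -> bool:
        """True if ``other`` (the fixed model) is nested in this spec."""
        return set(self.include) == set(other.include) and other.free is None and self.free is not None


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


class DriftDiffusionModel:
    """Two-choice diffusion model for one dataset, optionally grouped.

    Parameters
    ----------
    rt : response times in seconds (full RT, non-decision time included)
    upper : boolean array, True when the response was at the upper boundary
        (cooperation, in this package's convention)
    groups : optional label array defining the levels across which a single
        parameter may be freed (e.g. the stimulation condition)
    """

    def __init__(self, rt, upper, groups=None, fit_config: FitConfig = FitConfig()):
        rt = np.asarray(rt, dtype=float)
        upper = np.asarray(upper, dtype=bool)
        if rt.shape != upper.shape:
            raise ValueError("rt and upper must have the same shape")
        if np.any(~np.isfinite(rt)) or np.any(rt <= 0):
            raise ValueError("response times must be positive and finite")
        keep = rt >= fit_config.rt_floor
        self.n_excluded_fast = int((~keep).sum())
        rt, upper = rt[keep], upper[keep]
        if groups is None:
            groups = np.zeros(rt.shape, dtype=int)
        else:
            groups = np.asarray(groups)[keep]
        self.levels = sorted(pd.unique(groups).tolist())
        self.fit_config = fit_config
        self._data = []
        for lev in self.levels:
            m = groups == lev
            if m.sum() < fit_config.min_trials:
                raise ValueError(f"group level {lev!r} has {int(m.sum())} trials, "
                                 f"fewer than min_trials={fit_config.min_trials}")
            self._data.append((rt[m & upper], rt[m & ~upper]))
        self.nobs = int(rt.size)
        self.rt_min = float(rt.min())

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        rt_col: str = "subject_rt_s",
        choice_col: str = "subject_choice",
        group_col: Optional[str] = "stim_condition",
        upper_value: str = "cooperate",
        fit_config: FitConfig = FitConfig(),
    ) -> "DriftDiffusionModel":
        groups = df[group_col].to_numpy() if group_col is not None else None
        return cls(
            df[rt_col].to_numpy(dtype=float),
            df[choice_col].astype(str).to_numpy() == upper_value,
            groups=groups,
            fit_config=fit_config,
        )

    # -- parameter vector <-> DDMParams -------------------------------------

    def _unpack(self, x: np.ndarray, spec: ModelSpec) -> list[DDMParams]:
        """Transformed vector -> one DDMParams per group level."""
        names = list(spec.include)
        vals: dict[str, list[float]] = {}
        i = 0
        for name in names:
            if name == spec.free:
                vals[name] = [x[i + k] for k in range(len(self.levels))]
                i += len(self.levels)
            else:
                vals[name] = [x[i]] * len(self.levels)
                i += 1
        out = []
        for k in range(len(self.levels)):
            a = math.exp(vals["a"][k])
            b = 1.0 / (1.0 + math.exp(-vals["b"][k]))
            v = vals["v"][k]
            t0 = math.exp(vals["t0"][k])
            z = b * a
            kw = {}
            if "eta" in vals:
                kw["eta"] = math.exp(vals["eta"][k])
            if "sz" in vals:
                frac = 1.0 / (1.0 + math.exp(-vals["sz"][k]))
                kw["sz"] = frac * 2.0 * min(z, a - z) * 0.95
            if "st" in vals:
                frac = 1.0 / (1.0 + math.exp(-vals["st"][k]))
                kw["st"] = frac * 2.0 * t0 * 0.95
            out.append(DDMParams(a=a, z=z, v=v, t0=t0, **kw))
        return out

    def _n_free(self, spec: ModelSpec) -> int:
        n = len(spec.include)
        if spec.free is not None:
            n += len(self.levels) - 1
        return n

    # -- objectives ----------------------------------------------------------

    def deviance(self, params_by_level: Sequence[DDMParams]) -> float:
        """-2 log likelihood of the data under per-level parameters."""
        dev = 0.0
        for (rt_up, rt_lo), p in zip(self._data, params_by_level):
            for rts, boundary in ((rt_up, "upper"), (rt_lo, "lower")):
                if rts.size == 0:
                    continue
                f = fpt_density(rts, p, boundary, eps=1e-10)
                dev += -2.0 * float(np.log(np.maximum(f, DENSITY_FLOOR)).sum())
        return dev

    def _qmle_deviance(self, params_by_level: Sequence[DDMParams]) -> float:
        """Quantile-binned multinomial deviance (alternative objective).

        Observed RTs per (level, boundary) are binned at the configured
        quantiles of the *observed* distribution; predicted bin masses come
        from integrating the model density over each bin.
        """
        qs = np.asarray(self.fit_config.quantiles)
        dev = 0.0
        gl_x, gl_w = np.polynomial.legendre.leggauss(24)
        for (rt_up, rt_lo), p in zip(self._data, params_by_level):
            ntot = rt_up.size + rt_lo.size
            for rts, boundary in ((rt_up, "upper"), (rt_lo, "lower")):
                if rts.size == 0:
                    continue
                edges = np.concatenate(([self.fit_config.rt_floor],
                                        np.quantile(rts, qs), [max(rts.max() * 2, 15.0)]))
                counts, _ = np.histogram(rts, bins=edges)
                masses = np.empty(len(edges) - 1)
                for j in range(len(edges) - 1):
                    lo, hi = edges[j], edges[j + 1]
                    t = 0.5 * (hi - lo) * gl_x + 0.5 * (hi + lo)
                    masses[j] = 0.5 * (hi - lo) * float(np.sum(gl_w * fpt_density(t, p, boundary)))
                masses = np.maximum(masses, 1e-12)
                dev += -2.0 * float(np.sum(counts * np.log(masses)))
        return dev

    def _objective(self, x: np.ndarray, spec: ModelSpec) -> float:
        try:
            params = self._unpack(x, spec)
        except ValueError:
            return 1e12
        if self.fit_config.objective == "qmle":
            return self._qmle_deviance(params)
        return self.deviance(params)

    # -- fitting -------------------------------------------------------------

    def _start_vector(self, spec: ModelSpec) -> np.ndarray:
        n_up = sum(d[0].size for d in self._data)
        p_up = min(max(n_up / max(self.nobs, 1), 0.1), 0.9)
        a0 = 1.5
        b0 = min(max(p_up, 0.25), 0.75)
        v0 = math.log(p_up / (1 - p_up)) / a0
        t0_0 = max(0.85 * self.rt_min, 1e-3)
        start = {"a": math.log(a0), "b": math.log(b0 / (1 - b0)), "v": v0,
                 "t0": math.log(t0_0), "eta": math.log(0.3), "sz": -2.0, "st": -2.0}
        x = []
        for name in spec.include:
            reps = len(self.levels) if name == spec.free else 1
            x.extend([start[name]] * reps)
        return np.asarray(x)

    def _expand_start(self, spec: ModelSpec, warm: "DDMResults") -> Optional[np.ndarray]:
        """Map a tied fit's solution onto the start vector of a spec that
        frees one parameter (replicating the shared value across levels)."""
        if warm.spec.free is not None or set(warm.spec.include) - set(spec.include):
            return None
        defaults = {"eta": math.log(0.3), "sz": -2.0, "st": -2.0}
        pos = {name: i for i, name in enumerate(warm.spec.include)}
        x = []
        for name in spec.include:
            val = warm.x[pos[name]] if name in pos else defaults[name]
            reps = len(self.levels) if name == spec.free else 1
            x.extend([val] * reps)
        return np.asarray(x)

    def fit(self, spec: ModelSpec | None = None, free: Optional[str] = None,
            warm_start: Optional["DDMResults"] = None,
            restarts: Optional[int] = None) -> "DDMResults":
        """Minimise the deviance by Nelder-Mead with jittered restarts.

        ``free`` is a convenience for ``ModelSpec(include, free)`` where the
        variability parameter being freed is added to the include set.
        ``warm_start`` may be a previously obtained tied fit on the same data;
        its solution then seeds the search.  ``restarts`` overrides the fit
        configuration for this call (1 = single start, useful when warm).
        """
        if spec is None:
            if free == "z":  # accepted alias: the freed start point is fitted as the bias b = z/a
                free = "b"
            include = list(BASE_PARAMS)
            if free in VAR_PARAMS:
                include.append(free)
            spec = ModelSpec(include=tuple(include), free=free)
        x0 = self._start_vector(spec)
        if warm_start is not None:
            xw = self._expand_start(spec, warm_start)
            if xw is not None:
                x0 = xw
        rng = np.random.default_rng(self.fit_config.jitter_seed)
        best = None
        maxiter = self.fit_config.maxiter or 250 * x0.size
        n_starts = max(1, restarts if restarts is not None else self.fit_config.restarts)
        for k in range(n_starts):
            xk = x0 if k == 0 else x0 + 0.35 * rng.standard_normal(x0.size)
            res = optimize.minimize(
                self._objective, xk, args=(spec,), method="Nelder-Mead",
                options={"fatol": self.fit_config.fatol, "xatol": self.fit_config.xatol,
                         "maxiter": maxiter, "maxfev": maxiter},
            )
            if best is None or res.fun < best.fun:
                best = res
        params = self._unpack(best.x, spec)
        return DDMResults(
            model=self,
            spec=spec,
            params_by_level=dict(zip(self.levels, params)),
            deviance=float(best.fun),
            n_free_params=self._n_free(spec),
            converged=bool(best.success),
            n_iter=int(best.nit),
            x=best.x.copy(),
        )


@dataclass
class DDMResults:
    """Fit result: per-level parameter estimates and the deviance."""

    model: DriftDiffusionModel
    spec: ModelSpec
    params_by_level: dict
    deviance: float
    n_free_params: int
    converged: bool
    n_iter: int
    x: np.ndarray

    @property
    def levels(self):
        return list(self.params_by_level)

    def starting_bias(self) -> dict:
        """Starting point normalised by boundary separation, per level."""
        return {lev: p.b for lev, p in self.params_by_level.items()}

    def choice_probability(self, boundary: str = "upper") -> dict:
        return {lev: choice_probability(p, boundary) for lev, p in self.params_by_level.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lev, p in self.params_by_level.items():
            rows.append({"level": lev, "a": p.a, "b": p.b, "z": p.z, "v": p.v,
                         "t0": p.t0, "eta": p.eta, "sz": p.sz, "st": p.st})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Drift-diffusion model fit",
            f"  observations: {self.model.nobs}  (excluded fast RTs: {self.model.n_excluded_fast})",
            f"  free parameter across levels: {self.spec.free or 'none'}",
            f"  deviance: {self.deviance:.3f}   n free params: {self.n_free_params}"
            f"   converged: {self.converged}",
            "",
            self.to_frame().to_string(index=False, float_format=lambda f: f"{f:.4f}"),
        ]
        return "\n".join(lines)

    def plot_fit(self, level=None, ax=None, n_grid: int = 200):
        """Overlay the fitted RT densities (signed by boundary) on the data
        histogram for one group level."""
        import matplotlib.pyplot as plt

        level = level if level is not None else self.levels[0]
        idx = self.model.levels.index(level)
        rt_up, rt_lo = self.model._data[idx]
        p = self.params_by_level[level]
        if ax is None:
            _, ax = plt.subplots()
        allrt = np.concatenate([rt_up, rt_lo])
        grid = np.linspace(p.t0 + 1e-3, max(allrt.max() * 1.2, 2.0), n_grid)
        w_up = rt_up.size / max(allrt.size, 1)
        ax.hist(rt_up, bins=30, density=True, alpha=0.4, label="upper (cooperate)")
        ax.hist(rt_lo, bins=30, density=True, alpha=0.4, label="lower (deceive)")
        if rt_up.size:
            ax.plot(grid, fpt_density(grid, p, "upper") / max(w_up, 1e-9), lw=2)
        if rt_lo.size:
            ax.plot(grid, fpt_density(grid, p, "lower") / max(1 - w_up, 1e-9), lw=2)
        ax.set_xlabel("response time (s)")
        ax.set_ylabel("density")
        ax.legend()
        return ax


def nested_comparison(fit_fixed: DDMResults, fit_free: DDMResults) -> ChiSquareResult:
    """Chi-square difference test of a tied model against a model freeing one
    parameter across group levels."""
    if not fit_free.spec.nests(fit_fixed.spec):
        raise ValueError(
            f"free spec {fit_free.spec} does not nest fixed spec {fit_fixed.spec}"
        )
    df = fit_free.n_free_params - fit_fixed.n_free_params
    stat = max(fit_fixed.deviance - fit_free.deviance, 0.0)
    return ChiSquareResult(statistic=stat, df=df, p=float(stats.chi2.sf(stat, df)))


def nested_scan(model: DriftDiffusionModel, free_params: Sequence[str] = SEVEN_FREE) -> pd.DataFrame:
    """The seven-model scan: free each parameter in turn across the group
    levels and compare against the corresponding fully tied model.

    Variability parameters absent from the tied baseline are added (shared)
    to its include set when they are the freed parameter, so every comparison
    has exactly one degree of freedom per extra level.
    """
    rows = []
    base_fixed = model.fit(free=None)
    for name in free_params:
        if name in VAR_PARAMS:
            fixed = model.fit(ModelSpec(include=BASE_PARAMS + (name,), free=None))
        else:
            fixed = base_fixed
        free_fit = model.fit(free=name)
        cmp = nested_comparison(fixed, free_fit)
        row = {"free_parameter": name, "chi2": cmp.statistic, "df": cmp.df, "p": cmp.p,
               "deviance_fixed": fixed.deviance, "deviance_free": free_fit.deviance,
               "converged": fixed.converged and free_fit.converged}
        for lev, prm in free_fit.params_by_level.items():
            row[f"{name}[{lev}]"] = getattr(prm, "b" if name == "b" else name)
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_nested_comparison(pairs: Sequence[tuple[DDMResults, DDMResults]]) -> ChiSquareResult:
    """Cohort-level chi-square: per-subject fits are independent, so the
    per-subject deviance differences add, as do their degrees of freedom."""
    stat = 0.0
    df = 0
    for fixed, free in pairs:
        c = nested_comparison(fixed, free)
        stat += fixed.deviance - free.deviance
        df += c.df
    stat = max(stat, 0.0)
    return ChiSquareResult(statistic=stat, df=df, p=float(stats.chi2.sf(stat, df)))


def group_parameter_tests(
    subject_params: pd.DataFrame,
    condition_col: str = "condition",
    bonferroni_m: Optional[int] = None,
) -> pd.DataFrame:
    """Group-level tests on per-subject fitted parameters.

    Per condition: one-sample t-tests of starting bias against 0.5 and drift
    against 0.  Across conditions: paired t-tests per parameter with paired
    Cohen's d.  p-values are Bonferroni-adjusted with m = the number of tests
    in the table unless ``bonferroni_m`` is given.

    ``subject_params`` needs columns subject_id, ``condition_col``, a, b, v, t0.
    """
    conditions = sorted(subject_params[condition_col].unique())
    wide = subject_params.pivot(index="subject_id", columns=condition_col)
    n = wide.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 subjects with fits per condition, got {n}")
    rows = []

    def _safe_t(tval, pval, mean, null):
        # degenerate zero-variance samples: t = 0 (p = 1) at the null, else infinite
        if np.isnan(tval):
            return (0.0, 1.0) if np.isclose(mean, null) else (math.copysign(np.inf, mean - null), 0.0)
        return float(tval), float(pval)

    for cond in conditions:
        for par, null in (("b", 0.5), ("v", 0.0)):
            x = wide[(par, cond)].to_numpy(dtype=float)
            t, p = _safe_t(*stats.ttest_1samp(x, null), x.mean(), null)
            rows.append({"test": f"one_sample[{par} vs {null}]", "condition": cond,
                         "parameter": par, "mean": x.mean(), "t": float(t), "p_raw": float(p),
                         "cohens_d": float((x.mean() - null) / x.std(ddof=1)) if x.std(ddof=1) > 0 else np.nan,
                         "n": n})
    if len(conditions) == 2:
        c0, c1 = conditions
        for par in ("a", "b", "v", "t0"):
            if (par, c0) not in wide.columns:
                continue
            x = wide[(par, c1)].to_numpy(dtype=float)
            y = wide[(par, c0)].to_numpy(dtype=float)
            d = x - y
            t, p = _safe_t(*stats.ttest_rel(x, y), d.mean(), 0.0)
            sd = d.std(ddof=1)
            rows.append({"test": f"paired[{c1} - {c0}]", "condition": f"{c1}-{c0}",
                         "parameter": par, "mean": d.mean(), "t": float(t), "p_raw": float(p),
                         "cohens_d": float(d.mean() / sd) if sd > 0 else np.nan, "n": n})
    out = pd.DataFrame(rows)
    m = bonferroni_m if bonferroni_m is not None else len(out)
    out["p_bonferroni"] = np.minimum(out["p_raw"] * m, 1.0)
    return out
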