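"""Crossed random-effects LMM screening of substance matrices.

The substance matrix (samples x substances) is vectorised into one long
response vector; a Gaussian linear mixed model with many independent
variance components captures samples, substances, females, rooms and
sampling batches as crossed random effects, with random interactions of the
test predictors (cycle state, parity) and a random age slope within
substance.  Likelihood-ratio tests compare the full model to reduced models
lacking the test components, and per-substance conditional modes (BLUP
analogues) of the test components are the "slope estimates" screened by the
mean + 2*SD absolute-score rule to flag the most affected substances.

The solver maximises the profiled (restricted) likelihood over variance
ratios gamma_k = sigma_k^2 / sigma_e^2 using the scaled-indicator identity
V0 = I + sum_k gamma_k Z_k Z_k' = I + Zs Zs', so every evaluation reduces to
one Cholesky of the q x q matrix A = I + Zs'Zs (q = total random-effect
levels): memory and time scale with the nonzeros of the indicator blocks
plus q^2, not with the number of rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "VarComp",
    "ModelSpec",
    "FitResult",
    "LrtResult",
    "ScreenResult",
    "vectorise",
    "unvectorise",
    "build_model_spec",
    "fit_lmm",
    "lrt",
    "screen_substances",
    "vif",
]

FIXED_TERMS = (
    "cycle_state",
    "age_z",
    "parity",
    "side",
    "ultrasound",
    "a1",
    "a2",
    "a3",
    "a4",
)
METADATA_COLS = (
    "female",
    "room",
    "batch",
    "cycle_state",
    "age",
    "parity",
    "side",
    "ultrasound",
    "a1",
    "a2",
    "a3",
    "a4",
)
TEST_PREDICTORS = ("cycle", "age", "parity")


def vectorise(values: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Stack a samples x substances matrix into long format (sample-major).

    ``metadata`` must carry one row per sample (column ``sample_id``) with
    the covariates in METADATA_COLS.  Age is z-scored across the female-level
    values actually present (sample SD).  Row count is
    n_samples * n_substances.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    missing = [s for s in values.index if s not in meta.index]
    if missing:
        raise ValueError(f"metadata missing sample(s): {missing[:5]}")
    meta = meta.loc[values.index]
    fem_ages = meta.drop_duplicates("female").set_index("female")["age"].astype(float)
    sd = fem_ages.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        age_z = fem_ages * 0.0
    else:
        age_z = (fem_ages - fem_ages.mean()) / sd

    n_sub = values.shape[1]
    long = pd.DataFrame(
        {
            "y": values.to_numpy().ravel(),  # sample-major
            "sample": np.repeat(values.index.to_numpy(), n_sub),
            "substance": np.tile(values.columns.to_numpy(), values.shape[0]),
        }
    )
    for col in METADATA_COLS:
        if col == "age":
            continue
        long[col] = np.repeat(meta[col].to_numpy(), n_sub)
    long["age_z"] = long["female"].map(age_z).to_numpy()
    return long


def unvectorise(long: pd.DataFrame, column: str = "y") -> pd.DataFrame:
    """Inverse of :func:`vectorise`: recover the samples x substances matrix."""
    return long.pivot(index="sample", columns="substance", values=column).loc[
        pd.unique(long["sample"]), pd.unique(long["substance"])
    ]


@dataclass(frozen=True)
class VarComp:
    """One independent variance component.

    ``factors`` name the grouping columns whose interaction defines the
    levels; ``slope`` optionally names a numeric column multiplying the
    indicator (a random slope).  Each component contributes exactly one
    variance parameter.
    """

    factors: tuple[str, ...]
    slope: str | None = None

    @property
    def name(self) -> str:
        base = ":".join(self.factors)
        return f"{base}|{self.slope}" if self.slope else base


@dataclass
class ModelSpec:
    """Fixed terms + variance components; the full structure has 33 predictors."""

    fixed: tuple[str, ...]
    vc: tuple[VarComp, ...]
    response: str = "normalised"

    @property
    def n_predictors(self) -> int:
        """Distinct predictor variables, fixed + random, each interaction once."""
        return len(self.fixed) + len(self.vc)

    def drop(self, names: Sequence[str]) -> "ModelSpec":
        names = set(names)
        unknown = names - {c.name for c in self.vc}
        if unknown:
            raise ValueError(f"unknown variance component(s): {sorted(unknown)}")
        return ModelSpec(
            fixed=self.fixed,
            vc=tuple(c for c in self.vc if c.name not in names),
            response=self.response,
        )


# test-predictor variance components (cycle / parity interactions with
# substance, and the random age slope within substance)
TEST_COMPONENTS = {
    "cycle": "substance:cycle_state",
    "parity": "substance:parity",
    "age": "substance|age_z",
}


def build_model_spec(
    response: str = "normalised",
    include_test_predictors: bool = True,
    extra_drop: Sequence[str] = (),
) -> ModelSpec:
    """Enumerate the full model structure.

    9 fixed effects (cycle state, age, parity, genital side, ultrasound
    timing, four assistant flags), random intercepts for sample, substance,
    female, room and sampling batch, a random age slope within substance,
    and random interactions of substance x {cycle, parity, side, ultrasound,
    assistants}, female x {cycle, ultrasound, assistants}, room x {cycle,
    ultrasound} and batch x {cycle, ultrasound}: 33 predictor variables in
    total.  Dropping the three test predictors leaves the 30-term null.
    """
    vcs: list[VarComp] = [
        VarComp(("sample",)),
        VarComp(("substance",)),
        VarComp(("female",)),
        VarComp(("room",)),
        VarComp(("batch",)),
        VarComp(("substance",), slope="age_z"),
    ]
    for f in ("cycle_state", "parity", "side", "ultrasound", "a1", "a2", "a3", "a4"):
        vcs.append(VarComp(("substance", f)))
    for f in ("cycle_state", "ultrasound", "a1", "a2", "a3", "a4"):
        vcs.append(VarComp(("female", f)))
    for f in ("cycle_state", "ultrasound"):
        vcs.append(VarComp(("room", f)))
    for f in ("cycle_state", "ultrasound"):
        vcs.append(VarComp(("batch", f)))
    spec = ModelSpec(fixed=FIXED_TERMS, vc=tuple(vcs), response=response)
    if not include_test_predictors:
        spec = spec.drop(list(TEST_COMPONENTS.values()))
    if extra_drop:
        spec = spec.drop(extra_drop)
    return spec


def _fixed_design(long: pd.DataFrame, fixed: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(long))]
    names = ["Intercept"]
    for t in fixed:
        if t not in long.columns:
            raise ValueError(f"fixed term {t!r} not in data")
        s = long[t]
        if pd.api.types.is_numeric_dtype(s):
            cols.append(s.to_numpy(float))
            names.append(t)
        else:
            levels = sorted(pd.unique(s.astype(str)))
            for lv in levels[1:]:  # treatment coding, first level reference
                cols.append((s.astype(str) == lv).to_numpy(float))
                names.append(f"{t}[{lv}]")
    X = np.column_stack(cols)
    return X, names


def _component_matrix(long: pd.DataFrame, comp: VarComp) -> tuple[sparse.csc_matrix, list]:
    if len(comp.factors) == 1:
        keys = pd.Index(long[comp.factors[0]].astype(str))
        codes, levels = pd.factorize(keys, sort=True)
        levels = [(lv,) for lv in levels]
    else:
        tuples = list(zip(*(long[f].astype(str) for f in comp.factors)))
        codes, levels = pd.factorize(pd.Index(tuples), sort=True)
        levels = list(levels)
    data = long[comp.slope].to_numpy(float) if comp.slope else np.ones(len(long))
    Z = sparse.csc_matrix(
        (data, (np.arange(len(long)), codes)), shape=(len(long), len(levels))
    )
    return Z, levels


@dataclass
class FitResult:
    """A converged (or flagged) maximum-likelihood fit."""

    spec: ModelSpec
    method: str
    beta: pd.Series
    sigma2_resid: float
    variance_components: dict[str, float]  # sigma_k^2 on the data scale
    modes: dict[str, pd.Series]  # conditional modes per component
    loglik: float
    n_obs: int
    n_params: int  # fixed + variance parameters (incl. residual)
    converged: bool
    n_iter: int


def fit_lmm(long: pd.DataFrame, spec: ModelSpec, method: str = "ML") -> FitResult:
    """Fit the variance-components mixed model by (RE)ML.

    Variance ratios are optimised by L-BFGS-B from a residual-variance-only
    start (all ratios 0), constrained nonnegative; the residual variance and
    fixed effects are profiled out in closed form.  Conditional modes of
    every random component are returned for screening.
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    y = long["y"].to_numpy(float)
    n = y.size
    X, xnames = _fixed_design(long, spec.fixed)
    p = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("fixed-effects design is rank deficient")

    blocks = [_component_matrix(long, c) for c in spec.vc]
    sizes = [Z.shape[1] for Z, _ in blocks]
    K = len(blocks)
    if K:
        Z = sparse.hstack([Z for Z, _ in blocks], format="csc")
        ZtZ = (Z.T @ Z).toarray()
        ZtX = Z.T @ X
        Zty = Z.T @ y
    q = sum(sizes)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    block_of = np.repeat(np.arange(K), sizes) if K else np.empty(0, int)

    def profile(gamma: np.ndarray, want_grad: bool = False):
        """Return (deviance, beta, sigma2, extras[, grad]) at variance ratios gamma."""
        if K:
            s = np.sqrt(gamma)[block_of]
            A = ZtZ * s[:, None] * s[None, :]
            A[np.diag_indices(q)] += 1.0
            cf = cho_factor(A, lower=True)
            logdetV0 = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            ZtX_s = ZtX * s[:, None]
            Zty_s = Zty * s
            AinvZtX = cho_solve(cf, ZtX_s)
            AinvZty = cho_solve(cf, Zty_s)
            XtVX = XtX - ZtX_s.T @ AinvZtX
            XtVy = Xty - ZtX_s.T @ AinvZty
            yVy = yty - float(Zty_s @ AinvZty)
        else:
            s = np.empty(0)
            cf = None
            logdetV0 = 0.0
            XtVX, XtVy, yVy = XtX, Xty, yty
        beta = np.linalg.solve(XtVX, XtVy)
        rss = max(yVy - float(beta @ XtVy), 1e-300)
        if method == "ML":
            sigma2 = rss / n
            dev = n * np.log(2 * np.pi * sigma2) + logdetV0 + n
        else:
            sigma2 = rss / (n - p)
            sign, logdetX = np.linalg.slogdet(XtVX)
            dev = (n - p) * np.log(2 * np.pi * sigma2) + logdetV0 + logdetX + (n - p)
        if not want_grad:
            return dev, beta, sigma2, (cf, s)
        # analytic ML gradient (envelope theorem: d beta / d gamma drops out):
        # d dev/d gamma_k = -(n/rss) * ||Z_k' V0^-1 r||^2 + tr(Z_k' V0^-1 Z_k)
        t = Zty - ZtX @ beta
        w = t - ZtZ @ (s * cho_solve(cf, s * t))
        M = ZtZ * s[:, None]
        d2 = np.einsum("ij,ij->j", M, cho_solve(cf, M))
        per_col = -(n / rss) * w**2 + (np.diag(ZtZ) - d2)
        grad = np.array([per_col[block_of == k].sum() for k in range(K)])
        return dev, beta, sigma2, (cf, s), grad

    if K:
        if method == "ML":

            def obj(g):
                out = profile(g, want_grad=True)
                return out[0], out[4]

            res = optimize.minimize(
                obj,
                x0=np.zeros(K),
                jac=True,
                method="L-BFGS-B",
                bounds=[(0.0, None)] * K,
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
            )
        else:
            res = optimize.minimize(
                lambda g: profile(g)[0],
                x0=np.zeros(K),
                method="L-BFGS-B",
                bounds=[(0.0, None)] * K,
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
            )
        gamma = np.maximum(res.x, 0.0)
        converged, n_iter = bool(res.success), int(res.nit)
    else:
        gamma = np.empty(0)
        converged, n_iter = True, 0

    dev, beta, sigma2, (cf, s) = profile(gamma)
    loglik = -dev / 2.0

    modes: dict[str, pd.Series] = {}
    if K:
        t = Zty - ZtX @ beta
        u = s * cho_solve(cf, s * t)  # D^{1/2} A^{-1} D^{1/2} (Z'y - Z'X beta)
        off = 0
        for (Zb, levels), comp, sz in zip(blocks, spec.vc, sizes):
            vals = u[off : off + sz]
            idx = [lv if len(lv) > 1 else lv[0] for lv in levels]
            modes[comp.name] = pd.Series(vals, index=idx, name=comp.name)
            off += sz

    vcs = {c.name: float(g * sigma2) for c, g in zip(spec.vc, gamma)}
    return FitResult(
        spec=spec,
        method=method,
        beta=pd.Series(beta, index=xnames),
        sigma2_resid=float(sigma2),
        variance_components=vcs,
        modes=modes,
        loglik=float(loglik),
        n_obs=n,
        n_params=p + K + 1,
        converged=converged,
        n_iter=n_iter,
    )


@dataclass
class LrtResult:
    """Likelihood-ratio test of nested ML fits.

    Variance parameters sit on the boundary of their space under the null,
    so the nominal chi-square reference is conservative.
    """

    chi2: float
    df: int
    p: float


def lrt(full: FitResult, reduced: FitResult) -> LrtResult:
    if full.method != "ML" or reduced.method != "ML":
        raise ValueError("LRT requires both fits by ML (likelihoods not comparable under REML)")
    if not (full.converged and reduced.converged):
        raise ValueError("LRT refuses non-converged fits")
    if full.n_obs != reduced.n_obs:
        raise ValueError("fits are on different data")
    full_names = {c.name for c in full.spec.vc}
    red_names = {c.name for c in reduced.spec.vc}
    if not (red_names <= full_names and set(reduced.spec.fixed) <= set(full.spec.fixed)):
        raise ValueError("reduced model is not nested in the full model")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if df == 0:  # degenerate self-comparison
        return LrtResult(chi2=chi2, df=0, p=1.0)
    return LrtResult(chi2=chi2, df=df, p=float(chi2_dist.sf(chi2, df)))


@dataclass
class ScreenResult:
    """Per-substance scores with the mean + 2*SD flagging rule."""

    predictor: str
    scores: pd.Series  # index substance, absolute slope/contrast score
    directions: pd.Series  # index substance, direction label
    threshold: float
    flagged: list[str]

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame({"score": self.scores, "direction": self.directions})
        df["flagged"] = df.index.isin(self.flagged)
        df = df.sort_values("score", ascending=False)
        df["rank"] = np.arange(1, len(df) + 1)
        return df


def _modes_frame(modes: pd.Series) -> pd.DataFrame:
    """Pivot (substance, level) conditional modes to substances x levels (0-filled)."""
    idx = pd.MultiIndex.from_tuples(list(modes.index))
    wide = pd.Series(modes.to_numpy(), index=idx).unstack(fill_value=0.0)
    return wide


def screen_substances(fit: FitResult, predictor: str) -> ScreenResult:
    """Flag the substances most affected by cycle, age or parity.

    The "slope estimates" of a predictor are the conditional modes of its
    per-substance component: the random age slope (one estimate per
    substance) or, for the categorical predictors, the level modes of the
    substance interaction centred within substance (one estimate per
    substance and level).  A substance's score is its largest absolute
    estimate; the flagging threshold is mean + 2*SD (sample SD) over the
    population of ALL absolute slope estimates for the predictor, and a
    substance is flagged when its score reaches the threshold (the >=
    comparison keeps the degenerate SD = 0 case flagging everything at the
    mean).  Directions report the sign of the age slope, the higher parity
    level, or the cycle level with the highest mode.
    """
    if predictor not in TEST_COMPONENTS:
        raise ValueError(f"predictor must be one of {TEST_PREDICTORS}")
    comp = TEST_COMPONENTS[predictor]
    if comp not in fit.modes:
        raise ValueError(f"fit lacks the {comp!r} component needed for {predictor!r}")
    modes = fit.modes[comp]

    if predictor == "age":
        estimates = modes.copy()
        estimates.index = [i if isinstance(i, str) else i[0] for i in estimates.index]
        wide = estimates.to_frame("slope")
        scores = estimates.abs()
        directions = pd.Series(
            np.where(estimates >= 0, "increasing", "decreasing"), index=estimates.index
        )
    else:
        wide = _modes_frame(modes)
        if predictor == "parity" and wide.shape[1] != 2:
            raise ValueError("parity screening expects exactly two levels")
        centred = wide.sub(wide.mean(axis=1), axis=0)
        scores = centred.abs().max(axis=1)
        if predictor == "parity":
            contrast = wide.iloc[:, 1] - wide.iloc[:, 0]
            directions = pd.Series(
                np.where(contrast >= 0, f"higher in {wide.columns[1]}", f"higher in {wide.columns[0]}"),
                index=wide.index,
            )
        else:  # cycle
            directions = wide.idxmax(axis=1).map(lambda s: f"highest in {s}")
        wide = centred
    scores = scores.astype(float)
    pop = np.abs(wide.to_numpy(dtype=float).ravel())
    sd = float(np.std(pop, ddof=1)) if pop.size > 1 else 0.0
    threshold = float(pop.mean()) + 2.0 * sd
    flagged = sorted(scores.index[scores >= threshold - 1e-12])
    return ScreenResult(
        predictor=predictor,
        scores=scores,
        directions=directions,
        threshold=threshold,
        flagged=[str(f) for f in flagged],
    )


def vif(long: pd.DataFrame, fixed_terms: Sequence[str] = FIXED_TERMS) -> pd.Series:
    """Variance inflation factors of the fixed-effects design columns.

    Each non-intercept column is regressed on all the others (with
    intercept); VIF = 1/(1-R^2).  Perfectly collinear columns report inf.
    """
    X, names = _fixed_design(long, fixed_terms)
    if X.shape[1] < 3:  # intercept + >=2 terms
        raise ValueError("VIF needs at least two fixed-effect columns")
    out = {}
    for j in range(1, X.shape[1]):
        xj = X[:, j]
        others = np.delete(X, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((xj - xj.mean()) ** 2).sum())
        if ss_tot == 0:
            out[names[j]] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
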