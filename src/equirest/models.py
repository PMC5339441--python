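"""Mixed-model design for the lying-behaviour outcomes.

The inference design treats the four space-allowance treatments as an
*ordered* factor coded by orthonormal polynomial contrasts (third order for
outcomes pooled over surfaces, second order for per-surface outcomes), with
rank status (low/high) and the rank × treatment interaction as further fixed
effects.  The random structure nests the experimental condition in the
individual horse in the group.  Final models are found by backward stepwise
reduction: the least significant droppable term with p > 0.1 is removed,
respecting marginality (the interaction before its main effects; the cubic
treatment term before the quadratic before the linear), until every
remaining term has p ≤ 0.1.

Gaussian outcomes are fitted with ``statsmodels`` MixedLM (variance
components for the nesting); binary outcomes with binomial GEE clustered on
the horse (exchangeable working correlation), reported as Wald χ².  Skewed
outcomes are log- or logit-transformed before fitting and estimates are
back-transformed to the response scale, where they are medians rather than
means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import yaml

__all__ = [
    "TREATMENTS",
    "ModelSpec",
    "Term",
    "FitResult",
    "poly_contrasts",
    "OutcomeTransform",
    "make_transform",
    "build_terms",
    "fit_full_model",
    "stepwise_reduce",
    "estimate_response_scale",
    "default_model_specs",
]

TREATMENTS = ("T0", "T0.5", "T1", "T1.5")
RATIO_BY_TREATMENT = {"T0": 0.0, "T0.5": 0.5, "T1": 1.0, "T1.5": 1.5}
ALPHA_DROP = 0.1


# ---------------------------------------------------------------------------
# Ordered-factor polynomial contrasts

def poly_contrasts(n_levels: int = 4, order: int = 3) -> np.ndarray:
    """Orthonormal polynomial contrasts over equally spaced level scores.

    Returns an ``n_levels × order`` matrix whose k-th column is the degree-k
    orthogonal polynomial (linear, quadratic, ...), unit length, orthogonal
    to the intercept and to each other; signs follow the convention that the
    top level loads positively on each column (for four levels the linear
    column is proportional to (−3, −1, 1, 3)).
    """
    if order >= n_levels:
        raise ValueError(f"order ({order}) must be below n_levels ({n_levels})")
    x = np.arange(n_levels, dtype=float)
    vander = np.vander(x - x.mean(), N=order + 1, increasing=True)
    q, r = np.linalg.qr(vander)
    q = q[:, 1:]  # drop the intercept column
    # fix signs: last (highest-level) nonzero entry of each column positive
    for k in range(q.shape[1]):
        col = q[:, k]
        lead = col[np.flatnonzero(np.abs(col) > 1e-12)[-1]]
        if lead < 0:
            q[:, k] = -col
    return q


# ---------------------------------------------------------------------------
# Outcome transformations

@dataclass(frozen=True)
class OutcomeTransform:
    """Invertible outcome transformation (``inverse(forward(x)) == x``)."""

    kind: str  # none | log | logit
    offset: float = 0.0  # additive offset c for the log kind
    n: int | None = None  # sample size for the logit boundary shrink

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "none":
            return x
        if self.kind == "log":
            return np.log(x + self.offset)
        if self.kind == "logit":
            if np.nanmin(x) < 0 or np.nanmax(x) > 1:
                raise ValueError("logit requires proportions in [0, 1]")
            p = self._shrink(x)
            return np.log(p / (1 - p))
        raise ValueError(f"unknown transformation {self.kind!r}")

    def inverse(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.kind == "none":
            return y
        if self.kind == "log":
            return np.exp(y) - self.offset
        p = 1.0 / (1.0 + np.exp(-y))
        return self._unshrink(p)

    # boundary shrink p' = (p (n-1) + 1/2) / n keeps exact 0/1 inside (0, 1)
    def _shrink(self, p: np.ndarray) -> np.ndarray:
        if not self.n:
            return p
        return (p * (self.n - 1) + 0.5) / self.n

    def _unshrink(self, p: np.ndarray) -> np.ndarray:
        if not self.n:
            return p
        return (p * self.n - 0.5) / (self.n - 1)


def make_transform(kind: str, values: np.ndarray | None = None,
                   offset: float = 1.0) -> OutcomeTransform:
    """Transformation for an outcome column.

    ``log`` uses an additive offset (default 1 min) so zero durations stay
    finite; ``logit`` shrinks exact 0/1 toward ½ by 1/(2n) with n the number
    of non-missing observations.
    """
    if kind == "none":
        return OutcomeTransform("none")
    if kind == "log":
        return OutcomeTransform("log", offset=offset)
    if kind == "logit":
        n = int(np.sum(np.isfinite(values))) if values is not None else None
        return OutcomeTransform("logit", n=n)
    raise ValueError(f"unknown transformation {kind!r}")


# ---------------------------------------------------------------------------
# Model specification

@dataclass(frozen=True)
class ModelSpec:
    """One outcome's model: transformation, family, polynomial order, terms."""

    outcome: str
    transformation: str = "none"  # none | log | logit
    family: str = "gaussian"  # gaussian | binomial
    poly_order: int = 3  # 3 for totals, 2 for per-surface outcomes
    include_rank: bool = True
    include_interaction: bool = True

    @property
    def name(self) -> str:
        return self.outcome


def default_model_specs() -> list[ModelSpec]:
    """The study's outcome list: model type and transformation per outcome.

    Totals use a third-order treatment polynomial, per-surface outcomes a
    second-order one.  Durations on rubber mats / firm ground are
    log-transformed, lateral recumbency logit-transformed, and the two
    under-30-min flags are binomial.
    """
    return [
        ModelSpec("n_bouts_total", "none", "gaussian", 3),
        ModelSpec("n_bouts_litter", "none", "gaussian", 2),
        ModelSpec("n_bouts_rubber_mats", "none", "gaussian", 2),
        ModelSpec("n_bouts_firm_ground", "none", "gaussian", 2),
        ModelSpec("duration_min_total", "none", "gaussian", 3),
        ModelSpec("duration_min_litter", "none", "gaussian", 2),
        ModelSpec("duration_min_rubber_mats", "log", "gaussian", 2),
        ModelSpec("duration_min_firm_ground", "log", "gaussian", 2),
        ModelSpec("under_30min", "none", "binomial", 3),
        ModelSpec("under_30min_litter", "none", "binomial", 2),
        ModelSpec("pct_lateral", "logit", "gaussian", 3),
        ModelSpec("pct_present", "none", "gaussian", 3),
        ModelSpec("pct_forced", "none", "gaussian", 3),
    ]


def specs_from_yaml(path) -> list[ModelSpec]:
    """Load model specs from a YAML list of mappings (field names as in
    :class:`ModelSpec`)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or []
    return [ModelSpec(**entry) for entry in raw]


def specs_to_yaml(specs: list[ModelSpec], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([vars(s) | {} for s in specs], fh, sort_keys=False)


@dataclass(frozen=True)
class Term:
    """A droppable block of design columns with marginality constraints."""

    name: str
    columns: tuple[str, ...]
    order: int  # polynomial degree (0 for rank, highest degree for interaction)
    blocked_by: tuple[str, ...] = ()  # terms that must leave first


def build_terms(spec: ModelSpec) -> list[Term]:
    """Fixed-effect term structure for a spec.

    Treatment polynomial degrees are separate single-df terms reduced from
    the cubic down; the rank × treatment interaction is one joint block
    (dropped or retained as a whole) and must leave before rank or any
    treatment degree it involves can be considered.
    """
    k = spec.poly_order
    terms = []
    inter = f"rank:treatment^{k}"
    for d in range(1, k + 1):
        blocked = [f"treatment^{d + 1}"] if d < k else []
        if spec.include_rank and spec.include_interaction:
            blocked.append(inter)
        terms.append(Term(f"treatment^{d}", (f"tr{d}",), d, tuple(blocked)))
    if spec.include_rank:
        blocked = (inter,) if spec.include_interaction else ()
        terms.append(Term("rank", ("rank_low",), 0, blocked))
        if spec.include_interaction:
            terms.append(
                Term(inter, tuple(f"rank_tr{d}" for d in range(1, k + 1)), k)
            )
    return terms


def build_design(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Attach outcome and contrast columns to a metrics table.

    Expects columns ``treatment`` (labels T0..T1.5), ``rank_class``,
    ``horse_id`` and ``group``.  Derives ``under_30min_litter`` from the
    per-surface duration when absent, transforms the outcome, and drops
    rows with a missing outcome (undefined proportions).
    """
    df = data.copy()
    if spec.outcome == "under_30min_litter" and spec.outcome not in df.columns:
        df[spec.outcome] = df["duration_min_litter"] < 30.0
    y = df[spec.outcome].astype(float)
    if spec.outcome.startswith("pct_"):
        y = y / 100.0  # proportions for the transformation stage
    tf = make_transform(spec.transformation, y.to_numpy())
    with np.errstate(invalid="ignore"):
        df["_y"] = tf.forward(y.to_numpy()) if spec.family == "gaussian" else y
    df = df[np.isfinite(df["_y"])].copy()

    contrasts = poly_contrasts(len(TREATMENTS), spec.poly_order)
    level = df["treatment"].map({t: i for i, t in enumerate(TREATMENTS)})
    if level.isna().any():
        raise ValueError("treatment labels must be T0, T0.5, T1, T1.5")
    for d in range(1, spec.poly_order + 1):
        df[f"tr{d}"] = contrasts[level.to_numpy(), d - 1]
    df["rank_low"] = (df["rank_class"] == "low").astype(float)
    for d in range(1, spec.poly_order + 1):
        df[f"rank_tr{d}"] = df["rank_low"] * df[f"tr{d}"]
    df["condition"] = df["horse_id"].astype(str) + ":" + df["treatment"].astype(str)
    df.attrs["transform"] = tf
    return df


# ---------------------------------------------------------------------------
# Fitting

@dataclass
class TermStat:
    term: str
    statistic: float
    df_num: int
    df_den: float | None  # None for χ² tests
    p: float


@dataclass
class FitResult:
    """A fitted (possibly reduced) model for one outcome."""

    spec: ModelSpec
    terms: list[Term]  # retained terms
    stats: list[TermStat]
    params: pd.Series  # fixed effects incl. intercept
    cov: pd.DataFrame
    transform: OutcomeTransform
    nobs: int
    df_den: float
    path: list[str] = field(default_factory=list)  # dropped terms, in order
    warnings: list[str] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        return [t.name for t in self.terms]

    def stats_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.stats])


def _fit_gaussian(df: pd.DataFrame, cols: list[str]) -> tuple[pd.Series, pd.DataFrame, float, list[str]]:
    """MixedLM with random intercepts for group, horse and condition.

    Singular or non-convergent fits fall back to progressively simpler
    random structures, innermost level first, with a logged warning.
    """
    rhs = " + ".join(cols) if cols else "1"
    notes: list[str] = []
    structures = [
        {"re_formula": "1", "vc_formula": {"horse": "0 + C(horse_id)",
                                           "condition": "0 + C(condition)"}},
        {"re_formula": "1", "vc_formula": {"horse": "0 + C(horse_id)"}},
        {"re_formula": "1", "vc_formula": None},
    ]
    for i, struct in enumerate(structures):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM.from_formula(
                    f"_y ~ {rhs}", data=df, groups="group",
                    re_formula=struct["re_formula"], vc_formula=struct["vc_formula"],
                )
                res = model.fit(reml=True, method=["lbfgs", "powell"])
            fe = res.fe_params
            cov = res.cov_params().loc[fe.index, fe.index]
            if np.all(np.isfinite(fe)) and np.all(np.isfinite(cov.to_numpy())):
                if i > 0:
                    notes.append(f"random-effects structure simplified (level {i})")
                df_den = res.nobs - len(fe)
                return fe, cov, float(df_den), notes
        except Exception as exc:  # noqa: BLE001 - fall through to simpler structure
            notes.append(f"fit failed ({type(exc).__name__}); simplifying random effects")
    raise RuntimeError("all random-effects structures failed to fit")


def _fit_binomial(df: pd.DataFrame, cols: list[str]) -> tuple[pd.Series, pd.DataFrame, float, list[str]]:
    """Binomial GEE clustered on horse, exchangeable working correlation."""
    rhs = " + ".join(cols) if cols else "1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE.from_formula(
            f"_y ~ {rhs}", data=df, groups="horse_id",
            family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        res = model.fit()
    return res.params, res.cov_params(), np.inf, []


def _wald_stats(params: pd.Series, cov: pd.DataFrame, terms: list[Term],
                df_den: float) -> list[TermStat]:
    """Per-term Wald test: F against the residual df for Gaussian fits
    (matching conditional F-test reporting), χ² when df_den is infinite."""
    out = []
    for term in terms:
        cols = [c for c in term.columns if c in params.index]
        b = params[cols].to_numpy()
        v = cov.loc[cols, cols].to_numpy()
        q = len(cols)
        stat = float(b @ np.linalg.solve(v, b))
        if np.isfinite(df_den):
            f = stat / q
            p = float(sps.f.sf(f, q, df_den))
            out.append(TermStat(term.name, f, q, df_den, max(p, np.finfo(float).tiny)))
        else:
            p = float(sps.chi2.sf(stat, q))
            out.append(TermStat(term.name, stat, q, None, max(p, np.finfo(float).tiny)))
    return out


def _fit_terms(df: pd.DataFrame, spec: ModelSpec, terms: list[Term]) -> FitResult:
    cols = [c for t in terms for c in t.columns]
    fitter = _fit_gaussian if spec.family == "gaussian" else _fit_binomial
    params, cov, df_den, notes = fitter(df, cols)
    stats = _wald_stats(params, cov, terms, df_den)
    return FitResult(spec, list(terms), stats, params, cov,
                     df.attrs["transform"], len(df), df_den, warnings=notes)


def fit_full_model(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit the full fixed-effect structure (no reduction)."""
    df = build_design(data, spec)
    if df["group"].nunique() < 2 or df["horse_id"].nunique() < 4:
        raise ValueError("need at least 2 groups and 4 horses to fit the nesting")
    return _fit_terms(df, spec, build_terms(spec))


def stepwise_reduce(spec: ModelSpec, data: pd.DataFrame,
                    alpha_drop: float = ALPHA_DROP) -> FitResult:
    """Backward stepwise reduction with p > ``alpha_drop`` as the drop rule.

    At each step only *droppable* terms — those no retained term is marginal
    to — are candidates.  The candidate with the largest p above the
    threshold is removed (ties broken toward the higher polynomial order)
    and the model refitted; the loop stops when every droppable term has
    p ≤ ``alpha_drop``.  The drop order is recorded in ``path``.
    """
    df = build_design(data, spec)
    terms = build_terms(spec)
    path: list[str] = []
    notes: list[str] = []
    while True:
        result = _fit_terms(df, spec, terms)
        notes.extend(result.warnings)
        active = {t.name for t in terms}
        droppable = [t for t in terms if not (set(t.blocked_by) & active)]
        p_by_name = {s.term: s.p for s in result.stats}
        candidates = [t for t in droppable if p_by_name[t.name] > alpha_drop]
        if not candidates:
            result.path = path
            result.warnings = notes
            return result
        worst = max(candidates, key=lambda t: (p_by_name[t.name], t.order))
        path.append(worst.name)
        terms = [t for t in terms if t.name != worst.name]


def estimate_response_scale(fit: FitResult) -> pd.DataFrame:
    """Per treatment × rank estimates with 95% CI, back-transformed.

    Linear-predictor estimates and Wald intervals are pushed through the
    inverse transformation (monotone, so the CI ordering is preserved).
    Under log/logit the back-transformed values are medians of the response
    distribution, not means — flagged in the ``scale`` column.  Percentage
    outcomes are reported back on the 0-100 scale.
    """
    spec = fit.spec
    contrasts = poly_contrasts(len(TREATMENTS), spec.poly_order)
    z = sps.norm.ppf(0.975)
    is_pct = spec.outcome.startswith("pct_")
    scale_note = "median" if fit.transform.kind in ("log", "logit") else "mean"
    rows = []
    for rank_low in (0.0, 1.0):
        for i, t in enumerate(TREATMENTS):
            x = pd.Series(0.0, index=fit.params.index)
            x["Intercept"] = 1.0
            for d in range(1, spec.poly_order + 1):
                for col, val in ((f"tr{d}", contrasts[i, d - 1]),
                                 (f"rank_tr{d}", rank_low * contrasts[i, d - 1])):
                    if col in x.index:
                        x[col] = val
            if "rank_low" in x.index:
                x["rank_low"] = rank_low
            eta = float(x @ fit.params)
            se = float(np.sqrt(x @ fit.cov.to_numpy() @ x))
            lo, est, hi = (fit.transform.inverse(np.array([eta - z * se, eta, eta + z * se]))
                           if spec.family == "gaussian"
                           else 1 / (1 + np.exp(-np.array([eta - z * se, eta, eta + z * se]))))
            if is_pct:
                lo, est, hi = 100 * lo, 100 * est, 100 * hi
            rows.append({"treatment": t, "rank_class": "low" if rank_low else "high",
                         "estimate": est, "ci_low": lo, "ci_high": hi,
                         "scale": scale_note if spec.family == "gaussian" else "probability"})
    return pd.DataFrame(rows)
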