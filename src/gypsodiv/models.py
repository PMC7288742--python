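"""GLMs of the diversity metrics along the aridity gradient.

Each metric is regressed on the mean maximum temperature of the hottest
month (T), mean annual precipitation (P), their interaction and total plant
cover (a productivity covariate). The default model table assigns the
family/link used in the source analysis: Poisson(log) for richness,
quasi-Poisson(log) for CMG, Gaussian(identity) for everything else.

Per-term chi-square statistics come from Type-II likelihood-ratio tests:
each main effect is tested in the model without the interaction; the
interaction and cover are tested against the full model. For quasi-likelihood
and Gaussian fits the deviance difference is scaled by the full-model
Pearson dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .datasets import EnvironmentTable, ValidationError

TERMS = ("T", "P", "T:P", "cover")

FAMILIES = {
    ("poisson", "log"): lambda: sm.families.Poisson(sm.families.links.Log()),
    ("quasipoisson", "log"): lambda: sm.families.Poisson(sm.families.links.Log()),
    ("gaussian", "identity"): lambda: sm.families.Gaussian(
        sm.families.links.Identity()
    ),
}


@dataclass
class ModelSpec:
    response: str
    family: str
    link: str
    terms: tuple[str, ...] = TERMS

    def __post_init__(self) -> None:
        if (self.family, self.link) not in FAMILIES:
            raise ValidationError(
                f"unsupported family/link: {self.family}({self.link})"
            )
        if self.response == "NRI" and self.family != "gaussian":
            raise ValidationError("NRI can be negative; use gaussian/identity")


def default_model_table() -> list[ModelSpec]:
    """The eight response models with their standard family/link assignment."""
    return [
        ModelSpec("richness", "poisson", "log"),
        ModelSpec("diversity", "gaussian", "identity"),
        ModelSpec("GR", "gaussian", "identity"),
        ModelSpec("CMG", "quasipoisson", "log"),
        ModelSpec("GD", "gaussian", "identity"),
        ModelSpec("PSR", "gaussian", "identity"),
        ModelSpec("PSV", "gaussian", "identity"),
        ModelSpec("NRI", "gaussian", "identity"),
    ]


#: metrics-table column backing each response name
RESPONSE_COLUMNS = {
    "richness": "S",
    "diversity": "invSimpson",
    "GR": "GR",
    "CMG": "CMG",
    "GD": "GD",
    "PSR": "PSR",
    "PSV": "PSV",
    "NRI": "NRI",
}


def build_design(env: pd.DataFrame, center: bool = False) -> pd.DataFrame:
    """Design frame with columns T, P, T:P, cover (plus intercept added at fit).

    With ``center=True`` T and P are mean-centered before forming the
    interaction, which changes the interpretation (not the test) of the main
    effects under interaction.
    """
    t = env["Tmax"].astype(float)
    p = env["MAP"].astype(float)
    if center:
        t = t - t.mean()
        p = p - p.mean()
    design = pd.DataFrame(
        {"T": t, "P": p, "T:P": t * p, "cover": env["cover"].astype(float)},
        index=env.index,
    )
    return design


@dataclass
class GlmFit:
    """A fitted per-metric GLM plus everything needed for deviance tests."""

    spec: ModelSpec
    y: pd.Series
    design: pd.DataFrame
    result: object
    dispersion: float
    n_dropped: int = 0
    center: bool = False

    @property
    def coefficients(self) -> pd.Series:
        return self.result.params


def _fit(y: np.ndarray, x: pd.DataFrame, spec: ModelSpec):
    exog = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        raise ValidationError("singular design matrix (collinear predictors)")
    family = FAMILIES[(spec.family, spec.link)]()
    model = sm.GLM(y, exog, family=family)
    try:
        return model.fit()
    except ValueError:
        # constant responses make the scale estimate degenerate; the
        # coefficients and deviance are still well defined at fixed scale
        return model.fit(scale=1.0)


def fit_glm(
    spec: ModelSpec,
    metrics: pd.DataFrame,
    env: EnvironmentTable | pd.DataFrame,
    center: bool = False,
) -> GlmFit:
    """Fit one response metric against T, P, T×P and cover.

    NA responses are dropped pairwise (count recorded on the returned fit).
    Quasi-Poisson dispersion is estimated as Pearson chi-square / residual df.
    """
    env_df = env.table if isinstance(env, EnvironmentTable) else env
    column = RESPONSE_COLUMNS.get(spec.response, spec.response)
    if column not in metrics.columns:
        raise ValidationError(f"metrics table has no column {column!r}")
    y = metrics[column].reindex(env_df.index)
    keep = y.notna()
    n_dropped = int((~keep).sum())
    y = y[keep]
    if len(y) < 10:
        raise ValidationError(
            f"only {len(y)} non-NA observations for {spec.response}; need >= 10"
        )
    if spec.link == "log":
        # Poisson counts may be zero; a quasi-Poisson continuous response
        # must be strictly positive for the log-scale fit to make sense
        bad = (y < 0).any() if spec.family == "poisson" else (y <= 0).any()
        if bad:
            raise ValidationError(
                f"non-positive response values under log link for "
                f"{spec.response}; choose a gaussian/identity model"
            )
    design = build_design(env_df.loc[keep.index[keep]], center=center)
    result = _fit(y.to_numpy(), design, spec)
    if spec.family == "poisson":
        dispersion = 1.0
    else:
        dispersion = float(result.pearson_chi2 / result.df_resid)
    return GlmFit(spec, y, design, result, dispersion, n_dropped, center)


def significance_code(p_value: float) -> str:
    """Star codes: * 0.01<P<0.05, ** 0.001<P<0.01, *** P<0.001, else ns."""
    if np.isnan(p_value):
        return "ns"
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


def analysis_of_deviance(fit: GlmFit) -> pd.DataFrame:
    """Type-II likelihood-ratio table with one row per model term.

    Main effects T and P are each tested by dropping them from the model
    containing the other main effects and cover but not the interaction
    (marginality); T:P and cover are tested against the full model. The
    chi-square is the (dispersion-scaled) deviance difference on 1 df;
    coefficient signs come from the full model.
    """
    spec = fit.spec
    y = fit.y.to_numpy()
    full_terms = list(spec.terms)
    deviances = {}

    def dev(terms: list[str]) -> float:
        key = tuple(terms)
        if key not in deviances:
            deviances[key] = float(_fit(y, fit.design[list(terms)], spec).deviance)
        return deviances[key]

    full_dev = float(fit.result.deviance)
    deviances[tuple(full_terms)] = full_dev

    rows = []
    for term in full_terms:
        if term in ("T", "P"):
            base = [t for t in full_terms if t != "T:P"]
        else:
            base = full_terms
        reduced = [t for t in base if t != term]
        d_base = full_dev if base == full_terms else dev(base)
        d_reduced = dev(reduced)
        delta = max(d_reduced - d_base, 0.0)
        if fit.dispersion > 0:
            chi2 = delta / fit.dispersion
        else:  # constant response: nothing to explain
            chi2 = 0.0
        p_value = float(st.chi2.sf(chi2, df=1))
        coef = float(fit.result.params[term])
        rows.append(
            {
                "term": term,
                "chi_square": chi2,
                "sign": "+" if coef > 0 else ("-" if coef < 0 else "NA"),
                "p_value": p_value,
                "stars": significance_code(p_value),
            }
        )
    return pd.DataFrame(rows)


def collinearity_check(env: EnvironmentTable | pd.DataFrame) -> dict:
    """Pearson correlation between T and P with its t statistic and p-value.

    t = r sqrt(n−2) / sqrt(1−r²); constant predictors yield NA with a
    warning in the returned dict.
    """
    env_df = env.table if isinstance(env, EnvironmentTable) else env
    n = len(env_df)
    if n < 3:
        raise ValidationError("need at least 3 plots for a correlation check")
    t_col = env_df["Tmax"].to_numpy()
    p_col = env_df["MAP"].to_numpy()
    if np.ptp(t_col) == 0 or np.ptp(p_col) == 0:
        return {"r": np.nan, "r2": np.nan, "t": np.nan, "p": np.nan, "n": n,
                "warning": "constant predictor"}
    r, p_two_sided = st.pearsonr(t_col, p_col)
    if abs(r) < 1.0:
        t_stat = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    else:
        t_stat = np.inf if r > 0 else -np.inf
    return {"r": float(r), "r2": float(r**2), "t": float(t_stat),
            "p": float(p_two_sided), "n": n}


def correlation_t_statistic(r: float, n: int) -> float:
    """Closed form t = r sqrt(n−2) / sqrt(1−r²) for a Pearson correlation."""
    return float(r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2))


def model_report(
    metrics: pd.DataFrame,
    env: EnvironmentTable | pd.DataFrame,
    specs: list[ModelSpec] | None = None,
    center: bool = False,
) -> pd.DataFrame:
    """Analysis-of-deviance report across all responses (one row per term)."""
    if specs is None:
        specs = default_model_table()
    frames = []
    for spec in specs:
        fit = fit_glm(spec, metrics, env, center=center)
        table = analysis_of_deviance(fit)
        table.insert(0, "response", spec.response)
        table.insert(1, "family", spec.family)
        table.insert(2, "link", spec.link)
        table["dispersion"] = fit.dispersion
        table["n_obs"] = len(fit.y)
        table["n_dropped"] = fit.n_dropped
        frames.append(table)
    return pd.concat(frames, ignore_index=True)
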