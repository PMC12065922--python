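"""Linear mixed model of longitudinal study records and the empirical
decomposition of explained variation.

The response of record *j* of subject *i* is modelled as

    y_ij = alpha + time_ij' b1 + side_ij' b2 + depth_ij b3 + counts_ij b4
           + smoking_ij' b5 + BMI_ij b6 + season_ij' b7 + delta_i + eps_ij

with a subject random intercept delta_i ~ N(0, sigma_delta^2) and residual
eps_ij ~ N(0, sigma_eps^2), fitted by restricted maximum likelihood
(statsmodels ``MixedLM``).  Categorical covariates are effect-coded so that
each term's fitted contribution is invariant to the reference-level choice.

The *explained variation* of the fit partitions the response variance into
one fraction per fixed effect (the empirical variance of its fitted linear
contribution), a shared term (covariance between contributions, ~0 for
independent covariates), the subject fraction (sigma_delta^2) and the
residual fraction (sigma_eps^2); the fractions sum to one by construction.

A synthetic study-record generator with exactly this generative form
supports parameter-recovery and calibration experiments in place of the
unavailable clinical records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "STUDY_COLUMNS",
    "StudySimConfig",
    "VarianceDecomposition",
    "ExplainedVariationModel",
    "ExplainedVariationResults",
    "simulate_study",
    "simulate_wavelength_study",
    "fit_lmm",
    "explained_variation",
    "per_wavelength_variation",
]

#: Documented record columns (one row = one ROI summary observation).
STUDY_COLUMNS = ("subject", "repetition", "response", "time", "side", "depth",
                 "counts", "smoking", "bmi", "ws", "organ", "wavelength")

TIME_LEVELS = ("pre", "during", "post")

#: Default fixed-effect terms of the model.
CATEGORICAL_TERMS = ("time", "side", "smoking", "ws")
CONTINUOUS_TERMS = ("depth", "counts", "bmi")


# ---------------------------------------------------------------------------
# synthetic study records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudySimConfig:
    """Generative settings for synthetic longitudinal study records.

    ``*_effects`` map category levels to additive effects on the response;
    ``*_slope`` are per-unit effects of the continuous covariates.  Defaults
    mimic the study design: three treatment phases measured on both neck
    sides, with subject-level covariates (smoking, BMI) and a seasonal
    indicator.
    """

    n_subjects: int = 30
    n_repetitions: int = 6  # 3 phases x 2 sides per subject
    alpha: float = 1.0
    time_effects: dict = field(default_factory=lambda: {
        "pre": 0.0, "during": 0.0, "post": 0.0})
    side_effects: dict = field(default_factory=lambda: {
        "left": 0.0, "right": 0.0})
    smoking_effects: dict = field(default_factory=lambda: {
        "never": 0.0, "ever": 0.0})
    ws_effects: dict = field(default_factory=lambda: {
        "winter": 0.0, "summer": 0.0})
    depth_slope: float = 0.0
    counts_slope: float = 0.0
    bmi_slope: float = 0.0
    sigma_subject: float = 0.3
    sigma_resid: float = 0.3
    depth_range: tuple[float, float] = (5.0, 25.0)
    mean_counts: float = 400.0
    bmi_mean: float = 26.0
    bmi_sd: float = 4.0
    organ: str = "lymph_node"
    wavelength: float = 800.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.sigma_subject < 0 or self.sigma_resid < 0:
            raise ValueError("standard deviations must be >= 0")


def simulate_study(cfg: StudySimConfig) -> pd.DataFrame:
    """Generate records exactly following the model's generative form."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    sides = ("left", "right")
    for i in range(cfg.n_subjects):
        smoking = rng.choice(list(cfg.smoking_effects))
        bmi = rng.normal(cfg.bmi_mean, cfg.bmi_sd)
        delta = rng.normal(0.0, cfg.sigma_subject)
        for j in range(cfg.n_repetitions):
            time = TIME_LEVELS[j % 3]
            side = sides[(j // 3) % 2]
            ws = rng.choice(list(cfg.ws_effects))
            depth = rng.uniform(*cfg.depth_range)
            counts = int(rng.poisson(cfg.mean_counts)) + 1
            eps = rng.normal(0.0, cfg.sigma_resid)
            response = (cfg.alpha
                        + cfg.time_effects[time]
                        + cfg.side_effects[side]
                        + cfg.smoking_effects[smoking]
                        + cfg.ws_effects[ws]
                        + cfg.depth_slope * depth
                        + cfg.counts_slope * counts
                        + cfg.bmi_slope * bmi
                        + delta + eps)
            rows.append((i, j, response, time, side, depth, counts,
                         smoking, bmi, ws, cfg.organ, cfg.wavelength))
    return pd.DataFrame(rows, columns=STUDY_COLUMNS)


def simulate_wavelength_study(cfg: StudySimConfig, wavelengths,
                              time_effect_by_wavelength) -> pd.DataFrame:
    """Concatenate per-wavelength studies sharing one subject panel.

    ``time_effect_by_wavelength`` maps each wavelength to a scalar treatment
    effect applied as {pre: 0, during: e/2, post: e}; all other settings
    (including the seed, hence the subject panel and noise draws per
    wavelength index) come from ``cfg``.
    """
    frames = []
    for lam in wavelengths:
        e = float(time_effect_by_wavelength[lam])
        sub = StudySimConfig(**{**cfg.__dict__,
                                "time_effects": {"pre": 0.0, "during": e / 2,
                                                 "post": e},
                                "wavelength": float(lam)})
        frames.append(simulate_study(sub))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _effect_code(series: pd.Series, term: str) -> pd.DataFrame:
    """Effect (sum-to-zero) coding: L-1 columns, last level coded -1."""
    levels = sorted(series.astype(str).unique())
    cols = {}
    for lev in levels[:-1]:
        col = np.where(series.astype(str) == lev, 1.0,
                       np.where(series.astype(str) == levels[-1], -1.0, 0.0))
        cols[f"{term}[{lev}]"] = col
    return pd.DataFrame(cols, index=series.index)


def _build_design(data: pd.DataFrame, categorical, continuous):
    """Design matrix with intercept; returns (exog, term->columns map)."""
    parts = [pd.Series(1.0, index=data.index, name="Intercept")]
    term_columns = {}
    for term in categorical:
        if data[term].astype(str).nunique() < 2:
            continue  # constant covariate carries no variation
        coded = _effect_code(data[term], term)
        term_columns[term] = list(coded.columns)
        parts.append(coded)
    for term in continuous:
        col = data[term].astype(float)
        col.name = term
        term_columns[term] = [term]
        parts.append(col)
    exog = pd.concat(parts, axis=1)
    return exog, term_columns


# ---------------------------------------------------------------------------
# model and results
# ---------------------------------------------------------------------------

@dataclass
class VarianceDecomposition:
    """Fractions of response variance attributed to each source."""

    fractions: dict           # fixed-effect term -> fraction
    shared: float             # covariance between fixed-effect contributions
    subject: float            # sigma_delta^2 / total
    residual: float           # sigma_eps^2 / total

    def total(self) -> float:
        return sum(self.fractions.values()) + self.shared + self.subject \
            + self.residual

    def as_series(self) -> pd.Series:
        s = pd.Series(self.fractions, dtype=float)
        s["shared"] = self.shared
        s["subject"] = self.subject
        s["residual"] = self.residual
        return s


class ExplainedVariationResults:
    """Estimates, variance components and the explained-variation split."""

    def __init__(self, model: "ExplainedVariationModel", params: pd.Series,
                 bse: pd.Series, pvalues: pd.Series, sigma_subject2: float,
                 sigma_resid2: float, converged: bool, method: str):
        self.model = model
        self.params = params
        self.bse = bse
        self.pvalues = pvalues
        self.sigma_subject2 = float(sigma_subject2)
        self.sigma_resid2 = float(sigma_resid2)
        self.converged = bool(converged)
        self.method = method

    @property
    def fe_params(self) -> pd.Series:
        return self.params

    def contribution(self, term: str) -> np.ndarray:
        """Fitted linear contribution of one fixed-effect term per record."""
        cols = self.model.term_columns[term]
        X = self.model.exog[cols].to_numpy()
        beta = self.params[cols].to_numpy()
        return X @ beta

    def explained_variation(self) -> VarianceDecomposition:
        """Empirical decomposition of explained variation.

        Each term's share is the population variance of its fitted
        contribution across the records; covariance between term
        contributions goes into ``shared``; the subject and residual shares
        come from the fitted variance components.  Shares are normalised by
        their sum, so the decomposition adds to one exactly.
        """
        if not self.converged:
            raise RuntimeError("cannot decompose a non-converged fit")
        contribs = {t: self.contribution(t) for t in self.model.term_columns}
        var_terms = {t: float(np.var(c)) for t, c in contribs.items()}
        total_fixed = float(np.var(np.sum(list(contribs.values()), axis=0)))
        shared = total_fixed - sum(var_terms.values())
        total = total_fixed + self.sigma_subject2 + self.sigma_resid2
        if total <= 0:
            raise RuntimeError("degenerate fit: zero total variance")
        return VarianceDecomposition(
            fractions={t: v / total for t, v in var_terms.items()},
            shared=shared / total,
            subject=self.sigma_subject2 / total,
            residual=self.sigma_resid2 / total,
        )

    def summary(self) -> str:
        lines = [
            f"Explained-variation mixed model ({self.method.upper()}), "
            f"converged={self.converged}",
            f"observations: {len(self.model.data)}, "
            f"subjects: {self.model.data[self.model.subject_col].nunique()}",
            "",
            "Fixed effects:",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:<18} {self.params[name]: .5f}"
                f"  (se {self.bse.get(name, float('nan')): .5f},"
                f" p {self.pvalues.get(name, float('nan')): .4f})"
            )
        lines += [
            "",
            f"sigma^2 subject : {self.sigma_subject2:.6f}",
            f"sigma^2 residual: {self.sigma_resid2:.6f}",
            "",
            "Explained variation:",
        ]
        for name, frac in self.explained_variation().as_series().items():
            lines.append(f"  {name:<18} {100 * frac:6.2f} %")
        return "\n".join(lines)


class ExplainedVariationModel:
    """Mixed model of study records with a subject random intercept."""

    def __init__(self, data: pd.DataFrame, response: str = "response",
                 subject: str = "subject",
                 categorical=CATEGORICAL_TERMS,
                 continuous=CONTINUOUS_TERMS):
        data = pd.DataFrame(data).reset_index(drop=True)
        missing = {response, subject, *categorical, *continuous} - set(data)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        if not np.all(np.isfinite(data[response].astype(float))):
            raise ValueError("response contains non-finite values")
        counts = data.groupby(subject).size()
        if (counts >= 2).sum() < 2:
            raise ValueError(
                "need at least 2 subjects with at least 2 repetitions each"
            )
        self.data = data
        self.response_col = response
        self.subject_col = subject
        self.exog, self.term_columns = _build_design(data, categorical,
                                                     continuous)
        rank = np.linalg.matrix_rank(self.exog.to_numpy())
        if rank < self.exog.shape[1]:
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} < "
                f"{self.exog.shape[1]} columns); drop collinear covariates"
            )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs):
        return cls(data, **kwargs)

    def fit(self, method: str = "reml", tol: float = 1e-8
            ) -> ExplainedVariationResults:
        """Fit by REML (default) or, with ``method='ols'``, with the subject
        variance constrained to zero (ordinary least squares)."""
        endog = self.data[self.response_col].astype(float).to_numpy()
        exog = self.exog
        if method == "ols":
            res = sm.OLS(endog, exog).fit()
            return ExplainedVariationResults(
                self, res.params, res.bse, res.pvalues,
                sigma_subject2=0.0, sigma_resid2=float(res.scale),
                converged=True, method="ols")
        if method != "reml":
            raise ValueError("method must be 'reml' or 'ols'")
        groups = self.data[self.subject_col].to_numpy()
        # scale continuous columns to unit sd for optimizer conditioning;
        # estimates are transformed back afterwards
        names = list(exog.columns)
        scales = pd.Series(1.0, index=names)
        for name in names:
            if name == "Intercept":
                continue
            sd = float(exog[name].std())
            if sd > 0 and not set(exog[name].unique()) <= {-1.0, 0.0, 1.0}:
                scales[name] = sd
        exog_fit = exog / scales
        model = sm.MixedLM(endog, exog_fit, groups=groups)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = None
            for opt in (["lbfgs"], ["powell"], ["cg"]):
                try:
                    res = model.fit(reml=True, method=opt, gtol=tol,
                                    maxiter=2000)
                    break
                except np.linalg.LinAlgError:
                    continue
        if res is None or not res.converged:
            raise RuntimeError(
                "REML fit did not converge; inspect the design or rescale "
                "covariates"
            )
        params = pd.Series(res.fe_params, index=names) / scales
        bse = pd.Series(np.asarray(res.bse_fe), index=names) / scales
        pvalues = pd.Series(np.asarray(res.pvalues)[: len(names)], index=names)
        sigma_subject2 = float(np.asarray(res.cov_re)[0, 0])
        return ExplainedVariationResults(
            self, params, bse, pvalues, sigma_subject2,
            float(res.scale), res.converged, "reml")


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_lmm(records: pd.DataFrame, response: str = "response",
            **kwargs) -> ExplainedVariationResults:
    """Fit the mixed model to study records (REML)."""
    return ExplainedVariationModel(records, response=response, **kwargs).fit()


def explained_variation(fit: ExplainedVariationResults,
                        records=None) -> VarianceDecomposition:
    """Explained-variation decomposition of a converged fit."""
    return fit.explained_variation()


def per_wavelength_variation(records: pd.DataFrame,
                             response: str = "response") -> pd.DataFrame:
    """One explained-variation decomposition per acquisition wavelength.

    Returns a DataFrame indexed by wavelength (input order preserved) whose
    columns are the decomposition fractions.
    """
    wavelengths = list(pd.unique(records["wavelength"]))
    if len(wavelengths) < 2:
        raise ValueError("need records at >= 2 wavelengths")
    rows = {}
    for lam in wavelengths:
        sub = records[records["wavelength"] == lam]
        fit = fit_lmm(sub, response=response)
        rows[lam] = fit.explained_variation().as_series()
    out = pd.DataFrame(rows).T
    out.index.name = "wavelength"
    return out


def plot_variation_by_wavelength(table: pd.DataFrame, ax=None):
    """Stacked explained-variation fractions per wavelength."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    bottom = np.zeros(len(table))
    for col in table.columns:
        ax.bar(range(len(table)), table[col], bottom=bottom, label=col)
        bottom += table[col].to_numpy()
    ax.set_xticks(range(len(table)),
                  [f"{int(w)}" for w in table.index])
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("fraction of response variance")
    ax.legend(frameon=False, fontsize=8)
    return ax
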