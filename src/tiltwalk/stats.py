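"""Study-level inference for gait measures.

The long-format study table (participant x condition x repetition x
walking segment) is analysed with a linear mixed-effects model

    value ~ trial + trial:walkingSegment (+ walkingSegment)

with random intercepts for participant and for walking segment nested
within participant.  Condition contrasts are estimated marginal means
(EMMs) per trial x segment, compared pairwise with Tukey
(studentized-range) multiplicity adjustment.  Assumption checks
(Bartlett, Levene, Shapiro-Wilk), a 3xIQR extreme-point rule, per-subject
baseline correction and the yaw-CoP Pearson correlation round out the
analysis surface.

Degrees of freedom for contrast tests use the residual
(observations minus fixed-effect parameters) count, a containment-style
approximation; the choice is recorded in every contrast report.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from patsy import build_design_matrices
from scipy import stats as sps
from scipy.stats import studentized_range
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastResult",
    "LmeFit",
    "assumption_tests",
    "remove_extremes",
    "remove_extremes_table",
    "fit_lme",
    "pairwise_emm",
    "baseline_correct",
    "correlate",
    "significance_stars",
]

CONDITIONS = ("baseline", "supine", "RED", "LED")
EXTREME_IQR_FACTOR = 3.0
DF_METHOD = "containment (residual: n_obs - n_fixed_params)"


def validate_study_table(table: pd.DataFrame) -> None:
    """Key invariants of the long-format table."""
    required = {"participant", "trial", "repetition", "walkingSegment", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"study table missing columns {sorted(missing)}")
    if not set(table["walkingSegment"].unique()) <= {1, 2, 3}:
        raise ValueError("walkingSegment must be in {1, 2, 3}")
    keys = table[["participant", "trial", "repetition", "walkingSegment"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (participant, trial, repetition, WS) keys")


# ---------------------------------------------------------------------------
# assumption checks
# ---------------------------------------------------------------------------

def assumption_tests(table: pd.DataFrame, value_col: str = "value",
                     group_col: str = "trial") -> dict:
    """Equal-variance (Bartlett, Levene) and per-group normality
    (Shapiro-Wilk) checks across condition groups.

    Report only - nothing downstream branches on these p-values.
    Zero-variance groups are flagged as degenerate rather than crashing.
    """
    groups = {k: np.asarray(v, dtype=float)
              for k, v in table.groupby(group_col)[value_col]}
    for name, vals in groups.items():
        if vals.size < 3:
            raise ValueError(f"group {name!r} has fewer than 3 observations")
    degenerate = [name for name, vals in groups.items() if np.ptp(vals) == 0]
    report: dict = {"groups": list(groups), "degenerate_groups": degenerate}
    samples = list(groups.values())
    if degenerate:
        report["bartlett"] = report["levene"] = None
    else:
        b = sps.bartlett(*samples)
        l = sps.levene(*samples, center="median")
        report["bartlett"] = {"statistic": float(b.statistic), "p": float(b.pvalue)}
        report["levene"] = {"statistic": float(l.statistic), "p": float(l.pvalue)}
    shapiro = {}
    for name, vals in groups.items():
        if name in degenerate:
            shapiro[name] = None
        else:
            s = sps.shapiro(vals)
            shapiro[name] = {"statistic": float(s.statistic), "p": float(s.pvalue)}
    report["shapiro"] = shapiro
    return report


# ---------------------------------------------------------------------------
# extreme points
# ---------------------------------------------------------------------------

def remove_extremes(values: np.ndarray, factor: float = EXTREME_IQR_FACTOR) -> np.ndarray:
    """Drop points farther than ``factor``xIQR beyond the quartiles.

    Points exactly on the fence are retained.  Empty input passes
    through.  Idempotent: the fences are recomputed on the filtered data
    only by callers who choose to; a single application is the contract.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return v
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    if iqr == 0:            # degenerate spread: fences collapse, filter nothing
        return v
    keep = (v >= q1 - factor * iqr) & (v <= q3 + factor * iqr)
    return v[keep]


def remove_extremes_table(table: pd.DataFrame, value_col: str = "value",
                          factor: float = EXTREME_IQR_FACTOR) -> pd.DataFrame:
    """Apply the 3xIQR rule within every trial x walkingSegment cell."""
    g = table.groupby(["trial", "walkingSegment"], observed=True)[value_col]
    q1 = g.transform(lambda v: np.percentile(v, 25))
    q3 = g.transform(lambda v: np.percentile(v, 75))
    iqr = q3 - q1
    v = table[value_col]
    keep = (iqr == 0) | ((v >= q1 - factor * iqr) & (v <= q3 + factor * iqr))
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d extreme point(s) by the %gxIQR rule", n_drop, factor)
    return table[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    """One Tukey-adjusted pairwise condition contrast at a walking segment."""

    pair: tuple[str, str]
    ws: int
    estimate: float
    se: float
    p_unadjusted: float
    p_adjusted: float
    stars: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_adjusted <= 1.0):
            raise ValueError("adjusted p outside [0, 1]")
        if self.p_adjusted + 1e-12 < self.p_unadjusted:
            raise ValueError("adjusted p must be >= unadjusted p")


@dataclass
class LmeFit:
    """Fitted mixed model plus everything needed for EMM contrasts."""

    result: object                   # statsmodels MixedLMResults
    design_info: object
    fe_names: list[str]
    fe_params: np.ndarray
    fe_cov: np.ndarray
    df_resid: float
    conditions: list[str]
    ws_levels: list[int]
    converged: bool
    singular: bool

    def emm(self, trial: str, ws: int) -> float:
        """Estimated marginal mean of a trial x segment cell."""
        x = self._design_row(trial, ws)
        return float(x @ self.fe_params)

    def _design_row(self, trial: str, ws: int) -> np.ndarray:
        new = pd.DataFrame({"trial": [trial], "walkingSegment": [ws]})
        (x,) = build_design_matrices([self.design_info], new)
        return np.asarray(x)[0]

    def emm_table(self) -> pd.DataFrame:
        rows = [(tr, ws, self.emm(tr, ws))
                for tr in self.conditions for ws in self.ws_levels]
        return pd.DataFrame(rows, columns=["trial", "walkingSegment", "emm"])


def fit_lme(table: pd.DataFrame, value_col: str = "value") -> LmeFit:
    """Fit the mixed-effects condition model.

    Fixed effects: trial, walkingSegment (as a factor) and their
    interaction.  Random effects: intercept per participant plus a
    walkingSegment-within-participant variance component (any decay of a
    condition effect takes a different course per subject).  Estimated by
    REML through statsmodels MixedLM; a singular fit (a variance
    component estimated at zero) is reported with a warning flag, not an
    error.
    """
    data = table.rename(columns={value_col: "value"}).copy()
    validate_study_table(data)
    data["trial"] = pd.Categorical(
        data["trial"],
        categories=[c for c in CONDITIONS if c in set(data["trial"])],
    )
    formula = "value ~ C(trial) * C(walkingSegment)"
    model = smf.mixedlm(
        formula, data, groups=data["participant"],
        re_formula="1", vc_formula={"ws": "0 + C(walkingSegment)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True, method="lbfgs")
        except Exception:                         # pragma: no cover - fallback path
            res = model.fit(reml=True)
    k = len(res.fe_params)
    fe_cov = np.asarray(res.cov_params())[:k, :k]
    vc = np.concatenate([np.diag(np.atleast_2d(np.asarray(res.cov_re))),
                         np.ravel(np.asarray(res.vcomp))])
    singular = bool(np.any(vc <= 1e-10))
    if singular:
        logger.warning("singular mixed-model fit: a variance component is ~0")
    return LmeFit(
        result=res,
        design_info=model.data.design_info,
        fe_names=list(res.fe_params.index),
        fe_params=np.asarray(res.fe_params),
        fe_cov=fe_cov,
        df_resid=float(len(data) - k),
        conditions=list(data["trial"].cat.categories),
        ws_levels=sorted(int(w) for w in data["walkingSegment"].unique()),
        converged=bool(getattr(res, "converged", True)),
        singular=singular,
    )


def significance_stars(p: float) -> str:
    """Conventional cutoffs: *** < 0.001, ** < 0.01, * < 0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pairwise_emm(fit: LmeFit, ws: int) -> list[ContrastResult]:
    """All pairwise condition contrasts of EMMs at one walking segment.

    The Tukey adjustment refers each contrast's statistic to the
    studentized-range distribution with k = number of conditions, using
    the residual degrees of freedom (method named in ``DF_METHOD``).
    """
    if ws not in fit.ws_levels:
        raise ValueError(f"walking segment {ws} not in fitted model")
    conds = fit.conditions
    k = len(conds)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = conds[i], conds[j]
            c = fit._design_row(a, ws) - fit._design_row(b, ws)
            est = float(c @ fit.fe_params)
            se = float(np.sqrt(c @ fit.fe_cov @ c))
            tval = est / se
            p_un = float(2.0 * sps.t.sf(abs(tval), fit.df_resid))
            q = abs(tval) * np.sqrt(2.0)
            p_adj = float(np.clip(studentized_range.sf(q, k, fit.df_resid), 0.0, 1.0))
            p_adj = max(p_adj, p_un)
            out.append(ContrastResult(
                pair=(a, b), ws=ws, estimate=est, se=se,
                p_unadjusted=p_un, p_adjusted=p_adj,
                stars=significance_stars(p_adj),
            ))
    return out


# ---------------------------------------------------------------------------
# baseline-corrected correlation
# ---------------------------------------------------------------------------

def baseline_correct(table: pd.DataFrame, ws: int = 1,
                     value_col: str = "value") -> pd.DataFrame:
    """Per-subject condition averages minus the subject's baseline average.

    For the requested walking segment, each subject's repetitions are
    averaged per condition and the baseline average subtracted, yielding
    one corrected value per subject for each of supine, RED and LED.
    Subjects without baseline data at that segment are excluded (logged).
    """
    sub = table[table["walkingSegment"] == ws]
    means = (sub.groupby(["participant", "trial"], observed=True)[value_col]
             .mean().unstack("trial"))
    if "baseline" not in means.columns:
        raise ValueError("no baseline condition present")
    rows = []
    for pid, row in means.iterrows():
        if pd.isna(row.get("baseline")):
            logger.warning("participant %s lacks baseline at WS%d; excluded", pid, ws)
            continue
        for cond in ("supine", "RED", "LED"):
            if cond in row.index and not pd.isna(row[cond]):
                rows.append((pid, cond, float(row[cond] - row["baseline"])))
    return pd.DataFrame(rows, columns=["participant", "trial", "corrected"])


def correlate(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), int(x.size)
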