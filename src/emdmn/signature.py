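"""nCounter normalization, differential expression, the 9-gene
Emerin-pauperization score, and survival association.

The score of a sample is the mean of ``log2(count + 1)`` over the 9
signature genes (CXCR4, APOE, SPARC, VIM, GSN, ANXA2P2, SFRP1, COL18A1,
FN1); samples strictly above the cohort upper quartile of the score are
flagged "high". Group survival differences are summarised by the log-rank
test (implemented from its observed-minus-expected form and cross-checked
against ``lifelines``) and a univariate Cox proportional-hazards hazard
ratio with a 95% Wald confidence interval (fitted with ``lifelines``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter, KaplanMeierFitter

from .phantom import DEFAULT_SIGNATURE

__all__ = [
    "Signature",
    "SurvivalResult",
    "DEFAULT_HOUSEKEEPING",
    "ncounter_normalize",
    "differential_expression",
    "pauperization_score",
    "logrank_statistic",
    "survival_association",
]

#: The four most stably expressed housekeeping genes used for scaling.
DEFAULT_HOUSEKEEPING = ("CNOT4", "HDAC3", "DDX50", "CC2D1B")


@dataclass(frozen=True)
class Signature:
    """An expression signature; defaults to the 9-gene pauperization set."""

    genes: tuple[str, ...] = DEFAULT_SIGNATURE

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("signature genes must be unique")


@dataclass
class SurvivalResult:
    """Hazard ratio, CI, log-rank p and Kaplan-Meier curves for two groups."""

    hr: float
    ci95: tuple[float, float]
    logrank_p: float
    logrank_chi2: float
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def ncounter_normalize(
    raw: pd.DataFrame,
    neg_probes: list[str],
    pos_probes: list[str],
    hk_genes: list[str] | tuple[str, ...] = DEFAULT_HOUSEKEEPING,
) -> pd.DataFrame:
    """Background-correct and normalize an nCounter count table.

    Per sample, the background is the mean plus two standard deviations
    (ddof 0) of the negative-control probe counts, and endogenous counts
    below it are raised to it. Two multiplicative scalings follow, applied
    sequentially: each sample is scaled by (cohort mean of per-sample
    positive-control means) / (its own positive-control mean), then
    likewise with the housekeeping-gene means recomputed on the
    positive-control-scaled data. Control probe rows are dropped from the
    returned matrix (housekeeping genes are kept).

    ``raw`` is genes x samples; missing control rows raise ``KeyError``.
    """
    for name, probes in (("negative", neg_probes), ("positive", pos_probes),
                         ("housekeeping", hk_genes)):
        missing = [p for p in probes if p not in raw.index]
        if missing:
            raise KeyError(f"missing {name} control rows: {missing}")

    data = raw.astype(float).copy()
    neg = data.loc[list(neg_probes)]
    background = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=0)

    endog = data.drop(index=[p for p in (*neg_probes, *pos_probes)])
    endog = endog.clip(lower=background, axis=1)

    pos_means = data.loc[list(pos_probes)].mean(axis=0)
    pos_factor = pos_means.mean() / pos_means
    endog = endog.mul(pos_factor, axis=1)

    hk_means = endog.loc[list(hk_genes)].mean(axis=0)
    hk_factor = hk_means.mean() / hk_means
    return endog.mul(hk_factor, axis=1)


def differential_expression(
    matrix: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    epsilon: float = 0.5,
) -> pd.DataFrame:
    """Per-gene Mann-Whitney test and median-based log2 fold change.

    ``groups`` is boolean per sample (True = pauperized / case). The fold
    change is ``log2((median_case + eps) / (median_control + eps))`` with
    ``eps`` = 0.5 counts; the p-value is the two-sided Mann-Whitney U test
    (exact for small tie-free groups, normal approximation otherwise).
    Returns a DataFrame indexed by gene with columns ``log2fc`` and ``p``.
    """
    groups = np.asarray(groups, dtype=bool)
    if groups.shape[0] != matrix.shape[1]:
        raise ValueError("groups length must match the number of samples")
    n1, n0 = int(groups.sum()), int((~groups).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs at least two samples")
    case = matrix.loc[:, groups].to_numpy(dtype=float)
    ctrl = matrix.loc[:, ~groups].to_numpy(dtype=float)
    med1 = np.median(case, axis=1)
    med0 = np.median(ctrl, axis=1)
    log2fc = np.log2((med1 + epsilon) / (med0 + epsilon))
    res = stats.mannwhitneyu(case, ctrl, axis=1, alternative="two-sided",
                             method="auto")
    return pd.DataFrame({"log2fc": log2fc, "p": res.pvalue}, index=matrix.index)


def pauperization_score(
    matrix: pd.DataFrame,
    signature: Signature = Signature(),
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-sample pauperization score and upper-quartile flag.

    The score is the mean of ``log2(count + pseudocount)`` over the
    signature genes (``pseudocount`` 0 is allowed for strictly positive
    matrices). ``high_flag`` marks samples whose score strictly exceeds
    the cohort upper quartile (linear-interpolation quantile).

    Raises :class:`KeyError` naming any signature gene absent from the
    matrix.
    """
    missing = [g for g in signature.genes if g not in matrix.index]
    if missing:
        raise KeyError(f"signature genes missing from matrix: {missing}")
    sub = matrix.loc[list(signature.genes)].astype(float)
    if (sub.to_numpy() + pseudocount <= 0).any():
        raise ValueError("log2 undefined: counts + pseudocount must be positive")
    score = np.log2(sub + pseudocount).mean(axis=0)
    q3 = float(np.quantile(score.to_numpy(), 0.75))
    return pd.DataFrame({"score": score, "high_flag": score > q3})


def logrank_statistic(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank chi-square and p-value.

    Implements the standard (O - E)^2 / V form: at each distinct event
    time the observed events in group 1 are compared with the
    hypergeometric expectation given the risk sets, and the squared summed
    difference is referred to chi-square with 1 df.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & group).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def survival_association(
    survival: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    time_col: str = "time",
    event_col: str = "event",
) -> SurvivalResult:
    """Log-rank test, Cox hazard ratio and Kaplan-Meier curves, high vs low.

    ``groups`` is boolean per row of ``survival`` (True = high-score
    group); the hazard ratio is for high relative to low. When one group
    has no events the Cox model is not identified and the HR is reported
    missing (NaN) with a warning recorded on the result.
    """
    time = survival[time_col].to_numpy(dtype=float)
    event = survival[event_col].to_numpy(dtype=int)
    group = np.asarray(groups, dtype=bool)
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("events must be binary")

    chi2, p = logrank_statistic(time, event, group)

    km: dict[str, pd.DataFrame] = {}
    for name, sel in (("low", ~group), ("high", group)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel], label=name)
        km[name] = kmf.survival_function_

    warns: list[str] = []
    if event[group].sum() == 0 or event[~group].sum() == 0:
        warns.append("a group has zero events; hazard ratio not identified")
        return SurvivalResult(
            hr=float("nan"), ci95=(float("nan"), float("nan")),
            logrank_p=p, logrank_chi2=chi2, km_curves=km, warnings=warns,
        )

    df = pd.DataFrame({"time": time, "event": event, "high": group.astype(int)})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["high"]))
    lo, hi = cph.confidence_intervals_.loc["high"]
    return SurvivalResult(
        hr=hr,
        ci95=(float(np.exp(lo)), float(np.exp(hi))),
        logrank_p=p,
        logrank_chi2=chi2,
        km_curves=km,
        warnings=warns,
    )
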