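"""Inter-observer and inter-modality agreement statistics.

Implements the statistical battery used to validate the pipeline:

* ``icc_agreement`` — two-way random-effects, absolute-agreement,
  single-measure intraclass correlation (ICC(2,1)) with an F-based 95%
  confidence interval and a P value for ICC > 0.
* ``compare_dependent_r`` — Hotelling–Williams test for two dependent
  Pearson correlations sharing one variable (a plain Fisher z variant
  is exposed too, flagged as appropriate only for independent samples).
* ``cohen_kappa`` — unweighted (optionally linear-weighted) Cohen's
  kappa with large-sample standard errors for the CI and the P value
  against kappa = 0.
* ``interpret_kappa`` — the conventional agreement bands
  (<0.20 poor, 0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80 good,
  0.81–1.00 almost perfect).
* ``ancova_modality_observer`` — size ~ observer + modality +
  reference size, type-II F tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "icc_agreement",
    "compare_dependent_r",
    "fisher_z_independent",
    "cohen_kappa",
    "interpret_kappa",
    "ancova_modality_observer",
    "AgreementReport",
]

KAPPA_BANDS = (
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "good"),
    (1.00, "almost perfect"),
)


def icc_agreement(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> tuple[float, tuple[float, float], float]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Returns ``(icc, (ci_lo, ci_hi), p)`` where ``p`` tests ICC > 0 via
    F = MS_rows / MS_error.  Degenerate inputs (zero between-subject
    variance) return a defined non-positive ICC rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 paired measurements, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    k = 2
    data = np.column_stack([x, y])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return 0.0, (0.0, 0.0), 1.0
    icc = (msr - mse) / denom

    # perfect (or numerically perfect) agreement: the error mean square
    # vanishes up to float residue of the two-way decomposition
    if mse <= 1e-12 * max(msr, msc, 1e-300):
        p = 0.0 if msr > 0 else 1.0
        return float(icc), (float(icc), float(icc)), p

    # significance: F test of between-subject variance
    f_obs = msr / mse
    p = float(stats.f.sf(f_obs, n - 1, (n - 1) * (k - 1)))

    # McGraw & Wong (1996) confidence interval for ICC(A,1)
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    fj = msc / mse
    v = (a * fj + b) ** 2 / (
        (a * fj) ** 2 / (k - 1) + b**2 / ((n - 1) * (k - 1))
    )
    fl = stats.f.ppf(1 - alpha / 2, n - 1, v)
    fu = stats.f.ppf(1 - alpha / 2, v, n - 1)
    ci_lo = n * (msr - fl * mse) / (
        fl * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    ci_hi = n * (fu * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * fu * msr
    )
    ci_lo = float(min(ci_lo, icc))
    ci_hi = float(min(max(ci_hi, icc), 1.0))
    return float(icc), (ci_lo, ci_hi), p


def compare_dependent_r(
    r_ab: float, r_cb: float, r_ac: float, n: int
) -> tuple[float, float]:
    """Hotelling–Williams test for two overlapping dependent correlations.

    Compares corr(a, b) with corr(c, b) when both share variable ``b``
    and corr(a, c) is known, on the same sample of size ``n``.  Returns
    ``(t statistic, two-sided p)``; the statistic is positive when
    r_ab > r_cb.
    """
    for name, r in (("r_ab", r_ab), ("r_cb", r_cb), ("r_ac", r_ac)):
        if not np.isfinite(r) or abs(r) >= 1:
            raise ValueError(f"{name} must satisfy |r| < 1, got {r}")
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    det = 1 - r_ab**2 - r_cb**2 - r_ac**2 + 2 * r_ab * r_cb * r_ac
    rbar = 0.5 * (r_ab + r_cb)
    num = (r_ab - r_cb) * np.sqrt((n - 1) * (1 + r_ac))
    den = np.sqrt(
        2 * det * (n - 1) / (n - 3) + rbar**2 * (1 - r_ac) ** 3
    )
    if den == 0:
        raise ValueError("degenerate correlation matrix")
    t = float(num / den)
    p = float(2 * stats.t.sf(abs(t), n - 3))
    return t, p


def fisher_z_independent(r1: float, r2: float, n1: int, n2: int) -> tuple[float, float]:
    """Fisher z comparison of two correlations from *independent* samples.

    Exposed for completeness; inappropriate when the correlations share
    a variable measured on the same subjects (use
    :func:`compare_dependent_r` there).
    """
    for name, r in (("r1", r1), ("r2", r2)):
        if abs(r) >= 1:
            raise ValueError(f"{name} must satisfy |r| < 1, got {r}")
    if min(n1, n2) < 4:
        raise ValueError("need n >= 4 in both samples")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    z = float((z1 - z2) / se)
    return z, float(2 * stats.norm.sf(abs(z)))


def cohen_kappa(
    labels_a: Sequence,
    labels_b: Sequence,
    categories: Sequence | None = None,
    weighted: bool = False,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float], float]:
    """Cohen's kappa from the K x K contingency table.

    Returns ``(kappa, (ci_lo, ci_hi), p)``.  The CI uses the
    large-sample standard error of kappa-hat (Fleiss, Cohen & Everitt);
    the P value tests kappa > 0 with the null-hypothesis standard
    error.  ``weighted=True`` applies linear weights.

    If only one category occurs in both raters' labels, kappa is
    undefined: returns ``(nan, (nan, nan), nan)`` with a warning.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("label vectors must be non-empty")
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    if categories is None:
        categories = sorted(set(a.tolist()) | set(b.tolist()))
    categories = list(categories)
    K = len(categories)
    index = {c: i for i, c in enumerate(categories)}
    n = len(a)
    table = np.zeros((K, K), dtype=float)
    for ai, bi in zip(a, b):
        table[index[ai], index[bi]] += 1
    if K < 2 or len(set(a.tolist()) | set(b.tolist())) < 2:
        warnings.warn("kappa undefined: a single category present in both raters")
        return float("nan"), (float("nan"), float("nan")), float("nan")

    p = table / n
    p_row = p.sum(axis=1)
    p_col = p.sum(axis=0)
    if weighted:
        idx = np.arange(K)
        w = 1.0 - np.abs(idx[:, None] - idx[None, :]) / (K - 1)
    else:
        w = np.eye(K)
    po = float((w * p).sum())
    pe = float((w * (p_row[:, None] * p_col[None, :])).sum())
    if pe == 1.0:
        warnings.warn("kappa undefined: chance agreement is 1")
        return float("nan"), (float("nan"), float("nan")), float("nan")
    kappa = (po - pe) / (1 - pe)

    # large-sample SEs (generalised weighted form; reduces to the
    # unweighted Fleiss-Cohen-Everitt formulas for identity weights)
    w_row = (w * p_col[None, :]).sum(axis=1)  # expected weight by rater-A cat
    w_col = (w * p_row[:, None]).sum(axis=0)
    # SE of kappa-hat (for the CI)
    term = (w - (w_row[:, None] + w_col[None, :]) * (1 - kappa)) ** 2
    var_hat = ((p * term).sum() - (kappa - pe * (1 - kappa)) ** 2) / (
        n * (1 - pe) ** 2
    )
    se_hat = float(np.sqrt(max(var_hat, 0.0)))
    zc = stats.norm.ppf(1 - alpha / 2)
    ci = (float(kappa - zc * se_hat), float(min(kappa + zc * se_hat, 1.0)))
    # SE under H0: kappa = 0
    w0_row = (w * p_col[None, :]).sum(axis=1)
    w0_col = (w * p_row[:, None]).sum(axis=0)
    term0 = (w - (w0_row[:, None] + w0_col[None, :]) * 1.0) ** 2
    var0 = ((p_row[:, None] * p_col[None, :] * term0).sum() - pe**2) / (
        n * (1 - pe) ** 2
    )
    se0 = float(np.sqrt(max(var0, 1e-300)))
    z = kappa / se0
    pval = float(stats.norm.sf(z))  # one-sided: kappa > 0
    return float(kappa), ci, pval


def interpret_kappa(k: float) -> str:
    """Map a kappa value to its conventional agreement band."""
    if not np.isfinite(k) or k < -1 or k > 1:
        raise ValueError(f"kappa must be in [-1, 1], got {k}")
    if k <= 0.20:
        return "poor"
    for hi, label in KAPPA_BANDS[1:]:
        if k <= hi + 1e-12:
            return label
    return "almost perfect"


def ancova_modality_observer(
    table: pd.DataFrame,
    size_col: str = "solid_mm",
    observer_col: str = "observer",
    modality_col: str = "modality",
    covariate_col: str = "real_solid_mm",
) -> pd.DataFrame:
    """ANCOVA of measured size on observer + modality with the
    reference (thin-section) size as covariate.

    Expects a balanced long-format table with one row per
    (case, observer, modality).  Returns a DataFrame indexed by factor
    with columns ``F`` and ``p`` (type-II tests).

    Raises
    ------
    ValueError
        On missing columns or a rank-deficient design (e.g. a single
        observer or modality level).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in (size_col, observer_col, modality_col, covariate_col):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    df = table.rename(
        columns={
            size_col: "y",
            observer_col: "obs",
            modality_col: "mod",
            covariate_col: "ref",
        }
    )
    if df["obs"].nunique() < 2 or df["mod"].nunique() < 2:
        raise ValueError("need >= 2 observer and >= 2 modality levels")
    model = smf.ols("y ~ C(obs) + C(mod) + ref", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient ANCOVA design matrix")
    aov = sm.stats.anova_lm(model, typ=2)
    out = aov.loc[["C(obs)", "C(mod)", "ref"], ["F", "PR(>F)"]].rename(
        columns={"PR(>F)": "p"}, index={"C(obs)": "observer", "C(mod)": "modality"}
    )
    out.attrs["covariate_coef"] = float(model.params["ref"])
    return out


@dataclass
class AgreementReport:
    """Container for one full agreement battery (see module docstring)."""

    icc: float
    icc_ci: tuple[float, float]
    icc_p: float
    r_pairs: dict = field(default_factory=dict)
    r_compare: tuple[float, float] | None = None
    kappa: float | None = None
    kappa_ci: tuple[float, float] | None = None
    kappa_p: float | None = None
    kappa_band: str | None = None
    ancova: dict | None = None

    def __post_init__(self) -> None:
        if self.kappa is not None and np.isfinite(self.kappa):
            lo, hi = self.kappa_ci
            if not (lo <= self.kappa + 1e-9 and self.kappa - 1e-9 <= hi):
                raise ValueError("kappa CI must bracket the estimate")
            if self.kappa_band is None:
                self.kappa_band = interpret_kappa(max(-1.0, min(1.0, self.kappa)))

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "icc_ci": list(self.icc_ci),
            "icc_p": self.icc_p,
            "r_pairs": self.r_pairs,
            "r_compare": list(self.r_compare) if self.r_compare else None,
            "kappa": self.kappa,
            "kappa_ci": list(self.kappa_ci) if self.kappa_ci else None,
            "kappa_p": self.kappa_p,
            "kappa_band": self.kappa_band,
            "ancova": self.ancova,
        }
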