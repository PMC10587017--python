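"""Paired neutral-vs-extended statistics and cohort report tables.

Implements the study's statistical plan: paired t tests on the four
curve outcomes (kyphosis, coronal Cobb, peri-apical rotation, apical
rotation) with Bonferroni multiplicity control, percentage changes of the
position means, Pearson correlations between the plane-wise changes, and
t-distribution confidence intervals for the disc asymmetry metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedOutcome", "CorrelationResult", "percent_change", "paired_t",
    "pearson", "multiplicity", "build_report", "significance_power",
    "qq_plot",
]

#: The four primary curve outcomes, in report order.
PRIMARY_OUTCOMES = (
    ("kyphosis_deg", "Kyphosis"),
    ("cobb_deg", "Coronal Cobb"),
    ("periapical_rotation_deg", "Peri-apical rotation"),
    ("apical_rotation_deg", "Apical rotation"),
)


@dataclass(eq=False)
class PairedOutcome:
    """One outcome's paired comparison between the two positions."""

    name: str
    nsp: np.ndarray
    esp: np.ndarray
    nsp_mean: float
    nsp_sd: float
    esp_mean: float
    esp_sd: float
    delta_pct: float
    t: float
    p: float
    df: int
    significant: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between two change variables."""

    pair: tuple[str, str]
    r: float
    p: float


def percent_change(nsp_mean: float, esp_mean: float) -> float:
    """Percentage change of the extended mean relative to the neutral mean.

    ``100 * (esp - nsp) / nsp``; report tables round it to the nearest
    integer percent.

    Raises
    ------
    ValueError
        If the baseline (neutral) mean is zero.
    """
    if nsp_mean == 0:
        raise ValueError("percent change undefined for a zero baseline")
    return 100.0 * (esp_mean - nsp_mean) / nsp_mean


def paired_t(nsp, esp) -> tuple[float, float, int]:
    """Classical two-sided paired t test on the position differences.

    Returns ``(t, p, df)`` with ``df = n - 1``.

    Raises
    ------
    ValueError
        On unequal lengths, n < 2, or zero-variance differences (constant
        shift or identical vectors), for which t is undefined.
    """
    nsp = np.asarray(nsp, dtype=float)
    esp = np.asarray(esp, dtype=float)
    if nsp.shape != esp.shape or nsp.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    n = len(nsp)
    if n < 2:
        raise ValueError("paired t needs at least 2 pairs")
    diff = esp - nsp
    if np.std(diff, ddof=1) == 0:
        raise ValueError(
            "differences have zero variance — paired t is undefined"
        )
    res = stats.ttest_rel(esp, nsp)
    return float(res.statistic), float(res.pvalue), n - 1


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-transform p value.

    Raises
    ------
    ValueError
        If n < 3 or either variable has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("pearson needs two equal-length vectors, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson undefined for a zero-variance variable")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def multiplicity(
    p_values, alpha: float = 0.05, alt_threshold: float = 0.01
) -> tuple[list[bool], list[bool]]:
    """Bonferroni significance flags for a family of outcomes.

    Primary rule: ``p < alpha / k`` for k outcomes (k = 4 gives 0.0125).
    An alternative fixed-threshold rule (``p < alt_threshold``) is also
    returned so that both conventions can be printed side by side.
    """
    p_values = list(p_values)
    k = len(p_values)
    if k < 1:
        raise ValueError("need at least one p value")
    thr = alpha / k
    return ([p < thr for p in p_values],
            [p < alt_threshold for p in p_values])


def _ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """t-distribution confidence interval for a mean, df = n - 1."""
    n = len(values)
    m = float(np.mean(values))
    se = float(np.std(values, ddof=1)) / np.sqrt(n)
    h = stats.t.ppf(0.5 + level / 2, n - 1) * se
    return m - h, m + h


def build_report(cohort: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Assemble the cohort comparison tables from per-subject measurements.

    Parameters
    ----------
    cohort
        Tidy table with columns ``subject``, ``position`` (``NSP``/``ESP``)
        and the outcome columns ``kyphosis_deg``, ``cobb_deg``,
        ``periapical_rotation_deg``, ``apical_rotation_deg``; optionally
        ``ivd_asym_mm``, ``np_asym_mm``, ``cov_d_mm``, ``cov_d_apical_mm``
        for the disc tables.  Subjects missing either position are
        excluded with a warning.

    Returns
    -------
    dict with keys:
        ``angles`` — the four-outcome table (mean (SD) per position, Δ%,
        paired t, p, Bonferroni flag at alpha/4 and the alternative
        p < 0.01 flag);
        ``discs`` — asymmetry/CoV-distance table with SD and 95% CI;
        ``correlations`` — Pearson r between the plane-wise changes;
        ``outcomes`` — the raw :class:`PairedOutcome` objects;
        ``excluded`` — subjects dropped as incomplete.
    """
    required = {"subject", "position"}
    if not required <= set(cohort.columns):
        raise ValueError("cohort needs 'subject' and 'position' columns")
    counts = cohort.groupby("subject")["position"].nunique()
    complete = counts[counts == 2].index
    excluded = sorted(set(cohort["subject"]) - set(complete))
    if excluded:
        warnings.warn(f"excluding incomplete subject pairs: {excluded}",
                      stacklevel=2)
    df = cohort[cohort["subject"].isin(complete)]
    if df["subject"].nunique() < 2:
        raise ValueError("need at least 2 complete subject pairs")
    nsp = df[df.position == "NSP"].set_index("subject").sort_index()
    esp = df[df.position == "ESP"].set_index("subject").sort_index()

    outcomes: list[PairedOutcome] = []
    for col, label in PRIMARY_OUTCOMES:
        a, b = nsp[col].to_numpy(float), esp[col].to_numpy(float)
        t, p, dof = paired_t(a, b)
        outcomes.append(PairedOutcome(
            name=label, nsp=a, esp=b,
            nsp_mean=float(a.mean()), nsp_sd=float(a.std(ddof=1)),
            esp_mean=float(b.mean()), esp_sd=float(b.std(ddof=1)),
            delta_pct=percent_change(a.mean(), b.mean()),
            t=t, p=p, df=dof,
        ))
    sig, sig_alt = multiplicity([o.p for o in outcomes], alpha=alpha)
    for o, s in zip(outcomes, sig):
        o.significant = s
    angles = pd.DataFrame({
        "outcome": [o.name for o in outcomes],
        "NSP_mean": [round(o.nsp_mean) for o in outcomes],
        "NSP_sd": [round(o.nsp_sd, 1) for o in outcomes],
        "ESP_mean": [round(o.esp_mean) for o in outcomes],
        "ESP_sd": [round(o.esp_sd, 1) for o in outcomes],
        "delta_pct": [round(o.delta_pct) for o in outcomes],
        "t": [round(o.t, 2) for o in outcomes],
        "p": [o.p for o in outcomes],
        "significant_bonferroni": sig,
        "significant_p01": sig_alt,
    })

    disc_rows = []
    for col, label in (("ivd_asym_mm", "IVD EC-XC"),
                       ("np_asym_mm", "NP EC-XC"),
                       ("cov_d_mm", "CoV distance (all discs)"),
                       ("cov_d_apical_mm", "CoV distance (apex)")):
        if col not in df.columns:
            continue
        a, b = nsp[col].to_numpy(float), esp[col].to_numpy(float)
        try:
            _, p, _ = paired_t(a, b)
        except ValueError:
            p = np.nan
        for pos, v in (("NSP", a), ("ESP", b)):
            lci, uci = _ci(v)
            disc_rows.append({
                "metric": label, "position": pos,
                "mean": round(float(v.mean()), 1),
                "sd": round(float(v.std(ddof=1)), 1),
                "lci": round(lci, 1), "uci": round(uci, 1),
                "p": p,
            })
    discs = pd.DataFrame(disc_rows)

    # correlations between plane-wise changes (reductions, NSP − ESP)
    red = {col: nsp[col].to_numpy(float) - esp[col].to_numpy(float)
           for col, _ in PRIMARY_OUTCOMES}
    pairs = [
        ("kyphosis_deg", "apical_rotation_deg"),
        ("cobb_deg", "periapical_rotation_deg"),
        ("cobb_deg", "apical_rotation_deg"),
        ("kyphosis_deg", "cobb_deg"),
    ]
    corr_rows = []
    for xa, xb in pairs:
        try:
            r, p = pearson(red[xa], red[xb])
        except ValueError:
            r, p = np.nan, np.nan
        corr_rows.append({"x": f"{xa} reduction", "y": f"{xb} reduction",
                          "r": r, "p": p})
    return {
        "angles": angles,
        "discs": discs,
        "correlations": pd.DataFrame(corr_rows),
        "outcomes": outcomes,
        "excluded": excluded,
    }


def significance_power(
    delta_mean: float,
    delta_sd: float,
    n_subjects: int,
    alpha: float,
    n_replicates: int,
    rng: np.random.Generator | int,
) -> float:
    """Monte-Carlo power of the paired t test for a given change effect.

    Draws ``n_replicates`` cohorts of ``n_subjects`` paired differences
    from N(delta_mean, delta_sd²) and returns the fraction whose
    two-sided one-sample t test (equivalent to the paired t on the
    original pairs) falls below ``alpha``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    hits = 0
    for _ in range(n_replicates):
        d = rng.normal(delta_mean, delta_sd, n_subjects)
        p = stats.ttest_1samp(d, 0.0).pvalue
        hits += p < alpha
    return hits / n_replicates


def qq_plot(values, path) -> None:
    """Export a normal Q–Q plot of a sample (normality is inspected, not
    gated on)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    stats.probplot(np.asarray(values, dtype=float), dist="norm", plot=ax)
    ax.set_title("Normal Q-Q plot")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
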