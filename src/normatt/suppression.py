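"""Suppression indices and the statistical reporting chain.

Two suppression indices (SI) quantify how much an annular surround weakens
the response to the central stimulus:

* behavioral, from duration thresholds: ``SI = (T_cs - T_c) / T_c``
* fMRI, from GLM beta weights:          ``SI = B_c - B_cs``

Positive SI means suppression, negative means facilitation.  The reporting
chain on participant-level SI tables is: one-sample t tests of each design
cell against zero (Bonferroni-corrected alpha 0.05/4), a 2x2 repeated-
measures ANOVA with factors attention (narrow/wide) and surround direction
(same/opposite), and post hoc paired t tests (corrected alpha 0.05/2).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .nma import ConfigurationError

__all__ = [
    "TTestResult",
    "AnovaEffect",
    "StatsReport",
    "si_behavioral",
    "si_fmri",
    "si_table_from_thresholds",
    "si_table_from_betas",
    "one_sample_t_vs_zero",
    "paired_t",
    "rm_anova_2x2",
    "stats_report",
]

#: Bonferroni-corrected alphas as used in the reporting chain
ALPHA_ONE_SAMPLE = 0.05 / 4
ALPHA_POSTHOC = 0.05 / 2

_CELLS = [("narrow", "same"), ("narrow", "opposite"),
          ("wide", "same"), ("wide", "opposite")]

_CONDITION_CELL = {
    "narrow_same": ("narrow", "same"),
    "narrow_opp": ("narrow", "opposite"),
    "wide_same": ("wide", "same"),
    "wide_opp": ("wide", "opposite"),
}


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    alpha: float
    significant: bool
    degenerate: bool = False  # zero-variance input


@dataclass(frozen=True)
class AnovaEffect:
    effect: str
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class StatsReport:
    one_sample: dict[str, TTestResult]
    anova: dict[str, AnovaEffect]
    posthoc: dict[str, TTestResult]

    def to_dict(self) -> dict:
        return {
            "one_sample": {k: asdict(v) for k, v in self.one_sample.items()},
            "anova": {k: asdict(v) for k, v in self.anova.items()},
            "posthoc": {k: asdict(v) for k, v in self.posthoc.items()},
        }


# ---------------------------------------------------------------------------
# Suppression indices


def si_behavioral(t_c, t_cs):
    """Behavioral suppression index (T_cs - T_c) / T_c from duration thresholds."""
    t_c = np.asarray(t_c, dtype=float)
    t_cs = np.asarray(t_cs, dtype=float)
    if np.any(t_c <= 0) or np.any(t_cs <= 0) or not (np.all(np.isfinite(t_c)) and np.all(np.isfinite(t_cs))):
        raise ConfigurationError("thresholds must be positive and finite")
    out = (t_cs - t_c) / t_c
    return out if out.shape else float(out)


def si_fmri(b_c, b_cs):
    """fMRI suppression index B_c - B_cs from beta weights."""
    b_c = np.asarray(b_c, dtype=float)
    b_cs = np.asarray(b_cs, dtype=float)
    if not (np.all(np.isfinite(b_c)) and np.all(np.isfinite(b_cs))):
        raise ConfigurationError("beta weights must be finite")
    out = b_c - b_cs
    return out if out.shape else float(out)


def _si_table(df: pd.DataFrame, value_col: str, si_func, modality: str) -> pd.DataFrame:
    rows = []
    for pid, sub in df.groupby("participant"):
        vals = sub.set_index("condition")[value_col]
        if "center_only" not in vals.index:
            raise ConfigurationError(f"participant {pid} lacks a center_only entry")
        base = vals["center_only"]
        for cond, (attn, direction) in _CONDITION_CELL.items():
            if cond not in vals.index:
                raise ConfigurationError(f"participant {pid} lacks condition {cond}")
            rows.append((pid, attn, direction, float(si_func(base, vals[cond])), modality))
    return pd.DataFrame(rows, columns=["participant", "attention", "direction", "si", "modality"])


def si_table_from_thresholds(threshold_table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant behavioral SIs from a ``participant, condition,
    threshold_ms`` table, using each participant's single center-only
    threshold as the shared baseline."""
    return _si_table(threshold_table, "threshold_ms", si_behavioral, "behavioral")


def si_table_from_betas(beta_table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant fMRI SIs from a ``participant, condition, beta`` table."""
    return _si_table(beta_table, "beta", si_fmri, "fmri")


# ---------------------------------------------------------------------------
# Tests


def one_sample_t_vs_zero(values, alpha_corrected: float = ALPHA_ONE_SAMPLE) -> TTestResult:
    """Two-tailed one-sample t test of the mean against zero.

    Zero-variance samples return a flagged degenerate result instead of
    raising (t = 0, p = 1 when the values are identically zero; t = +/-inf,
    p = 0 otherwise), so permutation loops never abort.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ConfigurationError("need at least two observations")
    if not np.all(np.isfinite(x)):
        raise ConfigurationError("values must be finite")
    df = x.size - 1
    if np.ptp(x) == 0.0:
        if x[0] == 0.0:
            return TTestResult(0.0, df, 1.0, alpha_corrected, False, degenerate=True)
        t = np.inf if x[0] > 0 else -np.inf
        return TTestResult(float(t), df, 0.0, alpha_corrected, True, degenerate=True)
    res = stats.ttest_1samp(x, 0.0)
    return TTestResult(float(res.statistic), df, float(res.pvalue), alpha_corrected,
                       bool(res.pvalue < alpha_corrected))


def paired_t(values_a, values_b, alpha_corrected: float = ALPHA_POSTHOC) -> TTestResult:
    """Two-tailed paired t test; identical to the one-sample test applied to
    the pairwise differences."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("paired samples must have equal length")
    return one_sample_t_vs_zero(a - b, alpha_corrected)


def _cell_matrix(si_table: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Pivot an SI table into an (n_participants, 2, 2) array indexed
    [participant, attention(narrow, wide), direction(same, opposite)]."""
    pivot = si_table.pivot_table(index="participant", columns=["attention", "direction"],
                                 values="si")
    for cell in _CELLS:
        if cell not in pivot.columns:
            raise ConfigurationError(f"missing design cell {cell}")
    if pivot.isna().any().any():
        raise ConfigurationError("incomplete within-participant design")
    n = pivot.shape[0]
    if n < 2:
        raise ConfigurationError("need at least two participants")
    Y = np.empty((n, 2, 2))
    for i, attn in enumerate(("narrow", "wide")):
        for j, direction in enumerate(("same", "opposite")):
            Y[:, i, j] = pivot[(attn, direction)].to_numpy()
    return Y, list(pivot.index)


def rm_anova_2x2(si_table: pd.DataFrame) -> dict[str, AnovaEffect]:
    """2x2 repeated-measures ANOVA (attention x direction), within-subject
    sum-of-squares decomposition.

    Each effect is tested against its own effect-by-subject interaction with
    (1, n - 1) degrees of freedom; effect size is partial eta squared,
    SS_effect / (SS_effect + SS_error).
    """
    Y, _ = _cell_matrix(si_table)
    n = Y.shape[0]
    grand = Y.mean()
    subj = Y.mean(axis=(1, 2))          # (n,)
    a_means = Y.mean(axis=(0, 2))       # attention levels
    b_means = Y.mean(axis=(0, 1))       # direction levels
    sa = Y.mean(axis=2)                 # (n, 2) subject x attention
    sb = Y.mean(axis=1)                 # (n, 2) subject x direction
    cell = Y.mean(axis=0)               # (2, 2)

    ss_a = 2 * n * np.sum((a_means - grand) ** 2)
    ss_b = 2 * n * np.sum((b_means - grand) ** 2)
    ss_as = 2 * np.sum((sa - subj[:, None] - a_means[None, :] + grand) ** 2)
    ss_bs = 2 * np.sum((sb - subj[:, None] - b_means[None, :] + grand) ** 2)
    inter = cell - a_means[:, None] - b_means[None, :] + grand
    ss_ab = n * np.sum(inter ** 2)
    resid = (Y - cell[None] - sa[:, :, None] - sb[:, None, :]
             + subj[:, None, None] + a_means[None, :, None] + b_means[None, None, :]
             - grand)
    ss_abs = np.sum(resid ** 2)

    df_err = n - 1
    out = {}
    for name, ss_eff, ss_err in (("attention", ss_a, ss_as),
                                 ("direction", ss_b, ss_bs),
                                 ("interaction", ss_ab, ss_abs)):
        ms_err = ss_err / df_err
        F = np.inf if ms_err == 0 and ss_eff > 0 else (0.0 if ms_err == 0 else ss_eff / ms_err)
        p = 0.0 if np.isinf(F) else float(stats.f.sf(F, 1, df_err))
        np2 = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        out[name] = AnovaEffect(name, float(F), 1, df_err, p, float(np2))
    return out


def stats_report(si_table: pd.DataFrame) -> StatsReport:
    """Full reporting chain on one modality's SI table: per-cell one-sample
    t tests vs 0, the 2x2 RM ANOVA, and the two post hoc paired t tests
    (wide vs narrow, separately for same- and opposite-direction trials)."""
    Y, _ = _cell_matrix(si_table)
    one_sample = {}
    for i, attn in enumerate(("narrow", "wide")):
        for j, direction in enumerate(("same", "opposite")):
            one_sample[f"{attn}_{direction}"] = one_sample_t_vs_zero(Y[:, i, j])
    anova = rm_anova_2x2(si_table)
    posthoc = {
        "wide_vs_narrow_same": paired_t(Y[:, 1, 0], Y[:, 0, 0]),
        "wide_vs_narrow_opposite": paired_t(Y[:, 1, 1], Y[:, 0, 1]),
    }
    return StatsReport(one_sample=one_sample, anova=anova, posthoc=posthoc)
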