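"""Cohort-level statistics over per-subject ROI results.

Reproduces the study-style analysis: paired pre/post comparison per
tissue and field strength (two-level repeated-measures one-way ANOVA,
which for two timepoints is exactly the squared paired t-test), Welch
tests between field strengths, the BMI vs myocardial delta-R2*
correlation, and a normal-values summary table (mean +/- SD per cell).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

F_CAP = 1e12  # reported when within-subject variance is exactly zero

ALPHA = 0.05  # two-sided significance level


@dataclass(frozen=True)
class CohortRecord:
    """One subject x tissue observation: paired R2* with covariates."""

    subject_id: str
    field_strength: float
    tissue: str
    r2star_pre: float
    r2star_post: float
    bmi: float

    @property
    def delta(self) -> float:
        return self.r2star_post - self.r2star_pre


def records_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"subject_id": r.subject_id, "field_strength": r.field_strength,
         "tissue": r.tissue, "r2star_pre": r.r2star_pre,
         "r2star_post": r.r2star_post, "delta": r.delta, "bmi": r.bmi}
        for r in records
    ])


@dataclass(frozen=True)
class PrePostResult:
    f_statistic: float
    p_value: float
    n: int
    capped: bool  # True when within-subject variance was exactly zero

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def prepost_test(records: Sequence[CohortRecord]) -> PrePostResult:
    """Two-level repeated-measures one-way ANOVA of pre vs post R2*.

    Computed from its sums of squares: the condition effect has 1 degree
    of freedom and the subject-by-condition interaction n-1, so
    F(1, n-1) = t^2 of the paired t-test.  Zero within-subject variance
    with a nonzero effect yields a capped F with ``capped=True``.
    """
    _require_single_cell(records)
    if len({r.subject_id for r in records}) != len(records):
        dupes = sorted({r.subject_id for r in records if
                        sum(q.subject_id == r.subject_id for q in records) > 1})
        raise ValueError(f"duplicate/unpaired subjects: {dupes}")
    n = len(records)
    if n < 3:
        raise ValueError("need >= 3 paired records")
    pre = np.array([r.r2star_pre for r in records])
    post = np.array([r.r2star_post for r in records])
    if np.any(~np.isfinite(pre)) or np.any(~np.isfinite(post)):
        bad = [r.subject_id for r in records
               if not (np.isfinite(r.r2star_pre) and np.isfinite(r.r2star_post))]
        raise ValueError(f"missing values for subjects: {bad}")

    data = np.stack([pre, post], axis=1)          # subjects x conditions
    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)                  # df = 1
    ss_err = np.sum((data - subj_means[:, None] - cond_means[None, :] + grand) ** 2)
    df_err = n - 1
    if ss_err == 0.0:
        if ss_cond == 0.0:
            return PrePostResult(0.0, 1.0, n, False)
        return PrePostResult(F_CAP, 0.0, n, True)
    f = float(ss_cond / (ss_err / df_err))
    p = float(stats.f.sf(f, 1, df_err))
    return PrePostResult(f, p, n, False)


def _require_single_cell(records: Sequence[CohortRecord]) -> None:
    tissues = {r.tissue for r in records}
    fields = {r.field_strength for r in records}
    if len(tissues) != 1 or len(fields) != 1:
        raise ValueError("records must come from a single tissue and field strength")


def field_compare(records_a: Sequence[CohortRecord],
                  records_b: Sequence[CohortRecord],
                  quantity: str = "delta") -> tuple[float, float]:
    """Welch two-sample test of a quantity between two field groups.

    ``quantity`` is one of pre | post | delta.  Returns (t, two-sided p).
    """
    getter = {"pre": lambda r: r.r2star_pre, "post": lambda r: r.r2star_post,
              "delta": lambda r: r.delta}.get(quantity)
    if getter is None:
        raise ValueError("quantity must be pre, post or delta")
    a = np.array([getter(r) for r in records_a])
    b = np.array([getter(r) for r in records_b])
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.array_equal(a, b):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bmi_correlation(records: Sequence[CohortRecord]) -> tuple[float, float]:
    """Pearson correlation of BMI with delta-R2* (two-sided p)."""
    if len(records) < 3:
        raise ValueError("need >= 3 records with BMI")
    bmi = np.array([r.bmi for r in records])
    delta = np.array([r.delta for r in records])
    if np.std(bmi) == 0 or np.std(delta) == 0:
        raise ValueError("zero variance in BMI or delta-R2*")
    res = stats.pearsonr(bmi, delta)
    return float(res.statistic), float(res.pvalue)


def summarize(records: Sequence[CohortRecord], holm: bool = False) -> pd.DataFrame:
    """Normal-values summary: per (field, tissue) mean +/- SD and paired p.

    SDs use the n-1 denominator and are reported as NaN for single-subject
    cells; the paired p-value needs n >= 3.  ``holm`` optionally applies a
    Holm step-down correction across tissues within each field (off by
    default; raw per-tissue p-values are the reporting convention here).
    """
    df = records_frame(records)
    rows = []
    for (fs, tissue), g in df.groupby(["field_strength", "tissue"], sort=True):
        g = g.sort_values("subject_id", kind="stable")  # order invariance
        n = len(g)
        # a subject's ROI value can be missing (e.g. every pixel gated out
        # in a very short-T2* tissue); means skip NaN, the paired test uses
        # complete pairs only
        complete = g[g.r2star_pre.notna() & g.r2star_post.notna()]
        sd = (lambda s: float(s.std(ddof=1)) if s.notna().sum() >= 2 else np.nan)
        cell = {
            "field_strength": fs, "tissue": tissue, "n": n,
            "n_complete": len(complete),
            "pre_mean": float(g.r2star_pre.mean()), "pre_sd": sd(g.r2star_pre),
            "post_mean": float(g.r2star_post.mean()), "post_sd": sd(g.r2star_post),
            "change_mean": float(complete.delta.mean()), "change_sd": sd(complete.delta),
        }
        if len(complete) >= 3:
            recs = [CohortRecord(r.subject_id, fs, tissue, r.r2star_pre,
                                 r.r2star_post, r.bmi) for r in complete.itertuples()]
            cell["p_value"] = prepost_test(recs).p_value
        else:
            cell["p_value"] = np.nan
        rows.append(cell)
    out = pd.DataFrame(rows)
    if holm and out.p_value.notna().any():
        for fs, g in out.groupby("field_strength"):
            mask = g.p_value.notna()
            idx = g.index[mask]
            p = g.p_value[mask].to_numpy()
            order = np.argsort(p)
            m = len(p)
            adj = np.empty(m)
            running = 0.0
            for rank, j in enumerate(order):
                running = max(running, (m - rank) * p[j])
                adj[j] = min(1.0, running)
            out.loc[idx, "p_value_holm"] = adj
    return out
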