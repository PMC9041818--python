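"""Measurement precision and longitudinal change statistics.

Repeated re-scans of the same subjects give, per parameter, the intraclass
correlation coefficient (ICC), the root-mean-square percent coefficient of
variation (RMS%CV, the precision error of densitometry practice) and its
absolute counterpart RMS_SD.  The least significant change is 2.77 times
the precision error on either scale (LSC%CV = 2.77·RMS%CV, LSCSD =
2.77·RMS_SD); a longitudinal difference is only called real when it exceeds
the LSC, which yields the progression / repair / no-change taxonomy for
size parameters and increasing / decreasing / no-change for Er.BMD.

The default ICC model is the one-way random-effects single-rater ICC(1,1):
the repeats are repositioned re-scans read by a single reader, so there is
no rater factor to cross.  A two-way random-effects model (ICC(2,1),
absolute agreement) is available behind the ``model`` switch.  2.77 is used
as the literal conventional constant (1.96·√2 rounded as printed in the
densitometry literature), not recomputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LSC_MULTIPLIER",
    "PrecisionError",
    "load_repeated_measures",
    "icc",
    "icc_oneway",
    "rms_cv",
    "rms_cv_sd_only",
    "lsc",
    "precision_report",
    "classify_changes",
    "cumulative_probability",
    "paired_test",
    "SIZE_PARAMETERS",
    "BMD_PARAMETER",
]

LSC_MULTIPLIER = 2.77

SIZE_PARAMETERS = ("Er_V", "Er_D", "Er_D2", "Er_W", "Er_L")
BMD_PARAMETER = "Er_BMD"


class PrecisionError(ValueError):
    pass


def load_repeated_measures(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format repeated-measures table with columns
    subject, repeat, parameter, value; every subject must have the same
    number of repeats (k >= 2) per parameter."""
    required = {"subject", "repeat", "parameter", "value"}
    missing = required - set(df.columns)
    if missing:
        raise PrecisionError(f"repeated-measures table missing columns {missing}")
    if not np.isfinite(df["value"]).all():
        raise PrecisionError("values must be finite")
    counts = df.groupby(["parameter", "subject"])["repeat"].count()
    if counts.min() < 2:
        raise PrecisionError("every subject needs k >= 2 repeats")
    for param, c in counts.groupby(level=0):
        if c.nunique() != 1:
            raise PrecisionError(f"unbalanced repeats for parameter {param!r}")
    return df


def _wide(df: pd.DataFrame, parameter: str) -> np.ndarray:
    sub = df[df["parameter"] == parameter]
    if sub.empty:
        raise PrecisionError(f"no rows for parameter {parameter!r}")
    wide = sub.pivot(index="subject", columns="repeat", values="value")
    if wide.isna().any().any():
        raise PrecisionError(f"unbalanced table for parameter {parameter!r}")
    return wide.to_numpy(dtype=float)


def icc_oneway(rm: pd.DataFrame, parameter: str) -> float:
    """ICC(1,1) from the one-way ANOVA decomposition:
    (BMS − WMS) / (BMS + (k−1)·WMS).

    Negative estimates are returned raw, not clamped; callers may clamp for
    reporting.
    """
    x = _wide(rm, parameter)
    n, k = x.shape
    grand = x.mean()
    bss = k * ((x.mean(axis=1) - grand) ** 2).sum()
    wss = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum()
    if bss + wss == 0:
        raise PrecisionError("degenerate table: zero total variance")
    bms = bss / (n - 1)
    wms = wss / (n * (k - 1))
    return float((bms - wms) / (bms + (k - 1) * wms))


def icc(rm: pd.DataFrame, parameter: str, model: str = "oneway") -> float:
    """ICC under the configured model: ``oneway`` = ICC(1,1) (default),
    ``twoway`` = ICC(2,1), two-way random effects, absolute agreement."""
    if model == "oneway":
        return icc_oneway(rm, parameter)
    if model != "twoway":
        raise PrecisionError(f"unknown ICC model {model!r}")
    x = _wide(rm, parameter)
    n, k = x.shape
    grand = x.mean()
    bms = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    jms = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    ess = ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True)
            + grand) ** 2).sum()
    ems = ess / ((n - 1) * (k - 1))
    denom = bms + (k - 1) * ems + k * (jms - ems) / n
    if denom == 0:
        raise PrecisionError("degenerate table: zero total variance")
    return float((bms - ems) / denom)


def rms_cv(rm: pd.DataFrame, parameter: str) -> tuple[float, float]:
    """(RMS%CV, RMS_SD): root-mean-square over subjects of the per-subject
    percent CV (SD over repeats / mean, k−1 denominator) and of the
    per-subject SD."""
    x = _wide(rm, parameter)
    sd = x.std(axis=1, ddof=1)
    rms_sd = float(np.sqrt((sd ** 2).mean()))
    means = x.mean(axis=1)
    if (means <= 0).any():
        raise PrecisionError(
            "non-positive subject mean: %CV undefined (RMS_SD is still "
            "computable via rms_cv_sd_only)")
    cv = 100.0 * sd / means
    return float(np.sqrt((cv ** 2).mean())), rms_sd


def rms_cv_sd_only(rm: pd.DataFrame, parameter: str) -> float:
    x = _wide(rm, parameter)
    sd = x.std(axis=1, ddof=1)
    return float(np.sqrt((sd ** 2).mean()))


def lsc(precision_error: float) -> float:
    """Least significant change: 2.77 × the precision error (either scale)."""
    if precision_error < 0:
        raise PrecisionError("precision error must be >= 0")
    return LSC_MULTIPLIER * precision_error


def precision_report(rm: pd.DataFrame, parameters=None,
                     model: str = "oneway") -> pd.DataFrame:
    """Per-parameter ICC, RMS%CV, RMS_SD, LSC%CV and LSCSD."""
    rm = load_repeated_measures(rm)
    if parameters is None:
        parameters = sorted(rm["parameter"].unique())
    rows = []
    for p in parameters:
        cv, rms_sd = rms_cv(rm, p)
        x = _wide(rm, p)
        rows.append({
            "parameter": p, "n": x.shape[0], "k": x.shape[1],
            "ICC": icc(rm, p, model=model),
            "RMS_pct_CV": cv, "RMS_SD": rms_sd,
            "LSC_pct_CV": lsc(cv), "LSC_SD": lsc(rms_sd),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# longitudinal change


def _cutoffs(report: pd.DataFrame) -> dict:
    return dict(zip(report["parameter"], report["LSC_SD"]))


def classify_changes(baseline: pd.DataFrame, followup: pd.DataFrame,
                     report: pd.DataFrame,
                     parameters=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-erosion change calls against the LSCSD cutoffs.

    ``baseline``/``followup`` are frames with an ``id`` column and one
    column per parameter.  Erosions are matched by id; an id absent at
    baseline is a new erosion (size-parameter baseline 0), absent at
    follow-up a complete repair (follow-up 0).  Er.BMD is evaluated only for
    erosions identified at baseline and still measurable at follow-up.
    A difference is a change only when it exceeds the cutoff (|diff| equal
    to the LSCSD is still no_change).

    Returns ``(calls, percentages)``; per parameter the percentages sum
    to 100.
    """
    cut = _cutoffs(report)
    if parameters is None:
        parameters = [p for p in list(SIZE_PARAMETERS) + [BMD_PARAMETER]
                      if p in cut and p in baseline.columns]
    base = baseline.set_index("id")
    fup = followup.set_index("id")
    ids = sorted(set(base.index) | set(fup.index))
    rows = []
    for param in parameters:
        if param not in cut:
            raise PrecisionError(f"no LSCSD cutoff for parameter {param!r}")
        cutoff = float(cut[param])
        for eid in ids:
            in_base, in_fup = eid in base.index, eid in fup.index
            if param == BMD_PARAMETER:
                if not (in_base and in_fup):
                    continue  # BMD only for erosions present at both points
                b, f = float(base.at[eid, param]), float(fup.at[eid, param])
            else:
                b = float(base.at[eid, param]) if in_base else 0.0
                f = float(fup.at[eid, param]) if in_fup else 0.0
            diff = f - b
            if abs(diff) <= cutoff:
                call = "no_change"
            elif param == BMD_PARAMETER:
                call = "increasing" if diff > 0 else "decreasing"
            else:
                call = "progression" if diff > 0 else "repair"
            rows.append({"id": eid, "parameter": param, "baseline": b,
                         "followup": f, "diff": diff, "cutoff": cutoff,
                         "call": call})
    calls = pd.DataFrame(rows)
    pct = (calls.groupby("parameter")["call"]
           .value_counts(normalize=True).mul(100.0)
           .rename("percent").reset_index())
    return calls, pct


def cumulative_probability(diffs, lscsd: float) -> pd.DataFrame:
    """Plot-ready cumulative-probability table: sorted differences with
    probability (i − 0.5)/n and the ±LSCSD cutoff attached."""
    d = np.sort(np.asarray(diffs, dtype=float))
    if not np.isfinite(d).all():
        raise PrecisionError("differences must be finite")
    n = len(d)
    prob = (np.arange(1, n + 1) - 0.5) / n
    out = pd.DataFrame({"diff": d, "cum_prob": prob})
    out["lscsd_pos"] = lscsd
    out["lscsd_neg"] = -lscsd
    out["exceeds_lsc"] = np.abs(d) > lscsd
    return out


def paired_test(baseline, followup) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Exact null distribution for small samples without ties (scipy's
    default policy); zero differences are dropped (Wilcoxon's original
    treatment).  All-zero differences give p = 1 by convention, with a
    warning.
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if b.shape != f.shape:
        raise PrecisionError("baseline and follow-up must pair one-to-one")
    if np.all(b == f):
        warnings.warn("all paired differences are zero; p = 1 by convention",
                      stacklevel=2)
        return 0.0, 1.0
    res = stats.wilcoxon(f, b, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
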