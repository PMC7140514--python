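"""Group statistics as used in the figures: Student's t for single
comparisons, Dunnett's many-to-one and Tukey's all-pairs tests for multiple
comparison, plus mean +/- SD/SEM summary tables with optional normalisation
to a reference group's mean.

The post-hoc adjustments are delegated to scipy (multivariate-t reference
distribution for Dunnett, studentized range for Tukey); this module owns the
tidy contrast interface, significance stars and the summary conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidParameterError, MissingReferenceError


@dataclass
class ComparisonResult:
    """One group contrast: statistic, raw and family-adjusted p, stars."""

    contrast: str
    statistic: float
    p_raw: float
    p_adjusted: float
    method: str

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adjusted)

    def to_dict(self) -> dict:
        return {"contrast": self.contrast, "statistic": self.statistic,
                "p_raw": self.p_raw, "p_adjusted": self.p_adjusted,
                "method": self.method, "stars": self.stars}


def significance_stars(p: float) -> str:
    """Figure-legend stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if math.isnan(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else "ns"


def _group_arrays(data: pd.DataFrame) -> dict[str, np.ndarray]:
    missing = {"group", "value"} - set(data.columns)
    if missing:
        raise InvalidParameterError(f"data lacks columns: {sorted(missing)}")
    return {str(g): sub["value"].to_numpy(dtype=float)
            for g, sub in data.groupby("group", sort=False)}


def t_test(data: pd.DataFrame, equal_var: bool = True) -> ComparisonResult:
    """Two-sided Student's t-test (equal variance by default) on 2 groups."""
    groups = _group_arrays(data)
    if len(groups) != 2:
        raise InvalidParameterError("t_test requires exactly 2 groups")
    (ga, a), (gb, b) = groups.items()
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    p = float(res.pvalue)
    return ComparisonResult(f"{ga} vs {gb}", float(res.statistic), p, p,
                            "student_t" if equal_var else "welch_t")


def dunnett_test(data: pd.DataFrame, control: str,
                 seed: int | None = 0) -> list[ComparisonResult]:
    """Dunnett many-to-one comparisons against the designated control.

    The family-wise adjustment uses the multivariate-t reference
    distribution; ``seed`` fixes the quasi-random integration so results
    are reproducible.
    """
    groups = _group_arrays(data)
    if str(control) not in groups:
        raise MissingReferenceError(f"control group {control!r} not in data")
    ctrl = groups.pop(str(control))
    if not groups:
        raise InvalidParameterError("need at least one non-control group")
    names = list(groups)
    rng = np.random.default_rng(seed) if seed is not None else None
    res = sps.dunnett(*[groups[g] for g in names], control=ctrl, rng=rng)
    # raw per-contrast p from the pooled-variance t statistic
    n_all = [len(ctrl)] + [len(groups[g]) for g in names]
    df_pool = sum(n_all) - len(n_all)
    out = []
    for i, g in enumerate(names):
        p_raw = 2 * sps.t.sf(abs(res.statistic[i]), df_pool)
        out.append(ComparisonResult(
            f"{g} vs {control}", float(res.statistic[i]), float(p_raw),
            float(res.pvalue[i]), "dunnett"))
    return out


def tukey_hsd(data: pd.DataFrame) -> list[ComparisonResult]:
    """Tukey all-pairs comparisons with studentized-range adjustment."""
    groups = _group_arrays(data)
    if len(groups) < 3:
        raise InvalidParameterError(
            "tukey_hsd requires >= 3 groups; use t_test for 2")
    names = list(groups)
    res = sps.tukey_hsd(*[groups[g] for g in names])
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(res.pvalue[i, j])
            out.append(ComparisonResult(
                f"{names[i]} vs {names[j]}", float(res.statistic[i, j]),
                p, p, "tukey"))
    return out


def compare_groups(data: pd.DataFrame, method: str = "auto",
                   control: str | None = None,
                   seed: int | None = 0) -> list[ComparisonResult]:
    """Dispatch to the figure-appropriate test: t for two groups,
    Dunnett when a control is designated, Tukey for all-pairs."""
    n_groups = data["group"].nunique()
    if method == "auto":
        method = "t" if n_groups == 2 else ("dunnett" if control else "tukey")
    if method == "t":
        return [t_test(data)]
    if method == "dunnett":
        if control is None:
            raise MissingReferenceError("dunnett requires a control group")
        return dunnett_test(data, control, seed=seed)
    if method == "tukey":
        return tukey_hsd(data)
    raise InvalidParameterError(f"unknown method {method!r}")


def summarize_groups(data: pd.DataFrame, dispersion: str = "SD",
                     reference: str | None = None) -> pd.DataFrame:
    """Per-group mean, SD or SEM, and n; optionally normalise all group
    values to the reference group's mean (reference maps to 1.0)."""
    if dispersion not in ("SD", "SEM"):
        raise InvalidParameterError("dispersion must be 'SD' or 'SEM'")
    groups = _group_arrays(data)
    if reference is not None:
        if str(reference) not in groups:
            raise MissingReferenceError(f"reference group {reference!r} not in data")
        ref_mean = groups[str(reference)].mean()
        if ref_mean == 0:
            raise InvalidParameterError("reference mean is zero")
        groups = {g: v / ref_mean for g, v in groups.items()}
    rows = []
    for g, v in groups.items():
        n = len(v)
        sd = float(np.std(v, ddof=1)) if n >= 2 else math.nan
        disp = sd if dispersion == "SD" else sd / math.sqrt(n)
        rows.append((g, float(np.mean(v)), disp, n))
    return pd.DataFrame(rows, columns=["group", "mean", dispersion.lower(), "n"])
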