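"""Sex-difference testing across the four BLCS models.

For each fitted model (one per MRI metric) the four parameters of interest
— the baseline covariance ``phi``, the two coupling regressions ``gamma1``
and ``gamma2`` and the correlated-change covariance ``rho`` — are tested
for a sex difference by a chi-square difference test: the multigroup model
is refitted with the parameter constrained equal across the sexes and the
likelihood-ratio statistic of constrained versus free model is referred to
a chi-square distribution with the difference in degrees of freedom.  With
four metrics and four parameters the family comprises sixteen tests, which
are adjusted together by the Benjamini-Hochberg false discovery rate
step-up procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import FitResult

__all__ = [
    "DiffTestResult",
    "chisq_difference_test",
    "fdr_bh",
    "enumerate_test_family",
    "assemble_results",
    "TEST_PARAMETERS",
    "EFFECT_LABELS",
]

#: parameters tested for sex differences, in reporting order
TEST_PARAMETERS = ("phi", "gamma1", "gamma2", "rho")

#: report labels of the four effects of interest
EFFECT_LABELS = {
    "phi": "baseline correlation (PDS_t1 <-> MRI_t1)",
    "gamma1": "coupling (PDS_t1 -> dMRI)",
    "gamma2": "coupling (MRI_t1 -> dPDS)",
    "rho": "correlated change (dPDS <-> dMRI)",
}

#: small negative slack tolerated before a difference test is treated as a
#: failed (non-converged) refit
_NEGATIVE_TOL = 0.01


@dataclass
class DiffTestResult:
    """One equality-constraint test of a parameter across the two sexes."""

    model: str                  # MRI metric label (fa/md/ct/sa)
    parameter: str              # phi / gamma1 / gamma2 / rho
    chisq_diff: float
    df_diff: int
    p: float
    p_corr: float = math.nan    # filled in after family-wise FDR adjustment
    group_estimates: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict:
        return {"model": self.model, "parameter": self.parameter,
                "chisq_diff": self.chisq_diff, "df_diff": self.df_diff,
                "p": self.p, "p_corr": self.p_corr,
                **{f"est_{g}": v for g, v in self.group_estimates.items()}}


def chisq_difference_test(free: FitResult, constrained: FitResult,
                          *, model: str = "", parameter: str = ""
                          ) -> DiffTestResult:
    """Likelihood-ratio test of a cross-group equality constraint.

    ``free`` and ``constrained`` must be fits of the same data (checked via
    a data fingerprint) differing only in the constraint set.  Small
    negative differences from optimiser noise are clipped to zero; values
    below -0.01 indicate a non-converged refit and raise.
    """
    if free.data_fingerprint != constrained.data_fingerprint:
        raise ValueError("free and constrained fits use different data")
    if constrained.df <= free.df:
        raise ValueError("constrained model must have larger df than free")
    d_chisq = constrained.chisq - free.chisq
    d_df = constrained.df - free.df
    if d_chisq < -_NEGATIVE_TOL:
        raise ValueError(
            f"negative chi-square difference ({d_chisq:.4f}): the "
            "constrained refit did not converge to its optimum")
    if d_chisq < 0:
        import warnings
        warnings.warn(f"clipping small negative chi-square difference "
                      f"({d_chisq:.2e}) to 0", stacklevel=2)
        d_chisq = 0.0
    p = float(stats.chi2.sf(d_chisq, d_df)) if d_chisq > 0 else 1.0
    est = {}
    if parameter:
        est = {g: free.std_estimates[g][parameter] for g in free.groups}
    return DiffTestResult(model=model, parameter=parameter,
                          chisq_diff=float(d_chisq), df_diff=int(d_df), p=p,
                          group_estimates=est)


def fdr_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Adjusted value i is ``min over j >= i (in sorted order) of p_(j)*m/j``,
    capped at 1; output order matches the input order.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def enumerate_test_family(models: Sequence[str] = ("fa", "md", "ct", "sa"),
                          parameters: Sequence[str] = TEST_PARAMETERS,
                          fitted: Mapping[str, FitResult] | None = None
                          ) -> list[tuple[str, str]]:
    """The Cartesian family of (metric, parameter) sex-difference tests in
    stable order; 4 metrics x 4 parameters = 16 descriptors."""
    models = list(models)
    if len(set(models)) != len(models):
        raise ValueError("duplicate model labels")
    if fitted is not None:
        missing = [m for m in models if m not in fitted]
        if missing:
            raise ValueError(f"missing fitted model(s): {missing}")
    return list(product(models, parameters))


def assemble_results(fits: Mapping[str, FitResult],
                     tests: Sequence[DiffTestResult],
                     *, alpha: float = 0.05
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the per-group estimate table and the sex-difference table.

    Returns ``(estimates, differences)``: one estimate row per
    (metric, effect, group) with standardised Est/SE/z/p and a significance
    marker at raw p < alpha; one difference row per (metric, parameter)
    with the chi-square difference, raw p and FDR-adjusted p (marker at
    adjusted p < alpha).  FDR adjustment is applied across the supplied
    test family only.
    """
    for metric, fit in fits.items():
        if not fit.converged:
            import warnings
            warnings.warn(f"fit for {metric!r} did not converge; "
                          "its rows are flagged", stacklevel=2)
    seen = set()
    for t in tests:
        key = (t.model, t.parameter)
        if key in seen:
            raise ValueError(f"duplicate test descriptor {key}")
        seen.add(key)
        if t.model not in fits:
            raise ValueError(f"test references unknown model {t.model!r}")
        if t.parameter not in TEST_PARAMETERS:
            raise ValueError(f"unknown test parameter {t.parameter!r}")

    p_corr = fdr_bh([t.p for t in tests])
    for t, pc in zip(tests, p_corr):
        t.p_corr = float(pc)

    est_rows = []
    for metric, fit in fits.items():
        for param in TEST_PARAMETERS:
            for g in fit.groups:
                est = fit.std_estimates[g][param]
                se = fit.std_se[g][param]
                z = est / se if se and se > 0 else math.nan
                p = 2 * stats.norm.sf(abs(z)) if math.isfinite(z) else math.nan
                est_rows.append({
                    "metric": metric, "effect": param,
                    "label": EFFECT_LABELS[param], "group": g,
                    "est": est, "se": se, "z": z, "p": p,
                    "significant": bool(p < alpha) if math.isfinite(p) else False,
                    "converged": fit.converged,
                })
    diff_rows = [{**t.as_row(),
                  "significant": bool(t.p_corr < alpha)} for t in tests]
    return pd.DataFrame(est_rows), pd.DataFrame(diff_rows)
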