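"""Structure-activity statistics: descriptor correlations and group tests.

Optical responses are correlated against molecular descriptors —
Hammett substituent constants (sigma), HOMO energies (e_HOMO, eV) and
standard reduction potentials (E_red, V) — with plain Pearson statistics,
and groups (e.g. positively charged vs neutral analytes) are compared
with an unpaired t test.  Analytes missing a descriptor are dropped
pairwise and counted, mirroring how overlapping compound subsets (9, 18,
full library) are analyzed rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DescriptorRecord",
    "CorrelationResult",
    "pearson_correlation",
    "correlate_response_with_descriptor",
    "unpaired_t_test",
    "heuristic_response_rule",
    "bonferroni",
    "hammett_sigma_sum",
]


@dataclass(frozen=True)
class DescriptorRecord:
    """Molecular descriptors for one analyte (missing values allowed)."""

    analyte_id: str
    hammett_sigma: float | None = None
    e_homo: float | None = None
    e_red: float | None = None
    net_charge: int = 0
    has_vicinal_donors: bool | None = None
    conjugated: bool | None = None


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation plus the least-squares line through the points."""

    n: int
    r: float
    r_squared: float
    p_value: float
    slope: float
    intercept: float
    n_dropped: int = 0


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson r with a two-sided p from the t transform, plus the LS fit."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError(f"need n >= 3 points, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs contain non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return CorrelationResult(
        n=int(x.size),
        r=float(r),
        r_squared=float(r) ** 2,
        p_value=float(p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def correlate_response_with_descriptor(
    responses,
    descriptors,
    field: str,
    response_field: str = "normalized",
) -> CorrelationResult:
    """Join responses with descriptors on analyte_id and correlate.

    ``responses`` is a list of ResponseRecord-like objects (or a DataFrame
    with analyte_id + response_field); ``descriptors`` a list of
    DescriptorRecord (or a DataFrame).  Records lacking the descriptor are
    dropped and counted in ``n_dropped``.
    """
    rdf = responses if isinstance(responses, pd.DataFrame) else pd.DataFrame(
        {
            "analyte_id": [r.analyte_id for r in responses],
            response_field: [getattr(r, response_field) for r in responses],
        }
    )
    ddf = descriptors if isinstance(descriptors, pd.DataFrame) else pd.DataFrame(
        {
            "analyte_id": [d.analyte_id for d in descriptors],
            field: [getattr(d, field) for d in descriptors],
        }
    )
    if field not in ddf.columns:
        raise ValueError(f"descriptor field {field!r} not present")
    merged = rdf.merge(ddf[["analyte_id", field]], on="analyte_id", how="inner")
    complete = merged.dropna(subset=[field, response_field])
    n_dropped = len(merged) - len(complete)
    if len(complete) < 3:
        raise ValueError(
            f"fewer than 3 complete (response, {field}) pairs after join "
            f"({len(complete)} found, {n_dropped} dropped)"
        )
    res = pearson_correlation(
        complete[field].to_numpy(), complete[response_field].to_numpy()
    )
    return CorrelationResult(
        n=res.n,
        r=res.r,
        r_squared=res.r_squared,
        p_value=res.p_value,
        slope=res.slope,
        intercept=res.intercept,
        n_dropped=n_dropped,
    )


def unpaired_t_test(group_a, group_b, welch: bool = False) -> float:
    """Two-sided p for a difference of group means.

    Student's equal-variance t by default; ``welch=True`` drops the
    equal-variance assumption.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups contain non-finite values")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue)


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni-adjusted p values (off by default in all pipelines).

    Raw r/p values are reported by default; this adjustment is opt-in
    for users running many descriptor correlations at once.
    """
    p = np.asarray(p_values, dtype=float)
    return np.clip(p * p.size, 0.0, 1.0)


def hammett_sigma_sum(substituent_sigmas) -> float:
    """Compound-level Hammett constant as the sum of substituent sigmas.

    Used for multi-substituted compounds when no per-compound value is
    tabulated; a tabulated per-compound column takes precedence.
    """
    s = np.asarray(substituent_sigmas, dtype=float)
    if s.size == 0 or not np.isfinite(s).all():
        raise ValueError("need at least one finite substituent sigma")
    return float(s.sum())


def heuristic_response_rule(descriptor: DescriptorRecord) -> bool:
    """Necessary-condition heuristic for an optical response.

    Responsive analytes carry vicinal (ortho-positioned) hydrogen-bond
    donors on a pi-conjugated scaffold.  The rule is necessary, not
    sufficient: analytes satisfying it may still be unresponsive.
    """
    if descriptor.has_vicinal_donors is None or descriptor.conjugated is None:
        raise ValueError(
            f"analyte {descriptor.analyte_id!r} lacks donor/conjugation flags"
        )
    return bool(descriptor.has_vicinal_donors and descriptor.conjugated)
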