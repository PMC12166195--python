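"""Tidy analytics for N-metabolite tables.

Given a tidy treatment × organ × replicate × analyte concentration table,
this module computes the summaries used to compare N-source treatments:
per-replicate amino-acid ratios (e.g. Gln/Glu, Gln/Thea), total free amino
acid per sample, log2 fold-change matrices for heat maps, and the
concentration → per-organ content conversion.

The fold change of a value is the value divided by its analyte's grand
mean, where the grand mean is the mean of the per-treatment means (all
treatments weighted equally).  With that convention the non-log treatment-
mean fold changes of every analyte average to exactly 1, which the heat-map
colour scale relies on.  Dividing by the mean over all samples instead is
available via ``grand_mean="sample"`` (the two coincide for balanced
designs).  Missing values propagate as NaN, never as zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .simulate import MetaboliteTable

__all__ = [
    "RatioTable",
    "FoldChangeMatrix",
    "pair_ratio",
    "total_faa",
    "log2fc_matrix",
    "content_from_concentration",
]

_KEYS = ["treatment", "organ", "replicate"]


@dataclass(frozen=True)
class RatioTable:
    """Per-replicate analyte ratios: (treatment, organ, replicate, ratio_name, value)."""

    data: pd.DataFrame

    def by_treatment(self) -> pd.DataFrame:
        """Mean ± SD of the ratio per (treatment, organ)."""
        return (self.data.groupby(["treatment", "organ"], sort=False)["value"]
                .agg(["mean", "std", "count"]).reset_index())


@dataclass(frozen=True)
class FoldChangeMatrix:
    """log2 fold changes of measurements relative to across-treatment means.

    ``treatment_means``: wide frame, rows = (group keys + feature), columns =
    treatments, cells = log2(treatment mean / grand mean).
    ``per_sample``: the input long table with ``fc`` and ``log2fc`` columns.
    ``grand_means``: the per-row divisor on the original scale.
    """

    treatment_means: pd.DataFrame
    per_sample: pd.DataFrame
    grand_means: pd.Series
    grand_mean_kind: str = "treatment"


def _require_table(table: MetaboliteTable | pd.DataFrame) -> pd.DataFrame:
    return table.data if isinstance(table, MetaboliteTable) else table


def pair_ratio(table: MetaboliteTable | pd.DataFrame, numerator: str,
               denominator: str) -> RatioTable:
    """Per-replicate ratio of two analytes (e.g. Gln/Glu).

    Both analytes must be measured in every (treatment, organ, replicate)
    sample.  A nonpositive denominator yields a flagged record with a NaN
    value rather than a silent drop (``flag = "nonpositive_denominator"``).
    """
    df = _require_table(table)
    present = set(df["analyte"])
    for name in (numerator, denominator):
        if name not in present:
            raise ConfigurationError(f"analyte {name!r} not present in table")
    wide = (df[df["analyte"].isin([numerator, denominator])]
            .pivot_table(index=_KEYS, columns="analyte",
                         values="concentration", aggfunc="first",
                         observed=True))
    if wide[numerator].isna().any() or wide[denominator].isna().any():
        raise ConfigurationError(
            f"analytes {numerator!r}/{denominator!r} missing in some samples")
    num = wide[numerator].to_numpy(dtype=float)
    den = wide[denominator].to_numpy(dtype=float)
    bad = den <= 0
    value = np.where(bad, np.nan, num / np.where(bad, 1.0, den))
    out = wide.reset_index()[_KEYS].copy()
    out["ratio_name"] = f"{numerator}:{denominator}"
    out["value"] = value
    out["flag"] = np.where(bad, "nonpositive_denominator", "")
    return RatioTable(data=out)


def total_faa(table: MetaboliteTable | pd.DataFrame,
              analyte_set: Sequence[str]) -> pd.DataFrame:
    """Per-sample sum of the concentrations of a set of analytes.

    Returns one record per (treatment, organ, replicate) with a ``total``
    column.  Every analyte in the set must occur in the table.
    """
    df = _require_table(table)
    names = list(dict.fromkeys(analyte_set))
    if not names:
        raise ConfigurationError("analyte_set must be non-empty")
    unknown = [a for a in names if a not in set(df["analyte"])]
    if unknown:
        raise ConfigurationError(f"unknown analytes in set: {unknown}")
    sub = df[df["analyte"].isin(names)]
    out = (sub.groupby(_KEYS, sort=False)["concentration"].sum()
           .reset_index().rename(columns={"concentration": "total"}))
    return out


def log2fc_matrix(table: MetaboliteTable | pd.DataFrame,
                  value_field: str = "concentration",
                  feature_field: str = "analyte",
                  treatment_field: str = "treatment",
                  group_fields: Sequence[str] = ("organ",),
                  grand_mean: str = "treatment") -> FoldChangeMatrix:
    """log2 fold-change matrix of a long-form measurement table.

    Works for any long table (metabolite concentrations, gene expression
    levels, ...): rows are (group, feature) combinations — by default
    (organ, analyte) — columns are treatments.  For each row the grand mean
    is the mean of the per-treatment means (``grand_mean="treatment"``,
    default) or the mean over all samples (``"sample"``); each cell is
    log2(treatment mean / grand mean), and the per-sample long form carries
    log2(value / grand mean).

    Rows whose grand mean is zero are emitted with NaN cells and a warning.
    """
    if grand_mean not in ("treatment", "sample"):
        raise ConfigurationError("grand_mean must be 'treatment' or 'sample'")
    df = _require_table(table)
    keys = [*group_fields, feature_field]
    for col in (*keys, treatment_field, value_field):
        if col not in df.columns:
            raise ConfigurationError(f"column {col!r} not in table")

    tmeans = (df.groupby([*keys, treatment_field], sort=False)[value_field]
              .mean().unstack(treatment_field))
    if tmeans.isna().any().any():
        raise ConfigurationError(
            "every (row, treatment) cell needs at least one replicate")
    if grand_mean == "treatment":
        gm = tmeans.mean(axis=1)
    else:
        gm = df.groupby(keys, sort=False)[value_field].mean().reindex(tmeans.index)
    zero = gm == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} row(s) have zero grand mean; their fold "
            "changes are emitted as NaN", UserWarning, stacklevel=2)
    divisor = gm.mask(zero)
    with np.errstate(divide="ignore"):
        log2_tm = np.log2(tmeans.div(divisor, axis=0))

    per_sample = df.copy()
    gm_per_row = per_sample.join(divisor.rename("_gm"), on=keys)["_gm"]
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = per_sample[value_field].to_numpy(dtype=float) / gm_per_row.to_numpy()
        per_sample["fc"] = fc
        per_sample["log2fc"] = np.log2(fc, where=fc > 0,
                                       out=np.full_like(fc, np.nan))
        per_sample.loc[per_sample["fc"] == 0, "log2fc"] = -np.inf
    return FoldChangeMatrix(treatment_means=log2_tm, per_sample=per_sample,
                            grand_means=gm, grand_mean_kind=grand_mean)


def content_from_concentration(conc, mass):
    """Per-organ content = concentration (per g DW) × organ dry mass (g)."""
    c = np.asarray(conc, dtype=float)
    m = np.asarray(mass, dtype=float)
    if (c < 0).any() if c.ndim else c < 0:
        raise DomainError("concentration must be >= 0")
    if (m < 0).any() if m.ndim else m < 0:
        raise DomainError("mass must be >= 0")
    out = c * m
    return float(out) if out.ndim == 0 else out
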