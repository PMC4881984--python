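"""Efficiency-corrected relative qPCR expression.

Amplification efficiency per primer pair comes from a standard curve of
serial dilutions: Ct regressed on log10(relative concentration) gives a
slope s, and eff = 10**(-1/s) - 1 (perfect doubling: s = -1/log10(2) =
-3.3219, eff = 1).  Relative expression of a target gene, corrected by
both the target and reference efficiencies, is

    fold = (1 + eff_target) ** dCt_target / (1 + eff_ref) ** dCt_ref

with dCt = Ct_control - Ct_sample under the default convention, so that
fold > 1 means higher expression in the sample.  The alternative
``convention="sample-minus-control"`` uses dCt = Ct_sample - Ct_control
in both exponents (the reciprocal), for compatibility with reports that
write the formula that way.  With both efficiencies equal to 1 the
default convention reduces to the classic 2**-ddCt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "EfficiencyModel",
    "efficiency_from_dilutions",
    "relative_amount",
    "mean_ct",
    "choose_reference_gene",
    "fold_change_table",
]

#: Slope of an ideal (100 % efficient) standard curve, Ct per log10 unit.
IDEAL_SLOPE = -1.0 / np.log10(2.0)

_CONVENTIONS = ("control-minus-sample", "sample-minus-control")


@dataclass(frozen=True)
class EfficiencyModel:
    """Standard-curve fit for one primer pair."""

    gene: str
    efficiency: float
    slope: float
    intercept: float
    r_squared: float


def efficiency_from_dilutions(
    cts: Sequence[float],
    relative_concentrations: Sequence[float],
    gene: str = "",
) -> EfficiencyModel:
    """Fit a dilution standard curve and derive amplification efficiency.

    ``relative_concentrations`` must be strictly decreasing (e.g. 1, 0.5,
    0.25 for 1:2 serial dilutions); Cts are expected to increase with
    dilution, and a warning (with the r^2) is raised when they do not.
    """
    cts = np.asarray(cts, dtype=float)
    conc = np.asarray(relative_concentrations, dtype=float)
    if cts.size != conc.size or cts.size < 3:
        raise ValidationError("need >= 3 paired dilution points")
    if np.any(conc <= 0) or np.any(np.diff(conc) >= 0):
        raise ValidationError("concentrations must be positive, strictly decreasing")
    fit = stats.linregress(np.log10(conc), cts)
    r2 = float(fit.rvalue**2)
    if np.any(np.diff(cts) <= 0):
        warnings.warn(
            f"Cts not strictly increasing with dilution (r^2 = {r2:.4f})",
            stacklevel=2,
        )
    if fit.slope >= 0:
        raise ValidationError("standard curve slope must be negative")
    efficiency = float(10.0 ** (-1.0 / fit.slope) - 1.0)
    return EfficiencyModel(
        gene=gene,
        efficiency=efficiency,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
    )


def relative_amount(
    ct_target_sample: float,
    ct_target_control: float,
    ct_ref_sample: float,
    ct_ref_control: float,
    eff_target: float,
    eff_ref: float,
    convention: str = "control-minus-sample",
) -> float:
    """Efficiency-corrected fold change of a target gene vs a reference gene."""
    for name, eff in (("eff_target", eff_target), ("eff_ref", eff_ref)):
        if not (0 < eff <= 1.2):
            raise ValidationError(f"{name} must be in (0, 1.2]; got {eff}")
    if convention not in _CONVENTIONS:
        raise ValidationError(f"convention must be one of {_CONVENTIONS}")
    sign = 1.0 if convention == "control-minus-sample" else -1.0
    d_target = sign * (ct_target_control - ct_target_sample)
    d_ref = sign * (ct_ref_control - ct_ref_sample)
    return float((1 + eff_target) ** d_target / (1 + eff_ref) ** d_ref)


def mean_ct(table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates per (sample_id, group, gene)."""
    required = {"sample_id", "group", "gene", "ct"}
    if not required.issubset(table.columns):
        raise ValidationError(f"Ct table must have columns {sorted(required)}")
    return (
        table.groupby(["sample_id", "group", "gene"], as_index=False)["ct"].mean()
    )


def choose_reference_gene(table: pd.DataFrame, candidates: Sequence[str]) -> str:
    """Pick the candidate reference gene with lowest within-group Ct variance."""
    means = mean_ct(table)
    best, best_var = None, np.inf
    for gene in candidates:
        sub = means[means["gene"] == gene]
        if sub.empty:
            raise ValidationError(f"no Ct rows for candidate reference {gene!r}")
        var = sub.groupby("group")["ct"].var(ddof=1).mean()
        if np.isnan(var):
            var = 0.0
        if var < best_var:
            best, best_var = gene, var
    assert best is not None
    return best


def fold_change_table(
    table: pd.DataFrame,
    target_genes: Sequence[str],
    reference_gene: str,
    efficiencies: Mapping[str, float],
    control_group: str,
    convention: str = "control-minus-sample",
) -> pd.DataFrame:
    """Per-sample fold changes vs the control-group mean Cts.

    Replicates are averaged first; the control Ct per gene is the mean
    over control-group samples.  Returns one row per (sample, target
    gene) with the efficiency-corrected fold change.
    """
    means = mean_ct(table)
    ctrl = means[means["group"] == control_group]
    if ctrl.empty:
        raise ValidationError(f"no samples in control group {control_group!r}")
    ctrl_ct = ctrl.groupby("gene")["ct"].mean()
    for gene in (*target_genes, reference_gene):
        if gene not in ctrl_ct.index:
            raise ValidationError(f"control group lacks Cts for gene {gene!r}")
        if gene not in efficiencies:
            raise ValidationError(f"no efficiency provided for gene {gene!r}")
    rows = []
    by_sample = means.pivot_table(
        index=["sample_id", "group"], columns="gene", values="ct"
    )
    for (sample_id, group), cts in by_sample.iterrows():
        if pd.isna(cts.get(reference_gene)):
            continue
        for gene in target_genes:
            if pd.isna(cts.get(gene)):
                continue
            fold = relative_amount(
                ct_target_sample=float(cts[gene]),
                ct_target_control=float(ctrl_ct[gene]),
                ct_ref_sample=float(cts[reference_gene]),
                ct_ref_control=float(ctrl_ct[reference_gene]),
                eff_target=efficiencies[gene],
                eff_ref=efficiencies[reference_gene],
                convention=convention,
            )
            rows.append(
                {
                    "sample_id": sample_id,
                    "group": group,
                    "gene": gene,
                    "reference_gene": reference_gene,
                    "fold_change": fold,
                }
            )
    return pd.DataFrame(rows)
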