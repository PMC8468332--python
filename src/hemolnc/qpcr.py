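"""qPCR validation arm.

Primer amplification efficiency is estimated with the threshold-cycle
slope method, E = 10^(-1/slope), from a standard dilution series;
relative expression is computed with the efficiency-corrected Pfaffl
ratio E_target^dCt_target / E_ref^dCt_ref against a reference gene; and
the qPCR fold changes are correlated (Pearson on log10 FC) with the
RNA-Seq fold changes of the same lncRNAs for cross-platform validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .correlation_linking import pearson

ACCEPTED_E_RANGE = (1.0, 2.2)


@dataclass
class EfficiencyEstimate:
    primer_id: str
    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    flagged: bool = False

    @classmethod
    def from_fit(cls, primer_id, slope, intercept, r_squared) -> "EfficiencyEstimate":
        if slope >= 0:
            return cls(primer_id, slope, intercept, np.nan, r_squared, flagged=True)
        e = 10 ** (-1.0 / slope)
        lo, hi = ACCEPTED_E_RANGE
        return cls(primer_id, slope, intercept, e, r_squared, flagged=not (lo < e <= hi))


@dataclass
class RelativeExpression:
    target_id: str
    sample_id: str
    ratio: float

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("expression ratio must be positive")

    @property
    def log2(self) -> float:
        return float(np.log2(self.ratio))

    @property
    def log10(self) -> float:
        return float(np.log10(self.ratio))


def efficiency_from_dilution(
    series: pd.DataFrame, primer_id: str = ""
) -> EfficiencyEstimate:
    """CT-slope efficiency from a dilution series.

    ``series`` needs columns ``dilution`` (relative input amount) and
    ``ct``; technical replicates (rows sharing a dilution) are averaged
    before the OLS fit of Ct on log10(dilution).
    """
    mean_ct = series.groupby("dilution")["ct"].mean()
    if len(mean_ct) < 3:
        raise ValueError("need at least 3 distinct dilution points")
    x = np.log10(mean_ct.index.to_numpy(dtype=float))
    fit = stats.linregress(x, mean_ct.to_numpy())
    return EfficiencyEstimate.from_fit(
        primer_id, float(fit.slope), float(fit.intercept), float(fit.rvalue) ** 2
    )


def pfaffl_ratio(
    ct_target_ctrl: float,
    ct_target_trt: float,
    ct_ref_ctrl: float,
    ct_ref_trt: float,
    e_target: float,
    e_ref: float,
    target_id: str = "",
    sample_id: str = "",
) -> RelativeExpression:
    """Efficiency-corrected relative expression of treated vs control.

    ratio = E_t^(Ct_ctrl - Ct_trt of target) / E_ref^(Ct_ctrl - Ct_trt
    of reference); with both efficiencies equal to 2 this reduces to
    the familiar 2^-ddCt.
    """
    if e_target <= 0 or e_ref <= 0:
        raise ValueError("efficiencies must be positive")
    for ct in (ct_target_ctrl, ct_target_trt, ct_ref_ctrl, ct_ref_trt):
        if not np.isfinite(ct):
            raise ValueError("all Ct values must be finite")
    d_ct_target = ct_target_ctrl - ct_target_trt
    d_ct_ref = ct_ref_ctrl - ct_ref_trt
    ratio = e_target**d_ct_target / e_ref**d_ct_ref
    return RelativeExpression(target_id, sample_id, float(ratio))


def relative_expression_table(
    ct: pd.DataFrame,
    efficiencies: dict[str, float],
    ref_gene: str = "18S",
    control: str = "control",
) -> pd.DataFrame:
    """Per-individual Pfaffl ratios for every (target, stimulus).

    ``ct`` needs columns [individual, condition, target, ct]; technical
    replicates are averaged (arithmetic mean of Ct) first. The control
    Ct of each individual is that individual's unstimulated well.
    Returns a frame with columns [target, stimulus, individual, ratio].
    """
    mean_ct = (
        ct.groupby(["individual", "condition", "target"])["ct"].mean().reset_index()
    )
    pivot = mean_ct.pivot_table(
        index=["individual", "condition"], columns="target", values="ct"
    )
    rows = []
    targets = [t for t in pivot.columns if t != ref_gene]
    stimuli = sorted({c for _, c in pivot.index if c != control})
    for ind in sorted({i for i, _ in pivot.index}):
        for stim in stimuli:
            if (ind, stim) not in pivot.index or (ind, control) not in pivot.index:
                continue
            for tgt in targets:
                vals = (
                    pivot.loc[(ind, control), tgt],
                    pivot.loc[(ind, stim), tgt],
                    pivot.loc[(ind, control), ref_gene],
                    pivot.loc[(ind, stim), ref_gene],
                )
                if any(pd.isna(v) for v in vals):
                    continue
                rel = pfaffl_ratio(
                    *vals,
                    e_target=efficiencies[tgt],
                    e_ref=efficiencies[ref_gene],
                    target_id=tgt,
                    sample_id=f"{ind}:{stim}",
                )
                rows.append(
                    {"target": tgt, "stimulus": stim, "individual": ind, "ratio": rel.ratio}
                )
    return pd.DataFrame(rows)


def signed_fc_to_ratio(fc: float) -> float:
    """Signed fold change to ratio scale: -k maps to 1/k."""
    if fc == 0:
        raise ValueError("fold change of 0 is undefined on the signed scale")
    return fc if fc > 0 else -1.0 / fc


def cross_platform_correlation(
    rnaseq_fc: pd.Series, qpcr_fc: pd.Series
) -> tuple[float, float]:
    """Pearson r between log10 RNA-Seq and qPCR fold changes.

    Both inputs are signed fold changes indexed by matched validation
    keys (e.g. (lncRNA, stimulus)); negative values are converted to
    ratios before the log.
    """
    common = rnaseq_fc.index.intersection(qpcr_fc.index)
    if len(common) < 3:
        raise ValueError("need at least 3 matched fold-change pairs")
    x = np.log10([signed_fc_to_ratio(v) for v in rnaseq_fc.loc[common]])
    y = np.log10([signed_fc_to_ratio(v) for v in qpcr_fc.loc[common]])
    return pearson(x, y)
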