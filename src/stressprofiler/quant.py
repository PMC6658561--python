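"""Molecular quantification: ddCt relative expression, knockdown
efficiency, the infection-area rubric and methylation-expression coupling.

qPCR quantification follows the standard 2^-ddCt convention: per sample
dCt = Ct_target - Ct_reference; ddCt is taken against the mean dCt of the
calibrator group; fold change = 2^-ddCt.  No amplification-efficiency
correction is applied (none is measured for these assays).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as st

__all__ = [
    "InfectionScore",
    "relative_expression_ddct",
    "kd_efficiency",
    "infection_score",
    "methylation_expression_report",
]

#: Ct table columns: sample, gene, ct (one row per sample x gene, replicates
#: pre-averaged or carrying a 'replicate' column that is averaged here).
CT_COLUMNS = ("sample", "gene", "ct")


def _ct_wide(ct: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise KeyError(f"Ct table missing columns: {missing}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycle counts")
    wide = (
        ct[ct["gene"].isin(genes)]
        .groupby(["sample", "gene"])["ct"]
        .mean()  # technical replicates averaged on the Ct scale
        .unstack("gene")
    )
    return wide


def relative_expression_ddct(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    calibrator_samples: list | pd.Index,
) -> pd.DataFrame:
    """Fold change 2^-ddCt per sample, calibrated to a sample group.

    Every sample must carry both target and reference Ct; the calibrator
    group's mean dCt defines ddCt = dCt_sample - mean(dCt_calibrator).
    Returns a frame with columns [dct, ddct, fold].
    """
    wide = _ct_wide(ct, [target, reference])
    if reference not in wide.columns:
        raise KeyError(f"reference gene {reference!r} absent from Ct table")
    if target not in wide.columns:
        raise KeyError(f"target gene {target!r} absent from Ct table")
    incomplete = wide[[target, reference]].isna().any(axis=1)
    if incomplete.any():
        raise ValueError(
            f"samples missing target or reference Ct: {list(wide.index[incomplete])}"
        )
    dct = wide[target] - wide[reference]
    cal = dct.reindex(list(calibrator_samples)).dropna()
    if cal.empty:
        raise ValueError("no calibrator samples with usable dCt")
    ddct = dct - cal.mean()
    return pd.DataFrame({"dct": dct, "ddct": ddct, "fold": 2.0 ** (-ddct)})


def kd_efficiency(
    ct: pd.DataFrame,
    control_samples: list | pd.Index,
    target: str = "GILZ",
    overall_reference: str = "HPRT",
    infection_reference: str = "GFP",
) -> pd.DataFrame:
    """Knockdown efficiency under two normalizations.

    Target expression is normalized both to a housekeeping gene (HPRT:
    overall downregulation across the dissected tissue) and to the viral
    reporter (GFP: downregulation per infected unit), each as 2^-ddCt fold
    change against the control-virus group.  Samples without a reporter Ct
    (uninfected tissue) are flagged and excluded.
    """
    wide = _ct_wide(ct, [target, overall_reference, infection_reference])
    for g in (target, overall_reference, infection_reference):
        if g not in wide.columns:
            raise KeyError(f"gene {g!r} absent from Ct table")
    controls = [s for s in control_samples if s in wide.index]
    if not controls:
        raise ValueError("control-virus group absent from Ct table")
    uninfected = wide[infection_reference].isna()
    if uninfected.any():
        warnings.warn(
            f"{int(uninfected.sum())} sample(s) lack {infection_reference} Ct "
            "(uninfected): excluded", RuntimeWarning
        )
        wide = wide[~uninfected]
        controls = [s for s in controls if s in wide.index]
    out = pd.DataFrame(index=wide.index)
    for label, ref in (
        ("fold_vs_" + overall_reference.lower(), overall_reference),
        ("fold_vs_" + infection_reference.lower(), infection_reference),
    ):
        dct = wide[target] - wide[ref]
        ddct = dct - dct.loc[controls].mean()
        out[label] = 2.0 ** (-ddct)
    out["knockdown_percent_" + overall_reference.lower()] = 100.0 * (
        1.0 - out["fold_vs_" + overall_reference.lower()]
    )
    out["knockdown_percent_" + infection_reference.lower()] = 100.0 * (
        1.0 - out["fold_vs_" + infection_reference.lower()]
    )
    out["is_control"] = out.index.isin(controls)
    return out


@dataclass(frozen=True)
class InfectionScore:
    """Per-hemisphere infection rubric scores and their total."""

    left_area_mm2: float
    right_area_mm2: float
    left_score: int
    right_score: int

    @property
    def total(self) -> int:
        return self.left_score + self.right_score


#: Rubric bin upper edges (mm^2) for scores 1..4; >= the last edge scores 5.
#: The rubric says "<5, <10, <25, <50, >50"; exactly 50 mm^2 is assigned
#: score 5 (half-open-upwards convention).
_RUBRIC_EDGES = (5.0, 10.0, 25.0, 50.0)


def _side_score(area: float) -> int:
    if area < 0 or not np.isfinite(area):
        raise ValueError(f"infection area must be a finite non-negative mm^2, got {area}")
    for score, edge in enumerate(_RUBRIC_EDGES, start=1):
        if area < edge:
            return score
    return 5


def infection_score(left_area_mm2: float, right_area_mm2: float) -> InfectionScore:
    """1-5 rubric per injected hemisphere; bins [0,5) [5,10) [10,25) [25,50) [50,inf).

    Total = sum of the two side scores (range 2-10).
    """
    return InfectionScore(
        float(left_area_mm2),
        float(right_area_mm2),
        _side_score(float(left_area_mm2)),
        _side_score(float(right_area_mm2)),
    )


def methylation_expression_report(
    meth: pd.DataFrame,
    expr: pd.DataFrame,
    meth_value: str = "percent_methylation",
    expr_value: str = "fold",
) -> dict:
    """Couple % CpG methylation with relative expression across samples.

    Both frames are indexed by sample id; the report carries the Pearson
    r/p on the paired samples plus the paired scatter table for plotting.
    Methylation may be on the [0,1] or [0,100] scale; the unit is detected
    and recorded, and the correlation is scale-invariant either way.
    """
    common = meth.index.intersection(expr.index)
    if len(common) == 0:
        raise ValueError("no overlapping sample ids between methylation and expression")
    m = pd.to_numeric(meth.loc[common, meth_value], errors="coerce")
    e = pd.to_numeric(expr.loc[common, expr_value], errors="coerce")
    paired = pd.DataFrame({"methylation": m, "expression": e}).dropna()
    if len(paired) < 3:
        raise ValueError("need at least 3 paired samples")
    unit = "percent" if paired["methylation"].max() > 1.0 else "fraction"
    r, p, n = st.pearson_correlation(paired["methylation"], paired["expression"])
    return {"r": r, "p": p, "n": n, "unit": unit, "pairs": paired}
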