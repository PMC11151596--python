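"""Calibrating and combining two kcat predictors into one table.

Two predictors scored against the same enzyme typically disagree in scale:
for the wild type here one model family predicts markedly lower turnover
numbers than the other (e.g. a wild-type pair of 4.34 vs 16.64 s^-1, a
ratio of about 3.83). The default combination rule therefore rescales the
first predictor's whole table onto the second's scale using the wild-type
ratio:

    factor = K2(WT) / K1(WT)
    combined(v) = K1(v) * factor          (mode "wt_ratio")

which preserves the first predictor's ranking exactly and reproduces
K2(WT) for the wild type. A symmetric alternative takes the per-variant
geometric mean sqrt(K1(v) * K2(v)) over the shared variants (mode
"geometric_mean").

A published variant of the rule, written as
``[Max(k2/k1) / Min(k2/k1)] * Min(k2/k1)``, cancels algebraically to
``Max(k2/k1)`` — a dimensionless ratio, not a turnover number — so it
cannot serve as a kcat; it is exposed as :func:`max_ratio_diagnostic` for
auditing only, with Max/Min read over the per-variant ratio set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .predictors import PredictionTable

log = logging.getLogger(__name__)

MODES = ("wt_ratio", "geometric_mean")


@dataclass(frozen=True)
class CalibrationResult:
    """Scale calibration between two predictors, from their WT records."""

    factor: float       # dimensionless; = k2_wt / k1_wt in wt_ratio mode
    k1_wt: float        # s^-1
    k2_wt: float        # s^-1
    mode: str = "wt_ratio"


def _check_compatible(k1: PredictionTable, k2: PredictionTable) -> None:
    if k1.sequence_id != k2.sequence_id:
        raise ValueError(
            f"sequence_id mismatch: {k1.sequence_id!r} vs {k2.sequence_id!r}")
    if k1.substrate_smiles != k2.substrate_smiles:
        raise ValueError(
            f"substrate mismatch: {k1.substrate_smiles!r} vs "
            f"{k2.substrate_smiles!r}")


def calibrate(k1: PredictionTable, k2: PredictionTable,
              mode: str = "wt_ratio") -> CalibrationResult:
    """Compute the scale factor between two tables from their WT records.

    Both tables must carry a WT row and agree on sequence and substrate
    (hard error otherwise). Under ``wt_ratio`` the factor is
    ``K2(WT)/K1(WT)``; under ``geometric_mean`` no scale factor is used
    and 1.0 is recorded for audit symmetry.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    _check_compatible(k1, k2)
    k1_wt, k2_wt = k1.wt_kcat, k2.wt_kcat
    factor = k2_wt / k1_wt if mode == "wt_ratio" else 1.0
    log.info("calibration: k1_wt=%.4g k2_wt=%.4g mode=%s factor=%.4g",
             k1_wt, k2_wt, mode, factor)
    return CalibrationResult(factor=factor, k1_wt=k1_wt, k2_wt=k2_wt,
                             mode=mode)


def combine(k1: PredictionTable, k2: PredictionTable,
            cal: CalibrationResult) -> PredictionTable:
    """Merge two prediction tables into one combined table.

    ``wt_ratio``: every K1 variant is rescaled by the calibration factor
    (K2 enters only through the WT calibration), so the K1 ranking is
    preserved and combined(WT) = K2(WT) exactly.

    ``geometric_mean``: sqrt(K1(v) * K2(v)) over the intersection of the
    two variant sets; disjoint sets are an error.
    """
    _check_compatible(k1, k2)
    out = PredictionTable(
        predictor_id=f"combined[{cal.mode},factor={cal.factor:.6g}]",
        sequence_id=k1.sequence_id,
        substrate_smiles=k1.substrate_smiles,
    )
    if cal.mode == "wt_ratio":
        for label, kcat in k1.records.items():
            out.add(label, kcat * cal.factor)
    else:
        shared = [v for v in k1.records if v in k2.records]
        if not shared:
            raise ValueError("geometric_mean mode: variant sets are disjoint")
        for label in shared:
            out.add(label, math.sqrt(k1[label] * k2[label]))
    return out


def max_ratio_diagnostic(k1: PredictionTable,
                         k2: PredictionTable) -> dict[str, float]:
    """Audit diagnostic over the per-variant ratio set {K2(v)/K1(v)}.

    Returns max, min and max/min of the ratios over shared variants.
    These are dimensionless disagreement measures, not turnover numbers,
    and are never used as kcat.
    """
    shared = [v for v in k1.records if v in k2.records]
    if not shared:
        raise ValueError("no shared variants between tables")
    ratios = [k2[v] / k1[v] for v in shared]
    return {
        "max_ratio": max(ratios),
        "min_ratio": min(ratios),
        "spread": max(ratios) / min(ratios),
        "n_shared": float(len(shared)),
    }
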