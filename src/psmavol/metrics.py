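"""Scan-level aggregation and response classification.

Per-lesion metrics are aggregated per scan:

* PSMA-TV — whole-body tumor volume, sum of lesion volumes (ml);
* TLQ — sum over lesions of volume / SUVmean (ml), a burden measure that
  up-weights bulky low-uptake disease;
* meanSUVmax — unweighted mean of per-lesion SUVmax, a proxy for the
  average PSMA expression of the tumor burden.

Classification conventions are strict (`>`), fixed so boundary cases are
deterministic: volumetric response requires a decline *greater than* 30%,
biochemical (PSA) response a decline *greater than* 50%, and high PSMA
expression requires meanSUVmax *greater than* 14.3 (so exactly 14.3 is low).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

#: Volumetric response: decline in PSMA-TV strictly greater than this (%).
TV_RESPONSE_PCT = 30.0
#: Biochemical response: best PSA decline strictly greater than this (%).
PSA_RESPONSE_PCT = 50.0
#: High PSMA expression: baseline meanSUVmax strictly greater than this (SUV).
EXPRESSION_CUTOFF = 14.3


@dataclass(frozen=True)
class ScanMetrics:
    """Per-scan aggregates over all segmented metastases.

    With no lesions, volume metrics are 0 and ``mean_suv_max`` is NaN
    (missing marker).
    """

    scan_id: str
    timepoint: str
    psma_tv_ml: float
    tlq_sum: float
    mean_suv_max: float
    n_lesions: int


@dataclass(frozen=True)
class ResponseRecord:
    """Per-patient response and expression flags.

    ``tv_ratio`` follows the baseline/interim convention (responders have
    ratio > 1/0.7); ``tv_decline_pct`` is the human-facing quantity.
    NaN in a float field or None in a boolean field marks "missing".
    """

    patient_id: str
    tv_ratio: float
    tv_decline_pct: float
    tv_responder: bool | None
    psa_decline_pct: float
    psa_responder: bool | None
    low_expression: bool | None


def aggregate_scan(
    lesions: Sequence, scan_id: str = "scan", timepoint: str = "baseline"
) -> ScanMetrics:
    """Sum volume and TLQ over lesions; average SUVmax (unweighted)."""
    lesions = list(lesions)
    n = len(lesions)
    if n == 0:
        return ScanMetrics(scan_id, timepoint, 0.0, 0.0, float("nan"), 0)
    psma_tv = float(sum(l.volume_ml for l in lesions))
    tlq = float(sum(l.tlq_lesion for l in lesions))
    mean_suv_max = float(np.mean([l.suv_max for l in lesions]))
    return ScanMetrics(scan_id, timepoint, psma_tv, tlq, mean_suv_max, n)


def classify_tv_response(
    baseline: ScanMetrics | float, interim: ScanMetrics | float
) -> tuple[float, float, bool | None]:
    """(tv_ratio, tv_decline_pct, tv_responder) from two scans' PSMA-TV.

    Responder iff decline strictly > 30%. A vanished tumor volume
    (interim 0 with baseline > 0) is a 100% decline with infinite ratio
    stored as NaN-but-responder. Baseline 0 means response is undefined.
    """
    tv_b = baseline.psma_tv_ml if isinstance(baseline, ScanMetrics) else float(baseline)
    tv_i = interim.psma_tv_ml if isinstance(interim, ScanMetrics) else float(interim)
    if tv_b < 0 or tv_i < 0:
        raise InputError("tumor volumes must be >= 0")
    if tv_b == 0:
        return float("nan"), float("nan"), None
    decline = 100.0 * (1.0 - tv_i / tv_b)
    # rearranged comparison avoids float noise at an exact 30% boundary
    responder = 100.0 * (tv_b - tv_i) > TV_RESPONSE_PCT * tv_b
    ratio = tv_b / tv_i if tv_i > 0 else float("nan")
    return ratio, decline, responder


def classify_expression(baseline: ScanMetrics | float) -> bool | None:
    """Low expression iff baseline meanSUVmax <= 14.3 (missing -> None)."""
    v = baseline.mean_suv_max if isinstance(baseline, ScanMetrics) else float(baseline)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return not (v > EXPRESSION_CUTOFF)


def classify_psa_response(psa_baseline: float, psa_best: float) -> bool:
    """Biochemical response iff best PSA decline strictly > 50%."""
    if not psa_baseline > 0:
        raise InputError(f"baseline PSA must be > 0, got {psa_baseline}")
    # rearranged comparison avoids float noise at an exact 50% boundary
    return 100.0 * (psa_baseline - psa_best) > PSA_RESPONSE_PCT * psa_baseline


def build_response_record(
    patient_id: str,
    baseline: ScanMetrics,
    interim: ScanMetrics,
    psa_baseline: float | None = None,
    psa_best: float | None = None,
) -> ResponseRecord:
    """Assemble the full response record for one patient."""
    ratio, decline, responder = classify_tv_response(baseline, interim)
    low_expr = classify_expression(baseline)
    if psa_baseline is not None and psa_best is not None and psa_baseline > 0:
        psa_decline = 100.0 * (1.0 - psa_best / psa_baseline)
        psa_resp: bool | None = classify_psa_response(psa_baseline, psa_best)
    else:
        psa_decline, psa_resp = float("nan"), None
    return ResponseRecord(
        patient_id=patient_id,
        tv_ratio=ratio,
        tv_decline_pct=decline,
        tv_responder=responder,
        psa_decline_pct=psa_decline,
        psa_responder=psa_resp,
        low_expression=low_expr,
    )


def lesions_to_frame(
    lesions: Iterable, scan_id: str = "scan", timepoint: str = "baseline"
) -> pd.DataFrame:
    """Per-lesion table in the exchange format written by the CLI."""
    rows = [
        {
            "scan_id": scan_id,
            "timepoint": timepoint,
            "lesion_id": l.lesion_id,
            "suv_max": l.suv_max,
            "suv_mean": l.suv_mean,
            "volume_ml": l.volume_ml,
            "tlq_lesion": l.tlq_lesion,
        }
        for l in lesions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "scan_id", "timepoint", "lesion_id",
            "suv_max", "suv_mean", "volume_ml", "tlq_lesion",
        ],
    )
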