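"""Model assessment statistics and the acentric-factor definition.

The headline statistics are the average absolute percent deviation
AAD% = mean(100*|pred - exp|/|exp|), the root mean square error
RMSE = sqrt(mean((pred - exp)^2)), and counts of compounds whose absolute
percent deviation AD% falls above 10% or below 5% (strict inequalities, so
the three buckets <5%, [5%, 10%], >10% partition the set).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EvaluationReport:
    """Summary statistics plus per-compound deviations for one model/set."""

    n: int
    aad_percent: float
    rmse: float
    n_ad_gt_10: int
    n_ad_lt_5: int
    per_compound: pd.DataFrame  # columns: id, experimental, predicted, ad_percent, role
    flagged_small_denominator: list[str] = field(default_factory=list)

    @property
    def n_ad_mid(self) -> int:
        return self.n - self.n_ad_gt_10 - self.n_ad_lt_5


def evaluate(
    predicted,
    experimental,
    ids=None,
    roles=None,
    small_denominator: float = 0.05,
) -> EvaluationReport:
    """Compute AAD%, RMSE and the AD% bucket counts.

    AD% divides by |experimental|; an experimental value of exactly zero is
    an error, and compounds with |experimental| < ``small_denominator``
    (relevant for near-zero acentric factors, where percent deviations blow
    up) are listed in ``flagged_small_denominator``.
    """
    pred = np.asarray(predicted, dtype=float).ravel()
    exp = np.asarray(experimental, dtype=float).ravel()
    if len(pred) != len(exp):
        raise ValueError("predicted and experimental must have equal length")
    n = len(pred)
    if n == 0:
        raise ValueError("nothing to evaluate")
    if np.any(exp == 0):
        raise ValueError("experimental value of 0: AD% undefined")
    if ids is None:
        ids = [str(i) for i in range(n)]
    ids = [str(i) for i in ids]
    if roles is None:
        roles = [""] * n
    roles = list(roles)
    if len(ids) != n or len(roles) != n:
        raise ValueError("ids/roles must match data length")

    ad = 100.0 * np.abs(pred - exp) / np.abs(exp)
    rmse = float(np.sqrt(np.sum((pred - exp) ** 2) / n))
    table = pd.DataFrame(
        {"id": ids, "experimental": exp, "predicted": pred, "ad_percent": ad, "role": roles}
    )
    return EvaluationReport(
        n=n,
        aad_percent=float(ad.mean()),
        rmse=rmse,
        n_ad_gt_10=int(np.sum(ad > 10.0)),
        n_ad_lt_5=int(np.sum(ad < 5.0)),
        per_compound=table,
        flagged_small_denominator=[i for i, e in zip(ids, exp) if abs(e) < small_denominator],
    )


def acentric_factor_from_vp(reduced_vp_at_tr07: float) -> float:
    """Pitzer's definition: omega = -1 - log10 of the reduced saturation
    pressure evaluated at reduced temperature 0.7."""
    p = float(reduced_vp_at_tr07)
    if p <= 0:
        raise ValueError("reduced vapor pressure must be positive")
    return -1.0 - math.log10(p)


def parity_export(report: EvaluationReport, path) -> None:
    """Write (id, experimental, predicted, role) rows for parity plotting."""
    if report.n == 0:
        raise ValueError("empty report")
    report.per_compound[["id", "experimental", "predicted", "role"]].to_csv(path, index=False)


def report_to_dict(report: EvaluationReport) -> dict:
    """JSON-friendly summary (per-compound table included as records)."""
    return {
        "n": report.n,
        "aad_percent": report.aad_percent,
        "rmse": report.rmse,
        "n_ad_gt_10": report.n_ad_gt_10,
        "n_ad_lt_5": report.n_ad_lt_5,
        "flagged_small_denominator": report.flagged_small_denominator,
        "per_compound": report.per_compound.to_dict(orient="records"),
    }
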