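"""Paired-measurement error metrics and the bundled 20-fish reference study.

Automated measurements are scored against manual (caliper) ground truth with
three standard statistics over the n paired values per trait::

    RMSE = sqrt( sum (el_i - ml_i)^2 / n )        [cm]
    MAE  =       sum |el_i - ml_i|   / n          [cm]
    MRE  =       sum |el_i - ml_i| / ml_i / n     [dimensionless]

where ``el`` is the estimated and ``ml`` the manually measured value.  The
across-trait "average" row is the unweighted mean of the seven per-trait
statistics.

The module ships a reference study of 20 channel catfish (total length
12-17 cm): seven traits measured both manually and by the automated
dual-view pipeline.  It serves as a regression anchor for the metric
implementations and as example data; :func:`load_reference_pairs` checks the
file's SHA-256 before use.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "MeasurementPairs",
    "ErrorReport",
    "MetricsError",
    "rmse",
    "mae",
    "mre",
    "evaluate",
    "load_reference_table",
    "load_reference_pairs",
    "report_to_frame",
    "write_report",
]

#: Canonical trait order for reports.
CATEGORIES = ("FL", "BL", "BH", "BT", "HL", "THH", "THW")

#: Long display names for report output.
CATEGORY_TITLES = {
    "FL": "Full length",
    "BL": "Body length",
    "BH": "Body height",
    "BT": "Body thickness",
    "HL": "Head length",
    "THH": "Tail handle height",
    "THW": "Tail handle width",
}

_REFERENCE_CSV = "catfish20_measurements.csv"
_REFERENCE_SHA256 = "5fb2de378294a37bd5b6d898ca3bd00a2a29308cf901b9923a4b29a00986ebf4"


class MetricsError(ValueError):
    """Raised for empty, mismatched or non-positive-reference pairings."""


@dataclass(frozen=True)
class MeasurementPairs:
    """Paired estimated/manual values for one trait category."""

    category: str
    estimated: np.ndarray
    measured: np.ndarray

    def __post_init__(self) -> None:
        est = np.asarray(self.estimated, dtype=float)
        mea = np.asarray(self.measured, dtype=float)
        object.__setattr__(self, "estimated", est)
        object.__setattr__(self, "measured", mea)
        if est.ndim != 1 or mea.ndim != 1 or est.shape != mea.shape:
            raise MetricsError(
                f"{self.category}: estimated/measured must be equal-length 1-D, "
                f"got {est.shape} vs {mea.shape}"
            )
        if est.size == 0:
            raise MetricsError(f"{self.category}: empty pairing")

    @property
    def n(self) -> int:
        return int(self.estimated.size)


def rmse(pairs: MeasurementPairs) -> float:
    """Root mean square error, in cm."""
    d = pairs.estimated - pairs.measured
    return float(np.sqrt(np.mean(d * d)))


def mae(pairs: MeasurementPairs) -> float:
    """Mean absolute error, in cm."""
    return float(np.mean(np.abs(pairs.estimated - pairs.measured)))


def mre(pairs: MeasurementPairs) -> float:
    """Mean relative error (dimensionless), |el - ml| / ml averaged."""
    if np.any(pairs.measured <= 0):
        raise MetricsError(f"{pairs.category}: MRE needs strictly positive reference values")
    return float(np.mean(np.abs(pairs.estimated - pairs.measured) / pairs.measured))


@dataclass(frozen=True)
class ErrorReport:
    """Per-category MRE/MAE/RMSE plus their unweighted across-category means."""

    per_category: dict[str, dict[str, float]]  # category -> {MRE, MAE, RMSE, n}
    average: dict[str, float]  # {MRE, MAE, RMSE}


def evaluate(pairs_by_category: dict[str, MeasurementPairs] | list[MeasurementPairs]) -> ErrorReport:
    """Score every category and average the three metrics across categories."""
    if isinstance(pairs_by_category, dict):
        items = list(pairs_by_category.values())
    else:
        items = list(pairs_by_category)
    if not items:
        raise MetricsError("no categories to evaluate")
    per: dict[str, dict[str, float]] = {}
    for pairs in items:
        per[pairs.category] = {
            "MRE": mre(pairs),
            "MAE": mae(pairs),
            "RMSE": rmse(pairs),
            "n": pairs.n,
        }
    avg = {
        m: float(np.mean([per[c][m] for c in per])) for m in ("MRE", "MAE", "RMSE")
    }
    return ErrorReport(per_category=per, average=avg)


def load_reference_table() -> pd.DataFrame:
    """Load the bundled 20-fish manual-vs-automated measurement table.

    Columns are ``index`` plus ``manual_<trait>`` and ``auto_<trait>`` for
    the seven traits, values in cm.  The file's SHA-256 is verified so a
    corrupted installation fails loudly rather than shifting regression
    anchors.
    """
    ref = resources.files("fishmorph.data").joinpath(_REFERENCE_CSV)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _REFERENCE_SHA256:
        raise MetricsError(
            f"bundled reference table checksum mismatch: {digest} != {_REFERENCE_SHA256}"
        )
    import io

    return pd.read_csv(io.BytesIO(raw))


def load_reference_pairs() -> dict[str, MeasurementPairs]:
    """The bundled study as per-trait pairings (automated vs manual)."""
    table = load_reference_table()
    return {
        c: MeasurementPairs(
            category=c,
            estimated=table[f"auto_{c}"].to_numpy(),
            measured=table[f"manual_{c}"].to_numpy(),
        )
        for c in CATEGORIES
    }


def report_to_frame(report: ErrorReport) -> pd.DataFrame:
    """Report as a table: one row per category plus the Average row."""
    rows = []
    for c, stats in report.per_category.items():
        rows.append(
            {
                "category": CATEGORY_TITLES.get(c, c),
                "MRE": stats["MRE"],
                "MAE": stats["MAE"],
                "RMSE": stats["RMSE"],
                "n": stats["n"],
            }
        )
    rows.append({"category": "Average", **report.average, "n": np.nan})
    return pd.DataFrame(rows, columns=["category", "MRE", "MAE", "RMSE", "n"])


def write_report(report: ErrorReport, out_prefix: str | Path, meta: dict | None = None) -> None:
    """Write the report as ``<prefix>.csv`` and ``<prefix>.json``."""
    prefix = Path(out_prefix)
    report_to_frame(report).to_csv(prefix.with_suffix(".csv"), index=False)
    payload = {
        "per_category": report.per_category,
        "average": report.average,
    }
    if meta:
        payload["meta"] = meta
    prefix.with_suffix(".json").write_text(json.dumps(payload, indent=2) + "\n")
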