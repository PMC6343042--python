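"""Fermentation selectivity metrics and dehydrogenase activity arithmetic.

ABE (acetone–butanol–ethanol) fermentation summaries used to score
butanol-selective alcohol-dehydrogenase variants:

* B/E ratio — grams butanol per gram ethanol, the headline selectivity
  metric;
* butanol selectivity — butanol over total solvents
  (butanol + acetone + ethanol), bounded in [0, 1];
* butanol yield — grams butanol per gram glucose consumed;
* fold change of a metric over a baseline strain;
* dehydrogenase specific activity, where one unit (U) is the enzyme
  consuming 1 μmol NADH per minute, reported as mU per mg protein.

Titers are measured inputs (g/L); the module never predicts them.  Ratios
with zero or missing denominators are *flagged*, never raised, so whole
tables can be processed row-wise.  Values are kept at full precision;
rounding (half-to-even) is applied only when formatting reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

__all__ = [
    "FermentationRecord",
    "MetricReport",
    "AssayRecord",
    "be_ratio",
    "butanol_selectivity",
    "butanol_yield",
    "fold_change",
    "specific_activity",
    "rate_from_absorbance",
    "compute_metrics",
    "metrics_table",
]


@dataclass(frozen=True)
class FermentationRecord:
    """Per-strain titers in g/L; ``glucose_consumed`` is optional."""

    strain: str
    butanol: float
    acetone: float = 0.0
    ethanol: float = 0.0
    butyrate: float = 0.0
    acetate: float = 0.0
    glucose_consumed: float | None = None
    od600: float | None = None

    def __post_init__(self) -> None:
        for name in ("butanol", "acetone", "ethanol", "butyrate", "acetate"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValidationError(f"{self.strain}: {name} titer must be finite and >= 0")
        if self.glucose_consumed is not None:
            g = self.glucose_consumed
            if (isinstance(g, float) and math.isnan(g)):
                object.__setattr__(self, "glucose_consumed", None)
            elif g < 0:
                raise ValidationError(f"{self.strain}: glucose_consumed must be >= 0")


@dataclass(frozen=True)
class MetricReport:
    """Derived ratios for one strain; None + flag where undefined."""

    strain: str
    be_ratio: float | None
    butanol_selectivity: float | None
    butanol_yield: float | None
    undefined: frozenset[str] = frozenset()

    def rounded(self, ndigits: int = 2) -> dict:
        """Display rounding (banker's/half-to-even, Python's ``round``)."""
        def r(v):
            return None if v is None else round(v, ndigits)
        return {
            "strain": self.strain,
            "be_ratio": r(self.be_ratio),
            "butanol_selectivity": r(self.butanol_selectivity),
            "butanol_yield": r(self.butanol_yield),
            "undefined": sorted(self.undefined),
        }


def be_ratio(rec: FermentationRecord) -> float | None:
    """Butanol-to-ethanol mass ratio (g/g); None when ethanol is 0."""
    if rec.ethanol <= 0:
        return None
    return rec.butanol / rec.ethanol


def butanol_selectivity(rec: FermentationRecord) -> float | None:
    """Butanol over total solvents (g/g, in [0, 1]); None when no solvents."""
    total = rec.butanol + rec.acetone + rec.ethanol
    if total <= 0:
        return None
    return rec.butanol / total


def butanol_yield(rec: FermentationRecord) -> float | None:
    """Butanol produced per glucose consumed (g/g); None without glucose data."""
    if rec.glucose_consumed is None or rec.glucose_consumed <= 0:
        return None
    return rec.butanol / rec.glucose_consumed


def fold_change(value: float, baseline: float) -> float:
    """Ratio of a metric to its baseline-strain value."""
    if baseline <= 0 or not math.isfinite(baseline):
        raise ValidationError(f"fold_change baseline must be > 0, got {baseline}")
    return value / baseline


@dataclass(frozen=True)
class AssayRecord:
    """NADH-consumption assay: rate in μmol NADH/min, protein mass in mg."""

    nadh_rate: float
    protein_mass: float

    def __post_init__(self) -> None:
        if self.protein_mass <= 0 or not math.isfinite(self.protein_mass):
            raise ValidationError(f"protein_mass must be > 0, got {self.protein_mass}")
        if self.nadh_rate < 0 or not math.isfinite(self.nadh_rate):
            raise ValidationError(f"nadh_rate must be finite and >= 0, got {self.nadh_rate}")


def specific_activity(assay: AssayRecord) -> float:
    """Specific activity in mU per mg protein.

    1 U = 1 μmol NADH consumed per minute, so the rate in μmol/min *is* the
    activity in units; ×1000 converts to mU before dividing by protein mass.
    """
    return assay.nadh_rate * 1000.0 / assay.protein_mass


def rate_from_absorbance(delta_a340_per_min: float, extinction_mM_cm: float = 6.22,
                         path_cm: float = 1.0, volume_ml: float = 1.0) -> float:
    """Convert an A340 slope to μmol NADH/min via a user-supplied extinction
    coefficient (mM⁻¹ cm⁻¹; 6.22 is the textbook NADH value)."""
    if extinction_mM_cm <= 0 or path_cm <= 0 or volume_ml <= 0:
        raise ValidationError("extinction coefficient, path length and volume must be > 0")
    mM_per_min = delta_a340_per_min / (extinction_mM_cm * path_cm)
    return mM_per_min * volume_ml  # mM × mL = μmol


def compute_metrics(rec: FermentationRecord) -> MetricReport:
    """All derived ratios for one record, with undefined-value flags."""
    be = be_ratio(rec)
    sel = butanol_selectivity(rec)
    yld = butanol_yield(rec)
    undefined = set()
    if be is None:
        undefined.add("be_ratio")
    if sel is None:
        undefined.add("butanol_selectivity")
    if yld is None:
        undefined.add("butanol_yield")
    return MetricReport(rec.strain, be, sel, yld, frozenset(undefined))


def metrics_table(df: pd.DataFrame) -> pd.DataFrame:
    """Row-wise metrics for a titer table (schema from ``read_titer_table``).

    Returns the input columns plus ``be_ratio``, ``butanol_selectivity`` and
    ``butanol_yield`` (NaN where undefined).
    """
    records = []
    for _, row in df.iterrows():
        glucose = row.get("glucose_consumed")
        if glucose is not None and isinstance(glucose, float) and math.isnan(glucose):
            glucose = None
        rec = FermentationRecord(
            strain=str(row["strain"]),
            butanol=float(row["butanol"]),
            acetone=float(row.get("acetone", 0.0)),
            ethanol=float(row.get("ethanol", 0.0)),
            butyrate=float(row.get("butyrate", 0.0)),
            acetate=float(row.get("acetate", 0.0)),
            glucose_consumed=None if glucose is None else float(glucose),
        )
        rep = compute_metrics(rec)
        records.append(
            {
                "be_ratio": rep.be_ratio,
                "butanol_selectivity": rep.butanol_selectivity,
                "butanol_yield": rep.butanol_yield,
            }
        )
    out = df.copy()
    for col in ("be_ratio", "butanol_selectivity", "butanol_yield"):
        out[col] = [r[col] for r in records]
    return out
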