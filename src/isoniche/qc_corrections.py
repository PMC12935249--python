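"""Elemental QC and δ¹³C corrections for hair keratin samples.

Three stages, applied in this order:

1. **Atomic elemental ratios** from mass-percent C, N, S::

       C/N = (%C × 14.011) / (%N × 12.007)
       C/S = (%C × 32.060) / (%S × 12.007)
       N/S = (%N × 32.060) / (%S × 14.011)

   The atomic C/N ratio is the standard keratin-integrity check: intact
   hair keratin sits near 3.0–3.6; contamination (surface lipids, soil,
   degradation) drives it out of range.

2. **QC filtering**: a sample is retained iff its atomic C/N lies within
   the configured window (default 3.0–4.05), %C ≤ 50, %N ≤ 20, and a
   regional assignment is present. C/S and N/S windows are advisory by
   default: they flag but never exclude.

3. **δ¹³C corrections**: an affine lipid correction
   (``0.982·δ¹³C − 0.028``) removing the bias of ¹³C-depleted surface
   lipids, followed by a Suess-effect shift that restates each value
   relative to a pre-industrial atmospheric baseline so that samples from
   different collection years are comparable.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from .sample_io import IsotopeSample, SampleTable, ValidationError

__all__ = [
    "AtomicRatios",
    "QCConfig",
    "QCReport",
    "SuessModel",
    "atomic_ratios",
    "apply_qc",
    "lipid_correct",
    "suess_correct",
    "correct_table",
    "load_suess_model",
    "default_suess_model",
    "KERATIN_CN_WINDOW",
]

# Atomic masses used by the ratio formulas (u).
MASS_C = 12.007
MASS_N = 14.011
MASS_S = 32.060

#: General keratin acceptance window for atomic C/N cited in the hair
#: literature; the default QCConfig uses the wider 3.0–4.05 analysis window.
KERATIN_CN_WINDOW = (2.9, 3.6)

LIPID_SLOPE = 0.982
LIPID_INTERCEPT = -0.028


@dataclass(frozen=True)
class AtomicRatios:
    """Dimensionless atomic ratios; sulfur ratios absent without %S."""

    c_n: float
    c_s: float | None = None
    n_s: float | None = None


@dataclass(frozen=True)
class QCConfig:
    cn_min: float = 3.0
    cn_max: float = 4.05
    pctC_max: float = 50.0
    pctN_max: float = 20.0
    cs_range: tuple[float, float] = (300.0, 900.0)  # advisory
    ns_range: tuple[float, float] = (100.0, 300.0)  # advisory
    require_region: bool = True

    def __post_init__(self):
        if not self.cn_min < self.cn_max:
            raise ValueError("cn_min must be < cn_max")
        for lo, hi in (self.cs_range, self.ns_range):
            if not lo < hi:
                raise ValueError("interval lower bound must be < upper bound")


@dataclass
class SampleQC:
    sample_id: str
    retained: bool
    reasons: list[str] = field(default_factory=list)
    advisories: list[str] = field(default_factory=list)


@dataclass
class QCReport:
    per_sample: list[SampleQC]
    n_input: int
    n_retained: int
    n_excluded_by_reason: dict[str, int]

    def __post_init__(self):
        assert self.n_input == len(self.per_sample)
        assert self.n_retained == sum(q.retained for q in self.per_sample)


def atomic_ratios(pctC: float, pctN: float, pctS: float | None = None) -> AtomicRatios:
    """Atomic C/N (and, with %S, C/S and N/S) from mass percentages."""
    if pctC <= 0 or pctN <= 0:
        raise ValidationError(f"pctC and pctN must be positive (got {pctC}, {pctN})")
    c_n = (pctC * MASS_N) / (pctN * MASS_C)
    if pctS is None:
        return AtomicRatios(c_n=c_n)
    if pctS <= 0:
        raise ValidationError(f"pctS must be positive when supplied (got {pctS})")
    c_s = (pctC * MASS_S) / (pctS * MASS_C)
    n_s = (pctN * MASS_S) / (pctS * MASS_N)
    return AtomicRatios(c_n=c_n, c_s=c_s, n_s=n_s)


def qc_sample(sample: IsotopeSample, config: QCConfig = QCConfig()) -> SampleQC:
    """Retention decision with machine-readable reason codes for one sample."""
    ratios = atomic_ratios(sample.pctC, sample.pctN, sample.pctS)
    reasons: list[str] = []
    advisories: list[str] = []
    if not config.cn_min <= ratios.c_n <= config.cn_max:
        reasons.append("cn_out_of_range")
    if sample.pctC > config.pctC_max:
        reasons.append("pctC_high")
    if sample.pctN > config.pctN_max:
        reasons.append("pctN_high")
    if config.require_region and sample.region is None:
        reasons.append("missing_region")
    if ratios.c_s is not None and not config.cs_range[0] <= ratios.c_s <= config.cs_range[1]:
        advisories.append("cs_out_of_range")
    if ratios.n_s is not None and not config.ns_range[0] <= ratios.n_s <= config.ns_range[1]:
        advisories.append("ns_out_of_range")
    return SampleQC(sample.sample_id, retained=not reasons, reasons=reasons, advisories=advisories)


def apply_qc(table: SampleTable, config: QCConfig = QCConfig()) -> tuple[SampleTable, QCReport]:
    """Filter a table by the QC rules, preserving the order of retained rows.

    Every input row appears in the report exactly once; a non-retained
    sample carries at least one reason code. Idempotent: re-applying QC to
    the retained table excludes nothing further.
    """
    if len(table) == 0:
        raise ValidationError("cannot QC an empty table")
    decisions = [qc_sample(s, config) for s in table]
    retained = [s for s, q in zip(table, decisions) if q.retained]
    by_reason: dict[str, int] = {}
    for q in decisions:
        for r in q.reasons:
            by_reason[r] = by_reason.get(r, 0) + 1
    report = QCReport(
        per_sample=decisions,
        n_input=len(table),
        n_retained=len(retained),
        n_excluded_by_reason=by_reason,
    )
    return SampleTable(retained, table.provenance), report


def lipid_correct(d13C_measured: float) -> float:
    """Affine lipid correction: 0.982·δ¹³C_measured − 0.028 (‰)."""
    return LIPID_SLOPE * d13C_measured + LIPID_INTERCEPT


@dataclass(frozen=True)
class SuessModel:
    """Annual atmospheric δ¹³C series with a pre-industrial baseline.

    The correction adds back the fossil-fuel depletion accumulated by the
    sample's collection year: ``δ_cor = δ − (atm[year] − baseline)``.
    Later (more depleted) years therefore get larger positive shifts.
    """

    atm_series: dict[int, float]
    baseline: float = -6.4

    def __post_init__(self):
        for year, value in self.atm_series.items():
            if not -10.0 <= value <= -5.0:
                raise ValidationError(
                    f"atmospheric δ¹³C {value}‰ for {year} outside plausible [-10, -5]"
                )


def suess_correct(d13C_lipid_free: float, year: int, model: SuessModel) -> float:
    """Shift a δ¹³C value to the model's pre-industrial baseline."""
    if year not in model.atm_series:
        raise ValidationError(
            f"year {year} not covered by the atmospheric series "
            f"({min(model.atm_series)}–{max(model.atm_series)}); no extrapolation"
        )
    return d13C_lipid_free - (model.atm_series[year] - model.baseline)


def correct_table(table: SampleTable, model: SuessModel | None = None) -> SampleTable:
    """Apply lipid then Suess correction, writing ``d13C_cor`` on each sample.

    Samples without a collection year get the lipid correction only (their
    Suess shift is undefined); with a model supplied, a year outside the
    series is an error rather than silent passthrough.
    """
    if model is None:
        model = default_suess_model()
    out = []
    for s in table:
        v = lipid_correct(s.d13C_measured)
        if s.year is not None:
            v = suess_correct(v, s.year, model)
        out.append(replace(s, d13C_cor=v))
    return SampleTable(out, table.provenance)


def load_suess_model(path: str | Path, baseline: float = -6.4) -> SuessModel:
    """Load a two-column CSV (year, atmospheric δ¹³C ‰) as a SuessModel."""
    series: dict[int, float] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if len(header) < 2:
            raise ValidationError("Suess series CSV needs two columns: year, d13C_atm")
        for row in reader:
            if not row or not row[0].strip():
                continue
            series[int(row[0])] = float(row[1])
    if not series:
        raise ValidationError(f"no series rows in {path}")
    return SuessModel(atm_series=series, baseline=baseline)


def synthetic_atmospheric_series(start: int = 1850, end: int = 2023) -> dict[int, float]:
    """Smooth synthetic stand-in for the measured atmospheric δ¹³C record.

    Exponential decline from a −6.43‰ pre-industrial level,
    ``δ(t) = −6.429 − 0.006·exp(0.0217·(t − 1740))``, a parameterisation
    that tracks the well-documented fossil-fuel depletion (≈ −8.1‰ around
    2000). It is not measured data; substitute a measured annual series
    via :func:`load_suess_model` for publication-grade corrections.
    """
    return {
        t: -6.429 - 0.006 * math.exp(0.0217 * (t - 1740)) for t in range(start, end + 1)
    }


def default_suess_model() -> SuessModel:
    """Packaged synthetic atmospheric series (see data/ CSV), baseline −6.4‰."""
    ref = resources.files("isoniche.data").joinpath("suess_atmospheric_d13c_synthetic.csv")
    with resources.as_file(ref) as path:
        return load_suess_model(path)
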