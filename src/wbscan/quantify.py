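"""qPCR standard curves, noise filtering, normalization and specificity.

A qPCR standard curve is the least-squares line Ct = m * log10(c) + b over
a serial dilution; amplification efficiency E = 10^(-1/m) - 1 (m = -3.3219
at perfect doubling).  Quantities are back-computed from sample Cts by
inverting the fit.  Two chemistry-specific noise rules are applied before
any spatial reconstruction:

* hydrolysis-probe (TaqMan) and genomic assays run 40 cycles and any
  Ct > 35 is treated as noise;
* small-RNA and chemical-ligation assays run 50 cycles and a signal is
  noise unless its back-computed concentration falls inside the linear
  range of the assay's standard curve.

Per-well quantities are normalized against genomic 18S (a per-well
cell-content / extraction-efficiency reference), and figure-style outputs
scale tissue profiles to percent of the maximum averaged signal.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CHEMISTRIES",
    "CYCLE_MAX",
    "TAQMAN_CT_CUTOFF",
    "AmplificationRecord",
    "DilutionSeries",
    "StandardCurve",
    "CurveFitConfig",
    "NormalizedValue",
    "make_default_dilution_series",
    "fit_standard_curve",
    "quantify",
    "model_ct",
    "apply_noise_filters",
    "normalize_to_reference",
    "percent_of_max",
    "cross_reactivity_matrix",
    "read_plate_csv",
    "write_plate_csv",
]

#: Supported assay chemistries.
CHEMISTRIES = ("taqman", "genomic", "smallrna", "clqpcr")

#: PCR cycle count per chemistry; a censored ("Undetermined") reaction
#: means no amplification within this many cycles.
CYCLE_MAX = {"taqman": 40.0, "genomic": 40.0, "smallrna": 50.0, "clqpcr": 50.0}

#: Hydrolysis-probe / genomic noise threshold: Ct strictly above this is
#: discarded (35.0 itself is retained).
TAQMAN_CT_CUTOFF = 35.0

#: 1 zeptogram/ul in ng/ul.
ZG_PER_UL = 1e-12


@dataclass
class AmplificationRecord:
    """One well's qPCR result.  ``ct`` is None when censored."""

    well: str
    assay_id: str
    chemistry: str
    ct: float | None
    cycle_max: float | None = None
    noise: bool = False
    noise_reason: str = ""

    def __post_init__(self) -> None:
        if self.chemistry not in CHEMISTRIES:
            raise ValueError(f"unknown chemistry {self.chemistry!r}")
        if self.cycle_max is None:
            self.cycle_max = CYCLE_MAX[self.chemistry]
        if self.ct is not None and self.ct > self.cycle_max:
            raise ValueError(f"Ct {self.ct} exceeds cycle maximum {self.cycle_max}")

    @property
    def censored(self) -> bool:
        return self.ct is None


@dataclass
class DilutionSeries:
    """Replicate Cts at a strictly decreasing concentration ladder (ng/ul)."""

    concentrations: Sequence[float]
    cts: Sequence[Sequence[float | None]]  # replicate Cts per concentration
    diluent: str = "Poly(A)"
    assay_id: str = ""
    chemistry: str = "smallrna"

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if len(c) != len(self.cts):
            raise ValueError("one replicate list per concentration required")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        if len(c) > 1 and not np.all(np.diff(c) < 0):
            raise ValueError("concentrations must be strictly decreasing")

    def detection_fraction(self, i: int) -> float:
        reps = self.cts[i]
        if not reps:
            return 0.0
        return sum(ct is not None for ct in reps) / len(reps)

    def mean_ct(self, i: int) -> float:
        vals = [ct for ct in self.cts[i] if ct is not None]
        return float(np.mean(vals)) if vals else math.nan


def make_default_dilution_series(
    top: float = 10.0, bottom: float = ZG_PER_UL, fold: float = 10.0
) -> list[float]:
    """Geometric dilution ladder from ``top`` down to the first value <= ``bottom``.

    Defaults give the 14-point, 10-fold ladder from 10 ng/ul to 1 zg/ul.
    """
    if not (top >= bottom > 0):
        raise ValueError("need top >= bottom > 0")
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    concs = [top]
    # tolerate float drift at the bottom boundary
    while concs[-1] > bottom * (1 + 1e-9):
        concs.append(concs[-1] / fold)
    return concs


@dataclass(frozen=True)
class CurveFitConfig:
    """Linear-range detection settings for standard-curve fitting.

    The linear range is the longest contiguous run of usable concentration
    points whose joint fit keeps every residual within ``max_residual_ct``
    and R^2 at or above ``min_r_squared``.  A point is usable when its
    replicate detection fraction reaches ``detection_fraction`` (1.0: every
    replicate must amplify).
    """

    max_residual_ct: float = 0.5
    min_r_squared: float = 0.98
    min_points: int = 4
    detection_fraction: float = 1.0
    max_efficiency: float = 1.1


@dataclass(frozen=True)
class StandardCurve:
    slope: float                     # delta-Ct per log10(concentration)
    intercept: float                 # Ct at 1 ng/ul
    r_squared: float
    efficiency: float                # fraction; 1.0 = 100 %
    linear_range: tuple[float, float]  # (low, high) concentrations, ng/ul
    lod: float | None                # lowest reliably detected concentration
    assay_id: str = ""

    def in_linear_range(self, concentration: float) -> bool:
        low, high = self.linear_range
        # boundaries are exact by design; tiny relative slack only guards
        # against float round-trip drift
        return low * (1 - 1e-12) <= concentration <= high * (1 + 1e-12)


def _window_fit(logc: np.ndarray, ct: np.ndarray) -> tuple[float, float, float, np.ndarray]:
    res = stats.linregress(logc, ct)
    pred = res.slope * logc + res.intercept
    return res.slope, res.intercept, res.rvalue**2, ct - pred


def fit_standard_curve(
    series: DilutionSeries, config: CurveFitConfig = CurveFitConfig()
) -> StandardCurve:
    """Fit Ct = slope * log10(c) + intercept over the detected linear range."""
    usable = [
        i
        for i in range(len(series.concentrations))
        if series.detection_fraction(i) >= config.detection_fraction
    ]
    if len(usable) < config.min_points:
        raise ValueError(
            f"only {len(usable)} usable concentration points; need >= {config.min_points}"
        )
    conc = np.asarray([series.concentrations[i] for i in usable], dtype=float)
    mean_ct = np.asarray([series.mean_ct(i) for i in usable], dtype=float)
    logc = np.log10(conc)

    best: tuple[int, int] | None = None  # (start, stop) over usable points
    n = len(usable)
    for length in range(n, config.min_points - 1, -1):
        for start in range(0, n - length + 1):
            sl = slice(start, start + length)
            slope, intercept, r2, resid = _window_fit(logc[sl], mean_ct[sl])
            if (
                slope < 0
                and r2 >= config.min_r_squared
                and np.all(np.abs(resid) <= config.max_residual_ct)
            ):
                best = (start, start + length)
                break
        if best is not None:
            break
    if best is None:
        raise ValueError("no contiguous run of points satisfies the linearity rules")

    sl = slice(*best)
    slope, intercept, r2, _ = _window_fit(logc[sl], mean_ct[sl])
    efficiency = 10 ** (-1.0 / slope) - 1.0
    low = float(conc[sl].min())
    high = float(conc[sl].max())

    # LOD: lowest concentration (anywhere on the ladder) whose replicate
    # detection fraction clears the threshold.
    detected = [
        series.concentrations[i]
        for i in range(len(series.concentrations))
        if series.detection_fraction(i) >= config.detection_fraction
    ]
    lod = float(min(detected)) if detected else None

    return StandardCurve(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        efficiency=float(efficiency),
        linear_range=(low, high),
        lod=lod,
        assay_id=series.assay_id,
    )


def model_ct(concentration: float, curve: StandardCurve) -> float:
    """Forward model: expected Ct at a concentration."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    return curve.slope * math.log10(concentration) + curve.intercept


def quantify(ct: float | None, curve: StandardCurve) -> float:
    """Back-compute concentration from a Ct: c = 10^((ct - b) / m)."""
    if ct is None:
        raise ValueError("cannot quantify a censored (no-amplification) record")
    return 10 ** ((ct - curve.intercept) / curve.slope)


def apply_noise_filters(
    records: Iterable[AmplificationRecord],
    curves: Mapping[str, StandardCurve] | None = None,
    ct_cutoff: float = TAQMAN_CT_CUTOFF,
) -> list[AmplificationRecord]:
    """Flag noise wells per the chemistry-specific rules.

    Censored records are always noise.  TaqMan/genomic records are noise
    when Ct is strictly greater than ``ct_cutoff`` (default 35; Ct 35.0 is
    retained).  Small-RNA and CL-qPCR records are noise when their
    back-computed concentration falls outside the linear range of the
    assay's standard curve, which must be supplied.  Idempotent.
    """
    out = []
    curves = curves or {}
    for rec in records:
        rec = replace(rec, noise=False, noise_reason="")
        if rec.censored:
            rec.noise = True
            rec.noise_reason = "no amplification"
        elif rec.chemistry in ("taqman", "genomic"):
            if rec.ct > ct_cutoff:
                rec.noise = True
                rec.noise_reason = f"Ct {rec.ct:g} > {ct_cutoff:g}"
        else:  # smallrna / clqpcr: linear-range rule
            curve = curves.get(rec.assay_id)
            if curve is None:
                raise ValueError(
                    f"assay {rec.assay_id!r} ({rec.chemistry}) requires a standard curve"
                )
            conc = quantify(rec.ct, curve)
            if not curve.in_linear_range(conc):
                rec.noise = True
                rec.noise_reason = (
                    f"quantity {conc:.3g} outside linear range "
                    f"[{curve.linear_range[0]:.3g}, {curve.linear_range[1]:.3g}]"
                )
        out.append(rec)
    return out


@dataclass(frozen=True)
class NormalizedValue:
    raw_quantity: float | None
    reference_quantity: float | None
    ratio: float | None
    valid: bool


def _record_quantity(
    rec: AmplificationRecord, curves: Mapping[str, StandardCurve] | None
) -> float | None:
    if rec.noise or rec.censored:
        return None
    if curves and rec.assay_id in curves:
        return quantify(rec.ct, curves[rec.assay_id])
    return None


def normalize_to_reference(
    target: Iterable[AmplificationRecord],
    reference: Iterable[AmplificationRecord],
    curves: Mapping[str, StandardCurve] | None = None,
    method: str = "quantity-ratio",
) -> dict[str, NormalizedValue]:
    """Per-well target / genomic-18S normalization.

    ``quantity-ratio`` divides back-computed quantities (needs curves for
    both assays); ``ddct`` uses 2^-(Ct_target - Ct_reference), the standard
    curve-free fallback.  A well is invalid whenever either record is
    noise-flagged, censored or absent.
    """
    tmap = {r.well: r for r in target}
    rmap = {r.well: r for r in reference}
    wells = sorted(set(tmap) & set(rmap))
    if not wells:
        raise ValueError("target and reference share no wells")
    out: dict[str, NormalizedValue] = {}
    for w in wells:
        t, r = tmap[w], rmap[w]
        if t.noise or r.noise or t.censored or r.censored:
            out[w] = NormalizedValue(None, None, None, False)
            continue
        if method == "quantity-ratio":
            qt = _record_quantity(t, curves)
            qr = _record_quantity(r, curves)
            if qt is None or qr is None or qr <= 0:
                out[w] = NormalizedValue(qt, qr, None, False)
                continue
            out[w] = NormalizedValue(qt, qr, qt / qr, True)
        elif method == "ddct":
            ratio = 2.0 ** (-(t.ct - r.ct))
            out[w] = NormalizedValue(None, None, ratio, True)
        else:
            raise ValueError(f"unknown normalization method {method!r}")
    return out


def percent_of_max(profile: Mapping[str, float | None]) -> dict[str, float | None]:
    """Scale a per-tissue profile so the maximum valid value is 100."""
    valid = {k: v for k, v in profile.items() if v is not None and not math.isnan(v)}
    if not valid:
        raise ValueError("profile has no valid values")
    top = max(valid.values())
    if top <= 0:
        raise ValueError("maximum signal must be positive")
    return {
        k: (100.0 * v / top if v is not None and not math.isnan(v) else None)
        for k, v in profile.items()
    }


def cross_reactivity_matrix(
    panel: Mapping[tuple[str, str], float],
    matched: Mapping[str, str],
) -> pd.DataFrame:
    """Cross-reactivity in percent of each primer set's matched target.

    ``panel`` maps (primer_set, template) to a back-computed quantity
    (0 or NaN meaning below LOD / noise); ``matched`` names each primer
    set's perfect-match template.  Matched pairs are scaled to 100 %.
    """
    primer_sets = sorted(matched)
    templates = sorted({t for _, t in panel})
    mat = pd.DataFrame(0.0, index=primer_sets, columns=templates)
    for p in primer_sets:
        m = matched[p]
        base = panel.get((p, m))
        if base is None or not np.isfinite(base) or base <= 0:
            raise ValueError(f"matched quantity missing or zero for primer set {p!r}")
        for t in templates:
            q = panel.get((p, t), 0.0)
            if q is None or not np.isfinite(q) or q < 0:
                q = 0.0
            mat.loc[p, t] = 100.0 * q / base
    return mat


# ---------------------------------------------------------------------------
# plate-reader export I/O (SDS-style CSV dialect)
# ---------------------------------------------------------------------------

_HEADER_SENTINEL = "well"


def read_plate_csv(
    path_or_buf,
    assay_info: Mapping[str, tuple[str, float]] | None = None,
    sep: str = ",",
) -> list[AmplificationRecord]:
    """Read a plate-reader Ct export.

    Lines before the header are skipped until a line whose first field is
    ``Well`` (the SDS export preamble).  Required columns: Well, Detector
    (or Assay), Ct; "Undetermined" marks a censored reaction.  Optional
    Chemistry / CycleMax columns override ``assay_info``, which maps
    assay id -> (chemistry, cycle_max).
    """
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    start = None
    for i, line in enumerate(lines):
        first = line.split(sep)[0].strip().lower()
        if first == _HEADER_SENTINEL:
            start = i
            break
    if start is None:
        raise ValueError("no header line starting with 'Well' found")
    df = pd.read_csv(io.StringIO("\n".join(lines[start:])), sep=sep, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    assay_col = "detector" if "detector" in df.columns else "assay"
    if assay_col not in df.columns or "ct" not in df.columns:
        raise ValueError("need Well, Detector/Assay and Ct columns")
    records = []
    for _, row in df.iterrows():
        assay = str(row[assay_col]).strip()
        raw_ct = str(row["ct"]).strip()
        ct = None if raw_ct.lower() in ("undetermined", "", "nan") else float(raw_ct)
        if "chemistry" in df.columns and isinstance(row.get("chemistry"), str):
            chem = row["chemistry"].strip()
            cmax = float(row["cyclemax"]) if "cyclemax" in df.columns else CYCLE_MAX[chem]
        elif assay_info and assay in assay_info:
            chem, cmax = assay_info[assay]
        else:
            raise ValueError(
                f"chemistry for assay {assay!r} not in file or assay_info"
            )
        records.append(
            AmplificationRecord(
                well=str(row["well"]).strip(), assay_id=assay, chemistry=chem,
                ct=ct, cycle_max=cmax,
            )
        )
    return records


def write_plate_csv(records: Iterable[AmplificationRecord], path, preamble: str = "") -> None:
    """Write records in the same dialect :func:`read_plate_csv` accepts."""
    with open(path, "w") as fh:
        if preamble:
            for line in preamble.splitlines():
                fh.write(f"# {line}\n")
        fh.write("Well,Detector,Ct,Chemistry,CycleMax\n")
        for rec in records:
            ct = "Undetermined" if rec.ct is None else f"{rec.ct:.6f}"
            fh.write(f"{rec.well},{rec.assay_id},{ct},{rec.chemistry},{rec.cycle_max:g}\n")
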