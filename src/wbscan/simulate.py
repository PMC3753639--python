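"""Synthetic whole-body sections and forward qPCR models.

Every stage of the scanning-PCR pipeline can be exercised end to end
without animal data: a stylized 363-cell sagittal mouse section is labeled
with contiguous organ regions, an expression atlas assigns per-tissue
abundances to each target, and a log-linear assay model turns effective
abundance into replicate Cts with Gaussian noise and censoring at the
chemistry's cycle maximum.

The forward model is

    Ct = intercept + slope * log10(A_eff) + N(0, sd),   censored at cycle_max

with A_eff = extraction_efficiency * (abundance + sum of cross-reactive
contributions).  Zero effective abundance never amplifies.  The same model
generates dilution ladders for standard curves, cross-reactivity panels,
end-truncation panels (detection collapses beyond a tolerance of 2 nt,
mirroring the assay's requirement for a nearly intact 3'/5' terminus) and
an antagomir dosing scenario that depletes miR-16 everywhere except the
brain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    AnalysisLayout,
    SectionMatrix,
    build_default_section_matrix,
    map_to_analysis_plate,
)
from .quantify import (
    CYCLE_MAX,
    AmplificationRecord,
    DilutionSeries,
)

__all__ = [
    "TISSUES",
    "TissuedSection",
    "ExpressionAtlas",
    "AssayModel",
    "DoseScenario",
    "make_default_section",
    "default_atlas",
    "default_assay_models",
    "simulate_ct",
    "simulate_dilution_series",
    "simulate_cross_reactivity_panel",
    "simulate_truncation_panel",
    "apply_scenario",
]

TISSUES = (
    "brain",
    "spinal_cord",
    "heart",
    "lung",
    "liver",
    "kidney",
    "spleen",
    "muscle",
    "GI",
    "blood",
    "tumor",
    "background",
)


@dataclass
class TissuedSection:
    """A section matrix whose sample cells carry tissue labels and
    per-cell extraction efficiencies (multiplicative, > 0)."""

    matrix: SectionMatrix
    labels: dict[tuple[int, int], str]
    efficiency: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        cells = set(self.matrix.sample_order)
        if set(self.labels) != cells:
            raise ValueError("every sample cell must carry a tissue label")
        if any(e <= 0 for e in self.efficiency.values()):
            raise ValueError("extraction efficiencies must be positive")

    def organ_mask(self, tissue: str) -> np.ndarray:
        m = np.zeros(self.matrix.shape, dtype=bool)
        for cell, lab in self.labels.items():
            if lab == tissue:
                m[cell] = True
        return m

    def tissues_present(self) -> list[str]:
        return sorted(set(self.labels.values()))


@dataclass
class ExpressionAtlas:
    """Per-(target, tissue) abundances in standard-curve units (ng/ul)."""

    abundance: dict[str, dict[str, float]]  # target -> tissue -> ng/ul
    chemistry: dict[str, str]               # target -> assay chemistry

    def level(self, target: str, tissue: str) -> float:
        return self.abundance.get(target, {}).get(tissue, 0.0)

    def targets(self) -> list[str]:
        return sorted(self.abundance)

    def copy(self) -> "ExpressionAtlas":
        return ExpressionAtlas(
            {t: dict(v) for t, v in self.abundance.items()},
            dict(self.chemistry),
        )


@dataclass(frozen=True)
class AssayModel:
    """Log-linear Ct response of one assay."""

    assay_id: str
    chemistry: str = "smallrna"
    slope: float = -3.3219280948873623  # -1/log10(2): perfect doubling
    intercept: float = 20.0             # Ct at 1 ng/ul
    noise_sd: float = 0.2
    cross_reactivity: Mapping[str, float] = field(default_factory=dict)
    truncation_tolerance: int = 2

    @property
    def cycle_max(self) -> float:
        return CYCLE_MAX[self.chemistry]

    def matched_target(self) -> str:
        return self.assay_id

    def ct_for(self, abundance: float, rng: np.random.Generator | None = None) -> float | None:
        """One draw from the forward model; None when censored."""
        if abundance <= 0:
            return None
        ct = self.intercept + self.slope * math.log10(abundance)
        if rng is not None and self.noise_sd > 0:
            ct += rng.normal(0.0, self.noise_sd)
        if ct > self.cycle_max:
            return None
        return max(ct, 1.0)


@dataclass(frozen=True)
class DoseScenario:
    """Antagomir dosing: knock the targeted miRNA down outside spared
    tissues and deposit the dosed oligonucleotide itself."""

    treatment: str = "amo"               # "amo" | "vehicle"
    target: str = "miR-16"
    knockdown: float = 0.9
    spared: tuple[str, ...] = ("brain",)
    control: str = "miR-191"
    amo_target: str = "AMO-miR-16"
    amo_abundance: float = 1e-3          # deposited level outside spared tissues
    plasma_c0: float = 1.0               # ng/ul at t = 0
    plasma_lod: float = 1e-4
    plasma_horizon_h: float = 1.0        # undetectable within this many hours


# ---------------------------------------------------------------------------
# default section, atlas and assay panel
# ---------------------------------------------------------------------------

def _paint_organs(matrix: SectionMatrix) -> dict[tuple[int, int], str]:
    """Deterministic contiguous organ regions on the silhouette window."""
    shapes = [
        # (tissue, cy, cx, ry, rx) — first match wins
        ("brain", 7.5, 5.0, 2.6, 3.2),
        ("heart", 13.5, 12.0, 1.7, 1.9),
        ("lung", 10.5, 12.5, 2.2, 2.7),
        ("liver", 13.0, 16.5, 2.6, 3.1),
        ("kidney", 10.0, 22.0, 1.8, 2.3),
        ("spleen", 13.2, 21.0, 1.2, 1.5),
        ("GI", 16.0, 18.0, 2.7, 4.2),
        ("tumor", 8.0, 27.0, 1.5, 1.9),
    ]
    labels: dict[tuple[int, int], str] = {}
    for r, c in matrix.sample_order:
        lab = None
        for tissue, cy, cx, ry, rx in shapes:
            if ((r - cy) / ry) ** 2 + ((c - cx) / rx) ** 2 <= 1.0:
                lab = tissue
                break
        if lab is None:
            if r <= 7 and 9 <= c <= 27:
                lab = "spinal_cord"
            elif r == 12 and 13 <= c <= 14:
                lab = "blood"
            else:
                lab = "muscle"
        labels[(r, c)] = lab
    return labels


def make_default_section(
    seed: int = 0,
    brain_efficiency: float = 1.3,
    organ_cv: float = 0.0,
) -> TissuedSection:
    """The packaged 363-cell mouse section with organ labels.

    Extraction efficiency defaults to 1 everywhere with a mild elevation in
    the brain (higher cell density / extraction yield), which is exactly
    the bias genomic-18S normalization is meant to cancel.  ``organ_cv``
    adds seeded lognormal organ-level variation on top.
    """
    matrix = build_default_section_matrix()
    labels = _paint_organs(matrix)
    rng = np.random.default_rng(seed)
    organ_factor = {t: 1.0 for t in TISSUES}
    organ_factor["brain"] = brain_efficiency
    if organ_cv > 0:
        for t in sorted(organ_factor):
            organ_factor[t] *= float(rng.lognormal(0.0, organ_cv))
    efficiency = {cell: organ_factor[labels[cell]] for cell in matrix.sample_order}
    return TissuedSection(matrix, labels, efficiency)


# expressed level in curve units; well inside the default linear range
_HI = 1e-3
_LO = 0.0


def default_atlas() -> ExpressionAtlas:
    """Qualitative tissue-specific expression presets.

    miR-122 is liver-restricted, miR-208a heart-restricted, miR-124
    brain-restricted, miR-16 and miR-191 ubiquitous; genomic 18S is the
    uniform per-cell reference.  Abundances are two presence levels (0 or
    1e-3 ng/ul), not fitted organ magnitudes.
    """
    everywhere = {t: _HI for t in TISSUES}
    abundance = {
        "18S": dict(everywhere),
        "miR-122": {t: (_HI if t == "liver" else _LO) for t in TISSUES},
        "miR-208a": {t: (_HI if t == "heart" else _LO) for t in TISSUES},
        "miR-124": {t: (_HI if t == "brain" else _LO) for t in TISSUES},
        "miR-16": dict(everywhere),
        "miR-191": dict(everywhere),
        "AMO-miR-16": {t: _LO for t in TISSUES},
    }
    chemistry = {
        "18S": "genomic",
        "miR-122": "smallrna",
        "miR-208a": "smallrna",
        "miR-124": "smallrna",
        "miR-16": "smallrna",
        "miR-191": "smallrna",
        "AMO-miR-16": "clqpcr",
    }
    return ExpressionAtlas(abundance, chemistry)


def default_assay_models(noise_sd: float = 0.2) -> dict[str, AssayModel]:
    atlas = default_atlas()
    return {
        t: AssayModel(assay_id=t, chemistry=atlas.chemistry[t], noise_sd=noise_sd)
        for t in atlas.targets()
    }


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def simulate_ct(
    section: TissuedSection,
    atlas: ExpressionAtlas,
    model: AssayModel,
    seed: int = 0,
    layout: AnalysisLayout | None = None,
) -> list[AmplificationRecord]:
    """Simulate one assay across every sample well of the section.

    Records are keyed by analysis-plate well labels (via the layout's
    sample mapping), closing the loop with the scan pipeline.
    """
    if model.assay_id not in atlas.abundance:
        raise ValueError(f"atlas lacks target {model.assay_id!r}")
    if layout is None:
        layout = map_to_analysis_plate(section.matrix)
    rng = np.random.default_rng(seed)
    records = []
    for i, cell in enumerate(section.matrix.sample_order):
        tissue = section.labels[cell]
        a = atlas.level(model.assay_id, tissue)
        for other, frac in model.cross_reactivity.items():
            a += frac * atlas.level(other, tissue)
        a *= section.efficiency[cell]
        ct = model.ct_for(a, rng)
        records.append(
            AmplificationRecord(
                well=layout.well_for_sample(i).label,
                assay_id=model.assay_id,
                chemistry=model.chemistry,
                ct=ct,
            )
        )
    return records


def simulate_dilution_series(
    model: AssayModel,
    concentrations: Sequence[float],
    replicates: int = 3,
    seed: int = 0,
) -> DilutionSeries:
    """Replicate Cts from the forward model at each ladder concentration."""
    rng = np.random.default_rng(seed)
    cts = [
        [model.ct_for(c, rng) for _ in range(replicates)]
        for c in concentrations
    ]
    return DilutionSeries(
        concentrations=list(concentrations),
        cts=cts,
        assay_id=model.assay_id,
        chemistry=model.chemistry,
    )


def simulate_cross_reactivity_panel(
    models: Mapping[str, AssayModel],
    matched: Mapping[str, str],
    template_abundance: float = _HI,
    seed: int = 0,
    replicates: int = 4,
) -> dict[tuple[str, str], list[float | None]]:
    """Every primer set against every single template, in isolation.

    Returns replicate Cts per (primer_set, template); effective abundance
    is the template level scaled by the primer set's cross-reactivity
    fraction (1 for the matched pair).
    """
    rng = np.random.default_rng(seed)
    templates = sorted(set(matched.values()) | {
        t for m in models.values() for t in m.cross_reactivity
    })
    panel: dict[tuple[str, str], list[float | None]] = {}
    for p in sorted(models):
        model = models[p]
        for t in templates:
            if t == matched[p]:
                frac = 1.0
            else:
                frac = model.cross_reactivity.get(t, 0.0)
            a = frac * template_abundance
            panel[(p, t)] = [model.ct_for(a, rng) for _ in range(replicates)]
    return panel


def simulate_truncation_panel(
    template_length: int,
    depths: Iterable[int],
    model: AssayModel,
    seed: int = 0,
    abundance: float = _HI,
    end: str = "3p",
) -> dict[int, AmplificationRecord]:
    """Detectability of end-truncated targets at a fixed input amount.

    Removing up to ``truncation_tolerance`` nucleotides from either end
    (or both, for ``end='both'``) leaves detection intact; deeper
    truncation collapses the effective abundance to zero and the reaction
    censors.
    """
    if end not in ("3p", "5p", "both"):
        raise ValueError("end must be '3p', '5p' or 'both'")
    rng = np.random.default_rng(seed)
    out = {}
    for d in depths:
        if not (0 <= d <= template_length):
            raise ValueError(f"depth {d} outside 0..{template_length}")
        a = abundance if d <= model.truncation_tolerance else 0.0
        ct = model.ct_for(a, rng)
        out[d] = AmplificationRecord(
            well=f"T{d}_{end}",
            assay_id=model.assay_id,
            chemistry=model.chemistry,
            ct=ct,
        )
    return out


def apply_scenario(
    atlas: ExpressionAtlas, scenario: DoseScenario
) -> tuple[ExpressionAtlas, pd.DataFrame]:
    """Apply a dosing scenario to an atlas; returns (atlas, plasma table).

    Under treatment, the targeted miRNA is multiplied by (1 - knockdown)
    in every tissue except the spared set, the control target is left
    untouched, and the dosed oligonucleotide is deposited in every
    non-spared tissue.  The plasma time-course is a single-exponential
    decay whose rate is set so the level crosses the assay LOD within the
    configured horizon.
    """
    if scenario.target not in atlas.abundance:
        raise ValueError(f"unknown target {scenario.target!r}")
    out = atlas.copy()
    times_h = np.array([0.0, 5 / 60, 10 / 60, 0.5, 1.0, 4.0, 6.0, 24.0])
    if scenario.treatment == "vehicle":
        plasma = pd.DataFrame({"time_h": times_h, "concentration": 0.0})
        return out, plasma
    for tissue in out.abundance[scenario.target]:
        if tissue not in scenario.spared:
            out.abundance[scenario.target][tissue] *= 1.0 - scenario.knockdown
    if scenario.amo_target in out.abundance:
        for tissue in out.abundance[scenario.amo_target]:
            out.abundance[scenario.amo_target][tissue] = (
                0.0 if tissue in scenario.spared else scenario.amo_abundance
            )
    # decay rate: cross LOD at 90 % of the horizon
    k = math.log(scenario.plasma_c0 / scenario.plasma_lod) / (0.9 * scenario.plasma_horizon_h)
    conc = scenario.plasma_c0 * np.exp(-k * times_h)
    plasma = pd.DataFrame({"time_h": times_h, "concentration": conc})
    return out, plasma
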