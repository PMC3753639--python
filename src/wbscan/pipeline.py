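"""End-to-end scan: plate records -> filtered, normalized section grids.

Ties the quantification rules and the spatial reconstruction together the
way a scanning-PCR run is actually analysed: fit standard curves from the
reference wells (or accept pre-fitted ones), flag noise wells per
chemistry, back-compute quantities, normalize each target against genomic
18S well by well, and place the results on the section grid.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .geometry import AnalysisLayout, SectionMatrix
from .imaging import ValueGrid, grid_from_records
from .quantify import (
    AmplificationRecord,
    StandardCurve,
    apply_noise_filters,
    normalize_to_reference,
    quantify,
)

__all__ = ["scan_section"]


def scan_section(
    records_by_assay: Mapping[str, Iterable[AmplificationRecord]],
    matrix: SectionMatrix,
    layout: AnalysisLayout,
    curves: Mapping[str, StandardCurve] | None = None,
    reference_assay: str | None = "18S",
    method: str = "quantity-ratio",
) -> dict[str, ValueGrid]:
    """Reconstruct one normalized grid per non-reference assay.

    When ``reference_assay`` is set, every other assay is normalized
    against it per well (wells whose reference is noise become invalid);
    otherwise grids carry raw back-computed quantities.  Returns a grid
    per assay, keyed by assay id.
    """
    curves = curves or {}
    filtered = {
        assay: apply_noise_filters(list(recs), curves)
        for assay, recs in records_by_assay.items()
    }
    if reference_assay is not None and reference_assay not in filtered:
        raise ValueError(
            f"normalization requested but reference assay {reference_assay!r} "
            "has no records"
        )
    grids: dict[str, ValueGrid] = {}
    for assay, recs in filtered.items():
        if assay == reference_assay:
            continue
        if reference_assay is not None:
            normalized = normalize_to_reference(
                recs, filtered[reference_assay], curves, method=method
            )
            grids[assay] = grid_from_records(
                normalized, matrix, layout, assay_id=assay,
                normalization=f"{reference_assay}-{method}",
            )
        else:
            values = {
                r.well: (
                    quantify(r.ct, curves[assay])
                    if (not r.noise and not r.censored and assay in curves)
                    else None
                )
                for r in recs
            }
            grids[assay] = grid_from_records(
                values, matrix, layout, assay_id=assay, normalization="raw",
            )
    return grids
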