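# wbscan

Toolkit for **whole-body scanning PCR (WBS-PCR)**: a biodistribution imaging
approach in which a frozen sagittal whole-body section of a mouse is placed
on a pre-filled 1536-well plate, the tissue exposed to each well is lysed in
place, lysates are transferred to a 384-well qPCR plate, and the per-well
qPCR signals are reassembled into a spatial image of where an RNA or a
therapeutic oligonucleotide actually went.

The package is for scientists running (or simulating) such scans who need:

* **Assay design** for small RNAs (miRNA / siRNA) — an RT primer with a
  generic 5′ tail plus a 3′ *target-recognition sequence* (TRS,
  default 8 nt, range 6–12, with palindromic 3′-tetramer avoidance), a
  fluorophore-labelled forward primer (gene-specific region ≥ 12 nt,
  RT-primer overlap ≤ 3 nt) quenched by a BHQ-2 anti-primer — and
  **chemical-ligation qPCR (CL-qPCR)** ligator pairs (3′-phosphorothioate /
  5′-biphenylsulphonyl) for heavily modified oligonucleotides that no
  polymerase will read.
* **Quantification** — log-linear standard curves
  `Ct = m·log₁₀(c) + b` with amplification efficiency
  `E = 10^(−1/m) − 1`, automatic linear-range and LOD detection,
  chemistry-specific noise rules (TaqMan/genomic: Ct > 35 is noise at
  40 cycles; small-RNA/CL-qPCR: signals outside the standard curve's linear
  range are noise at 50 cycles), per-well normalization against genomic 18S,
  percent-of-max tissue profiles and cross-reactivity matrices.
* **Spatial reconstruction** — 363-well section matrices on the 1536 grid,
  deterministic mapping onto a 384-well analysis plate (363 samples +
  20 reference wells + 1 blank), value grids, PNG rendering and photo
  overlay, TSV and Analyze 7.5 export.
* **Simulation** — a synthetic 363-cell mouse section with contiguous organ
  regions, tissue-specific expression presets, censored log-linear Ct
  responses, cross-reactivity, end-truncation detection collapse and an
  antagomir dosing scenario, so the whole pipeline is testable end to end.

## Worked example

Design the small-RNA assay for miR-16 (`UAGCAGCACGUAAAUAUUGGCG`):

```bash
printf '>miR-16\nUAGCAGCACGUAAAUAUUGGCG\n' > mir16.fa
wbscan design mir16.fa --out design_out
```

prints the itemized rule report:

```
PASS    trs_length_bounds       TRS length 8
PASS    trs_matches_template_3prime
PASS    rt_3prime_not_palindromic       3' tetramer AATA
PASS    rt_tail_nonpriming
PASS    gene_specific_min_length        16 nt
PASS    overlap_with_rt_at_most_3       2 nt overlap
PASS    forward_3prime_not_palindromic
PASS    generic_region_complements_anti_primer
PASS    gene_specific_matches_template_5prime
PASS    overall
```

The TRS is the 8-nt reverse complement of the template's 3′ end
(`CGCCAATA`); the forward primer carries a 16-nt gene-specific region that
overlaps the RT primer footprint by only 2 nt; the generic region
`CTCCCTCCCTCGATTT` is the exact reverse complement of the anti-primer core
`AAATCGAGGGAGGGAG`.

Designing CL-qPCR ligators for the miR-16 antagomir
(`CGCCAAUAUUUACGUGCUGCUA`, the fully complementary 2′-MOE oligo):

```bash
printf 'CGCCAAUAUUUACGUGCUGCUA\n' > amo.fa
wbscan design amo.fa --ligators --junction-offset -1 --out ligator_out
```

emits `PS-ligator TTAAACCATAGCAGCACG` (3′-phosphorothioate) and
`BPS-ligator TAAATATTGGCGAACCAGT` (5′-biphenylsulphonyl): their
target-binding cores (10 nt + 12 nt) concatenate gaplessly to the
antagomir's reverse complement.

Simulate a full scan and reconstruct it:

```bash
wbscan simulate --seed 1 --noise-sd 0.1 --out sim
wbscan scan sim/records.csv --matrix sim/section_matrix.tsv \
    --layout sim/layout.tsv --standards sim/standards.csv --out scan_out
```

`sim/records.csv` holds 2541 well records (7 assays × 363 wells);
`scan_out/` then contains one 18S-normalized grid TSV and PNG per assay —
the liver-restricted miR-122 lights up only the liver region of the
silhouette, and the brain-elevated extraction efficiency visible in raw 18S
signals cancels out of every normalized image.

## Layout

| module | contents |
|---|---|
| `wbscan.geometry` | plate formats, well labels, section matrix, 384-well layout |
| `wbscan.design` | RT/forward/anti-primer and PS/BPS ligator design + validation |
| `wbscan.quantify` | standard curves, noise filters, 18S normalization, cross-reactivity |
| `wbscan.imaging` | value grids, rendering, photo overlay, TSV/Analyze export |
| `wbscan.simulate` | synthetic sections, atlases, forward Ct models, dosing scenarios |
| `wbscan.pipeline` | records → filtered, normalized section grids |
| `wbscan.cli` | `wbscan design / simulate / fit-curve / scan / render / smoke` |

See `docs/methods.md` for the underlying models, defaults and limitations.
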