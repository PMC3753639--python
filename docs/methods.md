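# Methods

## The measurement being modeled

Whole-body scanning PCR deconvolutes a 40-µm whole-body cryosection into
per-well tissue lysates on a 1536-well plate, quantifies a target in each
lysate by qPCR on a 384-well plate, and reassembles the signals into an
image. A mouse section typically covers 363 wells of the 1536 grid; on the
384-well analysis plate this leaves 20 wells for reference samples or
standards. `wbscan` implements the computational side of that platform:
assay design, per-well quantification with the platform's filtering and
normalization rules, and spatial reconstruction, plus a simulator that
generates statistically realistic synthetic runs.

## Plate geometry

Plate formats carry ANSI/SLAS physical geometry (1536-well pitch 2.25 mm,
384-well pitch 4.5 mm, standard A1 offsets); these defaults matter only for
photo overlay and are configurable. Well labels are A1-style with rows
A…Z, AA…AF on the 1536 grid.

The packaged section matrix is a stylized sagittal mouse silhouette on a
22-row × 33-column window of the 1536 grid, built from a fixed union of
ellipses and trimmed deterministically (cells farthest from the centroid
first, row-major tie-break) to exactly 363 cells. The real laboratory
matrix is drawn by hand around each section; any user-supplied mask of any
size is accepted, the packaged template just pins the canonical cell count.
Sample cells are enumerated row-major; the analysis layout fills the
384-well plate column-major (A1, B1, … P1, A2, …) with samples, then 20
reference wells, then 1 blank. 363 + 20 = 383, so one well of the 384 is
always left; making it an explicit blank honors the published 20-reference
accounting while keeping the role partition total. Both enumeration orders
are fixed so every export is reproducible byte for byte.

## Assay design rules

**RT primer.** The target-recognition sequence (TRS) is the reverse
complement of the template's 3′-terminal slice; default 8 nt, valid range
6–12. If the primer's 3′ tetramer is one of the eight self-complementary
motifs (ccgg, aatt, ggcc, ttaa, atat, tata, cgcg, gcgc) the TRS length is
adjusted — +1 first, then −1, then the remaining lengths 6–12 in order —
until the terminus is clean. The resolution order is a deterministic choice
of this package; the underlying rule only requires a single-nucleotide
adjustment. The generic 5′ tail is drawn from a small shipped library
(the laboratory tail sequence is not public); a tail is accepted only if it
shares no complementary run of ≥ 6 nt with the template (it must not prime
on the target) and lifts the full primer's nearest-neighbor melting
temperature (Biopython `Tm_NN`, 50 mM Na⁺, 2.5 mM Mg²⁺, 250 nM primer)
to ≥ 50 °C. The 50 °C floor is our default; the design rationale for the
tail is only "raise the Tm and balance G/C content".

**Forward primer.** Generic 5′ region = reverse complement of the
anti-primer core `AAATCGAGGGAGGGAG` (so unincorporated forward primers are
quenched by the BHQ-2-labelled anti-primer); gene-specific 3′ region = the
DNA copy of the template's 5′ portion, ≥ 12 nt, chosen *maximal* subject to
overlapping the TRS footprint by ≤ 3 template positions and a clean 3′
tetramer. Overlap is counted in template coordinates as positions covered
by both the gene-specific region and the TRS footprint. Maximality is a
package choice; fixed-length designs fit the same constraints.

**CL-qPCR ligators.** The analyte's reverse complement is split at
`floor(n/2) + junction_offset` into the PS-ligator core (gets a generic 5′
tail and the 3′-phosphorothioate) and the BPS-ligator core (5′-biphenyl-
sulphonyl plus generic 3′ tail); each core must be ≥ 8 nt and the tails
must not hybridize to the analyte (no ≥ 6-nt complementary run). The
published miR-16 antagomir pair (cores 10 + 12 nt of a 22-mer) corresponds
to `junction_offset = -1`, and the default tails are that pair's printed
tails. A self-reverse-complementary analyte makes the two cores each
other's reverse complements; the design is returned with a warning flag
since the two ligators can then template on each other.

`validate_assay` re-checks every rule independently of the designers, so
the closure property (designer output always validates) is a real test,
not a tautology.

## Quantification

Standard curves are ordinary least squares of mean Ct against
log₁₀(concentration). The *linear range* is the longest contiguous run of
usable ladder points (≥ 4) whose joint fit keeps every residual within
0.5 Ct and R² ≥ 0.98, searched longest-first, leftmost tie-break; a ladder
point is usable when all replicates amplified (detection fraction 1.0,
configurable). These linearity thresholds are package definitions — the
platform's protocol invokes a linear range without defining one — and are
exposed in `CurveFitConfig`. Efficiency is `10^(−1/slope) − 1`; the LOD is
the lowest concentration whose replicate detection fraction clears the
threshold. Concentrations are canonical ng/µl (1 zg/µl = 10⁻¹² ng/µl
exactly).

Noise rules: censored reactions are always noise; TaqMan/genomic wells with
Ct strictly greater than 35 are noise ("bigger than 35" is read literally,
so Ct = 35.0 is retained and the boundary is pinned by test);
small-RNA/CL-qPCR wells are noise when the back-computed quantity falls
outside the assay's linear range. The filter is idempotent and logs a
reason per well.

Normalization divides back-computed target quantity by back-computed
genomic-18S quantity per well (quantity ratio); when no curves exist the
2^(−ΔCt) fallback is available. Which of the two the original platform used
is not documented, so both are exposed; the quantity ratio is the default
because it respects per-assay efficiencies. Percent-of-max scales a
per-tissue profile so the largest valid mean is 100 %. Cross-reactivity
matrices scale each primer set's row to its perfect-match quantity
(diagonal ≡ 100 %); replicate quantities are averaged before the ratio.

## Spatial reconstruction

Per-well values are routed through the inverse layout mapping onto the
section window; reference and blank wells never reach the grid; noise and
missing wells become invalid (NaN) cells. Rendering is per-well
nearest-neighbor blocks (the plate's true resolution — no smoothing),
max-normalized so images are invariant under global rescaling; invalid
cells are transparent or bottom-of-colormap. Photo overlay uses a
scale-plus-translation registration (the plate lies flat on the sealed
photo); alpha 0 returns the photo bit-exactly, alpha 1 paints the
rendering. Grids export as TSV (NaN sentinel round-trips) and optionally
as Analyze 7.5 `.hdr`/`.img` pairs (little-endian float32, via nibabel)
for imaging viewers.

## Simulator

The default synthetic section labels the 363 silhouette cells with
contiguous organ regions (brain, spinal cord, heart, lung, liver, kidney,
spleen, GI, tumor, blood, muscle) painted from fixed ellipses.
Extraction efficiency defaults to 1 everywhere with a 1.3× elevation in
the brain, emulating the elevated genomic-18S signals that tissue density
differences produce in real sections — exactly the bias 18S normalization
exists to cancel; `organ_cv` adds seeded lognormal organ-level variation.

The forward model is `Ct = intercept + slope·log₁₀(A_eff) + N(0, σ)`
censored at the chemistry's cycle maximum (40 for TaqMan/genomic, 50 for
small-RNA/CL-qPCR), with `A_eff = efficiency × (abundance + Σ
cross-reactive contributions)`; cross-reactivity enters as additive
effective abundance before the log, the simplest model consistent with a
percentage readout. Defaults: slope −3.3219 (perfect doubling), intercept
20 Ct at 1 ng/µl, σ = 0.2 Ct. With these defaults the detectable range
spans 10 decades (10 ng/µl down to the 10⁻⁹ ng/µl censoring boundary on
the 50-cycle chemistries). Expression presets are qualitative two-level
(absent / 10⁻³ ng/µl) tissue patterns — liver-restricted miR-122,
heart-restricted miR-208a, brain-restricted miR-124, ubiquitous miR-16 and
miR-191 — not fitted organ magnitudes, since the per-organ abundances
behind the published profiles are not public.

End-truncation is modeled as a hard detection collapse: removing up to
2 nt from either end leaves the effective abundance unchanged, anything
deeper sets it to zero. The real assay shows a rapid but not perfectly
sharp sensitivity loss; the tolerance and the collapse are configurable.

The dosing scenario multiplies the targeted miRNA by (1 − knockdown) in
every tissue except the spared set (default: brain), deposits the dosed
antagomir in all non-spared tissues, leaves the control target untouched,
and generates a single-exponential plasma decay whose rate is set to cross
the assay LOD within a 1-hour horizon. This is a toy kinetic used to
exercise the CL-qPCR quantification path, not a pharmacokinetic model.

All simulator randomness flows through `numpy.random.default_rng(seed)`;
identical seeds give bit-identical outputs.

## What the synthetic tests do and do not show

Passing the end-to-end suites shows that the *computational* pipeline is
internally consistent: signals placed in an organ come back in that organ,
normalization cancels multiplicative extraction bias exactly, configured
knockdowns and cross-reactivities are recovered through the curve-fit
path. It does not validate lysis chemistry, extraction efficiency in real
tissue, polymerase behavior on modified templates, or diffusion between
wells — the simulator assumes none of these fail. Problem sizes (363-cell
sections, 14-point ladders, 50 fit repetitions, 100-template design
panels) were chosen as representative single-run scales; everything
completes in seconds.

## Known limitations

* No secondary-structure (hairpin/dimer) screening beyond the stated
  rules; no ligation kinetics; no Ct-calling from raw fluorescence —
  Ct values are inputs.
* Registration is scale + translation only; no histological warping.
* The packaged silhouette and organ map are stylized; real sections need
  user-supplied masks and photos.
* Group statistics (rank-sum / t tests across animals) are out of scope;
  use standard statistics packages on exported tables.
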