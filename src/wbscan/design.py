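"""Design rules for small-RNA RT-qPCR assays and chemical-ligation qPCR.

The small-RNA assay uses three oligos (Fig.-style architecture):

* an RT primer, doubling as the PCR reverse primer, built from a generic
  5' tail plus a 3' target-recognition sequence (TRS) complementary to the
  small RNA's 3' terminus;
* a fluorophore-labelled forward primer, a generic 5' region (the reverse
  complement of the quencher anti-primer) plus a gene-specific 3' region
  matching the template's 5' portion;
* a quencher-labelled anti-primer that silences unincorporated forward
  primers so fluorescence tracks double-stranded product.

Chemical-ligation qPCR (CL-qPCR) detects heavily modified oligonucleotides
(e.g. fully 2'-MOE antagomirs) that no polymerase will read: two DNA
ligators hybridize side-by-side on the analyte, a 3'-phosphorothioate
attacks the neighbour's 5'-biphenylsulphonyl leaving group, and the
carbon-sulphur-linked product is quantified by ordinary PCR.

All sequence bookkeeping is 5'->3' strings; reverse complements go through
Biopython.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as mt

__all__ = [
    "PALINDROME_BLOCKLIST",
    "DEFAULT_ANTI_PRIMER_CORE",
    "DEFAULT_TAIL_LIBRARY",
    "SmallRNATemplate",
    "RTPrimerDesign",
    "ForwardPrimerDesign",
    "AntiPrimer",
    "LigatorPair",
    "DesignConfig",
    "design_rt_primer",
    "design_forward_primer",
    "design_ligators",
    "validate_assay",
    "ValidationReport",
]

#: 3'-terminal tetramers that are their own reverse complement; a primer
#: ending in one of these self-anneals and the assay underperforms.
PALINDROME_BLOCKLIST = frozenset(
    {"ccgg", "aatt", "ggcc", "ttaa", "atat", "tata", "cgcg", "gcgc"}
)

#: Quencher-labelled anti-primer core (BHQ-2 at the 3' end).
DEFAULT_ANTI_PRIMER_CORE = "AAATCGAGGGAGGGAG"

#: Candidate generic 5' tails for the RT primer.  A tail is acceptable for
#: a given template only if it shares no complementary run of 6 nt or more
#: with it (it must not prime anywhere on the target).
DEFAULT_TAIL_LIBRARY = (
    "GCGAGCTGAGGTCGCACA",
    "CAGGTCCAGTTTCCGCGA",
    "GGCTGACCTCAGGTGCAG",
)

_DNA = {"A", "C", "G", "T"}


def _to_dna(seq: str) -> str:
    """Upper-case DNA copy of an RNA or DNA string (U -> T)."""
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - _DNA
    if bad:
        raise ValueError(f"non-ACGT/U characters in sequence: {sorted(bad)}")
    return s


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _longest_complementary_run(a: str, b: str) -> int:
    """Length of the longest perfect duplex between oligos ``a`` and ``b``.

    Equivalent to the longest common substring of ``a`` and revcomp(b).
    """
    rb = _revcomp(b)
    best = 0
    # O(len(a)*len(b)) dynamic program; primer-scale inputs only
    prev = [0] * (len(rb) + 1)
    for ca in a:
        cur = [0]
        for j, cb in enumerate(rb):
            v = prev[j] + 1 if ca == cb else 0
            cur.append(v)
            if v > best:
                best = v
        prev = cur
    return best


@dataclass(frozen=True)
class SmallRNATemplate:
    """A small-RNA (or single-strand oligonucleotide) target, 5'->3'."""

    sequence: str
    name: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.strip().upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - (_DNA | {"U"})
        if bad:
            raise ValueError(f"ambiguity codes not allowed: {sorted(bad)}")
        if not (16 <= len(seq) <= 30):
            raise ValueError(f"template length {len(seq)} outside 16-30 nt")

    @property
    def dna(self) -> str:
        return _to_dna(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AntiPrimer:
    core: str = DEFAULT_ANTI_PRIMER_CORE
    quencher_label: str = "BHQ2"


@dataclass(frozen=True)
class DesignConfig:
    """Tunable designer parameters.

    ``tm_min`` is the minimum acceptable melting temperature of the full RT
    primer in deg C (nearest-neighbor estimate); the generic tail exists to
    lift a short TRS above it.
    """

    trs_default: int = 8
    trs_min: int = 6
    trs_max: int = 12
    min_gene_specific: int = 12
    max_overlap: int = 3
    tm_min: float = 50.0
    na_mM: float = 50.0
    mg_mM: float = 2.5
    primer_nM: float = 250.0
    tail_library: tuple[str, ...] = DEFAULT_TAIL_LIBRARY
    min_core: int = 8
    junction_offset: int = 0
    ps_tail: str = "TTAAACCA"
    bps_tail: str = "AACCAGT"


@dataclass(frozen=True)
class RTPrimerDesign:
    trs: str
    trs_length: int
    generic_tail: str
    full_sequence: str
    tm_estimate: float
    template: SmallRNATemplate


@dataclass(frozen=True)
class ForwardPrimerDesign:
    generic_region: str
    gene_specific_region: str
    gene_specific_length: int
    overlap_with_rt: int
    full_sequence: str
    fluorophore_label: str = "FAM"


@dataclass(frozen=True)
class LigatorPair:
    ps_ligator: str          # 5' tail + upstream core, 3'-phosphorothioate
    bps_ligator: str         # 5'-biphenylsulphonyl, downstream core + 3' tail
    ps_core: str
    bps_core: str
    junction_index: int      # analyte position where the cores abut
    ligated_product: str
    palindromic_warning: bool = False


def _tm(seq: str, cfg: DesignConfig) -> float:
    return mt.Tm_NN(
        Seq(seq),
        Na=cfg.na_mM,
        Mg=cfg.mg_mM,
        dnac1=cfg.primer_nM,
        dnac2=0,
    )


def _terminal_tetramer_blocked(seq: str) -> bool:
    return len(seq) >= 4 and seq[-4:].lower() in PALINDROME_BLOCKLIST


def design_rt_primer(
    template: SmallRNATemplate, config: DesignConfig = DesignConfig()
) -> RTPrimerDesign:
    """Design the RT/reverse primer for a small-RNA template.

    The TRS is the reverse complement of the template's 3'-terminal slice,
    8 nt by default.  If the primer would end in a palindromic tetramer the
    TRS is extended by one nucleotide, then shortened by one, then the
    remaining lengths 6-12 are scanned, until the 3' terminus clears the
    blocklist.
    """
    n = len(template)
    if n < 16:
        raise ValueError(f"template too short ({n} nt; need >= 16)")
    tdna = template.dna

    tried: list[int] = []
    candidates = [config.trs_default, config.trs_default + 1, config.trs_default - 1]
    candidates += [
        k for k in range(config.trs_min, config.trs_max + 1) if k not in candidates
    ]
    chosen = None
    for k in candidates:
        if not (config.trs_min <= k <= config.trs_max) or k > n:
            continue
        trs = _revcomp(tdna[-k:])
        tried.append(k)
        if not _terminal_tetramer_blocked(trs):
            chosen = (k, trs)
            break
    if chosen is None:
        raise ValueError(
            f"no TRS length in {config.trs_min}-{config.trs_max} clears the "
            f"palindrome blocklist (tried {tried})"
        )
    k, trs = chosen

    tail = None
    for cand in config.tail_library:
        if _longest_complementary_run(cand, tdna) >= 6:
            continue
        if _tm(cand + trs, config) >= config.tm_min:
            tail = cand
            break
    if tail is None:
        raise ValueError("no generic tail in the library satisfies the Tm/complementarity rules")

    full = tail + trs
    return RTPrimerDesign(
        trs=trs,
        trs_length=k,
        generic_tail=tail,
        full_sequence=full,
        tm_estimate=_tm(full, config),
        template=template,
    )


def design_forward_primer(
    template: SmallRNATemplate,
    rt: RTPrimerDesign,
    anti: AntiPrimer = AntiPrimer(),
    config: DesignConfig = DesignConfig(),
) -> ForwardPrimerDesign:
    """Design the fluorophore-labelled forward primer.

    The gene-specific 3' region is the DNA copy of the template's 5'
    portion, maximal in length subject to overlapping the TRS footprint by
    at most ``max_overlap`` nt and not ending in a blocklisted tetramer.
    The generic 5' region is the reverse complement of the anti-primer
    core, so product-free forward primers are quenched.
    """
    if rt.template.sequence != template.sequence:
        raise ValueError("RT primer was designed for a different template")
    n = len(template)
    tdna = template.dna
    trs_start = n - rt.trs_length  # TRS footprint = template[trs_start:]
    generic = _revcomp(anti.core)

    end_max = min(n, trs_start + config.max_overlap)
    for end in range(end_max, config.min_gene_specific - 1, -1):
        region = tdna[:end]
        if len(region) < config.min_gene_specific:
            break
        if _terminal_tetramer_blocked(region):
            continue
        overlap = max(0, end - trs_start)
        return ForwardPrimerDesign(
            generic_region=generic,
            gene_specific_region=region,
            gene_specific_length=end,
            overlap_with_rt=overlap,
            full_sequence=generic + region,
        )
    raise ValueError(
        f"no gene-specific region of >= {config.min_gene_specific} nt with "
        f"<= {config.max_overlap} nt RT overlap exists for this template"
    )


def design_ligators(
    analyte: SmallRNATemplate, config: DesignConfig = DesignConfig()
) -> LigatorPair:
    """Split the analyte's reverse complement into a PS/BPS ligator pair.

    The full reverse complement of the analyte is cut at
    ``floor(n/2) + junction_offset``: the 5' part becomes the PS ligator
    core (3'-phosphorothioate, preceded by a generic 5' tail) and the 3'
    part the BPS ligator core (5'-biphenylsulphonyl, followed by a generic
    3' tail).  The ligated product is the seamless concatenation.
    """
    n = len(analyte)
    if n < 16:
        raise ValueError(f"analyte too short ({n} nt; need >= 16)")
    comp = _revcomp(analyte.dna)
    junction = n // 2 + config.junction_offset
    ps_core = comp[:junction]
    bps_core = comp[junction:]
    if len(ps_core) < config.min_core or len(bps_core) < config.min_core:
        raise ValueError(
            f"junction {junction} leaves a core below {config.min_core} nt"
        )
    for tail, where in ((config.ps_tail, "PS"), (config.bps_tail, "BPS")):
        if _longest_complementary_run(tail, analyte.dna) >= 6:
            raise ValueError(f"{where} tail hybridizes to the analyte (>= 6-nt run)")
    warning = ps_core == _revcomp(bps_core)
    return LigatorPair(
        ps_ligator=config.ps_tail + ps_core,
        bps_ligator=bps_core + config.bps_tail,
        ps_core=ps_core,
        bps_core=bps_core,
        junction_index=junction,
        ligated_product=config.ps_tail + comp + config.bps_tail,
        palindromic_warning=warning,
    )


@dataclass
class ValidationReport:
    checks: dict[str, bool] = field(default_factory=dict)
    messages: dict[str, str] = field(default_factory=dict)

    @property
    def overall_pass(self) -> bool:
        return all(self.checks.values()) if self.checks else False

    def add(self, name: str, ok: bool, message: str = "") -> None:
        self.checks[name] = bool(ok)
        if message:
            self.messages[name] = message

    def as_text(self) -> str:
        lines = []
        for name, ok in self.checks.items():
            status = "PASS" if ok else "FAIL"
            msg = self.messages.get(name, "")
            lines.append(f"{status}\t{name}" + (f"\t{msg}" if msg else ""))
        lines.append(("PASS" if self.overall_pass else "FAIL") + "\toverall")
        return "\n".join(lines)


def validate_assay(
    template: SmallRNATemplate,
    rt: RTPrimerDesign | None = None,
    forward: ForwardPrimerDesign | None = None,
    anti: AntiPrimer = AntiPrimer(),
    ligators: LigatorPair | None = None,
    config: DesignConfig = DesignConfig(),
) -> ValidationReport:
    """Itemized rule-compliance report for a design bundle."""
    rep = ValidationReport()
    tdna = template.dna
    n = len(template)

    if rt is not None:
        rep.add(
            "trs_length_bounds",
            config.trs_min <= rt.trs_length <= config.trs_max,
            f"TRS length {rt.trs_length}",
        )
        rep.add(
            "trs_matches_template_3prime",
            rt.trs == _revcomp(tdna[-rt.trs_length:]),
        )
        rep.add(
            "rt_3prime_not_palindromic",
            not _terminal_tetramer_blocked(rt.full_sequence),
            f"3' tetramer {rt.full_sequence[-4:]}",
        )
        rep.add(
            "rt_tail_nonpriming",
            _longest_complementary_run(rt.generic_tail, tdna) < 6,
        )
    if forward is not None:
        rep.add(
            "gene_specific_min_length",
            forward.gene_specific_length >= config.min_gene_specific,
            f"{forward.gene_specific_length} nt",
        )
        if rt is not None:
            trs_start = n - rt.trs_length
            overlap = max(0, forward.gene_specific_length - trs_start)
            rep.add(
                "overlap_with_rt_at_most_3",
                overlap <= config.max_overlap,
                f"{overlap} nt overlap",
            )
        rep.add(
            "forward_3prime_not_palindromic",
            not _terminal_tetramer_blocked(forward.full_sequence),
        )
        rep.add(
            "generic_region_complements_anti_primer",
            forward.generic_region == _revcomp(anti.core),
        )
        rep.add(
            "gene_specific_matches_template_5prime",
            tdna.startswith(forward.gene_specific_region[: forward.gene_specific_length])
            and forward.gene_specific_region == tdna[: forward.gene_specific_length],
        )
    if ligators is not None:
        rep.add(
            "ligator_cores_cover_analyte",
            ligators.ps_core + ligators.bps_core == _revcomp(tdna),
            "cores must concatenate gaplessly to the analyte's reverse complement",
        )
        rep.add(
            "ligator_core_min_length",
            len(ligators.ps_core) >= config.min_core
            and len(ligators.bps_core) >= config.min_core,
        )
        ps_tail = ligators.ps_ligator[: len(ligators.ps_ligator) - len(ligators.ps_core)]
        bps_tail = ligators.bps_ligator[len(ligators.bps_core):]
        rep.add(
            "ligator_tails_nonhybridizing",
            _longest_complementary_run(ps_tail, tdna) < 6
            and _longest_complementary_run(bps_tail, tdna) < 6,
        )
    return rep
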