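"""The structured prioritization workflow for SNVs and small indels.

The cascade applies, in order: virtual panel -> population frequency ->
clinical classification -> inheritance-aware zygosity consistency ->
compound-heterozygote pairing (with trio phasing when a pedigree is
available) -> deterministic ranking. Each stage is a pure subset filter
except compound-het pairing, which can retire a heterozygote whose only
retention rationale was a pair later shown to be in cis.

Candidates surviving the cascade are classified into one case outcome:
POSITIVE (genotype-complete pathogenic/likely-pathogenic configuration),
UNCERTAIN (genotype-complete configuration involving a VUS), PARTIAL
(monoallelic likely causative variant in an autosomal recessive gene),
UNSOLVED, or CARRIER_FINDINGS for carrier-screening referrals.
"""

from __future__ import annotations

import enum
import itertools
import logging
from dataclasses import dataclass, field

from .panels import ExceptionFlag, Mode, PanelLibrary, VirtualPanel, merge_panels, apply_panel
from .types import (
    AnnotatedVariant,
    CaseMode,
    ClinClass,
    Pedigree,
    SampleCase,
    Sex,
    Zygosity,
)

logger = logging.getLogger(__name__)

#: in-silico predictor labels counted as a deleterious vote during ranking
DELETERIOUS_LABELS = {"deleterious", "damaging", "probably_damaging", "d"}

# flag vocabulary
NO_FREQUENCY_DATA = "NO_FREQUENCY_DATA"
FREQUENCY_EXCEPTION = "FREQUENCY_EXCEPTION"
ZYGOSITY_EXCEPTION = "ZYGOSITY_EXCEPTION"
MONOALLELIC = "MONOALLELIC"
COMPHET_CANDIDATE = "COMPHET_CANDIDATE"
PHASE_UNKNOWN = "PHASE_UNKNOWN"
NEEDS_CONFIRMATION = "NEEDS_CONFIRMATION"
VAF_OUT_OF_RANGE = "VAF_OUT_OF_RANGE"
SEX_INCONSISTENT = "SEX_INCONSISTENT"

FUNNEL_STAGES = ("raw", "panel", "frequency", "classification", "zygosity", "final")


@dataclass
class FilterConfig:
    """Thresholds for the automatic filtering steps.

    Frequency ceilings are per inheritance mode: a variant in a gene with
    several modes is judged against the most permissive ceiling among them.
    Variant-allele-fraction bands flag (never drop) suspicious genotypes.
    Candidates surviving at depth below ``min_confirm_depth`` are flagged for
    orthogonal (Sanger) confirmation.
    """

    maf_max: dict[Mode, float] = field(
        default_factory=lambda: {
            Mode.AD: 0.001,
            Mode.AR: 0.01,
            Mode.XLD: 0.001,
            Mode.XLR: 0.01,
        }
    )
    het_vaf_range: tuple[float, float] = (0.3, 0.7)
    hom_vaf_min: float = 0.8
    min_confirm_depth: int = 20
    drop_classes: frozenset[ClinClass] = frozenset({ClinClass.B, ClinClass.LB})
    keep_cip_only_with_plp: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.het_vaf_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"bad het VAF band {self.het_vaf_range}")
        for m, t in self.maf_max.items():
            if not (0.0 <= t <= 1.0):
                raise ValueError(f"maf_max[{m}] out of [0,1]: {t}")
        if self.min_confirm_depth < 0:
            raise ValueError("min_confirm_depth must be >= 0")


class Phase(str, enum.Enum):
    TRANS = "TRANS"
    CIS = "CIS"
    UNKNOWN = "UNKNOWN"


@dataclass
class CompHetPair:
    """An unordered within-gene pair of heterozygotes with its phase call."""

    gene: str
    key_a: tuple[str, int, str, str]
    key_b: tuple[str, int, str, str]
    phase: Phase = Phase.UNKNOWN

    @property
    def keys(self) -> frozenset:
        return frozenset((self.key_a, self.key_b))


@dataclass
class Candidate:
    variant: AnnotatedVariant
    panel_modes: set[Mode] = field(default_factory=set)
    gene_flags: set[ExceptionFlag] = field(default_factory=set)
    pairing: tuple[str, int, str, str] | None = None
    rank: int = 0
    flags: set[str] = field(default_factory=set)


@dataclass
class FunnelReport:
    """Per-stage surviving variant counts along the filter cascade."""

    stages: list[tuple[str, int]]

    def __post_init__(self) -> None:
        counts = [c for _, c in self.stages]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError(f"funnel counts increase along cascade: {counts}")

    def count(self, stage: str) -> int:
        for name, c in self.stages:
            if name == stage:
                return c
        raise KeyError(stage)


class OutcomeLabel(str, enum.Enum):
    POSITIVE = "POSITIVE"
    UNCERTAIN = "UNCERTAIN"
    PARTIAL = "PARTIAL"
    UNSOLVED = "UNSOLVED"
    CARRIER_FINDINGS = "CARRIER_FINDINGS"


@dataclass
class CaseOutcome:
    label: OutcomeLabel
    supporting: list[Candidate] = field(default_factory=list)


class Segregation(str, enum.Enum):
    CONSISTENT = "CONSISTENT"
    INCONSISTENT = "INCONSISTENT"
    UNINFORMATIVE = "UNINFORMATIVE"


def _plp(v: AnnotatedVariant) -> bool:
    return v.clin_class in (ClinClass.P, ClinClass.LP)


def filter_frequency(
    variants: list[AnnotatedVariant],
    panel: VirtualPanel,
    cfg: FilterConfig,
) -> list[AnnotatedVariant]:
    """Drop variants too common for any inheritance mode of their gene.

    A variant survives when its largest population frequency is at or below
    the most permissive ceiling among its gene's modes, when its gene carries
    an exception flag (previously reported pathogenic alleles, hypomorphic
    alleles, incomplete penetrance), or when no frequency record exists at
    all (flagged ``NO_FREQUENCY_DATA`` — absence of a database entry must not
    hide a candidate).
    """
    kept = []
    for v in variants:
        entry = panel.entry(v.gene)
        if entry is None:
            continue  # pre: panel-filtered; unmatched genes cannot be judged
        if v.max_maf is None:
            v.flags.add(NO_FREQUENCY_DATA)
            kept.append(v)
            continue
        ceiling = max(cfg.maf_max[m] for m in entry.modes)
        if v.max_maf <= ceiling:
            kept.append(v)
        elif entry.exception_flags:
            v.flags.add(FREQUENCY_EXCEPTION)
            kept.append(v)
    return kept


def filter_classification(
    variants: list[AnnotatedVariant], cfg: FilterConfig
) -> list[AnnotatedVariant]:
    """Remove benign/likely-benign calls; route conflicting interpretations.

    CIP variants survive only when at least one submitter reported P/LP
    (the CIP-dagger rule); P, LP, VUS and unclassified variants pass through.
    """
    kept = []
    for v in variants:
        if v.clin_class in cfg.drop_classes:
            continue
        if v.clin_class is ClinClass.CIP and cfg.keep_cip_only_with_plp:
            if not v.cip_has_plp:
                continue
        kept.append(v)
    return kept


def check_zygosity_consistency(
    variants: list[AnnotatedVariant],
    panel: VirtualPanel,
    sex: Sex = Sex.UNKNOWN,
) -> list[AnnotatedVariant]:
    """Keep variants whose genotype fits >= 1 inheritance mode of their gene.

    AD: HET or HOM. AR: HOM; HET when the gene holds >= 2 surviving
    heterozygotes (compound-het candidates, flagged); a lone P/LP HET is kept
    and flagged MONOALLELIC (it can still ground a partial diagnosis). XLR:
    HEM in males, HOM in females, compound-het as AR for females, lone P/LP
    HET kept as carrier/partial. XLD: any non-reference genotype. Genes with
    exception flags bypass removal. A hemizygous call in a female sample is
    flagged SEX_INCONSISTENT and logged, never silently dropped into a mode.
    """
    het_per_gene: dict[str, int] = {}
    for v in variants:
        if v.zygosity is Zygosity.HET:
            g = v.gene.upper()
            het_per_gene[g] = het_per_gene.get(g, 0) + 1

    kept = []
    for v in variants:
        entry = panel.entry(v.gene)
        if entry is None:
            continue
        if v.zygosity is Zygosity.HEM and sex is Sex.FEMALE:
            logger.warning(
                "hemizygous genotype in female sample at %s:%d", v.chrom, v.pos
            )
            v.flags.add(SEX_INCONSISTENT)
        reasons: set[str] = set()
        n_het = het_per_gene.get(v.gene.upper(), 0)
        for mode in entry.modes:
            if mode is Mode.AD:
                if v.zygosity in (Zygosity.HET, Zygosity.HOM):
                    reasons.add("zyg:AD")
            elif mode is Mode.AR:
                if v.zygosity is Zygosity.HOM:
                    reasons.add("zyg:AR_HOM")
                elif v.zygosity is Zygosity.HET:
                    if n_het >= 2:
                        reasons.add("zyg:AR_COMPHET")
                    elif _plp(v):
                        reasons.add("zyg:AR_MONOALLELIC")
            elif mode is Mode.XLR:
                if v.zygosity is Zygosity.HEM and sex is not Sex.FEMALE:
                    reasons.add("zyg:XLR_HEM")
                elif v.zygosity is Zygosity.HOM:
                    reasons.add("zyg:XLR_HOM")
                elif v.zygosity is Zygosity.HET:
                    if n_het >= 2:
                        reasons.add("zyg:XLR_COMPHET")
                    elif _plp(v):
                        reasons.add("zyg:XLR_MONOALLELIC")
            elif mode is Mode.XLD:
                reasons.add("zyg:XLD")
        if not reasons and entry.exception_flags:
            reasons.add("zyg:exception")
            v.flags.add(ZYGOSITY_EXCEPTION)
        if reasons:
            if reasons & {"zyg:AR_MONOALLELIC", "zyg:XLR_MONOALLELIC"}:
                v.flags.add(MONOALLELIC)
            if reasons & {"zyg:AR_COMPHET", "zyg:XLR_COMPHET"}:
                v.flags.add(COMPHET_CANDIDATE)
            v.flags.update(reasons)
            kept.append(v)
    return kept


def _carries(
    ped: Pedigree, member_id: str | None, key: tuple[str, int, str, str]
) -> bool | None:
    """True/False when the member was genotyped, None when unknown.

    A member listed in the pedigree genotype map carries a variant iff an
    entry exists for its key; members absent from the map are ungenotyped.
    """
    if member_id is None or member_id not in ped.genotypes:
        return None
    return key in ped.genotypes[member_id]


def detect_compound_het(
    variants: list[AnnotatedVariant],
    pedigree: Pedigree | None = None,
    proband_id: str | None = None,
) -> list[CompHetPair]:
    """Enumerate within-gene heterozygote pairs and phase them when possible.

    Every unordered pair of HET variants sharing a gene is proposed. With
    parental genotypes, a pair is TRANS when each allele is carried by a
    different parent, CIS (and later discarded) when a single parent carries
    both while the other carries neither, and UNKNOWN otherwise.
    """
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in variants:
        if v.zygosity is Zygosity.HET:
            by_gene.setdefault(v.gene.upper(), []).append(v)

    father = mother = None
    if pedigree is not None and proband_id is not None:
        father, mother = pedigree.parents_of(proband_id)

    pairs: list[CompHetPair] = []
    for gene, hets in by_gene.items():
        for a, b in itertools.combinations(hets, 2):
            phase = Phase.UNKNOWN
            if pedigree is not None and (father or mother):
                fa = _carries(pedigree, father, a.key)
                fb = _carries(pedigree, father, b.key)
                ma = _carries(pedigree, mother, a.key)
                mb = _carries(pedigree, mother, b.key)
                if None not in (fa, fb, ma, mb):
                    if (fa and not fb and mb and not ma) or (
                        fb and not fa and ma and not mb
                    ):
                        phase = Phase.TRANS
                    elif (fa and fb and not ma and not mb) or (
                        ma and mb and not fa and not fb
                    ):
                        phase = Phase.CIS
            pairs.append(CompHetPair(gene=gene, key_a=a.key, key_b=b.key, phase=phase))
    return pairs


def check_segregation(
    candidate: Candidate,
    pedigree: Pedigree,
    proband_id: str | None = None,
    partner: Candidate | None = None,
) -> Segregation:
    """Judge a candidate genotype against relatives' genotypes and status.

    INCONSISTENT when an unaffected relative carries the full causal
    genotype: the variant itself under a dominant mode (full penetrance
    assumed unless the gene is flagged for incomplete penetrance or variable
    expressivity), the homozygous genotype under a recessive mode, or both
    members of a compound-het pair. UNINFORMATIVE when no relative was
    genotyped.
    """
    if proband_id is None:
        affected = [m for m in pedigree.members if m.affected]
        proband_id = affected[0].sample_id if affected else None
    relatives = [
        m
        for m in pedigree.members
        if m.sample_id != proband_id and m.sample_id in pedigree.genotypes
    ]
    if not relatives:
        return Segregation.UNINFORMATIVE

    v = candidate.variant
    dominant = bool(candidate.panel_modes & {Mode.AD, Mode.XLD})
    penetrant = ExceptionFlag.INCOMPLETE_PENETRANCE not in candidate.gene_flags
    for rel in relatives:
        if rel.affected:
            continue
        gt = pedigree.genotype(rel.sample_id, v.key)
        if gt is None:
            continue
        if dominant and penetrant:
            return Segregation.INCONSISTENT
        if gt in (Zygosity.HOM, Zygosity.HEM) and candidate.panel_modes & {
            Mode.AR,
            Mode.XLR,
        }:
            return Segregation.INCONSISTENT
        if (
            partner is not None
            and pedigree.genotype(rel.sample_id, partner.variant.key) is not None
            and candidate.panel_modes & {Mode.AR, Mode.XLR}
        ):
            # unaffected relative carries both alleles of the pair
            return Segregation.INCONSISTENT
    return Segregation.CONSISTENT


_CLASS_RANK = {
    ClinClass.P: 0,
    ClinClass.LP: 1,
    ClinClass.CIP: 2,
    ClinClass.VUS: 3,
    ClinClass.NONE: 4,
    ClinClass.LB: 5,
    ClinClass.B: 6,
}


def _deleterious_votes(v: AnnotatedVariant) -> int:
    return sum(
        1 for label in v.scores.values() if label.lower() in DELETERIOUS_LABELS
    )


def _sort_key(c: Candidate):
    v = c.variant
    return (
        _CLASS_RANK[v.clin_class],
        v.max_maf if v.max_maf is not None else 0.0,
        -_deleterious_votes(v),
        v.chrom,
        v.pos,
        v.ref,
        v.alt,
    )


def rank_candidates(candidates: list[Candidate]) -> list[Candidate]:
    """Assign a deterministic total order: class, rarity, predictor votes,
    then genomic position as the final tie-break. Ranks run 1..n."""
    ordered = sorted(candidates, key=_sort_key)
    for i, c in enumerate(ordered, start=1):
        c.rank = i
    return ordered


def _vaf_flags(v: AnnotatedVariant, cfg: FilterConfig) -> None:
    if v.vaf is None:
        return
    lo, hi = cfg.het_vaf_range
    if v.zygosity is Zygosity.HET and not (lo <= v.vaf <= hi):
        v.flags.add(VAF_OUT_OF_RANGE)
    elif v.zygosity in (Zygosity.HOM, Zygosity.HEM) and v.vaf < cfg.hom_vaf_min:
        v.flags.add(VAF_OUT_OF_RANGE)


def prioritize_case(
    case: SampleCase,
    variants: list[AnnotatedVariant],
    library: PanelLibrary,
    pedigree: Pedigree | None = None,
    cfg: FilterConfig | None = None,
) -> tuple[list[Candidate], FunnelReport]:
    """Run the full cascade for one case and record the per-stage funnel.

    Returns ranked candidates plus a six-stage funnel report (raw, panel,
    frequency, classification, zygosity, final). Surviving candidates with
    read depth below the confirmation floor are flagged NEEDS_CONFIRMATION.
    """
    cfg = cfg or FilterConfig()
    panel = merge_panels(library, case.panels)

    s_panel = apply_panel(variants, panel)
    s_freq = filter_frequency(s_panel, panel, cfg)
    s_class = filter_classification(s_freq, cfg)
    s_zyg = check_zygosity_consistency(s_class, panel, case.sex)

    pairs = detect_compound_het(s_zyg, pedigree, case.sample_id)
    noncis: dict[tuple, list[CompHetPair]] = {}
    for p in pairs:
        if p.phase is not Phase.CIS:
            noncis.setdefault(p.key_a, []).append(p)
            noncis.setdefault(p.key_b, []).append(p)

    final: list[Candidate] = []
    for v in s_zyg:
        comphet_only = v.flags & {"zyg:AR_COMPHET", "zyg:XLR_COMPHET"} and not (
            v.flags
            & {
                "zyg:AD",
                "zyg:AR_HOM",
                "zyg:XLD",
                "zyg:XLR_HEM",
                "zyg:XLR_HOM",
                "zyg:exception",
            }
            or _plp(v)  # lone P/LP HET stays monoallelic even unpaired
        )
        my_pairs = noncis.get(v.key, [])
        if comphet_only and not my_pairs:
            continue  # its only rationale was a pair now established as cis
        entry = panel.entry(v.gene)
        cand = Candidate(
            variant=v,
            panel_modes=set(entry.modes) if entry else set(),
            gene_flags=set(entry.exception_flags) if entry else set(),
            flags=set(v.flags),
        )
        if my_pairs:
            best = sorted(
                my_pairs, key=lambda p: (p.phase is not Phase.TRANS, sorted(p.keys))
            )[0]
            cand.pairing = next(k for k in best.keys if k != v.key)
            if best.phase is Phase.UNKNOWN:
                cand.flags.add(PHASE_UNKNOWN)
        _vaf_flags(v, cfg)
        cand.flags |= v.flags
        if v.depth is not None and v.depth < cfg.min_confirm_depth:
            cand.flags.add(NEEDS_CONFIRMATION)
        final.append(cand)

    ranked = rank_candidates(final)
    funnel = FunnelReport(
        stages=[
            ("raw", len(variants)),
            ("panel", len(s_panel)),
            ("frequency", len(s_freq)),
            ("classification", len(s_class)),
            ("zygosity", len(s_zyg)),
            ("final", len(ranked)),
        ]
    )
    for name, n in funnel.stages:
        logger.info("case=%s stage=%s count=%d", case.sample_id, name, n)
    return ranked, funnel


def _config_label(
    cands: list[Candidate], modes: set[Mode], sex: Sex
) -> tuple[str | None, list[Candidate]]:
    """Best genotype-complete configuration in one gene: 'plp', 'vus' or None."""
    causal = [c for c in cands if _plp(c.variant)]
    uncertain = [
        c
        for c in cands
        if c.variant.clin_class in (ClinClass.VUS, ClinClass.CIP)
    ]
    informative = causal + uncertain

    def complete(c: Candidate) -> bool:
        z = c.variant.zygosity
        if Mode.AD in modes and z in (Zygosity.HET, Zygosity.HOM):
            return True
        if Mode.XLD in modes:
            return True
        if modes & {Mode.AR, Mode.XLR}:
            if z is Zygosity.HOM:
                return True
            if z is Zygosity.HEM and Mode.XLR in modes and sex is not Sex.FEMALE:
                return True
        return False

    # single-variant configurations
    plp_single = [c for c in causal if complete(c)]
    if plp_single:
        return "plp", plp_single[:1]
    # biallelic pair configurations (trans-confirmed or phase-unknown)
    if modes & {Mode.AR, Mode.XLR}:
        by_key = {c.variant.key: c for c in informative}
        for c in informative:
            if c.pairing is not None and c.pairing in by_key:
                partner = by_key[c.pairing]
                pair = [c, partner]
                if all(_plp(x.variant) for x in pair):
                    return "plp", pair
        for c in informative:
            if c.pairing is not None and c.pairing in by_key:
                return "vus", [c, by_key[c.pairing]]
    vus_single = [c for c in uncertain if complete(c)]
    if vus_single:
        return "vus", vus_single[:1]
    return None, []


def classify_outcome(
    candidates: list[Candidate],
    case: SampleCase,
    segregation: dict[tuple, Segregation] | None = None,
) -> CaseOutcome:
    """Collapse a case's surviving candidates into one diagnostic outcome.

    POSITIVE requires a genotype-complete P/LP configuration; UNCERTAIN a
    genotype-complete configuration involving a VUS (or conflicting
    interpretation); PARTIAL a lone P/LP heterozygote in a recessive-mode
    gene; otherwise UNSOLVED. Carrier-screening cases report heterozygous
    P/LP findings in recessive genes as CARRIER_FINDINGS. Candidates already
    judged segregation-inconsistent are excluded.
    """
    if segregation:
        candidates = [
            c
            for c in candidates
            if segregation.get(c.variant.key) is not Segregation.INCONSISTENT
        ]

    if case.mode is CaseMode.CARRIER:
        findings = [
            c
            for c in candidates
            if _plp(c.variant)
            and c.variant.zygosity is Zygosity.HET
            and c.panel_modes & {Mode.AR, Mode.XLR}
        ]
        if findings:
            return CaseOutcome(OutcomeLabel.CARRIER_FINDINGS, findings)
        return CaseOutcome(OutcomeLabel.UNSOLVED, [])

    by_gene: dict[str, list[Candidate]] = {}
    for c in candidates:
        by_gene.setdefault(c.variant.gene.upper(), []).append(c)

    uncertain_support: list[Candidate] = []
    partial_support: list[Candidate] = []
    for gene, cands in sorted(by_gene.items()):
        modes = set().union(*(c.panel_modes for c in cands))
        label, support = _config_label(cands, modes, case.sex)
        if label == "plp":
            return CaseOutcome(OutcomeLabel.POSITIVE, support)
        if label == "vus" and not uncertain_support:
            uncertain_support = support
        if modes & {Mode.AR, Mode.XLR} and not partial_support:
            lone = [
                c
                for c in cands
                if _plp(c.variant)
                and c.variant.zygosity is Zygosity.HET
                and c.pairing is None
            ]
            if lone:
                partial_support = lone[:1]
    if uncertain_support:
        return CaseOutcome(OutcomeLabel.UNCERTAIN, uncertain_support)
    if partial_support:
        return CaseOutcome(OutcomeLabel.PARTIAL, partial_support)
    return CaseOutcome(OutcomeLabel.UNSOLVED, [])
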