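"""Synthetic fixtures: annotated variant tables, pedigrees, coverage
matrices with injected CNVs, and the pseudocontrol spike-in harness.

Everything here emulates the inputs of a targeted rare-disease panel
workflow at desk scale: a small invented genome (a handful of autosomes plus
X, a few hundred genes of 1-10 exons), background variant tables drawn from
a configurable class/frequency mix, causal genotypes spiked per inheritance
mode, and per-target depth matrices with multiplicative lognormal noise so a
deletion or duplication has an exact closed-form expected dose. Generators
are fully deterministic under a fixed seed, and truth manifests are
first-class outputs so validation never re-derives truth from generator
internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panels import ExceptionFlag, GenePanelEntry, Mode, PanelLibrary, VirtualPanel
from .prioritize import (
    FilterConfig,
    apply_panel,
    check_zygosity_consistency,
    filter_classification,
    filter_frequency,
    merge_panels,
    prioritize_case,
)
from .types import (
    AnnotatedVariant,
    CaseMode,
    ClinClass,
    CoverageMatrix,
    GenomicInterval,
    PedMember,
    Pedigree,
    SampleCase,
    Sex,
    Zygosity,
)

_GENOME_SEED = 987654321  # genome layout is a fixture, independent of draws
_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class Gene:
    name: str
    chrom: str
    exons: tuple[GenomicInterval, ...]


class SyntheticGenome:
    """A small invented contig set: autosomes 1-5 plus X, ~400 genes.

    Layout depends only on ``n_genes`` so panels, spikes and pedigrees built
    under different draw seeds share coordinates. The last 5% of genes live
    on X to exercise hemizygous logic.
    """

    def __init__(self, n_genes: int = 400):
        rng = np.random.default_rng(_GENOME_SEED)
        self.genes: dict[str, Gene] = {}
        n_x = max(1, n_genes // 20)
        for i in range(n_genes):
            name = f"GENE{i + 1:04d}"
            chrom = "X" if i >= n_genes - n_x else str(i % 5 + 1)
            slot = 1 + (i // 5 if chrom != "X" else i) * 100_000
            n_exons = int(rng.integers(1, 11))
            exons = []
            pos = slot
            for e in range(n_exons):
                length = int(rng.integers(80, 300))
                exons.append(
                    GenomicInterval(
                        chrom=chrom, start=pos, end=pos + length - 1,
                        label=f"{name}_ex{e + 1}",
                    )
                )
                pos += length + int(rng.integers(500, 5000))
            self.genes[name] = Gene(name=name, chrom=chrom, exons=tuple(exons))

    @property
    def gene_names(self) -> list[str]:
        return list(self.genes)

    def x_genes(self) -> list[str]:
        return [g for g, gg in self.genes.items() if gg.chrom == "X"]

    def autosomal_genes(self) -> list[str]:
        return [g for g, gg in self.genes.items() if gg.chrom != "X"]


@dataclass
class VariantSpike:
    """One causal genotype to plant: gene, inheritance mode, genotype pattern
    (HOM, HET, COMPHET, HEM) and the clinical class it should carry."""

    gene: str
    mode: Mode
    pattern: str
    clin_class: ClinClass = ClinClass.LP
    maf: float | None = 1e-5
    depth: int = 100
    cip_has_plp: bool = False


@dataclass
class CnvSpike:
    sample_id: str
    gene: str
    target_indices: list[int]
    dose: float


DEFAULT_CLASS_MIX = {
    ClinClass.P: 0.01,
    ClinClass.LP: 0.01,
    ClinClass.VUS: 0.15,
    ClinClass.CIP: 0.03,
    ClinClass.LB: 0.20,
    ClinClass.B: 0.30,
    ClinClass.NONE: 0.30,
}


@dataclass
class SimConfig:
    """Study conditions for the generators.

    The background class mix is dominated by benign/unclassified variation,
    as annotated panel data is in practice; frequencies are log-uniform over
    (1e-6, 0.5) with a 10% chance of no database record at all. Depth noise
    is multiplicative lognormal with sigma 0.05 (~5% inter-sample CV per
    target), the regime of a well-performing hybrid-capture batch; the dup
    dose threshold 1.3 sits ln(1.3)/0.05 = 5.2 noise sigmas away, so chance
    dose excursions are vanishingly rare while a true heterozygous deletion
    (dose 0.5) is a >13-sigma departure.
    """

    seed: int = 0
    n_background_variants: int = 300
    class_mix: dict[ClinClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    maf_bounds: tuple[float, float] = (1e-6, 0.5)
    maf_missing_rate: float = 0.10
    n_genes: int = 400
    fraction_on_panel: float = 0.05
    depth_noise: float = 0.05
    mean_depth: float = 120.0
    sex: Sex = Sex.MALE
    spikes: list[VariantSpike] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix probabilities sum to {total}, not 1")


def make_panel_library(
    cfg: SimConfig, genome: SyntheticGenome | None = None, n_panels: int = 3
) -> PanelLibrary:
    """Illustrative virtual panels over the synthetic genome.

    Each panel holds ``fraction_on_panel`` of the genes; autosomal genes get
    AD or AR (roughly half each), X genes XLR or XLD. Gene-mode assignment is
    deterministic under the config seed.
    """
    genome = genome or SyntheticGenome(cfg.n_genes)
    rng = np.random.default_rng((cfg.seed, 101))
    per_panel = max(1, int(round(cfg.fraction_on_panel * cfg.n_genes)))
    lib = PanelLibrary(design_version="S1")
    names = genome.gene_names
    for p in range(n_panels):
        chosen = sorted(
            rng.choice(len(names), size=min(per_panel, len(names)), replace=False)
        )
        entries = []
        for gi in chosen:
            gene = names[gi]
            on_x = genome.genes[gene].chrom == "X"
            if on_x:
                mode = Mode.XLR if rng.random() < 0.7 else Mode.XLD
            else:
                mode = Mode.AR if rng.random() < 0.5 else Mode.AD
            entries.append(GenePanelEntry(gene=gene, modes={mode}))
        lib.panels[f"SP{p + 1}"] = VirtualPanel(
            id=f"SP{p + 1}",
            name=f"Synthetic panel {p + 1}",
            category="synthetic",
            entries=entries,
        )
    return lib


def _rand_snv(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def _variant_at(
    genome: SyntheticGenome,
    gene: str,
    rng: np.random.Generator,
    used: set[tuple[str, int]],
) -> tuple[str, int, str, str]:
    g = genome.genes[gene]
    for _ in range(100):
        exon = g.exons[rng.integers(len(g.exons))]
        pos = int(rng.integers(exon.start, exon.end + 1))
        if (g.chrom, pos) not in used:
            used.add((g.chrom, pos))
            ref, alt = _rand_snv(rng)
            return g.chrom, pos, ref, alt
    raise RuntimeError(f"could not place a unique variant in {gene}")


def _spike_variants(
    spike: VariantSpike,
    genome: SyntheticGenome,
    cfg: SimConfig,
    rng: np.random.Generator,
    used: set[tuple[str, int]],
) -> list[AnnotatedVariant]:
    n = 2 if spike.pattern == "COMPHET" else 1
    out = []
    for _ in range(n):
        chrom, pos, ref, alt = _variant_at(genome, spike.gene, rng, used)
        if spike.pattern == "COMPHET":
            zyg = Zygosity.HET
        elif spike.pattern == "HEM":
            zyg = Zygosity.HEM
        else:
            zyg = Zygosity(spike.pattern)
        vaf = {
            Zygosity.HET: 0.5,
            Zygosity.HOM: 0.99,
            Zygosity.HEM: 0.99,
        }[zyg]
        out.append(
            AnnotatedVariant(
                chrom=chrom, pos=pos, ref=ref, alt=alt, gene=spike.gene,
                consequence="missense_variant",
                zygosity=zyg, vaf=vaf, depth=spike.depth,
                maf={"popdb": spike.maf} if spike.maf is not None else {},
                clin_class=spike.clin_class, cip_has_plp=spike.cip_has_plp,
                scores={"sift": "deleterious", "polyphen": "probably_damaging"},
                hgvs=f"{spike.gene}:c.{pos % 999 + 1}{ref}>{alt}",
            )
        )
    return out


def simulate_variant_table(
    cfg: SimConfig, genome: SyntheticGenome | None = None
) -> tuple[list[AnnotatedVariant], pd.DataFrame]:
    """Background variants plus planted causal genotypes, with truth manifest.

    The manifest lists every spiked variant key together with its spike
    metadata; a config with no spikes yields an empty manifest.
    """
    genome = genome or SyntheticGenome(cfg.n_genes)
    rng = np.random.default_rng((cfg.seed, 202))
    used: set[tuple[str, int]] = set()

    for s in cfg.spikes:
        if s.gene not in genome.genes:
            raise ValueError(f"spike gene {s.gene!r} not in synthetic gene set")

    classes = list(cfg.class_mix)
    probs = np.array([cfg.class_mix[c] for c in classes])
    names = genome.gene_names
    lo, hi = cfg.maf_bounds

    variants: list[AnnotatedVariant] = []
    for _ in range(cfg.n_background_variants):
        gene = names[rng.integers(len(names))]
        chrom, pos, ref, alt = _variant_at(genome, gene, rng, used)
        on_x = chrom == "X"
        if on_x and cfg.sex is Sex.MALE:
            zyg = Zygosity.HEM
        else:
            zyg = Zygosity.HOM if rng.random() < 0.15 else Zygosity.HET
        clin = classes[rng.choice(len(classes), p=probs)]
        maf = {}
        if rng.random() >= cfg.maf_missing_rate:
            maf["popdb"] = float(
                np.exp(rng.uniform(np.log(lo), np.log(hi)))
            )
        if zyg is Zygosity.HET:
            vaf = float(np.clip(rng.normal(0.5, 0.05), 0.05, 0.95))
        else:
            vaf = float(np.clip(rng.normal(0.97, 0.02), 0.5, 1.0))
        depth = max(1, int(rng.lognormal(np.log(cfg.mean_depth), 0.3)))
        variants.append(
            AnnotatedVariant(
                chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                consequence="missense_variant",
                zygosity=zyg, vaf=vaf, depth=depth, maf=maf,
                clin_class=clin,
                cip_has_plp=bool(rng.random() < 0.5) if clin is ClinClass.CIP else False,
            )
        )

    manifest_rows = []
    for i, spike in enumerate(cfg.spikes):
        for v in _spike_variants(spike, genome, cfg, rng, used):
            variants.append(v)
            manifest_rows.append(
                {
                    "spike_index": i,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "gene": spike.gene,
                    "mode": spike.mode.value,
                    "pattern": spike.pattern,
                    "clin_class": spike.clin_class.value,
                    "zygosity": v.zygosity.value,
                }
            )
    manifest = pd.DataFrame(
        manifest_rows,
        columns=[
            "spike_index", "chrom", "pos", "ref", "alt", "gene", "mode",
            "pattern", "clin_class", "zygosity",
        ],
    )
    variants.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return variants, manifest


def simulate_pedigree(
    proband_id: str,
    spiked: list[AnnotatedVariant],
    manifest: pd.DataFrame,
    structure: str = "TRIO",
    sex: Sex = Sex.MALE,
    cis: bool = False,
) -> Pedigree:
    """Mendelian-consistent family genotypes for the planted variants.

    Trio construction: a homozygous recessive spike makes each parent a
    heterozygous carrier; a compound-het spike places one allele per parent
    (trans) unless ``cis`` is requested, in which case the father carries
    both; a dominant spike is de novo (neither unaffected parent carries
    it); a hemizygous spike makes the mother a carrier.
    """
    if structure == "SINGLETON":
        return Pedigree(
            members=[PedMember(proband_id, None, None, sex, True)],
            genotypes={},
        )
    father, mother = f"{proband_id}_F", f"{proband_id}_M"
    members = [
        PedMember(proband_id, father, mother, sex, True),
        PedMember(father, None, None, Sex.MALE, False),
        PedMember(mother, None, None, Sex.FEMALE, False),
    ]
    gts: dict[str, dict] = {proband_id: {}, father: {}, mother: {}}
    by_key = {v.key: v for v in spiked}
    for idx in sorted(manifest["spike_index"].unique()) if len(manifest) else []:
        rows = manifest[manifest["spike_index"] == idx]
        keys = [
            (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
            for r in rows.itertuples()
        ]
        pattern = rows.iloc[0]["pattern"]
        for k in keys:
            v = by_key.get(k)
            if v is not None:
                gts[proband_id][k] = v.zygosity
        if pattern == "HOM":
            gts[father][keys[0]] = Zygosity.HET
            gts[mother][keys[0]] = Zygosity.HET
        elif pattern == "COMPHET" and len(keys) == 2:
            if cis:
                gts[father][keys[0]] = Zygosity.HET
                gts[father][keys[1]] = Zygosity.HET
            else:
                gts[father][keys[0]] = Zygosity.HET
                gts[mother][keys[1]] = Zygosity.HET
        elif pattern == "HEM":
            gts[mother][keys[0]] = Zygosity.HET
        # dominant HET spikes: de novo, parents carry nothing
    return Pedigree(members=members, genotypes=gts)


def simulate_coverage_matrix(
    cfg: SimConfig,
    n_targets: int = 60,
    n_samples: int = 12,
    spikes: list[CnvSpike] | None = None,
    targets_per_gene: int = 3,
) -> tuple[CoverageMatrix, pd.DataFrame]:
    """Depth matrix = per-target baseline x per-sample size factor x noise.

    Multiplicative lognormal noise (median 1) keeps the expected dose of a
    spiked CNV exactly equal to its nominal dose. The truth manifest lists
    every spiked (sample, gene, targets, dose).
    """
    if n_samples < 4:
        raise ValueError("need >= 4 samples for a usable reference batch")
    spikes = spikes or []
    rng = np.random.default_rng((cfg.seed, 303))
    baselines = cfg.mean_depth * rng.lognormal(0.0, 0.35, size=n_targets)
    size_factors = rng.lognormal(0.0, 0.2, size=n_samples)
    noise = (
        rng.lognormal(0.0, cfg.depth_noise, size=(n_targets, n_samples))
        if cfg.depth_noise > 0
        else np.ones((n_targets, n_samples))
    )
    depth = baselines[:, None] * size_factors[None, :] * noise

    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    targets = []
    for t in range(n_targets):
        gidx = t // targets_per_gene
        start = 1 + t * 1000
        targets.append(
            GenomicInterval(
                chrom=str(gidx % 5 + 1), start=start, end=start + 149,
                label=f"CGENE{gidx + 1:03d}",
            )
        )

    manifest_rows = []
    for sp in spikes:
        sidx = samples.index(sp.sample_id)
        for t in sp.target_indices:
            depth[t, sidx] *= sp.dose
        manifest_rows.append(
            {
                "sample_id": sp.sample_id,
                "gene": sp.gene or targets[sp.target_indices[0]].label,
                "targets": ",".join(map(str, sp.target_indices)),
                "dose": sp.dose,
            }
        )
    manifest = pd.DataFrame(
        manifest_rows, columns=["sample_id", "gene", "targets", "dose"]
    )
    return (
        CoverageMatrix(targets=targets, samples=samples, depth=depth),
        manifest,
    )


@dataclass
class PseudocontrolSpec:
    sample_id: str
    spikes: list[VariantSpike]
    panels: list[str]
    sex: Sex = Sex.MALE


@dataclass
class MissRecord:
    sample_id: str
    key: tuple[str, int, str, str]
    gene: str
    reason: str


@dataclass
class RecoveryReport:
    total_spiked: int
    recovered: int
    misses: list[MissRecord] = field(default_factory=list)

    @property
    def recovery_rate(self) -> float:
        return self.recovered / self.total_spiked if self.total_spiked else 1.0


def _diagnose_miss(
    key: tuple,
    variants: list[AnnotatedVariant],
    panel,
    sex: Sex,
    cfg: FilterConfig,
) -> str:
    """Name the first cascade stage at which a spiked variant disappears."""
    stage_fns = [
        ("panel", lambda vs: apply_panel(vs, panel)),
        ("frequency", lambda vs: filter_frequency(vs, panel, cfg)),
        ("classification", lambda vs: filter_classification(vs, cfg)),
        ("zygosity", lambda vs: check_zygosity_consistency(vs, panel, sex)),
    ]
    current = variants
    for name, fn in stage_fns:
        current = fn(current)
        if not any(v.key == key for v in current):
            return name
    return "comp_het_phase"


def run_pseudocontrol_validation(
    specs: list[PseudocontrolSpec],
    library: PanelLibrary,
    base_cfg: SimConfig,
    filter_cfg: FilterConfig | None = None,
    genome: SyntheticGenome | None = None,
) -> RecoveryReport:
    """Spike-in validation: does the cascade recover each planted genotype?

    Every pseudocontrol sample is prioritized end-to-end; a spike counts as
    recovered when all of its planted variants appear among the final ranked
    candidates. Each miss carries the name of the filter stage responsible.
    """
    filter_cfg = filter_cfg or FilterConfig()
    genome = genome or SyntheticGenome(base_cfg.n_genes)
    total = 0
    recovered = 0
    misses: list[MissRecord] = []
    for i, spec in enumerate(specs):
        cfg = replace(
            base_cfg, seed=base_cfg.seed + i + 1, spikes=spec.spikes, sex=spec.sex
        )
        variants, manifest = simulate_variant_table(cfg, genome)
        case = SampleCase(
            sample_id=spec.sample_id, sex=spec.sex, panels=spec.panels,
            mode=CaseMode.DIAGNOSTIC,
        )
        candidates, _ = prioritize_case(case, variants, library, None, filter_cfg)
        final_keys = {c.variant.key for c in candidates}
        panel = merge_panels(library, spec.panels)
        for row in manifest.itertuples():
            total += 1
            key = (str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
            if key in final_keys:
                recovered += 1
            else:
                misses.append(
                    MissRecord(
                        sample_id=spec.sample_id,
                        key=key,
                        gene=row.gene,
                        reason=_diagnose_miss(
                            key, variants, panel, spec.sex, filter_cfg
                        ),
                    )
                )
    return RecoveryReport(total_spiked=total, recovered=recovered, misses=misses)


def default_pseudocontrol_specs(
    cfg: SimConfig,
    library: PanelLibrary,
    genome: SyntheticGenome,
    n_controls: int = 20,
    panel_id: str = "SP1",
) -> list[PseudocontrolSpec]:
    """A standard validation design: one on-panel, filter-compatible causal
    spike per pseudocontrol, cycling over the panel's genes and matching the
    genotype pattern to each gene's inheritance mode."""
    panel = library[panel_id]
    rng = np.random.default_rng((cfg.seed, 404))
    specs = []
    entries = sorted(panel.entries, key=lambda e: e.gene)
    for i in range(n_controls):
        entry = entries[i % len(entries)]
        mode = sorted(entry.modes, key=lambda m: m.value)[0]
        pattern = {
            Mode.AD: "HET",
            Mode.AR: "HOM" if rng.random() < 0.6 else "COMPHET",
            Mode.XLD: "HET" if genome.genes[entry.gene].chrom != "X" else "HEM",
            Mode.XLR: "HEM",
        }[mode]
        sex = Sex.MALE if pattern == "HEM" else (
            Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
        )
        specs.append(
            PseudocontrolSpec(
                sample_id=f"PC{i + 1:03d}",
                spikes=[
                    VariantSpike(
                        gene=entry.gene,
                        mode=mode,
                        pattern=pattern,
                        clin_class=ClinClass.P if rng.random() < 0.5 else ClinClass.LP,
                    )
                ],
                panels=[panel_id],
                sex=sex,
            )
        )
    return specs


def write_vcf_and_annotations(
    variants: list[AnnotatedVariant],
    sample_id: str,
    vcf_path,
    ann_path,
) -> None:
    """Emit a minimal VCF 4.2 plus the sidecar annotation TSV for a sample.

    Genotypes encode the variant zygosities (1/1, 0/1, or haploid 1);
    AD/DP fields are synthesized from vaf and depth so the reader can
    reconstruct them.
    """
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    contigs = sorted({v.chrom for v in ordered})
    with open(vcf_path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c},length=100000000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + sample_id
            + "\n"
        )
        for v in ordered:
            depth = v.depth if v.depth is not None else 100
            vaf = v.vaf if v.vaf is not None else (0.5 if v.zygosity is Zygosity.HET else 1.0)
            alt_reads = int(round(depth * vaf))
            ref_reads = max(depth - alt_reads, 0)
            gt = {"HET": "0/1", "HOM": "1/1", "HEM": "1"}[v.zygosity.value]
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t99\tPASS\t.\t"
                f"GT:AD:DP\t{gt}:{ref_reads},{alt_reads}:{depth}\n"
            )
    score_keys = sorted({k for v in ordered for k in v.scores})
    maf_keys = sorted({k for v in ordered for k in v.maf})
    with open(ann_path, "w", encoding="utf-8") as fh:
        cols = (
            ["chrom", "pos", "ref", "alt", "gene", "consequence", "clin_class", "cip_has_plp"]
            + [f"maf_{k}" for k in maf_keys]
            + [f"score_{k}" for k in score_keys]
            + ["hgvs"]
        )
        fh.write("\t".join(cols) + "\n")
        for v in ordered:
            row = [
                v.chrom, str(v.pos), v.ref, v.alt, v.gene, v.consequence,
                v.clin_class.value, str(v.cip_has_plp).lower(),
            ]
            row += [repr(v.maf[k]) if k in v.maf else "" for k in maf_keys]
            row += [v.scores.get(k, "") for k in score_keys]
            row.append(v.hgvs)
            fh.write("\t".join(row) + "\n")
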