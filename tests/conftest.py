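import pytest
from hypothesis import settings

from panelprio.panels import (
    ExceptionFlag,
    GenePanelEntry,
    Mode,
    PanelLibrary,
    VirtualPanel,
)
from panelprio.synthetic import SimConfig, SyntheticGenome, make_panel_library
from panelprio.types import AnnotatedVariant, ClinClass, Zygosity

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def genome():
    return SyntheticGenome(400)


@pytest.fixture(scope="session")
def library(genome):
    return make_panel_library(SimConfig(seed=0), genome)


@pytest.fixture
def toy_panel():
    """A hand-built panel covering each inheritance mode and exception case."""
    return VirtualPanel(
        id="TOY",
        name="toy",
        category="test",
        entries=[
            GenePanelEntry("GAD", {Mode.AD}),
            GenePanelEntry("GAR", {Mode.AR}),
            GenePanelEntry("GXR", {Mode.XLR}),
            GenePanelEntry("GXD", {Mode.XLD}),
            GenePanelEntry(
                "GEXC", {Mode.AR}, {ExceptionFlag.KNOWN_PATHOGENIC}
            ),
            GenePanelEntry(
                "GPEN", {Mode.AD}, {ExceptionFlag.INCOMPLETE_PENETRANCE}
            ),
            GenePanelEntry("GBOTH", {Mode.AD, Mode.AR}),
        ],
    )


@pytest.fixture
def toy_library(toy_panel):
    return PanelLibrary(panels={"TOY": toy_panel})


def mkvar(
    gene="GAR",
    chrom="1",
    pos=1000,
    ref="A",
    alt="T",
    zyg=Zygosity.HET,
    clin=ClinClass.VUS,
    maf=1e-4,
    vaf=0.5,
    depth=100,
    **kw,
):
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        zygosity=zyg,
        clin_class=clin,
        maf={"popdb": maf} if maf is not None else {},
        vaf=vaf,
        depth=depth,
        **kw,
    )


@pytest.fixture
def make_variant():
    return mkvar
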