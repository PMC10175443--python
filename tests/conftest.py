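import numpy as np
import pytest

from microvar.config import SimulationConfig
from microvar.lineage import Lineage
from microvar.synth import Gene, Genome, ReferenceDB


@pytest.fixture
def tiny_config() -> SimulationConfig:
    """A fast 2-subject, 8-taxon study with the full 4-day replicate design."""
    return SimulationConfig(
        n_subjects=2, n_taxa=8, read_depth_shotgun=500, read_depth_amplicon=500,
        genome_length_range=(10_000, 20_000), seed=11,
    )


def make_refdb(spec: dict[str, str], length: int = 10_000,
               unique=((0, 1_000),), kos: dict[str, str] | None = None,
               ko_to_enzymes: dict[str, frozenset] | None = None) -> ReferenceDB:
    """Hand-build a ReferenceDB from {genome_id: lineage_string}.

    Every genome gets one gene at [0, 900) annotated with ``kos[genome_id]``
    (default KO shared by all genomes).
    """
    kos = kos or {}
    genomes = {}
    for gid, lin in spec.items():
        ko = kos.get(gid, "K00001")
        genomes[gid] = Genome(
            genome_id=gid,
            lineage=Lineage.parse(lin),
            length=length,
            unique_intervals=tuple(unique),
            genes=(Gene(f"{gid}_g1", 0, 900, ko),),
        )
    return ReferenceDB(
        genomes=genomes,
        ko_to_enzymes=ko_to_enzymes or {"K00001": frozenset({"EC001"})},
    )


@pytest.fixture
def enterics_refdb() -> ReferenceDB:
    """Five genomes in one family: 4 of one species + 1 congeneric, plus an
    out-of-genus cousin — the raw material for LCA threshold tests."""
    fam = "k__Bacteria;p__Proteobacteria;c__Gamma;o__Enterobacterales;f__Enterobacteriaceae"
    return make_refdb({
        "E1": f"{fam};g__Escherichia;s__Escherichia coli;t__K12",
        "E2": f"{fam};g__Escherichia;s__Escherichia coli;t__O157",
        "E3": f"{fam};g__Escherichia;s__Escherichia coli",
        "E4": f"{fam};g__Escherichia;s__Escherichia coli;t__B",
        "E5": f"{fam};g__Escherichia;s__Escherichia fergusonii",
        "S1": f"{fam};g__Salmonella;s__Salmonella enterica",
    })


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
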