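import pytest

from surfmut.annotation_store import AnnotationStore, ProteinRecord, TopologyFeature
from surfmut.synthetic_data import CohortSpec, ProteomeSpec, make_cohort, make_proteome

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def repeat_seq(length: int) -> str:
    return (AA20 * (length // len(AA20) + 1))[:length]


@pytest.fixture
def membrane_record() -> ProteinRecord:
    """120-residue membrane protein: ecto 1-50, TM 51-71, cyto 72-120."""
    return ProteinRecord(
        accession="MEMB1",
        gene_symbol="Memb1",
        sequence=repeat_seq(120),
        features=(
            TopologyFeature("extracellular", 1, 50),
            TopologyFeature("transmembrane", 51, 71),
            TopologyFeature("intracellular", 72, 120),
        ),
        location_labels=frozenset({"plasma_membrane"}),
    )


@pytest.fixture
def secreted_record() -> ProteinRecord:
    """100-residue secreted protein with a signal peptide at 1-20."""
    return ProteinRecord(
        accession="SECR1",
        gene_symbol="Secr1",
        sequence=repeat_seq(100),
        features=(TopologyFeature("signal_peptide", 1, 20),),
        location_labels=frozenset({"secreted"}),
    )


@pytest.fixture
def cytosolic_record() -> ProteinRecord:
    return ProteinRecord(
        accession="CYTO1",
        gene_symbol="Cyto1",
        sequence=repeat_seq(80),
        features=(),
        location_labels=frozenset({"intracellular_other"}),
    )


@pytest.fixture
def toy_store(membrane_record, secreted_record, cytosolic_record) -> AnnotationStore:
    return AnnotationStore([membrane_record, secreted_record, cytosolic_record])


@pytest.fixture(scope="session")
def synthetic_proteome():
    return make_proteome(ProteomeSpec(n_proteins=60, seed=11))


@pytest.fixture(scope="session")
def synthetic_store(synthetic_proteome):
    return synthetic_proteome[0]


@pytest.fixture(scope="session")
def synthetic_cohort(synthetic_store):
    spec = CohortSpec(n_patients=30, burden_median=40.0, burden_sigma=0.8, seed=5)
    return make_cohort(spec, synthetic_store)
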