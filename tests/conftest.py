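import pytest

from methclonal import (
    ClonalityParams,
    GenePanel,
    Laterality,
    MethylationStatus,
    SimulationConfig,
    TumourPair,
    TumourProfile,
    TumourRole,
    default_panel,
    simulate_cohort,
)

STATUS = {
    "M": MethylationStatus.METHYLATED,
    "U": MethylationStatus.UNMETHYLATED,
    "N": MethylationStatus.UNINFORMATIVE,
}


def make_pair(
    primary: str,
    second: str,
    panel: GenePanel,
    *,
    patient_id: str = "pt1",
    laterality: Laterality = Laterality.IPSILATERAL,
) -> TumourPair:
    """Build a pair from call strings like 'MUN' aligned with panel order."""
    assert len(primary) == len(second) == len(panel.genes)

    def profile(s: str, role: TumourRole, suffix: str) -> TumourProfile:
        return TumourProfile(
            sample_id=f"{patient_id}{suffix}",
            patient_id=patient_id,
            role=role,
            calls={g: STATUS[c] for g, c in zip(panel.genes, s)},
        )

    return TumourPair(
        patient_id=patient_id,
        laterality=laterality,
        primary=profile(primary, TumourRole.PRIMARY, "A"),
        second=profile(second, TumourRole.SECOND, "B"),
    )


def single_gene_panel(p: float, gene: str = "G1") -> GenePanel:
    return GenePanel((gene,), {gene: p}, source_label="test")


@pytest.fixture
def panel() -> GenePanel:
    return default_panel("cohort")


@pytest.fixture
def params() -> ClonalityParams:
    return ClonalityParams()


@pytest.fixture(scope="session")
def cohort29():
    """A seeded 16+13-pair synthetic cohort with its truth labels."""
    return simulate_cohort(SimulationConfig(seed=7))
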