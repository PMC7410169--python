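"""Ready-made demographic models for hominin introgression analyses.

The deep-introgression model covers two African humans, two Neanderthals and
a Denisovan (all diploid, the archaics with ancient sampling ages), a haploid
chimpanzee outgroup, and an unsampled ("ghost") super-archaic population.
Five migration bands at a common migration time describe the events under
study — ancient humans into Neanderthals (Hum->Nea), super-archaic into
Denisovans (Sup->Den) and into Africans (Sup->Afr) — plus two bands that act
as negative controls (Sup->Nea, Hum->Den).

Divergence times follow the consensus hominin phylogeny (Neanderthal/Denisovan
split ~415 kya, modern/archaic split ~575 kya, human/chimpanzee ~6 Mya); the
super-archaic divergence ``t_div`` and the migration time ``t_mig`` are the
free parameters.  The African effective size is 23,700; archaic sizes use a
simplified three-epoch decline standing in for full PSMC trajectories.
"""

from __future__ import annotations

from .demography import (
    DemographicModel,
    MigrationBand,
    Population,
    SampleConfig,
    default_time_grid,
)

__all__ = ["deep_introgression_model", "recent_introgression_model", "DEFAULT_PM"]

#: prior probability that a lineage follows a migration band
DEFAULT_PM = 0.01

# diploid effective sizes (defaults; user-configurable)
AFR_SIZE = 23_700
NEA_SIZES = [(0.0, 2_000), (150e3, 3_400), (350e3, 5_000)]
DEN_SIZES = [(0.0, 2_000), (150e3, 2_500), (350e3, 5_000)]
NEADEN_SIZE = 10_000
HND_SIZE = 18_500
ROOT_SIZE = 15_000


def _base_populations(t_div: float) -> list[Population]:
    return [
        Population("Root", sizes=ROOT_SIZE),
        Population("Chimp", parent="Root", divergence_time=6.0e6, sizes=20_000),
        Population("AncH", parent="Root", divergence_time=6.0e6, sizes=HND_SIZE),
        Population("Sup", parent="AncH", divergence_time=t_div, is_ghost=True),
        Population("HND", parent="AncH", divergence_time=t_div, sizes=HND_SIZE),
        Population("Afr", parent="HND", divergence_time=575e3, sizes=AFR_SIZE),
        Population("NeaDen", parent="HND", divergence_time=575e3, sizes=NEADEN_SIZE),
        Population("Nea", parent="NeaDen", divergence_time=415e3, sizes=NEA_SIZES),
        Population("Den", parent="NeaDen", divergence_time=415e3, sizes=DEN_SIZES),
    ]


def deep_introgression_samples() -> list[SampleConfig]:
    """Two Africans, two Neanderthals, one Denisovan (unphased diploids) and a
    haploid chimpanzee outgroup, with ancient sampling ages of 115/52/72 ky."""
    return [
        SampleConfig("Afr1", "Afr", age=0.0, ploidy=2, phased=False),
        SampleConfig("Afr2", "Afr", age=0.0, ploidy=2, phased=False),
        SampleConfig("Altai", "Nea", age=115e3, ploidy=2, phased=False),
        SampleConfig("Vindija", "Nea", age=52e3, ploidy=2, phased=False),
        SampleConfig("Denisova", "Den", age=72e3, ploidy=2, phased=False),
        SampleConfig("Chimp", "Chimp", age=0.0, ploidy=1, phased=True),
    ]


def deep_introgression_model(
    t_mig: float = 250e3,
    t_div: float = 1.0e6,
    p_mig: float = DEFAULT_PM,
    samples: list[SampleConfig] | None = None,
    include_controls: bool = True,
    generation_time: float = 29.0,
) -> DemographicModel:
    """The "old migration" model: Hum->Nea, Sup->Den, Sup->Afr bands at
    ``t_mig`` (plus Sup->Nea / Hum->Den control bands)."""
    bands = [
        MigrationBand("Afr", "Nea", t_mig, p_mig),
        MigrationBand("Sup", "Den", t_mig, p_mig),
        MigrationBand("Sup", "Afr", t_mig, p_mig),
    ]
    if include_controls:
        bands += [
            MigrationBand("Sup", "Nea", t_mig, p_mig),
            MigrationBand("Afr", "Den", t_mig, p_mig),
        ]
    return DemographicModel(
        grid=default_time_grid(),
        populations=_base_populations(t_div),
        bands=bands,
        samples=samples if samples is not None else deep_introgression_samples(),
        generation_time=generation_time,
    )


def recent_introgression_model(
    n_afr: int = 2,
    n_eur: int = 1,
    t_mig: float = 50e3,
    p_mig: float = DEFAULT_PM,
    generation_time: float = 29.0,
) -> DemographicModel:
    """Model for detecting the recent Nea->Hum event.

    All humans sit in a single population (no Afr/Eur divergence is modelled
    on this coarse time grid); a single Nea->Hum band at ``t_mig`` captures
    the archaic admixture into out-of-Africa humans.
    """
    pops = [
        Population("Root", sizes=ROOT_SIZE),
        Population("Chimp", parent="Root", divergence_time=6.0e6, sizes=20_000),
        Population("HND", parent="Root", divergence_time=6.0e6, sizes=HND_SIZE),
        Population("Hum", parent="HND", divergence_time=575e3, sizes=AFR_SIZE),
        Population("NeaDen", parent="HND", divergence_time=575e3, sizes=NEADEN_SIZE),
        Population("Nea", parent="NeaDen", divergence_time=415e3, sizes=NEA_SIZES),
        Population("Den", parent="NeaDen", divergence_time=415e3, sizes=DEN_SIZES),
    ]
    samples = [
        SampleConfig(f"Afr{i + 1}", "Hum", age=0.0, ploidy=2, phased=True)
        for i in range(n_afr)
    ]
    samples += [
        SampleConfig(f"Eur{i + 1}", "Hum", age=0.0, ploidy=2, phased=True)
        for i in range(n_eur)
    ]
    samples += [
        SampleConfig("Altai", "Nea", age=115e3, ploidy=2, phased=True),
        SampleConfig("Vindija", "Nea", age=52e3, ploidy=2, phased=True),
        SampleConfig("Chimp", "Chimp", age=0.0, ploidy=1, phased=True),
    ]
    bands = [MigrationBand("Nea", "Hum", t_mig, p_mig)]
    return DemographicModel(
        grid=default_time_grid(),
        populations=pops,
        bands=bands,
        samples=samples,
        generation_time=generation_time,
    )
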