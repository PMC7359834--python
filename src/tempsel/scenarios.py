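"""Ready-made configurations emulating the before/after remediation study.

These are the package's frozen reference conditions: an affected deme (MEL)
and a control deme (SFM) exchanging ~15% of parents per generation, one
six-allele candidate locus whose focal homozygote is selected against
(relative viability 0.5) in the affected deme until the intervention
generation and neutral afterwards, six polymorphic plus two monomorphic
microsatellites under stepwise mutation, and samples of 24 diploids per
site in two pre- and two post-intervention years.

Free parameters the study does not pin down (census sizes, initial allele
frequencies, sampling generations) were chosen once, via the deterministic
recursion, to give the affected deme a clearly detectable frequency change
while keeping every genotype category represented in pre-intervention
samples of 24; see the methods note for the reasoning.
"""

from __future__ import annotations

import numpy as np

from .simulate import (
    AFTER,
    BEFORE,
    ExpressionConfig,
    ExpressionGroup,
    MicrosatLocus,
    SimulationConfig,
    WaterConfig,
    WaterGroup,
)

AFFECTED_SITE = "MEL"
CONTROL_SITE = "SFM"
FOCAL_ALLELE = "GTCGC"
CANDIDATE_ALLELES = ["GTCGC", "CTCGC", "GTCGA", "CTCGA", "GTTGC", "CTTGC"]
MICROSAT_NAMES = [
    "Odon01", "Odon02", "Odon07", "Odon09", "Odon19", "Odon71",  # polymorphic
    "Odon39", "Odon59",  # monomorphic controls
]

#: Sampling generations: two before the intervention (which takes effect
#: after generation 6) and two well after it.
BEFORE_GENERATIONS = (0, 1)
AFTER_GENERATIONS = (12, 13)


def paper_like_genotype_config(
    seed: int = 0,
    deme_size: int = 2000,
    sample_size: int = 24,
    migration_rate: float = 0.15,
    selection: float = 0.5,
) -> SimulationConfig:
    """Two-deme candidate-vs-microsatellite scenario with a mid-run switch-off.

    ``selection`` is the viability penalty of the focal homozygote in the
    affected deme during the before epoch: that genotype has relative
    viability ``1 - selection`` (0.5 by default) while every other genotype,
    deme and epoch is neutral.
    """
    m = migration_rate
    # initial focal-allele frequency 0.65 affected / 0.35 control; the other
    # five alleles share the remainder in decreasing abundance
    rest_affected = np.array([0.14, 0.08, 0.06, 0.04, 0.03])
    rest_control = np.array([0.28, 0.15, 0.10, 0.07, 0.05])
    init = np.vstack(
        [
            np.concatenate([[0.65], rest_affected]),
            np.concatenate([[0.35], rest_control]),
        ]
    )
    microsats = [
        MicrosatLocus(alleles=[8, 10, 12, 14, 16], freqs=[0.30, 0.25, 0.20, 0.15, 0.10]),
        MicrosatLocus(alleles=[6, 7, 8, 9], freqs=[0.40, 0.30, 0.20, 0.10]),
        MicrosatLocus(alleles=[10, 12, 14, 16, 18, 20], freqs=[0.25, 0.22, 0.20, 0.15, 0.10, 0.08]),
        MicrosatLocus(alleles=[5, 6, 7], freqs=[0.50, 0.30, 0.20]),
        MicrosatLocus(alleles=[11, 13, 15, 17], freqs=[0.35, 0.30, 0.20, 0.15]),
        MicrosatLocus(alleles=[9, 10, 11, 12, 13], freqs=[0.30, 0.25, 0.20, 0.15, 0.10]),
        MicrosatLocus(alleles=[7], freqs=[1.0]),  # Odon39, monomorphic
        MicrosatLocus(alleles=[12], freqs=[1.0]),  # Odon59, monomorphic
    ]
    plan = []
    for gen in (*BEFORE_GENERATIONS, *AFTER_GENERATIONS):
        for deme in (0, 1):
            plan.append((gen, deme, sample_size))
    return SimulationConfig(
        deme_sizes=(deme_size, deme_size),
        migration=[[1 - m, m], [m, 1 - m]],
        candidate_alleles=list(CANDIDATE_ALLELES),
        candidate_init_freqs=init,
        fitness_by_epoch={(0, BEFORE): {"focal_homozygote": 1.0 - selection}},
        focal_allele=FOCAL_ALLELE,
        n_microsats=8,
        microsat_init_alleles=microsats,
        mu_stepwise=5e-4,
        n_generations=max(AFTER_GENERATIONS),
        switch_generation=6,
        sampling_plan=plan,
        seed=seed,
        deme_names=(AFFECTED_SITE, CONTROL_SITE),
        candidate_locus_name="odc",
        microsat_names=list(MICROSAT_NAMES),
    )


def paper_like_expression_config(seed: int = 0) -> ExpressionConfig:
    """Expression design: ~18-fold site ratio before, ~3.4-fold after.

    Library-size bounds reproduce the study's sequencing asymmetry
    (1.83-4.7 million filtered reads per individual before, 11.89-18.74
    million after); 3 individuals per site before, 6 after.
    """
    before_reads = (1.83e6, 4.7e6)
    after_reads = (11.89e6, 18.74e6)
    return ExpressionConfig(
        groups={
            (AFFECTED_SITE, BEFORE): ExpressionGroup(54.0, 4.0, 3, before_reads),
            (CONTROL_SITE, BEFORE): ExpressionGroup(3.0, 4.0, 3, before_reads),
            (AFFECTED_SITE, AFTER): ExpressionGroup(10.2, 4.0, 6, after_reads),
            (CONTROL_SITE, AFTER): ExpressionGroup(3.0, 4.0, 6, after_reads),
        },
        seed=seed,
    )


def paper_like_water_config(seed: int = 0, replicates: int = 4) -> WaterConfig:
    """Water chemistry: polluted signature at MEL before, converged after.

    Units: EC uS/cm, TDS/ions mg/L, DO mg/L, pH unitless.  The affected
    site's before-epoch means carry the pollution signature (high EC, TDS,
    NH4, Na, K; low DO); its after-epoch means approach the control site's.
    """
    variables = ["EC", "pH", "TDS", "NO3", "NH4", "Na", "K", "Ca", "Mg", "DO"]
    control = np.array([750.0, 7.9, 420.0, 2.0, 0.15, 45.0, 4.0, 80.0, 18.0, 9.0])
    polluted = np.array([1900.0, 7.4, 980.0, 6.0, 2.8, 150.0, 14.0, 150.0, 32.0, 4.5])
    recovered = control + 0.18 * (polluted - control)
    sd_control = np.array([60.0, 0.15, 35.0, 0.5, 0.05, 5.0, 0.6, 7.0, 2.0, 0.5])
    sd_polluted = np.array([170.0, 0.2, 90.0, 1.2, 0.6, 16.0, 2.0, 13.0, 3.5, 0.7])

    def cov(sd: np.ndarray) -> np.ndarray:
        corr = np.full((10, 10), 0.25)
        np.fill_diagonal(corr, 1.0)
        return corr * np.outer(sd, sd)

    return WaterConfig(
        groups={
            (AFFECTED_SITE, BEFORE): WaterGroup(polluted, cov(sd_polluted), [2007, 2011], replicates),
            (AFFECTED_SITE, AFTER): WaterGroup(recovered, cov(sd_control), [2016, 2017], replicates),
            (CONTROL_SITE, BEFORE): WaterGroup(control, cov(sd_control), [2007, 2011], replicates),
            (CONTROL_SITE, AFTER): WaterGroup(control, cov(sd_control), [2016, 2017], replicates),
        },
        variables=variables,
        seed=seed,
    )
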