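"""Bundled synthetic study panels.

These fixtures encode the experimental designs the pipeline is meant to
analyse, with ground-truth parameters taken where possible from published
apparent affinities (e.g. the mephedrone aptamer MMC1 at Kd ~ 15 uM, the
MDPV aptamer MA-46 at Kd ~ 18.8 uM, chlorpromazine at 0.6 uM, serotonin at
55 uM). Everything here is synthetic: the panels exist so that every
pipeline stage can be exercised and validated without plate-reader data.

Default kinetics: unprotected aptamer digests at 0.03 /min (≈ 93% digested
over a 90-minute read window, matching "lowest fluorescence within the
window"); the ligand-protected product leaks away at 0.002 /min (persists
over the window, gone on the ~14 h scale). The stem-loop screening library
is 73 nt with a 42-nt protected product; MA-46 is 46 nt with a 41-nt
protected product.
"""

from __future__ import annotations

from .models import (
    AptamerSpec,
    BindingParams,
    DigestionParams,
    LigandCondition,
    SamplingSchedule,
    SDParams,
)

#: Calibration concentration series (uM) for dose-response experiments.
CALIBRATION_CONCENTRATIONS_UM: tuple[float, ...] = (0, 25, 50, 100, 200, 400, 800)

#: Screening concentration (uM) for the mephedrone candidate panel.
SCREEN_CONCENTRATION_UM = 200.0

DEFAULT_DIGESTION = DigestionParams(
    k_unprotected=0.03,
    k_leak=0.002,
    amplitude=1000.0,
    background=0.0,
    noise_cv=0.05,
    exchange_mode="slow",
)

#: 90-minute read window sampled every 5 minutes after a 1 h incubation.
DEFAULT_SCHEDULE = SamplingSchedule.regular(90.0, 5.0, incubation_min=60.0)

DEFAULT_SD = SDParams(
    f_max=1000.0,
    quench_efficiency=0.9,
    kd_sd=60.0,
    max_displacement=0.85,
    noise_cv=0.0,
)

#: Ground-truth apparent affinities (uM) of the four true binders in the
#: 29-candidate mephedrone screen; the remaining 25 candidates are
#: non-binders. With the default kinetics and schedule these give noiseless
#: resistance values between ~0.80 and ~0.89 at 200 uM mephedrone.
SCREEN_BINDER_KD_UM: dict[str, float] = {
    "MMC1": 15.0,
    "MMC2": 10.0,
    "MMC3": 20.0,
    "MMC4": 30.0,
}

N_SCREEN_CANDIDATES = 29


def mephedrone_screen_panel() -> tuple[
    list[AptamerSpec], list[LigandCondition], list[BindingParams]
]:
    """The 29-candidate mephedrone screen: 4 binders, 25 non-binders,
    screened at 200 uM mephedrone against ligand-free controls."""
    aptamers = [
        AptamerSpec(
            aptamer_id=f"MMC{i}", full_length_nt=73, protected_length_nt=42
        )
        for i in range(1, N_SCREEN_CANDIDATES + 1)
    ]
    binding = [
        BindingParams(
            aptamer_id=a.aptamer_id,
            ligand_id="mephedrone",
            kd_app=SCREEN_BINDER_KD_UM.get(a.aptamer_id),
        )
        for a in aptamers
    ]
    conditions = [
        LigandCondition(ligand_id="mephedrone", concentration=SCREEN_CONCENTRATION_UM)
    ]
    return aptamers, conditions, binding


def mmc1_profile_panel() -> tuple[
    list[AptamerSpec], list[LigandCondition], list[BindingParams]
]:
    """Specificity profile of MMC1: the target (15 uM), a 10-fold-weaker
    analog (methedrone, 150 uM), and a panel of non-binding analogs, all at
    200 uM ligand."""
    mmc1 = AptamerSpec(aptamer_id="MMC1", full_length_nt=73, protected_length_nt=42)
    affinities: dict[str, float | None] = {
        "mephedrone": 15.0,
        "methedrone": 150.0,
        "methylone": None,
        "methcathinone": None,
        "4-FMC": None,
        "ethylone": None,
        "2-MMC": None,
        "3-MMC": None,
        "cathinone": None,
        "pyrovalerone": None,
        "amphetamine": None,
        "methamphetamine": None,
        "pseudoephedrine": None,
        "dopamine": None,
    }
    binding = [
        BindingParams(aptamer_id="MMC1", ligand_id=lig, kd_app=kd)
        for lig, kd in affinities.items()
    ]
    conditions = [
        LigandCondition(ligand_id=lig, concentration=200.0) for lig in affinities
    ]
    return [mmc1], conditions, binding


def artifact_demo_panel() -> tuple[
    AptamerSpec, list[LigandCondition], list[BindingParams]
]:
    """The assay-discordance demonstration around the MDPV aptamer MA-46.

    Conditions at 400 uM ligand with per-ligand fluorophore artifact
    factors: chlorpromazine is a tight binder whose -90% fluorophore
    attenuation (factor 0.1) produces a strand-displacement false negative;
    serotonin binds but is attenuated -35% (factor 0.65); acetyl fentanyl
    and diphenhydramine are non/weak binders whose +30% enhancement (factor
    1.3) produces false positives; morphine is an artifact-free non-binder.
    The digestion readout is unaffected by these factors.
    """
    ma46 = AptamerSpec(aptamer_id="MA-46", full_length_nt=46, protected_length_nt=41)
    rows = [
        # (ligand, kd_app uM or None, dye artifact factor)
        ("MDPV", 18.8, 1.0),
        ("chlorpromazine", 0.6, 0.1),
        ("serotonin", 55.0, 0.65),
        ("acetyl-fentanyl", None, 1.3),
        ("diphenhydramine", None, 1.3),
        ("morphine", None, 1.0),
    ]
    binding = [
        BindingParams(aptamer_id="MA-46", ligand_id=lig, kd_app=kd)
        for lig, kd, _ in rows
    ]
    conditions = [
        LigandCondition(ligand_id=lig, concentration=400.0, dye_artifact_factor=m)
        for lig, _, m in rows
    ]
    return ma46, conditions, binding
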