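"""Standard synthetic study configurations used across examples and checks.

Three named scenarios:

``study_config``
    Mirrors the real-world cohort composition: ~92% untreated, rare
    high-intensity use, mild confounding, efficacy gap in a 30% subgroup.

``policy_recovery_config``
    A benchmark with balanced arms (25% each), low outcome noise
    (``noise_sd = 5``) and response heterogeneity driven by exactly three of
    the twenty condition flags, so the ground-truth best arm varies across
    patients and recovery of the optimal policy is measurable.

``gap_config``
    Balanced-ish arms with a tunable efficacy-effectiveness gap: for the
    flagged subgroup the high-intensity effect is attenuated below the
    moderate-intensity effect, so moderate should be recommended there.
"""

from __future__ import annotations

import numpy as np

from .synthetic_cohort import GeneratorConfig

__all__ = ["study_config", "policy_recovery_config", "gap_config"]

_N_FLAGS = 20


def study_config(n_patients: int = 10_000, seed: int = 0) -> GeneratorConfig:
    """Realistic composition: mostly untreated, mild confounding, 30% gap."""
    return GeneratorConfig(
        n_patients=n_patients,
        seed=seed,
        n_condition_flags=_N_FLAGS,
        noise_sd=10.0,
        confounding_strength=0.5,
        gap_fraction=0.3,
        missing_lab_rate=0.05,
    )


def policy_recovery_config(n_patients: int = 6500, seed: int = 0) -> GeneratorConfig:
    """Balanced arms, low noise, heterogeneity on flags cond_02/03/04.

    True response surface (percent reduction):
        none:      0
        low:      15 + 6 * cond_04
        moderate: 25 + 4 * cond_03
        high:     35 - 18 * cond_02
    so the best arm is high when cond_02 = 0 and moderate when cond_02 = 1
    (cond_02 prevalence 0.5).
    """
    dim = 2 + _N_FLAGS
    het = {a: np.zeros(dim) for a in ("none", "low", "moderate", "high")}
    het["low"][2 + 4] = 6.0
    het["moderate"][2 + 3] = 4.0
    het["high"][2 + 2] = -18.0
    prevalences = [0.10, 0.0] + [0.08] * (_N_FLAGS - 2)
    prevalences[2] = 0.5
    prevalences[3] = 0.3
    prevalences[4] = 0.3
    return GeneratorConfig(
        n_patients=n_patients,
        seed=seed,
        n_condition_flags=_N_FLAGS,
        heterogeneity_coefs=het,
        noise_sd=5.0,
        confounding_strength=0.0,
        gap_fraction=0.0,
        arm_prevalence={"none": 0.25, "low": 0.25, "moderate": 0.25, "high": 0.25},
        missing_lab_rate=0.0,
        flag_prevalences=prevalences,
    )


def gap_config(
    n_patients: int = 4000, seed: int = 0, gap_fraction: float = 0.0
) -> GeneratorConfig:
    """Tunable efficacy gap; arms weighted toward the statin decisions."""
    return GeneratorConfig(
        n_patients=n_patients,
        seed=seed,
        n_condition_flags=_N_FLAGS,
        noise_sd=5.0,
        confounding_strength=0.2,
        gap_fraction=gap_fraction,
        gap_attenuation=0.4,
        arm_prevalence={"none": 0.25, "low": 0.20, "moderate": 0.30, "high": 0.25},
        missing_lab_rate=0.0,
    )
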