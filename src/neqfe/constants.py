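"""Physical constants and unit conversions.

All internal energies are kJ/mol; conversion to kcal/mol happens only at
the reporting layer.
"""

#: Boltzmann constant in kJ/mol/K (CODATA value used by GROMACS).
KB_KJ_PER_MOL_K: float = 0.0083144621

#: kJ per kcal.
KJ_PER_KCAL: float = 4.184


def kt_kj(temperature: float) -> float:
    """k_B*T in kJ/mol at *temperature* (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KJ_PER_MOL_K * temperature


def kt_kcal(temperature: float) -> float:
    """k_B*T in kcal/mol at *temperature* (K)."""
    return kt_kj(temperature) / KJ_PER_KCAL


def kj_to_kcal(x: float) -> float:
    return x / KJ_PER_KCAL


def kcal_to_kj(x: float) -> float:
    return x * KJ_PER_KCAL
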