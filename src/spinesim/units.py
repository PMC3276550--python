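"""Unit conversions between concentrations and molecule counts.

Concentrations are nM, volumes um^3, time s throughout the package.
"""

AVOGADRO = 6.02214076e23

# molecules per (nM * um^3): 1 nM = 1e-9 mol/L, 1 um^3 = 1e-15 L
NM_UM3_TO_MOLECULES = AVOGADRO * 1e-9 * 1e-15  # = 0.602214076


def molecules(conc_nM: float, volume_um3: float) -> float:
    """Expected molecule count for a concentration in a subvolume."""
    return conc_nM * volume_um3 * NM_UM3_TO_MOLECULES


def concentration(n_molecules: float, volume_um3: float) -> float:
    """Concentration in nM of a molecule count in a subvolume."""
    return n_molecules / (volume_um3 * NM_UM3_TO_MOLECULES)


def stochastic_rate(kf: float, order: int, volume_um3: float) -> float:
    """Per-subvolume propensity constant from a deterministic rate constant.

    Unimolecular rates (s^-1) are volume independent; bimolecular rates
    (nM^-1 s^-1) convert to a per-molecule-pair rate c such that the
    propensity c * nA * nB reproduces the mass-action flux kf*[A]*[B].
    """
    if order == 1:
        return kf
    if order == 2:
        if volume_um3 <= 0:
            raise ValueError("subvolume volume must be positive")
        return kf / (NM_UM3_TO_MOLECULES * volume_um3)
    raise ValueError(f"reaction order must be 1 or 2, got {order}")
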