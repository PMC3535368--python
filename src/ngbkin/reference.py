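"""Published study conditions used as model inputs.

The experiment these defaults emulate: 100 uM human neuroglobin (heme
orientation isomers populated B:A close to 2:1), 500 uM KCN injected at
t = 0, cyanide binding followed by real-time 1D 1H NMR at 298 K with one
spectrum roughly every 20 min, for five protein states: wild type with the
Cys46–Cys55 disulfide bridge oxidized (WT_ox) or reduced (WT_red), the
C120S mutant in both redox states, and the cysteine-free triple mutant
C46G/C55S/C120S (TM).

The measured per-state/per-isomer exponential time constants T (minutes)
and, where binding was incomplete at equilibrium, dissociation constants
K_d are treated as *inputs*: the apparent second-order rate constant
follows from 1/T = k_obs [CN-] and the microscopic rates are reconstructed
by :func:`ngbkin.kinetics.collapsed_rates`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kinetics
from .errors import ConfigurationError
from .units import SECONDS_PER_MINUTE

__all__ = [
    "STATES",
    "MeasuredRow",
    "MEASURED",
    "measured_row",
    "kobs_true",
    "DEFAULT_PROTEIN_TOTAL",
    "DEFAULT_LIGAND_TOTAL",
    "ISOMER_SPLIT",
    "MET_SHIFTS",
    "CYANOMET_SHIFTS",
    "default_isomers",
    "default_config",
    "recommended_duration_min",
]

STATES = kinetics.STATES


@dataclass(frozen=True)
class MeasuredRow:
    """One measured state/isomer: time constant and derived constants."""

    state: str
    isomer: str
    T_min: float                 # exponential time constant, minutes
    kobs_printed: float          # published apparent rate constant, M^-1 s^-1
    kd_printed: float | None     # published K_d, molar (None: complete binding)


#: Measured time constants and apparent constants for every state/isomer.
MEASURED = (
    MeasuredRow("WT_ox", "A", 19.0, 1.75, None),
    MeasuredRow("WT_ox", "B", 97.0, 0.34, None),
    MeasuredRow("WT_red", "A", 127.0, 0.26, 153e-6),
    MeasuredRow("WT_red", "B", 265.0, 0.12, 316e-6),
    MeasuredRow("C120S_ox", "A", 18.0, 1.85, None),
    MeasuredRow("C120S_ox", "B", 119.0, 0.28, None),
    MeasuredRow("C120S_red", "A", 138.0, 0.24, None),
    MeasuredRow("C120S_red", "B", 255.0, 0.13, None),
    MeasuredRow("TM", "A", 262.0, 0.12, 2.0e-3),
    MeasuredRow("TM", "B", 223.0, 0.14, 5.0e-3),
)

DEFAULT_PROTEIN_TOTAL = 100e-6   # molar
DEFAULT_LIGAND_TOTAL = 500e-6    # molar
ISOMER_SPLIT = {"A": 1.0 / 3.0, "B": 2.0 / 3.0}   # B:A = 2:1 populations

#: Low-field heme methyl shifts (ppm) of the unbound (met) protein used as
#: reporter resonances: the M8 methyl of the B conformer and the M5 methyl
#: of the A conformer.  The C120S spectra are indistinguishable from their
#: WT counterparts; the TM placements are nominal values near the WT_red
#: positions (the resonances shift slightly but were not tabulated).
MET_SHIFTS = {
    "WT_ox": {"B": 35.4, "A": 34.5},
    "WT_red": {"B": 36.7, "A": 35.4},
    "C120S_ox": {"B": 35.4, "A": 34.5},
    "C120S_red": {"B": 36.7, "A": 35.4},
    "TM": {"B": 36.5, "A": 35.2},
}

#: Cyanide-bound (cyanomet) reporter shifts, placed in the 18–20 ppm window
#: that is free of met-state heme resonances.  Nominal positions: the labels,
#: not the exact shifts, matter for the pipeline.
CYANOMET_SHIFTS = {"A": 19.5, "B": 18.5}


def measured_row(state: str, isomer: str) -> MeasuredRow:
    for row in MEASURED:
        if row.state == state and row.isomer == isomer:
            return row
    raise ConfigurationError(f"no measured data for state={state!r} isomer={isomer!r}")


def kobs_true(state: str, isomer: str, ligand_total: float = DEFAULT_LIGAND_TOTAL) -> float:
    """Unrounded apparent rate constant implied by the measured T."""
    row = measured_row(state, isomer)
    return 1.0 / (row.T_min * SECONDS_PER_MINUTE * ligand_total)


def default_isomers(
    state: str,
    protein_total: float = DEFAULT_PROTEIN_TOTAL,
    ligand_total: float = DEFAULT_LIGAND_TOTAL,
    K_H: float = 9.0,
    k_minus_H: float = 1.0,
) -> list[kinetics.IsomerSpec]:
    """Both heme-orientation isomers of one protein state at study conditions.

    Rates are collapsed from the unrounded T-derived k_obs (and published
    K_d when binding was incomplete) at the requested histidine equilibrium.
    """
    if state not in STATES:
        raise ConfigurationError(f"unknown protein state {state!r}")
    isomers = []
    for label in ("A", "B"):
        row = measured_row(state, label)
        kobs = kobs_true(state, label, ligand_total)
        rates = kinetics.collapsed_rates(kobs, kd=row.kd_printed, K_H=K_H, k_minus_H=k_minus_H)
        isomers.append(
            kinetics.IsomerSpec(
                label=label,
                total_conc=protein_total * ISOMER_SPLIT[label],
                rates=rates,
                redox_tag=state,
            )
        )
    return isomers


def recommended_duration_min(state: str, interval_min: float = 20.0, horizon: float = 4.0) -> float:
    """Acquisition length covering ``horizon`` time constants of the slower isomer."""
    t_max = max(measured_row(state, iso).T_min for iso in ("A", "B"))
    n = int(np.ceil(horizon * t_max / interval_min))
    return n * interval_min


def default_config(
    state: str,
    duration_min: float | None = None,
    interval_min: float = 20.0,
    protein_total: float = DEFAULT_PROTEIN_TOTAL,
    ligand_total: float = DEFAULT_LIGAND_TOTAL,
    reoxidation_tau_h: float | None = None,
    **isomer_kwargs,
) -> kinetics.SimulationConfig:
    """Simulation config for one protein state at the study conditions."""
    if duration_min is None:
        duration_min = recommended_duration_min(state, interval_min)
    times_min = np.arange(0.0, duration_min + 1e-9, interval_min)
    isomers = default_isomers(state, protein_total, ligand_total, **isomer_kwargs)
    if reoxidation_tau_h is not None and state in kinetics.REOXIDATION_PARTNER:
        # Receiver (oxidized) species carry the same nominal totals; they
        # start empty via initial_state(..., empty_keys=...) and fill by
        # red -> ox transfer.
        partner = kinetics.REOXIDATION_PARTNER[state]
        isomers += default_isomers(partner, protein_total, ligand_total, **isomer_kwargs)
    return kinetics.SimulationConfig(
        isomers=isomers,
        ligand_total=ligand_total,
        duration=duration_min * SECONDS_PER_MINUTE,
        output_times=times_min * SECONDS_PER_MINUTE,
        reoxidation_tau=None if reoxidation_tau_h is None else reoxidation_tau_h * 3600.0,
    )
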