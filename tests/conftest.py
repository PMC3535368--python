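import numpy as np
import pytest

from ngbkin import kinetics


@pytest.fixture
def single_isomer_config():
    """One isomer deep in the rapid pre-equilibrium regime, excess ligand."""
    rates = kinetics.RateConstants(k_H=50.0, k_minus_H=100.0, k_on_L=2.0, k_off_L=0.0)
    iso = kinetics.IsomerSpec(label="A", total_conc=1e-6, rates=rates, redox_tag="WT_ox")
    times = np.linspace(0.0, 6000.0, 25)
    return kinetics.SimulationConfig(
        isomers=[iso], ligand_total=500e-6, duration=6000.0, output_times=times
    )


def grid_scan_ligand_free(spec, n_coarse=100_000, n_fine=10_000):
    """Bisection-free oracle for the equilibrium free-ligand concentration.

    Dense scan of the ligand-conservation function, refined once around the
    sign change.  Stays independent of the solver under test.
    """
    def excess(L):
        total = L - spec.ligand_total
        for _, tot, kd in spec.species:
            total = total + tot * L / (L + kd)
        return total

    grid = np.linspace(0.0, spec.ligand_total, n_coarse)
    g = excess(grid)
    i = int(np.argmin(np.abs(g)))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_coarse - 1)]
    fine = np.linspace(lo, hi, n_fine)
    return float(fine[np.argmin(np.abs(excess(fine)))])
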