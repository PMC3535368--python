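"""Mass-action model of ligand binding to a hexacoordinate globin.

In the resting ferric protein the heme iron is axially ligated by both the
proximal and the distal histidine.  An external ligand (here the cyanide
anion) can only bind after the distal histidine transiently dissociates,
giving the competitive internal-ligation scheme

    hexa  <-- k_-H / k_H -->  penta  -- k_on,L [L] -->  penta·L

When histidine exchange is rapid compared with ligation
(``k_on,L·[L] << k_H, k_-H``) the scheme collapses to a single apparent
second-order binding step with rate constant

    k_obs = k_on,L / (1 + K_H),        K_H = k_H / k_-H

so the observed kinetics report directly on histidine–iron bond stability
(``K_H``) and ligand access to the pentacoordinate iron (``k_on,L``).

Heme b additionally sits in the pocket in two orientations (the A and B
isomers, related by a 180-degree rotation about the alpha–gamma meso axis)
that are chemically distinct and interconvert too slowly to matter on the
binding timescale.  The model therefore treats each orientation (and each
cysteine redox state of the protein) as an independent protein species,
all competing for one shared ligand pool.

This module provides the full mass-action right-hand side, a deterministic
stiff integrator, the closed-form pseudo-first-order limits, and a coupled
binding-equilibrium solver with ligand depletion.  Internal units are molar
and seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, DomainError, IntegrationError

__all__ = [
    "RateConstants",
    "IsomerSpec",
    "SpeciesConc",
    "SystemState",
    "SimulationConfig",
    "EquilibriumSpec",
    "EquilibriumResult",
    "mass_action_rhs",
    "integrate",
    "initial_state",
    "effective_kobs",
    "apparent_kobs",
    "collapsed_rates",
    "pseudo_first_order_bound_fraction",
    "solve_equilibrium",
    "induced_equilibrium_spec",
    "REOXIDATION_PARTNER",
]

#: Protein state labels understood by the model.
STATES = ("WT_ox", "WT_red", "C120S_ox", "C120S_red", "TM")

#: Slow air reoxidation converts cysteine-reduced protein back to the
#: disulfide-bridged form, preserving heme orientation and ligation state.
REOXIDATION_PARTNER = {"WT_red": "WT_ox", "C120S_red": "C120S_ox"}

_CHANNELS = ("hexa", "penta", "bound")


@dataclass(frozen=True)
class RateConstants:
    """Microscopic rates of the hexa <-> penta -> bound scheme for one isomer.

    Parameters
    ----------
    k_H : float
        Distal-histidine rebinding rate, penta -> hexa, s^-1.
    k_minus_H : float
        Histidine dissociation rate, hexa -> penta, s^-1.
    k_on_L : float
        Second-order ligand association to pentacoordinate iron, M^-1 s^-1.
    k_off_L : float
        First-order ligand dissociation, s^-1.
    """

    k_H: float
    k_minus_H: float
    k_on_L: float
    k_off_L: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_H", "k_minus_H", "k_on_L", "k_off_L"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise DomainError(f"rate constant {name} must be finite and >= 0, got {v}")

    @property
    def K_H(self) -> float:
        """Histidine–iron equilibrium constant k_H / k_-H (hexa over penta)."""
        if self.k_minus_H == 0:
            raise DomainError("K_H is infinite when k_minus_H = 0")
        return self.k_H / self.k_minus_H


@dataclass(frozen=True)
class IsomerSpec:
    """One protein species: a heme orientation within one redox state."""

    label: str
    total_conc: float
    rates: RateConstants
    redox_tag: str = "WT_ox"

    def __post_init__(self) -> None:
        if self.label not in ("A", "B"):
            raise ConfigurationError(f"isomer label must be 'A' or 'B', got {self.label!r}")
        if not self.total_conc > 0:
            raise DomainError(f"total_conc must be > 0, got {self.total_conc}")
        if self.redox_tag not in STATES:
            raise ConfigurationError(
                f"redox_tag must be one of {STATES}, got {self.redox_tag!r}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.redox_tag, self.label)


@dataclass
class SpeciesConc:
    """Concentrations (molar) of the three ligation states of one isomer."""

    hexa: float = 0.0
    penta: float = 0.0
    bound: float = 0.0

    @property
    def total(self) -> float:
        return self.hexa + self.penta + self.bound

    @property
    def unbound(self) -> float:
        """Ligand-free protein (hexa + penta): what a met-state resonance sees."""
        return self.hexa + self.penta


@dataclass
class SystemState:
    """Concentrations of every protein sub-species plus free ligand at one time.

    ``species`` maps ``(redox_tag, label)`` to a :class:`SpeciesConc`.
    """

    time: float
    species: dict[tuple[str, str], SpeciesConc]
    ligand_free: float

    def require_nonnegative(self) -> None:
        if self.ligand_free < 0:
            raise DomainError(f"negative free ligand concentration: {self.ligand_free}")
        for key, sc in self.species.items():
            for ch in _CHANNELS:
                if getattr(sc, ch) < 0:
                    raise DomainError(f"negative concentration for {key} {ch}")

    def protein_total(self, key: tuple[str, str]) -> float:
        return self.species[key].total

    def ligand_total(self) -> float:
        return self.ligand_free + sum(sc.bound for sc in self.species.values())


@dataclass
class SimulationConfig:
    """Everything needed to integrate the mixture model.

    Times are seconds (internal canonical unit); ``output_times`` must be
    strictly increasing and lie within ``[0, duration]``.  ``reoxidation_tau``
    optionally turns on a first-order, ligation-state-preserving red -> ox
    conversion (air reoxidation of the disulfide bridge) with that time
    constant; it requires the matching oxidized isomer to be present.
    """

    isomers: list[IsomerSpec]
    ligand_total: float
    duration: float
    output_times: np.ndarray
    reoxidation_tau: float | None = None
    integrator_rel_tol: float = 1e-8
    integrator_abs_tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.ligand_total < 0:
            raise DomainError(f"ligand_total must be >= 0, got {self.ligand_total}")
        if self.duration < 0:
            raise DomainError("duration must be >= 0")
        self.output_times = np.asarray(self.output_times, dtype=float)
        if self.output_times.ndim != 1:
            raise ConfigurationError("output_times must be one-dimensional")
        if self.output_times.size:
            if np.any(np.diff(self.output_times) <= 0):
                raise ConfigurationError("output_times must be strictly increasing")
            if self.output_times[0] < 0 or self.output_times[-1] > self.duration + 1e-9:
                raise ConfigurationError("output_times must lie within [0, duration]")
        keys = [iso.key for iso in self.isomers]
        if len(set(keys)) != len(keys):
            raise ConfigurationError("duplicate (redox_tag, label) isomer keys")
        if self.reoxidation_tau is not None:
            if not self.reoxidation_tau > 0:
                raise DomainError("reoxidation_tau must be > 0 when set")
            present = set(keys)
            for tag, label in present:
                partner = REOXIDATION_PARTNER.get(tag)
                if partner is not None and (partner, label) not in present:
                    raise ConfigurationError(
                        f"reoxidation requires isomer ({partner!r}, {label!r}) "
                        f"to receive material from ({tag!r}, {label!r})"
                    )

    def isomer(self, key: tuple[str, str]) -> IsomerSpec:
        for iso in self.isomers:
            if iso.key == key:
                return iso
        raise ConfigurationError(f"unknown isomer {key!r}")

    @property
    def keys(self) -> list[tuple[str, str]]:
        return [iso.key for iso in self.isomers]


# ---------------------------------------------------------------------------
# closed-form limits


def effective_kobs(rates: RateConstants) -> float:
    """Apparent second-order rate constant under rapid pre-equilibrium.

    Returns ``k_on_L / (1 + K_H)``: only the pentacoordinate fraction
    ``1/(1 + K_H)`` of the unbound protein is competent for ligation, so a
    stabler histidine–iron bond (larger K_H) slows observed binding.
    Raises :class:`DomainError` when ``k_minus_H = 0`` (K_H infinite).
    """
    if rates.k_minus_H == 0:
        raise DomainError("effective_kobs undefined for k_minus_H = 0 (K_H infinite)")
    return rates.k_on_L / (1.0 + rates.k_H / rates.k_minus_H)


def apparent_kobs(rates: RateConstants) -> float:
    """Like :func:`effective_kobs` but tolerating the fully open channel.

    With ``k_H = 0`` there is no hexacoordinate trap and the apparent rate
    is ``k_on_L`` regardless of ``k_minus_H``.
    """
    if rates.k_minus_H == 0:
        if rates.k_H == 0:
            return rates.k_on_L
        raise DomainError("apparent k_obs undefined: k_minus_H = 0 with k_H > 0")
    return effective_kobs(rates)


def collapsed_rates(
    kobs: float,
    kd: float | None = None,
    K_H: float = 9.0,
    k_minus_H: float = 1.0,
) -> RateConstants:
    """Microscopic rates reproducing an observed (k_obs, K_d) pair.

    Experiments determine only the apparent constants; the microscopic
    histidine exchange rates are unknown.  This helper places the system
    deep in the rapid pre-equilibrium regime at a chosen ``K_H`` (default 9,
    i.e. 90 % hexacoordinate at rest, with ``k_minus_H`` = 1 s^-1), and
    back-computes ``k_on_L = kobs * (1 + K_H)`` and
    ``k_off_L = kd * kobs`` (0 when ``kd`` is None, irreversible binding).
    """
    if kobs < 0:
        raise DomainError("kobs must be >= 0")
    if K_H < 0 or not k_minus_H > 0:
        raise DomainError("require K_H >= 0 and k_minus_H > 0")
    k_off = 0.0 if kd is None else float(kd) * kobs
    return RateConstants(
        k_H=K_H * k_minus_H,
        k_minus_H=k_minus_H,
        k_on_L=kobs * (1.0 + K_H),
        k_off_L=k_off,
    )


def pseudo_first_order_bound_fraction(
    kobs: float, koff: float, L: float, t, mode: str = "paper"
):
    """Bound fraction of a single species under pseudo-first-order kinetics.

    mode="paper"
        ``1 - exp(-kobs * L * t)`` — the observed rate is ``kobs * [L]`` with
        the plateau handled separately, the convention used to convert the
        measured time constants (``1/T = k_obs [CN-]``).
    mode="reversible"
        ``f_eq * (1 - exp(-(kobs*L + koff) * t))`` with
        ``f_eq = kobs*L / (kobs*L + koff)`` — the exact relaxation of the
        reversible two-state system at fixed ligand concentration.

    ``t`` is in seconds and may be an array.
    """
    t = np.asarray(t, dtype=float)
    if kobs < 0 or koff < 0 or L < 0 or np.any(t < 0):
        raise DomainError("kobs, koff, L and t must all be >= 0")
    if mode == "paper":
        out = 1.0 - np.exp(-kobs * L * t)
    elif mode == "reversible":
        rate = kobs * L + koff
        if rate == 0:
            out = np.zeros_like(t)
        else:
            f_eq = kobs * L / rate
            out = f_eq * (1.0 - np.exp(-rate * t))
    else:
        raise DomainError(f"mode must be 'paper' or 'reversible', got {mode!r}")
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# mass-action dynamics


def _pack(state: SystemState, config: SimulationConfig) -> np.ndarray:
    y = np.empty(3 * len(config.isomers) + 1)
    for i, key in enumerate(config.keys):
        if key not in state.species:
            raise ConfigurationError(f"state is missing isomer {key!r}")
        sc = state.species[key]
        y[3 * i : 3 * i + 3] = (sc.hexa, sc.penta, sc.bound)
    extra = set(state.species) - set(config.keys)
    if extra:
        raise ConfigurationError(f"state contains isomers unknown to config: {sorted(extra)}")
    y[-1] = state.ligand_free
    return y


def _unpack(t: float, y: np.ndarray, config: SimulationConfig) -> SystemState:
    species = {}
    for i, key in enumerate(config.keys):
        h, p, b = y[3 * i : 3 * i + 3]
        species[key] = SpeciesConc(hexa=h, penta=p, bound=b)
    return SystemState(time=t, species=species, ligand_free=y[-1])


def _rhs_vec(t: float, y: np.ndarray, config: SimulationConfig) -> np.ndarray:
    dy = np.zeros_like(y)
    L = y[-1]
    index = {key: i for i, key in enumerate(config.keys)}
    for i, iso in enumerate(config.isomers):
        h, p, b = y[3 * i : 3 * i + 3]
        r = iso.rates
        open_flux = r.k_minus_H * h          # hexa -> penta
        close_flux = r.k_H * p               # penta -> hexa
        bind_flux = r.k_on_L * p * L         # penta + L -> bound
        release_flux = r.k_off_L * b         # bound -> penta + L
        dy[3 * i + 0] += close_flux - open_flux
        dy[3 * i + 1] += open_flux - close_flux - bind_flux + release_flux
        dy[3 * i + 2] += bind_flux - release_flux
        dy[-1] += release_flux - bind_flux
        if config.reoxidation_tau is not None:
            partner = REOXIDATION_PARTNER.get(iso.redox_tag)
            if partner is not None:
                j = index[(partner, iso.label)]
                k_reox = 1.0 / config.reoxidation_tau
                for ch in range(3):
                    flux = k_reox * y[3 * i + ch]
                    dy[3 * i + ch] -= flux
                    dy[3 * j + ch] += flux
    return dy


def mass_action_rhs(state: SystemState, config: SimulationConfig) -> SystemState:
    """Time derivative of every concentration under mass action.

    Returns a :class:`SystemState` whose fields hold d(conc)/dt in M/s.
    Protein is conserved per isomer family (summing over redox tags when
    reoxidation is active) and ligand flux mirrors the net binding flux by
    construction.
    """
    state.require_nonnegative()
    y = _pack(state, config)
    dy = _rhs_vec(state.time, y, config)
    return _unpack(state.time, dy, config)


def initial_state(
    config: SimulationConfig,
    his_equilibrated: bool = True,
    empty_keys: tuple[tuple[str, str], ...] = (),
) -> SystemState:
    """Pre-injection state: no ligand bound, full ligand pool free.

    With ``his_equilibrated`` the hexa/penta split of each isomer sits at the
    histidine–iron equilibrium ``hexa = K_H/(1+K_H) * total`` (the resting
    protein); otherwise everything starts hexacoordinate.  Keys listed in
    ``empty_keys`` start with zero material (e.g. the oxidized receiver
    species of a reoxidation run, populated only by red -> ox transfer).
    """
    species = {}
    for iso in config.isomers:
        tot = 0.0 if iso.key in empty_keys else iso.total_conc
        if his_equilibrated and iso.rates.k_minus_H > 0:
            KH = iso.rates.K_H
            species[iso.key] = SpeciesConc(hexa=tot * KH / (1 + KH), penta=tot / (1 + KH))
        else:
            species[iso.key] = SpeciesConc(hexa=tot)
    return SystemState(time=0.0, species=species, ligand_free=config.ligand_total)


def integrate(config: SimulationConfig, initial: SystemState) -> list[SystemState]:
    """Integrate the mass-action system, sampled at ``config.output_times``.

    Uses a stiff-capable adaptive method (LSODA) at the configured
    tolerances; the result is deterministic for fixed inputs.  Conservation
    of protein and ligand holds within the integrator tolerances.
    """
    initial.require_nonnegative()
    y0 = _pack(initial, config)
    times = config.output_times
    if times.size == 0:
        return []
    if config.duration == 0 or (times.size == 1 and times[0] == initial.time):
        return [replace(initial, species={k: replace(v) for k, v in initial.species.items()})]
    t0 = float(initial.time)
    t_end = max(config.duration, float(times[-1]))
    sol = solve_ivp(
        _rhs_vec,
        (t0, t_end),
        y0,
        method="LSODA",
        t_eval=times,
        rtol=config.integrator_rel_tol,
        atol=config.integrator_abs_tol,
        args=(config,),
    )
    if not sol.success:
        reached = sol.t[-1] if sol.t.size else t0
        raise IntegrationError(
            f"integration failed between t = {reached:.6g} s and {t_end:.6g} s: {sol.message}"
        )
    # Clip integrator-level negative round-off (within abs tolerance) to zero.
    y = np.where((sol.y < 0) & (sol.y > -10 * config.integrator_abs_tol), 0.0, sol.y)
    return [_unpack(float(t), y[:, j], config) for j, t in enumerate(sol.t)]


# ---------------------------------------------------------------------------
# coupled binding equilibrium with ligand depletion


@dataclass(frozen=True)
class EquilibriumSpec:
    """Independent binding species competing for one ligand pool.

    ``species`` is a list of ``(label, total_conc, K_d)`` with all K_d > 0.
    """

    species: list[tuple[str, float, float]]
    ligand_total: float

    def __post_init__(self) -> None:
        if self.ligand_total < 0:
            raise DomainError("ligand_total must be >= 0")
        for label, tot, kd in self.species:
            if tot < 0:
                raise DomainError(f"total_conc for {label!r} must be >= 0")
            if not kd > 0:
                raise DomainError(f"K_d for {label!r} must be > 0")


@dataclass(frozen=True)
class EquilibriumResult:
    ligand_free: float
    bound: dict[str, float]
    free_fraction: dict[str, float]


def solve_equilibrium(spec: EquilibriumSpec, rel_tol: float = 1e-10) -> EquilibriumResult:
    """Free ligand and per-species bound concentrations at equilibrium.

    Solves the ligand-conservation equation

        L + sum_i total_i * L / (L + K_d,i) = ligand_total

    for ``L`` in ``[0, ligand_total]`` by bisection.  The left-hand side is
    strictly increasing in L, so the root is unique and always bracketed.
    """
    L_tot = spec.ligand_total
    if L_tot == 0 or not spec.species:
        bound = {label: 0.0 for label, _, _ in spec.species}
        frac = {label: 1.0 for label, _, _ in spec.species}
        return EquilibriumResult(ligand_free=L_tot, bound=bound, free_fraction=frac)

    def excess(L: float) -> float:
        return L + sum(tot * L / (L + kd) for _, tot, kd in spec.species) - L_tot

    lo, hi = 0.0, L_tot
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0.0:
            hi = mid
        else:
            lo = mid
        if hi - lo <= rel_tol * max(hi, 1e-300):
            break
    L_free = 0.5 * (lo + hi)
    bound = {label: tot * L_free / (L_free + kd) for label, tot, kd in spec.species}
    frac = {label: kd / (L_free + kd) for label, tot, kd in spec.species}
    return EquilibriumResult(ligand_free=L_free, bound=bound, free_fraction=frac)


def induced_equilibrium_spec(config: SimulationConfig) -> EquilibriumSpec:
    """Equilibrium spec implied by a kinetic config (requires k_off_L > 0).

    The effective dissociation constant of the collapsed scheme is
    ``K_d = k_off_L / k_obs`` with ``k_obs = k_on_L / (1 + K_H)``: histidine
    competition weakens apparent affinity by the factor ``1 + K_H``.
    """
    species = []
    for iso in config.isomers:
        if iso.rates.k_off_L <= 0:
            raise DomainError(
                f"isomer {iso.key!r} has k_off_L = 0; no finite equilibrium K_d"
            )
        kd = iso.rates.k_off_L / apparent_kobs(iso.rates)
        species.append(("/".join(iso.key), iso.total_conc, kd))
    return EquilibriumSpec(species=species, ligand_total=config.ligand_total)
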