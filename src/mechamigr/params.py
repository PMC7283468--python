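"""Model parameters, validation, unit handling, and the parameter-study grid.

All internal computation is in SI units (m, s, N, Pa).  Config documents may
declare values with a convenience-unit suffix (``"2 nN"``, ``"30 min"``,
``"3.5 um"``); they are converted once at load time.

The tunable surface splits into two groups:

* the published model parameters (cell radius, cortex stiffness, adhesion
  kinetics, rupture force, ...), and
* *extension* parameters for the standard discrete-membrane energies, contact
  mechanics and friction whose exact published forms live outside the model's
  core description; their defaults come from the calibration procedures
  described in ``docs/methods.md`` and every one is overridable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, fields, asdict
from typing import Iterable, Sequence

import yaml

__all__ = [
    "ParamSet",
    "Condition",
    "Setup",
    "ParamValidationError",
    "load_params",
    "serialize_params",
    "enumerate_conditions",
    "stiffness_to_modulus",
    "TABLE2_KECM",
    "TABLE2_ROFF",
]


class ParamValidationError(ValueError):
    """A parameter failed validation; the message names the offending key."""


#: Substrate ligand stiffness values of the published study grid [N/m].
TABLE2_KECM = (1e-3, 3.5e-3, 1.2e-2, 4.16e-2, 1.44e-1, 5e-1)
#: Zero-force FA disassembly rates of the published study grid [1/s].
TABLE2_ROFF = (5e-2, 1.08e-2, 2.3e-3, 5e-4)

# Multipliers to SI for the unit suffixes a config document may use.
_UNIT_FACTORS = {
    "m": 1.0, "um": 1e-6, "µm": 1e-6, "nm": 1e-9, "mm": 1e-3,
    "s": 1.0, "min": 60.0, "h": 3600.0,
    "N": 1.0, "nN": 1e-9, "pN": 1e-12, "uN": 1e-6,
    "N/m": 1.0, "nN/um": 1e-3, "pN/nm": 1e-3,
    "N*s/m": 1.0, "N.s/m": 1.0,
    "1/s": 1.0, "1/min": 1.0 / 60.0,
    "1/N": 1.0, "1/nN": 1e9, "1/pN": 1e12,
    "m^2/s": 1.0, "um^2/s": 1e-12,
    "1/m": 1.0, "1/um": 1e6, "1/nm": 1e9,
    "1/m^2/s": 1.0, "1/um^2/s": 1e12,
    "Pa": 1.0, "kPa": 1e3,
    "J": 1.0,
    "m^2": 1.0, "um^2": 1e-12,
    "N*m^2": 1.0,
}


def _to_si(value, key: str) -> float:
    """Convert a config value (number or ``"number unit"`` string) to SI."""
    if isinstance(value, bool):
        raise ParamValidationError(f"{key}: expected a number, got a boolean")
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        parts = value.split()
        if len(parts) == 2 and parts[1] in _UNIT_FACTORS:
            try:
                return float(parts[0]) * _UNIT_FACTORS[parts[1]]
            except ValueError:
                pass
        try:
            return float(value)
        except ValueError:
            raise ParamValidationError(
                f"{key}: cannot parse {value!r} (unknown unit or malformed number)"
            ) from None
    raise ParamValidationError(f"{key}: unsupported value type {type(value).__name__}")


@dataclass(frozen=True)
class ParamSet:
    """Validated model parameters in SI units.

    Attributes
    ----------
    R_c
        Cell radius [m].
    L_fib_min0
        Minimum initial stress-fiber length [m].
    k_cortex
        Cortex edge spring constant [N/m].
    Lambda_d
        Cortex edge damping constant [N s/m].
    k_gen
        Globular-actin source rate on periphery triangles [molecules/m^2/s].
    k_deg
        Globular-actin decay rate [1/s].
    D_actin
        Surface diffusivity of globular actin [m^2/s].
    k_FA
        Focal-adhesion spring stiffness [N/m].
    L_FA0, L_ECM0
        Rest lengths of the FA and ligand springs [m].
    r_on_FA
        FA binding rate [1/s].
    zeta_FA
        FA mechanosensitivity (force scale of catch-like stabilization) [1/N].
    lambda_ref
        Refractory duration after rupture / full retraction [s].
    k_prot
        Protrusion gain: force per unit actin concentration on a
        lamellipodium triangle [N m^2 / molecule].  Calibrated so the mean
        per-triangle protrusion force on the initialized spread cell is
        0.12 nN (see docs/methods.md).
    F_am
        Reference actomyosin force of one stress fiber unit [N].
    F_rup
        FA rupture force [N].
    L_thr
        Stall threshold on the change of the 10 s moving-average fiber
        length between consecutive comparisons [m].
    mu
        Logistic slope of stress-fiber weakening with shortening [1/m].
    dL50
        Fiber shortening at which the contractile force is halved [m].
    n_thr
        Number of ruptures within ``rupture_window`` that triggers a full
        (collective) retraction [count].
    n_str_max
        Strengthening cap [count].
    beta_front, beta_rear
        Polarity factors on the FA disassembly rate (rear FAs are less
        stable) [dimensionless].
    outside_Lm_factor
        Disassembly-rate multiplier for FAs that left the lamella.
    bind_distance
        Maximum vertical node–substrate distance for FA formation [m].
    dt
        Time step [s].
    ma_window
        Moving-average window for fiber-length filtering [s].
    rupture_window
        Trailing window for counting ruptures toward a full retraction [s].
    """

    # -- published model parameters -------------------------------------
    R_c: float = 8e-6
    L_fib_min0: float = 8e-6
    k_cortex: float = 2.9e-4
    Lambda_d: float = 5e-1
    k_gen: float = 1.18e11
    k_deg: float = 0.016
    D_actin: float = 8e-14
    k_FA: float = 1e3
    L_FA0: float = 1e-10
    L_ECM0: float = 1.4e-9
    r_on_FA: float = 5e-3
    zeta_FA: float = 1.21e9
    lambda_ref: float = 1800.0
    k_prot: float = 7.379e-23
    F_am: float = 1.0e-9
    F_rup: float = 7.7e-9
    L_thr: float = 7.5e-11
    mu: float = 5.0e6
    dL50: float = 3.5e-6
    n_thr: int = 15
    n_str_max: int = 5
    beta_front: float = 1.0
    beta_rear: float = 2.0
    outside_Lm_factor: float = 10.0
    bind_distance: float = 7.5e-8
    dt: float = 0.05
    ma_window: float = 10.0
    rupture_window: float = 60.0

    # -- extension parameters (documented design choices) ----------------
    #: Local per-triangle area stiffness [N/m].
    k_area_loc: float = 2e-2
    #: Global area stiffness [N/m].
    k_area_glob: float = 5e-4
    #: Volume stiffness (pressure per relative volume change) [Pa].
    k_vol: float = 4e3
    #: Hinge bending stiffness [J].
    k_bend: float = 3e-18
    #: Contact friction per interface node [N s/m].
    Gamma_subs: float = 5e-1
    #: Stokes-like liquid drag per node [N s/m].
    Gamma_liquid: float = 1e-3
    #: Lamellipodium threshold, as a fraction of the source steady state.
    theta_Lp: float = 0.17
    #: Lamellum threshold, as a fraction of the source steady state.
    theta_Lm: float = 0.09
    #: Maximum duration of the attach-and-spread initialization phase [s].
    init_duration: float = 1800.0

    # contact-mechanics extension parameters
    #: Effective contact modulus of the cortex–substrate pair [Pa].
    E_contact: float = 1e8
    #: Dugdale adhesive stress of the transient contact [Pa].
    sigma0_contact: float = 2.5e4
    #: Dugdale adhesive range (gap below which adhesive stress acts) [m].
    h_contact: float = 4e-7
    #: Cap on the fitted-sphere radius used in contact (flat patches) [m].
    R_contact_max: float = 3.2e-5
    #: Linear node–plane repulsion penalty [N/m] (keeps nodes within ~1 nm).
    k_wall: float = 10.0
    #: Stress-fiber pairing attempt rate per unbound FA [1/s].
    sf_pair_rate: float = 5e-2
    #: Height below which a node counts as in the cell–substrate interface [m].
    interface_height: float = 4.5e-7

    def __post_init__(self):
        positive = [
            "R_c", "L_fib_min0", "k_cortex", "Lambda_d", "k_gen", "k_deg",
            "D_actin", "k_FA", "L_FA0", "L_ECM0", "r_on_FA", "zeta_FA",
            "lambda_ref", "k_prot", "F_am", "F_rup", "L_thr", "mu", "dL50",
            "beta_front", "beta_rear", "outside_Lm_factor", "bind_distance",
            "dt", "ma_window", "rupture_window", "k_area_loc", "k_area_glob",
            "k_vol", "k_bend", "Gamma_subs", "Gamma_liquid", "theta_Lp",
            "theta_Lm", "init_duration", "E_contact", "sigma0_contact",
            "h_contact", "R_contact_max", "k_wall", "sf_pair_rate", "interface_height",
        ]
        for name in positive:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ParamValidationError(f"{name}: must be a finite positive number, got {v!r}")
        for name in ("n_thr", "n_str_max"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 1):
                raise ParamValidationError(f"{name}: must be an integer >= 1, got {v!r}")
        if self.beta_rear <= self.beta_front:
            raise ParamValidationError(
                f"beta_rear ({self.beta_rear}) must exceed beta_front ({self.beta_front})"
            )
        if self.theta_Lm >= self.theta_Lp:
            raise ParamValidationError(
                f"theta_Lm ({self.theta_Lm}) must be below theta_Lp ({self.theta_Lp})"
            )
        for name in ("ma_window", "rupture_window"):
            ratio = getattr(self, name) / self.dt
            if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio):
                raise ParamValidationError(
                    f"{name} ({getattr(self, name)}) must be an integer multiple of dt ({self.dt})"
                )

    # convenience -------------------------------------------------------
    @property
    def G_star(self) -> float:
        """Steady-state actin concentration on a source triangle, k_gen/k_deg."""
        return self.k_gen / self.k_deg

    def series_stiffness(self, k_ECM: float) -> float:
        """Series stiffness of the FA + ligand spring pair [N/m]."""
        return 1.0 / (1.0 / self.k_FA + 1.0 / k_ECM)

    def replace(self, **overrides) -> "ParamSet":
        d = asdict(self)
        d.update(overrides)
        return ParamSet(**d)


@dataclass(frozen=True)
class Condition:
    """A substrate condition: ligand stiffness and zero-force FA disassembly rate."""

    k_ECM: float
    r_off_FA0: float

    def __post_init__(self):
        if not (self.k_ECM > 0):
            raise ParamValidationError(f"k_ECM: must be positive, got {self.k_ECM!r}")
        if not (0.0 < self.r_off_FA0 < 1.0):
            raise ParamValidationError(
                f"r_off_FA0: must be in (0, 1) per second, got {self.r_off_FA0!r}"
            )


@dataclass(frozen=True)
class Setup:
    """Mechanosensing switches: FA maturation and SF strengthening."""

    FA_mat: bool = True
    SF_str: bool = True

    @property
    def label(self) -> str:
        return (f"FAmat[{'ON' if self.FA_mat else 'OFF'}]"
                f"||SFstr[{'ON' if self.SF_str else 'OFF'}]")


ALL_SETUPS = (
    Setup(FA_mat=False, SF_str=False),
    Setup(FA_mat=True, SF_str=False),
    Setup(FA_mat=False, SF_str=True),
    Setup(FA_mat=True, SF_str=True),
)

_FIELD_NAMES = {f.name for f in fields(ParamSet)}
_INT_FIELDS = {"n_thr", "n_str_max"}


def load_params(document: str | dict | None = None, **overrides) -> ParamSet:
    """Build a validated :class:`ParamSet` from a YAML document and overrides.

    Parameters
    ----------
    document
        YAML text, a pre-parsed mapping, or None for pure defaults.  Values
        may be numbers (SI) or ``"number unit"`` strings in one of the
        declared convenience units (``um``, ``nN``, ``min``, ...).
    **overrides
        Programmatic key=value overrides applied after the document.

    Raises
    ------
    ParamValidationError
        On unknown keys, unparsable values, or physical-validity violations.
    """
    data: dict = {}
    if document is not None:
        parsed = yaml.safe_load(document) if isinstance(document, str) else dict(document)
        if parsed is None:
            parsed = {}
        if not isinstance(parsed, dict):
            raise ParamValidationError("config document must be a key-value mapping")
        data.update(parsed)
    data.update(overrides)

    unknown = sorted(set(data) - _FIELD_NAMES)
    if unknown:
        raise ParamValidationError(f"unknown parameter key(s): {', '.join(unknown)}")

    converted = {}
    for key, value in data.items():
        if key in _INT_FIELDS:
            v = _to_si(value, key)
            if abs(v - round(v)) > 1e-9:
                raise ParamValidationError(f"{key}: must be an integer, got {value!r}")
            converted[key] = int(round(v))
        else:
            converted[key] = _to_si(value, key)
    return ParamSet(**converted)


def serialize_params(params: ParamSet) -> str:
    """Serialize a ParamSet to a YAML document (SI units; round-trips with load_params)."""
    return yaml.safe_dump(asdict(params), sort_keys=True)


def enumerate_conditions(
    stiffness_list: Sequence[float],
    rate_list: Sequence[float],
    setups: Iterable[Setup] = ALL_SETUPS,
    reps: int = 5,
    base_seed: int = 0,
):
    """Enumerate the parameter-study run manifest.

    The cross product of conditions x setups x replicates, in deterministic
    order, with a unique seed per run derived from ``base_seed``.

    Returns
    -------
    pandas.DataFrame
        Columns: run_id, k_ECM, r_off_FA0, FA_mat, SF_str, rep, seed.
    """
    import pandas as pd

    setups = list(setups)
    if not stiffness_list or not rate_list or not setups:
        raise ParamValidationError("stiffness_list, rate_list and setups must be nonempty")
    if reps < 1:
        raise ParamValidationError("reps must be >= 1")
    pairs = list(itertools.product(stiffness_list, rate_list))
    if len(set(pairs)) != len(pairs):
        raise ParamValidationError("duplicate condition pairs in the grid")
    for k, r in pairs:
        Condition(k_ECM=k, r_off_FA0=r)  # validates

    rows = []
    run_id = 0
    for setup in setups:
        for (k, r) in pairs:
            for rep in range(reps):
                seed = (int(base_seed) + run_id) % (2**31 - 1)
                rows.append({
                    "run_id": run_id,
                    "k_ECM": k,
                    "r_off_FA0": r,
                    "FA_mat": setup.FA_mat,
                    "SF_str": setup.SF_str,
                    "rep": rep,
                    "seed": seed,
                })
                run_id += 1
    manifest = pd.DataFrame(rows)
    if manifest["seed"].duplicated().any():
        raise ParamValidationError("seed collision in run manifest")
    return manifest


#: Characteristic length converting ligand spring stiffness to an approximate
#: Young's modulus.  Recovered from the six printed (k_ECM, E_ECM) pairs of the
#: study grid, which are all consistent with E = k_ECM / (4 um).
L_CHAR_MODULUS = 4e-6


def stiffness_to_modulus(k_ECM: float) -> float:
    """Approximate Young's modulus [kPa] for a ligand spring stiffness [N/m].

    Linear conversion E = k_ECM / L_char with L_char = 4 um, which matches all
    six printed stiffness/modulus pairs of the study grid to 3 significant
    figures.
    """
    if not (k_ECM > 0):
        raise ParamValidationError(f"k_ECM must be positive, got {k_ECM!r}")
    return k_ECM / L_CHAR_MODULUS / 1e3
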