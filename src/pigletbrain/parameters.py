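"""Physiological parameters of the reduced piglet-brain model.

The model is controlled by ten named physiological parameters (the set that
is screened and fitted) plus a dictionary of structural constants that define
the vascular, oxygen-transport and metabolic machinery.  Two reference sets
ship with the package: the *default* (normal-physiology) values and the
*optimised* values obtained by calibrating the model to a hypoxia-ischaemia
(HI) cohort.  The optimised set differs from the default set by fixed
percentage changes; either can be reconstructed from the other.
"""

from __future__ import annotations

import dataclasses
import json
import math
from importlib import resources
from typing import Iterator, Mapping

import yaml

__all__ = [
    "ParameterSet",
    "default_parameters",
    "optimised_parameters",
    "percent_change",
    "default_bounds",
    "FITTED_NAMES",
    "STRUCTURAL_DEFAULTS",
    "load_parameters",
    "save_parameters",
]

#: Names of the ten physiological parameters exposed to screening and fitting.
FITTED_NAMES = (
    "cco_tot",
    "lac_n",
    "hbtot_n",
    "pa_n",
    "ph_m_n",
    "k_aut",
    "r_m",
    "oxfrac_n",
    "f_carotid",
    "glu_rate_n",
)

#: Units of the named parameters, for reports and serialised files.
UNITS = {
    "cco_tot": "mM",
    "lac_n": "mM",
    "hbtot_n": "mM",
    "pa_n": "mmHg",
    "ph_m_n": "pH",
    "k_aut": "1",
    "r_m": "cm",
    "oxfrac_n": "1",
    "f_carotid": "1",
    "glu_rate_n": "mM/s",
}

# Structural constants: fixed machinery of the reduced model.  These are not
# screened or fitted; they set the vessel mechanics, oxygen transport,
# metabolic stoichiometry and proton handling.  Units in the comments.
STRUCTURAL_DEFAULTS: dict[str, float] = {
    "r_n": 0.0187,        # cm, baseline arterial radius
    "r_0": 0.0126,        # cm, elastic tension anchor radius
    "r_t": 0.0210,        # cm, radius of peak active wall tension
    "n_m": 1.83,          # -, active-tension shape exponent
    "sig_e0": 0.02,       # mmHg*cm, elastic tension scale
    "k_sig": 4.0,         # -, elastic exponential stiffness
    "sig_coll": 0.05,     # mmHg*cm, collapse tension offset
    "t_max": 1.0,         # mmHg*cm, peak active tension at full activation
    "k_r": 0.005,         # cm/(mmHg*cm*s), radius relaxation rate
    "p_v": 4.0,           # mmHg, venous pressure
    "g_pa": 0.3,          # -, myogenic (pressure) activation gain
    "g_o2": 1.2,          # -, metabolic (O2) vasodilation gain
    "g_co2": 1.0,         # -, CO2 vasodilation gain
    "paco2_n": 40.0,      # mmHg, reference arterial CO2 tension
    "sao2_n": 0.96,       # -, reference arterial O2 saturation
    "s_v_n": 0.64,        # -, baseline venous O2 saturation
    "hb_ref": 5.40,       # mM, reference haemoglobin for flow calibration
    "h_t": 2.5,           # -, venous-equilibration Hill exponent
    "o2c_n": 0.024,       # mM, baseline tissue O2 concentration
    "km_o2": 0.030,       # mM, O2 Michaelis constant of oxidative metabolism
    "k_ox": 0.05,         # 1/s, CuA redox turnover rate
    "km_adp": 0.15,       # mM, ADP Michaelis constant of oxidative demand
    "frac_an_n": 0.05,    # -, baseline anaerobic fraction of glucose flux
    "k_pasteur": 0.5,     # -, glycolytic upregulation gain on ATP deficit
    "n_atp_ox": 30.0,     # -, ATP per glucose from oxidative phosphorylation
    "atp_n": 2.40,        # mM, baseline ATP
    "adn_tot": 2.70,      # mM, total adenine pool (ATP + ADP)
    "cr_tot": 12.0,       # mM, total creatine pool (PCr + Cr)
    "pi_n": 1.50,         # mM, baseline inorganic phosphate
    "km_pi": 0.05,        # mM, Pi Michaelis constant of ATP synthesis
    "k_ck": 0.20,         # 1/(mM*s), creatine kinase rate constant
    "keq_ck": 6.8,        # -, creatine kinase equilibrium constant
    "beta_buf": 20.0,     # mM per pH unit, intracellular buffering capacity
    "h_per_atp": 0.35,    # -, protons per unit net ATP hydrolysis imbalance
    "k_ph_rec": 0.0015,   # 1/s, proton extrusion (pH recovery) rate
    "vb_n": 0.04,         # -, baseline blood volume fraction of tissue
    "w_art": 0.30,        # -, arterial share of blood volume
    "s_v_floor": 0.02,    # -, smooth floor on venous saturation
    "mu_soft": 0.05,      # -, softplus scale for vascular activation
}


@dataclasses.dataclass(frozen=True)
class ParameterSet:
    """Named physiological parameters plus structural constants.

    Attributes
    ----------
    cco_tot : float
        Total cytochrome-c-oxidase (CuA) concentration in tissue, mM.
    lac_n : float
        Normal cytoplasmic lactate concentration, mM.
    hbtot_n : float
        Normal total haemoglobin concentration of blood (haem basis), mM.
    pa_n : float
        Normal arterial blood pressure, mmHg.
    ph_m_n : float
        Normal extra-mitochondrial (intracellular reference) pH.
    k_aut : float
        Autoregulation constant in [0, 1]; 1 = intact pressure
        autoregulation, 0 = purely passive vessel.
    r_m : float
        Special radius of the elastic-tension relationship, cm; sets the
        width of the active wall-tension curve.
    oxfrac_n : float
        Normal oxidised fraction of CuA centres, in [0, 1].
    f_carotid : float
        Normal fraction of cerebral blood flow carried by the carotid
        arteries, in [0, 1]; occlusion removes this share of conductance.
    glu_rate_n : float
        Normal glucose metabolism rate, mM/s.
    structural : mapping
        Fixed constants of the reduced model (see ``STRUCTURAL_DEFAULTS``).
    """

    cco_tot: float
    lac_n: float
    hbtot_n: float
    pa_n: float
    ph_m_n: float
    k_aut: float
    r_m: float
    oxfrac_n: float
    f_carotid: float
    glu_rate_n: float
    structural: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(STRUCTURAL_DEFAULTS)
    )

    def __post_init__(self) -> None:
        for name in ("cco_tot", "lac_n", "hbtot_n", "pa_n", "glu_rate_n", "r_m"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        for name in ("k_aut", "oxfrac_n", "f_carotid"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if not (6.0 <= self.ph_m_n <= 7.8):
            raise ValueError(f"ph_m_n must lie in [6.0, 7.8], got {self.ph_m_n!r}")
        missing = set(STRUCTURAL_DEFAULTS) - set(self.structural)
        if missing:
            raise ValueError(f"structural constants missing: {sorted(missing)}")

    # -- dict-like access over the named (fitted) parameters ---------------
    def __getitem__(self, name: str) -> float:
        if name in FITTED_NAMES:
            return getattr(self, name)
        return self.structural[name]

    def names(self) -> Iterator[str]:
        return iter(FITTED_NAMES)

    def replace(self, **updates: float) -> "ParameterSet":
        """Return a copy with named parameters (or structural keys) replaced."""
        named = {k: v for k, v in updates.items() if k in FITTED_NAMES}
        struct = {k: v for k, v in updates.items() if k not in FITTED_NAMES}
        unknown = set(struct) - set(STRUCTURAL_DEFAULTS)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        new_struct = dict(self.structural)
        new_struct.update(struct)
        return dataclasses.replace(self, structural=new_struct, **named)

    def to_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in FITTED_NAMES}
        return d


# Default (normal physiology) values of the ten named parameters and the
# optimised values found by calibrating to HI cohort data.  The two sets are
# linked by the percentage changes reported by ``percent_change``.
_DEFAULTS = {
    "cco_tot": 0.0022,
    "lac_n": 3.00,
    "hbtot_n": 5.40,
    "pa_n": 50.0,
    "ph_m_n": 7.0495,
    "k_aut": 1.00,
    "r_m": 0.0126,
    "oxfrac_n": 0.670,
    "f_carotid": 0.80,
    "glu_rate_n": 0.00440,
}

_OPTIMISED = {
    "cco_tot": 0.007,
    "lac_n": 5.00,
    "hbtot_n": 6.35,
    "pa_n": 53.7,
    "ph_m_n": 7.05,
    "k_aut": 1.00,
    "r_m": 0.0117,
    "oxfrac_n": 0.678,
    "f_carotid": 0.64,
    "glu_rate_n": 0.00352,
}


def default_parameters() -> ParameterSet:
    """Baseline (normal-physiology) parameter set."""
    return ParameterSet(**_DEFAULTS)


def optimised_parameters() -> ParameterSet:
    """Parameter set calibrated to the HI cohort (the fitted values)."""
    return ParameterSet(**_OPTIMISED)


def percent_change(optimised: float, default: float) -> float:
    """Percentage change of ``optimised`` relative to ``default``.

    Raises
    ------
    ZeroDivisionError
        If ``default`` is zero.
    """
    if default == 0:
        raise ZeroDivisionError("percent change undefined for zero default")
    return 100.0 * (optimised - default) / default


# Screening/fitting ranges express each parameter's physiological
# uncertainty, not a uniform factor: tissue concentrations are only loosely
# known (the chromophore pool least of all), whereas reference pressure,
# anatomical fractions and vessel radii are tightly constrained.
_RANGE_FACTORS = {
    "cco_tot": (0.25, 4.0),
    "lac_n": (0.5, 2.0),
    "hbtot_n": (0.7, 1.5),
    "pa_n": (0.85, 1.15),
    "glu_rate_n": (0.7, 1.4),
    "r_m": (0.9, 1.1),
    "oxfrac_n": (0.9, 1.1),
}
_RANGE_ABSOLUTE = {
    "ph_m_n": (6.9, 7.2),
    "k_aut": (0.5, 1.0),
    "f_carotid": (0.6, 0.95),
}


def default_bounds(
    p: ParameterSet | None = None,
    names: tuple[str, ...] | list[str] = FITTED_NAMES,
) -> dict[str, tuple[float, float]]:
    """Per-parameter screening and fitting bounds around a parameter set.

    Multiplicative widths follow the physiological uncertainty of each
    quantity; pH, the autoregulation constant and the carotid fraction use
    absolute windows.  Fractions are clamped to their admissible interval
    and ``r_m`` stays below the active-tension peak radius.
    """
    p = default_parameters() if p is None else p
    bounds: dict[str, tuple[float, float]] = {}
    for name in names:
        v = getattr(p, name)
        if name in _RANGE_ABSOLUTE:
            bounds[name] = _RANGE_ABSOLUTE[name]
            continue
        lo_f, hi_f = _RANGE_FACTORS[name]
        lo, hi = lo_f * v, hi_f * v
        if name == "r_m":
            # active-tension width requires r_m below the peak radius r_t
            hi = min(hi, 0.95 * p.structural["r_t"])
        elif name == "oxfrac_n":
            # a fully oxidised CuA pool leaves no turnover capacity
            hi = min(hi, 0.98)
        bounds[name] = (lo, hi)
    return bounds


# ---------------------------------------------------------------------------
# Serialisation: JSON/YAML files mapping name -> {value, unit, lower, upper}.
# ---------------------------------------------------------------------------

def _as_record(p: ParameterSet) -> dict[str, dict[str, float | str]]:
    bounds = default_bounds()
    return {
        name: {
            "value": getattr(p, name),
            "unit": UNITS[name],
            "lower": bounds[name][0],
            "upper": bounds[name][1],
        }
        for name in FITTED_NAMES
    }


def save_parameters(p: ParameterSet, path: str) -> None:
    """Write a parameter file (JSON or YAML, chosen by extension)."""
    rec = _as_record(p)
    text_path = str(path)
    if text_path.endswith((".yaml", ".yml")):
        with open(text_path, "w") as fh:
            yaml.safe_dump(rec, fh, sort_keys=False)
    else:
        with open(text_path, "w") as fh:
            json.dump(rec, fh, indent=1)
            fh.write("\n")


def load_parameters(path: str) -> ParameterSet:
    """Read a parameter file written by :func:`save_parameters`.

    Unlisted names fall back to package defaults; structural constants are
    always the packaged defaults.
    """
    text_path = str(path)
    with open(text_path) as fh:
        if text_path.endswith((".yaml", ".yml")):
            rec = yaml.safe_load(fh)
        else:
            rec = json.load(fh)
    vals = dict(_DEFAULTS)
    for name, entry in rec.items():
        if name not in FITTED_NAMES:
            raise KeyError(f"unknown parameter {name!r} in {path}")
        vals[name] = float(entry["value"] if isinstance(entry, dict) else entry)
    return ParameterSet(**vals)


def load_bounds(path: str) -> dict[str, tuple[float, float]]:
    """Read {name: (lower, upper)} from a parameter file with bounds."""
    text_path = str(path)
    with open(text_path) as fh:
        if text_path.endswith((".yaml", ".yml")):
            rec = yaml.safe_load(fh)
        else:
            rec = json.load(fh)
    out = {}
    for name, entry in rec.items():
        out[name] = (float(entry["lower"]), float(entry["upper"]))
    return out


def packaged_parameters(which: str = "defaults") -> ParameterSet:
    """Load one of the shipped parameter files (``defaults`` or
    ``optimised_table``)."""
    fname = {"defaults": "defaults.json", "optimised_table": "optimised_table.json"}[
        which
    ]
    ref = resources.files("pigletbrain.data").joinpath(fname)
    with resources.as_file(ref) as path:
        return load_parameters(str(path))
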