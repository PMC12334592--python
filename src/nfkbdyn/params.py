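"""Model parameters.

All rate constants live in one flat, ordered namespace so that the compiled
ODE right-hand side receives a plain float vector.  Internal time is seconds;
concentrations are arbitrary units with total NF-kB normalized to 1 (in
nuclear-volume units).  Calibration operates on log10-transformed values.

The core (pre-DNA) module is a two-feedback nuclear-shuttling NF-kB model:
IKK activated by CI puncta counts, IKK-driven IkBa degradation releasing
NF-kB, NF-kB-induced IkBa resynthesis (transcription + translation) that
re-sequesters and exports nuclear NF-kB, and an A20-type feedback that
accelerates IKK inactivation.  Its constants are configuration, not claims:
defaults were tuned once to the behavioral contracts (basal nuclear-to-
cytoplasmic ratio inside (0.01, 0.3), transient pulse response that adapts
back toward baseline) and are fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Ordered parameter names; index = position in the vector passed to the RHS.
PARAM_NAMES: tuple[str, ...] = (
    # IKK module
    "ka",        # CI-coupling activation rate (1/puncta/s)
    "ki",        # basal IKK inactivation (1/s)
    "ka20",      # A20 enhancement of IKK inactivation (1/conc)
    "kr",        # inactive-IKK recycling (1/s)
    # IkBa / NF-kB binding and degradation
    "kb",        # IkB-NFkB association (1/conc/s)
    "kdis",      # complex dissociation (1/s)
    "kc",        # IKK-mediated degradation of complexed IkBa (1/conc/s)
    "kc2",       # IKK-mediated degradation of free IkBa (1/conc/s)
    "kdeg_f",    # constitutive free-IkBa degradation (1/s)
    "kdeg_b",    # constitutive complexed-IkBa degradation (1/s)
    # transport (cv = cytoplasmic/nuclear volume ratio)
    "kin_N",     # free NF-kB nuclear import (1/s)
    "kout_N",    # free NF-kB nuclear export (1/s)
    "kin_I",     # free IkBa nuclear import (1/s)
    "kout_I",    # free IkBa nuclear export (1/s)
    "kout_C",    # IkBa:NFkB complex nuclear export (1/s)
    # IkBa transcription / translation
    "ktr",       # NF-kB-induced IkBa transcription Vmax (conc/s)
    "ktr0",      # basal IkBa transcription (conc/s)
    "K_tr",      # half-max nuclear NF-kB for transcription (conc)
    "h_tr",      # transcription Hill coefficient
    "kdeg_t",    # IkBa mRNA degradation (1/s)
    "ktl",       # translation (protein per mRNA per s)
    # A20 feedback
    "ktr_a20",   # NF-kB-induced A20 transcription Vmax (conc/s)
    "kdeg_a20",  # A20 protein degradation (1/s)
    # geometry
    "cv",        # cytoplasmic/nuclear volume ratio (dimensionless)
    # DNA binding & pioneering (the chromatin extension)
    "ka1d",      # DNA association scale (conc/s; rate law carries no mass-action NFkB factor)
    "kdNFKB",    # cooperativity half-saturation (nuclear NF-kB units)
    "h2",        # cooperativity Hill coefficient
    "Ps0",       # basal permissiveness (fixed = 1)
    "Ps",        # inducible permissiveness amplitude
    "KDNA",      # pioneering half-saturation (NFkBDNA units)
    "h3",        # pioneering Hill coefficient
    "ka2a",      # IkBa stripping of DNA-bound NF-kB (1/conc/s)
    "kd1d",      # basal DNA dissociation (1/s)
    "dna_on",    # variant switch: 1 with DNA module, 0 without
    # second inhibitor (IkBe / IkBb variants)
    "ikbx_mode",   # 0 none, 1 inducible+delayed (IkBe), 2 constitutive (IkBb)
    "V_ikbx",      # transcription Vmax (conc/s)
    "K_delay",     # delay Hill midpoint (seconds)
    "n_delay",     # delay Hill coefficient
    "kb_x",        # second-inhibitor association (1/conc/s)
    "kdis_x",      # dissociation (1/s)
    "kc_x",        # IKK-mediated degradation (1/conc/s)
    "kdeg_fx",     # free degradation (1/s)
    "kdeg_bx",     # complexed degradation (1/s)
    "kdeg_tx",     # mRNA degradation (1/s)
    "ktl_x",       # translation (1/s)
)

P_INDEX = {name: i for i, name in enumerate(PARAM_NAMES)}
N_PARAMS = len(PARAM_NAMES)

_BASE_DEFAULTS: dict[str, float] = {
    "ka": 4.46e-6,
    "ki": 7.32e-3,
    "ka20": 8.15,
    "kr": 8.77e-5,
    "kb": 0.3,
    "kdis": 1.0e-4,
    "kc": 0.144,
    "kc2": 0.144,
    "kdeg_f": 8.0e-4,
    "kdeg_b": 3.59e-5,
    "kin_N": 3.0e-3,
    "kout_N": 5.0e-5,
    "kin_I": 1.10e-2,
    "kout_I": 3.0e-4,
    "kout_C": 8.0e-3,
    "ktr": 1.21e-4,
    "ktr0": 2.0e-8,
    "K_tr": 0.08,
    "h_tr": 2.0,
    "kdeg_t": 1.72e-3,
    "ktl": 0.5,
    "ktr_a20": 4.0e-5,
    "kdeg_a20": 2.0e-4,
    "cv": 3.5,
    # DNA module
    "ka1d": 1.27e-5,
    "kdNFKB": 3.05e-3,
    "h2": 4.0,
    "Ps0": 1.0,
    "Ps": 2.56,
    "KDNA": 0.0399,
    "h3": 2.0,
    "ka2a": 1.99e-3,
    "kd1d": 7.51e-5,
    "dna_on": 1.0,
    # second inhibitor defaults (inactive unless a variant turns them on)
    "ikbx_mode": 0.0,
    "V_ikbx": 4.0e-5,
    "K_delay": 2700.0,     # 45-minute transcriptional delay, in seconds
    "n_delay": 6.0,
    "kb_x": 0.5,
    "kdis_x": 5.0e-5,
    "kc_x": 0.3,
    "kdeg_fx": 1.0e-4,
    "kdeg_bx": 2.0e-5,
    "kdeg_tx": 4.0e-4,
    "ktl_x": 0.5,
}

VARIANTS = ("d2fc", "d2fc2", "d2fc_ikbe", "d2fc_ikbb")

#: Variant-specific default overrides (applied before user values).  The
#: constitutive inhibitor's synthesis is scaled to a secondary-inhibitor
#: share of the IkBa pool rather than the inducible Vmax.
_VARIANT_OVERRIDES: dict[str, dict[str, float]] = {
    "d2fc_ikbb": {"V_ikbx": 2.0e-9},
}


@dataclass(frozen=True)
class ParameterSet:
    """Named rate constants for one model variant.

    Immutable; use :meth:`with_updates` to derive modified sets.  ``Ps0`` is
    fixed to 1 by convention and ``dna_on``/``ikbx_mode`` are set by the
    variant, not by the user.
    """

    variant: str = "d2fc2"
    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        vals = dict(_BASE_DEFAULTS)
        vals.update(_VARIANT_OVERRIDES.get(self.variant, {}))
        vals.update(self.values)
        vals["Ps0"] = 1.0
        vals["dna_on"] = 1.0 if self.variant == "d2fc2" else 0.0
        vals["ikbx_mode"] = {"d2fc_ikbe": 1.0, "d2fc_ikbb": 2.0}.get(self.variant, 0.0)
        unknown = set(vals) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        for name in PARAM_NAMES:
            if vals[name] < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {vals[name]}")
        for name in ("h_tr", "h2", "h3", "n_delay"):
            if vals[name] < 1:
                raise ValueError(f"Hill coefficient {name} must be >= 1")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def vector(self) -> np.ndarray:
        return np.array([self.values[n] for n in PARAM_NAMES], dtype=float)

    def with_updates(self, **updates: float) -> "ParameterSet":
        vals = dict(self.values)
        vals.update(updates)
        return replace(self, values=vals)

    def to_dict(self) -> dict:
        return {"variant": self.variant, "values": dict(self.values)}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(variant=d.get("variant", "d2fc2"), values=dict(d.get("values", {})))


def default_parameters(variant: str = "d2fc2") -> ParameterSet:
    return ParameterSet(variant=variant)


#: Free parameters calibrated for each variant (the DNA/coupling constants
#: for the chromatin model; feedback constants for the reduced model, which
#: has no DNA knobs to vary).
FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "d2fc2": ("ka", "ka1d", "Ps", "KDNA", "ka2a", "kd1d"),
    "d2fc": ("ka", "ki", "kr", "ktr", "K_tr", "kc"),
    "d2fc_ikbe": ("ka", "V_ikbx", "kb_x", "kc_x", "ktr", "K_tr"),
    "d2fc_ikbb": ("ka", "V_ikbx", "kb_x", "kc_x", "ktr", "K_tr"),
}


def log10_bounds(p: ParameterSet, names: tuple[str, ...] | None = None,
                 decades: float = 1.0) -> dict[str, tuple[float, float]]:
    """Symmetric log10 prior bounds (+- decades) around the values in ``p``.

    Stand-in priors: the biophysical ranges used in the original study are
    not printed, so bounds ship as editable configuration centered on the
    current parameter values.
    """
    names = names or FREE_PARAMS[p.variant]
    out = {}
    for n in names:
        v = p[n]
        if v <= 0:
            raise ValueError(f"cannot take log10 bounds around zero parameter {n}")
        c = np.log10(v)
        out[n] = (c - decades, c + decades)
    return out
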