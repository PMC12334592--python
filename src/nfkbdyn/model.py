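"""ODE models of IKK -> NF-kB signal transduction driven by CI puncta counts.

Variants
--------
``d2fc``      two-feedback core model (IkBa transcriptional feedback, A20-type
              IKK inactivation), no DNA binding.
``d2fc2``     core + NF-kB-DNA binding with cooperativity (DCoop) and
              chromatin-pioneering permissiveness (NPio).
``d2fc_ikbe`` core + a second, NF-kB-inducible inhibitor with a 45-minute
              transcriptional delay (Hill function of time, in seconds).
``d2fc_ikbb`` core + a second, constitutively expressed inhibitor.

Internal time is seconds; the I/O boundary (trajectories, grids) is minutes.
The CI forcing enters as an analytic sum of four Gaussians, so the integrator
never sees interpolation kinks.

Note on the DNA-binding rate law: the association flux is
``ka1d * DCoop * NPio`` with *no* extra mass-action factor in free nuclear
NF-kB; DCoop -> 0 as NF-kB -> 0 supplies the vanishing limit.  Numerically the
NF-kB argument of DCoop is clipped at 0 so the flux shuts off smoothly at the
boundary (a safeguard, not a model change).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import odeint
from scipy.optimize import brentq

from .params import ParameterSet, P_INDEX, PARAM_NAMES, VARIANTS
from .trajectories import CITrajectory, default_grid
from .features import GaussianSumFit, fit_gaussian_sum

# --- species indices -------------------------------------------------------

SPECIES: tuple[str, ...] = (
    "IKKn", "IKK", "IKKi",
    "C.NFkB", "C.IkBa", "C.IkBaNFkB",
    "N.NFkB", "N.IkBa", "N.IkBaNFkB",
    "IkBat", "A20", "A20t",
    "N.NFkBDNA",
    "C.IkBx", "C.IkBxNFkB", "IkBxt",
)
S_INDEX = {name: i for i, name in enumerate(SPECIES)}
N_SPECIES = len(SPECIES)

_I = P_INDEX  # shorthand

SECONDS_PER_MIN = 60.0
STEADY_STATE_SECONDS = 10 * 24 * 3600.0   # ten simulated days

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class SimulationError(RuntimeError):
    """Integration failed or produced materially negative concentrations."""


# --- elementary rate laws (exposed as plain functions; also inlined in the
#     compiled RHS) ---------------------------------------------------------


def ikk_activation_rate(ikk_neutral: float, ikk_spots_t: float, ka: float) -> float:
    """IKKn -> IKK activation flux: ka * IKKSpots(t) * IKKn."""
    return ka * ikk_spots_t * ikk_neutral


def hill(x: float, K: float, h: float) -> float:
    x = max(x, 0.0)
    if x == 0.0:
        return 0.0
    r = (x / K) ** h
    return r / (1.0 + r)


def dna_binding_rate(nfkb_nuc: float, nfkb_dna: float, p: ParameterSet) -> float:
    """NF-kB -> NFkBDNA association flux: ka1d * DCoop * NPio (as printed)."""
    dcoop = hill(nfkb_nuc, p["kdNFKB"], p["h2"])
    npio = p["Ps0"] + p["Ps"] * hill(nfkb_dna, p["KDNA"], p["h3"])
    return p["ka1d"] * dcoop * npio


def npio_value(nfkb_dna: float, p: ParameterSet) -> float:
    """Chromatin permissiveness NPio in [Ps0, Ps0 + Ps]."""
    return p["Ps0"] + p["Ps"] * hill(nfkb_dna, p["KDNA"], p["h3"])


def dna_unbinding_rates(nfkb_dna: float, ikba_nuc: float, p: ParameterSet) -> tuple[float, float]:
    """(IkBa-stripping flux, basal dissociation flux) of DNA-bound NF-kB."""
    return p["ka2a"] * ikba_nuc * nfkb_dna, p["kd1d"] * nfkb_dna


def ikbe_transcription_rate(t_seconds: float, nfkb_nuc: float, p: ParameterSet) -> float:
    """Delayed inducible transcription: V(NFkB) * t^n / (t^n + K_delay^n).

    Evaluated in log space so steep delay coefficients (step-like delays)
    cannot overflow.
    """
    v = p["V_ikbx"] * hill(nfkb_nuc, p["K_tr"], p["h_tr"])
    if t_seconds <= 0.0:
        return 0.0
    n, K = p["n_delay"], p["K_delay"]
    z = n * np.log(t_seconds / K)
    if z > 50.0:
        return v
    if z < -50.0:
        return 0.0
    e = np.exp(z)
    return v * e / (1.0 + e)


# --- compiled right-hand side ---------------------------------------------

# parameter vector layout: PARAM_NAMES values followed by one trailing flag
# stim_phase (1.0 during a stimulated response, 0.0 during equilibration);
# the delay clock of the IkBe variant only runs while stimulated.

_IX = {n: i for i, n in enumerate(PARAM_NAMES)}


def _pvec(p: ParameterSet, stim_phase: float) -> np.ndarray:
    return np.concatenate([p.vector(), [stim_phase]])


@njit(cache=True)
def _gauss_sum(tmin, ga, gb, gc):
    s = 0.0
    for i in range(ga.shape[0]):
        z = (tmin - gb[i]) / gc[i]
        s += ga[i] * np.exp(-z * z)
    return s if s > 0.0 else 0.0


@njit(cache=True)
def _rhs(y, t, p, ga, gb, gc):
    (ka, ki, ka20, kr, kb, kdis, kc, kc2, kdeg_f, kdeg_b,
     kin_N, kout_N, kin_I, kout_I, kout_C,
     ktr, ktr0, K_tr, h_tr, kdeg_t, ktl, ktr_a20, kdeg_a20, cv,
     ka1d, kdNFKB, h2, Ps0, Ps, KDNA, h3, ka2a, kd1d, dna_on,
     ikbx_mode, V_ikbx, K_delay, n_delay, kb_x, kdis_x, kc_x,
     kdeg_fx, kdeg_bx, kdeg_tx, ktl_x, stim) = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9],
        p[10], p[11], p[12], p[13], p[14],
        p[15], p[16], p[17], p[18], p[19], p[20], p[21], p[22], p[23],
        p[24], p[25], p[26], p[27], p[28], p[29], p[30], p[31], p[32], p[33],
        p[34], p[35], p[36], p[37], p[38], p[39], p[40],
        p[41], p[42], p[43], p[44], p[45])

    IKKn, IKK, IKKi = y[0], y[1], y[2]
    NFc, Ic, Cc = y[3], y[4], y[5]
    NFn, In, Cn = y[6], y[7], y[8]
    It, A20, A20t = y[9], y[10], y[11]
    Dna = y[12]
    Ix, Cx, Ixt = y[13], y[14], y[15]

    spots = _gauss_sum(t / 60.0, ga, gb, gc) if stim > 0.5 else 0.0

    act = ka * spots * IKKn
    inact = ki * (1.0 + ka20 * A20) * IKK
    recyc = kr * IKKi

    assoc_c = kb * NFc * Ic
    dis_c = kdis * Cc
    degC_c = (kc * IKK + kdeg_b) * Cc
    degI_c = (kc2 * IKK + kdeg_f) * Ic

    assoc_n = kb * NFn * In
    dis_n = kdis * Cn
    degC_n = kdeg_b * Cn
    degI_n = kdeg_f * In

    nfn_pos = NFn if NFn > 0.0 else 0.0
    rh = (nfn_pos / K_tr) ** h_tr
    hillN = rh / (1.0 + rh)

    # DNA binding (chromatin extension)
    bind = 0.0
    strip = 0.0
    basal_dis = 0.0
    if dna_on > 0.5:
        rc = (nfn_pos / kdNFKB) ** h2
        dcoop = rc / (1.0 + rc)
        dna_pos = Dna if Dna > 0.0 else 0.0
        rp = (dna_pos / KDNA) ** h3
        npio = Ps0 + Ps * rp / (1.0 + rp)
        bind = ka1d * dcoop * npio
        strip = ka2a * In * Dna
        basal_dis = kd1d * Dna

    # second inhibitor (cytoplasmic)
    trans_x = 0.0
    assoc_x = 0.0
    dis_x = 0.0
    degCx = 0.0
    degIx = 0.0
    if ikbx_mode > 0.5:
        if ikbx_mode > 1.5:        # constitutive (IkBb)
            trans_x = V_ikbx
        else:                      # inducible with delay clock (IkBe)
            if stim > 0.5 and t > 0.0:
                z = n_delay * np.log(t / K_delay)   # log-space Hill, overflow-safe
                if z > 50.0:
                    trans_x = V_ikbx * hillN
                elif z >= -50.0:
                    e = np.exp(z)
                    trans_x = V_ikbx * hillN * e / (1.0 + e)
        assoc_x = kb_x * NFc * Ix
        dis_x = kdis_x * Cx
        degCx = (kc_x * IKK + kdeg_bx) * Cx
        degIx = (kc_x * IKK + kdeg_fx) * Ix

    dy = np.empty(16)
    dy[0] = -act + recyc
    dy[1] = act - inact
    dy[2] = inact - recyc
    dy[3] = (-kin_N * NFc + kout_N * NFn / cv - assoc_c + dis_c + degC_c
             - assoc_x + dis_x + degCx)
    dy[4] = ktl * It - kin_I * Ic + kout_I * In / cv - assoc_c + dis_c - degI_c
    dy[5] = assoc_c - dis_c - degC_c + kout_C * Cn / cv
    dy[6] = (cv * kin_N * NFc - kout_N * NFn - assoc_n + dis_n + degC_n
             - bind + basal_dis)
    dy[7] = cv * kin_I * Ic - kout_I * In - assoc_n + dis_n - degI_n - strip
    dy[8] = assoc_n - dis_n - degC_n - kout_C * Cn + strip
    dy[9] = ktr0 + ktr * hillN - kdeg_t * It
    dy[10] = ktl * A20t - kdeg_a20 * A20
    dy[11] = ktr_a20 * hillN - kdeg_t * A20t
    dy[12] = bind - strip - basal_dis
    dy[13] = ktl_x * Ixt - assoc_x + dis_x - degIx
    dy[14] = assoc_x - dis_x - degCx
    dy[15] = trans_x - kdeg_tx * Ixt
    return dy


_ZERO_G = np.zeros(4)
_ONE_C = np.ones(4)


# --- declarative reaction network ------------------------------------------


@dataclass(frozen=True)
class Reaction:
    name: str
    stoichiometry: dict            # species -> net coefficient (concentration units)
    constitutive: bool = False     # nonzero flux at the all-zero state


@dataclass
class ModelSpec:
    """Declarative description of one model variant's reaction network."""

    variant: str
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]

    def to_json(self, path=None) -> str:
        payload = {
            "variant": self.variant,
            "species": list(self.species),
            "reactions": [
                {"name": r.name, "stoichiometry": r.stoichiometry,
                 "constitutive": r.constitutive}
                for r in self.reactions
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _core_reactions(cv: float) -> list[Reaction]:
    # transport stoichiometry carries the volume factors so that total
    # amounts (nuclear-volume units) are conserved
    return [
        Reaction("ikk_activation", {"IKKn": -1, "IKK": 1}),
        Reaction("ikk_inactivation", {"IKK": -1, "IKKi": 1}),
        Reaction("ikk_recycling", {"IKKi": -1, "IKKn": 1}),
        Reaction("assoc_cyt", {"C.NFkB": -1, "C.IkBa": -1, "C.IkBaNFkB": 1}),
        Reaction("dissoc_cyt", {"C.IkBaNFkB": -1, "C.NFkB": 1, "C.IkBa": 1}),
        Reaction("ikba_deg_complex_cyt", {"C.IkBaNFkB": -1, "C.NFkB": 1}),
        Reaction("ikba_deg_free_cyt", {"C.IkBa": -1}),
        Reaction("assoc_nuc", {"N.NFkB": -1, "N.IkBa": -1, "N.IkBaNFkB": 1}),
        Reaction("dissoc_nuc", {"N.IkBaNFkB": -1, "N.NFkB": 1, "N.IkBa": 1}),
        Reaction("ikba_deg_complex_nuc", {"N.IkBaNFkB": -1, "N.NFkB": 1}),
        Reaction("ikba_deg_free_nuc", {"N.IkBa": -1}),
        Reaction("nfkb_import", {"C.NFkB": -1, "N.NFkB": cv}),
        Reaction("nfkb_export", {"N.NFkB": -1, "C.NFkB": 1.0 / cv}),
        Reaction("ikba_import", {"C.IkBa": -1, "N.IkBa": cv}),
        Reaction("ikba_export", {"N.IkBa": -1, "C.IkBa": 1.0 / cv}),
        Reaction("complex_export", {"N.IkBaNFkB": -1, "C.IkBaNFkB": 1.0 / cv}),
        Reaction("ikba_transcription", {"IkBat": 1}, constitutive=True),
        Reaction("ikba_mrna_decay", {"IkBat": -1}),
        Reaction("ikba_translation", {"IkBat": 0, "C.IkBa": 1}),
        Reaction("a20_transcription", {"A20t": 1}),
        Reaction("a20_mrna_decay", {"A20t": -1}),
        Reaction("a20_translation", {"A20t": 0, "A20": 1}),
        Reaction("a20_decay", {"A20": -1}),
    ]


def build_model(variant: str = "d2fc2", p: ParameterSet | None = None) -> ModelSpec:
    """Declarative reaction network for one variant.

    The network is introspectable (species diff, stoichiometry, JSON export)
    and, combined with :func:`reaction_fluxes`, yields the same derivatives
    as the compiled right-hand side used for simulation.  Transport
    stoichiometry carries the cytoplasmic/nuclear volume ratio from ``p``
    (variant defaults if omitted).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if p is None:
        p = ParameterSet(variant=variant)
    cv = p["cv"]
    rxns = _core_reactions(cv)
    species = [s for s in SPECIES if s not in ("N.NFkBDNA", "C.IkBx", "C.IkBxNFkB", "IkBxt")]
    if variant in ("d2fc2",):
        species.append("N.NFkBDNA")
        rxns += [
            Reaction("dna_binding", {"N.NFkB": -1, "N.NFkBDNA": 1}),
            Reaction("dna_stripping", {"N.NFkBDNA": -1, "N.IkBa": -1, "N.IkBaNFkB": 1}),
            Reaction("dna_basal_dissociation", {"N.NFkBDNA": -1, "N.NFkB": 1}),
        ]
    if variant in ("d2fc_ikbe", "d2fc_ikbb"):
        species += ["C.IkBx", "C.IkBxNFkB", "IkBxt"]
        constitutive = variant == "d2fc_ikbb"
        rxns += [
            Reaction("ikbx_transcription", {"IkBxt": 1}, constitutive=constitutive),
            Reaction("ikbx_mrna_decay", {"IkBxt": -1}),
            Reaction("ikbx_translation", {"IkBxt": 0, "C.IkBx": 1}),
            Reaction("assoc_x", {"C.NFkB": -1, "C.IkBx": -1, "C.IkBxNFkB": 1}),
            Reaction("dissoc_x", {"C.IkBxNFkB": -1, "C.NFkB": 1, "C.IkBx": 1}),
            Reaction("ikbx_deg_complex", {"C.IkBxNFkB": -1, "C.NFkB": 1}),
            Reaction("ikbx_deg_free", {"C.IkBx": -1}),
        ]
    return ModelSpec(variant=variant, species=tuple(species), reactions=tuple(rxns))


def reaction_fluxes(state: np.ndarray, t_seconds: float, p: ParameterSet,
                    spots: float = 0.0, stim_phase: bool = True) -> dict[str, float]:
    """Evaluate each reaction's rate law at a state (Python mirror of the RHS).

    Used for sanity checks and introspection; the compiled RHS is the
    simulation path and the two are cross-checked in the test suite.
    """
    y = np.asarray(state, dtype=float)
    g = {n: y[S_INDEX[n]] for n in SPECIES}
    hillN = hill(g["N.NFkB"], p["K_tr"], p["h_tr"])
    out = {
        "ikk_activation": ikk_activation_rate(g["IKKn"], spots, p["ka"]),
        "ikk_inactivation": p["ki"] * (1.0 + p["ka20"] * g["A20"]) * g["IKK"],
        "ikk_recycling": p["kr"] * g["IKKi"],
        "assoc_cyt": p["kb"] * g["C.NFkB"] * g["C.IkBa"],
        "dissoc_cyt": p["kdis"] * g["C.IkBaNFkB"],
        "ikba_deg_complex_cyt": (p["kc"] * g["IKK"] + p["kdeg_b"]) * g["C.IkBaNFkB"],
        "ikba_deg_free_cyt": (p["kc2"] * g["IKK"] + p["kdeg_f"]) * g["C.IkBa"],
        "assoc_nuc": p["kb"] * g["N.NFkB"] * g["N.IkBa"],
        "dissoc_nuc": p["kdis"] * g["N.IkBaNFkB"],
        "ikba_deg_complex_nuc": p["kdeg_b"] * g["N.IkBaNFkB"],
        "ikba_deg_free_nuc": p["kdeg_f"] * g["N.IkBa"],
        "nfkb_import": p["kin_N"] * g["C.NFkB"],
        "nfkb_export": p["kout_N"] * g["N.NFkB"],
        "ikba_import": p["kin_I"] * g["C.IkBa"],
        "ikba_export": p["kout_I"] * g["N.IkBa"],
        "complex_export": p["kout_C"] * g["N.IkBaNFkB"],
        "ikba_transcription": p["ktr0"] + p["ktr"] * hillN,
        "ikba_mrna_decay": p["kdeg_t"] * g["IkBat"],
        "ikba_translation": p["ktl"] * g["IkBat"],
        "a20_transcription": p["ktr_a20"] * hillN,
        "a20_mrna_decay": p["kdeg_t"] * g["A20t"],
        "a20_translation": p["ktl"] * g["A20t"],
        "a20_decay": p["kdeg_a20"] * g["A20"],
    }
    if p["dna_on"] > 0.5:
        strip, basal = dna_unbinding_rates(g["N.NFkBDNA"], g["N.IkBa"], p)
        out["dna_binding"] = dna_binding_rate(g["N.NFkB"], g["N.NFkBDNA"], p)
        out["dna_stripping"] = strip
        out["dna_basal_dissociation"] = basal
    if p["ikbx_mode"] > 0.5:
        if p["ikbx_mode"] > 1.5:
            out["ikbx_transcription"] = p["V_ikbx"]
        else:
            out["ikbx_transcription"] = (
                ikbe_transcription_rate(t_seconds, g["N.NFkB"], p) if stim_phase else 0.0)
        out["ikbx_mrna_decay"] = p["kdeg_tx"] * g["IkBxt"]
        out["ikbx_translation"] = p["ktl_x"] * g["IkBxt"]
        out["assoc_x"] = p["kb_x"] * g["C.NFkB"] * g["C.IkBx"]
        out["dissoc_x"] = p["kdis_x"] * g["C.IkBxNFkB"]
        out["ikbx_deg_complex"] = (p["kc_x"] * g["IKK"] + p["kdeg_bx"]) * g["C.IkBxNFkB"]
        out["ikbx_deg_free"] = (p["kc_x"] * g["IKK"] + p["kdeg_fx"]) * g["C.IkBx"]
    return out


# --- conserved quantities and derived channels ------------------------------


def total_nfkb(state: np.ndarray, p: ParameterSet) -> float:
    """Total NF-kB amount in nuclear-volume units (conserved by construction)."""
    y = np.atleast_2d(state)
    cv = p["cv"]
    tot = (cv * (y[..., S_INDEX["C.NFkB"]] + y[..., S_INDEX["C.IkBaNFkB"]]
                 + y[..., S_INDEX["C.IkBxNFkB"]])
           + y[..., S_INDEX["N.NFkB"]] + y[..., S_INDEX["N.IkBaNFkB"]]
           + y[..., S_INDEX["N.NFkBDNA"]])
    return tot if tot.size > 1 else float(tot[0])


def nuclear_nfkb(state: np.ndarray) -> np.ndarray:
    """Total nuclear RelA concentration: free + IkBa-complexed + DNA-bound."""
    y = np.atleast_2d(state)
    return (y[..., S_INDEX["N.NFkB"]] + y[..., S_INDEX["N.IkBaNFkB"]]
            + y[..., S_INDEX["N.NFkBDNA"]])


def nuc_cyt_ratio(state: np.ndarray) -> float:
    """Basal nuclear/cytoplasmic NF-kB concentration ratio R (imaging convention)."""
    y = np.asarray(state, dtype=float)
    nuc = y[S_INDEX["N.NFkB"]] + y[S_INDEX["N.IkBaNFkB"]] + y[S_INDEX["N.NFkBDNA"]]
    cyt = y[S_INDEX["C.NFkB"]] + y[S_INDEX["C.IkBaNFkB"]] + y[S_INDEX["C.IkBxNFkB"]]
    return float(nuc / cyt)


# --- steady state and forward simulation ------------------------------------


@dataclass
class SteadyState:
    state: np.ndarray
    R: float
    resid_norm: float            # max |dy/dt| / (|y| + atol), 1/s
    stationary: bool


def _initial_state(p: ParameterSet) -> np.ndarray:
    y0 = np.zeros(N_SPECIES)
    y0[S_INDEX["IKKn"]] = 1.0
    y0[S_INDEX["C.IkBaNFkB"]] = 1.0 / p["cv"]   # total NF-kB amount = 1
    y0[S_INDEX["C.IkBa"]] = 0.02
    return y0


def _integrate(y0, t_eval_s, p, ga, gb, gc, stim_phase, rtol, atol):
    pv = _pvec(p, 1.0 if stim_phase else 0.0)
    sol, info = odeint(_rhs, y0, t_eval_s, args=(pv, ga, gb, gc),
                       rtol=rtol, atol=atol, mxstep=100000, full_output=True,
                       tfirst=False)
    if info["message"] != "Integration successful.":
        raise SimulationError(f"ODE integration failed: {info['message']}")
    if sol.min() < -1e-6:
        raise SimulationError(f"negative concentration {sol.min():.3e} beyond tolerance")
    return sol


def run_to_steady_state(model: ModelSpec | str, p: ParameterSet,
                        duration_s: float = STEADY_STATE_SECONDS,
                        rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                        resid_tol: float = 1e-10) -> SteadyState:
    """Equilibrate the unstimulated model (IKKSpots = 0) for ten days."""
    variant = model.variant if isinstance(model, ModelSpec) else model
    if p.variant != variant:
        raise ValueError(f"parameter set variant {p.variant!r} != model variant {variant!r}")
    t_eval = np.linspace(0.0, duration_s, 25)
    sol = _integrate(_initial_state(p), t_eval, p, _ZERO_G, _ONE_C, _ONE_C,
                     stim_phase=False, rtol=rtol, atol=atol)
    y = np.maximum(sol[-1], 0.0)
    dy = _rhs(y, duration_s, _pvec(p, 0.0), _ZERO_G, _ONE_C, _ONE_C)
    resid = float(np.max(np.abs(dy) / (np.abs(y) + 1e-8)))
    return SteadyState(state=y, R=nuc_cyt_ratio(y), resid_norm=resid,
                       stationary=resid < resid_tol)


@dataclass
class SimulationResult:
    times_min: np.ndarray
    states: np.ndarray               # (n_times, n_species)
    fold_change: np.ndarray          # total nuclear RelA / basal total nuclear RelA
    npio: np.ndarray                 # chromatin permissiveness NPio(t)
    nfkb_dna: np.ndarray
    nfkb_dna_cum_auc: np.ndarray     # cumulative trapezoid of NFkBDNA (conc*min)
    steady_state: SteadyState
    diagnostics: dict = field(default_factory=dict)


def simulate_response(model: ModelSpec | str, p: ParameterSet,
                      ci_input: GaussianSumFit | CITrajectory,
                      steady_state: SteadyState | None = None,
                      times_min: np.ndarray | None = None,
                      horizon_min: float = 180.0,
                      rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL
                      ) -> SimulationResult:
    """Simulate the stimulated response from steady state.

    ``ci_input`` may be a Gaussian-sum fit (used directly as the analytic
    forcing) or a raw CI trajectory (Gaussian-fitted first).
    """
    variant = model.variant if isinstance(model, ModelSpec) else model
    if steady_state is None:
        steady_state = run_to_steady_state(variant, p, rtol=rtol, atol=atol)
    if isinstance(ci_input, CITrajectory):
        ci_input = fit_gaussian_sum(ci_input)
    if times_min is None:
        times_min = default_grid(int(round(horizon_min / 4.0)) + 1, 4.0)
    times_min = np.asarray(times_min, dtype=float)
    ga = np.ascontiguousarray(ci_input.a, dtype=float)
    gb = np.ascontiguousarray(ci_input.b, dtype=float)
    gc = np.ascontiguousarray(ci_input.c, dtype=float)

    sol = _integrate(steady_state.state, times_min * SECONDS_PER_MIN, p,
                     ga, gb, gc, stim_phase=True, rtol=rtol, atol=atol)
    nuc = nuclear_nfkb(sol)
    basal = nuclear_nfkb(steady_state.state[None, :])[0]
    dna = sol[:, S_INDEX["N.NFkBDNA"]]
    npio = np.array([npio_value(d, p) for d in dna])
    cum = np.concatenate([[0.0], np.cumsum(
        0.5 * (dna[1:] + dna[:-1]) * np.diff(times_min))])
    return SimulationResult(
        times_min=times_min, states=sol, fold_change=nuc / basal, npio=npio,
        nfkb_dna=dna, nfkb_dna_cum_auc=cum, steady_state=steady_state,
        diagnostics={"variant": variant, "rtol": rtol, "atol": atol})


# --- chromatin-opening equilibrium sub-model --------------------------------


def _submodel_net_flux(free: float, total: float, npio_const: float,
                       ikba_ss: float, p: ParameterSet) -> float:
    bound = total - free
    dcoop = hill(free, p["kdNFKB"], p["h2"])
    binding = p["ka1d"] * dcoop * npio_const * free
    unbinding = (p["kd1d"] + p["ka2a"] * ikba_ss) * bound
    return binding - unbinding


def free_nfkb_fraction(total_nuclear_nfkb: float, npio_const: float,
                       p: ParameterSet, ikba_ss: float) -> float:
    """Equilibrium free fraction of nuclear NF-kB in the two-species sub-model.

    Only free and DNA-bound NF-kB are dynamic; nuclear IkBa is frozen at its
    pre-stimulus steady-state value and the permissiveness is held at
    ``npio_const``.  Binding flux is ka1d * DCoop * NPio_const * [N.NFkB];
    unbinding is kd1d * [NFkBDNA] + ka2a * [IkBa_ss] * [NFkBDNA].
    """
    total = float(total_nuclear_nfkb)
    if total < 0:
        raise ValueError("total nuclear NF-kB must be >= 0")
    if total == 0.0:
        return 1.0
    if npio_const <= 0.0:
        return 1.0
    f = lambda free: _submodel_net_flux(free, total, npio_const, ikba_ss, p)
    lo, hi = 0.0, total
    if f(lo) > 0 or f(hi) < 0:   # monotone flux balance should bracket a root
        raise RuntimeError("no equilibrium bracket in [0, total]")
    free = brentq(f, lo, hi, xtol=1e-14 * max(total, 1.0), rtol=1e-14)
    return float(free / total)


def submodel_dynamic_free_fraction(total_nuclear_nfkb: float, npio_const: float,
                                   p: ParameterSet, ikba_ss: float,
                                   t_end_s: float = 2.0e6) -> float:
    """Long-time free fraction from direct integration of the two-ODE sub-model
    (the independent dynamic route to the same equilibrium)."""
    total = float(total_nuclear_nfkb)
    if total == 0.0 or npio_const <= 0.0:
        return 1.0

    def rhs(y, t):
        return [-_submodel_net_flux(y[0], total, npio_const, ikba_ss, p)]

    sol = odeint(rhs, [total], [0.0, t_end_s / 2, t_end_s], rtol=1e-12, atol=1e-14)
    return float(sol[-1, 0] / total)
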