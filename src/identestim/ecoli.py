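"""18-state skeleton of *E. coli* K-12 central carbon metabolism.

The skeleton encodes the literature mass-balance structure of the
glycolysis / pentose-phosphate / phosphotransferase-system network: one
balance for extracellular glucose (feed, pulse and PTS uptake) and 17
intracellular metabolite balances, each with a −μ·C dilution term, wired
to 30 named kinetic rates.

The literature rate expressions for this network are elaborate
(allosteric, multi-substrate, reversible); they are *pluggable* here.  A
rate registry maps each rate symbol to a callable, and any symbol left
unregistered falls back to a generic irreversible Michaelis–Menten form
over its consumed in-network substrates (zero-order for the two synthesis
drains with no in-network substrate), with parameters named in the
field's usual enzyme-kinetics style, ``rmax_<enzyme>`` /
``K_<enzyme>_<substrate>``.  This preserves the full
18-state test surface for identifiability studies without fixing any
particular kinetic proposal.
"""

from __future__ import annotations

from typing import Callable, Mapping

from .model import KineticModel

__all__ = [
    "ECOLI_STATES",
    "ECOLI_RATES",
    "ECOLI_STOICHIOMETRY",
    "UNKNOWN_IC_STATES",
    "MEASURED_STATES",
    "build_ecoli_skeleton",
]

#: 18 dynamic states: extracellular glucose + 17 intracellular metabolites
ECOLI_STATES = (
    "glc",     # extracellular glucose
    "g6p",     # glucose-6-phosphate
    "f6p",     # fructose-6-phosphate
    "fdp",     # fructose-1,6-bisphosphate
    "gap",     # glyceraldehyde-3-phosphate
    "dhap",    # dihydroxyacetone phosphate
    "pgp",     # 1,3-diphosphoglycerate
    "3pg",     # 3-phosphoglycerate
    "2pg",     # 2-phosphoglycerate
    "pep",     # phosphoenolpyruvate
    "pyr",     # pyruvate
    "6pg",     # 6-phosphogluconate
    "ribu5p",  # ribulose-5-phosphate
    "xyl5p",   # xylulose-5-phosphate
    "sed7p",   # sedoheptulose-7-phosphate
    "rib5p",   # ribose-5-phosphate
    "e4p",     # erythrose-4-phosphate
    "g1p",     # glucose-1-phosphate
)

#: signed incidence of the 30 kinetic rates onto the intracellular states.
#: (The PTS uptake term on extracellular glucose carries the biomass
#: scaling −C_x/ρ_x and is added at build time.)
ECOLI_STOICHIOMETRY = {
    "r_PTS": {"g6p": 1, "pep": -1, "pyr": 1},
    "r_PGI": {"g6p": -1, "f6p": 1},
    "r_G6PDH": {"g6p": -1, "6pg": 1},
    "r_PGM": {"g6p": -1, "g1p": 1},
    "r_PFK": {"f6p": -1, "fdp": 1},
    "r_ALDO": {"fdp": -1, "gap": 1, "dhap": 1},
    "r_TIS": {"dhap": -1, "gap": 1},
    "r_GAPDH": {"gap": -1, "pgp": 1},
    "r_PGK": {"pgp": -1, "3pg": 1},
    "r_PGluMu": {"3pg": -1, "2pg": 1},
    "r_ENO": {"2pg": -1, "pep": 1},
    "r_PK": {"pep": -1, "pyr": 1},
    "r_PDH": {"pyr": -1},
    "r_PEPCxylase": {"pep": -1},
    "r_DAHPS": {"pep": -1, "e4p": -1},
    "r_Synth1": {"pep": -1},
    "r_Synth2": {"pyr": -1},
    "r_MurSynth": {"f6p": -2},
    "r_TrpSynth": {"gap": 1, "pyr": 1},
    "r_MetSynth": {"pyr": 1},
    "r_SerSynth": {"3pg": -1},
    "r_G3PDH": {"dhap": -1},
    "r_PGDH": {"6pg": -1, "ribu5p": 1},
    "r_Ru5P": {"ribu5p": -1, "xyl5p": 1},
    "r_R5PI": {"ribu5p": -1, "rib5p": 1},
    "r_TKa": {"xyl5p": -1, "rib5p": -1, "sed7p": 1, "gap": 1},
    "r_TKb": {"xyl5p": -1, "e4p": -1, "f6p": 1, "gap": 1},
    "r_TA": {"sed7p": -1, "gap": -1, "f6p": 1, "e4p": 1},
    "r_RPPK": {"rib5p": -1},
    "r_G1PAT": {"g1p": -1},
}

ECOLI_RATES = tuple(ECOLI_STOICHIOMETRY)

#: in-network substrates of each rate (states it consumes), used by the
#: generic fallback: the rate carries one saturation factor per consumed
#: substrate so no balance can be driven negative.  The PTS additionally
#: consumes extracellular glucose.  Rates with no consumed in-network
#: state (the two synthesis inflows) fall back to zero order.
def _consumed_substrates(rate: str) -> tuple:
    subs = [s for s, c in ECOLI_STOICHIOMETRY[rate].items() if c < 0]
    if rate == "r_PTS":
        subs = ["glc"] + subs
    return tuple(subs)

#: the five intracellular metabolites whose initial concentrations were
#: not available from measurements and must be bootstrapped/estimated
UNKNOWN_IC_STATES = frozenset({"pgp", "3pg", "xyl5p", "sed7p", "g1p"})

#: the 13 species with measured temporal profiles
MEASURED_STATES = (
    "glc", "dhap", "e4p", "pyr", "fdp", "rib5p", "ribu5p",
    "2pg", "pep", "gap", "g6p", "f6p", "6pg",
)

#: nominal steady-state-like intracellular concentrations (mM), used as
#: default initial conditions; values for the unknown-IC states are
#: nominal placeholders only — the estimation workflow bootstraps them.
_DEFAULT_ICS = {
    "glc": 2.0,
    "g6p": 3.48, "f6p": 0.60, "fdp": 0.272, "gap": 0.218, "dhap": 0.167,
    "pgp": 0.008, "3pg": 2.13, "2pg": 0.399, "pep": 2.67, "pyr": 2.67,
    "6pg": 0.808, "ribu5p": 0.111, "xyl5p": 0.138, "sed7p": 0.276,
    "rib5p": 0.398, "e4p": 0.098, "g1p": 0.653,
}

#: default forcing constants; C_x = 0 switches the PTS drain on glucose
#: off and D = f_pulse = 0 gives a closed batch.  ρ_x (cytoplasmic
#: density scaling of the uptake term) defaults to 1 so the term is
#: well-defined whenever C_x is set.
DEFAULT_FORCING = {
    "D": 0.0,           # dilution rate of the reactor (s⁻¹)
    "C_glc_feed": 0.0,  # feed glucose concentration (mM)
    "f_pulse": 0.0,     # glucose pulse term (mM·s⁻¹)
    "C_x": 0.0,         # biomass concentration
    "rho_x": 1.0,       # biomass density scaling of intracellular rates
}


def _mm_rate(rate: str, substrates: tuple) -> tuple[Callable, dict]:
    """Generic irreversible (multi-substrate) Michaelis-Menten fallback."""
    enz = rate[2:]  # strip the r_ prefix
    vname = f"rmax_{enz}"
    knames = {s: f"K_{enz}_{s}" for s in substrates}

    def law(c, p, _subs=substrates, _v=vname, _k=knames):
        r = p[_v]
        for s in _subs:
            cs = c[s]
            r *= cs / (p[_k[s]] + cs)
        return r

    defaults = {vname: 1.0}
    defaults.update({k: 0.5 for k in knames.values()})
    return law, defaults


def _zero_order_rate(rate: str) -> tuple[Callable, dict]:
    enz = rate[2:]
    vname = f"rmax_{enz}"

    def law(c, p, _v=vname):
        return p[_v]

    # synthesis drains are small relative to glycolytic flux
    return law, {vname: 1e-3}


def build_ecoli_skeleton(
    rate_registry: Mapping[str, Callable] | None = None,
    *,
    parameters: Mapping[str, float] | None = None,
    mu: float = 2.78e-5,
    forcing: Mapping[str, float] | None = None,
    initial_conditions: Mapping[str, float] | None = None,
    unknown_ics=UNKNOWN_IC_STATES,
) -> KineticModel:
    """Assemble the 18-state skeleton.

    Parameters
    ----------
    rate_registry
        Named callables ``r(states, params)`` overriding any of the 30
        rate symbols in :data:`ECOLI_RATES`; unregistered symbols get the
        generic Michaelis-Menten fallback.  Unknown symbols are rejected.
    parameters
        Parameter values; merged over the fallback defaults.  Callers
        supplying their own rate laws must supply the parameters those
        laws reference.
    mu
        Specific growth rate (s⁻¹); default 2.78×10⁻⁵ ≈ 0.1 h⁻¹, a typical
        glucose-limited continuous-culture setting.
    forcing
        Overrides for :data:`DEFAULT_FORCING` (D, C_glc_feed, f_pulse,
        C_x, rho_x).
    """
    registry = dict(rate_registry or {})
    unknown_symbols = set(registry) - set(ECOLI_RATES)
    if unknown_symbols:
        raise ValueError(f"unknown rate symbols in registry: {sorted(unknown_symbols)}")

    fc = dict(DEFAULT_FORCING)
    if forcing:
        bad = set(forcing) - set(fc)
        if bad:
            raise ValueError(f"unknown forcing constants: {sorted(bad)}")
        fc.update(forcing)
    if fc["rho_x"] == 0:
        raise ValueError("rho_x must be non-zero")

    rate_laws: dict[str, Callable] = {}
    params: dict[str, float] = {}
    for rate in ECOLI_RATES:
        if rate in registry:
            rate_laws[rate] = registry[rate]
            continue
        substrates = _consumed_substrates(rate)
        if not substrates:
            law, defaults = _zero_order_rate(rate)
        else:
            law, defaults = _mm_rate(rate, substrates)
        rate_laws[rate] = law
        params.update(defaults)
    if parameters:
        params.update(parameters)

    stoich = {r: dict(c) for r, c in ECOLI_STOICHIOMETRY.items()}
    # glucose balance: D(C_feed − C_glc) + f_pulse − (C_x/ρ_x)·r_PTS
    stoich["r_PTS"]["glc"] = -fc["C_x"] / fc["rho_x"]

    forcing_terms = {}
    if fc["D"] != 0 or fc["f_pulse"] != 0:
        D, feed, pulse = fc["D"], fc["C_glc_feed"], fc["f_pulse"]

        def glc_forcing(t, c, _D=D, _feed=feed, _pulse=pulse):
            return _D * (_feed - c["glc"]) + _pulse

        forcing_terms["glc"] = glc_forcing

    ics = dict(_DEFAULT_ICS)
    if initial_conditions:
        ics.update(initial_conditions)

    return KineticModel(
        state_names=ECOLI_STATES,
        parameters=params,
        rate_laws=rate_laws,
        stoichiometry=stoich,
        initial_conditions=ics,
        unknown_ics=frozenset(unknown_ics),
        dilution_rate=mu,
        extracellular=frozenset({"glc"}),
        forcing=forcing_terms,
        output_map=MEASURED_STATES,
    )
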