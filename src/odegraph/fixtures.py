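"""Programmatic builders for the worked example models.

These are the package's test corpus and documentation examples: the
classic SIR epidemic model, an extended SIR with an environmental pathogen
compartment, a five-variable innate-immune-regulation model (which
exercises the extension-node path), and the Lotka–Volterra predator–prey
model.

The operator vocabulary has no unary minus, so a right-hand side that is a
single negative term (classic SIR's dS/dt = -b_d*S*I) is expressed with
the subtraction-fold idiom ``x - x - x``, which is an exact IEEE negation.

Default parameter values are documented constants of this package, chosen
once so each model shows its canonical qualitative behaviour (see
``docs/methods.md``); they are not taken from any external source.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .extensions import load_extension
from .graph import ModelGraph
from .simulation import SimulationConfig

IMMUNE_EXTENSION_FILENAME = "immune_extension.py"


def immune_extension_source() -> str:
    """Source text of the extension file the immune model references."""
    return (resources.files("odegraph") / "data"
            / IMMUNE_EXTENSION_FILENAME).read_text(encoding="utf-8")


def _immune_extension_path() -> Path:
    return Path(str(resources.files("odegraph") / "data"
                    / IMMUNE_EXTENSION_FILENAME))


# --- classic SIR --------------------------------------------------------

@dataclass(frozen=True)
class SIRParams:
    """Classic SIR: infection by mass action, first-order recovery."""

    b_d: float = 0.002   # infection rate coefficient (per contact per time)
    g: float = 0.1       # recovery rate coefficient (per time)
    S0: float = 999.0
    I0: float = 1.0
    R0: float = 0.0


def build_sir(params: SIRParams = SIRParams()) -> ModelGraph:
    """dS/dt = -b_d*S*I,  dI/dt = b_d*S*I - g*I,  dR/dt = g*I."""
    g = ModelGraph("classic SIR", "susceptible-infectious-recovered")
    S = g.add_term("S", params.S0)
    I = g.add_term("I", params.I0)
    R = g.add_term("R", params.R0)
    b_d = g.add_term("b_d", params.b_d)
    rec = g.add_term("g", params.g)

    infection = g.add_expression("*", "infection", 3)
    g.connect(b_d, infection, 0)
    g.connect(S, infection, 1)
    g.connect(I, infection, 2)

    recover = g.add_expression("*", "recover", 2)
    g.connect(rec, recover, 0)
    g.connect(I, recover, 1)

    i_eq = g.add_expression("-", "I eq", 2)
    g.connect(infection, i_eq, 0)
    g.connect(recover, i_eq, 1)

    # x - x - x == -x exactly: negation via subtraction fold
    s_eq = g.add_expression("-", "S eq", 3)
    for pin in range(3):
        g.connect(infection, s_eq, pin)

    g.connect(s_eq, g.add_assigner(S), 0)
    g.connect(i_eq, g.add_assigner(I), 0)
    g.connect(recover, g.add_assigner(R), 0)

    g.sim_config = SimulationConfig(0.0, 0.25, 100.0,
                                    x_label="Time (days)",
                                    y_label="Individuals")
    return g


# --- extended SIR with environmental pathogen ---------------------------

@dataclass(frozen=True)
class ExtendedSIRParams:
    """SIR with demography plus an environmental pathogen compartment E.

    Susceptibles are infected by direct contact (b_d) or via environmental
    pathogen (b_e); infected hosts shed pathogen at rate p, which decays at
    rate c; births (b) and natural death (n) keep host turnover. Summing
    the host equations gives d(S+I+R)/dt = b - n*(S+I+R), so the host total
    relaxes to b/n.
    """

    b: float = 10.0      # birth rate (individuals per time)
    b_d: float = 0.01    # direct-contact infection rate
    b_e: float = 0.005   # environmental infection rate
    n: float = 0.1       # natural death rate
    g: float = 0.2       # recovery rate
    p: float = 1.0       # pathogen shedding rate
    c: float = 1.0       # pathogen decay rate
    S0: float = 99.0
    I0: float = 1.0
    R0: float = 0.0
    E0: float = 0.0


def build_extended_sir(
        params: ExtendedSIRParams = ExtendedSIRParams()) -> ModelGraph:
    """Four state variables (S, I, R, E), seven constants.

    dS/dt = b - b_d*S*I - b_e*S*E - n*S
    dI/dt = b_d*S*I + b_e*S*E - g*I - n*I
    dR/dt = g*I - n*R
    dE/dt = p*I - c*E
    """
    g = ModelGraph("extended SIR",
                   "SIR with demography and environmental pathogen")
    S = g.add_term("S", params.S0)
    I = g.add_term("I", params.I0)
    R = g.add_term("R", params.R0)
    E = g.add_term("E", params.E0)
    b = g.add_term("b", params.b)
    b_d = g.add_term("b_d", params.b_d)
    b_e = g.add_term("b_e", params.b_e)
    n = g.add_term("n", params.n)
    rec = g.add_term("g", params.g)
    p = g.add_term("p", params.p)
    c = g.add_term("c", params.c)

    def product(name, *operands):
        e = g.add_expression("*", name, len(operands))
        for pin, op in enumerate(operands):
            g.connect(op, e, pin)
        return e

    infection = product("infection", b_d, S, I)
    env_infection = product("env infection", b_e, S, E)
    s_death = product("S death", n, S)
    recover = product("recover", rec, I)
    i_death = product("I death", n, I)
    r_death = product("R death", n, R)
    shedding = product("shedding", p, I)
    decay = product("decay", c, E)

    s_eq = g.add_expression("-", "S eq", 4)
    g.connect(b, s_eq, 0)
    g.connect(infection, s_eq, 1)
    g.connect(env_infection, s_eq, 2)
    g.connect(s_death, s_eq, 3)

    i_gain = g.add_expression("+", "I gain", 2)
    g.connect(infection, i_gain, 0)
    g.connect(env_infection, i_gain, 1)
    i_eq = g.add_expression("-", "I eq", 3)
    g.connect(i_gain, i_eq, 0)
    g.connect(recover, i_eq, 1)
    g.connect(i_death, i_eq, 2)

    r_eq = g.add_expression("-", "R eq", 2)
    g.connect(recover, r_eq, 0)
    g.connect(r_death, r_eq, 1)

    e_eq = g.add_expression("-", "E eq", 2)
    g.connect(shedding, e_eq, 0)
    g.connect(decay, e_eq, 1)

    g.connect(s_eq, g.add_assigner(S, "S ode"), 0)
    g.connect(i_eq, g.add_assigner(I, "I ode"), 0)
    g.connect(r_eq, g.add_assigner(R, "R ode"), 0)
    g.connect(e_eq, g.add_assigner(E, "E ode"), 0)

    g.sim_config = SimulationConfig(0.0, 0.5, 300.0,
                                    x_label="Time (days)",
                                    y_label="Individuals / pathogen load")
    return g


# --- innate immune regulation -------------------------------------------

@dataclass(frozen=True)
class ImmuneParams:
    """Innate immune response regulation after tissue injury.

    Neutrophils (N) migrate in, driven by tissue damage (TD) and
    pro-inflammatory cytokines (CH); their activity causes further damage.
    Regulatory macrophages (M_reg), recruited by neutrophils, clear damage
    and produce anti-inflammatory cytokines (AC) that divide down both
    neutrophil migration and cytokine production through the factor
    (1 + alpha*AC).
    """

    beta_N: float = 0.1    # neutrophil activity coefficient (damage making)
    m_N: float = 0.05      # neutrophil natural death
    s_N: float = 0.1       # neutrophil source scaling
    alpha: float = 1.0     # anti-inflammatory inhibition strength
    gamma: float = 0.5     # M_reg recruitment by neutrophils
    m_Mreg: float = 0.05   # M_reg decay
    beta_C: float = 0.5    # pro-inflammatory cytokine production
    m_C: float = 0.1       # pro-inflammatory cytokine decay
    beta_AC: float = 0.5   # anti-inflammatory cytokine production
    m_AC: float = 0.1      # anti-inflammatory cytokine decay
    k: float = 1.0         # damage clearance by M_reg
    N0: float = 0.0
    Mreg0: float = 0.0
    CH0: float = 0.0
    AC0: float = 0.0
    TD0: float = 1.0


def build_immune_model(
        params: ImmuneParams = ImmuneParams()) -> ModelGraph:
    """Five state variables (N, M_reg, CH, AC, TD); inhibition by division.

    dN/dt     = s_N*(TD + CH)/(1 + alpha*AC) - beta_N*N - m_N*N
    dM_reg/dt = gamma*N - m_Mreg*M_reg
    dCH/dt    = beta_C*N/(1 + alpha*AC) - m_C*CH
    dAC/dt    = beta_AC*M_reg - m_AC*AC
    dTD/dt    = beta_N*N - k*M_reg*TD

    The factor (1 + alpha*AC) is built with the ``inhibition`` extension
    node shipped in the package's data directory; the graph records a
    relative reference to that file.
    """
    ext_path = _immune_extension_path()
    inhibition = load_extension(ext_path)[0]

    g = ModelGraph("immune regulation",
                   "innate immune response regulation after tissue injury")
    g.extension_refs = [IMMUNE_EXTENSION_FILENAME]
    g.extensions = {inhibition.name: inhibition}

    N = g.add_term("N", params.N0)
    Mreg = g.add_term("M_reg", params.Mreg0)
    CH = g.add_term("CH", params.CH0)
    AC = g.add_term("AC", params.AC0)
    TD = g.add_term("TD", params.TD0)
    beta_N = g.add_term("beta_N", params.beta_N)
    m_N = g.add_term("m_N", params.m_N)
    s_N = g.add_term("s_N", params.s_N)
    alpha = g.add_term("alpha", params.alpha)
    gamma = g.add_term("gamma", params.gamma)
    m_Mreg = g.add_term("m_Mreg", params.m_Mreg)
    beta_C = g.add_term("beta_C", params.beta_C)
    m_C = g.add_term("m_C", params.m_C)
    beta_AC = g.add_term("beta_AC", params.beta_AC)
    m_AC = g.add_term("m_AC", params.m_AC)
    k = g.add_term("k", params.k)

    def product(name, *operands):
        e = g.add_expression("*", name, len(operands))
        for pin, op in enumerate(operands):
            g.connect(op, e, pin)
        return e

    def subtract(name, *operands):
        e = g.add_expression("-", name, len(operands))
        for pin, op in enumerate(operands):
            g.connect(op, e, pin)
        return e

    inhib = g.add_expression(inhibition, "AC inhibition", 2)
    g.connect(alpha, inhib, 0)
    g.connect(AC, inhib, 1)

    signal = g.add_expression("+", "damage signal", 2)
    g.connect(TD, signal, 0)
    g.connect(CH, signal, 1)
    migration_drive = product("migration drive", s_N, signal)
    migration = g.add_expression("/", "N migration", 2)
    g.connect(migration_drive, migration, 0)
    g.connect(inhib, migration, 1)

    n_activity = product("N activity loss", beta_N, N)
    n_death = product("N death", m_N, N)
    n_eq = subtract("N eq", migration, n_activity, n_death)

    mreg_eq = subtract("M_reg eq", product("M_reg recruit", gamma, N),
                       product("M_reg death", m_Mreg, Mreg))

    ch_drive = product("CH drive", beta_C, N)
    ch_production = g.add_expression("/", "CH production", 2)
    g.connect(ch_drive, ch_production, 0)
    g.connect(inhib, ch_production, 1)
    ch_eq = subtract("CH eq", ch_production, product("CH decay", m_C, CH))

    ac_eq = subtract("AC eq", product("AC production", beta_AC, Mreg),
                     product("AC decay", m_AC, AC))

    damage = product("TD source", beta_N, N)
    td_elim = product("TD elimination", k, Mreg, TD)
    td_eq = subtract("TD eq", damage, td_elim)

    g.connect(n_eq, g.add_assigner(N, "N ode"), 0)
    g.connect(mreg_eq, g.add_assigner(Mreg, "M_reg ode"), 0)
    g.connect(ch_eq, g.add_assigner(CH, "CH ode"), 0)
    g.connect(ac_eq, g.add_assigner(AC, "AC ode"), 0)
    g.connect(td_eq, g.add_assigner(TD, "TD ode"), 0)

    g.sim_config = SimulationConfig(0.0, 0.5, 300.0,
                                    x_label="Time (hours)",
                                    y_label="Concentration (a.u.)")
    return g


# --- Lotka–Volterra predator–prey ---------------------------------------

@dataclass(frozen=True)
class PredatorPreyParams:
    """Standard Lotka–Volterra form.

    dx/dt = alpha*x - beta*x*y  (prey), dy/dt = delta*x*y - gamma*y
    (predator). The quantity delta*x - gamma*ln(x) + beta*y - alpha*ln(y)
    is a first integral.
    """

    alpha: float = 1.1
    beta: float = 0.4
    delta: float = 0.1
    gamma: float = 0.4
    x0: float = 10.0
    y0: float = 10.0


def build_predator_prey(
        params: PredatorPreyParams = PredatorPreyParams()) -> ModelGraph:
    g = ModelGraph("predator-prey", "Lotka-Volterra predator-prey model")
    x = g.add_term("x", params.x0)
    y = g.add_term("y", params.y0)
    alpha = g.add_term("alpha", params.alpha)
    beta = g.add_term("beta", params.beta)
    delta = g.add_term("delta", params.delta)
    gamma = g.add_term("gamma", params.gamma)

    def product(name, *operands):
        e = g.add_expression("*", name, len(operands))
        for pin, op in enumerate(operands):
            g.connect(op, e, pin)
        return e

    growth = product("prey growth", alpha, x)
    predation = product("predation", beta, x, y)
    conversion = product("conversion", delta, x, y)
    mortality = product("predator death", gamma, y)

    x_eq = g.add_expression("-", "x eq", 2)
    g.connect(growth, x_eq, 0)
    g.connect(predation, x_eq, 1)
    y_eq = g.add_expression("-", "y eq", 2)
    g.connect(conversion, y_eq, 0)
    g.connect(mortality, y_eq, 1)

    g.connect(x_eq, g.add_assigner(x, "x ode"), 0)
    g.connect(y_eq, g.add_assigner(y, "y ode"), 0)

    g.sim_config = SimulationConfig(0.0, 0.05, 50.0,
                                    x_label="Time",
                                    y_label="Population")
    return g


ALL_FIXTURES = {
    "sir": build_sir,
    "extended-sir": build_extended_sir,
    "immune": build_immune_model,
    "predator-prey": build_predator_prey,
}


def materialize(name: str, directory) -> list[Path]:
    """Write a fixture's IR file (and any extension files) into a directory.

    Returns the written paths; the model file comes first.
    """
    from . import ir

    if name not in ALL_FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"choose from {sorted(ALL_FIXTURES)}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    graph = ALL_FIXTURES[name]()
    model_path = directory / f"{name.replace('-', '_')}.json"
    ir.save(graph, model_path)
    written = [model_path]
    if graph.extension_refs:
        ext_path = directory / IMMUNE_EXTENSION_FILENAME
        ext_path.write_text(immune_extension_source(), encoding="utf-8")
        written.append(ext_path)
    return written
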