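"""Predict circuit behaviour from a wired netlist.

The pipeline per input condition:

1. **Transcription** — each species' transcript abundance is its plasmid
   copy scale times a leaky Hill response to its inducer:
   ``copy_scale * (leak + (1 - leak) * c^n / (K^n + c^n))``.  Constitutive
   and unwired species sit at full induction.
2. **Competitive hybridization equilibrium** — switch sensor sites,
   triggers and antisenses equilibrate through simultaneous bimolecular
   binding reactions (S + T <=> S.T, T + A <=> T.A) with association
   constants ``K = exp(-dG / energy_scale)`` from duplex energies.  The
   antisense out-competes the switch because its duplex with the trigger
   is more favourable (overhang pairing), pulling trigger away from the
   sensor — strand displacement and direct capture reach the same final
   state, so a single equilibrium covers both mechanisms.
3. **Readout** — a reporter's level is basal plus gain times the fraction
   of switch molecules with at least one triggered sensor (OR gates) or
   all sensors triggered (AND parts).

Truth tables call a row ON when its level crosses a threshold calibrated
as the geometric mean of a reference BUFFER gate's ON and OFF levels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fold import DEFAULT_MODEL, EnergyModel, duplex_energy, structure_energy
from .parts import CircuitNetlist, ConcatenatedSwitch

__all__ = [
    "ExpressionParams",
    "Binding",
    "EquilibriumState",
    "SolverError",
    "TruthTableResult",
    "transcription_levels",
    "solve_equilibrium",
    "two_species_closed_form",
    "netlist_bindings",
    "readout",
    "calibrate_threshold",
    "truth_table",
    "dose_grid",
]


@dataclass(frozen=True)
class ExpressionParams:
    """Tunable constants of the expression and equilibrium model.

    All concentrations are relative units (a low-copy plasmid's transcript
    pool is 1).  ``energy_scale`` converts duplex energies into association
    constants, ``K = exp(-dG/energy_scale)``; the default is chosen so a
    cognate ~30-bp trigger-switch interaction binds strongly
    (K * abundance >> 1) while a leak-level trigger pool does not saturate
    its sensor.  These are model constants, not measured cellular numbers.
    """

    copy_scale: dict[str, float] = field(
        default_factory=lambda: {"low": 1.0, "medium": 3.0, "high": 9.0}
    )
    leak_fraction: float = 0.02
    hill_K: dict[str, float] = field(default_factory=dict)
    default_hill_K: float = 0.25
    hill_n: float = 2.0
    reporter_gain: float = 100.0
    reporter_basal: float = 1.0
    energy_scale: float = 30.0
    include_stem_opening: bool = True
    on_conc: float = 1.0
    threshold: float | None = None  # absolute override for Boolean calls
    digitality_ratio: float = 3.0
    master_switch: bool = True  # arabinose-induced T7 polymerase, globally on

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.copy_scale.values()):
            raise ValueError("copy scales must be positive")
        if not (0 <= self.leak_fraction < 1):
            raise ValueError("leak_fraction must be in [0, 1)")
        if self.hill_n <= 0 or self.energy_scale <= 0:
            raise ValueError("hill_n and energy_scale must be positive")

    def hill(self, inducer: str, conc: float) -> float:
        if conc < 0:
            raise ValueError(f"negative concentration for {inducer}")
        if conc == 0:
            return 0.0
        K = self.hill_K.get(inducer, self.default_hill_K)
        cn = conc**self.hill_n
        return cn / (K**self.hill_n + cn)


DEFAULT_PARAMS = ExpressionParams()


# ---------------------------------------------------------------------------
# transcription


def transcription_levels(
    netlist: CircuitNetlist,
    inducer_concs: dict[str, float],
    params: ExpressionParams = DEFAULT_PARAMS,
) -> dict[str, float]:
    """Per-species transcript abundance under the given inducer condition.

    Operator-wired species follow the leaky Hill response of the inducer
    bound to their operator; constitutive and unwired species are fully
    expressed.  Switches are unwired (they sit behind the bare promoter).
    """
    if not params.master_switch:
        return {name: 0.0 for name in netlist.species_names()}
    op_inducer = {op: ind for ind, op in netlist.inducer_map.items()}
    out: dict[str, float] = {}
    for sw in netlist.switches:
        level = params.copy_scale[netlist.plasmids.get(sw.name, "low")]
        out[sw.name] = level
    for sp in list(netlist.triggers) + list(netlist.antisenses):
        scale = params.copy_scale[netlist.plasmids.get(sp.name, "medium")]
        if sp.operator in ("constitutive", "none"):
            theta = 1.0
        else:
            inducer = op_inducer.get(sp.operator)
            conc = inducer_concs.get(inducer, 0.0) if inducer else 0.0
            theta = params.hill(inducer or sp.operator, conc)
        out[sp.name] = scale * (params.leak_fraction + (1 - params.leak_fraction) * theta)
    return out


# ---------------------------------------------------------------------------
# equilibrium solver


@dataclass(frozen=True)
class Binding:
    """One bimolecular association a + b <=> a.b with constant K."""

    a: str
    b: str
    K: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.K) or self.K < 0:
            raise ValueError(f"K must be finite and >= 0 (got {self.K})")


class SolverError(RuntimeError):
    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (residual {residual:.3e})")
        self.residual = residual


@dataclass
class EquilibriumState:
    """Free and complexed concentrations at equilibrium."""

    free: dict[str, float]
    complexes: dict[tuple[str, str], float]
    totals: dict[str, float]

    def conservation_residual(self) -> float:
        """Worst relative mass-conservation error over all species."""
        worst = 0.0
        for name, total in self.totals.items():
            mass = self.free[name] + sum(
                c for (a, b), c in self.complexes.items() if name in (a, b)
            )
            denom = max(total, 1e-300)
            worst = max(worst, abs(mass - total) / denom)
        return worst

    def bound_fraction(self, name: str, partner: str) -> float:
        """Fraction of ``name``'s total bound in the complex with ``partner``."""
        total = self.totals[name]
        if total == 0:
            return 0.0
        c = self.complexes.get((name, partner), 0.0) + self.complexes.get((partner, name), 0.0)
        return c / total


def solve_equilibrium(
    totals: dict[str, float],
    bindings: list[Binding],
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> EquilibriumState:
    """Solve the coupled binding equilibria by damped fixed-point iteration.

    Each free concentration obeys ``free_x = total_x / (1 + sum_b K_b *
    free_partner)``; iterating this map with under-relaxation converges to
    the unique non-negative equilibrium of a bipartite-competition network.
    Raises :class:`SolverError` with the residual on non-convergence.
    """
    for name, t in totals.items():
        if t < 0:
            raise ValueError(f"negative total for {name}")
    partners: dict[str, list[tuple[str, float]]] = {n: [] for n in totals}
    for b in bindings:
        if b.a not in totals or b.b not in totals:
            raise ValueError(f"binding {b.a}-{b.b} references unknown species")
        partners[b.a].append((b.b, b.K))
        partners[b.b].append((b.a, b.K))

    free = {n: float(t) for n, t in totals.items()}
    damp = 0.5
    converged = False
    for _ in range(max_iter):
        delta = 0.0
        for n, t in totals.items():
            denom = 1.0 + sum(K * free[p] for p, K in partners[n])
            new = t / denom
            old = free[n]
            free[n] = damp * new + (1 - damp) * old
            scale = max(abs(old), abs(new), 1e-300)
            delta = max(delta, abs(new - old) / scale)
        if delta < tol:
            converged = True
            break
    complexes = {(b.a, b.b): b.K * free[b.a] * free[b.b] for b in bindings}
    state = EquilibriumState(free=free, complexes=complexes, totals=dict(totals))
    residual = state.conservation_residual()
    if not converged or residual > 1e-9:
        raise SolverError("equilibrium solver did not converge", residual)
    return state


def two_species_closed_form(s_total: float, t_total: float, K: float) -> float:
    """Complex concentration of a single S + T <=> S.T binding (quadratic)."""
    if K == 0:
        return 0.0
    b = s_total + t_total + 1.0 / K
    disc = b * b - 4.0 * s_total * t_total
    return (b - math.sqrt(disc)) / 2.0


# ---------------------------------------------------------------------------
# netlist -> binding network


def _sensor_site(switch_name: str, sensor_name: str) -> str:
    return f"{switch_name}:{sensor_name}"


def netlist_bindings(
    netlist: CircuitNetlist,
    model: EnergyModel = DEFAULT_MODEL,
    params: ExpressionParams = DEFAULT_PARAMS,
) -> list[Binding]:
    """Association constants for every declared interaction edge.

    Trigger-sensor constants include the cost of opening the sequestering
    stem (the trigger must displace stem_top from stem_bottom), so the
    effective dG is the trigger-sensing-domain duplex energy minus the
    hairpin stem energy.  Trigger-antisense constants use the full duplex
    energy — this asymmetry is the thermodynamic driving force.
    """
    sensors = {s.name: (own, s) for own, s in netlist.sensors()}
    bindings: list[Binding] = []
    for e in netlist.activation_edges():
        sensor_name = e.sensor or e.target
        own, sensor = sensors[sensor_name]
        trig = netlist.trigger(e.source)
        dg = duplex_energy(trig.seq, sensor.sensing_seq, model).energy
        if params.include_stem_opening:
            stem_dg = structure_energy(sensor.seq, sensor.target_pairs(), model)
            dg -= stem_dg  # stem_dg < 0: opening it costs energy
        K = math.exp(-dg / params.energy_scale)
        bindings.append(Binding(a=_sensor_site(own, sensor_name), b=trig.name, K=K))
    for e in netlist.annihilation_edges():
        anti = netlist.antisense(e.source)
        trig = netlist.trigger(e.target)
        dg = duplex_energy(trig.seq, anti.seq, model).energy
        K = math.exp(-dg / params.energy_scale)
        bindings.append(Binding(a=trig.name, b=anti.name, K=K))
    return bindings


def _site_totals(
    netlist: CircuitNetlist, abundances: dict[str, float]
) -> dict[str, float]:
    """Expand switch abundances to per-sensor-site totals."""
    totals: dict[str, float] = {}
    for own, sensor in netlist.sensors():
        totals[_sensor_site(own, sensor.name)] = abundances[own]
    for t in netlist.triggers:
        totals[t.name] = abundances[t.name]
    for a in netlist.antisenses:
        totals[a.name] = abundances[a.name]
    return totals


def simulate_condition(
    netlist: CircuitNetlist,
    inducer_concs: dict[str, float],
    params: ExpressionParams = DEFAULT_PARAMS,
    model: EnergyModel = DEFAULT_MODEL,
    bindings: list[Binding] | None = None,
) -> tuple[EquilibriumState, dict[str, float]]:
    """Transcription + equilibrium + readout for one inducer condition."""
    abundances = transcription_levels(netlist, inducer_concs, params)
    totals = _site_totals(netlist, abundances)
    if bindings is None:
        bindings = netlist_bindings(netlist, model, params)
    state = solve_equilibrium(totals, bindings)
    return state, readout(state, netlist, params)


# ---------------------------------------------------------------------------
# readout


def readout(
    state: EquilibriumState,
    netlist: CircuitNetlist,
    params: ExpressionParams = DEFAULT_PARAMS,
) -> dict[str, float]:
    """Reporter levels: basal plus gain times the triggered-switch fraction.

    For an OR-type concatenated switch the relevant fraction is molecules
    with *at least one* sensor occupied (sensors are treated as
    independent sites: 1 - prod(1 - f_k)); an AND part needs *all* sensors
    occupied (prod f_k).
    """
    trigger_names = {t.name for t in netlist.triggers}
    levels: dict[str, float] = {}
    for sw in netlist.switches:
        sensor_list = (
            list(sw.sensors) if isinstance(sw, ConcatenatedSwitch) else [sw]
        )
        fractions = []
        for sensor in sensor_list:
            site = _sensor_site(sw.name, sensor.name)
            f = sum(
                state.bound_fraction(site, t) for t in trigger_names
                if (site, t) in state.complexes or (t, site) in state.complexes
            )
            fractions.append(min(f, 1.0))
        combine = sw.combine if isinstance(sw, ConcatenatedSwitch) else "or"
        if combine == "and":
            frac_on = float(np.prod(fractions))
        else:
            frac_on = 1.0 - float(np.prod([1.0 - f for f in fractions]))
        levels[netlist.reporters[sw.name]] = (
            params.reporter_basal + params.reporter_gain * frac_on
        )
    return levels


# ---------------------------------------------------------------------------
# Boolean threshold and truth tables


def calibrate_threshold(
    netlist: CircuitNetlist,
    params: ExpressionParams = DEFAULT_PARAMS,
    model: EnergyModel = DEFAULT_MODEL,
) -> float:
    """Geometric mean of a reference BUFFER gate's ON and OFF levels.

    The reference is the netlist's first activation edge taken in
    isolation: its sensor at switch copy number with its trigger either
    fully induced or at transcriptional leak.  An absolute override in
    ``params.threshold`` wins.
    """
    if params.threshold is not None:
        return params.threshold
    bindings = netlist_bindings(netlist, model, params)
    edge = netlist.activation_edges()[0]
    site = _sensor_site(edge.target, edge.sensor or edge.target)
    K = next(b.K for b in bindings if {b.a, b.b} == {site, edge.source})
    s_total = params.copy_scale["low"]
    t_on = params.copy_scale["medium"]
    t_off = t_on * params.leak_fraction
    lvls = []
    for t_total in (t_on, t_off):
        c = two_species_closed_form(s_total, t_total, K)
        lvls.append(params.reporter_basal + params.reporter_gain * (c / s_total))
    return math.sqrt(lvls[0] * lvls[1])


@dataclass(frozen=True)
class TruthTableRow:
    inputs: tuple[int, ...]
    levels: dict[str, float]
    calls: dict[str, bool]
    margins: dict[str, float]


@dataclass
class TruthTableResult:
    """Predicted level, Boolean call and margin per reporter for every
    input combination."""

    inputs: tuple[str, ...]
    channels: tuple[str, ...]
    rows: list[TruthTableRow]
    threshold: float

    def calls(self, channel: str) -> dict[tuple[int, ...], bool]:
        return {r.inputs: r.calls[channel] for r in self.rows}

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec: dict = {bit: v for bit, v in zip(self.inputs, r.inputs)}
            for ch in self.channels:
                rec[f"{ch}_level"] = r.levels[ch]
                rec[f"{ch}_call"] = int(r.calls[ch])
                rec[f"{ch}_margin"] = r.margins[ch]
            recs.append(rec)
        return pd.DataFrame(recs)


def truth_table(
    netlist: CircuitNetlist,
    params: ExpressionParams = DEFAULT_PARAMS,
    on_concs: dict[str, float] | None = None,
    model: EnergyModel = DEFAULT_MODEL,
) -> TruthTableResult:
    """Evaluate all 2^n input combinations at on/off inducer concentrations."""
    if not netlist.inducer_map:
        raise ValueError("netlist is not wired; call wire_inducers first")
    inducers = list(netlist.inducer_map)
    # order inducers by the bit they carry so rows follow netlist.inputs
    bit_of = {}
    op_inducer = {op: ind for ind, op in netlist.inducer_map.items()}
    for sp in list(netlist.triggers) + list(netlist.antisenses):
        bit = netlist.input_bits.get(sp.name)
        ind = op_inducer.get(sp.operator)
        if bit and bit != "const" and ind:
            bit_of[ind] = bit
    inducers.sort(key=lambda ind: netlist.inputs.index(bit_of.get(ind, ind)))
    on = on_concs or {ind: DEFAULT_PARAMS.on_conc for ind in inducers}
    bindings = netlist_bindings(netlist, model, params)
    thr = calibrate_threshold(netlist, params, model)
    channels = tuple(dict.fromkeys(netlist.reporters.values()))
    rows = []
    for combo in itertools.product((0, 1), repeat=len(inducers)):
        concs = {ind: (on[ind] if bit else 0.0) for ind, bit in zip(inducers, combo)}
        try:
            _, levels = simulate_condition(netlist, concs, params, model, bindings)
        except SolverError as exc:
            raise SolverError(f"input row {combo}: {exc}", exc.residual) from exc
        rows.append(
            TruthTableRow(
                inputs=combo,
                levels=levels,
                calls={ch: levels[ch] >= thr for ch in channels},
                margins={ch: levels[ch] / thr for ch in channels},
            )
        )
    return TruthTableResult(
        inputs=tuple(netlist.inputs), channels=channels, rows=rows, threshold=thr
    )


def dose_grid(
    netlist: CircuitNetlist,
    grid: dict[str, list[float]],
    params: ExpressionParams = DEFAULT_PARAMS,
    model: EnergyModel = DEFAULT_MODEL,
    channel: str | None = None,
) -> pd.DataFrame:
    """Reporter level over a 2-D inducer concentration grid.

    Rows are concentrations of the first inducer in ``grid``, columns the
    second; for a single-inducer grid a one-column frame is returned.
    """
    inducers = list(grid)
    if not inducers or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    if any(c < 0 for v in grid.values() for c in v):
        raise ValueError("grid concentrations must be non-negative")
    bindings = netlist_bindings(netlist, model, params)
    if channel is None:
        channel = next(iter(dict.fromkeys(netlist.reporters.values())))
    if len(inducers) == 1:
        ind = inducers[0]
        vals = [
            simulate_condition(netlist, {ind: c}, params, model, bindings)[1][channel]
            for c in grid[ind]
        ]
        return pd.DataFrame({channel: vals}, index=pd.Index(grid[ind], name=ind))
    ind_r, ind_c = inducers[0], inducers[1]
    data = np.zeros((len(grid[ind_r]), len(grid[ind_c])))
    for i, cr in enumerate(grid[ind_r]):
        for j, cc in enumerate(grid[ind_c]):
            _, levels = simulate_condition(
                netlist, {ind_r: cr, ind_c: cc}, params, model, bindings
            )
            data[i, j] = levels[channel]
    return pd.DataFrame(
        data,
        index=pd.Index(grid[ind_r], name=ind_r),
        columns=pd.Index(grid[ind_c], name=ind_c),
    )
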