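"""In-process numerical simulation: integrate, export CSV, render reports.

The ODE system is recovered from the graph's assigner expression trees and
integrated with :func:`scipy.integrate.solve_ivp` using an adaptive
explicit Runge–Kutta 5(4) method by default (a stiff alternative is
selectable via ``SimulationConfig.method``). The solver steps adaptively;
results are reported on the fixed user grid ``t0, t0+Δt, ...``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .errors import (
    ConfigError,
    EvaluationError,
    InvalidModelError,
    SimulationError,
)

_GRID_SNAP = 1e-9  # relative-to-step tolerance for landing on end_time


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation settings: reporting grid, axis labels, solver tolerances.

    ``time_step`` is the output grid spacing only; integration accuracy is
    governed by ``rel_tol``/``abs_tol`` and the adaptive solver.
    """

    start_time: float = 0.0
    time_step: float = 0.1
    end_time: float = 50.0
    x_label: str = "Time"
    y_label: str = "Population"
    rel_tol: float = 1e-6
    abs_tol: float = 1e-9
    method: str = "RK45"

    def check(self) -> None:
        if not self.time_step > 0:
            raise ConfigError(f"time_step must be > 0, got {self.time_step}")
        if self.end_time < self.start_time:
            raise ConfigError(
                f"end_time ({self.end_time}) must be >= start_time "
                f"({self.start_time})")
        if not self.rel_tol > 0 or not self.abs_tol > 0:
            raise ConfigError("solver tolerances must be positive")


@dataclass
class SimulationResult:
    """Time grid plus one trajectory per state variable."""

    times: np.ndarray
    trajectories: np.ndarray  # shape (n_variables, n_times)
    variable_names: list[str]

    def series(self, name: str) -> np.ndarray:
        return self.trajectories[self.variable_names.index(name)]


def time_grid(start: float, step: float, end: float) -> np.ndarray:
    """The reporting grid ``start, start+step, ...``.

    Built by count rather than accumulation so floating-point drift cannot
    change the number of points; the last point is snapped to ``end`` when
    it lands there within ``step * 1e-9``.
    """
    if end == start:
        return np.array([float(start)])
    n = int(math.floor((end - start) / step + _GRID_SNAP))
    times = start + step * np.arange(n + 1, dtype=float)
    if abs(times[-1] - end) <= step * _GRID_SNAP:
        times[-1] = end
    return times


def compile_rhs(graph) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the graph's assigners into a derivative function f(t, y).

    The returned function evaluates each state variable's expression tree
    under bindings drawn from the state vector (variables) and term values
    (constants); output order matches ``classify_terms``. Refuses a graph
    that fails validation.
    """
    from .expression import build_expression_tree, evaluate

    violations = graph.validate()
    if violations:
        raise InvalidModelError(violations)

    var_ids, const_ids = graph.classify_terms()
    var_names = [graph.node(i).name for i in var_ids]
    constants = {graph.node(i).name: graph.node(i).value for i in const_ids}
    trees = []
    for vid in var_ids:
        assigner = next(a for a in graph.assigners() if a.target == vid)
        trees.append(build_expression_tree(graph, assigner.id))

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        bindings = dict(constants)
        for name, value in zip(var_names, y):
            bindings[name] = value
        out = np.empty(len(trees))
        for i, tree in enumerate(trees):
            try:
                out[i] = evaluate(tree, bindings)
            except EvaluationError as exc:
                raise SimulationError(
                    f"at t={t}: {exc}", time=t,
                    expression_text=exc.expression_text) from exc
        return out

    return rhs


def initial_state(graph) -> tuple[list[str], np.ndarray]:
    """State-variable names and initial values, in classification order."""
    var_ids, _ = graph.classify_terms()
    names = [graph.node(i).name for i in var_ids]
    y0 = np.array([graph.node(i).value for i in var_ids], dtype=float)
    return names, y0


def simulate(graph, config: SimulationConfig | None = None) -> SimulationResult:
    """Integrate the model and report on the configured fixed grid.

    Uses the graph's own ``sim_config`` unless one is passed explicitly.
    Raises SimulationError if the integrator fails (carrying the failing
    time and, for expression-level failures such as division by zero, the
    rendered offending subexpression).
    """
    config = graph.sim_config if config is None else config
    config.check()
    rhs = compile_rhs(graph)
    names, y0 = initial_state(graph)
    times = time_grid(config.start_time, config.time_step, config.end_time)

    if len(times) == 1:
        return SimulationResult(times, y0[:, None].copy(), names)

    from scipy.integrate import solve_ivp

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        y0,
        method=config.method,
        t_eval=times,
        rtol=config.rel_tol,
        atol=config.abs_tol,
    )
    if not sol.success:
        raise SimulationError(
            f"integration failed: {sol.message}",
            time=float(sol.t[-1]) if sol.t.size else config.start_time)
    if not np.all(np.isfinite(sol.y)):
        bad = np.argwhere(~np.isfinite(sol.y))
        t_bad = float(sol.t[bad[0][1]])
        raise SimulationError(
            f"non-finite state encountered at t={t_bad}", time=t_bad)
    trajectories = sol.y.copy()
    trajectories[:, 0] = y0  # initial row is the exact initial condition
    return SimulationResult(sol.t.copy(), trajectories, names)


def write_csv(result: SimulationResult, path) -> None:
    """Write ``t`` plus one column per variable, round-trippable precision."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t"] + list(result.variable_names))
        for j, t in enumerate(result.times):
            row = [repr(float(t))]
            row += [repr(float(v)) for v in result.trajectories[:, j]]
            writer.writerow(row)


def read_csv(path) -> SimulationResult:
    """Parse a CSV written by :func:`write_csv` (exact round-trip)."""
    with Path(path).open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    header, data = rows[0], rows[1:]
    arr = np.array([[float(x) for x in row] for row in data])
    return SimulationResult(arr[:, 0], arr[:, 1:].T.copy(), header[1:])


def render_report(graph, result: SimulationResult, path) -> None:
    """Write a multi-page PDF: combined plot, then one page per variable."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages

    config = graph.sim_config
    with PdfPages(Path(path)) as pdf:
        fig, ax = plt.subplots(figsize=(8, 5))
        for name in result.variable_names:
            ax.plot(result.times, result.series(name), label=name)
        ax.set_xlabel(config.x_label)
        ax.set_ylabel(config.y_label)
        ax.set_title(graph.name)
        ax.legend()
        pdf.savefig(fig)
        plt.close(fig)
        for name in result.variable_names:
            fig, ax = plt.subplots(figsize=(8, 5))
            ax.plot(result.times, result.series(name))
            ax.set_xlabel(config.x_label)
            ax.set_ylabel(config.y_label)
            ax.set_title(name)
            pdf.savefig(fig)
            plt.close(fig)
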