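#!/usr/bin/env python3
"""{{ model_name }} — standalone ODE simulation.

Auto-generated from a node-graph model. Runs with no arguments; optional
arguments override the output paths:

    python this_script.py [results.csv] [combined.png] [per-variable-prefix]

State variables: {{ populations | map(attribute="identifier") | join(", ") }}
"""

import csv
import math
import sys

import numpy as np
from scipy.integrate import solve_ivp

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt


def node(func=None, **_kwargs):
    """Decorator used by extension functions; a no-op outside the GUI."""
    if func is None:
        return lambda f: f
    return func

{% for src in extension_sources %}

{{ src }}
{% endfor %}

# --- model definition ---------------------------------------------------

initial_values = [{% for p in populations %}{{ p.initial_value }}{% if not loop.last %}, {% endif %}{% endfor %}]
constant_values = ({% for c in constants %}{{ c.value }}, {% endfor %})

start_time = {{ sim.start_time }}
time_step = {{ sim.time_step }}
end_time = {{ sim.end_time }}
rel_tol = {{ sim.rel_tol }}
abs_tol = {{ sim.abs_tol }}
method = "{{ sim.method }}"


def system(t: np.float64, y: np.ndarray, *constants) -> np.ndarray:
    {% for arg in populations %}{{ arg.identifier }}, {% endfor %} = y
    {%- if constants %}
    {% for arg in constants %}{{ arg.identifier }}, {% endfor %} = constants
    {%- endif %}
    return np.array([
{% for ode in odes %}        {{ ode.rhs_text }},
{% endfor %}    ])


# --- integration on the fixed reporting grid ----------------------------

if end_time == start_time:
    times = np.array([float(start_time)])
else:
    n = int(math.floor((end_time - start_time) / time_step + 1e-9))
    times = start_time + time_step * np.arange(n + 1, dtype=float)
    if abs(times[-1] - end_time) <= time_step * 1e-9:
        times[-1] = end_time

if len(times) == 1:
    trajectories = np.array(initial_values, dtype=float)[:, None]
else:
    solution = solve_ivp(
        system,
        (times[0], times[-1]),
        initial_values,
        method=method,
        t_eval=times,
        rtol=rel_tol,
        atol=abs_tol,
        args=constant_values,
    )
    if not solution.success:
        sys.exit(f"integration failed: {solution.message}")
    trajectories = solution.y.copy()
    trajectories[:, 0] = np.array(initial_values, dtype=float)

# --- outputs ------------------------------------------------------------

variable_names = [{% for p in populations %}"{{ p.identifier }}"{% if not loop.last %}, {% endif %}{% endfor %}]
csv_path = sys.argv[1] if len(sys.argv) > 1 else "{{ csv_path }}"
combined_path = sys.argv[2] if len(sys.argv) > 2 else "{{ combined_plot_path }}"
plot_prefix = sys.argv[3] if len(sys.argv) > 3 else "{{ plot_prefix }}"

with open(csv_path, "w", newline="", encoding="utf-8") as fh:
    writer = csv.writer(fh)
    writer.writerow(["t"] + variable_names)
    for j, t in enumerate(times):
        writer.writerow([repr(float(t))]
                        + [repr(float(v)) for v in trajectories[:, j]])

fig, ax = plt.subplots(figsize=(8, 5))
for i, name in enumerate(variable_names):
    ax.plot(times, trajectories[i], label=name)
ax.set_xlabel("{{ sim.x_label }}")
ax.set_ylabel("{{ sim.y_label }}")
ax.legend()
fig.savefig(combined_path)
plt.close(fig)

for i, name in enumerate(variable_names):
    fig, ax = plt.subplots(figsize=(8, 5))
    ax.plot(times, trajectories[i])
    ax.set_xlabel("{{ sim.x_label }}")
    ax.set_ylabel("{{ sim.y_label }}")
    ax.set_title(name)
    fig.savefig(f"{plot_prefix}{name}.png")
    plt.close(fig)

print(f"wrote {csv_path} ({len(times)} rows, {len(variable_names)} variables)")
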