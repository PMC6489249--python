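"""Quick-look matplotlib plots for solved models and protocols."""

from __future__ import annotations

import numpy as np


def plot_load_displacement(curve, ax=None):
    """Navicular drop versus axial load (the validation-protocol figure)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(curve.loads, curve.navicular_drop, "o-", color="tab:blue")
    ax.set_xlabel("axial load (N)")
    ax.set_ylabel("navicular drop (mm)")
    ax.set_title("Navicular load-displacement")
    ax.grid(True, alpha=0.3)
    return ax


def plot_sagittal(result, ax=None, annotate=False):
    """Medial (sagittal, X-Z) view of a solved pose: landmarks and taut
    elements, line width scaled by tension."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    positions = result.landmark_positions()
    pts = np.array(list(positions.values()))
    ax.plot(pts[:, 0], pts[:, 2], ".", ms=2, color="0.6")

    model = result.model
    states = result.segment_states()
    fmax = max(result.element_forces.values()) or 1.0
    for el in model.elements:
        force = result.element_forces[el.name]
        if force <= 0:
            continue
        xs, zs = [], []
        for rp in el.route:
            seg = model.segments[rp.segment]
            R, t = states[rp.segment]
            p = seg.origin + t + R @ rp.local
            xs.append(p[0])
            zs.append(p[2])
        color = {"ligament": "tab:blue", "graft": "tab:red", "muscle": "tab:green"}[el.kind]
        ax.plot(xs, zs, color=color, lw=0.5 + 2.5 * force / fmax, alpha=0.7)
        if annotate:
            ax.annotate(el.name, (xs[0], zs[0]), fontsize=5)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_aspect("equal")
    ax.set_xlabel("anterior (mm)")
    ax.set_ylabel("vertical (mm)")
    ax.set_title(f"{model.scenario} at {model.load_case.axial_load:.0f} N")
    return ax
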