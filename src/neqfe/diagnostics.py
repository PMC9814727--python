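"""Work-distribution overlap diagnostics for bi-directional estimates.

The convergence measure compares a first-order and a second-order estimate
of the forward/reverse work-distribution overlap. It lives in [−1, 1]: well
converged estimates return values close to 0, while disjoint work
distributions push the measure towards 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .work_io import WorkSet

__all__ = ["OverlapReport", "convergence_measure", "distribution_summary"]


def _fermi(x: np.ndarray) -> np.ndarray:
    """φ(x) = 1/(1+exp(x)), evaluated without overflow."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    return out


@dataclass(frozen=True)
class OverlapReport:
    """Result of :func:`convergence_measure`."""

    measure: float
    a_first: float
    a_second: float
    dg_used: float
    n_forward: int
    n_reverse: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.measure <= 1.0 + 1e-12:
            raise ValueError("measure must lie in [-1, 1]")


def convergence_measure(ws: WorkSet, dg: float) -> OverlapReport:
    """Overlap-based convergence measure evaluated at ΔG = *dg* (kJ/mol).

    With φ the Fermi function and f = dg/kT:

        f_i = φ(u_i^F − f)   over forward reduced works,
        g_j = φ(u_j^R + f)   over reverse reduced works,
        a1  = (mean f_i + mean g_j)/2
        a2  = mean(f_i²) + mean(g_j²)
        measure = (a1 − a2)/(a1 + a2)

    a1 and a2 are first- and second-moment estimates of the same overlap
    integral, so they agree (measure ≈ 0) when both work distributions are
    well sampled around ΔG. Disjoint distributions make every φ underflow
    and the measure is reported as exactly 1 (no overlap).
    """
    if ws.n_forward == 0 or ws.n_reverse == 0:
        raise ValueError("convergence measure requires both directions")
    f = dg / ws.kt
    fi = _fermi(ws.u_forward - f)
    gj = _fermi(ws.u_reverse + f)
    a1 = 0.5 * (fi.mean() + gj.mean())
    a2 = float(np.mean(fi**2) + np.mean(gj**2))
    if a1 + a2 == 0.0:
        measure = 1.0
    else:
        measure = (a1 - a2) / (a1 + a2)
    return OverlapReport(
        measure=float(measure), a_first=float(a1), a_second=float(a2),
        dg_used=float(dg), n_forward=ws.n_forward, n_reverse=ws.n_reverse,
    )


def distribution_summary(ws: WorkSet, dg: float) -> dict:
    """Per-direction descriptive statistics of the work distributions.

    Returns a dict with one entry per non-empty direction holding n, mean
    work, std (ddof=1, requires ≥2 samples) and the dissipated work
    ⟨W⟩ − ΔG (forward) or ⟨W⟩ + ΔG (reverse), each in kJ/mol and kT.
    """
    kt = ws.kt
    out: dict[str, dict] = {"dg_used": float(dg), "temperature": ws.temperature}
    for direction, w, sign in (("forward", ws.w_forward, -1.0), ("reverse", ws.w_reverse, +1.0)):
        if w.size == 0:
            continue
        mean = float(w.mean())
        dissipated = mean + sign * dg
        entry = {
            "n": int(w.size),
            "mean_kJmol": mean,
            "mean_kt": mean / kt,
            "dissipated_kJmol": dissipated,
            "dissipated_kt": dissipated / kt,
        }
        if w.size >= 2:
            std = float(w.std(ddof=1))
            entry["std_kJmol"] = std
            entry["std_kt"] = std / kt
        out[direction] = entry
    return out
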