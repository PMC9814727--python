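"""Free-energy estimators on non-equilibrium work samples.

Uni-directional estimation uses Jarzynski's equality; bi-directional
estimation uses the maximum-likelihood acceptance-ratio estimator (BAR).
Uncertainties come from bootstrap resampling of the work samples.

Reduced units u = W/(k_B*T) are used internally; returned ΔG values are
kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .work_io import FORWARD, REVERSE, WorkSet

__all__ = [
    "FreeEnergyEstimate",
    "jarzynski",
    "bar",
    "bar_reduced",
    "bootstrap_se",
    "chain_windows",
    "zwanzig",
]

#: Root-finding tolerance for the BAR self-consistency equation, in kT.
BAR_TOL = 1e-8


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A ΔG estimate with its uncertainty and provenance.

    ``dg`` and ``se`` are kJ/mol. ``convergence`` is the work-distribution
    overlap measure in [−1, 1] and is only attached to BAR estimates.
    """

    dg: float
    se: float
    method: str
    n_forward: int
    n_reverse: int
    temperature: float
    convergence: float | None = None

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be non-negative")
        if self.n_forward + self.n_reverse < 1:
            raise ValueError("at least one sample required")
        if self.convergence is not None and self.method != "bar":
            raise ValueError("convergence measure only applies to method='bar'")

    @property
    def dg_kcal(self) -> float:
        return self.dg / 4.184

    @property
    def se_kcal(self) -> float:
        return self.se / 4.184


def jarzynski(
    works: Sequence[float] | np.ndarray,
    direction: str,
    temperature: float,
    n_boot: int = 0,
    seed: int | None = None,
) -> FreeEnergyEstimate:
    """Uni-directional ΔG via Jarzynski's equality, exp(−βΔG) = ⟨exp(−βW)⟩.

    For forward works ΔG = −kT ln⟨exp(−u)⟩; for reverse works the ΔG *of the
    forward process* is +kT ln⟨exp(−u)⟩ (works are stored as performed in
    their own direction). The exponential average is evaluated with a
    log-sum-exp shift, so it cannot overflow.

    With ``n_boot > 0`` the standard error is filled by :func:`bootstrap_se`.
    """
    from .constants import kt_kj

    w = np.atleast_1d(np.asarray(works, dtype=float))
    if w.size == 0:
        raise ValueError("empty work sample")
    if direction not in (FORWARD, REVERSE):
        raise ValueError(f"direction must be 'forward' or 'reverse', got {direction!r}")
    kt = kt_kj(temperature)
    u = w / kt
    log_mean = logsumexp(-u) - np.log(u.size)
    if direction == FORWARD:
        dg = -kt * log_mean
        ws = WorkSet(w_forward=w, w_reverse=np.empty(0), temperature=temperature)
        method = "jarzynski_forward"
        n_f, n_r = w.size, 0
    else:
        dg = kt * log_mean
        ws = WorkSet(w_forward=np.empty(0), w_reverse=w, temperature=temperature)
        method = "jarzynski_reverse"
        n_f, n_r = 0, w.size

    se = 0.0
    if n_boot > 0 and w.size > 1:
        if seed is None:
            raise ValueError("seed required for bootstrap")
        se = bootstrap_se(ws, method, n_boot=n_boot, seed=seed)
    return FreeEnergyEstimate(
        dg=float(dg), se=se, method=method,
        n_forward=int(n_f), n_reverse=int(n_r), temperature=temperature,
    )


def bar_reduced(u_forward: np.ndarray, u_reverse: np.ndarray) -> float:
    """Solve the BAR self-consistency equation in reduced units.

    Returns the root f of

        g(f) = Σ_i 1/(1+exp(M + u_i^F − f)) − Σ_j 1/(1+exp(−M + u_j^R + f))

    with M = ln(n_F/n_R); g is strictly monotone in f so the root is
    unique. Works follow the work-as-performed convention (reversible
    limit: u^F = ΔG/kT, u^R = −ΔG/kT).
    """
    uf = np.atleast_1d(np.asarray(u_forward, dtype=float))
    ur = np.atleast_1d(np.asarray(u_reverse, dtype=float))
    if uf.size == 0 or ur.size == 0:
        raise ValueError("bar requires both directions; use jarzynski for one-sided data")
    m = np.log(uf.size / ur.size)
    if uf.size == 1 and ur.size == 1:
        return float((uf[0] - ur[0]) / 2.0)

    def g(f: float) -> float:
        with np.errstate(over="ignore"):
            term_f = np.sum(1.0 / (1.0 + np.exp(np.clip(m + uf - f, -700, 700))))
            term_r = np.sum(1.0 / (1.0 + np.exp(np.clip(-m + ur + f, -700, 700))))
        return term_f - term_r

    span = max(np.max(np.abs(uf)), np.max(np.abs(ur))) + abs(m) + 10.0
    return float(brentq(g, -span, span, xtol=BAR_TOL))


def bar(
    ws: WorkSet,
    n_boot: int = 0,
    seed: int | None = None,
    with_convergence: bool = True,
) -> FreeEnergyEstimate:
    """Bi-directional maximum-likelihood (BAR) ΔG estimate for a work set.

    The standard error is filled by bootstrap when ``n_boot > 0`` (seed
    required); with a single sample per direction the closed form
    f = (u^F − u^R)/2 is used and se is reported as 0.
    """
    if ws.n_forward == 0 or ws.n_reverse == 0:
        raise ValueError("bar requires both directions; use jarzynski for one-sided data")
    f = bar_reduced(ws.u_forward, ws.u_reverse)
    dg = f * ws.kt
    se = 0.0
    if n_boot > 0 and (ws.n_forward > 1 or ws.n_reverse > 1):
        if seed is None:
            raise ValueError("seed required for bootstrap")
        se = bootstrap_se(ws, "bar", n_boot=n_boot, seed=seed)
    convergence = None
    if with_convergence:
        from .diagnostics import convergence_measure

        convergence = convergence_measure(ws, dg).measure
    return FreeEnergyEstimate(
        dg=float(dg), se=se, method="bar",
        n_forward=ws.n_forward, n_reverse=ws.n_reverse,
        temperature=ws.temperature, convergence=convergence,
    )


def _estimator_fn(name: str) -> Callable[[WorkSet], float]:
    if name == "bar":
        return lambda ws: bar_reduced(ws.u_forward, ws.u_reverse) * ws.kt
    if name == "jarzynski_forward":
        return lambda ws: jarzynski(ws.w_forward, FORWARD, ws.temperature).dg
    if name == "jarzynski_reverse":
        return lambda ws: jarzynski(ws.w_reverse, REVERSE, ws.temperature).dg
    raise ValueError(f"unknown estimator {name!r}")


def bootstrap_se(ws: WorkSet, estimator: str, n_boot: int = 1000, seed: int = 0) -> float:
    """Bootstrap standard error of an estimator over a work set (kJ/mol).

    Each direction is resampled with replacement independently, preserving
    sample sizes; the estimator is re-run and the sd (ddof=1) over
    replicates is returned. Replicate i draws from a fresh
    ``default_rng(seed + i)`` stream so results are reproducible and
    independent of replicate scheduling.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    fn = _estimator_fn(estimator)
    values = np.empty(n_boot)
    failures = 0
    for i in range(n_boot):
        rng = np.random.default_rng(seed + i)
        wf = ws.w_forward
        wr = ws.w_reverse
        if wf.size:
            wf = rng.choice(wf, size=wf.size, replace=True)
        if wr.size:
            wr = rng.choice(wr, size=wr.size, replace=True)
        try:
            values[i] = fn(WorkSet(w_forward=wf, w_reverse=wr, temperature=ws.temperature))
        except (ValueError, RuntimeError):
            values[i] = np.nan
            failures += 1
    if failures > 0.01 * n_boot:
        raise RuntimeError(f"estimator failed in {failures}/{n_boot} bootstrap replicates")
    return float(np.nanstd(values, ddof=1))


def zwanzig(du: Sequence[float] | np.ndarray, temperature: float) -> float:
    """Exponential-averaging (Zwanzig) ΔG for one window (kJ/mol).

    ΔG = −kT ln⟨exp(−ΔU/kT)⟩ over energy-difference samples ΔU (kJ/mol).
    """
    from .constants import kt_kj

    du = np.atleast_1d(np.asarray(du, dtype=float))
    if du.size == 0:
        raise ValueError("empty sample")
    kt = kt_kj(temperature)
    return float(-kt * (logsumexp(-du / kt) - np.log(du.size)))


def chain_windows(
    per_window: Sequence[WorkSet] | Sequence[np.ndarray],
    temperature: float | None = None,
    n_boot: int = 0,
    seed: int | None = None,
) -> FreeEnergyEstimate:
    """Chain per-window estimates into a total: ΔG = Σ ΔG_w, se in quadrature.

    Each window is either a :class:`WorkSet` (estimated by BAR; method tag
    ``bar_chain``) or an array of energy-difference samples ΔU in kJ/mol
    (estimated by exponential averaging; method tag ``zwanzig_chain``, needs
    ``temperature``).
    """
    if len(per_window) == 0:
        raise ValueError("at least one window required")
    dgs, ses = [], []
    n_f = n_r = 0
    is_workset = isinstance(per_window[0], WorkSet)
    method = "bar_chain" if is_workset else "zwanzig_chain"
    for idx, window in enumerate(per_window):
        try:
            if is_workset:
                if temperature is None:
                    temperature = window.temperature
                est = bar(window, n_boot=n_boot, seed=seed, with_convergence=False)
                dgs.append(est.dg)
                ses.append(est.se)
                n_f += est.n_forward
                n_r += est.n_reverse
            else:
                if temperature is None:
                    raise ValueError("temperature required for energy-difference windows")
                dgs.append(zwanzig(window, temperature))
                se_w = 0.0
                if n_boot > 0 and np.size(window) > 1:
                    if seed is None:
                        raise ValueError("seed required for bootstrap")
                    ws = WorkSet(w_forward=np.asarray(window, dtype=float),
                                 temperature=temperature)
                    se_w = bootstrap_se(ws, "jarzynski_forward", n_boot=n_boot, seed=seed)
                ses.append(se_w)
                n_f += int(np.size(window))
        except ValueError as exc:
            raise ValueError(f"window {idx} failed: {exc}") from exc
    return FreeEnergyEstimate(
        dg=float(np.sum(dgs)), se=float(np.sqrt(np.sum(np.square(ses)))),
        method=method, n_forward=n_f, n_reverse=n_r, temperature=float(temperature),
    )
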