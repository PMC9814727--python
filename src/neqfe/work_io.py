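"""Reading dH/dλ traces and assembling work sets.

A non-equilibrium alchemical transition is recorded as a time series of
∂H/∂λ. Integrating ∂H/∂λ over the λ schedule of the switch yields the work
performed on the system during that transition. Works are stored "as
performed in their own direction": for a reversible process the forward
(0→1) work equals ΔG and the reverse (1→0) work equals −ΔG.

Energies are kJ/mol throughout; times are ps; snapshot origin times are ns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import kt_kj

__all__ = [
    "DhdlTrace",
    "WorkSet",
    "parse_dhdl_xvg",
    "read_dhdl_xvg",
    "integrate_work",
    "truncate_workset",
    "read_works_csv",
    "write_works_csv",
]

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class DhdlTrace:
    """One transition's ∂H/∂λ time series.

    Parameters
    ----------
    times : ndarray
        Simulation times in ps, strictly increasing.
    dhdl : ndarray
        ∂H/∂λ in kJ/mol, same length as *times*.
    direction : {"forward", "reverse"}
        Forward drives λ 0→1; reverse drives λ 1→0.
    lam : ndarray, optional
        Explicit per-sample λ values. When absent a schedule is supplied
        at integration time.
    origin_time : float, optional
        Time (ns) of the equilibrium snapshot this transition started from.
    """

    times: np.ndarray
    dhdl: np.ndarray
    direction: str = FORWARD
    lam: np.ndarray | None = None
    origin_time: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        dhdl = np.asarray(self.dhdl, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "dhdl", dhdl)
        if times.ndim != 1 or dhdl.shape != times.shape:
            raise ValueError("times and dhdl must be 1-D arrays of equal length")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.direction not in (FORWARD, REVERSE):
            raise ValueError(f"direction must be 'forward' or 'reverse', got {self.direction!r}")
        if self.lam is not None:
            lam = np.asarray(self.lam, dtype=float)
            object.__setattr__(self, "lam", lam)
            if lam.shape != times.shape:
                raise ValueError("lam must match times in length")
            if lam.min() < -1e-12 or lam.max() > 1 + 1e-12:
                raise ValueError("lam endpoints must lie within [0, 1]")
            dlam = np.diff(lam)
            if self.direction == FORWARD and np.any(dlam < 0):
                raise ValueError("forward trace requires non-decreasing lam")
            if self.direction == REVERSE and np.any(dlam > 0):
                raise ValueError("reverse trace requires non-increasing lam")

    @property
    def n_samples(self) -> int:
        return int(self.times.size)

    @property
    def switching_time(self) -> float:
        """Transition time τ in ps (times[-1] − times[0])."""
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class WorkSet:
    """Forward and reverse work samples at a stated temperature.

    ``w_forward``/``w_reverse`` hold work values in kJ/mol in the
    work-as-performed convention. ``origin_forward``/``origin_reverse``
    optionally record the equilibrium snapshot time (ns) each transition
    started from.
    """

    w_forward: np.ndarray = field(default_factory=lambda: np.empty(0))
    w_reverse: np.ndarray = field(default_factory=lambda: np.empty(0))
    temperature: float = 298.15
    origin_forward: np.ndarray | None = None
    origin_reverse: np.ndarray | None = None

    def __post_init__(self) -> None:
        wf = np.atleast_1d(np.asarray(self.w_forward, dtype=float))
        wr = np.atleast_1d(np.asarray(self.w_reverse, dtype=float))
        object.__setattr__(self, "w_forward", wf)
        object.__setattr__(self, "w_reverse", wr)
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if wf.size == 0 and wr.size == 0:
            raise ValueError("at least one direction must be non-empty")
        if not (np.all(np.isfinite(wf)) and np.all(np.isfinite(wr))):
            raise ValueError("work values must be finite")
        for attr, w in (("origin_forward", wf), ("origin_reverse", wr)):
            origins = getattr(self, attr)
            if origins is not None:
                origins = np.atleast_1d(np.asarray(origins, dtype=float))
                object.__setattr__(self, attr, origins)
                if origins.shape != w.shape:
                    raise ValueError(f"{attr} must match work array length")

    @property
    def kt(self) -> float:
        """k_B*T in kJ/mol."""
        return kt_kj(self.temperature)

    @property
    def u_forward(self) -> np.ndarray:
        """Reduced forward works W/(k_B*T)."""
        return self.w_forward / self.kt

    @property
    def u_reverse(self) -> np.ndarray:
        """Reduced reverse works W/(k_B*T)."""
        return self.w_reverse / self.kt

    @property
    def n_forward(self) -> int:
        return int(self.w_forward.size)

    @property
    def n_reverse(self) -> int:
        return int(self.w_reverse.size)


def parse_dhdl_xvg(
    source: str | Iterable[str] | io.TextIOBase,
    direction: str = FORWARD,
    origin_time: float | None = None,
    value_columns: Sequence[int] = (1,),
) -> DhdlTrace:
    """Parse an XVG-dialect dH/dλ file into a :class:`DhdlTrace`.

    Lines starting with ``#`` or ``@`` are metadata and skipped. Data lines
    are whitespace-separated numbers: column 0 is time (ps) and, by default,
    column 1 is ∂H/∂λ (kJ/mol). ``value_columns`` selects which columns are
    summed into the ∂H/∂λ value (multi-component λ files).

    Duplicate time stamps are deduplicated keeping the last occurrence
    (restarted trajectories append corrected frames).
    """
    if isinstance(source, str):
        lines: Iterable[str] = io.StringIO(source)
    else:
        lines = source

    times: list[float] = []
    values: list[float] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("@"):
            continue
        tokens = line.split()
        try:
            t = float(tokens[0])
            v = sum(float(tokens[c]) for c in value_columns)
        except (ValueError, IndexError) as exc:
            raise ValueError(f"parse error at line {lineno}: {raw.rstrip()!r}") from exc
        times.append(t)
        values.append(v)

    if not times:
        raise ValueError("no samples")
    # keep last occurrence of duplicated time stamps, preserve time order
    t_arr = np.asarray(times)
    v_arr = np.asarray(values)
    order = np.argsort(t_arr, kind="stable")
    t_arr, v_arr = t_arr[order], v_arr[order]
    keep = np.ones(t_arr.size, dtype=bool)
    keep[:-1] = np.diff(t_arr) > 0
    t_arr, v_arr = t_arr[keep], v_arr[keep]
    if t_arr.size < 2:
        raise ValueError("insufficient samples")
    return DhdlTrace(times=t_arr, dhdl=v_arr, direction=direction, origin_time=origin_time)


def read_dhdl_xvg(path, **kwargs) -> DhdlTrace:
    """Read a dH/dλ XVG file from *path*. See :func:`parse_dhdl_xvg`."""
    with open(path) as fh:
        return parse_dhdl_xvg(fh, **kwargs)


def _linear_schedule(trace: DhdlTrace) -> np.ndarray:
    t0, t1 = trace.times[0], trace.times[-1]
    if t1 == t0:
        raise ValueError("degenerate schedule: t1 == t0")
    lam = (trace.times - t0) / (t1 - t0)
    if trace.direction == REVERSE:
        lam = 1.0 - lam
    return lam


def integrate_work(trace: DhdlTrace, schedule: str | Sequence[float] = "linear") -> float:
    """Integrate ∂H/∂λ over λ into the work of the transition (kJ/mol).

    ``schedule`` is either ``"linear"`` (λ linear in time over the trace,
    reversed for reverse transitions) or an explicit per-sample λ array.
    The work is the trapezoidal line integral along the λ path as actually
    traversed: forward transitions integrate 0→1, reverse transitions 1→0,
    so a reversible reverse transition yields −ΔG (work-as-performed
    convention used by the estimators).
    """
    if trace.n_samples < 2:
        raise ValueError("insufficient samples")
    if isinstance(schedule, str):
        if schedule != "linear":
            raise ValueError(f"unknown schedule {schedule!r}")
        lam = trace.lam if trace.lam is not None else _linear_schedule(trace)
    else:
        lam = np.asarray(schedule, dtype=float)
        if lam.shape != trace.times.shape:
            raise ValueError("explicit schedule must match trace length")
    dlam = np.diff(lam)
    if trace.direction == FORWARD and np.any(dlam < 0):
        raise ValueError("non-monotone λ schedule for forward transition")
    if trace.direction == REVERSE and np.any(dlam > 0):
        raise ValueError("non-monotone λ schedule for reverse transition")
    return float(np.trapezoid(trace.dhdl, lam))


def truncate_workset(ws: WorkSet, fraction: float) -> WorkSet:
    """Keep only transitions starting within the first *fraction* of sampling.

    Per direction independently, transitions with
    ``origin_time <= fraction * max(origin_time)`` survive. Models a shorter
    equilibrium simulation with the number of transitions reduced
    accordingly.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return ws

    def _cut(w: np.ndarray, origins: np.ndarray | None):
        if w.size == 0:
            return w, origins
        if origins is None:
            raise ValueError("origin times required for truncation")
        mask = origins <= fraction * origins.max()
        return w[mask], origins[mask]

    wf, of = _cut(ws.w_forward, ws.origin_forward)
    wr, orr = _cut(ws.w_reverse, ws.origin_reverse)
    if wf.size == 0 and wr.size == 0:
        raise ValueError("no transitions survive truncation")
    return WorkSet(
        w_forward=wf, w_reverse=wr, temperature=ws.temperature,
        origin_forward=of, origin_reverse=orr,
    )


def write_works_csv(ws: WorkSet, path_or_buf) -> None:
    """Write a work set as CSV with columns direction, origin_time_ns, work_kJmol."""
    rows = []
    for direction, w, origins in (
        (FORWARD, ws.w_forward, ws.origin_forward),
        (REVERSE, ws.w_reverse, ws.origin_reverse),
    ):
        for i, wi in enumerate(w):
            o = float(origins[i]) if origins is not None else np.nan
            rows.append((direction, o, float(wi)))
    df = pd.DataFrame(rows, columns=["direction", "origin_time_ns", "work_kJmol"])
    df.to_csv(path_or_buf, index=False)


def read_works_csv(path_or_buf, temperature: float = 298.15) -> WorkSet:
    """Read a works CSV (columns direction, origin_time_ns, work_kJmol)."""
    df = pd.read_csv(path_or_buf)
    required = {"direction", "work_kJmol"}
    if not required.issubset(df.columns):
        raise ValueError(f"works CSV must have columns {sorted(required)}")
    if df.empty:
        raise ValueError("no samples")
    out = {}
    for direction in (FORWARD, REVERSE):
        sub = df[df["direction"] == direction]
        out[direction] = (
            sub["work_kJmol"].to_numpy(dtype=float),
            sub["origin_time_ns"].to_numpy(dtype=float)
            if "origin_time_ns" in sub and sub["origin_time_ns"].notna().all() and len(sub)
            else None,
        )
    return WorkSet(
        w_forward=out[FORWARD][0],
        w_reverse=out[REVERSE][0],
        temperature=temperature,
        origin_forward=out[FORWARD][1],
        origin_reverse=out[REVERSE][1],
    )


def workset_from_traces(
    traces: Iterable[DhdlTrace],
    temperature: float,
    schedule: str | Sequence[float] = "linear",
) -> WorkSet:
    """Integrate a collection of traces into one :class:`WorkSet`."""
    wf, wr, of, orr = [], [], [], []
    any_origin_f = any_origin_r = True
    for tr in traces:
        w = integrate_work(tr, schedule)
        if tr.direction == FORWARD:
            wf.append(w)
            of.append(tr.origin_time)
            any_origin_f &= tr.origin_time is not None
        else:
            wr.append(w)
            orr.append(tr.origin_time)
            any_origin_r &= tr.origin_time is not None
    return WorkSet(
        w_forward=np.asarray(wf), w_reverse=np.asarray(wr), temperature=temperature,
        origin_forward=np.asarray(of, dtype=float) if wf and any_origin_f else None,
        origin_reverse=np.asarray(orr, dtype=float) if wr and any_origin_r else None,
    )
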