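"""Biolayer-interferometry binding kinetics: simulation and fitting.

The observable is the 1:1 Langmuir (single-site) model.  During
association at analyte concentration C,

    R(t) = Req * (1 - exp(-kobs * t)),   kobs = kon*C + koff,
    Req  = Rmax * C / (C + KD),          KD = koff / kon,

and during dissociation the response decays from the association end
value, R(t) = R(t_end) * exp(-koff * (t - t_end)); the dissociation
amplitude is tied to the association phase (curve continuity).

Two estimators are provided:

* a *global* fit sharing kon, koff and Rmax across a dilution series,
  fitted jointly over both phases by multistart nonlinear least squares
  (Langmuir fits are multimodal in poor data, hence the log-spaced grid);
* a *steady-state* fit of plateau responses Req(C) = Rmax*C/(C+KD),
  for analytes whose kinetics are too fast or too weak to fit — the
  equilibrium estimate is the mean of the final 10% of each association
  window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "KineticsParams",
    "BLITrace",
    "KineticsFit",
    "KineticsError",
    "IdentifiabilityError",
    "simulate_trace",
    "fit_langmuir_global",
    "fit_steady_state",
    "write_trace_csv",
    "read_trace_csv",
    "read_manifest",
]


class KineticsError(ValueError):
    pass


class IdentifiabilityError(KineticsError):
    """Too few distinct concentrations (or no signal) to constrain the fit."""


@dataclass(frozen=True)
class KineticsParams:
    kon: float   # 1/(M s)
    koff: float  # 1/s
    rmax: float  # response units (nm)

    def __post_init__(self) -> None:
        if not (self.kon > 0 and self.koff > 0 and self.rmax > 0):
            raise KineticsError(
                f"kon, koff, rmax must all be > 0 (got {self.kon}, {self.koff}, {self.rmax})"
            )

    @property
    def kd(self) -> float:
        return self.koff / self.kon


@dataclass
class BLITrace:
    concentration: float  # M
    times: np.ndarray     # s, strictly increasing
    responses: np.ndarray # nm
    t_assoc_end: float    # s, association/dissociation boundary

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.responses = np.asarray(self.responses, float)
        if self.times.shape != self.responses.shape:
            raise KineticsError("times and responses differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise KineticsError("times must be strictly increasing")
        if not (self.times[0] <= self.t_assoc_end <= self.times[-1]):
            raise KineticsError("t_assoc_end outside the time range")


@dataclass
class KineticsFit:
    model: str  # langmuir_global | steady_state
    params: KineticsParams | None
    kd: float
    rmax: float
    per_trace_rss: list[float]
    converged: bool
    n_traces: int
    non_saturating: bool = False
    details: dict = field(default_factory=dict)


def model_response(
    params: KineticsParams, concentration: float, times: np.ndarray, t_assoc_end: float
) -> np.ndarray:
    """Noise-free two-phase 1:1 model evaluated at ``times``."""
    c = concentration
    kobs = params.kon * c + params.koff
    req = params.rmax * c / (c + params.kd)
    t = np.asarray(times, float)
    r = np.empty_like(t)
    assoc = t <= t_assoc_end
    r[assoc] = req * (1.0 - np.exp(-kobs * t[assoc]))
    r_end = req * (1.0 - math.exp(-min(kobs * t_assoc_end, 700.0)))
    r[~assoc] = r_end * np.exp(-params.koff * (t[~assoc] - t_assoc_end))
    return r


def simulate_trace(
    params: KineticsParams,
    concentration: float,
    t_assoc: float = 300.0,
    t_dissoc: float = 600.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 1,
) -> BLITrace:
    """Simulate a two-phase sensorgram with optional Gaussian noise.

    ``noise_sd = 0`` returns the exact model curve; defaults mirror a
    300 s association / 600 s dissociation assay design.
    """
    if concentration <= 0 or t_assoc <= 0 or t_dissoc <= 0 or dt <= 0:
        raise KineticsError("concentration, phase durations and dt must be > 0")
    if dt >= min(t_assoc, t_dissoc):
        raise KineticsError("dt must be smaller than both phase durations")
    times = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    r = model_response(params, concentration, times, t_assoc)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    return BLITrace(concentration=concentration, times=times, responses=r, t_assoc_end=t_assoc)


def _residuals(log_params: np.ndarray, traces: list[BLITrace]) -> np.ndarray:
    lp = np.clip(log_params, -12.0, 12.0)  # keep LM line searches finite
    p = KineticsParams(kon=10.0 ** lp[0], koff=10.0 ** lp[1], rmax=10.0 ** lp[2])
    out = [
        tr.responses - model_response(p, tr.concentration, tr.times, tr.t_assoc_end)
        for tr in traces
    ]
    return np.concatenate(out)


def _check_traces(traces: list[BLITrace]) -> None:
    if len({tr.concentration for tr in traces}) < 2:
        raise IdentifiabilityError(
            "global 1:1 fit needs >= 2 traces at distinct concentrations"
        )
    peak = max(float(np.max(np.abs(tr.responses))) for tr in traces)
    if peak <= 0 or all(float(np.std(tr.responses)) < 1e-12 for tr in traces):
        raise IdentifiabilityError("all traces are flat: no binding signal to fit")


def fit_langmuir_global(
    traces: list[BLITrace],
    kon_range: tuple[float, float] = (1e3, 1e7),
    koff_range: tuple[float, float] = (1e-5, 1e-1),
    n_starts: int = 5,
    seed: int = 1,
) -> KineticsFit:
    """Global 1:1 fit of kon, koff, Rmax shared across a dilution series.

    Multistart over an ``n_starts`` x ``n_starts`` log-spaced (kon, koff)
    grid; the lowest-RSS solution wins, ties broken toward the smallest
    kon.  Deterministic for fixed inputs (the grid has no jitter; ``seed``
    is accepted for interface symmetry with the simulators).
    """
    _check_traces(traces)
    rmax0 = max(float(np.max(tr.responses)) for tr in traces)
    rmax0 = max(rmax0, 1e-6)
    kons = np.logspace(np.log10(kon_range[0]), np.log10(kon_range[1]), n_starts)
    koffs = np.logspace(np.log10(koff_range[0]), np.log10(koff_range[1]), n_starts)

    candidates = []  # (rss, kon, result)
    for kon0 in kons:
        for koff0 in koffs:
            x0 = np.log10([kon0, koff0, rmax0])
            try:
                res = least_squares(
                    _residuals, x0, args=(traces,), method="lm", xtol=1e-12, ftol=1e-12
                )
            except Exception:
                continue
            res.x = np.clip(res.x, -12.0, 12.0)  # match the residual clamp
            candidates.append((float(np.sum(res.fun**2)), 10.0 ** res.x[0], res))
    if not candidates:
        raise KineticsError("all multistart fits failed")
    # lowest RSS wins; numerically tied starts resolve to the smallest kon
    best_rss = min(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] <= best_rss * (1 + 1e-9) + 1e-300]
    rss_best, _, res = min(tied, key=lambda c: c[1])
    p = KineticsParams(kon=10.0 ** res.x[0], koff=10.0 ** res.x[1], rmax=10.0 ** res.x[2])
    per_rss = [
        float(np.sum((tr.responses - model_response(p, tr.concentration, tr.times, tr.t_assoc_end)) ** 2))
        for tr in traces
    ]
    return KineticsFit(
        model="langmuir_global",
        params=p,
        kd=p.kd,
        rmax=p.rmax,
        per_trace_rss=per_rss,
        converged=bool(res.success),
        n_traces=len(traces),
        details={"total_rss": rss_best, "n_starts": n_starts**2},
    )


def equilibrium_estimates(traces: list[BLITrace], tail_fraction: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Per-trace plateau estimate: mean response over the final ``tail_fraction``
    of the association window."""
    conc, req = [], []
    for tr in traces:
        assoc = tr.times <= tr.t_assoc_end
        t_assoc = tr.times[assoc]
        window = t_assoc >= tr.t_assoc_end * (1.0 - tail_fraction)
        conc.append(tr.concentration)
        req.append(float(np.mean(tr.responses[assoc][window])))
    order = np.argsort(conc)
    return np.asarray(conc)[order], np.asarray(req)[order]


def fit_steady_state(traces: list[BLITrace], tail_fraction: float = 0.1) -> KineticsFit:
    """Fit Req(C) = Rmax*C/(C+KD) to per-trace equilibrium plateaus.

    kon/koff are undefined for this model.  When the fitted KD exceeds the
    highest analyte concentration the series does not saturate and the fit
    is flagged ``non_saturating`` (wide-confidence warning, not an error).
    """
    if len({tr.concentration for tr in traces}) < 3:
        raise IdentifiabilityError("steady-state fit needs >= 3 distinct concentrations")
    conc, req = equilibrium_estimates(traces, tail_fraction)
    if np.max(np.abs(req)) <= 0:
        raise IdentifiabilityError("all plateau responses are zero")

    def resid(x: np.ndarray) -> np.ndarray:
        kd, rmax = 10.0 ** x[0], 10.0 ** x[1]
        return req - rmax * conc / (conc + kd)

    best = None
    for kd0 in np.logspace(np.log10(conc.min() / 10), np.log10(conc.max() * 100), 7):
        x0 = np.log10([kd0, max(req.max(), 1e-9)])
        res = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14)
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res)
    res = best[1]
    kd, rmax = 10.0 ** res.x[0], 10.0 ** res.x[1]
    rss = float(np.sum(res.fun**2))
    return KineticsFit(
        model="steady_state",
        params=None,
        kd=float(kd),
        rmax=float(rmax),
        per_trace_rss=[rss],
        converged=bool(res.success),
        n_traces=len(traces),
        non_saturating=bool(kd > conc.max()),
        details={"concentrations_M": conc.tolist(), "req_nm": req.tolist()},
    )


# ----------------------------------------------------------------------------
# trace CSV I/O (one file per well + a manifest)


def write_trace_csv(trace: BLITrace, path: str) -> None:
    pd.DataFrame({"time_s": trace.times, "response_nm": trace.responses}).to_csv(
        path, index=False, float_format="%.6g"
    )


def read_trace_csv(path: str, concentration: float, t_assoc_end: float) -> BLITrace:
    df = pd.read_csv(path)
    return BLITrace(
        concentration=concentration,
        times=df["time_s"].to_numpy(float),
        responses=df["response_nm"].to_numpy(float),
        t_assoc_end=t_assoc_end,
    )


def read_manifest(manifest_path: str) -> list[BLITrace]:
    """Manifest CSV columns: file, concentration_M, t_assoc_end_s (paths
    relative to the manifest's directory)."""
    mdir = Path(manifest_path).parent
    df = pd.read_csv(manifest_path)
    return [
        read_trace_csv(mdir / row.file, float(row.concentration_M), float(row.t_assoc_end_s))
        for row in df.itertuples(index=False)
    ]
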