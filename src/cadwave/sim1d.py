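"""1D frequency-gradient segmentation-clock simulator.

A row of independent phase oscillators spans the AP axis.  Each cell's phase
velocity is proportional to the local gradient level, saturating at the
reference frequency ``omega_ref`` (one cycle per ~3 h at full posterior
level).  Because posterior cells run faster, iso-phase contours sweep from
posterior to anterior as kinematic waves — no signalling between cells is
involved — and binarising the phase yields travelling, shrinking expression
stripes like those of *Tc-eve*.

Expression is read out as high during the first half of each cycle, and only
inside the oscillating domain: a cell that has never experienced a non-zero
frequency shows no expression (a zero gradient abolishes expression rather
than freezing it on).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gradient import GradientDescriptors, TemporalGradient

__all__ = [
    "SimConfig1D",
    "SpaceTimePattern",
    "Stripe",
    "StageClass",
    "simulate_1d",
    "analytic_phase",
    "detect_stripes",
    "posterior_cycle_durations",
    "classify_stage",
    "roman",
]

#: minimum run length (cells) for a run of high expression to count as a stripe
MIN_STRIPE_CELLS = 2


@dataclass(frozen=True)
class SimConfig1D:
    """Configuration of the 1D oscillator array.

    ``omega_ref`` is the saturated clock frequency in cycles per hour
    (default 1/3, i.e. a 3-hour period); ``g_ref`` is the gradient level at
    which the frequency saturates.  Cells sit at ``x_i = (i + 0.5) / n_cells``.
    """

    n_cells: int = 200
    dt: float = 0.01
    t_start: float = 13.5
    t_end: float = 23.0
    omega_ref: float = 1.0 / 3.0
    g_ref: float = 1.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.omega_ref <= 0 or self.g_ref <= 0:
            raise ValueError("omega_ref and g_ref must be > 0")
        if self.n_cells < 2:
            raise ValueError("need at least 2 cells")

    @property
    def x(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) / self.n_cells

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.dt))
        return self.t_start + np.arange(n + 1) * self.dt


@dataclass(frozen=True)
class SpaceTimePattern:
    """Unwrapped phases and binary expression of the array over time.

    ``phi`` has shape (n_times, n_cells), is >= 0 and non-decreasing in time
    at every cell; ``expr`` is the binarised, domain-gated readout.
    """

    times: np.ndarray
    x: np.ndarray
    phi: np.ndarray
    expr: np.ndarray
    config: SimConfig1D

    @property
    def posterior_phase(self) -> np.ndarray:
        """Unwrapped phase trace of the posterior-most cell."""
        return self.phi[:, -1]

    def frame_at(self, t: float) -> int:
        """Index of the stored frame closest to time ``t``."""
        t0, t1 = self.times[0], self.times[-1]
        if not (t0 - 1e-9 <= t <= t1 + 1e-9):
            raise ValueError(f"t={t} outside simulated range [{t0}, {t1}]")
        return int(np.argmin(np.abs(self.times - t)))


def simulate_1d(cfg: SimConfig1D, tg: TemporalGradient) -> SpaceTimePattern:
    """Integrate the phase of every cell under the given gradient.

    The frequency field is ``omega_ref * min(level, g_ref) / g_ref``.  Since
    the phase velocity does not depend on the phase, time stepping is a pure
    cumulative quadrature; the per-step frequency is evaluated at the step
    midpoint (exact for frequencies constant within a step, second-order
    accurate otherwise).  Fully deterministic.
    """
    x = cfg.x
    times = cfg.times
    mid = times[:-1] + 0.5 * cfg.dt
    level_mid = tg.level(x[None, :], mid[:, None])
    omega = cfg.omega_ref * np.minimum(level_mid, cfg.g_ref) / cfg.g_ref
    phi = np.vstack([np.zeros(cfg.n_cells), np.cumsum(omega * cfg.dt, axis=0)])
    # oscillating domain: cells whose frequency has been positive at least once
    active = np.vstack([np.zeros(cfg.n_cells, dtype=bool),
                        np.logical_or.accumulate(omega > 0.0, axis=0)])
    expr = ((np.mod(phi, 1.0) < 0.5) & active).astype(np.uint8)
    return SpaceTimePattern(times=times, x=x, phi=phi, expr=expr, config=cfg)


def analytic_phase(d: GradientDescriptors, cfg: SimConfig1D, x, t):
    """Closed-form phase for a static gradient: ``omega(x) * (t - t_start)``.

    Serves as the independent oracle for the simulator in the static case.
    Raises if handed a time-varying gradient.
    """
    if isinstance(d, TemporalGradient):
        if not d.is_static:
            raise ValueError("analytic_phase requires a static gradient")
        d = d.steady
    level = d.profile(x)
    omega = cfg.omega_ref * np.minimum(level, cfg.g_ref) / cfg.g_ref
    return omega * (np.asarray(t, dtype=float) - cfg.t_start)


@dataclass(frozen=True)
class Stripe:
    """One expression stripe delimited by cell-edge positions (AP fractions)."""

    anterior: float
    posterior: float
    complete: bool

    def __post_init__(self):
        if not self.anterior < self.posterior:
            raise ValueError("anterior border must lie anterior of posterior border")

    @property
    def width(self) -> float:
        return self.posterior - self.anterior


def detect_stripes(expr_row, min_width: int = MIN_STRIPE_CELLS):
    """Extract stripes from one binary expression row.

    Returns ``(stripes, domain_anterior_border)``.  Stripes are maximal runs
    of high expression of at least ``min_width`` cells, ordered anterior to
    posterior, with borders at cell edges (run of cells i..j spans
    ``i/n`` to ``(j+1)/n``).  The posterior-most run is flagged incomplete
    while it still touches the oscillating posterior end (its posterior border
    has not yet formed).  The domain anterior border is the anterior edge of
    the anterior-most stripe; with no stripes the list is empty and the border
    is ``None`` (the stripe has not formed yet).
    """
    row = np.asarray(expr_row).astype(bool)
    n = len(row)
    edges = np.diff(np.concatenate([[0], row.astype(np.int8), [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)  # exclusive
    stripes = []
    for s, e in zip(starts, ends):
        if e - s < min_width:
            continue
        touches_posterior = e == n and row[-1]
        stripes.append(Stripe(anterior=s / n, posterior=e / n,
                              complete=not touches_posterior))
    if not stripes:
        return [], None
    return stripes, stripes[0].anterior


def posterior_cycle_durations(pattern: SpaceTimePattern) -> list[float]:
    """Durations of completed oscillation cycles at the posterior cell.

    Cycle ``k`` runs from the time the unwrapped posterior phase reaches
    ``k - 1`` to the time it reaches ``k``; cycle 1 starts at ``t_start``.
    Crossing times are linearly interpolated on the stored grid.  Returns an
    empty list if not even one cycle completes.
    """
    phi = pattern.posterior_phase
    times = pattern.times
    n_complete = int(np.floor(phi[-1] + 1e-12))
    if n_complete < 1:
        return []
    targets = np.arange(1, n_complete + 1, dtype=float)
    crossings = np.interp(targets, phi, times)
    boundaries = np.concatenate([[times[0]], crossings])
    return list(np.diff(boundaries))


@dataclass(frozen=True)
class StageClass:
    """Posterior oscillation stage: cycle number and high(1)/low(0) phase."""

    cycle: int
    phase: int

    def __post_init__(self):
        if self.cycle < 1:
            raise ValueError("cycle must be a positive integer")
        if self.phase not in (0, 1):
            raise ValueError("phase must be 0 or 1")

    @property
    def label(self) -> str:
        """Staging label, e.g. ``'II.1'`` for the high phase of cycle 2."""
        return f"{roman(self.cycle)}.{self.phase}"


_ROMAN = (
    (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
)


def roman(n: int) -> str:
    """Roman numeral for a small positive integer."""
    if n < 1:
        raise ValueError("roman numerals start at 1")
    out = []
    for value, sym in ((1000, "M"), (900, "CM"), (500, "D"), (400, "CD"),
                       (100, "C"), (90, "XC"), (50, "L"), (40, "XL")) + _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


def classify_stage(pattern: SpaceTimePattern, t: float) -> StageClass:
    """Stage of the embryo at time ``t`` from the posterior phase.

    ``cycle = floor(phi) + 1`` and ``phase = 1`` during the first half of the
    cycle, rendered as e.g. ``'I.1'`` for the high phase of the first cycle.
    """
    t0, t1 = pattern.times[0], pattern.times[-1]
    if not (t0 - 1e-9 <= t <= t1 + 1e-9):
        raise ValueError(f"t={t} outside simulated range [{t0}, {t1}]")
    phi = float(np.interp(t, pattern.times, pattern.posterior_phase))
    return StageClass(cycle=int(np.floor(phi)) + 1, phase=1 if (phi % 1.0) < 0.5 else 0)
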