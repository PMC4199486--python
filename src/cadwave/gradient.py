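"""Parametric model of the posterior *Tc-cad* expression gradient.

The blastoderm expression of *caudal* in *Tribolium* is well approximated by a
posterior-to-anterior gradient that is zero anteriorly, rises linearly from an
anterior border and saturates in a posterior plateau.  Three descriptors
summarise it: the plateau level, the anterior border position and the ramp
slope.  On top of the static shape, the gradient builds up exponentially in
time early in the blastoderm and retracts toward the posterior late, which is
what turns a clock modulated by it into travelling, eventually frozen, stripes.

Positions are anterior-posterior (AP) axis fractions in [0, 1] with 0 at the
anterior pole; intensities are arbitrary units; times are hours after egg lay
(AEL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GradientDescriptors",
    "TemporalGradient",
    "CONDITIONS",
    "condition_preset",
    "evaluate_profile",
    "temporal_level",
]

#: Closed set of modelled genotypes: wild type plus the RNAi knockdowns of
#: *Tc-cad* regulators characterised in the study.
CONDITIONS = ("WT", "cad_mild", "lgs", "pan", "apc1", "zen1", "lgs_zen1")


def _check_x(x):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError("AP position x must lie in [0, 1] (axis fraction)")
    return x


@dataclass(frozen=True)
class GradientDescriptors:
    """The three descriptors of a linear-with-plateau gradient.

    Parameters
    ----------
    plateau : float
        Maximum posterior intensity (a.u., >= 0).
    border : float
        Anterior border of expression, as AP axis fraction in [0, 1].
    slope : float
        Ramp slope in intensity per unit axis fraction (> 0).

    The ramp must reach the plateau within the axis:
    ``border + plateau / slope <= 1``.
    """

    plateau: float
    border: float
    slope: float

    def __post_init__(self):
        if not self.plateau >= 0.0:
            raise ValueError(f"plateau must be >= 0, got {self.plateau}")
        if not 0.0 <= self.border <= 1.0:
            raise ValueError(f"border must be in [0, 1], got {self.border}")
        if not self.slope > 0.0:
            raise ValueError(f"slope must be > 0, got {self.slope}")
        if self.border + self.plateau / self.slope > 1.0 + 1e-9:
            raise ValueError(
                "ramp does not reach the plateau within the axis: "
                f"border + plateau/slope = {self.border + self.plateau / self.slope:.4f} > 1"
            )

    @property
    def plateau_start(self) -> float:
        """AP position where the ramp meets the plateau."""
        return self.border + self.plateau / self.slope

    def profile(self, x):
        """Intensity at AP fraction ``x`` (scalar or array)."""
        x = _check_x(x)
        return np.clip(self.slope * (x - self.border), 0.0, self.plateau)

    def to_dict(self) -> dict:
        return {"plateau": self.plateau, "border": self.border, "slope": self.slope}

    @classmethod
    def from_dict(cls, d: dict) -> "GradientDescriptors":
        return cls(plateau=float(d["plateau"]), border=float(d["border"]), slope=float(d["slope"]))


def evaluate_profile(d: GradientDescriptors, x):
    """Linear-with-plateau intensity at AP fraction ``x``.

    Zero anterior of the border, ``slope * (x - border)`` on the ramp, and
    ``plateau`` posterior of where the ramp saturates.  Continuous and
    non-decreasing in ``x``.
    """
    return d.profile(x)


@dataclass(frozen=True)
class TemporalGradient:
    """A linear-with-plateau gradient with buildup and posterior retraction.

    The steady spatial shape is scaled by an exponential buildup factor
    ``B(t) = 1 - exp(-(t - t_on)/tau)`` for ``t > t_on`` (0 before onset;
    identically 1 when ``tau == 0``).  From ``retraction_onset`` the anterior
    border shifts toward the posterior at ``retraction_speed`` axis fractions
    per hour with plateau and slope unchanged (the border is clamped at 1).

    Buildup is multiplicative and spatially uniform: the measured plateau and
    slope grow together over 14-16 h AEL while the border stays put, which is
    exactly what a uniform scaling of a fixed shape produces.
    """

    steady: GradientDescriptors
    t_on: float = 13.5
    tau: float = 0.5
    retraction_onset: float = math.inf
    retraction_speed: float = 0.0

    def __post_init__(self):
        if self.tau < 0.0:
            raise ValueError("tau must be >= 0 (0 = instantaneous buildup)")
        if self.retraction_speed < 0.0:
            raise ValueError("retraction_speed must be >= 0")

    def buildup(self, t):
        """Buildup factor B(t) in [0, 1]."""
        t = np.asarray(t, dtype=float)
        if self.tau == 0.0:
            return np.ones_like(t)
        return np.where(t > self.t_on, -np.expm1(-(t - self.t_on) / self.tau), 0.0)

    def border_at(self, t):
        """Anterior border position at time ``t`` (clamped at 1)."""
        t = np.asarray(t, dtype=float)
        shift = self.retraction_speed * np.maximum(0.0, t - self.retraction_onset)
        return np.minimum(self.steady.border + shift, 1.0)

    def level(self, x, t):
        """Gradient intensity at AP fraction ``x`` and time ``t``.

        ``x`` and ``t`` broadcast against each other, so a full space-time
        field is obtained with ``level(x[None, :], t[:, None])``.
        """
        x = _check_x(x)
        b = self.border_at(t)
        ramp = np.clip(self.steady.slope * (x - b), 0.0, self.steady.plateau)
        return self.buildup(t) * ramp

    @property
    def is_static(self) -> bool:
        """True when the profile never changes shape or amplitude."""
        return self.tau == 0.0 and (
            self.retraction_speed == 0.0 or math.isinf(self.retraction_onset)
        )

    def to_dict(self) -> dict:
        return {
            "steady": self.steady.to_dict(),
            "t_on": self.t_on,
            "tau": self.tau,
            "retraction_onset": self.retraction_onset,
            "retraction_speed": self.retraction_speed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TemporalGradient":
        return cls(
            steady=GradientDescriptors.from_dict(d["steady"]),
            t_on=float(d.get("t_on", 13.5)),
            tau=float(d.get("tau", 0.5)),
            retraction_onset=float(d.get("retraction_onset", math.inf)),
            retraction_speed=float(d.get("retraction_speed", 0.0)),
        )

    def with_overrides(self, **kwargs) -> "TemporalGradient":
        """Return a copy with descriptor or timing fields replaced.

        Descriptor fields (``plateau``, ``border``, ``slope``) address the
        steady shape; the rest address the temporal parameters.
        """
        desc_keys = {k: kwargs.pop(k) for k in ("plateau", "border", "slope") if k in kwargs}
        steady = replace(self.steady, **desc_keys) if desc_keys else self.steady
        return replace(self, steady=steady, **kwargs)


def temporal_level(tg: TemporalGradient, x, t):
    """Gradient intensity of ``tg`` at AP fraction ``x`` and time ``t`` (h AEL)."""
    return tg.level(x, t)


# Phenomenological presets for each genotype.  The absolute numbers are free
# choices (the study reports only WT-normalised ratios); what matters, and what
# the tests pin down, are the orderings relative to WT:
#   lgs / cad_mild : border more posterior, plateau lower, slope slightly lower
#   pan            : border more anterior, plateau lower, slope much lower
#   apc1           : border more anterior, plateau/slope as WT, slower buildup
#   zen1           : border more anterior, everything else as WT
#   lgs_zen1       : border between WT and lgs, plateau between lgs and WT,
#                    slope as lgs, buildup as WT
_WT_TIMING = dict(t_on=13.5, tau=0.5, retraction_onset=20.0, retraction_speed=0.05)

_PRESETS: dict[str, TemporalGradient] = {
    "WT": TemporalGradient(GradientDescriptors(1.0, 0.40, 2.5), **_WT_TIMING),
    "cad_mild": TemporalGradient(GradientDescriptors(0.65, 0.48, 2.3), **_WT_TIMING),
    "lgs": TemporalGradient(GradientDescriptors(0.70, 0.50, 2.25), **_WT_TIMING),
    "pan": TemporalGradient(GradientDescriptors(0.65, 0.30, 1.0), **_WT_TIMING),
    "apc1": TemporalGradient(
        GradientDescriptors(1.0, 0.32, 2.5), **{**_WT_TIMING, "tau": 1.5}
    ),
    "zen1": TemporalGradient(GradientDescriptors(1.0, 0.32, 2.5), **_WT_TIMING),
    "lgs_zen1": TemporalGradient(GradientDescriptors(0.85, 0.45, 2.25), **_WT_TIMING),
}


def condition_preset(name: str) -> TemporalGradient:
    """Gradient preset for a genotype.

    Parameters
    ----------
    name : str
        One of ``CONDITIONS``.

    Raises
    ------
    KeyError
        For unknown names, listing the valid ones.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown condition {name!r}; valid conditions: {', '.join(CONDITIONS)}"
        ) from None
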