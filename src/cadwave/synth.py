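"""Synthetic-data generator emulating the study's measured inputs.

Two kinds of raw data feed the analysis stages and both are emulated here so
every stage is testable end-to-end without any downloads:

* per-embryo AP intensity profiles — a linear-with-plateau truth curve
  sampled at equally spaced positions along an embryo-specific axis length,
  corrupted by multiplicative and additive Gaussian measurement noise plus a
  constant staining background;
* staged cohorts from timed egg collections — embryo ages drawn uniformly
  within each collection window and mapped to cycle classes by the true
  boundary times.

Everything is reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gradient import GradientDescriptors
from .timing import CohortCounts

__all__ = [
    "ProfileNoiseModel",
    "CohortSpec",
    "synth_profiles",
    "profiles_to_long",
    "synth_cohort",
]


@dataclass(frozen=True)
class ProfileNoiseModel:
    """Measurement-noise model for synthetic intensity profiles.

    ``mult_sd`` scales the signal multiplicatively (stain intensity varies
    between and within embryos), ``add_sd`` is additive sensor noise,
    ``background`` a constant offset, ``length_cv`` the coefficient of
    variation of the lognormally distributed AP axis length, and
    ``n_samples`` the number of equally spaced positions per embryo.
    """

    mult_sd: float = 0.1
    add_sd: float = 0.02
    background: float = 0.05
    length_cv: float = 0.05
    n_samples: int = 50
    base_length: float = 100.0

    def __post_init__(self):
        if min(self.mult_sd, self.add_sd, self.background, self.length_cv) < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if self.base_length <= 0:
            raise ValueError("base_length must be > 0")


def synth_profiles(truth: GradientDescriptors, noise: ProfileNoiseModel,
                   n_embryos: int, seed=None) -> list[pd.DataFrame]:
    """Generate raw (native-unit) profile tables for ``n_embryos`` embryos.

    Each table has columns ``position`` (native units in [0, axis_length])
    and ``intensity``, with ``axis_length``, ``embryo_id`` and the generating
    fractional positions stored in ``DataFrame.attrs``.  Intensity is
    ``truth(x) * (1 + eps_mult) + eps_add + background`` clipped at zero.
    """
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    rng = np.random.default_rng(seed)
    if noise.length_cv > 0:
        sigma = np.sqrt(np.log1p(noise.length_cv**2))
        mu = np.log(noise.base_length) - sigma**2 / 2
        lengths = rng.lognormal(mu, sigma, size=n_embryos)
    else:
        lengths = np.full(n_embryos, noise.base_length)
    tables = []
    frac = np.linspace(0.0, 1.0, noise.n_samples)
    for i in range(n_embryos):
        signal = truth.profile(frac)
        eps_mult = rng.normal(0.0, noise.mult_sd, size=noise.n_samples) if noise.mult_sd else 0.0
        eps_add = rng.normal(0.0, noise.add_sd, size=noise.n_samples) if noise.add_sd else 0.0
        intensity = np.maximum(signal * (1.0 + eps_mult) + eps_add + noise.background, 0.0)
        df = pd.DataFrame({"position": frac * lengths[i], "intensity": intensity})
        df.attrs["axis_length"] = float(lengths[i])
        df.attrs["embryo_id"] = f"e{i:04d}"
        df.attrs["x"] = frac
        tables.append(df)
    return tables


def profiles_to_long(tables: list[pd.DataFrame], condition: str = "WT") -> pd.DataFrame:
    """Stack raw profile tables into the long CSV dialect the readers accept."""
    rows = []
    for df in tables:
        rows.append(pd.DataFrame({
            "embryo_id": df.attrs["embryo_id"],
            "condition": condition,
            "position": df["position"],
            "intensity": df["intensity"],
            "axis_length": df.attrs["axis_length"],
        }))
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic staged cohort.

    ``true_boundaries`` are the cycle start/end times (hours AEL; cycle k
    spans ``[s_k, s_{k+1})``); ``windows`` the timed collection windows;
    ``n_per_window`` embryos are sampled per window.
    """

    true_boundaries: tuple
    windows: tuple
    n_per_window: int
    seed: int = 0

    def __post_init__(self):
        bounds = tuple(float(b) for b in self.true_boundaries)
        windows = tuple((float(a), float(b)) for a, b in self.windows)
        object.__setattr__(self, "true_boundaries", bounds)
        object.__setattr__(self, "windows", windows)
        if len(bounds) < 2 or np.any(np.diff(bounds) <= 0):
            raise ValueError("true_boundaries must be >= 2 strictly increasing times")
        if self.n_per_window < 1:
            raise ValueError("n_per_window must be >= 1")


def synth_cohort(spec: CohortSpec) -> CohortCounts:
    """Sample a staged cohort and tabulate class counts per window.

    Ages are uniform within each window; an age in ``[s_k, s_{k+1})`` shows
    cycle class ``k+1``, ages before the first boundary class 0 ("no stripe
    yet") and ages past the last boundary the next class up.  A window lying
    entirely outside the boundary span is rejected (all its embryos would be
    out of range).
    """
    bounds = np.asarray(spec.true_boundaries)
    lo, hi = bounds[0], bounds[-1]
    for a, b in spec.windows:
        if b <= lo or a >= hi:
            raise ValueError(
                f"window ({a:g}-{b:g}) lies entirely outside the cycle span "
                f"[{lo:g}, {hi:g}]: all embryos out of range"
            )
    rng = np.random.default_rng(spec.seed)
    per_window = []
    for a, b in spec.windows:
        ages = rng.uniform(a, b, size=spec.n_per_window)
        per_window.append(np.searchsorted(bounds, ages, side="right"))
    all_classes = sorted(set(np.concatenate(per_window).tolist()))
    counts = np.zeros((len(spec.windows), len(all_classes)), dtype=int)
    cidx = {c: j for j, c in enumerate(all_classes)}
    for w, labels in enumerate(per_window):
        for c, n in zip(*np.unique(labels, return_counts=True)):
            counts[w, cidx[int(c)]] = int(n)
    return CohortCounts(windows=spec.windows, classes=tuple(all_classes), counts=counts)
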