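"""Quantification of measured AP intensity profiles.

Fits per-embryo intensity profiles to the linear-with-plateau gradient model,
and compares the three fitted descriptors (plateau, anterior border, slope)
across conditions with bootstrap confidence intervals and permutation tests.

The fit is organised statsmodels-style: build a :class:`LinearPlateauModel`
from one profile, call :meth:`~LinearPlateauModel.fit` and read the estimates
off the returned :class:`LinearPlateauResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .gradient import GradientDescriptors

__all__ = [
    "IntensityProfile",
    "normalize_profile",
    "LinearPlateauModel",
    "LinearPlateauResults",
    "fit_linear_plateau",
    "DescriptorStats",
    "bootstrap_descriptor_stats",
    "normalize_to_reference",
    "compare_conditions",
    "DESCRIPTOR_NAMES",
]

DESCRIPTOR_NAMES = ("plateau", "border", "slope")


@dataclass(frozen=True)
class IntensityProfile:
    """One embryo's background-subtracted AP intensity profile.

    ``x`` are AP axis fractions in [0, 1], strictly increasing, at least 10 of
    them; ``intensity`` are non-negative arbitrary units.
    """

    x: np.ndarray
    intensity: np.ndarray
    embryo_id: str = ""
    ap_length: float | None = None

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        I = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "intensity", I)
        if x.shape != I.shape or x.ndim != 1:
            raise ValueError("x and intensity must be 1-D arrays of equal length")
        if len(x) < 10:
            raise ValueError(f"profile needs at least 10 samples, got {len(x)}")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        if x[0] < 0 or x[-1] > 1:
            raise ValueError("x must lie in [0, 1]")
        if np.any(I < 0):
            raise ValueError("intensity must be >= 0 (background-subtracted)")


def normalize_profile(raw_x, raw_intensity, axis_length, background=0.0,
                      embryo_id: str = "") -> IntensityProfile:
    """Convert native-unit measurements to an axis-normalised profile.

    Positions are divided by the embryo's AP axis length; the scalar
    background is subtracted with a floor at zero.  Pass ``background="auto"``
    to estimate it as the 5th percentile of the raw intensities.  Raises if
    the axis length is not positive or if no intensity exceeds the background
    (empty signal).
    """
    if axis_length <= 0:
        raise ValueError(f"axis_length must be > 0, got {axis_length}")
    raw_x = np.asarray(raw_x, dtype=float)
    raw_I = np.asarray(raw_intensity, dtype=float)
    if isinstance(background, str):
        if background != "auto":
            raise ValueError("background must be a number or 'auto'")
        background = float(np.percentile(raw_I, 5.0))
    if np.any(raw_x < 0) or np.any(raw_x > axis_length):
        raise ValueError("raw positions must lie within [0, axis_length]")
    if not np.any(raw_I > background):
        raise ValueError("all intensities at or below background: empty signal")
    return IntensityProfile(
        x=raw_x / axis_length,
        intensity=np.maximum(0.0, raw_I - background),
        embryo_id=embryo_id,
        ap_length=float(axis_length),
    )


def _ramp_shape(x, border, knee):
    """Unit-slope linear-with-plateau shape with knots (border, knee)."""
    return np.clip(x - border, 0.0, knee - border)


class LinearPlateauModel:
    """Least-squares fit of a profile to the linear-with-plateau curve.

    The curve is parameterised by its two knots — the anterior ``border``
    where expression starts and the ``knee`` where the ramp meets the
    plateau — plus the ramp ``slope``.  Conditional on the knots the model is
    linear in the slope, so the slope is profiled out in closed form and the
    search is a deterministic two-stage procedure: an exhaustive grid over
    knot pairs taken from the observed positions, then a bounded Nelder-Mead
    polish of the best cell.  This avoids the local minima that plague joint
    nonlinear fitting of kinked curves.

    Parameters
    ----------
    intensity : array-like
        Observed intensities (the response).
    x : array-like
        AP fractions in [0, 1], need not be equally spaced.
    """

    #: knee - border below this is treated as a vertical step (degenerate slope)
    MIN_RAMP_EXTENT = 1e-3

    def __init__(self, intensity, x):
        self.intensity = np.asarray(intensity, dtype=float)
        self.x = np.asarray(x, dtype=float)
        if self.x.shape != self.intensity.shape or self.x.ndim != 1:
            raise ValueError("x and intensity must be 1-D arrays of equal length")
        if len(np.unique(self.x)) < 4:
            raise ValueError("underdetermined: need at least 4 distinct x positions")
        self.nobs = len(self.x)

    @classmethod
    def from_profile(cls, profile: IntensityProfile) -> "LinearPlateauModel":
        return cls(profile.intensity, profile.x)

    # -- internals ---------------------------------------------------------
    def _profiled_rss(self, border, knee):
        """RSS with the slope concentrated out; returns (rss, slope)."""
        g = _ramp_shape(self.x, border, knee)
        sgg = float(g @ g)
        if sgg <= 0.0:
            return float(self.intensity @ self.intensity), 0.0
        s = float(self.intensity @ g) / sgg
        if s < 0.0:  # negative gradients are not part of the model family
            s = 0.0
            return float(self.intensity @ self.intensity), s
        resid = self.intensity - s * g
        return float(resid @ resid), s

    def _grid_search(self):
        xs = np.unique(np.concatenate([[0.0], self.x, [1.0]]))
        if len(xs) > 80:  # subsample dense profiles; the polish recovers precision
            xs = np.unique(np.quantile(xs, np.linspace(0, 1, 80)))
        best = (np.inf, 0.0, 0.0)  # rss, border, knee
        I = self.intensity
        for b in xs:
            knees = xs[xs > b + self.MIN_RAMP_EXTENT]
            if len(knees) == 0:
                continue
            # vectorised over candidate knees
            g = np.clip(self.x[None, :] - b, 0.0, (knees - b)[:, None])
            sgg = np.einsum("ij,ij->i", g, g)
            sig = g @ I
            with np.errstate(divide="ignore", invalid="ignore"):
                s = np.where(sgg > 0, sig / sgg, 0.0)
            s = np.maximum(s, 0.0)
            rss = I @ I - 2 * s * sig + s * s * sgg
            k = int(np.argmin(rss))
            if rss[k] < best[0] - 1e-15:
                best = (float(rss[k]), float(b), float(knees[k]))
        return best

    def fit(self) -> "LinearPlateauResults":
        """Run the grid search and local polish; always deterministic."""
        rss0, b0, k0 = self._grid_search()

        def objective(p):
            b, k = p
            if not (0.0 <= b < k <= 1.0) or k - b < self.MIN_RAMP_EXTENT:
                return np.inf
            return self._profiled_rss(b, k)[0]

        res = optimize.minimize(
            objective,
            x0=[b0, k0],
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
        )
        if np.isfinite(res.fun) and res.fun <= rss0:
            b, k = res.x
        else:
            b, k = b0, k0
        rss, slope = self._profiled_rss(b, k)
        plateau = slope * (k - b)
        # Degenerate geometries: a ramp so steep that no data point falls
        # strictly inside it (constant-like profile fitted with a step), or a
        # slope pinned at the lower bound (flat-zero profile).
        interior = np.sum((self.x > b + 1e-12) & (self.x < k - 1e-12))
        degenerate = interior < 1 or (k - b) <= 1.05 * self.MIN_RAMP_EXTENT or slope <= 1e-9
        if slope <= 1e-9:
            slope = 1e-9  # keep GradientDescriptors constructible
        descriptors = GradientDescriptors(plateau=plateau, border=float(b), slope=float(slope))
        return LinearPlateauResults(
            model=self, descriptors=descriptors, knee=float(k),
            rss=float(rss), degenerate=bool(degenerate),
        )


@dataclass(frozen=True)
class LinearPlateauResults:
    """Fit results: descriptors, residual sum of squares, diagnostics."""

    model: LinearPlateauModel
    descriptors: GradientDescriptors
    knee: float
    rss: float
    degenerate: bool

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def fittedvalues(self) -> np.ndarray:
        d = self.descriptors
        return d.slope * _ramp_shape(self.model.x, d.border, self.knee)

    def summary(self) -> str:
        d = self.descriptors
        lines = [
            "Linear-with-plateau gradient fit",
            f"  n points   : {self.nobs}",
            f"  plateau    : {d.plateau:.6g} a.u.",
            f"  border     : {d.border:.6g} (AP fraction)",
            f"  slope      : {d.slope:.6g} a.u. / AP fraction",
            f"  rss        : {self.rss:.6g}",
            f"  degenerate : {self.degenerate}",
        ]
        return "\n".join(lines)


def fit_linear_plateau(profile: IntensityProfile) -> LinearPlateauResults:
    """Convenience wrapper: fit one :class:`IntensityProfile`."""
    return LinearPlateauModel.from_profile(profile).fit()


# ---------------------------------------------------------------------------
# group-level statistics
# ---------------------------------------------------------------------------

def _descriptor_frame(fits) -> pd.DataFrame:
    """Coerce a list of fit results (or a ready frame) to a descriptor table."""
    if isinstance(fits, pd.DataFrame):
        missing = [c for c in DESCRIPTOR_NAMES if c not in fits.columns]
        if missing:
            raise ValueError(f"descriptor frame missing columns: {missing}")
        return fits[list(DESCRIPTOR_NAMES)].astype(float)
    rows = []
    for f in fits:
        d = f.descriptors if hasattr(f, "descriptors") else f
        rows.append({k: getattr(d, k) for k in DESCRIPTOR_NAMES})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DescriptorStats:
    """Per-descriptor mean and percentile-bootstrap 95% CI over embryos."""

    mean: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    n_embryos: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.mean, "ci_low": self.ci_low, "ci_high": self.ci_high,
             "n": self.n_embryos}
        )


def bootstrap_descriptor_stats(fits, n_boot: int = 2000, seed=None) -> DescriptorStats:
    """Mean and 95% CI of each descriptor, bootstrapping over embryos.

    Embryos (not sample points) are the resampling unit, matching how the
    per-condition error bars are built from independent embryos.
    """
    frame = _descriptor_frame(fits)
    n = len(frame)
    if n < 3:
        raise ValueError(f"need at least 3 embryos, got {n}")
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for stable percentile CIs")
    rng = np.random.default_rng(seed)
    values = frame.to_numpy()
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = values[idx].mean(axis=1)  # (n_boot, 3)
    lo, hi = np.percentile(boot_means, [2.5, 97.5], axis=0)
    cols = list(frame.columns)
    return DescriptorStats(
        mean=pd.Series(values.mean(axis=0), index=cols),
        ci_low=pd.Series(lo, index=cols),
        ci_high=pd.Series(hi, index=cols),
        n_embryos=n,
    )


def normalize_to_reference(cond_fits, ref_fits, n_boot: int = 2000, seed=None) -> pd.DataFrame:
    """Per-descriptor ratio of condition mean to reference mean, with 95% CI.

    Both groups are bootstrapped independently; the CI is the percentile
    interval of the ratio of resampled means.  This is how knockdown
    descriptors are reported relative to wild type.
    """
    cond = _descriptor_frame(cond_fits).to_numpy()
    ref = _descriptor_frame(ref_fits).to_numpy()
    if len(cond) < 3 or len(ref) < 3:
        raise ValueError("need at least 3 embryos per group")
    ref_mean = ref.mean(axis=0)
    if np.any(ref_mean == 0):
        raise ValueError("reference mean is zero for some descriptor; ratio undefined")
    rng = np.random.default_rng(seed)
    ic = rng.integers(0, len(cond), size=(n_boot, len(cond)))
    ir = rng.integers(0, len(ref), size=(n_boot, len(ref)))
    ratios = cond[ic].mean(axis=1) / ref[ir].mean(axis=1)
    lo, hi = np.percentile(ratios, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {"ratio": cond.mean(axis=0) / ref_mean, "ci_low": lo, "ci_high": hi},
        index=list(DESCRIPTOR_NAMES),
    )


def compare_conditions(fits_a, fits_b, descriptor: str, n_perm: int = 10000,
                       seed=None) -> float:
    """Two-sided permutation p-value for a difference in descriptor means.

    Group labels are permuted ``n_perm`` times; the p-value uses the add-one
    convention ``(1 + #{|perm| >= |obs|}) / (n_perm + 1)`` so it is never 0.
    Degenerate data (all values equal) gives p = 1.
    """
    if descriptor not in DESCRIPTOR_NAMES:
        raise ValueError(f"unknown descriptor {descriptor!r}; one of {DESCRIPTOR_NAMES}")
    a = _descriptor_frame(fits_a)[descriptor].to_numpy()
    b = _descriptor_frame(fits_b)[descriptor].to_numpy()
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 embryos per group")
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)
    rng = np.random.default_rng(seed)
    count = 0
    # permute in blocks to bound memory on large n_perm
    block = max(1, min(n_perm, 2_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        perm = rng.permuted(np.broadcast_to(pooled, (m, n)), axis=1)
        diffs = perm[:, :na].mean(axis=1) - perm[:, na:].mean(axis=1)
        count += int(np.sum(np.abs(diffs) >= obs - 1e-12))
        done += m
    return (1 + count) / (n_perm + 1)
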