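"""Table, config and pattern I/O shared by the analysis stages and the CLI."""

from __future__ import annotations

import json
import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .fitting import IntensityProfile, normalize_profile
from .timing import CohortCounts

__all__ = [
    "read_profiles",
    "write_pattern",
    "read_pattern_csv",
    "read_cohort",
    "write_cohort",
    "load_gradient_config",
    "save_gradient_config",
    "write_provenance",
    "spawn_seeds",
]

PATTERN_FORMATS = ("csv", "pgm", "png")


def _read_table(path) -> pd.DataFrame:
    """Read a CSV/TSV table with delimiter sniffing."""
    return pd.read_csv(path, sep=None, engine="python")


def read_profiles(path):
    """Read per-embryo intensity profiles from a long-format CSV/TSV.

    Required columns: ``embryo_id``, ``intensity`` and either ``x`` (AP
    fractions in [0, 1]) or ``position`` with ``axis_length`` (native units).
    An optional ``condition`` column labels the genotype.  Returns
    ``(profiles, conditions)`` where ``conditions`` maps embryo_id to label.
    """
    frame = _read_table(path)
    for col in ("embryo_id", "intensity"):
        if col not in frame.columns:
            raise ValueError(f"missing required column: {col!r}")
    has_x = "x" in frame.columns
    has_native = "position" in frame.columns and "axis_length" in frame.columns
    if not has_x and not has_native:
        raise ValueError("need either an 'x' column or 'position' + 'axis_length'")
    bad = pd.to_numeric(frame["intensity"], errors="coerce").isna() & frame["intensity"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"non-numeric intensity at data row {row + 1}")
    frame["intensity"] = pd.to_numeric(frame["intensity"])
    if has_x and frame["x"].max() > 1.0 + 1e-9 and not has_native:
        raise ValueError("column 'x' has values outside [0, 1] and no axis_length "
                         "is given to normalise them")
    profiles = []
    conditions = {}
    for embryo_id, sub in frame.groupby("embryo_id", sort=True):
        if has_x:
            sub = sub.sort_values("x")
            prof = IntensityProfile(
                x=sub["x"].to_numpy(dtype=float),
                intensity=np.maximum(sub["intensity"].to_numpy(dtype=float), 0.0),
                embryo_id=str(embryo_id),
            )
        else:
            sub = sub.sort_values("position")
            length = float(sub["axis_length"].iloc[0])
            prof = normalize_profile(
                sub["position"].to_numpy(dtype=float),
                sub["intensity"].to_numpy(dtype=float),
                axis_length=length,
                background=0.0,
                embryo_id=str(embryo_id),
            )
        profiles.append(prof)
        if "condition" in sub.columns:
            conditions[str(embryo_id)] = str(sub["condition"].iloc[0])
    return profiles, conditions


def _pattern_values(pattern) -> np.ndarray:
    values = getattr(pattern, "values", pattern)
    values = np.asarray(values)
    if values.ndim == 1:
        values = values[None, :]
    return values.astype(np.uint8)


def write_pattern(pattern, path, fmt: str | None = None):
    """Write a binary pattern as CSV (bit-exact), PGM (text) or PNG.

    Images render 1 as white and 0 as black, matching the convention of
    showing the high phase of oscillation in white.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in PATTERN_FORMATS:
        raise ValueError(f"unknown pattern format {fmt!r}; one of {PATTERN_FORMATS}")
    values = _pattern_values(pattern)
    if fmt == "csv":
        np.savetxt(path, values, fmt="%d", delimiter=",")
    elif fmt == "pgm":
        ny, nx = values.shape
        with open(path, "w") as fh:
            fh.write(f"P2\n{nx} {ny}\n255\n")
            for row in values:
                fh.write(" ".join("255" if v else "0" for v in row) + "\n")
    else:
        Image.fromarray((values * 255).astype(np.uint8), mode="L").save(path)
    return path


def read_pattern_csv(path) -> np.ndarray:
    """Reload a CSV-exported pattern bit-exactly."""
    return np.loadtxt(path, delimiter=",", dtype=int, ndmin=2).astype(np.uint8)


def read_cohort(path) -> CohortCounts:
    """Read a class-count table (window_start, window_end, class_label, count)."""
    return CohortCounts.from_long(_read_table(path))


def write_cohort(cohort: CohortCounts, path):
    rows = []
    for (a, b), row in zip(cohort.windows, cohort.counts):
        for c, n in zip(cohort.classes, row):
            rows.append({"window_start": a, "window_end": b,
                         "class_label": c, "count": int(n)})
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def load_gradient_config(path):
    """Load a TemporalGradient from a YAML/JSON key-value file."""
    from .gradient import TemporalGradient

    with open(path) as fh:
        data = yaml.safe_load(fh)
    return TemporalGradient.from_dict(data)


def save_gradient_config(tg, path):
    with open(path, "w") as fh:
        yaml.safe_dump(tg.to_dict(), fh, sort_keys=False)
    return path


def write_provenance(out_dir, command: str, params: dict, seed=None):
    """Write a provenance record (parameters, seed, version) beside outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "command": command,
        "version": __version__,
        "seed": seed,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "params": {k: (v if isinstance(v, (int, float, str, bool, type(None)))
                       else str(v)) for k, v in params.items()},
    }
    path = out_dir / f"{command}.provenance.json"
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)
    return path


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Expand a global seed into ``n`` deterministic child seeds (< 2**31)."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]
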