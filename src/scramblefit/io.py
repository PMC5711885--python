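"""File I/O: assay/trace/spot CSVs, config files, and report writers.

CSV dialect: comma-separated, mandatory header row, UTF-8, '.' decimal.
Percentages are stored as numbers on the 0-100 scale, probabilities on
0-1.  JSON reports carry provenance (seed, config hash) so a run can be
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .kinetics import DithioniteTrace, TraceFit
from .occupancy import AssayPoint, OccupancyFit, VesiclePopulation
from .photobleach import SpotTrace, StepDistribution

__all__ = [
    "read_assay_csv",
    "read_trace_csv",
    "write_trace_csv",
    "read_spot_matrix_csv",
    "write_spot_matrix_csv",
    "load_config",
    "population_from_config",
    "config_hash",
    "occupancy_report",
    "fitted_curve_frame",
    "trace_summary_frame",
    "distribution_report",
]


def read_assay_csv(path, population: VesiclePopulation | None = None
                   ) -> list[AssayPoint]:
    """Load assay end points: columns ``ppr`` plus ``f_end`` or ``p_active``."""
    if population is None:
        population = VesiclePopulation()
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # surface the file name in parse errors
        raise ValueError(f"cannot parse assay CSV {path}: {exc}") from exc
    if df.empty:
        raise ValueError(f"assay CSV {path} contains no data rows")
    if "ppr" not in df.columns:
        raise ValueError(f"assay CSV {path} lacks required column 'ppr'")
    points = []
    for i, row in df.iterrows():
        try:
            if "f_end" in df.columns and not pd.isna(row["f_end"]):
                points.append(
                    AssayPoint.from_measurement(float(row["ppr"]),
                                                float(row["f_end"]), population)
                )
            elif "p_active" in df.columns:
                from .occupancy import ppr_star

                points.append(
                    AssayPoint(
                        ppr=float(row["ppr"]),
                        ppr_star=ppr_star(float(row["ppr"]), population),
                        f_end=None,
                        p_active=float(row["p_active"]),
                    )
                )
            else:
                raise ValueError("need column 'f_end' or 'p_active'")
        except ValueError as exc:
            raise ValueError(f"{path} line {i + 2}: {exc}") from exc
    return points


def read_trace_csv(path) -> DithioniteTrace:
    """Load a quench trace: columns ``time_s``, ``fluorescence_norm``."""
    df = pd.read_csv(path)
    for col in ("time_s", "fluorescence_norm"):
        if col not in df.columns:
            raise ValueError(f"trace CSV {path} lacks required column '{col}'")
    return DithioniteTrace(
        times=df["time_s"].to_numpy(float),
        fluorescence=df["fluorescence_norm"].to_numpy(float),
    )


def write_trace_csv(trace: DithioniteTrace, path) -> None:
    pd.DataFrame(
        {"time_s": trace.times, "fluorescence_norm": trace.fluorescence}
    ).to_csv(path, index=False)


def read_spot_matrix_csv(path, frame_rate: float = 20.0) -> list[SpotTrace]:
    """Load a frames-by-spots intensity matrix (one column per spot)."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"spot matrix {path} contains no data")
    return [
        SpotTrace(intensity=df[c].to_numpy(float), frame_rate=frame_rate)
        for c in df.columns
    ]


def write_spot_matrix_csv(traces: Sequence[SpotTrace], path) -> None:
    pd.DataFrame(
        {f"spot_{i:04d}": tr.intensity for i, tr in enumerate(traces)}
    ).to_csv(path, index=False)


def load_config(path) -> dict[str, Any]:
    """Read a YAML or JSON configuration file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def population_from_config(config: dict[str, Any]) -> VesiclePopulation:
    """Build a VesiclePopulation from the ``population`` config section."""
    section = config.get("population", config)
    allowed = {
        "mean_radius", "sd_radius", "refractory_fraction",
        "lipid_radius_epsilon", "f_o", "f_max",
    }
    return VesiclePopulation(**{k: v for k, v in section.items() if k in allowed})


def config_hash(config: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _provenance(seed, config) -> dict[str, Any]:
    return {"seed": seed, "config_hash": config_hash(config or {})}


def occupancy_report(fit: OccupancyFit, seed=None, config=None) -> dict[str, Any]:
    """JSON-ready summary of an occupancy fit (fit-constant scale 1e-4)."""
    return {
        "alpha": fit.alpha,
        "alpha_se": fit.alpha_se,
        "alpha_x1e4": fit.alpha * 1e4,
        "molar_mass": fit.molar_mass,
        "molar_mass_se": fit.molar_mass_se,
        "oligomer_order": str(fit.oligomer),
        "n_points": fit.n_points,
        "provenance": _provenance(seed, config),
    }


def fitted_curve_frame(fit: OccupancyFit, x_max: float, n: int = 200) -> pd.DataFrame:
    """Fitted p(>=1) curve with its 95% confidence band."""
    x = np.linspace(0.0, x_max, n)
    lo, hi = fit.ci_band(x)
    return pd.DataFrame(
        {"ppr_star": x, "p_fit": fit.predict(x), "p_lower95": lo, "p_upper95": hi}
    )


def trace_summary_frame(fits: Sequence[TraceFit], label: str = "") -> pd.DataFrame:
    """One summary row: n, half-life mean+/-SEM, drift-slope mean+/-SEM."""
    hl = np.array([f.half_life for f in fits])
    s = np.array([f.s_slope for f in fits])
    n = len(fits)
    sem = lambda v: float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return pd.DataFrame(
        [{
            "label": label,
            "n": n,
            "half_life_s": float(hl.mean()),
            "half_life_sem": sem(hl),
            "slope_x1e4": float(s.mean() * 1e4),
            "slope_sem_x1e4": sem(s) * 1e4,
        }]
    )


def distribution_report(dist: StepDistribution, seed=None, config=None
                        ) -> dict[str, Any]:
    return {
        "fractions": {str(k): v for k, v in dist.fractions.items()},
        "sem": {str(k): v for k, v in dist.sem.items()},
        "uncountable_fraction": dist.uncountable_fraction,
        "n_movies": dist.n_movies,
        "provenance": _provenance(seed, config),
    }
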