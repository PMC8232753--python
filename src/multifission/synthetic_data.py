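"""Synthetic noisy observations and packaged reference tables.

Real synchronized-culture experiments sample a handful of observables
(cell count, optical density, DNA per cell, RNA, dry matter, cell volume,
starch) in biological triplicate every 1–2 hours over a 24–25 h cycle.
This module emulates that sampling on top of a simulated trajectory:
replicate measurements are the true value times a multiplicative lognormal
factor with unit mean, since all observables are positive concentrations
or counts.  It also packages the published treatment-comparison tables and
the printed scenario constants so that the statistics layer can be
exercised without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .cycle_engine import CultureTrajectory

__all__ = [
    "NoiseModel",
    "ObservationSeries",
    "generate_observations",
    "table_fixtures",
    "light_anchor_fixture",
    "scenario_constants",
    "OBSERVABLES",
]

#: trajectory columns exposed as measurable observables, plus the OD proxy
OBSERVABLES = (
    "cell_conc_1e6_per_ml",
    "od750",
    "dna_pg_per_cell",
    "rna_rel",
    "dry_matter_ug_per_ml",
    "volume_um3",
    "starch_ug_per_ml",
)

#: optical density corresponding to the reference initial dry matter; the
#: published analyses use OD only for relative factors, so the absolute
#: scale is an arbitrary documented convention (OD 0.25 at 100 µg/mL)
OD_PER_UG_ML = 0.25 / 100.0


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for emulated assays.

    ``cv`` is the coefficient of variation of the multiplicative lognormal
    measurement error (unit mean); ``replicates`` the number of biological
    replicates (3 in the experiments emulated); ``sampling_interval`` the
    assay spacing in hours.
    """

    cv: float = 0.05
    replicates: int = 3
    sampling_interval: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError(f"cv must be nonnegative, got {self.cv}")
        if self.replicates < 1:
            raise ValueError(f"need at least one replicate, got {self.replicates}")
        if self.sampling_interval <= 0:
            raise ValueError("sampling interval must be positive")


@dataclass
class ObservationSeries:
    """Replicate × time measurement matrices for each observable."""

    time: np.ndarray
    observables: dict[str, np.ndarray]  # shape (replicates, len(time))
    scenario: str
    noise: NoiseModel

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame with a ``replicate`` column."""
        rows = []
        for name, mat in self.observables.items():
            for r in range(mat.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "time_h": self.time,
                            "observable": name,
                            "replicate": r + 1,
                            "value": mat[r],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def replicate_mean(self, name: str) -> np.ndarray:
        return self.observables[name].mean(axis=0)


def generate_observations(
    traj: CultureTrajectory, noise: NoiseModel
) -> ObservationSeries:
    """Sample a trajectory on the assay grid and apply replicate noise.

    Each measurement is ``true * exp(sigma * Z - sigma**2 / 2)`` with
    ``sigma**2 = ln(1 + cv**2)``, i.e. lognormal with mean exactly one, so
    replicate means are unbiased for the true trajectory.  Identical
    ``(trajectory, noise)`` inputs give bitwise-identical output.
    """
    dt = traj.config.time_step
    if noise.sampling_interval < dt - 1e-12:
        raise ValueError(
            f"sampling interval {noise.sampling_interval} h finer than the "
            f"simulation step {dt} h"
        )
    t_grid = traj.data["time_h"].to_numpy()
    stride = max(int(round(noise.sampling_interval / dt)), 1)
    idx = np.arange(0, len(t_grid), stride)
    time = t_grid[idx]

    truths = {}
    for name in OBSERVABLES:
        if name == "od750":
            truths[name] = traj.data["dry_matter_ug_per_ml"].to_numpy()[idx] * OD_PER_UG_ML
        else:
            truths[name] = traj.data[name].to_numpy()[idx]

    rng = np.random.default_rng(noise.seed)
    sigma = float(np.sqrt(np.log1p(noise.cv**2)))
    obs = {}
    for name, truth in truths.items():
        if noise.cv == 0:
            mat = np.tile(truth, (noise.replicates, 1))
        else:
            z = rng.standard_normal((noise.replicates, len(time)))
            mat = truth[None, :] * np.exp(sigma * z - 0.5 * sigma**2)
        obs[name] = mat
    return ObservationSeries(
        time=time, observables=obs, scenario=traj.config.name, noise=noise
    )


def _read_table(name: str) -> pd.DataFrame:
    with resources.files("multifission.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def table_fixtures() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two packaged treatment-comparison tables.

    Table 1 compares division numbers and cell-number doubling times and
    table 2 mass multiplication factors and mass doubling times across
    heavy-water concentrations (0 / 70 / 99 %, the latter also pre-adapted)
    and light intensities (150–400 µmol photons m⁻²s⁻¹).  Entries that the
    source marks unreliable (cell death and lysis) are missing values.
    """
    return _read_table("table1.csv"), _read_table("table2.csv")


def light_anchor_fixture() -> pd.DataFrame:
    """Packaged (incident, mean, dry_matter) light-calibration anchors."""
    return _read_table("light_anchors.csv")


def scenario_constants() -> dict[str, object]:
    """Printed experimental constants used for calibration and checks."""
    return {
        "initial_dna_pg_per_cell": 0.1,
        "max_dna_pg_per_cell": 1.6,
        "initial_dry_matter_ug_per_ml": 100.0,
        "final_dry_matter_ug_per_ml": {500: 1600.0, 250: 1300.0, 110: 400.0},
        "initial_mean_light": {500: 360.0, 250: 180.0, 110: 80.0},
        "final_mean_light": {500: 160.0, 250: 85.0, 110: 50.0},
        "initial_cell_volume_um3": 25.0,
        "light_schedule_h": (18.0, 7.0),
        "replication_rounds": {500: 4, 250: (3, 4), 110: 2},
        "starch_fold": {500: 10.0, 250: 8.0, 110: 2.0},
        "inter_replication_gap_h": 2.0,
        "growth_idle_interval_h": (4.0, 6.0),
    }
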