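"""Named scenario presets.

The three ``fig5_*`` presets reproduce the synchronized-culture experiments
at incident 500 / 250 / 110 µmol photons m⁻²s⁻¹ under the standard
18 h light : 7 h dark regime, starting from 100 µg mL⁻¹ dry matter and
0.1 pg DNA per cell.  The mixed cohort at 250 µE encodes the observation
that only about half of the population completes the fourth replication
round.  The ``d2o_*`` presets model growth in deuterated water as scalar
retardation of the growth rate (``rho_growth``, from the mass doubling-time
fold retardations) and of every cell-cycle phase (``rho_division``, from
the cell-number doubling-time fold retardations), under continuous light as
in the heavy-water experiments.
"""

from __future__ import annotations

from dataclasses import replace

from .cycle_engine import ScenarioConfig

__all__ = ["PRESETS", "get_preset", "list_presets"]


def _build() -> dict[str, ScenarioConfig]:
    sync = ((18.0, 7.0),)
    presets = {
        "fig5_500": ScenarioConfig(
            name="fig5_500", I_i=500.0, light_schedule=sync, cohort_fractions={4: 1.0}
        ),
        "fig5_250": ScenarioConfig(
            name="fig5_250",
            I_i=250.0,
            light_schedule=sync,
            cohort_fractions={3: 0.5, 4: 0.5},
        ),
        "fig5_110": ScenarioConfig(
            name="fig5_110", I_i=110.0, light_schedule=sync, cohort_fractions={2: 1.0}
        ),
        "sync_18L7D": ScenarioConfig(
            name="sync_18L7D", I_i=500.0, light_schedule=sync, cohort_fractions={4: 1.0}
        ),
        "continuous_control": ScenarioConfig(
            name="continuous_control",
            I_i=300.0,
            light_schedule=None,
            cohort_fractions={3: 1.0},
            horizon=24.0,
        ),
        # deuterium presets: retardation factors are the mean fold
        # retardations of the mass (growth) and cell-number (division)
        # doubling times across the four tested light intensities
        "d2o_70": ScenarioConfig(
            name="d2o_70",
            I_i=300.0,
            light_schedule=None,
            cohort_fractions={2: 1.0},
            retardation=(1.20, 1.55),
            horizon=60.0,
        ),
        "d2o_99": ScenarioConfig(
            name="d2o_99",
            I_i=300.0,
            light_schedule=None,
            cohort_fractions={1: 1.0},
            retardation=(18.28, 14.40),
            horizon=400.0,
        ),
        "d2o_99_adapted": ScenarioConfig(
            name="d2o_99_adapted",
            I_i=300.0,
            light_schedule=None,
            cohort_fractions={1: 1.0},
            retardation=(3.93, 4.27),
            horizon=120.0,
        ),
    }
    return presets


PRESETS: dict[str, ScenarioConfig] = _build()


def list_presets() -> list[str]:
    return sorted(PRESETS)


def get_preset(name: str, **overrides) -> ScenarioConfig:
    """Return a copy of the named preset, optionally with field overrides."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(list_presets())}"
        ) from None
    return replace(base, **overrides) if overrides else base
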