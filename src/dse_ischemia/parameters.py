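"""Quantitative speckle-tracking parameter schema.

Each parameter carries its unit, a typical healthy rest-phase distribution,
the healthy stress response (chronotropic/inotropic shift under dobutamine)
and the direction in which acute ischemia pushes the stress-phase value:

* longitudinal strain and strain rate are negative (shortening) — ischemia
  blunts them toward 0;
* times to peak are prolonged;
* the systolic velocity S' response is blunted (reduced);
* post-systolic shortening and positive (stretching) systolic strain grow.

The rest means/SDs are representative of published normal ranges for
apical-view speckle tracking and fix the scale on which standardized
ischemic effect sizes act.
"""

from __future__ import annotations

from dataclasses import dataclass

# ischemia direction codes:
#   "toward_zero"  shift opposes the sign of the healthy mean (blunting)
#   "increase"     shift is positive on the natural scale
#   "decrease"     shift is negative on the natural scale
_TOWARD_ZERO = "toward_zero"
_INCREASE = "increase"
_DECREASE = "decrease"


@dataclass(frozen=True)
class ParameterSpec:
    """Distributional schema for one quantitative parameter."""

    name: str
    unit: str
    rest_mean: float
    rest_sd: float
    stress_shift: float  # healthy mean change from rest to peak stress
    ischemia_direction: str

    def ischemic_sign(self) -> float:
        """Sign of the additive ischemic shift on the natural scale."""
        if self.ischemia_direction == _INCREASE:
            return 1.0
        if self.ischemia_direction == _DECREASE:
            return -1.0
        # blunting: push the stress value back toward 0
        return -1.0 if (self.rest_mean + self.stress_shift) > 0 else 1.0


PARAMETERS: dict[str, ParameterSpec] = {
    p.name: p
    for p in (
        ParameterSpec("s_velocity", "cm/s", 6.0, 1.2, 3.0, _TOWARD_ZERO),
        ParameterSpec("e_velocity", "cm/s", -6.5, 1.5, -1.0, _TOWARD_ZERO),
        ParameterSpec("a_velocity", "cm/s", -2.5, 1.0, -0.5, _TOWARD_ZERO),
        ParameterSpec("time_to_s", "ms", 150.0, 30.0, -60.0, _INCREASE),
        ParameterSpec("time_to_max_strain", "ms", 380.0, 40.0, -80.0, _INCREASE),
        ParameterSpec("systolic_strain", "%", -18.0, 3.5, -2.0, _TOWARD_ZERO),
        ParameterSpec("post_systolic_strain", "%", -19.0, 3.5, -2.0, _DECREASE),
        ParameterSpec("maximal_strain", "%", -19.5, 3.5, -2.0, _TOWARD_ZERO),
        ParameterSpec("radial_systolic_strain", "%", 35.0, 10.0, 10.0, _DECREASE),
        ParameterSpec("systolic_strain_rate", "1/s", -1.1, 0.3, -1.2, _TOWARD_ZERO),
        ParameterSpec("a_strain_rate", "1/s", 1.1, 0.4, 0.7, _DECREASE),
        ParameterSpec("radial_displacement", "mm", 6.0, 2.0, 2.0, _DECREASE),
        ParameterSpec("positive_systolic_strain", "%", 0.2, 0.3, 0.0, _INCREASE),
    )
}

PARAMETER_NAMES: tuple[str, ...] = tuple(PARAMETERS)

PHASES: tuple[str, ...] = ("rest", "stress")
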