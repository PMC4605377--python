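"""Osmotic-challenge scenarios: phase schedules and per-parameter responses.

A scenario is an ordered list of phases.  Each phase applies one stress agent
(identified by its osmolality in mOsmol/kg), lasts ``duration_min`` minutes and
is imaged at ``frames_per_min``.  Within a phase every biometric parameter
relaxes exponentially toward an asymptote expressed as a fractional change of
its pre-challenge baseline; a phase with no declared response for a parameter
relaxes that parameter back toward baseline (amplitude 0) — this is how the
reversal (return-to-isotonic) phases behave.

Packaged scenarios ``control``, ``group1`` ... ``group4`` mirror the study's
five experimental arms; ``model_eye`` images a static calibration model eye.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

#: Parameters a scenario can drive.  IRIS_SAG is the geometric sag of the iris
#: wings (what the IC measurement recovers); LSI drives the lens opacification
#: multiplier.
RESPONSE_PARAMS = ("CCT", "ACD", "LT", "CRD", "LSI", "IRIS_SAG")

#: Reference osmolality of the isotonic agent (mOsmol/kg).
ISOTONIC_MOSM = 250.0

#: Relaxation time constant used when a phase declares no response for a
#: parameter (reversal toward baseline), minutes.
DEFAULT_REVERSAL_TAU = 4.0


def tonicity(osmolality: float) -> str:
    """Classify an agent: above / below / at the 250 mOsmol/kg reference."""
    if osmolality > ISOTONIC_MOSM:
        return "hypertonic"
    if osmolality < ISOTONIC_MOSM:
        return "hypotonic"
    return "isotonic"


class PhaseResponse(BaseModel):
    """Exponential relaxation of one parameter within one phase.

    ``amplitude`` is the asymptotic fractional change relative to baseline
    (e.g. -0.207 for a 20.7 % decrease); ``tau_min`` the time constant.
    """

    amplitude: float = 0.0
    tau_min: float = Field(default=DEFAULT_REVERSAL_TAU, gt=0)


class Phase(BaseModel):
    osmolality: float = Field(gt=0)
    duration_min: float = Field(gt=0)
    frames_per_min: float = Field(gt=0)
    label: Optional[str] = None
    responses: dict[str, PhaseResponse] = Field(default_factory=dict)

    @field_validator("responses")
    @classmethod
    def _known_params(cls, v: dict[str, PhaseResponse]) -> dict[str, PhaseResponse]:
        unknown = set(v) - set(RESPONSE_PARAMS)
        if unknown:
            raise ValueError(f"unknown response parameters: {sorted(unknown)}")
        return v

    @property
    def tonicity(self) -> str:
        return tonicity(self.osmolality)

    def response(self, param: str) -> PhaseResponse:
        return self.responses.get(param, PhaseResponse())

    def display_label(self, index: int) -> str:
        return self.label or f"phase{index + 1}-{self.tonicity}"


class OsmoticScenario(BaseModel):
    """Full study arm: baseline repeats followed by ordered phases."""

    name: str = "scenario"
    preset: str = "mouse"  # baseline geometry/optics preset
    baseline_repeats: int = Field(default=5, ge=1)
    phases: list[Phase] = Field(min_length=1)
    imaging: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_preset(self) -> "OsmoticScenario":
        if self.preset not in ("mouse", "model_eye"):
            raise ValueError(f"unknown preset {self.preset!r}")
        return self

    @property
    def total_duration(self) -> float:
        return sum(p.duration_min for p in self.phases)

    def phase_windows(self) -> list[tuple[float, float, Phase]]:
        """(start, end) minutes of every phase; challenges start at t = 0."""
        out, t0 = [], 0.0
        for p in self.phases:
            out.append((t0, t0 + p.duration_min, p))
            t0 += p.duration_min
        return out

    def frame_times(self) -> list[tuple[float, str]]:
        """Timestamps (min) and phase labels of every acquisition.

        Baseline repeats are imaged once per minute ending at t = 0; each
        phase is then imaged at its own frequency, the first frame one
        inter-frame interval after phase onset.
        """
        frames = [(-float(k), "baseline") for k in range(self.baseline_repeats - 1, -1, -1)]
        for i, (t0, _, phase) in enumerate(self.phase_windows()):
            n = int(round(phase.duration_min * phase.frames_per_min))
            dt = 1.0 / phase.frames_per_min
            lab = phase.display_label(i)
            frames.extend((t0 + (j + 1) * dt, lab) for j in range(n))
        return frames


def _packaged(name: str):
    return resources.files("octeye") / "scenarios" / f"{name}.yaml"


def packaged_scenarios() -> list[str]:
    root = resources.files("octeye") / "scenarios"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_scenario(source: str | Path) -> OsmoticScenario:
    """Load a scenario from a YAML path or a packaged scenario name."""
    path = Path(source)
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
    else:
        pkg = _packaged(str(source))
        if not pkg.is_file():
            raise FileNotFoundError(
                f"scenario {source!r} is neither a YAML file nor a packaged "
                f"scenario (available: {', '.join(packaged_scenarios())})"
            )
        text = pkg.read_text()
    return OsmoticScenario.model_validate(yaml.safe_load(text))
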