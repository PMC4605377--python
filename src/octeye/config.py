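"""Run configuration shared by the CLI subcommands."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, field_validator

from .scenario import packaged_scenarios


class RunConfig(BaseModel):
    """Validated knobs of one pipeline run."""

    scenario: str = "control"            # packaged name or YAML path
    outdir: Path = Path("octeye_out")
    seed: int = 0
    noise: bool = False
    lsi_fraction: float = Field(default=0.15, gt=0, le=1)
    seeds_csv: Optional[Path] = None
    imaging: dict[str, float] = Field(default_factory=dict)

    @field_validator("scenario")
    @classmethod
    def _scenario_exists(cls, v: str) -> str:
        if v in packaged_scenarios() or Path(v).exists():
            return v
        raise ValueError(
            f"scenario {v!r} not found (packaged: {', '.join(packaged_scenarios())})")

    @field_validator("seeds_csv")
    @classmethod
    def _seeds_exist(cls, v: Optional[Path]) -> Optional[Path]:
        if v is not None and not v.exists():
            raise ValueError(f"seed file {v} does not exist")
        return v
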