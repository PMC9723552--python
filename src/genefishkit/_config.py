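"""Run configuration shared by the CLI subcommands, with named presets."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .errors import InvalidParameterError
from .thermo import HybridizationConditions


@dataclass(frozen=True)
class RunConfig:
    """Defaults for hybridization conditions and screening thresholds.

    ``stringent_fa`` (35%) is the usual polynucleotide design point;
    ``relaxed_fa_grid`` the candidate buffers for broadened specificity.
    """

    na_molar: float = 0.39
    hyb_temp_c: float = 46.0
    tm_margin_c: float = 0.0
    stringent_fa: float = 35.0
    relaxed_fa_grid: tuple[float, ...] = (15.0, 20.0, 25.0, 30.0)
    identity_threshold: float = 80.0
    min_hits: int = 4
    k: int = 5
    min_len: int = 300
    max_len: int = 500
    preset: str | None = None

    def __post_init__(self) -> None:
        # delegate range validation to the thermo types
        HybridizationConditions(self.na_molar, self.stringent_fa, self.hyb_temp_c, self.tm_margin_c)
        for fa in self.relaxed_fa_grid:
            if not 0.0 <= fa <= 100.0:
                raise InvalidParameterError(f"relaxed FA value out of range: {fa}")
        if not 0.0 <= self.identity_threshold <= 100.0:
            raise InvalidParameterError(f"identity_threshold out of range: {self.identity_threshold}")
        if self.min_hits < 1:
            raise InvalidParameterError("min_hits must be >= 1")

    def conditions(self, fa_percent: float | None = None) -> HybridizationConditions:
        return HybridizationConditions(
            na_molar=self.na_molar,
            fa_percent=self.stringent_fa if fa_percent is None else fa_percent,
            hyb_temp_c=self.hyb_temp_c,
            tm_margin_c=self.tm_margin_c,
        )


#: the five-probe 442-456 bp design with the 4-of-5 / 80% screening rule and
#: the 35% -> 15% FA relaxation
PRESETS: dict[str, dict] = {
    "paper2021": dict(
        k=5,
        min_len=442,
        max_len=456,
        identity_threshold=80.0,
        min_hits=4,
        stringent_fa=35.0,
        relaxed_fa_grid=(15.0,),
    ),
}


def load_config(path=None, preset: str | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file, preset name and overrides."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise InvalidParameterError(f"{path}: config must be a mapping")
        values.update(loaded)
    if preset is not None:
        if preset not in PRESETS:
            raise InvalidParameterError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
            )
        values.update(PRESETS[preset])
        values["preset"] = preset
    values.update({k: v for k, v in overrides.items() if v is not None})
    if "relaxed_fa_grid" in values:
        values["relaxed_fa_grid"] = tuple(values["relaxed_fa_grid"])
    return RunConfig(**values)
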