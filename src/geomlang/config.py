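"""Run configuration: presets, seeds, schema-checked config files."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from .language import CostModel, LanguageError
from .predictor import PRESETS, PredictorParams

_KNOWN_KEYS = {
    "preset",
    "sigma",
    "sigma2",
    "k_max",
    "p_nest",
    "p_p",
    "restricted_k",
    "group",
    "n_subjects",
    "n_runs",
    "seed",
    "atom_cost",
    "variation_overhead",
    "output_dir",
}


@dataclass
class RunConfig:
    """Everything that determines a run's outputs.

    Serialized into output manifests so any artifact can be regenerated.
    """

    preset: str = "adult"
    params: PredictorParams = field(default_factory=lambda: PRESETS["adult"])
    group: str = "adult"
    n_subjects: int = 300
    n_runs: int = 300
    seed: int = 0
    cost_model: CostModel = field(default_factory=CostModel)
    output_dir: str = "."

    def manifest(self) -> dict:
        return {
            "preset": self.preset,
            "params": asdict(self.params),
            "group": self.group,
            "n_subjects": self.n_subjects,
            "n_runs": self.n_runs,
            "seed": self.seed,
            "cost_model": asdict(self.cost_model),
            "axes": {"H": 7, "V": 3, "A": 1, "B": 5},
            "output_dir": self.output_dir,
        }


def load_config(path: Optional[str] = None, text: Optional[str] = None) -> RunConfig:
    """Load a YAML/JSON config; unknown keys are rejected by name, missing
    keys fall back to defaults (an empty file is the adult preset)."""
    if text is None:
        with open(path) as fh:
            text = fh.read()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise LanguageError(f"config must be a mapping, got {type(data).__name__}")
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise LanguageError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    preset = data.get("preset", "adult")
    if preset not in PRESETS:
        raise LanguageError(
            f"unknown preset {preset!r} (choose from {sorted(PRESETS)})"
        )
    base = PRESETS[preset]
    params = PredictorParams(
        sigma=float(data.get("sigma", base.sigma)),
        sigma2=float(data.get("sigma2", base.sigma2)),
        k_max=int(data.get("k_max", base.k_max)),
        p_nest=float(data.get("p_nest", base.p_nest)),
        p_p=float(data.get("p_p", base.p_p)),
        restricted_k=bool(data.get("restricted_k", base.restricted_k)),
    )
    cm = CostModel(
        atom_cost=int(data.get("atom_cost", 2)),
        variation_overhead=int(data.get("variation_overhead", 1)),
    )
    return RunConfig(
        preset=preset,
        params=params,
        group=str(data.get("group", "adult" if preset == "adult" else "child")),
        n_subjects=int(data.get("n_subjects", 300)),
        n_runs=int(data.get("n_runs", 300)),
        seed=int(data.get("seed", 0)),
        cost_model=cm,
        output_dir=str(data.get("output_dir", ".")),
    )
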