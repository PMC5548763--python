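"""Pipeline configuration: paths, thresholds, and mode flags."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    # input paths (optional when simulating)
    genes_path: str | None = None
    mirnas_path: str | None = None
    tf_list_path: str | None = None
    cv_list_path: str | None = None
    tf_targets_path: str | None = None
    mirna_targets_path: str | None = None
    annotations_path: str | None = None
    ground_truth_path: str | None = None

    # thresholds
    pcc_threshold: float = 0.9
    de_sd_multiplier: float = 2.0
    pcc_filter_sd: float = 1.0
    percentile_cut: float = 0.01
    min_module_size: int = 10
    fdr: float = 0.05

    # mode flags
    de_center: str = "mean"          # "mean" or "zero"
    sd_kind: str = "sample"          # "sample" (ddof=1) or "population"
    tab_specific_tf_mirna_edges: bool = True
    hub_k_tf: int = 5
    hub_k_mirna: int = 3

    seed: int = 0

    @property
    def sd_ddof(self) -> int:
        return 1 if self.sd_kind == "sample" else 0

    def validate(self, check_paths: bool = False) -> None:
        for name in ("pcc_threshold", "de_sd_multiplier", "pcc_filter_sd", "fdr"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(name, "must be positive")
        if not 0.0 < self.percentile_cut < 0.5:
            raise ConfigurationError("percentile_cut", "must be in (0, 0.5)")
        if self.min_module_size < 1:
            raise ConfigurationError("min_module_size", "must be >= 1")
        if self.de_center not in ("mean", "zero"):
            raise ConfigurationError("de_center", "must be 'mean' or 'zero'")
        if self.sd_kind not in ("sample", "population"):
            raise ConfigurationError("sd_kind",
                                     "must be 'sample' or 'population'")
        if check_paths:
            for name, value in asdict(self).items():
                if name.endswith("_path") and value is not None \
                        and not Path(value).is_file():
                    raise ConfigurationError(name, f"file not found: {value}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("<root>", "config file must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(sorted(unknown)[0], "unknown field")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
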