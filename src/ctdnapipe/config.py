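"""Run configuration: every tunable threshold in the pipeline, with the
published defaults.  All allele-fraction thresholds are fractions in [0, 1];
conversion from percent happens here and nowhere else.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any

import yaml


@dataclass(frozen=True)
class RunConfig:
    # tissue filtering
    tissue_vaf_floor: float = 0.05          # strict: retained requires vaf > floor
    tissue_vaf_ceiling: float = 0.98        # applies to the gnomAD branch only
    exon_distance_max: int = 5              # bp from exon boundary (splice window)
    gnomad_tissue_max: float = 0.01         # branch (b) population-frequency gate
    local_cohort_max: int = 5               # > this in local germline cohort -> excluded
    cosmic_hotspot_min: int = 5             # same-position COSMIC cases for driver/hotspot
    origin_vaf_window: tuple[float, float] = (0.35, 0.60)
    origin_similarity_window: float = 0.10  # "similar VAF" companion window
    wbc_germline_band: tuple[float, float] = (0.40, 0.60)

    # plasma caller pass thresholds
    caller_vaf_floor: float = 0.0005
    caller_lod_floor: float = 4.0
    gnomad_plasma_max: float = 0.005

    # UMI support
    umi_min_total: int = 3
    umi_min_per_strand: int = 1

    # tumour-agnostic cascade
    blacklist_recurrence_threshold: int = 10   # strictly more samples -> blacklisted
    plasma_depth_floor: int = 100              # total reads; exclusion if fewer
    clinvar_multi_source_min: int = 2
    germline_plasma_band: tuple[float, float] = (0.40, 0.55)

    # CH exclusion
    wbc_read_threshold: int = 4                # strictly more alt reads -> CH evidence
    wbc_vaf_threshold: float = 0.0005          # 0.05%; see wbc_vaf_threshold_alt
    wbc_vaf_threshold_alt: float = 0.005       # alternative published reading (0.5%)
    paired_plasma_ratio: float = 4.0           # CH if post VAF > diagnostic VAF / ratio

    # ddPCR
    droplet_volume_nl: float = 0.85
    ci_level: float = 0.95
    lod_min_molecules: int = 3

    seed: int = 0

    def replace(self, **kwargs: Any) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("origin_vaf_window", "wbc_germline_band", "germline_plasma_band"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


DEFAULT_CONFIG = RunConfig()
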