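"""Run configuration: detection constants, classification thresholds and
bootstrap settings, loadable from YAML with defaults chosen for cultured
human fibroblasts imaged at ~0.1 µm/px."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class DetectionConfig:
    """Constants of the structure-detection stage.

    All sizes are physical (µm / µm²) except the few pixel-scale kernel
    radii, which are resolution-bound rather than sample-bound.
    """

    #: rolling-ball background radius for the nucleus plane, px
    background_radius_px: int = 50
    #: nuclei smaller than this are specks, µm²
    nucleus_min_area_um2: float = 20.0
    #: minimum separation of watershed seed maxima when splitting
    #: touching nuclei, µm (about one fibroblast-nucleus radius)
    nucleus_split_min_distance_um: float = 4.0
    #: percentile window for per-plane contrast normalization
    contrast_percentiles: tuple[float, float] = (1.0, 99.9)
    #: closing radius bridging residual sub-gaps in the merged signal, px
    cilium_closing_radius_px: int = 2
    #: merged-signal components below this are noise, µm²
    cilium_min_area_um2: float = 0.15
    #: LoG blob scales for basal-body puncta, px
    blob_sigma_px: tuple[float, float] = (1.0, 3.0)
    #: threshold on the scale-normalized LoG response
    blob_threshold: float = 0.1
    #: a basal body anchors a cilium if within this of an endpoint, µm
    base_anchor_radius_um: float = 1.0
    #: a cilium belongs to a nucleus if base within this of its boundary, µm
    nucleus_assignment_radius_um: float = 15.0


@dataclass
class MorphometryConfig:
    """Constants of the per-cilium measurement stage."""

    #: skeleton spurs shorter than this are pruned before path finding, px
    spur_length_px: int = 3
    #: corrected length below which a round candidate is a "spot", µm
    spot_length_um: float = 1.0
    #: circularity (4*pi*area/perimeter^2) above which a short candidate
    #: is a "spot"
    spot_circularity: float = 0.6
    #: search-region dilation around the cilium mask for IFT88, px
    ift_dilation_px: int = 3
    #: restrict the IFT search region to within this of the distal
    #: skeleton endpoint when emulating manual tip-only scoring, µm
    tip_radius_um: float = 1.0


@dataclass
class BootstrapConfig:
    n_boot: int = 10000
    seed: int = 20210527


@dataclass
class RunConfig:
    """Full configuration of an analysis run; serializable to YAML."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    pixel_size_um: float | None = None
    channel_map: dict[str, int] | None = None
    calibration_path: str | None = None
    reference_path: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for name, sub in (
            ("detection", DetectionConfig),
            ("morphometry", MorphometryConfig),
            ("bootstrap", BootstrapConfig),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                known = {f.name for f in fields(sub)}
                extra = set(kwargs[name]) - known
                if extra:
                    raise ValueError(f"unknown {name} option(s): {sorted(extra)}")
                sect = dict(kwargs[name])
                for k, v in sect.items():
                    if isinstance(v, list):
                        sect[k] = tuple(v)
                kwargs[name] = sub(**sect)
        known = {f.name for f in fields(cls)}
        extra = set(kwargs) - known
        if extra:
            raise ValueError(f"unknown config option(s): {sorted(extra)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)
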