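"""Pipeline configuration: every stage threshold in one YAML-serializable
object, defaulting to the published values."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .catalog import FilterThresholds
from .errors import ConfigError
from .genotyping_qc import QcThresholds
from .synthdata import SynthConfig

__all__ = [
    "PairingThresholds",
    "ArrayThresholds",
    "AbundanceSettings",
    "EnrichmentSettings",
    "PipelineConfig",
]


@dataclass(frozen=True)
class PairingThresholds:
    min_identity: float = 95.0
    max_evalue: float = 1e-5
    coverage_window: tuple[float, float] = (25.0, 800.0)
    min_length: int = 500


@dataclass(frozen=True)
class ArrayThresholds:
    clean_window: int = 50
    min_end_distance: int = 20
    min_score: float = 0.60


@dataclass(frozen=True)
class AbundanceSettings:
    decile: float = 0.10
    depth_mode: str = "floor"  # or "interpolate"


@dataclass(frozen=True)
class EnrichmentSettings:
    nodesize: int = 5
    method: str = "classic"  # or "elim"
    alpha_elim: float = 0.01
    adjust: str = "BH"  # families; "none" to disable
    min_in_top: int = 2


@dataclass(frozen=True)
class PipelineConfig:
    """Aggregated stage settings; defaults reproduce every published
    threshold exactly."""

    pairing: PairingThresholds = PairingThresholds()
    filters: FilterThresholds = FilterThresholds()
    flank_width: int = 100
    array: ArrayThresholds = ArrayThresholds()
    qc: QcThresholds = QcThresholds()
    abundance: AbundanceSettings = AbundanceSettings()
    enrichment: EnrichmentSettings = EnrichmentSettings()
    synth: SynthConfig = SynthConfig()
    rng_seed: int = 0
    log_level: str = "INFO"

    # ------------------------------------------------------------ yaml io
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pairing"]["coverage_window"] = list(d["pairing"]["coverage_window"])
        d["synth"]["contig_len_range"] = list(d["synth"]["contig_len_range"])
        d["synth"]["mean_depth_range"] = list(d["synth"]["mean_depth_range"])
        return d

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, section, tuple_fields=()):
            data = dict(d.get(section, {}))
            for tf in tuple_fields:
                if tf in data:
                    data[tf] = tuple(data[tf])
            try:
                return klass(**data)
            except TypeError as exc:
                raise ConfigError(f"bad {section} section: {exc}") from exc

        return cls(
            pairing=build(PairingThresholds, "pairing", ("coverage_window",)),
            filters=build(FilterThresholds, "filters"),
            flank_width=int(d.get("flank_width", 100)),
            array=build(ArrayThresholds, "array"),
            qc=build(QcThresholds, "qc"),
            abundance=build(AbundanceSettings, "abundance"),
            enrichment=build(EnrichmentSettings, "enrichment"),
            synth=build(
                SynthConfig, "synth", ("contig_len_range", "mean_depth_range")
            ),
            rng_seed=int(d.get("rng_seed", 0)),
            log_level=str(d.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("pipeline config must be a YAML mapping")
        return cls.from_dict(data)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self,
            rng_seed=seed,
            synth=dataclasses.replace(self.synth, rng_seed=seed),
        )
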