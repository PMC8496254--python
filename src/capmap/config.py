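"""Structured pipeline configuration (YAML/JSON) shared by the CLI."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .filtering import FilterParams
from .genotyping import CallingParams
from .grouping import GroupingParams
from .ordering import OrderingParams
from .simulate import SelectionSpec, SimConfig

_SECTIONS = {
    "simulate": SimConfig,
    "calling": CallingParams,
    "filtering": FilterParams,
    "grouping": GroupingParams,
    "ordering": OrderingParams,
}


def _build(klass, section: str, payload: dict):
    payload = dict(payload or {})
    known = {f.name for f in dataclasses.fields(klass)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    try:
        return klass(**payload)
    except TypeError as exc:
        raise ConfigError(f"bad section {section!r}: {exc}") from exc


@dataclass
class PipelineConfig:
    """All stage parameters plus the master seed and thread count.

    The master ``seed`` is pushed into the simulator and ordering sections
    unless those sections set their own.
    """

    seed: int = 0
    threads: int = 1
    simulate: SimConfig = field(default_factory=SimConfig)
    calling: CallingParams = field(default_factory=CallingParams)
    filtering: FilterParams = field(default_factory=FilterParams)
    grouping: GroupingParams = field(default_factory=GroupingParams)
    ordering: OrderingParams = field(default_factory=OrderingParams)

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        seed = int(data.pop("seed", 0))
        threads = int(data.pop("threads", 1))

        sections = {}
        for name, klass in _SECTIONS.items():
            payload = dict(data.pop(name, {}) or {})
            if name == "simulate":
                if "selection_loci" in payload:
                    payload["selection_loci"] = tuple(
                        SelectionSpec(**s) for s in payload["selection_loci"])
                if "chrom_lengths_cM" in payload:
                    payload["chrom_lengths_cM"] = tuple(payload["chrom_lengths_cM"])
            if name in ("simulate", "ordering"):
                payload.setdefault("seed", seed)
            sections[name] = _build(klass, name, payload)
        if data:
            raise ConfigError(f"unknown top-level config keys: {sorted(data)}")
        return cls(seed=seed, threads=threads, **sections)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_mapping(data)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self,
            seed=seed,
            simulate=dataclasses.replace(self.simulate, seed=seed),
            ordering=dataclasses.replace(self.ordering, seed=seed),
        )
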