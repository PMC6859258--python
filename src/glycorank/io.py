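"""Config schema, run manifests, and result serialization.

YAML configs carry a ``schema_version`` and a ``kind`` (``experiment`` or
``synthetic``); unknown keys warn rather than fail so configs stay
forward-compatible, while a schema-version mismatch is a hard error.
Every result file embeds a :class:`RunManifest` so outputs are traceable
to a command, config checksum, seed and software version. All fields of
a result other than the manifest timestamp are deterministic functions of
config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Any, Dict, List, Sequence, Union

import yaml

from . import __version__
from .errors import ValidationError
from .simulate import GENERATOR_NAME, ExperimentConfig, PatientProfile
from .stats import ExperimentResult
from .synthetic import SyntheticSpec

logger = logging.getLogger("glycorank")

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunManifest:
    command: str
    config_hash: str
    seed: int
    software_version: str
    generator: str
    timestamp: str

    def as_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)


def config_hash(config: Union[ExperimentConfig, SyntheticSpec]) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()


def make_manifest(command: str, config: Union[ExperimentConfig, SyntheticSpec]) -> RunManifest:
    return RunManifest(
        command=command,
        config_hash=config_hash(config),
        seed=config.seed,
        software_version=__version__,
        generator=GENERATOR_NAME,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


_KINDS = {"experiment": ExperimentConfig, "synthetic": SyntheticSpec}


def load_config(path) -> Union[ExperimentConfig, SyntheticSpec]:
    """Load and validate a YAML config; defaults are applied, unknown keys
    warn, and a wrong ``schema_version`` is an error."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    version = raw.pop("schema_version", None)
    if version != SCHEMA_VERSION:
        raise ValidationError(
            f"{path}: schema_version {version!r} not supported (expected {SCHEMA_VERSION})"
        )
    kind = raw.pop("kind", "experiment")
    if kind not in _KINDS:
        raise ValidationError(f"{path}: unknown config kind {kind!r}")
    cls = _KINDS[kind]
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - fields
    for key in sorted(unknown):
        logger.warning("config %s: ignoring unknown key %r", path, key)
    kwargs = {k: v for k, v in raw.items() if k in fields}
    if cls is ExperimentConfig:
        required = {"target_disease", "pool", "substitutes"}
        missing = required - set(kwargs)
        if missing:
            raise ValidationError(
                f"{path}: missing required fields: {', '.join(sorted(missing))}"
            )
        kwargs["pool"] = tuple(kwargs["pool"])
        kwargs["substitutes"] = tuple(kwargs["substitutes"])
        kwargs.setdefault("m", len(kwargs["substitutes"]))
    config = cls(**kwargs)
    config.validate()
    return config


def save_config(config: Union[ExperimentConfig, SyntheticSpec], path) -> None:
    """Write a config in the YAML dialect :func:`load_config` reads."""
    kind = "experiment" if isinstance(config, ExperimentConfig) else "synthetic"
    doc = {"schema_version": SCHEMA_VERSION, "kind": kind}
    doc.update(dataclasses.asdict(config))
    for key in ("pool", "substitutes"):
        if key in doc:
            doc[key] = list(doc[key])
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def result_to_dict(result: ExperimentResult, manifest: RunManifest) -> Dict[str, Any]:
    return {
        "manifest": manifest.as_dict(),
        "config": {
            **dataclasses.asdict(result.config),
            "pool": list(result.config.pool),
            "substitutes": list(result.config.substitutes),
        },
        "table": [list(row) for row in result.table],
        "rank1_freq": dict(sorted(result.rank1_freq.items())),
        "p_value": result.p_value,
        "p_value_scientific": f"{result.p_value:.6e}",
        "generator": result.generator,
        "per_profile": [list(row) for row in result.per_profile],
    }


def write_result(result: ExperimentResult, path, manifest: RunManifest) -> None:
    """JSON with stable key order, plus a ``.tsv`` per-profile mirror next
    to it. Re-reading the JSON reproduces the 2×2 counts exactly."""
    doc = result_to_dict(result, manifest)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    tsv_path = str(path)
    tsv_path = tsv_path[: -len(".json")] + ".tsv" if tsv_path.endswith(".json") else tsv_path + ".tsv"
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("base_id\tarm\trank_of_target\n")
        for base_id, arm, rank in result.per_profile:
            fh.write(f"{base_id}\t{arm}\t{rank}\n")


def read_result(path) -> Dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_profiles(profiles: Sequence[PatientProfile], path) -> None:
    """Profile TSV: base_id, arm, comma-joined sorted terms, seed record."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("base_id\tarm\tterms\tseed_path\n")
        for p in profiles:
            fh.write(f"{p.base_id}\t{p.arm}\t{','.join(sorted(p.terms))}\t{p.seed_path}\n")


def read_profiles(path) -> List[PatientProfile]:
    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            base_id, arm, terms, seed_path = line.rstrip("\n").split("\t")
            out.append(
                PatientProfile(
                    terms=frozenset(terms.split(",")),
                    base_id=int(base_id),
                    arm=arm,
                    seed_path=seed_path,
                )
            )
    return out
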