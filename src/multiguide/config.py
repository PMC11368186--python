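"""Run configuration: a flat key-value file with sections, strictly
validated (unknown keys are rejected), with CLI flags overriding file
values."""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError
from .guide_search import MatchPolicy, ProximityPolicy, RepeatFilterPolicy

_SCHEMA: dict[str, dict[str, type]] = {
    "genome": {"fasta": str, "chromosomes": str},
    "regions": {"gtf": str, "repeats": str},
    "policy": {
        "guide_len": int,
        "seed_len": int,
        "distal_len": int,
        "max_distal_mm": int,
        "pam": str,
        "require_5prime_g": bool,
        "require_pam_at_hits": bool,
        "max_unit_len": int,
        "min_units": int,
        "min_site_spacing": int,
        "respect_softmask": bool,
    },
    "selection": {
        "n_candidates": int,
        "seed": int,
        "multiplicities": str,
        "out_prefix": str,
    },
}


@dataclass
class RunConfig:
    genome: str
    chromosomes: list[str]
    gtf: str | None = None
    repeats: str | None = None
    n_candidates: int = 10_000
    seed: int = 0
    multiplicities: list[int] = field(default_factory=list)
    out_prefix: str = "multiguide_out"
    respect_softmask: bool = False
    match_policy: MatchPolicy = field(default_factory=MatchPolicy)
    repeat_policy: RepeatFilterPolicy = field(default_factory=RepeatFilterPolicy)
    proximity_policy: ProximityPolicy = field(default_factory=ProximityPolicy)

    def parameter_lines(self) -> list[str]:
        """All parameters as key=value lines for the reproducibility log."""
        lines = [
            f"genome={self.genome}",
            f"gtf={self.gtf}",
            f"repeats={self.repeats}",
            f"chromosomes={','.join(self.chromosomes)}",
            f"n_candidates={self.n_candidates}",
            f"seed={self.seed}",
            f"multiplicities={','.join(map(str, self.multiplicities))}",
            f"out_prefix={self.out_prefix}",
            f"respect_softmask={self.respect_softmask}",
        ]
        for pol in (self.match_policy, self.repeat_policy, self.proximity_policy):
            for k, v in vars(pol).items():
                lines.append(f"{k}={v}")
        return lines


def _coerce(section: str, key: str, raw: str):
    kind = _SCHEMA[section][key]
    if kind is bool:
        low = raw.strip().lower()
        if low in ("1", "true", "yes", "on"):
            return True
        if low in ("0", "false", "no", "off"):
            return False
        raise ConfigurationError(f"[{section}] {key}: not a boolean: {raw!r}")
    if kind is int:
        try:
            return int(raw)
        except ValueError:
            raise ConfigurationError(f"[{section}] {key}: not an integer: {raw!r}")
    return raw.strip()


def load_config(path: str | Path, overrides: dict | None = None) -> RunConfig:
    """Parse and validate a configuration file; *overrides* (flat key ->
    value, from CLI flags) take precedence over file values."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    parser = configparser.ConfigParser()
    try:
        parser.read(path)
    except configparser.Error as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc

    values: dict[str, object] = {}
    for section in parser.sections():
        if section not in _SCHEMA:
            raise ConfigurationError(f"{path}: unknown section [{section}]")
        for key, raw in parser.items(section):
            if key not in _SCHEMA[section]:
                raise ConfigurationError(
                    f"{path}: unknown key {key!r} in section [{section}]"
                )
            values[key] = _coerce(section, key, raw)
    for key, val in (overrides or {}).items():
        if val is not None:
            values[key] = val

    if "fasta" not in values:
        raise ConfigurationError("missing required key 'fasta' in [genome]")
    if "chromosomes" not in values:
        raise ConfigurationError("missing required key 'chromosomes' in [genome]")

    def split_list(raw, conv=str):
        if isinstance(raw, (list, tuple)):
            return [conv(x) for x in raw]
        return [conv(x.strip()) for x in str(raw).split(",") if x.strip()]

    match_policy = MatchPolicy(
        guide_len=int(values.get("guide_len", 20)),
        seed_len=int(values.get("seed_len", 12)),
        distal_len=int(values.get("distal_len", 8)),
        max_distal_mm=int(values.get("max_distal_mm", 2)),
        pam=str(values.get("pam", "NGG")),
        require_5prime_g=bool(values.get("require_5prime_g", True)),
        require_pam_at_hits=bool(values.get("require_pam_at_hits", True)),
    )
    repeat_policy = RepeatFilterPolicy(
        max_unit_len=int(values.get("max_unit_len", 2)),
        min_units=int(values.get("min_units", 4)),
    )
    proximity_policy = ProximityPolicy(
        min_site_spacing=int(values.get("min_site_spacing", 10_000))
    )
    return RunConfig(
        genome=str(values["fasta"]),
        chromosomes=split_list(values["chromosomes"]),
        gtf=values.get("gtf"),
        repeats=values.get("repeats"),
        n_candidates=int(values.get("n_candidates", 10_000)),
        seed=int(values.get("seed", 0)),
        multiplicities=split_list(values.get("multiplicities", ""), int),
        out_prefix=str(values.get("out_prefix", "multiguide_out")),
        respect_softmask=bool(values.get("respect_softmask", False)),
        match_policy=match_policy,
        repeat_policy=repeat_policy,
        proximity_policy=proximity_policy,
    )


def default_config_text() -> str:
    """Defaults in configuration-file form (for --show-defaults)."""
    lines = []
    defaults = {
        "genome": {"fasta": "<path>", "chromosomes": "<name,name,...>"},
        "regions": {"gtf": "<path>", "repeats": "<path>"},
        "policy": {
            "guide_len": 20,
            "seed_len": 12,
            "distal_len": 8,
            "max_distal_mm": 2,
            "pam": "NGG",
            "require_5prime_g": True,
            "require_pam_at_hits": True,
            "max_unit_len": 2,
            "min_units": 4,
            "min_site_spacing": 10000,
            "respect_softmask": False,
        },
        "selection": {
            "n_candidates": 10000,
            "seed": 0,
            "multiplicities": "2,4,6,8",
            "out_prefix": "multiguide_out",
        },
    }
    for section, keys in defaults.items():
        lines.append(f"[{section}]")
        for k, v in keys.items():
            lines.append(f"{k} = {v}")
        lines.append("")
    return "\n".join(lines)
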