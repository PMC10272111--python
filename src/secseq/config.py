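"""Pipeline configuration: defaults, YAML loading, strict validation.

All analysis knobs live in one flat :class:`PipelineConfig`. Unknown keys in a
YAML file are rejected (typos must not silently fall back to defaults), and
every violation is reported at once rather than one at a time.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Raised when a configuration file violates the schema.

    ``violations`` holds one human-readable message per offending key.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid configuration:\n" + "\n".join(f"  - {v}" for v in violations)
        )


@dataclass
class PipelineConfig:
    """Tunable parameters of the SEC-seq analysis.

    Parameters
    ----------
    quantile
        Quantile of the non-IgG (IGHM/IGHA) secretion-barcode null
        distribution that defines the SEC-hi cutoff. The low cutoff is
        mirrored about the null mean.
    r_min
        Minimum per-donor Pearson correlation for a gene to count as a
        cross-donor consensus surrogate marker.
    bin_width
        Pseudotime bin width for the secretor-fraction profile.
    fdr_alpha
        Benjamini-Hochberg significance level for differential expression.
    target_sum
        Per-cell depth normalization target before log1p.
    """

    quantile: float = 0.90
    r_min: float = 0.10
    bin_width: float = 0.05
    fdr_alpha: float = 0.10
    target_sum: float = 1e4
    min_genes_per_cell: int = 200
    min_counts_per_cell: int = 500
    sec_feature: str = "SEC-IgG"
    nanovial_feature: str = "Nanovial"
    min_null_cells: int = 50
    min_bin_cells: int = 10
    top_k: int = 40
    per_donor_gates: bool = False
    fallback_gate_quantile: float = 0.5
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


_RANGE_CHECKS: dict[str, tuple[float, float, bool]] = {
    # key: (low, high, endpoints allowed)
    "quantile": (0.5, 1.0, False),
    "r_min": (0.0, 1.0, True),
    "bin_width": (0.0, 1.0, False),
    "fdr_alpha": (0.0, 1.0, False),
    "fallback_gate_quantile": (0.0, 1.0, True),
}


def _validate(raw: Mapping[str, Any]) -> PipelineConfig:
    known = {f.name: f.type for f in fields(PipelineConfig)}
    violations: list[str] = []
    for key in raw:
        if key not in known:
            violations.append(f"unknown key: {key!r}")
    clean: dict[str, Any] = {}
    for key, value in raw.items():
        if key not in known:
            continue
        if key in _RANGE_CHECKS:
            lo, hi, closed = _RANGE_CHECKS[key]
            ok = isinstance(value, (int, float)) and not isinstance(value, bool)
            if ok:
                ok = (lo <= value <= hi) if closed else (lo < value < hi)
            if not ok:
                bounds = f"[{lo}, {hi}]" if closed else f"({lo}, {hi})"
                violations.append(f"{key}: {value!r} not a number in {bounds}")
                continue
        if key in ("min_genes_per_cell", "min_counts_per_cell", "min_null_cells",
                   "min_bin_cells", "top_k", "seed"):
            if not isinstance(value, int) or isinstance(value, bool) or value < 0:
                violations.append(f"{key}: {value!r} not a non-negative integer")
                continue
        if key == "target_sum":
            if not isinstance(value, (int, float)) or value <= 0:
                violations.append(f"target_sum: {value!r} not a positive number")
                continue
        if key in ("sec_feature", "nanovial_feature") and not isinstance(value, str):
            violations.append(f"{key}: {value!r} not a string")
            continue
        if key == "per_donor_gates" and not isinstance(value, bool):
            violations.append(f"per_donor_gates: {value!r} not a boolean")
            continue
        clean[key] = value
    if violations:
        raise ConfigError(violations)
    return PipelineConfig(**clean)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML configuration file, filling defaults.

    An empty (or absent) file yields the full default configuration. Unknown
    keys and out-of-range values raise :class:`ConfigError` listing every
    violation.
    """
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        return PipelineConfig()
    if not isinstance(raw, Mapping):
        raise ConfigError([f"top level must be a mapping, got {type(raw).__name__}"])
    return _validate(raw)
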