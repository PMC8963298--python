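"""Pipeline parameters and the flat key=value parameter file.

The parameter-file grammar (one ``key=value`` per line, ``#`` comments)
and the key names are defined by this package; see the README for the
documented key set.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["PipelineConfig", "read_config", "write_config"]

PCA_OUTLIER_MODES = ("leave", "to_na", "winsorize")


@dataclass
class PipelineConfig:
    """User-tunable thresholds plus fixed internal settings.

    The first nine fields are the user parameters accepted in the
    parameter file (together with ``rng_seed``). ``extreme_missingness``
    and ``pc_min_components`` are fixed internal settings and are not
    accepted as parameter-file keys.
    """

    feature_missingness_max: float = 0.2
    sample_missingness_max: float = 0.2
    tsa_sd_threshold: float = 5.0
    outlier_iqr_multiplier: float = 5.0
    pca_outlier_mode: str = "leave"
    tree_cut_height: float = 0.5
    pc_sd_threshold: float = 5.0
    exclude_derived: bool = False
    batch_normalization_column: str | None = None
    rng_seed: int = 1234

    # fixed internal settings
    extreme_missingness: float = 0.8
    pc_min_components: int = 2

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for key in ("feature_missingness_max", "sample_missingness_max"):
            v = getattr(self, key)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{key} must be a fraction in [0, 1], got {v}")
        for key in ("tsa_sd_threshold", "outlier_iqr_multiplier", "pc_sd_threshold"):
            v = getattr(self, key)
            if not v > 0:
                raise ValueError(f"{key} must be > 0, got {v}")
        if not (0.0 < self.tree_cut_height <= 1.0):
            raise ValueError(
                f"tree_cut_height must be in (0, 1], got {self.tree_cut_height}"
            )
        if self.pca_outlier_mode not in PCA_OUTLIER_MODES:
            raise ValueError(
                f"pca_outlier_mode must be one of {PCA_OUTLIER_MODES}, "
                f"got {self.pca_outlier_mode!r}"
            )
        if not isinstance(self.exclude_derived, bool):
            raise ValueError("exclude_derived must be boolean")
        self.rng_seed = int(self.rng_seed)


# keys accepted in the parameter file, with their parsers
def _as_bool(s: str) -> bool:
    low = s.strip().lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no"):
        return False
    raise ValueError(f"expected TRUE/FALSE, got {s!r}")


def _as_optional_str(s: str):
    s = s.strip()
    return s if s and s.lower() not in ("none", "na") else None


_PARSERS = {
    "feature_missingness_max": float,
    "sample_missingness_max": float,
    "tsa_sd_threshold": float,
    "outlier_iqr_multiplier": float,
    "pca_outlier_mode": str.strip,
    "tree_cut_height": float,
    "pc_sd_threshold": float,
    "exclude_derived": _as_bool,
    "batch_normalization_column": _as_optional_str,
    "rng_seed": int,
}

DOCUMENTED_KEYS = tuple(_PARSERS)


def read_config(path) -> PipelineConfig:
    """Parse a flat ``key=value`` parameter file into a :class:`PipelineConfig`.

    Missing keys take their documented defaults; unknown keys are an error.
    """
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in _PARSERS:
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
        if key in values:
            raise ValueError(f"{path}:{lineno}: duplicate parameter {key!r}")
        try:
            values[key] = _PARSERS[key](val)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad value for {key!r}: {exc}") from exc
    return PipelineConfig(**values)


def write_config(config: PipelineConfig, path) -> None:
    lines = []
    for f in fields(config):
        if f.name in ("extreme_missingness", "pc_min_components"):
            continue
        v = getattr(config, f.name)
        if v is None:
            v = ""
        elif isinstance(v, bool):
            v = "TRUE" if v else "FALSE"
        lines.append(f"{f.name}={v}")
    Path(path).write_text("\n".join(lines) + "\n")
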