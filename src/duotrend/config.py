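"""Pipeline configuration: a flat key-value file plus validated defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and coding for a full pipeline run.

    Thresholds: ``alpha`` is the family-wise significance level applied to
    Holm-adjusted p-values; ``fdr_q`` the (liberal) FDR threshold applied to
    BH q-values, used for the cross-platform concordance classification.
    ``age_codes`` are the coded values of the ordered age groups,
    strictly increasing, spanning one unit per year by convention.
    """

    mrna_path: str | None = None
    protein_path: str | None = None
    metadata_path: str | None = None
    phenotype_path: str | None = None
    reference_path: str | None = None
    out_dir: str = "duotrend_out"
    alpha: float = 0.05
    fdr_q: float = 0.1
    age_codes: tuple = (-0.5, 0.0, 0.5)
    rank_offset: float = 0.5
    seed: int = 0
    pca_components: int = 4

    def validate(self) -> None:
        for name in ("alpha", "fdr_q"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        codes = tuple(float(c) for c in self.age_codes)
        if any(b <= a for a, b in zip(codes, codes[1:])):
            raise ValueError(f"age codes must be strictly increasing, got {codes}")
        if not (0.0 <= self.rank_offset <= 0.5):
            raise ValueError(f"rank offset must lie in [0, 0.5], got {self.rank_offset}")
        if int(self.seed) != self.seed or self.seed < 0:
            raise ValueError(f"seed must be a non-negative integer, got {self.seed}")
        if self.pca_components < 1:
            raise ValueError("pca_components must be >= 1")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a flat ``key = value`` text file ('#' starts a comment)."""
        kwargs = {}
        valid = {f.name: f.type for f in fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in valid:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = _coerce(key, value)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _coerce(key: str, value: str):
    if key == "age_codes":
        return tuple(float(v) for v in value.replace(",", " ").split())
    if key in ("alpha", "fdr_q", "rank_offset"):
        return float(value)
    if key in ("seed", "pca_components"):
        return int(value)
    if value.lower() in ("none", ""):
        return None
    return value
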