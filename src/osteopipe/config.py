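"""Analysis configuration: every tunable threshold of the pipeline in one place.

Defaults are the study conditions: FDR < 0.05 with |log2FC| > 1 for the
strict differential-expression pass, the 0.25-in-2-samples expression
filter, rank-overlap step 200, 500 permutation iterations, 1000-UMI and
10%-mitochondrial QC cutoffs, and the basal-plus-extension regulatory
domain parameters (5 kb upstream, 1 kb downstream, 1 Mb cap).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path


@dataclass
class AnalysisConfig:
    fdr_threshold: float = 0.05
    log2fc_threshold: float = 1.0
    expr_filter_min: float = 0.25
    expr_filter_min_samples: int = 2
    rrho_step: int = 200
    perm_iterations: int = 500
    umi_cutoff: int = 1000
    mito_cutoff: float = 0.10
    marker_logfc_min: float = 0.02
    top_k_brain: int = 150
    top_k_nosology: int = 400
    basal_upstream: int = 5000
    basal_downstream: int = 1000
    max_extension: int = 1_000_000
    promoter_window: int = 3000
    random_seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "fdr_threshold", "log2fc_threshold", "expr_filter_min", "rrho_step",
            "umi_cutoff", "mito_cutoff", "basal_upstream", "basal_downstream",
            "max_extension",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.perm_iterations < 1:
            raise ValueError("perm_iterations must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Read a flat ``key = value`` text file; unknown keys are rejected."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value, got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            caster = float if known[key] in ("float", float) else int
            kwargs[key] = caster(value)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")
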