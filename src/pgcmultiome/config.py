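"""Pipeline and simulation configuration.

Every analysis threshold is a named field with the workflow's published
default; all of them can be overridden from a nested YAML config file so the
defaults are starting points, not constants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import ValidationError


@dataclass
class PipelineConfig:
    """All tunable thresholds of the analysis pipeline.

    QC bounds are strict inequalities (a cell at exactly a bound is
    excluded). ``chrY_region`` bounds the Y-chromosome peak region used for
    fragment-based sexing, excluding the pseudoautosomal region.
    """

    # RNA cell QC
    rna_count_min: float = 1000
    rna_count_max: float = 25000
    pct_mito_max: float = 25.0
    # ATAC cell QC
    atac_count_min: float = 1000
    atac_count_max: float = 100000
    nucleosome_signal_max: float = 2.0
    tss_enrichment_min: float = 1.0
    # peak filtering
    peak_width_min: int = 20
    peak_width_max: int = 10000
    # differential testing
    de_min_pct: float = 0.25
    de_logfc: float = 0.25
    dap_min_pct: float = 0.001
    dap_logfc: float = 0.1
    alpha: float = 0.05
    # peak-gene linkage
    link_distance: int = 500000
    link_p: float = 0.05
    n_background: int = 200
    # peak annotation
    tss_region: tuple[int, int] = (-3000, 3000)
    # sexing
    chrY_region: tuple[int, int] = (1, 90000000)
    y_genes: tuple[str, ...] = ("Kdm5d", "Eif2s3y", "Uty", "Ddx3y")
    rank_ceiling: int = 1500
    # clustering / reduction
    n_hvg: int = 2000
    n_pcs: int = 50
    rna_dims: int = 18
    lsi_dims: int = 30
    knn_k: int = 20
    resolution: float = 0.3
    # motif analysis
    motif_threshold_frac: float = 0.8
    chromvar_iterations: int = 50
    # cell-cell communication
    permutations: int = 1000
    lr_min_frac: float = 0.1
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        pairs = [
            ("rna_count_min", "rna_count_max"),
            ("atac_count_min", "atac_count_max"),
            ("peak_width_min", "peak_width_max"),
        ]
        for lo, hi in pairs:
            if getattr(self, lo) >= getattr(self, hi):
                raise ValidationError(f"{lo} must be < {hi}")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.tss_region[0] >= self.tss_region[1]:
            raise ValidationError("tss_region min must be < max")
        if self.chrY_region[0] >= self.chrY_region[1]:
            raise ValidationError("chrY_region min must be < max")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("tss_region", "chrY_region", "y_genes"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data.get("pipeline", data))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# Marker panels for the count-based cell-type triage. Names follow the mouse
# fetal gonad markers the triage was designed around; the synthetic generator
# plants genes under the same names.
DEFAULT_MARKERS = {
    "germ_positive": ["Ddx4", "Pou5f1"],
    "soma_exclusion": [
        "Foxl2",
        "Runx1",
        "Sox9",
        "Insl3",
        "Wt1",
        "Plvap",
        "Mafb",
        "Pdgfra",
        "Nr2f2",
        "Tspan8",
        "Krt19",
    ],
    "supporting_positive": ["Wt1"],
    "supporting_exclusion": [
        "Ddx4",
        "Pou5f1",
        "Plvap",
        "Pecam1",
        "Pdgfra",
        "Nr2f2",
    ],
}
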