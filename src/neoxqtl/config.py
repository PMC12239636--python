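"""Run configuration: validated, serializable, reproducible from seed."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimStage(_Strict):
    enabled: bool = True
    n_f2: int = 181
    n_markers: int = 822
    n_families: int = 15
    genotype_error_rate: float = 0.001
    missing_rate: float = 0.05
    neoy_contamination_rate: float = 0.10
    viability_survival: float = 0.0
    viability_region: tuple[int, int] = (26_900_000, 49_000_000)
    with_inversions: bool = True
    qtl_mean_az_hemi: float = 149.0
    qtl_mean_ut_hemi: float = 76.0
    qtl_mean_het_female: float = 90.0
    qtl_mean_ut_female: float = 76.0
    qtl_resid_sd: float = 10.0
    qtl_pos_bp: int = 58_300_000


class QcStage(_Strict):
    gq_min: float = 30
    dp_min: float = 20
    marker_missing_max: float = 0.68
    individual_missing_max: float = 0.99
    min_gap_bp: int = 100_000
    distortion_alpha: float = 0.01


class MapStage(_Strict):
    error_prob: float = 0.001
    map_function: str = "haldane"
    error_lod_cutoff: float | None = 4.0
    validate_order: bool = False
    sex_specific: bool = True


class ScanStage(_Strict):
    phenotypes: list[str] = ["generation_time", "body_size"]
    step_cm: float = 1.0
    n_perm: int = 1000
    alpha: float = 0.05
    x_specific: bool = True
    error_prob: float = 0.001
    bayes_prob: float = 0.95
    sex_adjust_autosomes: bool = False


class MareyStage(_Strict):
    min_run: int = 11
    span: float = 0.7
    degree: int = 2
    density_window_bp: int = 500_000


class XoStage(_Strict):
    n_tests: int = 12
    focal_region: tuple[int, int] = (26_900_000, 49_000_000)
    ancestral_start_bp: int = 48_000_000
    exclude_prefix_bp: int = 25_000_000


class CoverageStage(_Strict):
    window_bp: int = 50_000
    hemizygous_max: float = 0.6
    similar_min: float = 0.85
    min_run: int = 5


class RunConfig(_Strict):
    """Full pipeline configuration; unknown keys are rejected."""

    seed: int = 1
    x_chrom: str = "X"
    log_level: str = "INFO"
    vcf: str | None = None
    sample_sheet: str | None = None
    phenotype_table: str | None = None
    annotation: str | None = None
    depth_male: str | None = None
    depth_female: str | None = None
    p0_az_id: str = "P0_AZ_male"
    p0_ut_id: str = "P0_UT_female"
    simulate: SimStage = SimStage()
    qc: QcStage = QcStage()
    linkmap: MapStage = MapStage()
    scan: ScanStage = ScanStage()
    marey: MareyStage = MareyStage()
    xo: XoStage = XoStage()
    coverage: CoverageStage = CoverageStage()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
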