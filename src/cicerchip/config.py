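"""Pipeline configuration with the study's printed thresholds as defaults.

Unknown keys are rejected (pydantic ``extra="forbid"``).  Every threshold
default equals the value the workflow publishes: MAF >= 0.05, GC 40-70%,
QUAL >= 30, conversion score >= 0.3, DQC >= 0.82, call rate >= 97%,
FLD >= 3.6, HetSO >= -0.1, HetSO-OTV >= -0.3, HomRO >= 0.6 / 0.3,
rf <= 0.35 with LOD >= 6, segregation test at P < 0.01, and 1000
permutations at alpha = 0.05 for the QTL LOD threshold.
"""

from __future__ import annotations

import yaml
from pydantic import BaseModel, ConfigDict


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Section):
    n_chrom: int = 8
    chrom_length: int = 200_000
    gene_count: int = 40
    ssr_count: int = 20
    gc_target: float = 0.5
    n_accessions: int = 429
    snp_rate: float = 1.25e-3
    indel_rate: float = 5e-5
    maf_alpha: float = 0.8
    maf_beta: float = 0.8
    n_ril: int = 150
    residual_het_rate: float = 0.02
    missing_rate: float = 0.005
    markers_per_group: int = 12
    marker_spacing_cm: float = 5.0
    cluster_separation: float = 10.0
    otv_fraction: float = 0.0
    dqc_low_fraction: float = 0.02
    n_monomorphic: int = 50
    traits: dict[str, list[tuple[str, float, float]]] = {
        "trait1": [("G01", 25.0, 1.0)],
        "trait2": [("G03", 30.0, 1.0), ("G05", 10.0, 0.7)],
    }
    sigma: float = 1.0
    environments: list[tuple[str, str, float]] = [
        ("L1", "2016", 0.0),
        ("L2", "2016", 0.0),
        ("L1", "2017", 0.0),
    ]


class DesignConfig(_Section):
    maf_min: float = 0.05
    gc_min: float = 0.40
    gc_max: float = 0.70
    qual_min: float = 30.0
    score_min: float = 0.3
    flank: int = 35


class QcConfig(_Section):
    dqc_min: float = 0.82
    sample_cr_min: float = 0.97
    snp_cr_min: float = 0.97
    fld_min: float = 3.6
    hom_fld_min: float = 6.5
    het_so_min: float = -0.1
    het_so_otv_min: float = -0.3
    hom_ro_1_min: float = 0.6
    hom_ro_2_min: float = 0.3
    minor_hom_min: int = 2
    var_x_max: float = 0.25
    var_y_max: float = 0.25
    inbred_penalty: int = 12


class MapConfig(_Section):
    rf_max: float = 0.35
    lod_min: float = 6.0
    seg_alpha: float = 0.01
    min_group_size: int = 2


class QtlConfig(_Section):
    p_in: float = 0.001
    p_out: float = 0.002
    n_perm: int = 1000
    alpha: float = 0.05
    step_cm: float = 1.0
    merge_cm: float = 5.0
    support_drop: float = 1.0
    robust_pve: float = 10.0
    co_window_cm: float = 10.0


class StagesConfig(_Section):
    simulate: bool = True
    design: bool = True
    qc: bool = True
    map: bool = True
    qtl: bool = True


class PipelineConfig(_Section):
    seed: int = 1
    stages: StagesConfig = StagesConfig()
    simulate: SimulateConfig = SimulateConfig()
    design: DesignConfig = DesignConfig()
    qc: QcConfig = QcConfig()
    map: MapConfig = MapConfig()
    qtl: QtlConfig = QtlConfig()

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


#: The workflow's published threshold values, asserted by the config self-test.
PAPER_DEFAULTS = {
    ("design", "maf_min"): 0.05,
    ("design", "gc_min"): 0.40,
    ("design", "gc_max"): 0.70,
    ("design", "qual_min"): 30.0,
    ("design", "score_min"): 0.3,
    ("design", "flank"): 35,
    ("qc", "dqc_min"): 0.82,
    ("qc", "sample_cr_min"): 0.97,
    ("qc", "snp_cr_min"): 0.97,
    ("qc", "fld_min"): 3.6,
    ("qc", "het_so_min"): -0.1,
    ("qc", "het_so_otv_min"): -0.3,
    ("qc", "hom_ro_1_min"): 0.6,
    ("qc", "hom_ro_2_min"): 0.3,
    ("qc", "inbred_penalty"): 12,
    ("map", "rf_max"): 0.35,
    ("map", "lod_min"): 6.0,
    ("map", "seg_alpha"): 0.01,
    ("qtl", "n_perm"): 1000,
    ("qtl", "alpha"): 0.05,
    ("qtl", "robust_pve"): 10.0,
}


def assert_paper_defaults(config: PipelineConfig | None = None) -> None:
    """Verify that every published threshold default is in place."""
    cfg = config or PipelineConfig()
    for (section, key), expected in PAPER_DEFAULTS.items():
        actual = getattr(getattr(cfg, section), key)
        if actual != expected:
            raise AssertionError(
                f"{section}.{key} = {actual!r}, expected published default "
                f"{expected!r}"
            )
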