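"""Pipeline configuration with field-standard parameter names and defaults."""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any


@dataclasses.dataclass
class PipelineConfig:
    """All tunable parameters of the quantification pipeline.

    MBR parameters follow the conventional names: up to ``mbr_top_runs``
    donor runs per acceptor with pairwise correlation above
    ``mbr_min_corr``; the retention-time pairing window is
    ``mbr_rt_window`` minutes and the ion-mobility window ``mbr_im_window``
    1/K0.  Transfer FDR is controlled at ion, peptide and protein level.
    """

    # -- MBR donor selection / region finding
    mbr: bool = True
    mbr_top_runs: int = 10
    mbr_min_corr: float = 0.0
    mbr_rt_window: float = 1.0     # tau, min
    mbr_im_window: float = 0.05    # tau, 1/K0
    # -- transfer FDR
    ion_fdr: float = 0.01
    peptide_fdr: float = 0.01
    protein_fdr: float = 0.01
    lda_min_class: int = 20
    em_min_scores: int = 100
    em_max_iter: int = 1000
    em_tol: float = 1e-8
    em_true_components: int = 2  # Gaussian sub-components of the true population
    kde_null: bool = True          # kernel-density decoy null (Gaussian if False)
    kl_floor: float = 1e-6
    lambda_coef: float = 4.9384e-4
    rt_diff_reference: str = "aligned"  # "aligned" (d_i + m) or "donor" (raw donor RT)
    # -- peak tracing
    ppm_tolerance: float = 10.0
    msms_rt_halfwidth: float = 0.4  # min, window around a PSM's RT for seeding
    boundary_fraction: float = 0.01
    smooth_window: int = 7
    smooth_polyorder: int = 2
    resample_interval: float | None = None  # min; None -> median raw spacing
    rt_pad: float = 0.3             # min, boundary extension beyond the query region
    min_rt_halfwidth: float = 0.1   # min, floor on query half-width
    min_im_halfwidth: float = 0.025
    # -- normalization / protein roll-up
    normalize: bool = True
    min_ions: int = 2
    # -- misc
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
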