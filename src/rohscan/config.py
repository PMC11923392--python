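"""Run configuration: every stage tunable in one serializable object.

Defaults reproduce the pipeline's standard settings (GQ/depth masking
at 30/6, MAC 3, 70% site call rate, HDplot |D| <= 5, 1-kb thinning,
MAF 0.01/0.05 panels, 10%/20% individual missingness, 50-SNP ROH
windows with 5-Mb minimum runs, 100 bootstrap iterations, 10,000 F_ST
loci, POD-calibrated scan thresholds with 20 dB decisive evidence).
A single master seed drives every stochastic stage; per-stage seeds
are derived deterministically from it.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import numpy as np
import yaml

from .qc import QCParams
from .roh import ROHParams


@dataclass
class MaskParams:
    min_window_bp: int = 1000


@dataclass
class DiversityParams:
    n_boot: int = 100
    window_bp: int = 5_000_000
    subsample_k: int = 9
    n_reps: int = 100
    unbiased: bool = True  # 2n/(2n-1) gene-diversity correction


@dataclass
class FstParams:
    n_loci: int = 10_000
    clamp_negative: bool = False


@dataclass
class ScanParams:
    n_pod_snps: int = 100_000
    bf_threshold_db: float = 20.0
    beta_max: float = 0.3


@dataclass
class RunConfig:
    seed: int = 0
    qc: QCParams = field(default_factory=QCParams)
    roh: ROHParams = field(default_factory=ROHParams)
    mask: MaskParams = field(default_factory=MaskParams)
    diversity: DiversityParams = field(default_factory=DiversityParams)
    fst: FstParams = field(default_factory=FstParams)
    scan: ScanParams = field(default_factory=ScanParams)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        mix = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return int(mix.generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs: dict = {}
        for f in fields(cls):
            if f.name not in data:
                continue
            value = data[f.name]
            typ = {
                "qc": QCParams,
                "roh": ROHParams,
                "mask": MaskParams,
                "diversity": DiversityParams,
                "fst": FstParams,
                "scan": ScanParams,
            }.get(f.name)
            kwargs[f.name] = typ(**value) if typ and isinstance(value, dict) else value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
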