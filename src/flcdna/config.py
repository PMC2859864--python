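"""Run configuration: every numeric threshold of the pipeline in one place.

Defaults are the study criteria the filters implement (E-value cut-offs
1e-180 / 1e-50 / 1e-30 / 1e-10, identity 97%, mutual coverage 80%, mapping
identity/coverage 90%, SNP identity floor 99.5%, Q30 trimming, 50 nt
minimum read length, 10% homopolymer rule, 10 aa minimum protein).  A
YAML config file and command-line flags override them; precedence is
CLI > file > defaults.  The effective config is serialized into every
output directory for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .curation import CurationThresholds
from .spliced import SplicedParams


@dataclass
class RunConfig:
    seed: int = 1
    n_genes: int = 60
    outdir: str = "flcdna_out"
    threads: int = 1                    # scheduling only; never results

    # read preprocessing
    quality_min: float = 30.0
    min_read_len: int = 50
    homopolymer_frac: float = 0.10

    # curation thresholds
    redundancy_evalue: float = 1e-180
    redundancy_identity: float = 0.97
    redundancy_coverage: float = 0.80
    ncrna_evalue: float = 1e-180
    pathogen_evalue: float = 1e-30
    chimera_evalue: float = 1e-50
    group_evalue: float = 1e-50

    # CDS selection
    protein_evalue: float = 1e-10
    min_protein_aa: int = 10

    # spliced alignment / mapping
    min_intron: int = 60
    intron_penalty: int = 40
    noncanonical_extra: int = 20
    map_evalue: float = 1e-50
    map_identity: float = 0.90
    map_coverage: float = 0.90
    map_margin: int = 2000              # 12 kb covers real-data introns;
                                        # simulated introns are < 2 kb
    snp_identity_floor: float = 0.995

    def __post_init__(self):
        if not (0 <= self.redundancy_identity <= 1):
            raise ValueError("redundancy_identity outside [0, 1]")
        if not (0 <= self.map_identity <= 1 and 0 <= self.map_coverage <= 1):
            raise ValueError("mapping thresholds outside [0, 1]")
        if self.min_intron < 20:
            raise ValueError("min_intron must be >= 20")

    def curation_thresholds(self) -> CurationThresholds:
        return CurationThresholds(
            redundancy_evalue=self.redundancy_evalue,
            redundancy_identity=self.redundancy_identity,
            redundancy_coverage=self.redundancy_coverage,
            ncrna_evalue=self.ncrna_evalue,
            pathogen_evalue=self.pathogen_evalue,
            chimera_evalue=self.chimera_evalue,
            group_evalue=self.group_evalue)

    def spliced_params(self) -> SplicedParams:
        return SplicedParams(min_intron=self.min_intron,
                             intron_penalty=self.intron_penalty,
                             noncanonical_extra=self.noncanonical_extra)

    @classmethod
    def load(cls, path=None, **overrides) -> "RunConfig":
        data: dict = {}
        if path is not None:
            with open(path) as fh:
                loaded = yaml.safe_load(fh) or {}
            known = {f.name for f in fields(cls)}
            bad = set(loaded) - known
            if bad:
                raise ValueError(f"unknown config keys: {sorted(bad)}")
            data.update(loaded)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def dump(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
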