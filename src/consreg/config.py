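"""Run configuration shared by the CLI subcommands.

Defaults follow the pipeline's published operating point: broad peaks
filtered at p < 0.01, TSS score >= 10, 1 kb TSS windows, the at-least-two
rules for experiments and cell lines, TBA cutoffs 5e-02..1e-05 with 1e-05 as
the stringent default, PFM quality filters (>=50 sites, enriched in <=50% of
CREs), the >1% common-allele threshold, and 100K background regions (a
5,000-region profile covers desk-scale testing).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    peak_format: str = "narrow"
    broad_pvalue_max: float = 0.01
    tss_min_score: float = 10.0
    tss_window: int = 1000
    min_experiments: int = 2
    min_cell_lines: int = 2
    tba_cutoffs: tuple[float, ...] = (5e-02, 1e-02, 1e-03, 1e-04, 1e-05)
    default_cutoff: float = 1e-05
    pfm_min_sequences: int = 50
    pfm_max_cre_fraction: float = 0.50
    pfm_pseudocount: float = 1.0
    common_af_threshold: float = 0.01
    n_background_regions: int = 100_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "tba_cutoffs" in data:
            data["tba_cutoffs"] = tuple(float(x) for x in data["tba_cutoffs"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tba_cutoffs"] = list(self.tba_cutoffs)
        return d
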