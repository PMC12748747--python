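"""Run configuration binding every pipeline stage together."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

from .duplex import FilterParams
from .simulate import KineticsModel
from .substrate import DEFAULT_WINDOW

MODES = ("simulate", "analyze", "quantify", "all")


@dataclass
class RunConfig:
    substrate: str = "gt5"  # demo name or path to a YAML/JSON substrate config
    mode: str = "all"
    outdir: str = "duplexrepair_out"
    seed: int = 1

    # kinetics
    kinetics_mode: str = "parallel_independent"
    k_top: float = 0.2
    k_bottom: float = 0.2
    k_second: float = 0.1
    first_strand: str = "top"
    insertion_probs: Dict[str, float] = field(default_factory=lambda: {"direct": 1.0})
    p_ribo: float = 0.0
    k_rer: float = 0.0
    harvest_time: float = 10.0

    # library
    n_molecules: int = 500
    oversampling_mean: float = 30.0
    error_rate: float = 0.0
    umi_length: int = 10
    barcode: str = "ACGTAC"
    sample: str = "s1"
    max_phasing: int = 5

    # substrate products
    insertion_labels: List[str] = field(default_factory=list)
    window: int = DEFAULT_WINDOW

    # analysis
    min_family_fraction: float = 0.02
    min_strand_fraction: float = 0.20
    n_input_templates: Optional[int] = None  # defaults to n_molecules in simulate mode
    max_edit: int = 1
    umi_clustering: bool = False

    # analyze-only inputs
    fastq: Optional[str] = None
    # quantify inputs
    qpcr_csv: Optional[str] = None
    dpcr_csv: Optional[str] = None
    timepoint: Optional[float] = None

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.mode == "analyze" and not self.fastq:
            raise ValueError("analyze mode requires a fastq input")
        # delegate detailed validation to the domain types
        self.kinetics()
        self.filter_params()

    def kinetics(self) -> KineticsModel:
        return KineticsModel(
            mode=self.kinetics_mode,
            k_top=self.k_top,
            k_bottom=self.k_bottom,
            k_second=self.k_second,
            first_strand=self.first_strand,
            insertion_probs=dict(self.insertion_probs),
            p_ribo=self.p_ribo,
            k_rer=self.k_rer,
        )

    def filter_params(self) -> FilterParams:
        return FilterParams(
            min_family_fraction=self.min_family_fraction,
            min_strand_fraction=self.min_strand_fraction,
            n_input_templates=self.n_input_templates or self.n_molecules,
        )

    def as_dict(self) -> Dict:
        return asdict(self)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import json

        import yaml

        path = Path(path)
        with open(path) as handle:
            data = (
                yaml.safe_load(handle)
                if path.suffix in (".yaml", ".yml")
                else json.load(handle)
            )
        return cls.from_mapping(data or {})
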