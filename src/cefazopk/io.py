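"""Dataset and results I/O plus run configuration.

The dataset dialect is a NONMEM-style CSV: mandatory columns ``ID, TIME,
DV, AMT, EVID, MDV`` (TIME in minutes, DV in mg/L, AMT in mg; EVID 1 =
dose, 0 = observation; MDV 1 = missing DV) plus the covariate columns,
dot-decimal regardless of locale.  Result CSVs carry a comment header
with the package version, the seed and a hash of the configuration so a
run can be traced back to its inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec
from .dataset import ALL_COLUMNS, EVENT_COLUMNS, DatasetError, PKDataset
from .model import PARAM_NAMES, PopulationModel, reference_model

__all__ = ["read_dataset", "write_dataset", "RunConfig", "load_config",
           "write_table", "config_hash", "model_from_config"]


def read_dataset(path) -> PKDataset:
    """Read and validate a long-format dataset CSV.

    Comment lines starting with ``#`` are ignored.  Raises
    :class:`~cefazopk.dataset.DatasetError` naming the offending rows or
    columns when validation fails.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing mandatory columns {missing}")
    if "BLQ" not in df.columns:
        df["BLQ"] = 0
    return PKDataset(df)


def write_dataset(data: PKDataset, path, *, seed: Optional[int] = None,
                  cfg_hash: Optional[str] = None) -> None:
    """Write a dataset in the CSV dialect (round-trips with read_dataset)."""
    _write_with_header(data.df, path, seed=seed, cfg_hash=cfg_hash)


def _write_with_header(df: pd.DataFrame, path, *, seed=None, cfg_hash=None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# cefazopk {__version__}")
        if seed is not None:
            fh.write(f" seed={seed}")
        if cfg_hash is not None:
            fh.write(f" config={cfg_hash}")
        fh.write("\n")
        df.to_csv(fh, index=False)


def write_table(df: pd.DataFrame, path, *, seed=None, cfg_hash=None) -> None:
    """Write a results table CSV with the provenance comment header."""
    _write_with_header(df, path, seed=seed, cfg_hash=cfg_hash)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run (YAML or JSON on disk)."""

    output_dir: str = "results"
    dataset_path: Optional[str] = None        # None: simulate the cohort
    seed: int = 0
    log_level: str = "INFO"

    # model block
    covariate_mode: str = "natural_additive"
    egfr_unit_scale: float = 1.0
    fixed_model: bool = False                 # True: skip estimation, use values below
    model_values: Optional[Dict] = None       # overrides for reference_model fields

    # cohort block (only fields that differ from the study defaults)
    cohort: Dict = field(default_factory=dict)

    # estimation block
    estimation: Dict = field(default_factory=dict)   # SAEMSettings fields
    n_bootstrap: int = 500
    ofv_nmc: int = 1000
    run_bootstrap: bool = True
    run_stepwise: bool = True

    # simulation block
    mic_grid: tuple = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0)
    pta_window_min: float = 407.0
    pta_n_subjects: int = 65
    pta_n_replicates: int = 500
    redose_mics: tuple = (1.5, 2.0, 3.0, 4.0)
    redose_coverage: float = 0.90
    vpc_nsim: int = 1000

    def __post_init__(self):
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a non-negative integer")
        if self.dataset_path is not None and not Path(self.dataset_path).exists():
            raise FileNotFoundError(self.dataset_path)
        self.mic_grid = tuple(self.mic_grid)
        self.redose_mics = tuple(self.redose_mics)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(**self.cohort)


def load_config(path) -> RunConfig:
    """Load a YAML or JSON config file into a validated RunConfig."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def config_hash(cfg: RunConfig) -> str:
    """Short digest of the scientific configuration (paths excluded, so the
    same analysis written to a different directory hashes identically)."""
    payload = asdict(cfg)
    payload.pop("output_dir", None)
    payload.pop("log_level", None)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def model_from_config(cfg: RunConfig) -> PopulationModel:
    """The model implied by the config: the reference estimates, the chosen
    covariate mode/eGFR scale, and any explicit value overrides."""
    m = reference_model(covariate_mode=cfg.covariate_mode,
                        egfr_unit_scale=cfg.egfr_unit_scale)
    if cfg.model_values:
        vals = dict(cfg.model_values)
        pops = {k: vals.pop(k) for k in list(vals)
                if k in PARAM_NAMES}
        if pops:
            m = m.with_pop_values(**pops)
        if vals:
            m = replace(m, **vals)
    return m
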