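"""Phenotype/pedigree file I/O and pipeline configuration.

One flat CSV schema carries the plot data:

    trial,year,season,treatment,design,rep,block,genotype,yield_kg_ha,dtf_days,ph_cm

Controlled vocabularies: season in {dry, wet}; treatment in {non-stress,
drought}; design in {alpha_lattice, rcbd, augmented_rcbd}.  Tokens are
normalized (case, surrounding whitespace) with a logged coercion; unknown
tokens and duplicated plot keys are fatal with row numbers.  The empty
string, "NA" and "." are missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

PHENO_COLUMNS = [
    "trial", "year", "season", "treatment", "design", "rep", "block",
    "genotype", "yield_kg_ha", "dtf_days", "ph_cm",
]
NA_TOKENS = ["", "NA", "."]
VOCAB = {
    "season": {"dry", "wet"},
    "treatment": {"non-stress", "drought"},
    "design": {"alpha_lattice", "rcbd", "augmented_rcbd"},
}
_NORMALIZE = {
    "treatment": {"nonstress": "non-stress", "non_stress": "non-stress", "ns": "non-stress", "dr": "drought"},
    "design": {"alpha-lattice": "alpha_lattice", "augmented-rcbd": "augmented_rcbd", "augmented": "augmented_rcbd"},
}


class IOError_(ValueError):
    pass


def read_phenotypes(path) -> pd.DataFrame:
    """Read and validate a phenotype CSV (header-driven, any column order)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"phenotype CSV missing columns: {missing}")
    df = df[PHENO_COLUMNS].copy()
    for col in ("yield_kg_ha", "dtf_days", "ph_cm"):
        df[col] = pd.to_numeric(df[col].replace(NA_TOKENS, np.nan), errors="raise")
    df["year"] = pd.to_numeric(df["year"], errors="raise").astype(int)
    for col, vocab in VOCAB.items():
        raw = df[col]
        norm = raw.str.strip().str.lower()
        norm = norm.replace(_NORMALIZE.get(col, {}))
        coerced = (norm != raw).sum()
        if coerced:
            logger.info("read_phenotypes: normalized %d %s tokens", int(coerced), col)
        bad = ~norm.isin(vocab)
        if bad.any():
            rows = (df.index[bad] + 2).tolist()[:10]  # 1-based incl. header
            raise IOError_(
                f"unknown {col} tokens {sorted(set(norm[bad]))} at rows {rows}"
            )
        df[col] = norm
    for col in ("trial", "rep", "block", "genotype"):
        df[col] = df[col].str.strip()
    key = df[["trial", "rep", "block", "genotype"]]
    dup = key.duplicated()
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:10]
        raise IOError_(f"duplicated plot keys at rows {rows}")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.15g")


def read_blues(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_blues(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.15g")


def read_bv_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_bv_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.15g")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, loadable from YAML."""

    mode: str = "simulate"  # simulate | files
    output_dir: str = "gaintrend_out"
    phenotypes: Optional[str] = None
    pedigree: Optional[str] = None
    checks: Optional[str] = None  # file with one check/released id per line
    seed: int = 1
    sim: dict = dc_field(default_factory=dict)
    qc: dict = dc_field(
        default_factory=lambda: {
            "missing_threshold": 0.20,
            "outlier_alpha": 0.05,
            "outlier_family": "trial",
        }
    )
    stage1: dict = dc_field(
        default_factory=lambda: {
            "use_dtf_covariate": True,
            "traits": ["yield", "dtf"],
            "combined_weights": None,
        }
    )
    stage2: dict = dc_field(
        default_factory=lambda: {
            "contexts": ["non-stress", "drought", "combined"],
            "reliability_form": "paper",
        }
    )
    trends: dict = dc_field(
        default_factory=lambda: {
            "percent_gain_baseline": "subset_mean",
            "loess_span": 0.75,
        }
    )
    panel: dict = dc_field(
        default_factory=lambda: {"n_target": 200, "reliability_min": 0.4}
    )

    def validate(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise IOError_(f"unknown mode {self.mode!r}")
        if self.mode == "files" and not (self.phenotypes and self.pedigree):
            raise IOError_("files mode needs phenotypes and pedigree paths")
        if not 0 <= self.qc.get("missing_threshold", 0.2) <= 1:
            raise IOError_("qc.missing_threshold must be in [0, 1]")
        if not 0 < self.qc.get("outlier_alpha", 0.05) < 1:
            raise IOError_("qc.outlier_alpha must be in (0, 1)")
        if self.qc.get("outlier_family", "trial") not in ("trial", "global"):
            raise IOError_("qc.outlier_family must be 'trial' or 'global'")
        if self.trends.get("percent_gain_baseline") not in (
            "subset_mean", "first_year_prediction",
        ):
            raise IOError_("trends.percent_gain_baseline invalid")
        if self.stage2.get("reliability_form") not in ("paper", "inbreeding-corrected"):
            raise IOError_("stage2.reliability_form invalid")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise IOError_(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        for key, val in raw.items():
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(val, dict):
                current.update(val)
            else:
                setattr(cfg, key, val)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)
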