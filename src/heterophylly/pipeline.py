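"""End-to-end orchestration: configuration, stage wiring, manifest.

The pipeline runs simulate -> DE (five *C. palustris* comparisons plus the
*C. terrestris* comparison) -> cascade on in-memory objects; the CLI layers
file I/O on top of these functions.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import __version__
from .cascade import CandidateReport, run_cascade
from .de import CountMatrix, compute_tpm, filter_low_expression, run_comparison
from .simulate import SimulatedStudy

__all__ = ["PipelineConfig", "run_de_stage", "run_full_pipeline", "manifest"]

CP_COMPARISONS = {
    # label -> (treatment condition, stage)
    "aerial": ("aerial", "primordium"),
    "agno3": ("agno3", "primordium"),
    "uniconazole": ("uniconazole", "primordium"),
    "aba": ("aba", "primordium"),
    "mature": ("aerial", "mature"),
}


@dataclass
class PipelineConfig:
    """Thresholds and design constants of the analysis.

    Defaults are the published decision rules: DEGs at FDR < 0.05 with
    |log2FC| > 1, a TPM floor of 1 for the low-expression filter and the
    unexpressed-ortholog rule, and GO terms annotating >= 5 population
    genes.
    """

    fdr_threshold: float = 0.05
    lfc_threshold: float = 1.0
    tpm_floor: float = 1.0
    min_term_size: int = 5
    seed: int = 0
    n_genes: int = 2000
    n_ct_genes: int = 800
    reference_condition: str = "submerged"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("fdr_threshold", "lfc_threshold", "tpm_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_term_size < 1:
            raise ValueError("min_term_size must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        extra = {k: v for k, v in raw.items() if k not in cls.__dataclass_fields__}
        return cls(**known, extra=extra)


def run_de_stage(counts: CountMatrix, config: PipelineConfig, species: str = "Cp") -> dict:
    """TPM filter + all comparisons for one species' count matrix.

    Returns a dict of DEG tables keyed by comparison label, each reindexed
    to the *filtered* gene universe of that species.  For *C. terrestris*
    only the aerial-vs-submerged primordium comparison exists.
    """
    tpm = compute_tpm(counts)
    kept = filter_low_expression(tpm, config.tpm_floor)
    filtered = counts.subset_genes(kept)

    if species == "Ct":
        labels = {"ct": ("aerial", "primordium")}
    else:
        labels = CP_COMPARISONS
    tables = {}
    for label, (treatment, stage) in labels.items():
        tables[label] = run_comparison(
            filtered,
            treatment=treatment,
            reference=config.reference_condition,
            comparison_label=label,
            stage=stage,
            fdr_threshold=config.fdr_threshold,
            lfc_threshold=config.lfc_threshold,
        )
    return {"tables": tables, "tpm": tpm, "kept_genes": kept}


def _reindex_full(table: pd.DataFrame, universe, comparison: str) -> pd.DataFrame:
    """Extend a DEG table to a larger universe; absent genes are non-DEGs.

    Genes removed by the low-expression filter carry no evidence of
    differential expression, so they re-enter with call "none".
    """
    out = table.reindex(universe)
    missing = out["gene_id"].isna()
    out.loc[missing, "gene_id"] = out.index[missing]
    out.loc[missing, "comparison"] = comparison
    out.loc[missing, ["log2fc", "pvalue", "qvalue"]] = [0.0, 1.0, 1.0]
    out.loc[missing, "call"] = "none"
    return out


def run_full_pipeline(study: SimulatedStudy, config: PipelineConfig) -> dict:
    """simulate -> DE -> cascade on a simulated two-species study."""
    cp = run_de_stage(study.cp_counts, config, species="Cp")
    ct = run_de_stage(study.ct_counts, config, species="Ct")

    cp_universe = cp["kept_genes"]
    deg_tables = {
        k: _reindex_full(cp["tables"][k], cp_universe, k)
        for k in ("aerial", "agno3", "aba", "uniconazole")
    }
    mature = _reindex_full(cp["tables"]["mature"], cp_universe, "mature")
    ct_universe = study.ct_counts.genes
    ct_full = _reindex_full(ct["tables"]["ct"], ct_universe, "ct")

    report = run_cascade(
        deg_tables,
        mature,
        study.orthology,
        ct_full,
        ct["tpm"],
        study.annotation,
        tpm_threshold=config.tpm_floor,
    )
    return {"report": report, "cp": cp, "ct": ct}


def manifest(config: PipelineConfig, outputs: dict | None = None) -> dict:
    """Reproducibility record: config (and its hash), seed, versions."""
    import numpy, pandas, scipy  # noqa: PLC0415

    cfg = asdict(config)
    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    record = {
        "config": cfg,
        "config_sha256": cfg_hash,
        "seed": config.seed,
        "versions": {
            "heterophylly": __version__,
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
    }
    if outputs:
        record["outputs"] = {
            name: hashlib.sha256(open(path, "rb").read()).hexdigest()
            for name, path in outputs.items()
        }
    return record


def cascade_agreement(report: CandidateReport, truth: pd.DataFrame) -> dict:
    """Planted-vs-recovered accounting for a simulated study.

    Sensitivity of candidate recovery (planted SHARED4/SHARED3 in the
    candidate set), exclusion recovery (planted CT_* genes excluded), and
    the retained-set precision against the planted truth.
    """
    table = report.table
    planted_candidates = truth.index[truth["category"].isin(["SHARED4", "SHARED3_NOT_UNI"])]
    planted_excluded = truth.index[truth["category"].isin(["CT_CONSISTENT", "CT_UNEXPRESSED"])]

    in_universe = table.index
    found = table.index[table["category"] != "NONE"]
    cand_hit = planted_candidates.intersection(found)
    excl_hit = [
        g
        for g in planted_excluded
        if g in in_universe and not table.loc[g, "retained"] and table.loc[g, "category"] != "NONE"
    ]
    retained = report.retained_genes()
    truth_retained = set(planted_candidates)
    precision = (
        len(set(retained) & truth_retained) / len(retained) if len(retained) else float("nan")
    )
    return {
        "candidate_sensitivity": len(cand_hit) / len(planted_candidates),
        "exclusion_sensitivity": len(excl_hit) / len(planted_excluded),
        "retained_precision": precision,
    }
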