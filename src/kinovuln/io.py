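"""Table I/O, schema validation, configuration and pipeline orchestration.

All interchange is flat text: TSV for the expression matrix and result
tables, CSV for screen/dose/combo/caliper tables, JSON for fit
parameters and run manifests, YAML for configuration.  ``read_table``
validates a named column schema and collects row-level errors with
line numbers; ``run_pipeline`` chains DE -> screen -> integration,
writing every intermediate artifact plus a manifest stamped with a
hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import expression as de_mod
from . import integration, screen as screen_mod
from .synthetic import ExpressionStudy

__all__ = [
    "TableSchema", "read_table", "SCREEN_SCHEMA", "DOSE_SCHEMA",
    "COMBO_SCHEMA", "CALIPER_SCHEMA",
    "read_expression_study", "write_expression_study",
    "PipelineConfig", "run_pipeline",
]

WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")


def _valid_well(v: str) -> bool:
    return bool(WELL_RE.match(str(v)))


@dataclass(frozen=True)
class TableSchema:
    """Named column specification for a flat table.

    ``columns`` maps column name -> dtype ("str", "float", "int");
    ``validators`` maps column name -> predicate on the parsed value;
    ``unique_key`` lists columns whose combination must be unique;
    ``nullable`` lists columns where empty values are allowed.
    """

    name: str
    columns: dict
    validators: dict = field(default_factory=dict)
    unique_key: tuple = ()
    nullable: tuple = ()


SCREEN_SCHEMA = TableSchema(
    name="screen wells",
    columns={"plate_id": "str", "well": "str", "sirna_id": "str",
             "gene": "str", "role": "str", "absorbance": "float"},
    validators={"well": _valid_well,
                "role": lambda v: v in ("sample", "control", "empty")},
    unique_key=("plate_id", "well"),
    nullable=("gene",),
)
DOSE_SCHEMA = TableSchema(
    name="dose-response",
    columns={"agent": "str", "dose_nM": "float", "replicate": "int",
             "viability_pct": "float"},
    validators={"dose_nM": lambda v: v > 0},
)
COMBO_SCHEMA = TableSchema(
    name="combination grid",
    columns={"dose_a_nM": "float", "dose_b_nM": "float",
             "inhibition_fraction": "float"},
    validators={"dose_a_nM": lambda v: v > 0, "dose_b_nM": lambda v: v > 0,
                "inhibition_fraction": lambda v: 0.0 <= v <= 1.0},
)
CALIPER_SCHEMA = TableSchema(
    name="caliper",
    columns={"animal_id": "str", "arm": "str", "day": "float",
             "L_mm": "float", "W_mm": "float", "H_mm": "float"},
    validators={"L_mm": lambda v: v > 0, "W_mm": lambda v: v > 0,
                "H_mm": lambda v: v > 0},
)

_CASTERS = {"str": str, "float": float, "int": int}


class TableValidationError(ValueError):
    """Raised with every collected row-level problem, line-numbered."""

    def __init__(self, name: str, problems: list[str]):
        self.problems = problems
        super().__init__(f"{name}: " + "; ".join(problems[:10]) +
                         ("" if len(problems) <= 10 else f" (+{len(problems) - 10} more)"))


def read_table(path, schema: TableSchema, sep: str = ",") -> pd.DataFrame:
    """Read and validate a delimited table against a schema.

    Header line required.  Missing columns, unparseable values, failed
    validators and duplicate keys are collected with their 1-based file
    line numbers and raised together.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    problems: list[str] = []
    missing = [c for c in schema.columns if c not in raw.columns]
    if missing:
        raise TableValidationError(schema.name, [f"missing columns {missing}"])

    parsed = {}
    for col, kind in schema.columns.items():
        caster = _CASTERS[kind]
        values = []
        for i, v in enumerate(raw[col]):
            line = i + 2  # 1-based, after header
            if v == "":
                if col in schema.nullable:
                    values.append(None)
                    continue
                problems.append(f"line {line}: empty value in {col!r}")
                values.append(None)
                continue
            try:
                pv = caster(v)
            except ValueError:
                problems.append(f"line {line}: cannot parse {col!r} value {v!r}")
                values.append(None)
                continue
            check = schema.validators.get(col)
            if check is not None and not check(pv):
                problems.append(f"line {line}: invalid {col!r} value {v!r}")
            values.append(pv)
        parsed[col] = values
    table = pd.DataFrame(parsed)

    if schema.unique_key:
        dup = table.duplicated(subset=list(schema.unique_key), keep=False)
        for i in table.index[dup & ~table.duplicated(subset=list(schema.unique_key))]:
            key = tuple(table.loc[i, list(schema.unique_key)])
            problems.append(f"line {i + 2}: duplicate key {key}")
    if problems:
        raise TableValidationError(schema.name, problems)
    return table


# ---------------------------------------------------------------------------
# Expression matrix I/O
# ---------------------------------------------------------------------------

def write_expression_study(study: ExpressionStudy, expr_path, groups_path) -> None:
    """Write the log2 matrix as TSV and the sample->group map as CSV."""
    study.values.to_csv(expr_path, sep="\t", index_label="gene")
    study.groups.rename("group").to_csv(groups_path, index_label="sample")


def read_expression_study(expr_path, groups_path,
                          linear_scale: bool = False) -> ExpressionStudy:
    """Read an expression TSV (genes x samples) plus a group-map CSV.

    ``linear_scale=True`` log2-transforms linear intensities on input
    (values must then be positive); by default the matrix is assumed
    to be already on log2 scale.
    """
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, index_col=0)["group"]
    if linear_scale:
        if (values <= 0).any().any():
            raise ValueError("linear-scale input must be strictly positive")
        import numpy as np
        values = np.log2(values)
    return ExpressionStudy(values, groups)


# ---------------------------------------------------------------------------
# Pipeline configuration and orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every threshold and path the end-to-end pipeline uses.

    Threshold defaults are the study's printed cutoffs: two-fold
    (fc_log2=1.0) at FDR 0.1 for expression, mean Z < -2 (stringent -3)
    for the screen, Bliss excess delta 0.1, foci threshold 10.
    """

    expression_tsv: str = ""
    groups_csv: str = ""
    screen_csv: str = ""
    annotations: list[str] = field(default_factory=list)
    out_dir: str = "kinovuln_run"
    fc_log2: float = 1.0
    fdr: float = 0.1
    z_hit: float = -2.0
    z_stringent: float = -3.0
    synergy_delta: float = 0.1
    foci_threshold: int = 10
    background: float = 0.0
    de_test: str = "student_t"
    arm_test: str = "welch_t"
    seed: int = 0

    def validate(self) -> None:
        if self.fc_log2 < 0 or not 0 <= self.fdr <= 1:
            raise ValueError("fc_log2 must be >= 0 and fdr in [0, 1]")
        if self.z_hit <= self.z_stringent:
            raise ValueError("z_hit must exceed z_stringent")
        if self.synergy_delta <= 0 or self.foci_threshold < 0:
            raise ValueError("synergy_delta must be > 0, foci_threshold >= 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run DE -> screen scoring -> candidate integration end to end.

    Writes every intermediate artifact (DE table, over-expressed set,
    per-well and per-gene screen tables, hit lists, candidate table),
    a log recording thresholds and seed, and a manifest with the
    config hash and a checksum of every output.  Re-running with the
    same inputs and config is byte-identical.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config_hash={config.config_hash()}", f"seed={config.seed}",
                 f"fc_log2={config.fc_log2}", f"fdr={config.fdr}",
                 f"z_hit={config.z_hit}", f"z_stringent={config.z_stringent}",
                 f"de_test={config.de_test}", f"background={config.background}"]

    def fail(stage: str, exc: Exception):
        (out / "FAILED").write_text(f"stage={stage}\n{exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- differential expression -------------------------------------
    try:
        study = read_expression_study(config.expression_tsv, config.groups_csv)
        de = de_mod.differential_expression(study, test=config.de_test)
        de["dysregulated"] = de_mod._selection_mask(de, config.fc_log2, config.fdr, "both")
        de["overexpressed"] = de_mod._selection_mask(de, config.fc_log2, config.fdr, "up")
        overexpressed = set(de.loc[de["overexpressed"], "gene"])
        if config.annotations:
            cats = [de_mod.load_annotation(a) for a in config.annotations]
            overexpressed = de_mod.funnel_intersection(overexpressed, cats)
    except RuntimeError:
        raise
    except Exception as exc:
        fail("de", exc)

    de.to_csv(out / "de_table.tsv", sep="\t", index=False, float_format="%.6g")
    (out / "overexpressed.txt").write_text(
        "".join(f"{g}\n" for g in sorted(overexpressed)))

    # --- screen scoring ----------------------------------------------
    try:
        wells = read_table(config.screen_csv, SCREEN_SCHEMA)
        normalized, scores, hits, stringent = screen_mod.score_screen(
            wells, background=config.background,
            threshold=config.z_hit, stringent=config.z_stringent)
    except Exception as exc:
        fail("screen", exc)

    normalized.to_csv(out / "screen_normalized.csv", index=False, float_format="%.6g")
    scores.drop(columns=["z_values"]).to_csv(
        out / "gene_scores.tsv", sep="\t", index=False, float_format="%.6g")
    (out / "hits.txt").write_text("".join(f"{g}\n" for g in sorted(hits)))
    (out / "stringent_hits.txt").write_text(
        "".join(f"{g}\n" for g in sorted(stringent)))

    # --- integration --------------------------------------------------
    try:
        candidates = integration.intersect_candidates(overexpressed, hits, de, scores)
    except Exception as exc:
        fail("integrate", exc)
    integration.candidate_report(candidates, out / "candidates.tsv")

    (out / "run.log").write_text("".join(f"{line}\n" for line in log_lines))
    artifacts = sorted(p for p in out.iterdir()
                       if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_hash": config.config_hash(),
        "outputs": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
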