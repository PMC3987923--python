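"""Synthetic data generators for every pipeline input.

Each generator emulates one data structure of an integrated
target-nomination study in medulloblastoma: a small tumor-vs-normal
log2 expression matrix, an arrayed kinome siRNA viability screen on
96-well plates, single-agent dose-response tables, dose-pair
combination matrices, and xenograft caliper series.  Effects are
planted with known truth labels so every downstream stage can be
tested for recovery and null calibration without any external data.

Truth labels are returned in sidecar tables, never embedded in the
data frames the pipeline itself consumes.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doseresponse import four_pl
from .bliss import bliss_expected

__all__ = [
    "ExpressionSimParams",
    "ScreenSimParams",
    "DoseSimParams",
    "ComboSimParams",
    "XenoSimParams",
    "ExpressionStudy",
    "generate_expression",
    "generate_screen",
    "generate_dose_response",
    "generate_combination",
    "generate_xenograft",
]

PLATE_ROWS = string.ascii_uppercase[:8]   # A..H
PLATE_COLS = list(range(1, 13))           # 1..12


# ---------------------------------------------------------------------------
# Expression study
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSimParams:
    """Parameters of the tumor-vs-normal expression simulation.

    Defaults mirror the discovery design: 16 tumors against 3 normal
    cerebella, with planted over-expressed genes whose true log2
    fold-change is drawn around ``mean_log2fc_planted``.
    """

    n_genes: int = 1000
    n_tumor: int = 16
    n_normal: int = 3
    frac_overexpressed: float = 0.05
    mean_log2fc_planted: float = 1.5
    sd_log2fc_planted: float = 0.2
    noise_sd: float = 0.2
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_tumor <= 0 or self.n_normal <= 0:
            raise ValueError("n_genes, n_tumor and n_normal must be positive")
        if not 0.0 <= self.frac_overexpressed <= 1.0:
            raise ValueError("frac_overexpressed must lie in [0, 1]")
        if self.noise_sd < 0 or self.sd_log2fc_planted < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class ExpressionStudy:
    """A gene x sample log2 expression matrix with group labels."""

    values: pd.DataFrame                 # genes x samples, log2 scale
    groups: pd.Series                    # sample -> {"tumor", "normal"}

    def __post_init__(self) -> None:
        if not set(self.groups.index) == set(self.values.columns):
            raise ValueError("group labels must cover exactly the sample columns")
        labels = set(self.groups)
        if not labels <= {"tumor", "normal"}:
            raise ValueError(f"unknown group labels: {labels - {'tumor', 'normal'}}")
        for g in ("tumor", "normal"):
            if (self.groups == g).sum() == 0:
                raise ValueError(f"group {g!r} is empty")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_columns(self, group: str) -> pd.Index:
        return self.groups.index[self.groups == group]


def generate_expression(params: ExpressionSimParams) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Simulate a log2 expression study with planted over-expressed genes.

    Returns the study plus a truth table (gene, planted, true_log2fc).
    Planted genes receive a tumor-specific shift drawn from
    N(mean_log2fc_planted, sd_log2fc_planted); every value carries iid
    Gaussian log2 noise.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    genes = [f"GENE{i:05d}" for i in range(params.n_genes)]
    tumor = [f"MB{i + 1:02d}" for i in range(params.n_tumor)]
    normal = [f"CB{i + 1:02d}" for i in range(params.n_normal)]
    samples = tumor + normal

    n_planted = int(round(params.frac_overexpressed * params.n_genes))
    planted_idx = rng.choice(params.n_genes, size=n_planted, replace=False)
    true_fc = np.zeros(params.n_genes)
    true_fc[planted_idx] = rng.normal(
        params.mean_log2fc_planted, params.sd_log2fc_planted, size=n_planted
    )

    baseline = rng.normal(params.baseline_mean, params.baseline_sd, size=params.n_genes)
    mat = np.tile(baseline[:, None], (1, len(samples)))
    mat[:, : params.n_tumor] += true_fc[:, None]
    mat += rng.normal(0.0, params.noise_sd, size=mat.shape)

    values = pd.DataFrame(mat, index=genes, columns=samples)
    groups = pd.Series(
        ["tumor"] * params.n_tumor + ["normal"] * params.n_normal,
        index=samples, name="group",
    )
    planted = np.zeros(params.n_genes, dtype=bool)
    planted[planted_idx] = True
    truth = pd.DataFrame({"gene": genes, "planted": planted, "true_log2fc": true_fc})
    return ExpressionStudy(values, groups), truth


# ---------------------------------------------------------------------------
# Arrayed siRNA screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimParams:
    """Parameters of the kinome siRNA screen simulation.

    The default library matches the screened one: 710 kinase genes,
    3 independent siRNAs each (2130 sample wells), with a triplicate
    of non-silencing control wells on every 96-well plate.
    ``essential_genes`` maps gene id to a fractional viability
    reduction in [0, 1] (0.3 = 30% fewer viable cells).
    """

    n_genes: int = 710
    sirnas_per_gene: int = 3
    sample_wells_per_plate: int = 80
    controls_per_plate: int = 3
    background: float = 0.05
    base_signal: float = 1.0
    plate_effect_sd: float = 0.15
    well_noise_sd: float = 0.05
    essential_genes: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.sirnas_per_gene <= 0:
            raise ValueError("n_genes and sirnas_per_gene must be positive")
        if self.sample_wells_per_plate < 1:
            raise ValueError("sample_wells_per_plate must be >= 1")
        if self.controls_per_plate < 1:
            raise ValueError("every plate needs at least one control well")
        if self.sample_wells_per_plate + self.controls_per_plate > 96:
            raise ValueError("layout exceeds a 96-well plate")
        for gene, eff in self.essential_genes.items():
            if not 0.0 <= eff <= 1.0:
                raise ValueError(f"effect for {gene} outside [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return [f"KIN{i:04d}" for i in range(self.n_genes)]


def _well_names() -> list[str]:
    return [f"{r}{c}" for r in PLATE_ROWS for c in PLATE_COLS]


def generate_screen(params: ScreenSimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an arrayed viability screen.

    One well per reagent; reagents fill plates sequentially in
    row-major well order, skipping the fixed control positions at the
    end of each plate's layout.  Absorbance follows::

        background + plate_effect * base_signal * (1 - effect(gene)) + noise

    with a lognormal multiplicative plate effect and Gaussian well
    noise.  Returns (wells, truth); wells has columns plate_id, well,
    sirna_id, gene, role, absorbance.
    """
    params.validate()
    unknown = set(params.essential_genes) - set(params.gene_ids)
    if unknown:
        raise ValueError(f"essential genes not in library: {sorted(unknown)}")
    rng = np.random.default_rng(params.seed)

    genes = params.gene_ids
    reagents = [
        (f"{g}_si{j + 1}", g) for g in genes for j in range(params.sirnas_per_gene)
    ]
    n_reagents = len(reagents)
    n_plates = math.ceil(n_reagents / params.sample_wells_per_plate)

    all_wells = _well_names()
    # controls sit in the last wells of the row-major layout (plate-fixed)
    layout = all_wells[: params.sample_wells_per_plate + params.controls_per_plate]
    sample_positions = layout[: params.sample_wells_per_plate]
    control_positions = layout[params.sample_wells_per_plate:]

    rows = []
    k = 0
    for p in range(n_plates):
        plate_id = f"P{p + 1:02d}"
        plate_effect = rng.lognormal(mean=0.0, sigma=params.plate_effect_sd)
        for pos in sample_positions:
            if k >= n_reagents:
                break
            sirna_id, gene = reagents[k]
            k += 1
            effect = params.essential_genes.get(gene, 0.0)
            signal = plate_effect * params.base_signal * (1.0 - effect)
            ab = params.background + signal + rng.normal(0.0, params.well_noise_sd)
            rows.append((plate_id, pos, sirna_id, gene, "sample", max(ab, 0.0)))
        for j, pos in enumerate(control_positions):
            signal = plate_effect * params.base_signal
            ab = params.background + signal + rng.normal(0.0, params.well_noise_sd)
            rows.append((plate_id, pos, f"NSC_{plate_id}_{j + 1}", None, "control",
                         max(ab, 0.0)))

    wells = pd.DataFrame(
        rows, columns=["plate_id", "well", "sirna_id", "gene", "role", "absorbance"]
    )
    truth = pd.DataFrame(
        {
            "gene": genes,
            "essential": [g in params.essential_genes for g in genes],
            "effect": [params.essential_genes.get(g, 0.0) for g in genes],
        }
    )
    return wells, truth


@dataclass
class JointSimParams:
    """Parameters of a joint expression + screen simulation.

    The screen's gene library doubles as the expression study's gene
    universe.  The first ``n_dual`` genes are planted as both
    over-expressed and essential (the true therapeutic candidates);
    ``n_overexpressed_only`` and ``n_essential_only`` genes are planted
    in only one modality as distractors.
    """

    screen: ScreenSimParams = field(default_factory=ScreenSimParams)
    expression: ExpressionSimParams = field(default_factory=ExpressionSimParams)
    n_dual: int = 6
    n_overexpressed_only: int = 14
    n_essential_only: int = 10
    essential_effect: float = 0.5
    # planted over-expression is left-truncated so every gene labelled
    # over-expressed genuinely exceeds the two-fold selection criterion
    min_log2fc_planted: float = 1.2
    seed: int = 0

    def validate(self) -> None:
        self.screen.validate()
        n_planted = self.n_dual + self.n_overexpressed_only + self.n_essential_only
        if n_planted > self.screen.n_genes:
            raise ValueError("more planted genes than the library holds")
        if not 0.0 <= self.essential_effect <= 1.0:
            raise ValueError("essential_effect must lie in [0, 1]")
        if self.min_log2fc_planted < 0:
            raise ValueError("min_log2fc_planted must be non-negative")


def generate_joint_study(params: JointSimParams
                         ) -> tuple[ExpressionStudy, pd.DataFrame, pd.DataFrame]:
    """Simulate matched expression and screen data over one gene universe.

    Returns (expression study, screen wells, truth).  The truth table
    has one row per library gene with ``overexpressed``, ``essential``
    and ``dual`` flags; exactly the ``dual`` genes should survive the
    full nomination pipeline.
    """
    params.validate()
    genes = params.screen.gene_ids
    dual = genes[: params.n_dual]
    oe_only = genes[params.n_dual: params.n_dual + params.n_overexpressed_only]
    ess_only = genes[params.n_dual + params.n_overexpressed_only:
                     params.n_dual + params.n_overexpressed_only + params.n_essential_only]

    sp = ScreenSimParams(**{**params.screen.__dict__,
                            "essential_genes": {g: params.essential_effect
                                                for g in dual + ess_only},
                            "seed": params.seed})
    wells, _ = generate_screen(sp)

    ep = ExpressionSimParams(**{**params.expression.__dict__,
                                "n_genes": len(genes),
                                "frac_overexpressed": 0.0,
                                "seed": params.seed + 1})
    study, _ = generate_expression(ep)
    values = study.values.copy()
    values.index = genes
    rng = np.random.default_rng(params.seed + 2)
    tumor_cols = study.group_columns("tumor")
    for g in list(dual) + list(oe_only):
        shift = rng.normal(params.expression.mean_log2fc_planted,
                           params.expression.sd_log2fc_planted)
        while shift < params.min_log2fc_planted:  # rejection-sample the truncation
            shift = rng.normal(params.expression.mean_log2fc_planted,
                               params.expression.sd_log2fc_planted)
        values.loc[g, tumor_cols] += shift
    study = ExpressionStudy(values, study.groups)

    oe_set, ess_set = set(dual) | set(oe_only), set(dual) | set(ess_only)
    truth = pd.DataFrame({
        "gene": genes,
        "overexpressed": [g in oe_set for g in genes],
        "essential": [g in ess_set for g in genes],
        "dual": [g in dual for g in genes],
    })
    return study, wells, truth


# ---------------------------------------------------------------------------
# Dose-response
# ---------------------------------------------------------------------------

@dataclass
class DoseSimParams:
    """Parameters of a single-agent viability dose-response simulation."""

    true_bottom: float = 0.0
    true_top: float = 100.0
    true_ic50: float = 150.0          # nM
    true_hill: float = 1.2
    doses: tuple[float, ...] = (10.0, 30.0, 60.0, 100.0, 150.0, 300.0, 600.0, 1200.0)
    replicates: int = 3
    noise_sd: float = 5.0             # percent-viability units
    agent: str = "drug"
    seed: int = 0

    def validate(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        if doses.size == 0:
            raise ValueError("dose list must not be empty")
        if np.any(doses <= 0):
            raise ValueError("doses must be strictly positive")
        if np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if not self.true_bottom < self.true_top:
            raise ValueError("bottom must be below top")
        if self.true_ic50 <= 0 or self.true_hill <= 0:
            raise ValueError("ic50 and hill must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def generate_dose_response(params: DoseSimParams) -> pd.DataFrame:
    """Simulate replicate percent-viability readings around a 4PL curve.

    Returns a table with columns agent, dose_nM, replicate, viability_pct.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    rows = []
    for d in params.doses:
        mu = four_pl(d, params.true_bottom, params.true_top,
                     params.true_ic50, params.true_hill)
        for r in range(params.replicates):
            rows.append((params.agent, d, r + 1,
                         mu + rng.normal(0.0, params.noise_sd)))
    return pd.DataFrame(rows, columns=["agent", "dose_nM", "replicate", "viability_pct"])


# ---------------------------------------------------------------------------
# Drug-combination grid
# ---------------------------------------------------------------------------

@dataclass
class ComboSimParams:
    """Parameters of a dose-pair combination simulation.

    ``fit_a`` / ``fit_b`` are (bottom, top, ic50, hill) tuples for the
    two single agents; ``excess`` is the planted deviation from Bliss
    independence on the inhibition-fraction scale (0 = independent).
    """

    fit_a: tuple[float, float, float, float] = (0.0, 100.0, 593.0, 1.0)
    fit_b: tuple[float, float, float, float] = (0.0, 100.0, 150.0, 1.2)
    doses_a: tuple[float, ...] = (100.0, 200.0, 400.0, 800.0, 1600.0, 3200.0)
    doses_b: tuple[float, ...] = (12.5, 25.0, 50.0, 100.0, 200.0, 400.0)
    excess: float = 0.0
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not -1.0 <= self.excess <= 1.0:
            raise ValueError("excess must lie in [-1, 1]")
        for doses in (self.doses_a, self.doses_b):
            if len(doses) == 0 or any(d <= 0 for d in doses):
                raise ValueError("dose grids must be non-empty and positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _inhibition_from_curve(dose: float, curve: tuple[float, float, float, float]) -> float:
    bottom, top, ic50, hill = curve
    viability = four_pl(dose, bottom, top, ic50, hill)
    return float(np.clip(1.0 - viability / 100.0, 0.0, 1.0))


def generate_combination(params: ComboSimParams) -> pd.DataFrame:
    """Simulate a dose-pair inhibition grid around the Bliss expectation.

    Observed fraction = clip(f_bliss + excess + noise, 0, 1) at every
    grid cell.  Returns columns dose_a_nM, dose_b_nM, inhibition_fraction.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    rows = []
    for da in params.doses_a:
        fa = _inhibition_from_curve(da, params.fit_a)
        for db in params.doses_b:
            fb = _inhibition_from_curve(db, params.fit_b)
            f = bliss_expected(fa, fb) + params.excess
            if params.noise_sd > 0:
                f += rng.normal(0.0, params.noise_sd)
            rows.append((da, db, float(np.clip(f, 0.0, 1.0))))
    return pd.DataFrame(rows, columns=["dose_a_nM", "dose_b_nM", "inhibition_fraction"])


# ---------------------------------------------------------------------------
# Xenograft caliper series
# ---------------------------------------------------------------------------

@dataclass
class XenoSimParams:
    """Parameters of a two-arm subcutaneous xenograft simulation.

    Ellipsoid tumor volume pi/6 * L * W * H grows exponentially at
    ``growth_rate`` per day in controls; the treated arm's rate is
    multiplied by ``treatment_effect`` (1 = no effect).  Caliper
    dimensions carry multiplicative lognormal measurement noise.
    """

    n_per_arm: int = 10
    v0_mean: float = 150.0            # mm^3 at day 0
    v0_cv: float = 0.2
    growth_rate: float = 0.06         # per day
    treatment_effect: float = 1.0
    measurement_cv: float = 0.15
    days: tuple[float, ...] = (0, 7, 14, 21, 28, 35, 42, 49, 56, 63)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if self.v0_mean <= 0:
            raise ValueError("v0_mean must be positive")
        if any(d < 0 for d in self.days) or len(self.days) == 0:
            raise ValueError("days must be non-empty and non-negative")
        if not 0.0 < self.treatment_effect <= 1.0:
            raise ValueError("treatment_effect must lie in (0, 1]")
        if self.measurement_cv < 0 or self.v0_cv < 0:
            raise ValueError("coefficients of variation must be non-negative")


def generate_xenograft(params: XenoSimParams) -> pd.DataFrame:
    """Simulate per-animal caliper measurements for control and treated arms.

    Returns columns animal_id, arm, day, L_mm, W_mm, H_mm.  The implied
    ellipsoid volume pi/6*L*W*H equals the true exponential trajectory
    times a lognormal measurement factor (exactly, when cv = 0).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    sigma_v0 = math.sqrt(math.log(1.0 + params.v0_cv ** 2)) if params.v0_cv else 0.0
    sigma_m = (math.sqrt(math.log(1.0 + params.measurement_cv ** 2))
               if params.measurement_cv else 0.0)

    rows = []
    for arm, rate in (("control", params.growth_rate),
                      ("treated", params.growth_rate * params.treatment_effect)):
        for i in range(params.n_per_arm):
            animal = f"{arm[:3].upper()}{i + 1:02d}"
            v0 = params.v0_mean * (rng.lognormal(-0.5 * sigma_v0 ** 2, sigma_v0)
                                   if sigma_v0 else 1.0)
            # mild per-animal prolate shape, constant over the study
            aspect = rng.uniform(1.0, 1.4)
            for day in params.days:
                v_true = v0 * math.exp(rate * day)
                v_obs = v_true * (rng.lognormal(-0.5 * sigma_m ** 2, sigma_m)
                                  if sigma_m else 1.0)
                # decompose volume into L >= W = H with the chosen aspect
                s = (6.0 * v_obs / math.pi / aspect) ** (1.0 / 3.0)
                rows.append((animal, arm, day, aspect * s, s, s))
    return pd.DataFrame(rows, columns=["animal_id", "arm", "day", "L_mm", "W_mm", "H_mm"])
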