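"""Synthetic ground-truth generators for the full analysis chain.

Nothing here is measured data: these generators emulate the statistical
structure the cohort analyses assume — a bolus-shaped arterial input, depot-
ordered kinetic parameters (supraclavicular brown fat > upper-chest >
abdominal subcutaneous fat, with skeletal muscle about 3-fold above the
supraclavicular depot in net uptake), BMI and type-2-diabetes effects on the
supraclavicular net uptake rate, adipose/muscle/blood voxel phantoms, and
qPCR Ct tables.  Every generator is deterministic given its seed and every
output carries the parameters that generated it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParamsError, LayoutError
from .kinetic import (
    FrameSchedule,
    KineticParameters,
    PlasmaInputFunction,
    TimeActivityCurve,
    default_grid,
    frame_average,
    macro_ki,
    solve_2tc,
)
from .voi import CANONICAL_SPACING_MM, ImageVolume, VOIMask

__all__ = [
    "FengInputParams",
    "feng_input",
    "default_input_function",
    "simulate_tac",
    "DepotPriors",
    "default_depot_priors",
    "CohortSpec",
    "SubjectRecord",
    "CohortTable",
    "simulate_cohort",
    "RegionSpec",
    "PhantomLayout",
    "default_phantom_layout",
    "make_phantom",
    "QPCRDesign",
    "simulate_qpcr",
    "DEPOTS",
]

DEPOTS = ("SCV", "UCH", "ABD", "muscle")


# ---------------------------------------------------------------------------
# Input function


@dataclass(frozen=True)
class FengInputParams:
    """Coefficients of the Feng tri-exponential bolus model.

    Cp(t) = (A1*t - A2 - A3)*exp(l1*t) + A2*exp(l2*t) + A3*exp(l3*t),
    which vanishes at t = 0 by construction.  A1 is kBq/mL/min; A2, A3 are
    kBq/mL; eigenvalues l1 < l2 <= l3 < 0 (1/min), l1 carrying the fast
    bolus decay.  Defaults give an arterial curve whose peak falls inside
    the first minute, matching a 12 x 5 s early-frame design.
    """

    A1: float = 851.1
    A2: float = 21.9
    A3: float = 20.8
    l1: float = -4.13
    l2: float = -0.12
    l3: float = -0.01

    def __post_init__(self):
        if not (self.l1 < self.l2 <= self.l3 < 0):
            raise InvalidParamsError("eigenvalues must satisfy l1 < l2 <= l3 < 0")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        cp = (
            (self.A1 * t - self.A2 - self.A3) * np.exp(self.l1 * t)
            + self.A2 * np.exp(self.l2 * t)
            + self.A3 * np.exp(self.l3 * t)
        )
        # t == 0 cancels algebraically; return it exactly despite roundoff
        return np.where(t <= 0, 0.0, cp)


def feng_input(p: FengInputParams, t_check_max: float = 25.0) -> PlasmaInputFunction:
    """Wrap Feng coefficients as a PlasmaInputFunction (Cb == Cp).

    Raises
    ------
    InvalidParamsError
        If the curve dips negative anywhere on [0, t_check_max] minutes.
    """
    t = np.linspace(0.0, t_check_max, 2501)
    if np.any(p(t) < -1e-9):
        raise InvalidParamsError("Feng curve goes negative on the check interval")
    return PlasmaInputFunction(p)


def default_input_function() -> PlasmaInputFunction:
    return feng_input(FengInputParams())


# ---------------------------------------------------------------------------
# Noisy TAC simulation


def simulate_tac(
    params: KineticParameters,
    input_fn: PlasmaInputFunction,
    schedule: FrameSchedule,
    noise_level: float = 0.2,
    seed: int = 0,
) -> TimeActivityCurve:
    """Noiseless frame means plus frame-duration-scaled Gaussian noise.

    Noise SD per frame is ``noise_level * sqrt(value_i / dt_i_min)`` — a
    count-statistics proxy in which long frames average more events and are
    therefore less noisy.  Values are clipped at zero.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    curves = solve_2tc(params, input_fn, default_grid(schedule))
    clean = frame_average(curves, schedule)
    if noise_level == 0:
        return clean
    rng = np.random.default_rng(seed)
    sd = noise_level * np.sqrt(np.maximum(clean.values, 0.0) / schedule.durations_min)
    noisy = np.clip(clean.values + rng.normal(0.0, 1.0, clean.values.size) * sd, 0.0, None)
    return TimeActivityCurve(schedule=schedule, values=noisy)


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass(frozen=True)
class DepotPriors:
    """Log-normal priors (median, log-SD) per depot and parameter.

    Default medians anchor the supraclavicular net uptake rate at
    Ki = 0.012 mL/min/cm^3 and skeletal muscle at about 3x that, with
    upper-chest and abdominal subcutaneous fat below the supraclavicular
    depot; spreads make neighbouring depot distributions overlap.
    """

    medians: dict[str, dict[str, float]]
    log_sd: dict[str, dict[str, float]]

    def draw(self, depot: str, rng: np.random.Generator) -> KineticParameters:
        med = self.medians[depot]
        sd = self.log_sd[depot]
        vals = {
            k: med[k] * np.exp(sd[k] * rng.standard_normal()) for k in ("K1", "k2", "k3", "vb")
        }
        vals["vb"] = float(min(vals["vb"], 0.29))
        return KineticParameters(**vals)


def default_depot_priors() -> DepotPriors:
    # Median micro-parameters chosen so median Ki = K1*k3/(k2+k3) comes out
    # at 0.012 (SCV), 0.008 (UCH), 0.005 (ABD) and 0.036 (muscle) mL/min/cm^3.
    medians = {
        "SCV": {"K1": 0.050, "k2": 0.40, "k3": 0.12632, "vb": 0.03},
        "UCH": {"K1": 0.040, "k2": 0.40, "k3": 0.10, "vb": 0.025},
        "ABD": {"K1": 0.030, "k2": 0.40, "k3": 0.08, "vb": 0.02},
        "muscle": {"K1": 0.120, "k2": 0.35, "k3": 0.15, "vb": 0.04},
    }
    sd = {"K1": 0.25, "k2": 0.25, "k3": 0.25, "vb": 0.2}
    return DepotPriors(medians=medians, log_sd={d: dict(sd) for d in medians})


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition knobs for a simulated cohort.

    ``bmi_effect`` is the slope of log supraclavicular Ki per BMI unit
    (negative: uptake declines with adiposity); ``t2d_effect`` is the
    multiplicative supraclavicular-Ki factor applied to subjects flagged
    with type 2 diabetes.
    """

    n: int = 50
    bmi_effect: float = -0.04  # per kg/m^2, on log SCV Ki
    t2d_fraction: float = 5.0 / 36.0
    t2d_effect: float = 0.6
    noise_level: float = 0.2
    seed: int = 0
    bmi_range: tuple[float, float] = (20.0, 38.0)
    bmi_ref: float = 29.0  # centre of the BMI range; scaling anchor

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("cohort needs n >= 3")
        if not (0.0 <= self.t2d_fraction <= 1.0):
            raise ValueError("t2d_fraction must be in [0, 1]")


@dataclass
class SubjectRecord:
    subject_id: str
    bmi: float
    t2d: bool
    weight_kg: float
    dose_MBq: float
    true_params: dict[str, KineticParameters]
    true_ki: dict[str, float]
    tacs: dict[str, TimeActivityCurve]


@dataclass
class CohortTable:
    spec: CohortSpec
    subjects: list[SubjectRecord]
    input_fn: PlasmaInputFunction

    def covariates(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "bmi": [s.bmi for s in self.subjects],
                "t2d": [s.t2d for s in self.subjects],
                "weight_kg": [s.weight_kg for s in self.subjects],
                "dose_MBq": [s.dose_MBq for s in self.subjects],
            }
        )

    def true_ki_table(self) -> pd.DataFrame:
        rows = [
            {"subject_id": s.subject_id, "depot": d, "true_ki": s.true_ki[d]}
            for s in self.subjects
            for d in DEPOTS
        ]
        return pd.DataFrame(rows)


def simulate_cohort(
    spec: CohortSpec,
    priors: DepotPriors | None = None,
    input_fn: PlasmaInputFunction | None = None,
    schedule: FrameSchedule | None = None,
) -> CohortTable:
    """Draw a cohort: covariates, depot parameters, and noisy depot TACs.

    BMI is uniform over ``spec.bmi_range``; the supraclavicular K1 (hence
    Ki, proportionally) is scaled by exp(bmi_effect*(BMI - bmi_ref)) and by
    ``t2d_effect`` for T2D subjects.  Ground truth is retained alongside
    every simulated curve.
    """
    if priors is None:
        priors = default_depot_priors()
    if input_fn is None:
        input_fn = default_input_function()
    if schedule is None:
        schedule = FrameSchedule.canonical()
    rng = np.random.default_rng(spec.seed)
    subjects = []
    for i in range(spec.n):
        bmi = float(rng.uniform(*spec.bmi_range))
        t2d = bool(rng.random() < spec.t2d_fraction)
        height_m = float(rng.normal(1.70, 0.09))
        weight_kg = float(bmi * height_m**2)
        dose = float(rng.uniform(287.0, 347.0))
        true_params: dict[str, KineticParameters] = {}
        tacs: dict[str, TimeActivityCurve] = {}
        for depot in DEPOTS:
            p = priors.draw(depot, rng)
            if depot == "SCV":
                scale = np.exp(spec.bmi_effect * (bmi - spec.bmi_ref))
                if t2d:
                    scale *= spec.t2d_effect
                p = KineticParameters(K1=p.K1 * scale, k2=p.k2, k3=p.k3, vb=p.vb)
            true_params[depot] = p
            tac_seed = int(rng.integers(0, 2**31 - 1))
            tacs[depot] = simulate_tac(
                p, input_fn, schedule, noise_level=spec.noise_level, seed=tac_seed
            )
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i + 1:03d}",
                bmi=bmi,
                t2d=t2d,
                weight_kg=weight_kg,
                dose_MBq=dose,
                true_params=true_params,
                true_ki={d: macro_ki(true_params[d]) for d in DEPOTS},
                tacs=tacs,
            )
        )
    return CohortTable(spec=spec, subjects=subjects, input_fn=input_fn)


# ---------------------------------------------------------------------------
# Voxel phantoms


@dataclass(frozen=True)
class RegionSpec:
    """A rectangular block region in voxel-index space."""

    name: str
    start: tuple[int, int, int]
    shape: tuple[int, int, int]
    hu_mean: float
    hu_sd: float
    pet_kbq_ml: float
    pet_sd: float = 0.0


@dataclass(frozen=True)
class PhantomLayout:
    shape: tuple[int, int, int] = (40, 40, 40)
    regions: tuple[RegionSpec, ...] = ()
    background_hu: float = 0.0  # water-equivalent soft tissue
    background_pet: float = 0.05


def default_phantom_layout() -> PhantomLayout:
    """Blocks for three adipose depots, a muscle block and a blood pool.

    The supraclavicular block is 10x10x5 = 500 voxels, i.e. about 6.44 mL
    at the canonical 2.344 mm isotropic spacing — above the 5.0 mL VOI floor.
    """
    return PhantomLayout(
        shape=(40, 40, 40),
        regions=(
            RegionSpec("SCV", (4, 4, 4), (10, 10, 5), -100.0, 10.0, 2.0),
            RegionSpec("UCH", (4, 20, 4), (10, 10, 6), -110.0, 10.0, 1.5),
            RegionSpec("ABD", (20, 4, 4), (12, 10, 6), -105.0, 10.0, 1.0),
            RegionSpec("muscle", (20, 20, 4), (10, 10, 8), 45.0, 10.0, 6.0),
            RegionSpec("blood", (16, 16, 20), (6, 6, 6), 40.0, 5.0, 12.0),
        ),
    )


def make_phantom(
    layout: PhantomLayout | None = None,
    spacing: float = CANONICAL_SPACING_MM,
    seed: int = 0,
) -> tuple[ImageVolume, ImageVolume, dict[str, VOIMask]]:
    """Build paired CT/PET block phantoms with ground-truth label masks.

    CT blocks get Gaussian HU jitter around their stated mean; PET blocks
    are constant (plus optional jitter).  Raises LayoutError on overlapping
    or out-of-bounds regions.
    """
    if layout is None:
        layout = default_phantom_layout()
    rng = np.random.default_rng(seed)
    shape = layout.shape
    ct = np.full(shape, layout.background_hu, dtype=float)
    pet = np.full(shape, layout.background_pet, dtype=float)
    occupancy = np.zeros(shape, dtype=bool)
    labels: dict[str, VOIMask] = {}
    sp = (spacing, spacing, spacing)
    for region in layout.regions:
        sl = tuple(
            slice(s, s + d) for s, d in zip(region.start, region.shape)
        )
        if any(
            s < 0 or s + d > n for s, d, n in zip(region.start, region.shape, shape)
        ):
            raise LayoutError(f"region {region.name!r} extends outside the volume")
        if occupancy[sl].any():
            raise LayoutError(f"region {region.name!r} overlaps another region")
        occupancy[sl] = True
        block = tuple(region.shape)
        ct[sl] = region.hu_mean + region.hu_sd * rng.standard_normal(block)
        pet_block = np.full(block, region.pet_kbq_ml)
        if region.pet_sd > 0:
            pet_block = np.clip(
                pet_block + region.pet_sd * rng.standard_normal(block), 0.0, None
            )
        pet[sl] = pet_block
        m = np.zeros(shape, dtype=bool)
        m[sl] = True
        labels[region.name] = VOIMask(m, spacing=sp)
    return (
        ImageVolume(ct, spacing=sp, flavor="ct"),
        ImageVolume(pet, spacing=sp, flavor="pet"),
        labels,
    )


# ---------------------------------------------------------------------------
# qPCR tables


@dataclass(frozen=True)
class QPCRDesign:
    """Group sizes and gene panel for a simulated qPCR experiment.

    Defaults mirror a brown-fat expression contrast: groups sized like a
    high- vs low-BAT-volume split, and a panel of BCAA-catabolism and
    thermogenesis genes quantified against the RPLP0 housekeeping gene.
    """

    groups: dict[str, int] = field(
        default_factory=lambda: {"LBAT": 7, "HBAT": 16}
    )
    genes: tuple[str, ...] = ("UCP1", "SLC25A44", "BCKDHB", "BCAT1", "BCAT2")
    mu_ref: float = 18.0
    sd_ref: float = 0.5
    gene_offset: float = 5.0
    noise_sd: float = 0.8


def simulate_qpcr(
    design: QPCRDesign | None = None,
    effects: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a Ct table: subject_id, group, gene, ct_target, ct_ref.

    Reference Ct ~ Normal(mu_ref, sd_ref) per subject; target Ct =
    mu_ref + gene_offset - log2(fold_change)*[group affected] + noise, so a
    fold-change of 4 lowers delta-Ct by exactly 2 in the noiseless limit.
    ``effects[gene][group]`` is the fold-change of that gene in that group
    (default 1 everywhere).
    """
    if design is None:
        design = QPCRDesign()
    effects = effects or {}
    for gene_fx in effects.values():
        if any(fc <= 0 for fc in gene_fx.values()):
            raise ValueError("fold-changes must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for group, n in design.groups.items():
        for _ in range(n):
            sid += 1
            ct_ref = rng.normal(design.mu_ref, design.sd_ref)
            for gene in design.genes:
                fc = effects.get(gene, {}).get(group, 1.0)
                ct_t = (
                    design.mu_ref
                    + design.gene_offset
                    - np.log2(fc)
                    + rng.normal(0.0, design.noise_sd)
                )
                rows.append(
                    {
                        "subject_id": f"Q{sid:03d}",
                        "group": group,
                        "gene": gene,
                        "ct_target": float(ct_t),
                        "ct_ref": float(ct_ref),
                    }
                )
    return pd.DataFrame(rows)
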