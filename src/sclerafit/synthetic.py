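"""Seeded generators for every input the pipeline consumes.

Defaults encode the study structure the analysis assumes: a two-arm
cohort (14 control / 16 treated animals, three timepoints) whose
group-level effects are the generator parameters; compression traces
produced by the forward poroelastic model under the tare + three-step
protocol; linear-response assay plates; and two-channel masked images
with condition-dependent intensity ratios.  Every generator is
deterministic given its seed and ships its ground truth.

Default effect sizes (control drift and treated offsets per timepoint)
and group mean material parameters are the study's reported group
statistics, so that the generator -> pipeline round trip reproduces
them by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .poroelastic import (
    CLEParameters,
    LoadingProgram,
    RelaxationTrace,
    SampleGeometry,
    StrainStep,
    load_history,
)
from .assays import IHCImageSet, StandardCurve, TissueSample, fit_standard_curve

__all__ = [
    "OutcomeConfig",
    "CohortConfig",
    "TraceConfig",
    "gen_cohort",
    "gen_relaxation_dataset",
    "gen_assay_plate",
    "gen_ihc_images",
    "DEFAULT_OUTCOMES",
]

TIMEPOINTS = ("t0", "t1wk", "t2wk")


# --------------------------------------------------------------------------
# cohort generator


@dataclass(frozen=True)
class OutcomeConfig:
    """Generator parameters for one biometry/refraction outcome.

    ``ctrl_drift`` is the mean within-animal change of the control group
    from baseline per timepoint; ``treated_offset`` is the additional
    treated-group mean shift at each timepoint (the between-group
    effect).  Noise decomposes into a per-animal intercept, a per
    animal-by-timepoint deviation, and per-eye noise.
    """

    baseline_mean: float
    sd_animal: float
    sd_time: float
    sd_eye: float
    ctrl_drift: dict = field(default_factory=dict)
    treated_offset: dict = field(default_factory=dict)
    positive: bool = True

    def __post_init__(self) -> None:
        for name in ("sd_animal", "sd_time", "sd_eye"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _default_outcomes() -> dict[str, OutcomeConfig]:
    # Noise SDs are chosen so the generated 2-week between-group shift SD
    # (and, for AL, the within-animal delta SD) approximate the reported
    # spreads; effect means are the reported group effects.
    return {
        "RE": OutcomeConfig(
            baseline_mean=3.0,
            sd_animal=1.9,
            sd_time=0.8,
            sd_eye=0.5,
            ctrl_drift={"t1wk": 0.3, "t2wk": 0.6},
            treated_offset={"t1wk": -3.7, "t2wk": -5.7},
            positive=False,
        ),
        "VCD": OutcomeConfig(
            baseline_mean=600.0,
            sd_animal=20.0,
            sd_time=12.0,
            sd_eye=8.0,
            ctrl_drift={"t1wk": -25.2, "t2wk": -45.1},
            treated_offset={"t1wk": 20.7, "t2wk": 32.3},
        ),
        "AL": OutcomeConfig(
            baseline_mean=3300.0,
            sd_animal=30.0,
            sd_time=11.7,
            sd_eye=10.0,
            ctrl_drift={"t1wk": 82.6, "t2wk": 132.1},
            treated_offset={"t1wk": 8.3, "t2wk": 12.9},
        ),
        "ACD": OutcomeConfig(
            baseline_mean=400.0,
            sd_animal=10.0,
            sd_time=6.0,
            sd_eye=4.0,
            ctrl_drift={"t1wk": 19.9, "t2wk": 35.7},
            treated_offset={"t1wk": -7.0, "t2wk": -7.7},
        ),
        "CCT": OutcomeConfig(
            baseline_mean=100.0,
            sd_animal=4.0,
            sd_time=2.0,
            sd_eye=2.0,
            ctrl_drift={"t1wk": 1.0, "t2wk": 2.0},
            treated_offset={"t1wk": 0.0, "t2wk": 0.0},
        ),
        "LT": OutcomeConfig(
            baseline_mean=2000.0,
            sd_animal=20.0,
            sd_time=8.0,
            sd_eye=6.0,
            ctrl_drift={"t1wk": 60.0, "t2wk": 110.0},
            treated_offset={"t1wk": 0.0, "t2wk": 0.0},
        ),
        "RT": OutcomeConfig(
            baseline_mean=200.0,
            sd_animal=6.0,
            sd_time=3.0,
            sd_eye=2.0,
            ctrl_drift={"t1wk": -2.0, "t2wk": -4.0},
            treated_offset={"t1wk": 0.0, "t2wk": 0.0},
        ),
    }


DEFAULT_OUTCOMES = _default_outcomes


@dataclass(frozen=True)
class CohortConfig:
    """Two-arm longitudinal cohort layout (Ctrl 14, treated 16 animals)."""

    n_ctrl: int = 14
    n_treated: int = 16
    timepoints: tuple[str, ...] = TIMEPOINTS
    outcomes: dict = field(default_factory=_default_outcomes)
    baseline_age_days: float = 28.0
    age_jitter_days: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_ctrl < 1 or self.n_treated < 1:
            raise ValueError("group sizes must be >= 1")


def gen_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Long-format biometry/refraction table for one synthetic cohort.

    Columns: animal_id, eye, treatment, timepoint, age_days, outcome,
    value, excluded, reason.  Ground truth (per-animal latent means) is
    attached as ``result.attrs["truth"]``.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is mandatory (no unseeded generation)")
    rng = np.random.default_rng(seed)

    animals = [("Ctrl", f"C{i:02d}") for i in range(config.n_ctrl)] + [
        ("RA", f"R{i:02d}") for i in range(config.n_treated)
    ]
    week_of = {tp: i for i, tp in enumerate(config.timepoints)}
    rows = []
    truth_rows = []
    for treatment, animal in animals:
        age_jit = rng.normal(0.0, config.age_jitter_days)
        intercepts = {
            name: rng.normal(0.0, oc.sd_animal) for name, oc in config.outcomes.items()
        }
        for tp in config.timepoints:
            age = config.baseline_age_days + 7.0 * week_of[tp] + age_jit
            for name, oc in config.outcomes.items():
                mean = oc.baseline_mean + oc.ctrl_drift.get(tp, 0.0)
                if treatment == "RA":
                    mean += oc.treated_offset.get(tp, 0.0)
                latent = mean + intercepts[name] + rng.normal(0.0, oc.sd_time)
                truth_rows.append(
                    {
                        "animal_id": animal,
                        "treatment": treatment,
                        "timepoint": tp,
                        "outcome": name,
                        "latent_mean": latent,
                        "group_mean": mean,
                    }
                )
                for eye in ("OD", "OS"):
                    value = latent + rng.normal(0.0, oc.sd_eye)
                    if oc.positive:
                        # keep strictly positive outcomes in-range (3 SD floor)
                        floor = mean - 3.0 * (oc.sd_animal + oc.sd_time + oc.sd_eye)
                        value = max(value, max(floor, 1e-6))
                    rows.append(
                        {
                            "animal_id": animal,
                            "eye": eye,
                            "treatment": treatment,
                            "timepoint": tp,
                            "age_days": age,
                            "outcome": name,
                            "value": value,
                            "excluded": False,
                            "reason": "",
                        }
                    )
    table = pd.DataFrame(rows)
    table.attrs["truth"] = pd.DataFrame(truth_rows)
    table.attrs["seed"] = seed
    return table


# --------------------------------------------------------------------------
# relaxation-trace generator


def _default_group_truths() -> dict[str, CLEParameters]:
    # group mean moduli/conductivities reported for the two arms
    return {
        "Ctrl": CLEParameters(H_plus_A=160e3, H_minus_A=30e3, k=0.73e-14),
        "RA": CLEParameters(H_plus_A=104e3, H_minus_A=30e3, k=0.96e-14),
    }


@dataclass(frozen=True)
class TraceConfig:
    """Generator parameters for synthetic compression tests.

    ``group_truths`` are per-group mean material parameters; optional
    ``strain_trend`` scales (H+A, k) per step index to emulate
    strain-dependent properties.  ``truth_cv`` is the lognormal
    coefficient of variation of per-sample truths around the group mean
    (0 for exact means).  Load noise is multiplicative with an additive
    sensor floor.
    """

    geometry: SampleGeometry = field(default_factory=SampleGeometry)
    program: LoadingProgram = field(default_factory=LoadingProgram)
    group_truths: dict = field(default_factory=_default_group_truths)
    strain_trend: dict = field(default_factory=dict)  # step -> (fH, fk)
    truth_cv: float = 0.0
    load_noise_sd: float = 0.0  # multiplicative, relative
    sensor_floor_N: float = 0.0  # additive gaussian SD
    sampling_rate: float = 2.0
    tare_approach_s: float = 30.0
    tare_hold_s: float = 60.0
    tare_strain: float = 0.05  # fraction of nominal thickness taken up by tare
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.truth_cv < 0 or self.load_noise_sd < 0 or self.sensor_floor_N < 0:
            raise ValueError("noise parameters must be >= 0")


def _with_tare(
    trace: RelaxationTrace, config: TraceConfig, nominal_thickness: float
) -> RelaxationTrace:
    """Prepend a tare approach + hold to a post-tare model trace."""
    fs = config.sampling_rate
    d_tare = config.tare_strain * nominal_thickness
    tare_load = config.program.tare_load
    n_app = max(int(round(config.tare_approach_s * fs)), 2)
    n_hold = max(int(round(config.tare_hold_s * fs)), 2)
    t_app = np.arange(n_app) / fs
    t_hold = config.tare_approach_s + np.arange(n_hold) / fs
    d_app = d_tare * (t_app / config.tare_approach_s)
    l_app = tare_load * (t_app / config.tare_approach_s)
    t0 = config.tare_approach_s + config.tare_hold_s
    time = np.concatenate([t_app, t_hold, trace.time + t0 + 1.0 / fs])
    disp = np.concatenate(
        [d_app, np.full(n_hold, d_tare), trace.displacement + d_tare]
    )
    load = np.concatenate(
        [l_app, np.full(n_hold, tare_load), trace.load + tare_load]
    )
    return RelaxationTrace(
        time=time,
        displacement=disp,
        load=load,
        sample_id=trace.sample_id,
        nominal_thickness=nominal_thickness,
        radius=trace.radius,
    )


def gen_relaxation_dataset(
    config: TraceConfig,
    n_per_group: dict | None = None,
    seed: int | None = None,
    include_tare: bool = True,
) -> tuple[list[RelaxationTrace], pd.DataFrame]:
    """Synthetic traces plus their ground-truth table.

    Traces come from the forward model (per step, superposed), with a
    kinematic tare phase prepended so the full tare -> segmentation ->
    fit pipeline is exercised.  Default arm sizes are the study's
    compression-test arms (Ctrl 8, treated 10).
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is mandatory (no unseeded generation)")
    rng = np.random.default_rng(seed)
    if n_per_group is None:
        n_per_group = {"Ctrl": 8, "RA": 10}

    geom = config.geometry
    nominal = geom.thickness / (1.0 - config.tare_strain)
    traces: list[RelaxationTrace] = []
    truth_rows = []
    for group, n in n_per_group.items():
        base = config.group_truths[group]
        for i in range(n):
            sid = f"{group}-{i:02d}"
            if config.truth_cv > 0:
                sigma = math.sqrt(math.log(1.0 + config.truth_cv**2))
                fh = rng.lognormal(-0.5 * sigma**2, sigma)
                fk = rng.lognormal(-0.5 * sigma**2, sigma)
            else:
                fh = fk = 1.0
            sample_load = None
            t_ref = None
            step_params = []
            for j, step in enumerate(config.program.steps, start=1):
                th, tk = config.strain_trend.get(j, (1.0, 1.0))
                p = CLEParameters(
                    H_plus_A=base.H_plus_A * fh * th,
                    H_minus_A=base.H_minus_A,
                    k=base.k * fk * tk,
                )
                step_params.append(p)
                truth_rows.append(
                    {
                        "sample_id": sid,
                        "treatment": group,
                        "step": j,
                        "target_strain": step.target_strain,
                        "H_plus_A_Pa": p.H_plus_A,
                        "k_m4_per_Ns": p.k,
                        "H_minus_A_Pa": p.H_minus_A,
                    }
                )
            # per-step parameters: superpose each step's incremental
            # response with its own material truth
            prev_strain = 0.0
            t_total = config.program.duration
            n_samp = int(round(t_total * config.sampling_rate)) + 1
            t_ref = np.arange(n_samp) / config.sampling_rate
            sample_load = np.zeros(n_samp)
            t_off = 0.0
            for j, (step, p) in enumerate(zip(config.program.steps, step_params)):
                inc = step.target_strain - prev_strain
                single = LoadingProgram(
                    tare_load=0.0,
                    steps=(StrainStep(inc, step.ramp_duration, 1e9),),
                )
                sample_load += load_history(p, geom, single, t_ref - t_off)
                t_off += step.ramp_duration + step.hold_duration
                prev_strain = step.target_strain
            disp = config.program.strain_at(t_ref) * geom.thickness
            trace = RelaxationTrace(
                time=t_ref,
                displacement=disp,
                load=sample_load,
                sample_id=sid,
                nominal_thickness=geom.thickness,
                radius=geom.radius,
            )
            if include_tare:
                trace = _with_tare(trace, config, nominal)
            load = trace.load.copy()
            if config.load_noise_sd > 0:
                load *= 1.0 + config.load_noise_sd * rng.standard_normal(len(load))
            if config.sensor_floor_N > 0:
                load += config.sensor_floor_N * rng.standard_normal(len(load))
            trace.load = load
            traces.append(trace)
    truth = pd.DataFrame(truth_rows)
    truth.attrs["seed"] = seed
    return traces, truth


# --------------------------------------------------------------------------
# assay-plate generator


def gen_assay_plate(
    truth_mass_fractions: dict[str, float],
    dry_mass_mg: float,
    analyte: str = "DNA",
    *,
    slope: float = 0.5,
    blank: float = 0.05,
    noise_sd: float = 0.0,
    digest_volume_uL: float = 200.0,
    n_standards: int = 8,
    seed: int = 0,
) -> tuple[StandardCurve, list[TissueSample], pd.DataFrame]:
    """Standards + triplicate sample absorbances from a linear response.

    ``truth_mass_fractions`` maps sample id -> true ug analyte per mg
    dry mass; the implied digest concentration must fall inside the
    assay working range.
    """
    from .assays import WORKING_RANGES

    rng = np.random.default_rng(seed)
    lo, hi = WORKING_RANGES[analyte]
    std_conc = np.linspace(lo, hi, n_standards)
    std_abs = blank + slope * std_conc
    if noise_sd > 0:
        std_abs = std_abs + noise_sd * rng.standard_normal(n_standards)
    curve = fit_standard_curve(std_conc, std_abs, analyte=analyte)

    samples = []
    truth_rows = []
    for sid, mass_fraction in truth_mass_fractions.items():
        conc = mass_fraction * dry_mass_mg / digest_volume_uL
        if not lo <= conc <= hi:
            raise ValueError(
                f"truth {mass_fraction} ug/mg implies digest concentration "
                f"{conc:.3g} outside working range [{lo}, {hi}]"
            )
        a = blank + slope * conc
        trip = np.full(3, a)
        if noise_sd > 0:
            trip = trip + noise_sd * rng.standard_normal(3)
        samples.append(
            TissueSample(
                sample_id=sid,
                dry_mass_mg=dry_mass_mg,
                digest_volume_uL=digest_volume_uL,
                absorbances={analyte: trip},
            )
        )
        truth_rows.append(
            {"sample_id": sid, "analyte": analyte, "mass_fraction_ug_per_mg": mass_fraction}
        )
    return curve, samples, pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# IHC image generator


def gen_ihc_images(
    ratios: dict[str, float],
    *,
    shape: tuple[int, int] = (128, 128),
    buffer_mean: float = 400.0,
    band: tuple[int, int] = (44, 84),
    optic_nerve_row: int = 64,
    noise_scale: float = 0.0,
    regional_ratios: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
) -> IHCImageSet:
    """Two-channel 12-bit image set with a scleral band of known ratios.

    ``ratios`` maps "DS"/"C4S" to the target normalized fluorescence
    (ChB/buffer and ChAC/buffer respectively).  ``regional_ratios``
    optionally overrides per region ("superior"/"inferior").  Noise is
    Poisson-like (gaussian with variance proportional to intensity).
    """
    for name, r in ratios.items():
        if r <= 0:
            raise ValueError(f"ratio {name} must be positive, got {r}")
    r0, r1 = band
    if r0 < 0 or r1 > shape[0]:
        raise ValueError("mask band outside image")
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, :] = True
    cond_ratio = {"buffer": 1.0, "ChB": ratios["DS"], "ChAC": ratios["C4S"]}

    images = {}
    for cond, ratio in cond_ratio.items():
        img = np.full(shape, 0.05 * buffer_mean)
        target = np.full(shape, buffer_mean * ratio)
        if regional_ratios and cond != "buffer":
            key = "DS" if cond == "ChB" else "C4S"
            sup = regional_ratios.get("superior", {}).get(key, ratio)
            inf = regional_ratios.get("inferior", {}).get(key, ratio)
            target[:optic_nerve_row, :] = buffer_mean * sup
            target[optic_nerve_row:, :] = buffer_mean * inf
        img = np.where(mask, target, img)
        if noise_scale > 0:
            img = img + noise_scale * np.sqrt(np.clip(img, 0, None)) * (
                rng.standard_normal(shape)
            )
        images[cond] = np.clip(np.round(img), 0, 4095).astype(np.uint16)
    return IHCImageSet(images=images, mask=mask, optic_nerve_row=optic_nerve_row)
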